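"""Individualized coil placement by exhaustive NTA grid search.

Evaluates NTA over a position x orientation search space for one synthetic
subject and reports the optimum. The study plants the pathology so the true
best site is known: the scalp projection of the mirrored partner region.
"""

import numpy as np

from tmstarget import SearchSpace, grid_search, make_planted_cohort
from tmstarget.synthetic import StudySpec

study = make_planted_cohort(StudySpec(), seed=0)
subject = study.subjects[0]

space = SearchSpace.from_ranges(
    np.linspace(0.2, 0.8, 8), np.linspace(0.2, 0.8, 8), "0:-165:15"
)
print(f"searching {space.shape[0]} positions x {space.shape[1]} orientations...")

grid = grid_search(subject, space)
position, theta = grid.optimum
print(f"optimum: p_nz={position.p_nz:.3f}, p_al={position.p_al:.3f}, "
      f"theta={theta:.0f} deg, NTA={np.nanmax(grid.values):.3f}")

truth = study.truth["optimal_cpc"]
print(f"planted truth: p_nz={truth.p_nz:.3f}, p_al={truth.p_al:.3f}")
print(f"position error: ({abs(position.p_nz - truth.p_nz):.3f}, "
      f"{abs(position.p_al - truth.p_al):.3f}) CPC units "
      f"(grid step is {0.6 / 7:.3f})")
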