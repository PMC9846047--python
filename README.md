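# tmstarget

Network-based targeting of transcranial magnetic stimulation (TMS) coil
placement. The package implements a model in which the therapeutic value of
a coil placement is scored not by the anatomical site it stimulates, but by
how well the **whole-brain network** it engages opposes the **pathological
network** of the disease being treated — and uses that score to optimize
the placement per patient.

It is written for computational neuroimaging and neuromodulation
researchers: people who have a scalp surface, a voxel-wise functional
connectome, and a disease activity map, and want to ask *where (and at what
handle angle) should the coil go for this patient?*

## The model

A coil placement is a scalp position `s` in **continuous proportional
coordinates** (CPC) — a pair `(p_nz, p_al) ∈ [0,1]²` measuring proportional
arc distances along the nasion→inion and left→right preauricular surface
curves — plus a handle orientation `θ ∈ (−180°, 180°]` in the tangent
plane, with 0° pointing backward and clockwise (seen from outside) negative.

For a placement, the chain is:

1. **Local effect** `E_l`: the E-field magnitude induced in gray matter
   (from an external FEM volume, or the built-in analytic stand-in) is
   thresholded at a percentage of its robust peak. Suprathreshold voxels
   get signed weights: positive for high-frequency (> 5 Hz, excitatory)
   protocols, negative for low-frequency (≤ 1 Hz, inhibitory).
2. **Stimulation network** (the connectome-weighted profile of the
   stimulated region):

   `E_n = C · E_l / ‖E_l‖₁`

   where `C` is the voxel-wise signed resting-state functional-connectivity
   matrix, so `E_n` is the weight-normalized combination of connectivity
   maps seeded in the stimulated cortex.
3. **Pathological network** `P = I_pt − I_hc`: the patient-minus-control
   activity difference, built either from voxel-wise state maps or from a
   coordinate-based meta-analysis foci table (signed spheres).
4. **Network targeting accuracy**:

   `NTA(s, θ) = −corr(E_n(s, θ), P)`

   the spatial anti-correlation between the stimulation network and the
   pathological network, hypothesized to predict treatment outcome. The
   individualized optimum is the `(s, θ)` maximizing NTA over a search
   grid.

Cohort-level validation follows the same logic as the retrospective
studies this model family was tested on: Pearson correlation of NTA with
clinical improvement (one-tailed), an outcome-permutation null, a
network-relocation null (foci moved to random gray-matter sites), partial
correlations controlling sex/age, two-way position × orientation ANOVA,
and threshold/radius sensitivity sweeps.

Everything runs on synthetic data generated by the package itself — an
analytic head with fiducials, a gray-matter shell, a modular connectome
with anti-correlated networks, and cohorts with a known NTA–outcome
coupling — so the full pipeline is testable without any imaging downloads.

## Worked example

```bash
python examples/03_optimize_placement.py
```

prints (seed 0):

```
searching 64 positions x 12 orientations...
optimum: p_nz=0.714, p_al=0.457, theta=0 deg, NTA=0.130
planted truth: p_nz=0.748, p_al=0.500
position error: (0.034, 0.043) CPC units (grid step is 0.086)
```

The synthetic study plants a hyperactive pathology in the anterior network
whose mirrored partner region is anti-correlated with it; the grid search
recovers that partner's scalp projection to within half a grid step. The
other examples walk the CPC geometry (`01`), the placement→NTA chain
(`02`), the cohort validation statistics (`04`), and the robustness sweeps
(`05`).

A thin CLI wraps the same library for shell use:

```bash
tmstarget simulate --seed 0 --out study/         # write a synthetic study
tmstarget score    config.yaml --out results/    # NTA of listed placements
tmstarget optimize config.yaml --out results/    # per-subject grid search
tmstarget cohort   config.yaml --out results/    # validation statistics
```

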