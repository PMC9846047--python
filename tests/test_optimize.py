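import numpy as np
import pytest

from tmstarget import (
    BrainMap,
    CPCCoordinate,
    NTAGrid,
    SearchSpace,
    StimulationProtocol,
    Subject,
    SyntheticEfieldSource,
    VoxelGrid,
    connectome_from_timeseries,
    grid_anova,
    grid_search,
    nta,
    nta_for_placement,
    seed_map,
    threshold_sensitivity,
)
from tmstarget.errors import DataError, DegenerateAnovaError
from tmstarget.optimize import FixedEfieldSource
from tmstarget.synthetic import (
    ConnectomeSpec,
    GridSpec,
    HeadSpec,
    make_connectome,
    make_head,
    make_shell_grid,
)


def grid_n(n):
    return VoxelGrid((n, 1, 1), np.eye(4), np.ones((n, 1, 1), bool))


class TestNTA:
    def test_perfect_anticorrelation(self):
        g = grid_n(6)
        v = np.random.default_rng(0).standard_normal(6)
        assert nta(BrainMap(g, v), BrainMap(g, -v)) == pytest.approx(1.0)
        assert nta(BrainMap(g, v), BrainMap(g, v)) == pytest.approx(-1.0)

    def test_negated_pearson_oracle(self):
        rng = np.random.default_rng(1)
        g = grid_n(6)
        a, b = rng.standard_normal(6), rng.standard_normal(6)
        expected = -np.corrcoef(a, b)[0, 1]
        assert nta(BrainMap(g, a), BrainMap(g, b)) == pytest.approx(expected, abs=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(2)
        g = grid_n(10)
        for _ in range(20):
            v = nta(BrainMap(g, rng.standard_normal(10)), BrainMap(g, rng.standard_normal(10)))
            assert -1.0 <= v <= 1.0


@pytest.fixture(scope="module")
def small_subject():
    """Sphere head, coarse shell, seeded connectome, planted one-voxel pathology."""
    head_spec = HeadSpec(radius_mm=85.0)
    head = make_head(head_spec)
    grid = make_shell_grid(head_spec, GridSpec(voxel_size_mm=9.0, min_up_frac=0.05))
    conn, _ = make_connectome(
        grid, ConnectomeSpec(t_timepoints=120, mirror_coupling=0.4), seed=7
    )
    rng = np.random.default_rng(7)
    pathology = BrainMap(grid, rng.standard_normal(grid.n_voxels))
    return Subject(
        "sub-test", head, grid, conn, pathology,
        StimulationProtocol(10.0), SyntheticEfieldSource(),
    )


class TestNtaForPlacement:
    def test_hf_lf_are_exact_negatives(self, small_subject):
        placement = (CPCCoordinate(0.6, 0.45), -45.0)
        hf = nta_for_placement(small_subject, placement)
        lf_subject = Subject(
            "lf", small_subject.scalp, small_subject.grid, small_subject.connectome,
            small_subject.pathology, StimulationProtocol(1.0), small_subject.efield_source,
        )
        lf = nta_for_placement(lf_subject, placement)
        assert hf == pytest.approx(-lf, abs=1e-12)

    def test_singleton_support_equals_seed_column_nta(self, small_subject):
        # an E-field with a single dominant voxel thresholds to a singleton,
        # so the chain must reduce to the seed-map correlation
        g = small_subject.grid
        e = np.zeros(g.n_voxels)
        e[11] = 1.0
        sub = Subject(
            "single", small_subject.scalp, g, small_subject.connectome,
            small_subject.pathology, StimulationProtocol(10.0),
            FixedEfieldSource(BrainMap(g, e)), threshold_percent=50.0,
        )
        value = nta_for_placement(sub, (CPCCoordinate(0.5, 0.5), 0.0))
        expected = nta(seed_map(small_subject.connectome, 11), small_subject.pathology)
        assert value == pytest.approx(expected, abs=1e-12)

    def test_deterministic(self, small_subject):
        placement = (CPCCoordinate(0.55, 0.6), -30.0)
        assert nta_for_placement(small_subject, placement) == nta_for_placement(
            small_subject, placement
        )


class TestSearchSpace:
    def test_orientation_shorthand_twelve_steps(self):
        space = SearchSpace.from_ranges([0.5], [0.5], "0:-165:15")
        assert space.orientations == tuple(-15.0 * k for k in range(12))

    def test_mdd_style_space_size(self):
        space = SearchSpace.from_ranges(
            np.linspace(0.3, 0.7, 25), np.linspace(0.3, 0.7, 5), "0:-165:15"
        )
        assert space.shape == (125, 12)

    def test_duplicate_positions_rejected(self):
        c = CPCCoordinate(0.5, 0.5)
        with pytest.raises(DataError, match="duplicate"):
            SearchSpace((c, c), (0.0,))

    def test_orientation_domain(self):
        with pytest.raises(DataError):
            SearchSpace((CPCCoordinate(0.5, 0.5),), (-180.0,))


class TestNTAGrid:
    def test_argmax_lexicographic_tie_break(self):
        space = SearchSpace.from_ranges([0.4, 0.6], [0.4, 0.6], [0.0, -15.0])
        values = np.full(space.shape, 0.5)
        g = NTAGrid("s", space, values)
        assert g.argmax == (0, 0)
        values2 = values.copy()
        values2[2, 1] = 0.9
        assert NTAGrid("s", space, values2).argmax == (2, 1)

    def test_nan_cells_excluded_from_argmax(self):
        space = SearchSpace.from_ranges([0.4, 0.6], [0.5], [0.0])
        values = np.array([[np.nan], [0.2]])
        assert NTAGrid("s", space, values).argmax == (1, 0)

    def test_all_nan_grid_rejected(self):
        space = SearchSpace.from_ranges([0.5], [0.5], [0.0])
        with pytest.raises(DataError, match="failed"):
            NTAGrid("s", space, np.array([[np.nan]]))


class TestGridSearch:
    def test_single_placement_space(self, small_subject):
        space = SearchSpace((CPCCoordinate(0.55, 0.5),), (-45.0,))
        g = grid_search(small_subject, space)
        assert g.optimum == (CPCCoordinate(0.55, 0.5), -45.0)
        assert g.values[0, 0] == pytest.approx(
            nta_for_placement(small_subject, (CPCCoordinate(0.55, 0.5), -45.0))
        )

    def test_argmax_invariant_to_positive_rescaling_of_pathology(self, small_subject):
        space = SearchSpace.from_ranges([0.45, 0.6, 0.75], [0.4, 0.6], [0.0, -90.0])
        g1 = grid_search(small_subject, space)
        scaled = Subject(
            "scaled", small_subject.scalp, small_subject.grid, small_subject.connectome,
            BrainMap(small_subject.grid, 3.0 * small_subject.pathology.values + 1.0),
            small_subject.protocol, small_subject.efield_source,
        )
        g2 = grid_search(scaled, space)
        assert g1.argmax == g2.argmax
        assert np.allclose(g1.values, g2.values, atol=1e-10)


def _anova_oracle(y):
    """Brute-force balanced two-way sums-of-squares decomposition."""
    n, a, b = y.shape
    grand = y.mean()
    ss = {"position": 0.0, "orientation": 0.0, "interaction": 0.0, "error": 0.0}
    for i in range(a):
        ss["position"] += n * b * (y[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss["orientation"] += n * a * (y[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            cell = y[:, i, j].mean()
            ss["interaction"] += n * (
                cell - y[:, i, :].mean() - y[:, :, j].mean() + grand
            ) ** 2
            ss["error"] += ((y[:, i, j] - cell) ** 2).sum()
    df = {"position": a - 1, "orientation": b - 1,
          "interaction": (a - 1) * (b - 1), "error": a * b * (n - 1)}
    ms_err = ss["error"] / df["error"]
    return {k: (ss[k] / df[k]) / ms_err for k in ("position", "orientation", "interaction")}


def _grids_from_array(y):
    n, a, b = y.shape
    space = SearchSpace.from_ranges(
        np.linspace(0.3, 0.7, a), [0.5], [-15.0 * j for j in range(b)]
    )
    return [NTAGrid(f"s{i}", space, y[i]) for i in range(n)]


class TestGridAnova:
    def test_additive_design_matches_ss_oracle(self):
        rng = np.random.default_rng(3)
        n, a, b = 6, 5, 4
        pos_eff = rng.standard_normal(a)
        ori_eff = rng.standard_normal(b)
        y = pos_eff[None, :, None] + ori_eff[None, None, :] + 0.3 * rng.standard_normal((n, a, b))
        result = grid_anova(_grids_from_array(y))
        oracle = _anova_oracle(y)
        for name in ("position", "orientation", "interaction"):
            assert result[f"F_{name}"] == pytest.approx(oracle[name], abs=1e-8)
        assert result["df_position"] == a - 1
        assert result["df_error"] == a * b * (n - 1)

    def test_statsmodels_cross_check(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(4)
        y = rng.standard_normal((4, 3, 3))
        result = grid_anova(_grids_from_array(y))
        rows = [
            {"y": y[s, i, j], "pos": i, "ori": j}
            for s in range(4) for i in range(3) for j in range(3)
        ]
        fit = ols("y ~ C(pos) * C(ori)", pd.DataFrame(rows)).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert result["F_position"] == pytest.approx(table.loc["C(pos)", "F"], rel=1e-8)
        assert result["F_orientation"] == pytest.approx(table.loc["C(ori)", "F"], rel=1e-8)
        assert result["F_interaction"] == pytest.approx(
            table.loc["C(pos):C(ori)", "F"], rel=1e-8
        )

    def test_constant_identical_grids_degenerate(self):
        y = np.zeros((3, 2, 2))
        with pytest.raises(DegenerateAnovaError):
            grid_anova(_grids_from_array(y))

    def test_incomplete_grids_rejected(self):
        y = np.random.default_rng(5).standard_normal((3, 2, 2))
        grids = _grids_from_array(y)
        bad = np.array(y[0])
        bad[0, 0] = np.nan
        grids[0] = NTAGrid("s0", grids[0].space, bad)
        with pytest.raises(DataError, match="complete"):
            grid_anova(grids)

    def test_single_subject_rejected(self):
        y = np.random.default_rng(6).standard_normal((1, 2, 2))
        with pytest.raises(DataError):
            grid_anova(_grids_from_array(y))


class TestThresholdSensitivity:
    def test_two_percent_sweep_shape(self, small_subject):
        placements = [
            (CPCCoordinate(0.5, 0.4), 0.0),
            (CPCCoordinate(0.6, 0.55), -45.0),
            (CPCCoordinate(0.7, 0.6), -90.0),
        ]
        table, pairs = threshold_sensitivity(small_subject, placements, [75.0, 99.0])
        assert len(table) == 6
        assert len(pairs) == 1
        assert set(table["percent"]) == {75.0, 99.0}

    def test_duplicate_percents_give_identical_columns(self, small_subject):
        placements = [(CPCCoordinate(0.5, 0.5), 0.0), (CPCCoordinate(0.65, 0.5), -30.0)]
        table, _ = threshold_sensitivity(small_subject, placements, [80.0, 80.0])
        by_placement = table.groupby("placement")["nta"].nunique()
        assert (by_placement == 1).all()

    def test_single_percent_rejected(self, small_subject):
        with pytest.raises(DataError):
            threshold_sensitivity(small_subject, [(CPCCoordinate(0.5, 0.5), 0.0)], [75.0])
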