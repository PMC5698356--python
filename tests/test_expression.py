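"""Expression statistics: loaders, fold-change filter, normalization,
the GO-grouped global ANOVA, per-GO tests, and deviation profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sporeclock.expression import (
    GENOTYPES,
    TIMEPOINTS,
    ExpressionMatrix,
    ExpressionValidationError,
    GOMap,
    _twoway_anova,
    deviation_profile,
    directional_tests,
    fold_change_loci,
    global_fit,
    load_expression,
    load_go_map,
    normalize_expression,
    temporal_tests,
)


def matrix_from_cells(cells: np.ndarray, loci=None, n_reps=2) -> ExpressionMatrix:
    """Build a matrix whose replicate FPKM equal the given (n, 6) cell values."""
    n = cells.shape[0]
    loci = loci or [f"L{i:03d}" for i in range(n)]
    cols = [
        (g, t, r)
        for g in GENOTYPES
        for t in TIMEPOINTS
        for r in range(1, n_reps + 1)
    ]
    data = np.repeat(cells, n_reps, axis=1)
    df = pd.DataFrame(
        data, index=pd.Index(loci, name="locus_id"),
        columns=pd.MultiIndex.from_tuples(cols),
    )
    return ExpressionMatrix(df)


class TestLoaders:
    def test_expression_round_trip_is_bit_identical(self, tmp_path):
        m = matrix_from_cells(np.array([[1.5, 2.0, 0.0, 3.25, 4.5, 10.0],
                                        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]]))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        m.to_tsv(p1)
        load_expression(p1).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_negative_fpkm_names_the_locus(self, tmp_path):
        path = tmp_path / "neg.tsv"
        cols = "\t".join(
            f"{g}_{t}h_r{r}" for g in GENOTYPES for t in TIMEPOINTS for r in (1, 2)
        )
        path.write_text(
            f"locus_id\t{cols}\nLBAD\t1\t1\t1\t1\t1\t1\t1\t1\t1\t1\t-2\t1\n"
        )
        with pytest.raises(ExpressionValidationError, match="LBAD"):
            load_expression(path)

    def test_duplicate_locus_rows_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        cols = "\t".join(
            f"{g}_{t}h_r{r}" for g in GENOTYPES for t in TIMEPOINTS for r in (1,)
        )
        row = "\t".join(["1"] * 6)
        path.write_text(f"locus_id\t{cols}\nLA\t{row}\nLA\t{row}\n")
        with pytest.raises(ExpressionValidationError, match="duplicate"):
            load_expression(path)

    def test_malformed_sample_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("locus_id\tancestor_18_r1\nLA\t1\n")
        with pytest.raises(ExpressionValidationError, match="malformed|crossing"):
            load_expression(path)

    def test_go_map_round_trip(self, tmp_path):
        gm = GOMap({"LA": frozenset({"GO:1", "GO:2"}), "LB": frozenset({"GO:1"})})
        path = tmp_path / "go.tsv"
        gm.to_tsv(path)
        back = load_go_map(path)
        assert back.memberships == gm.memberships
        assert back.terms == ["GO:1", "GO:2"]

    def test_synthetic_output_loads_with_loci_preserved(self, tmp_path, planted_matrix):
        m, _ = planted_matrix
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        assert load_expression(p).n_loci == m.n_loci


class TestFoldChange:
    def test_identical_genotypes_give_empty_set(self):
        cells = np.tile([5.0, 6.0, 7.0, 5.0, 6.0, 7.0], (4, 1))
        assert fold_change_loci(matrix_from_cells(cells)) == set()

    def test_hand_computed_boundary_case(self):
        # ancestor 10, derived 25 at 18 h only: |log2(25.1/10.1)| ~ 1.31 > 1
        cells = np.array([[10.0, 6.0, 7.0, 25.0, 6.0, 7.0]])
        assert fold_change_loci(matrix_from_cells(cells), pseudocount=0.1) == {"L000"}
        # 2-fold exactly is not "> 1" after pseudocount
        cells2 = np.array([[10.0, 6.0, 7.0, 20.0, 6.0, 7.0]])
        assert fold_change_loci(matrix_from_cells(cells2), pseudocount=0.1) == set()

    def test_planted_fourfold_loci_recovered_at_zero_noise(self, small_universe):
        from sporeclock.synthetic import PlantedTruth, simulate_expression

        truth = PlantedTruth(
            fold_change_multipliers={"locus_00005": 4.0, "locus_00017": 0.2},
            noise_sd=0.0,
            seed=3,
        )
        m = simulate_expression(small_universe, truth, n_background_loci=10)
        assert fold_change_loci(m) == {"locus_00005", "locus_00017"}


class TestNormalization:
    def test_equal_cells_give_uniform_shares(self):
        m = matrix_from_cells(np.full((3, 6), 7.7))
        norm = normalize_expression(m)
        assert np.allclose(norm.shares.to_numpy(), 1 / 6)

    def test_all_zero_locus_flagged_with_zero_shares(self):
        cells = np.array([[0.0] * 6, [1.0, 2, 3, 4, 5, 6]])
        norm = normalize_expression(matrix_from_cells(cells))
        assert norm.zero_loci == {"L000"}
        assert np.allclose(norm.shares.loc["L000"].to_numpy(), 0.0)

    @given(
        arrays(
            np.float64,
            (5, 6),
            elements=st.floats(0.0, 1e5, allow_nan=False),
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_shares_sum_to_one_or_zero(self, cells):
        norm = normalize_expression(matrix_from_cells(cells))
        sums = norm.shares.sum(axis=1).to_numpy()
        assert np.all(
            (np.abs(sums - 1.0) < 1e-12) | (np.abs(sums) < 1e-12)
        )

    def test_transform_order_is_log_then_share(self):
        # uniform FPKM rescaling changes shares because log(x+1) is applied first
        cells = np.array([[1.0, 2, 3, 4, 5, 6]])
        a = normalize_expression(matrix_from_cells(cells)).shares.to_numpy()
        b = normalize_expression(matrix_from_cells(cells * 10)).shares.to_numpy()
        assert not np.allclose(a, b)
        expected = np.log1p(cells) / np.log1p(cells).sum()
        assert np.allclose(a, expected)


class TestGlobalFit:
    @pytest.mark.parametrize("g", [2, 5, 28])
    def test_design_degrees_of_freedom(self, g):
        rng = np.random.default_rng(g)
        loci = []
        memberships = {}
        n_per = 3
        for i in range(g):
            for j in range(n_per):
                lid = f"L{i}_{j}"
                loci.append(lid)
                memberships[lid] = frozenset({f"GO:{i}"})
        cells = rng.uniform(1, 100, size=(len(loci), 6))
        norm = normalize_expression(matrix_from_cells(cells, loci=loci))
        fit = global_fit(norm, GOMap(memberships))
        assert fit.df_model == 4 * g - 1
        assert fit.df_resid == 2 * g
        assert fit.adj_r_squared <= 1.0

    def test_equal_cell_means_give_zero_f(self):
        loci = ["A1", "A2", "B1", "B2"]
        memberships = {
            "A1": frozenset({"GO:a"}), "A2": frozenset({"GO:a"}),
            "B1": frozenset({"GO:b"}), "B2": frozenset({"GO:b"}),
        }
        cells = np.full((4, 6), 3.0)
        norm = normalize_expression(matrix_from_cells(cells, loci=loci))
        fit = global_fit(norm, GOMap(memberships))
        assert fit.f_statistic == pytest.approx(0.0, abs=1e-20) or np.isnan(
            fit.f_statistic
        )
        assert fit.adj_r_squared <= 0.0 or np.isnan(fit.adj_r_squared)

    def test_planted_structure_yields_high_adjusted_r2(self, small_universe):
        from sporeclock.synthetic import PlantedTruth, simulate_expression

        effects = {f"GO:{i:04d}": (0.02 if i % 2 else -0.02) for i in range(10)}
        truth = PlantedTruth(directional_effects=effects, noise_sd=0.002, seed=5)
        m = simulate_expression(small_universe, truth, n_background_loci=0)
        fit = global_fit(normalize_expression(m), small_universe)
        assert fit.adj_r_squared > 0.8

    def test_empty_term_dropped(self, small_universe):
        from sporeclock.synthetic import PlantedTruth, simulate_expression

        truth = PlantedTruth(noise_sd=0.003, seed=6)
        m = simulate_expression(small_universe, truth, n_background_loci=0)
        gm = GOMap({**small_universe.memberships, "ghost": frozenset({"GO:none"})})
        norm = normalize_expression(m)  # 'ghost' locus absent from matrix
        fit = global_fit(norm, gm)
        assert fit.n_terms == 10


class TestGroupAnova:
    def test_closed_form_matches_statsmodels(self):
        """Dual-route check of the balanced two-way ANOVA sums of squares."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(12)
        n = 8
        y = rng.uniform(0.1, 0.3, size=(n, 2, 3))
        p_g, p_i, effect, slope = _twoway_anova(y)
        rows = [
            {"y": y[l, g, t], "g": g, "t": TIMEPOINTS[t]}
            for l in range(n)
            for g in range(2)
            for t in range(3)
        ]
        fit = smf.ols("y ~ C(g) * C(t)", data=pd.DataFrame(rows)).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert p_g == pytest.approx(table.loc["C(g)", "PR(>F)"], rel=1e-8)
        assert p_i == pytest.approx(table.loc["C(g):C(t)", "PR(>F)"], rel=1e-8)

    def test_planted_directional_terms_flagged_with_sign(self, planted_matrix, small_universe):
        m, truth = planted_matrix
        stats = directional_tests(normalize_expression(m), small_universe)
        by_term = {s.term: s for s in stats}
        assert by_term["GO:0000"].directional and by_term["GO:0000"].direction == 1
        assert by_term["GO:0001"].directional and by_term["GO:0001"].direction == -1
        assert by_term["GO:0005"].directional is False

    def test_identical_genotype_shares_not_flagged(self):
        rng = np.random.default_rng(2)
        half = rng.uniform(1, 50, size=(6, 3))
        cells = np.hstack([half, half])  # ancestor == derived
        loci = [f"L{i}" for i in range(6)]
        gm = GOMap(
            {l: frozenset({"GO:x"}) for l in loci[:3]}
            | {l: frozenset({"GO:y"}) for l in loci[3:]}
        )
        stats = directional_tests(normalize_expression(matrix_from_cells(cells, loci=loci)), gm)
        assert not any(s.directional for s in stats)

    def test_temporal_slope_signs_track_planted_divergence(self, planted_matrix, small_universe):
        m, truth = planted_matrix
        stats = temporal_tests(normalize_expression(m), small_universe)
        by_term = {s.term: s for s in stats}
        assert by_term["GO:0002"].temporal and by_term["GO:0002"].slope_sign == 1
        assert by_term["GO:0003"].temporal and by_term["GO:0003"].slope_sign == -1

    def test_constant_genotype_offset_not_temporal(self, planted_matrix, small_universe):
        m, truth = planted_matrix
        stats = temporal_tests(normalize_expression(m), small_universe)
        by_term = {s.term: s for s in stats}
        assert by_term["GO:0000"].temporal is False

    def test_tiny_terms_reported_untested(self):
        cells = np.random.default_rng(4).uniform(1, 20, size=(3, 6))
        loci = ["L0", "L1", "L2"]
        gm = GOMap({
            "L0": frozenset({"GO:solo"}),
            "L1": frozenset({"GO:pair"}),
            "L2": frozenset({"GO:pair"}),
        })
        stats = directional_tests(normalize_expression(matrix_from_cells(cells, loci=loci)), gm)
        solo = next(s for s in stats if s.term == "GO:solo")
        assert solo.tested is False and solo.directional is False


class TestDeviationProfile:
    def test_equal_shares_give_zero_deviations(self):
        loci = ["L0", "L1"]
        gm = GOMap({l: frozenset({"GO:x"}) for l in loci})
        norm = normalize_expression(matrix_from_cells(np.full((2, 6), 4.0), loci=loci))
        prof = deviation_profile(norm, gm)
        assert np.allclose(prof["deviation"], 0.0)

    def test_per_term_deviations_center_to_zero(self, planted_matrix, small_universe):
        m, _ = planted_matrix
        prof = deviation_profile(normalize_expression(m), small_universe)
        sums = prof.groupby("term")["deviation"].sum()
        assert (sums.abs() < 1e-12).all()

    def test_planted_late_divergence_shape(self, small_universe):
        from sporeclock.synthetic import PlantedTruth, simulate_expression

        truth = PlantedTruth(temporal_slopes={"GO:0002": 0.005}, noise_sd=0.0, seed=8)
        m = simulate_expression(small_universe, truth, n_background_loci=0)
        prof = deviation_profile(normalize_expression(m), small_universe)
        derived = prof[(prof.term == "GO:0002") & (prof.genotype == "derived")]
        series = derived.sort_values("time")["deviation"].to_numpy()
        assert series[0] < series[1] < series[2]
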