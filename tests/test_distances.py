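"""p-distance and evolutionary-distance transforms, matrices, imputation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sketch2phylo import (
    DistanceMatrix,
    EvoModelParams,
    SketchParams,
    TransformParams,
    analytic_p,
    b1_from_freqs,
    b2_from_freq_pair,
    bottom_sketch,
    build_distance_matrix,
    delta_v11,
    ei_gamma_distance,
    ei_log_distance,
    fit_a_to_points,
    fit_equiv_a,
    impute_missing,
    p_from_jaccard,
    p_from_mash_distance,
    pc_distance,
    read_phylip,
    write_phylip,
)
from sketch2phylo.distances import IMPUTED


class TestPFromJaccard:
    @pytest.mark.parametrize(
        "j,k,expected",
        [(1.0, 21, 0.0), (0.9, 21, 0.002571), (0.1, 16, 0.10107)],
    )
    def test_values(self, j, k, expected):
        assert p_from_jaccard(j, k) == pytest.approx(expected, abs=1e-5)

    def test_zero_jaccard_is_unusable(self):
        assert math.isnan(p_from_jaccard(0.0, 21))

    @settings(derandomize=True, max_examples=50)
    @given(j=st.floats(min_value=1e-6, max_value=1.0), k=st.integers(min_value=1, max_value=31))
    def test_range_and_monotonicity(self, j, k):
        p = p_from_jaccard(j, k)
        assert 0.0 <= p < 1.0
        assert p_from_jaccard(min(1.0, j * 1.01), k) <= p + 1e-15


class TestMashInversion:
    def test_values(self):
        assert p_from_mash_distance(0.0) == 0.0
        assert p_from_mash_distance(0.2) == pytest.approx(0.181269, abs=1e-6)
        with pytest.raises(ValueError):
            p_from_mash_distance(-0.1)

    def test_roundtrip_with_pc(self):
        for D in np.linspace(0.0, 2.0, 21):
            assert pc_distance(p_from_mash_distance(D)) == pytest.approx(D, abs=1e-12)


class TestFrequencyCoefficients:
    def test_b1_printed_values(self):
        assert b1_from_freqs([0.25, 0.25, 0.25, 0.25]) == pytest.approx(0.75)
        assert b1_from_freqs([0.10, 0.30, 0.40, 0.20]) == pytest.approx(0.70)
        assert b1_from_freqs([1, 0, 0, 0]) == 0.0

    def test_b2_pairs(self):
        f = [0.25] * 4
        assert b2_from_freq_pair(f, f) == pytest.approx(b1_from_freqs(f))
        assert b2_from_freq_pair([1, 0, 0, 0], [0, 1, 0, 0]) == 1.0
        at_rich = [0.40, 0.10, 0.10, 0.40]
        assert b2_from_freq_pair(at_rich, at_rich) == pytest.approx(0.66)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            b1_from_freqs([0.5, 0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            b2_from_freq_pair([0.25] * 4, [0.3, 0.3, 0.3, 0.2])


class TestTransforms:
    def test_ei_log_values(self):
        assert ei_log_distance(0.0, TransformParams(0.75, 0.75)) == 0.0
        assert pc_distance(0.1) == pytest.approx(0.105361, abs=1e-6)
        assert ei_log_distance(0.3, TransformParams(0.75, 0.75)) == pytest.approx(0.383120, abs=1e-6)

    def test_pc_is_ei_with_unit_coefficients(self):
        grid = np.linspace(0.0, 0.9, 40)
        np.testing.assert_allclose(pc_distance(grid), ei_log_distance(grid, TransformParams(1.0, 1.0)))

    def test_ei_gamma_closed_form(self):
        tp = TransformParams(0.75, 0.75, 1.0)
        assert ei_gamma_distance(0.3, tp) == pytest.approx(0.5, abs=1e-12)
        assert ei_gamma_distance(0.0, tp) == 0.0

    def test_infinite_a_dispatches_to_log_form(self):
        tp = TransformParams(0.75, 0.75, math.inf)
        assert ei_gamma_distance(0.3, tp) == ei_log_distance(0.3, TransformParams(0.75, 0.75))

    def test_missing_when_p_reaches_b2(self):
        assert math.isnan(ei_log_distance(0.8, TransformParams(0.75, 0.75)))
        assert math.isnan(ei_gamma_distance(0.75, TransformParams(0.75, 0.75, 1.0)))

    def test_delta_values(self):
        tp = TransformParams(0.75, 0.75)
        assert delta_v11(0.0, tp) == 0.0
        assert delta_v11(0.2, tp) == pytest.approx(0.26486, abs=1e-4)
        assert delta_v11(0.35, tp) == pytest.approx(0.640654, abs=1e-4)
        assert math.isnan(delta_v11(0.9, tp))  # argument of outer log non-positive

    def test_gamma_converges_to_log_form(self):
        """sup over p of |EI+G(a) - EI| vanishes as the shape grows."""
        grid = np.linspace(0.0, 0.5, 200)
        tp_log = TransformParams(0.75, 0.75)
        gaps = []
        for a in (1e3, 1e6):
            gap = np.max(np.abs(ei_gamma_distance(grid, TransformParams(0.75, 0.75, a)) - ei_log_distance(grid, tp_log)))
            gaps.append(gap)
        assert gaps[0] < 1e-3 and gaps[1] < 1e-6 and gaps[1] < gaps[0]

    @settings(derandomize=True, max_examples=50)
    @given(
        p=st.floats(min_value=0.01, max_value=0.5),
        a=st.floats(min_value=0.1, max_value=50.0),
    )
    def test_monotone_in_p_and_a(self, p, a):
        tp = TransformParams(0.75, 0.75, a)
        assert ei_gamma_distance(min(p * 1.01, 0.6), tp) > ei_gamma_distance(p, tp)
        tp_bigger_a = TransformParams(0.75, 0.75, a * 1.5)
        assert ei_gamma_distance(p, tp_bigger_a) < ei_gamma_distance(p, tp)


class TestEquivalenceFitter:
    def test_self_fit_identifiability(self):
        target = lambda p: ei_gamma_distance(p, TransformParams(0.75, 0.75, 0.5))
        assert fit_equiv_a(target, 0.75, 0.75) == pytest.approx(0.5, abs=1e-4)

    def test_grid_step_halving_invariance(self):
        target = lambda p: delta_v11(p, TransformParams(0.75, 0.75))
        g1 = np.arange(0.001, 0.35, 0.001)
        g2 = np.arange(0.0005, 0.35, 0.0005)
        a1 = fit_equiv_a(target, 0.75, 0.75, p_grid=g1)
        a2 = fit_equiv_a(target, 0.75, 0.75, p_grid=g2)
        assert abs(a1 - a2) < 1e-3

    def test_recovers_gamma_shape_from_analytic_curve(self):
        """Fitting (p(d), d) points from the JC+Γ closed form recovers the shape."""
        for alpha in (0.25, 1.0, 2.0):
            model = EvoModelParams(gamma_shape=alpha)
            d = np.linspace(0.01, 1.0, 100)
            p = np.array([analytic_p(x, model) for x in d])
            assert fit_a_to_points(p, d, 0.75, 0.75) == pytest.approx(alpha, abs=1e-3)

    def test_nonfinite_target_rejected(self):
        with pytest.raises(ValueError):
            fit_equiv_a(lambda p: np.full_like(p, np.nan), 0.75, 0.75)


def _matrix_from_genomes(genome_pair_factory, model="ei-gamma", **kwargs):
    recs = []
    for s in range(3):
        a, b, _ = genome_pair_factory(0.1, 4000, seed=10 + s)
        recs.append(a)
    params = SketchParams(k=13, sigma=1024)
    sketches = [bottom_sketch(r, params) for r in recs]
    return build_distance_matrix(sketches, model=model, **kwargs)


class TestDistanceMatrix:
    def test_identical_genomes_give_zero_matrix(self, genome_pair_factory):
        rec, _, _ = genome_pair_factory(0.1, 3000, seed=20)
        params = SketchParams(k=13, sigma=512)
        from sketch2phylo import GenomeRecord

        sketches = [
            bottom_sketch(GenomeRecord.from_sequence(f"t{i}", rec.sequence), params) for i in range(3)
        ]
        dm = build_distance_matrix(sketches)
        off = dm.values[np.triu_indices(3, 1)]
        assert np.allclose(off, 0.0)

    def test_symmetry_and_zero_diagonal(self, genome_pair_factory):
        dm = _matrix_from_genomes(genome_pair_factory)
        assert np.allclose(dm.values, dm.values.T, equal_nan=True)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_pc_equals_forced_unit_ei(self, genome_pair_factory):
        recs = []
        for s in range(3):
            a, _, _ = genome_pair_factory(0.15, 4000, seed=30 + s)
            recs.append(a)
        params = SketchParams(k=13, sigma=1024)
        sketches = [bottom_sketch(r, params) for r in recs]
        pc = build_distance_matrix(sketches, model="pc")
        from sketch2phylo.distances import pair_table

        tab = pair_table(sketches, model="pc")
        expected = pc_distance(tab["p_hat"].to_numpy())
        got = pc.values[np.triu_indices(3, 1)]
        np.testing.assert_allclose(np.sort(got), np.sort(expected))

    def test_fewer_than_three_rejected(self, genome_pair_factory):
        a, b, _ = genome_pair_factory(0.1, 2000, seed=40)
        params = SketchParams(k=13, sigma=256)
        with pytest.raises(ValueError):
            build_distance_matrix([bottom_sketch(a, params), bottom_sketch(b, params)])


class TestImputation:
    def test_minimum_over_third_taxa(self):
        # u,v missing; via x: 0.2+0.3=0.5, via y: 0.25+0.35=0.6 -> 0.5
        taxa = ["u", "v", "x", "y"]
        vals = np.array(
            [
                [0.0, np.nan, 0.2, 0.25],
                [np.nan, 0.0, 0.3, 0.35],
                [0.2, 0.3, 0.0, 0.4],
                [0.25, 0.35, 0.4, 0.0],
            ]
        )
        dm = impute_missing(DistanceMatrix(taxa, vals))
        assert dm.values[0, 1] == pytest.approx(0.5)
        assert dm.reasons[0, 1] == IMPUTED
        assert dm.values[0, 1] >= max(0.2, 0.3)
        # original entries untouched
        assert dm.values[2, 3] == 0.4

    def test_no_missing_is_identity(self):
        vals = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        dm = DistanceMatrix(["a", "b", "c"], vals)
        out = impute_missing(dm)
        np.testing.assert_array_equal(out.values, vals)

    def test_unresolvable_pair_raises_with_names(self):
        vals = np.full((3, 3), np.nan)
        np.fill_diagonal(vals, 0.0)
        vals[0, 1] = vals[1, 0] = 0.5
        with pytest.raises(ValueError, match="'a'.*'c'|'c'.*'a'"):
            impute_missing(DistanceMatrix(["a", "b", "c"], vals))


class TestPhylipIO:
    def test_roundtrip_and_byte_stability(self, tmp_path):
        vals = np.array([[0, 0.12345678901, 2], [0.12345678901, 0, 3], [2, 3, 0]], float)
        dm = DistanceMatrix(["a", "b", "c"], vals)
        p1 = tmp_path / "m1.phy"
        write_phylip(dm, p1)
        back = read_phylip(p1)
        assert back.taxa == dm.taxa
        np.testing.assert_array_equal(back.values, dm.values)
        p2 = tmp_path / "m2.phy"
        write_phylip(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert len(p1.read_text().splitlines()) == 4

    def test_labels_with_spaces_rejected(self, tmp_path):
        dm = DistanceMatrix(["a b", "c", "d"], np.zeros((3, 3)))
        with pytest.raises(ValueError, match="whitespace"):
            write_phylip(dm, tmp_path / "m.phy")

    def test_missing_entries_rejected(self, tmp_path):
        vals = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="impute"):
            write_phylip(DistanceMatrix(["a", "b", "c"], vals), tmp_path / "m.phy")
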