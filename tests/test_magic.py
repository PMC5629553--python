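import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modscan import ExpressionMatrix, ScreenConfig
from modscan.magic import (
    ON_INTENSIFIED,
    call_differential_edges,
    fisher_transform,
    group_correlations,
    inverse_fisher,
    magic_pvalue,
    pair_statistics,
    partition_samples,
)
from modscan.synthdata import PlantedModulator, SyntheticSpec, generate


class TestPartition:
    def test_group_size_matches_286_sample_cohort(self):
        rng = np.random.default_rng(0)
        E = ExpressionMatrix(
            ["m", "x"], [f"s{i}" for i in range(286)], rng.standard_normal((2, 286))
        )
        part = partition_samples(E, "m", 0.25)
        # k=71 is the only group size consistent with an average of
        # 241.5 = 973*k/286 on-modulators per sample
        assert part.k == 71
        assert 973 * part.k / 286 == pytest.approx(241.5, abs=0.05)

    def test_small_cohort_floor(self):
        rng = np.random.default_rng(1)
        E = ExpressionMatrix(
            ["m", "x"], [f"s{i}" for i in range(16)], rng.standard_normal((2, 16))
        )
        assert partition_samples(E, "m", 0.25).k == 4

    def test_on_group_dominates_off_group(self, toy_matrix):
        part = partition_samples(toy_matrix, "gA", 0.25)
        vals = toy_matrix.values[0]
        assert vals[part.on_samples].min() >= vals[part.off_samples].max()

    def test_all_equal_expression_uses_stable_tie_rule(self):
        E = ExpressionMatrix(
            ["m", "x"],
            [f"s{i}" for i in range(16)],
            np.vstack([np.zeros(16), np.arange(16.0)]),
        )
        part = partition_samples(E, "m", 0.25)
        assert part.k == 4
        assert set(part.on_samples) & set(part.off_samples) == set()
        # stable sort on (value, sample order): ties resolved by column order
        np.testing.assert_array_equal(np.sort(part.off_samples), [0, 1, 2, 3])

    def test_unknown_modulator_and_tiny_groups_error(self, toy_matrix):
        with pytest.raises(KeyError):
            partition_samples(toy_matrix, "nope", 0.25)
        small = ExpressionMatrix(
            ["m"], [f"s{i}" for i in range(8)], np.arange(8.0).reshape(1, 8)
        )
        with pytest.raises(ValueError, match="group size"):
            partition_samples(small, "m", 0.25)


class TestGroupCorrelations:
    def _matrix(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(24)
        values = np.vstack([base, base, -base, rng.standard_normal(24)])
        return ExpressionMatrix(["m", "same", "anti", "other"], [f"s{i}" for i in range(24)], values)

    def test_identical_and_antisymmetric_genes(self):
        E = self._matrix()
        part = partition_samples(E, "other", 0.25)
        c_on, c_off = group_correlations(E, part)
        assert c_on[0, 1] == pytest.approx(1.0)
        assert c_off[0, 1] == pytest.approx(1.0)
        assert c_on[0, 2] == pytest.approx(-1.0)
        assert c_off[0, 2] == pytest.approx(-1.0)

    def test_matches_hand_pearson(self):
        # on-group values (1,2,3,4) vs (1,2,3,5): r via covariance/variance oracle
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        cov = ((x - x.mean()) * (y - y.mean())).sum()
        r_hand = cov / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        E = ExpressionMatrix(
            ["m", "gx", "gy"],
            [f"s{i}" for i in range(16)],
            np.vstack(
                [
                    np.arange(16.0),
                    np.concatenate([np.zeros(12), x]),
                    np.concatenate([np.zeros(12), y]),
                ]
            ),
        )
        part = partition_samples(E, "m", 0.25)
        c_on, _ = group_correlations(E, part)
        assert c_on[1, 2] == pytest.approx(r_hand, abs=1e-12)

    def test_constant_row_in_group_is_nan(self):
        E = self._matrix()
        E.values[3, :] = 5.0  # constant everywhere
        part = partition_samples(E, "m", 0.25)
        c_on, c_off = group_correlations(E, part)
        assert np.isnan(c_on[3, 0]) and np.isnan(c_off[3, 0])


class TestFisherTransform:
    def test_zero_maps_to_zero(self):
        assert fisher_transform(0.0, 286) == 0.0

    def test_closed_form_at_half(self):
        # sqrt(68.5)/2 * ln(3), evaluated independently
        expected = np.sqrt(286 / 4 - 3) / 2 * np.log((1 + 0.5) / (1 - 0.5))
        assert fisher_transform(0.5, 286) == pytest.approx(expected, rel=1e-12)
        assert fisher_transform(0.5, 286) == pytest.approx(4.546, abs=5e-4)

    def test_clipping_keeps_extremes_finite(self):
        v = fisher_transform(1.0, 286)
        assert np.isfinite(v) and v > 50
        assert np.isfinite(fisher_transform(-1.0, 286))

    def test_rejects_insufficient_samples(self):
        with pytest.raises(ValueError):
            fisher_transform(0.5, 12)

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_odd_and_increasing(self, a, b):
        f = lambda c: fisher_transform(c, 100)
        assert f(-a) == pytest.approx(-f(a), abs=1e-10)
        if a < b:
            assert f(a) < f(b)


class TestInverseFisher:
    def test_zero_fixed_point_both_modes(self):
        assert inverse_fisher(0.0, 71.5, "exact") == 0.0
        assert inverse_fisher(0.0, 71.5, "verbatim") == 0.0

    @pytest.mark.parametrize("c", [-0.9, -0.5, 0.0, 0.5, 0.9])
    def test_exact_mode_round_trip(self, c):
        i = fisher_transform(c, 286)
        assert inverse_fisher(i, 286 / 4, "exact") == pytest.approx(c, abs=1e-10)

    def test_verbatim_mode_closed_form(self):
        assert inverse_fisher(4.546, 71.5, "verbatim") == pytest.approx(
            np.tanh(4.546) / np.sqrt(68.5), rel=1e-12
        )
        assert inverse_fisher(4.546, 71.5, "verbatim") == pytest.approx(0.1208, abs=5e-4)

    def test_verbatim_mode_saturates(self):
        assert abs(inverse_fisher(50.0, 71.5, "verbatim")) <= 1 / np.sqrt(68.5) + 1e-12

    def test_rejects_small_assigned_size(self):
        with pytest.raises(ValueError):
            inverse_fisher(1.0, 3.0)


class TestMagicPvalue:
    def test_equal_interactions_give_p_one(self):
        assert magic_pvalue(1.7, 1.7) == pytest.approx(1.0)

    def test_normal_quantile_oracle(self):
        delta = np.sqrt(2) * 1.959964
        assert magic_pvalue(delta, 0.0) == pytest.approx(0.05, abs=1e-6)

    def test_strictly_decreasing_in_delta(self):
        deltas = np.linspace(0, 10, 30)
        ps = [magic_pvalue(d, 0.0) for d in deltas]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_p_in_unit_interval_even_for_huge_stat(self):
        p = magic_pvalue(1e6, 0.0)
        assert 0 < p <= 1

    def test_magnitude_variant_is_conservative(self):
        # opposite signs: signed stat is larger, so signed p is smaller
        assert magic_pvalue(2.0, -2.0, "signed") < magic_pvalue(2.0, -2.0, "magnitude")


class TestCallDifferentialEdges:
    def _planted(self, seed=0):
        spec = SyntheticSpec(
            n_genes=20,
            n_samples=200,
            planted=[PlantedModulator("MOD", [("Ta", "Tb")], rho_on=0.8, rho_off=0.0)],
            seed=seed,
        )
        return generate(spec)[0]

    def test_planted_pair_called_with_direction(self):
        E = self._planted()
        part = partition_samples(E, "MOD", 0.25)
        edges = call_differential_edges(E, part, p_max=1e-5, score_min=0.4)
        pairs = {e.pair for e in edges}
        assert ("Ta", "Tb") in pairs
        edge = next(e for e in edges if e.pair == ("Ta", "Tb"))
        assert edge.direction == ON_INTENSIFIED
        assert edge.magic_p < 1e-5 and edge.magic_score >= 0.4
        # direct recomputation of the pair's statistics
        st = pair_statistics(E.values, part.on_samples, part.off_samples)
        i, j = E.gene_index("Ta"), E.gene_index("Tb")
        assert edge.magic_p == pytest.approx(st.p[i, j])
        assert edge.magic_score == pytest.approx(st.score[i, j])

    def test_identical_groups_yield_no_edges(self, indep_matrix):
        """Duplicated sample blocks: both groups see the same values, delta-I = 0."""
        from modscan.magic import ModulatorPartition

        E = ExpressionMatrix(
            indep_matrix.gene_ids,
            [f"s{i}" for i in range(30)],
            np.hstack([indep_matrix.values[:, :15]] * 2),
        )
        part = ModulatorPartition("G0001", np.arange(15), np.arange(15, 30), 0.25)
        edges = call_differential_edges(E, part, p_max=0.5, score_min=0.0)
        assert edges == []

    def test_infinite_score_threshold_vacuous(self):
        E = self._planted()
        part = partition_samples(E, "MOD", 0.25)
        assert call_differential_edges(E, part, score_min=np.inf) == []

    def test_modulator_pairs_excluded_by_default(self):
        E = self._planted()
        part = partition_samples(E, "MOD", 0.25)
        edges = call_differential_edges(E, part, p_max=1.0, score_min=0.0)
        assert all("MOD" not in e.pair for e in edges)

    def test_gene_order_invariance(self):
        E = self._planted()
        order = list(reversed(range(E.n_genes)))
        E2 = ExpressionMatrix(
            [E.gene_ids[i] for i in order], list(E.sample_ids), E.values[order]
        )
        kw = dict(p_max=1e-4, score_min=0.2)
        e1 = {e.pair for e in call_differential_edges(E, partition_samples(E, "MOD"), **kw)}
        e2 = {
            tuple(sorted(e.pair))
            for e in call_differential_edges(E2, partition_samples(E2, "MOD"), **kw)
        }
        assert {tuple(sorted(p)) for p in e1} == e2


class TestSwapSymmetry:
    def test_swap_preserves_stats_and_flips_direction(self):
        spec = SyntheticSpec(
            n_genes=10,
            n_samples=120,
            planted=[PlantedModulator("MOD", [("Ta", "Tb")], rho_on=0.8, rho_off=0.0)],
            seed=4,
        )
        E = generate(spec)[0]
        part = partition_samples(E, "MOD", 0.25)
        fwd = call_differential_edges(E, part, p_max=1e-4, score_min=0.2)
        rev = call_differential_edges(E, part.swapped(), p_max=1e-4, score_min=0.2)
        assert len(fwd) == len(rev) > 0
        for a, b in zip(fwd, rev):
            assert a.pair == b.pair
            assert a.delta_i == pytest.approx(b.delta_i)
            assert a.magic_p == pytest.approx(b.magic_p)
            assert a.magic_score == pytest.approx(b.magic_score)
            assert a.direction != b.direction
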