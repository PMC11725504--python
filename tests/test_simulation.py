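import numpy as np
import pytest

from trajalign import (
    evaluate_battery,
    invert_pair,
    perturb_split_real_style,
    simulate_convergent_pair,
    simulate_divergent_pair,
    simulate_matching_pair,
    simulate_unrelated_pair,
)
from trajalign.simulation import (
    DIVERGENCE_NOISE_SD,
    SimulatedPair,
    change_point_kernel,
    expected_ranges,
)


class TestDeterminism:
    @pytest.mark.parametrize(
        "factory",
        [
            lambda s: simulate_matching_pair(s),
            lambda s: simulate_divergent_pair(0.5, s),
            lambda s: simulate_unrelated_pair(s),
        ],
        ids=["matching", "divergent", "unrelated"],
    )
    def test_same_seed_bit_identical(self, factory):
        a, b = factory(11), factory(11)
        np.testing.assert_array_equal(a.ref_expr, b.ref_expr)
        np.testing.assert_array_equal(a.query_expr, b.query_expr)
        c = factory(12)
        assert not np.array_equal(a.ref_expr, c.ref_expr)


class TestMatchingPair:
    def test_shared_mean_and_noise_scale(self):
        pair = simulate_matching_pair(3)
        assert pair.label == "matching"
        assert len(pair.ref_expr) == len(pair.query_expr) == 300
        np.testing.assert_array_equal(pair.branch_ref, pair.branch_query)
        diff = pair.ref_expr - pair.query_expr
        assert abs(diff.mean()) < 0.5
        assert np.std(diff) == pytest.approx(np.sqrt(2) * pair.noise_sd, rel=0.25)


class TestChangePointKernel:
    def test_zero_before_rbf_after(self):
        t = np.linspace(0, 1, 101)
        K = change_point_kernel(t, 0.5)
        var = np.diag(K)
        assert var[t < 0.35].max() < 0.01
        assert var[t > 0.65].min() > 0.5

    def test_expected_range_arithmetic_identity(self):
        for t_cp in (0.25, 0.5, 0.75):
            (mlo, mhi), (xlo, xhi) = expected_ranges(t_cp, 15)
            assert mlo + xhi == 15
            assert mhi + xlo == 15
            assert mlo <= mhi and xlo <= xhi


class TestDivergencePair:
    def test_branches_agree_before_and_split_after(self):
        pair = simulate_divergent_pair(0.5, 7)
        t = pair.times
        pre = t < 0.45
        post = t > 0.6
        pre_gap = np.abs(pair.branch_ref[pre] - pair.branch_query[pre])
        post_gap = np.abs(pair.branch_ref[post] - pair.branch_query[post])
        assert pre_gap.mean() < 0.25 * DIVERGENCE_NOISE_SD
        assert post_gap.min() > 2 * DIVERGENCE_NOISE_SD

    def test_label_by_change_point(self):
        assert simulate_divergent_pair(0.75, 1).label == "div_late"
        assert simulate_divergent_pair(0.25, 1).label == "div_early"

    def test_invalid_change_point(self):
        with pytest.raises(ValueError):
            simulate_divergent_pair(1.5, 0)


class TestConvergencePair:
    def test_inversion_is_involution(self):
        pair = simulate_divergent_pair(0.75, 5)
        back = invert_pair(invert_pair(pair))
        np.testing.assert_array_equal(back.ref_expr, pair.ref_expr)
        assert back.label == pair.label
        assert back.t_cp == pair.t_cp

    def test_convergent_mirrors_divergent(self):
        conv = simulate_convergent_pair(0.25, 9)
        assert conv.label == "conv_early"
        assert conv.t_cp == pytest.approx(0.25)
        # mismatched early: branches split at the start, agree at the end
        t = conv.times
        gap = np.abs(conv.branch_ref - conv.branch_query)
        assert gap[t < 0.1].min() > 2 * DIVERGENCE_NOISE_SD
        assert gap[t > 0.35].mean() < 0.25 * DIVERGENCE_NOISE_SD


class TestUnrelatedPair:
    def test_levels_well_separated(self):
        pair = simulate_unrelated_pair(2)
        assert pair.label == "unrelated"
        gap = abs(pair.branch_ref.mean() - pair.branch_query.mean())
        assert gap > 1.5


class TestPerturbSplit:
    def _trajectory(self, rng, n=1000):
        t = rng.uniform(size=n)
        expr = np.stack([np.sin(3 * t) + 2, t * 2 + 1], axis=1)
        return expr, t

    def test_unperturbed_split_partitions_cells(self, rng):
        expr, t = self._trajectory(rng)
        ref, query = perturb_split_real_style(expr, t, n_perturbed_bins=0, seed=0)
        assert ref.n_cells + query.n_cells == 1000
        assert ref.n_genes == query.n_genes == 2

    def test_delete_removes_early_query_bins(self, rng):
        expr, t = self._trajectory(rng)
        ref, query = perturb_split_real_style(
            expr, t, n_bins=50, mode="delete", n_perturbed_bins=10, seed=0
        )
        # query support starts at former bin 11; re-normalized to [0, 1]
        assert query.pseudotime.min() == 0.0 and query.pseudotime.max() == 1.0
        assert query.n_cells < 500
        assert ref.pseudotime.min() < 0.05

    def test_shift_adds_sd_to_early_bins(self, rng):
        expr, t = self._trajectory(rng)
        ref0, q0 = perturb_split_real_style(expr, t, mode="shift", n_perturbed_bins=0, seed=0)
        ref1, q1 = perturb_split_real_style(expr, t, mode="shift", n_perturbed_bins=10, seed=0)
        np.testing.assert_array_equal(ref0.expression, ref1.expression)
        margin = np.quantile(t, 0.0) + 10 / 50 * (t.max() - t.min())
        early = q1.pseudotime <= margin + 1e-12
        assert np.all(q1.expression[early] > q0.expression[early])
        late = q1.pseudotime > margin + 1e-9
        np.testing.assert_allclose(q1.expression[late], q0.expression[late])


class TestEvaluateBattery:
    def _pair(self, label, mis=(3, 5)):
        return SimulatedPair(
            ref_expr=np.zeros(1),
            query_expr=np.zeros(1),
            times=np.zeros(1),
            label=label,
            expected_match_range=(15 - mis[1], 15 - mis[0]),
            expected_mismatch_range=mis,
        )

    def test_matching_templates(self):
        rep = evaluate_battery(
            ["MMMMM", "MMMIIIDDD"], [self._pair("matching"), self._pair("matching")]
        )
        assert rep.per_pair[0][1] is True
        assert rep.per_pair[1][1] is False
        assert rep.accuracy["matching"] == 0.5

    def test_divergence_needs_counts_in_range(self):
        ok = "M" * 11 + "IIII" + "DDDD"
        short = "M" * 13 + "II" + "DD"
        island = "M" * 5 + "II" + "M" * 4 + "IIDDDD"
        rep = evaluate_battery(
            [ok, short, island], [self._pair("div_late")] * 3
        )
        flags = [okflag for _, okflag, _ in rep.per_pair]
        assert flags == [True, False, False]

    def test_convergence_mirrored(self):
        rep = evaluate_battery(
            ["III" + "DDD" + "M" * 11], [self._pair("conv_early", mis=(3, 5))]
        )
        assert rep.per_pair[0][1] is True

    def test_unrelated_requires_pure_mismatch(self):
        rep = evaluate_battery(
            ["ID" * 5, "IDM" + "ID" * 4],
            [self._pair("unrelated"), self._pair("unrelated")],
        )
        assert [f for _, f, _ in rep.per_pair] == [True, False]

    def test_overall_accuracy(self):
        rep = evaluate_battery(["MMM"], [self._pair("matching")])
        assert rep.overall_accuracy == 1.0
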