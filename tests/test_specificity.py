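import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootspec.expression import TissueProfile
from rootspec.specificity import (
    ScreeningThresholds,
    call_tissue_genes,
    classic_tau,
    screen,
    tau,
)

# independently frozen via 40-digit arbitrary-precision evaluation of the formula
TAU_100_10_0_0 = 0.8268087645058531011


def profile(values, gene_id="g", tissues=None):
    tissues = tissues or [f"t{i}" for i in range(len(values))]
    return TissueProfile(gene_id=gene_id, tissue_values=dict(zip(tissues, values)))


class TestTau:
    def test_single_tissue_expression_gives_one(self):
        assert tau([0, 0, 50, 0]) == pytest.approx(1.0, abs=1e-15)

    def test_uniform_expression_gives_zero(self):
        assert tau([7.3] * 5) == pytest.approx(0.0, abs=1e-15)

    def test_worked_value_matches_arbitrary_precision_oracle(self):
        assert tau([100, 10, 0, 0]) == pytest.approx(TAU_100_10_0_0, abs=1e-12)

    def test_all_zero_gene_is_undefined(self):
        assert math.isnan(tau([0.0, 0.0, 0.0]))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            tau([5.0])
        with pytest.raises(ValueError):
            tau([1.0, -2.0])

    def test_accepts_profile_objects(self):
        assert tau(profile([100, 10, 0, 0])) == pytest.approx(TAU_100_10_0_0, abs=1e-12)

    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=13)
           .filter(lambda xs: max(xs) >= 1e-9))
    @settings(max_examples=200, derandomize=True)
    def test_bounded_in_unit_interval(self, xs):
        t = tau(xs)
        assert -1e-12 <= t <= 1.0 + 1e-12

    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=13)
           .filter(lambda xs: max(xs) >= 1e-9),
           st.randoms(use_true_random=False))
    @settings(max_examples=100, derandomize=True)
    def test_invariant_under_tissue_permutation(self, xs, rnd):
        perm = list(xs)
        rnd.shuffle(perm)
        assert tau(perm) == pytest.approx(tau(xs), rel=1e-12, abs=1e-12)

    def test_lowering_a_non_max_value_never_decreases_tau(self):
        base = [50.0, 10.0, 3.0, 0.5]
        t0 = tau(base)
        for i in range(1, 4):
            lowered = list(base)
            lowered[i] /= 2
            assert tau(lowered) >= t0 - 1e-12

    def test_not_scale_invariant(self):
        # the log-based normalization deliberately depends on absolute TPM
        assert tau([100, 10, 0, 0]) != pytest.approx(tau([10, 1, 0, 0]), abs=1e-6)

    def test_classic_tau_is_scale_invariant_comparison_mode(self):
        assert classic_tau([100, 10, 0, 0]) == pytest.approx(
            classic_tau([10, 1, 0, 0]), abs=1e-12
        )


def brute_force_criterion(xmax, xsec):
    """Literal restatement of the three screening rules."""
    if xsec != 0 and 2 < xmax <= 20 and xmax / xsec >= 4:
        return 1
    if xsec != 0 and xmax > 20 and xmax / xsec >= 10:
        return 2
    if xsec == 0 and xmax >= 1:
        return 3
    return 0


class TestScreen:
    def test_criterion2_gene_is_specific(self):
        r = screen(profile([30, 2, 0, 0], tissues=["root", "leaf", "shoot", "ovary"]))
        assert (r.xmax, r.xsec, r.max_tissue) == (30, 2, "root")
        assert r.criterion == 2
        assert r.tau > 0.85 and r.is_specific

    def test_criterion3_solo_expression(self):
        r = screen(profile([5, 0, 0, 0]))
        assert r.criterion == 3 and r.tau == pytest.approx(1.0) and r.is_specific

    def test_low_xmax_gap_fails_screening(self):
        # no rule admits 0 < xmax <= 2 with a non-zero second tissue
        r = screen(profile([1.5, 0.1, 0, 0]))
        assert r.criterion == 0 and not r.is_specific

    def test_tied_maximum_is_not_specific(self):
        r = screen(profile([30, 30, 0, 0], tissues=["root", "leaf", "a", "b"]))
        assert r.xsec == r.xmax == 30
        assert r.max_tissue == "leaf"  # lexicographically first tied tissue
        assert r.criterion == 0 and not r.is_specific

    def test_all_zero_gene_is_not_specific(self):
        r = screen(profile([0, 0, 0]))
        assert math.isnan(r.tau) and not r.is_specific

    def test_boundary_comparisons_are_exact(self):
        # xmax exactly 20 with ratio 4 -> rule 1; xmax just above -> needs ratio 10
        assert screen(profile([20, 5, 0.1])).criterion == 1
        assert screen(profile([20.5, 5, 0.1])).criterion == 0
        assert screen(profile([20.5, 2.05, 0.1])).criterion == 2
        # solo expression below 1 fails rule 3
        assert screen(profile([0.9, 0, 0])).criterion == 0

    def test_agrees_with_brute_force_restatement_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            n = rng.integers(2, 14)
            x = rng.choice(
                [0.0, rng.uniform(0, 3), rng.uniform(0, 25), rng.uniform(0, 200)],
                size=n,
            )
            # sprinkle exact ties and zeros
            if rng.random() < 0.3:
                x[rng.integers(0, n)] = x.max()
            p = profile(list(x))
            r = screen(p)
            assert r.xmax == x.max()
            assert r.xsec == sorted(x)[-2] if len(set(x)) > 1 else True
            assert r.criterion == brute_force_criterion(r.xmax, r.xsec)
            t = tau(list(x))
            expect_specific = (not math.isnan(t)) and t > 0.85 and r.criterion != 0
            assert r.is_specific == expect_specific

    def test_custom_thresholds_are_respected(self):
        th = ScreeningThresholds(tau_min=0.99)
        r = screen(profile([30, 2, 0, 0]), th)
        assert r.criterion == 2 and not r.is_specific  # tau ~0.89 < 0.99


class TestCallTissueGenes:
    def _profiles(self):
        return [
            profile([30, 2, 0, 0], "root_hi", ["root", "leaf", "a", "b"]),
            profile([5, 0, 0, 0], "root_solo", ["root", "leaf", "a", "b"]),
            profile([0, 40, 1, 0], "leaf_hi", ["root", "leaf", "a", "b"]),
            profile([3, 3, 3, 3], "flat", ["root", "leaf", "a", "b"]),
        ]

    def test_returns_only_matching_tissue_sorted_by_tau(self):
        res = call_tissue_genes(self._profiles(), "root")
        assert [r.gene_id for r in res] == ["root_solo", "root_hi"]  # tau 1.0 first

    def test_leaf_specific_gene_absent_from_root_call(self):
        assert "leaf_hi" not in {r.gene_id for r in call_tissue_genes(self._profiles(), "root")}
        assert {r.gene_id for r in call_tissue_genes(self._profiles(), "leaf")} == {"leaf_hi"}

    def test_tissue_without_specific_genes_gives_empty_list(self):
        assert call_tissue_genes(self._profiles(), "a") == []

    def test_unknown_tissue_label_is_an_error(self):
        with pytest.raises(ValueError, match="unknown tissue"):
            call_tissue_genes(self._profiles(), "petal")

    def test_calls_partition_genes_across_tissues(self):
        profs = self._profiles()
        seen: dict[str, str] = {}
        for tissue in ["root", "leaf", "a", "b"]:
            for r in call_tissue_genes(profs, tissue):
                assert r.gene_id not in seen
                seen[r.gene_id] = tissue
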