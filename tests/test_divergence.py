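"""Jensen-Shannon divergence, wild-type null, and designability metrics."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hamascreen import (
    activity_entropy,
    blosum_score,
    designability_table,
    eligibility_1pct,
    jensen_shannon_distance,
    kl_divergence,
    position_top3,
    wt_null_threshold,
)
from hamascreen.divergence import (
    DivergenceResult,
    DivergenceUndefinedError,
    FIRST_SHELL_POSITIONS,
)
from hamascreen.io import parse_variant_label
from hamascreen.normalize import NormalizedVariant, VariantProfile
from hamascreen.panel import DEFAULT_PANEL


def prob_vectors(n=19):
    return (
        st.lists(st.floats(1e-9, 1.0), min_size=n, max_size=n)
        .map(np.array)
        .map(lambda v: v / v.sum())
    )


class TestKLDivergence:
    def test_identical_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == pytest.approx(0.0)

    def test_one_bit(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_asymmetric_and_undefined(self):
        # the reverse direction is undefined, which is why the JSD
        # compares against the mixture instead
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)
        with pytest.raises(DivergenceUndefinedError):
            kl_divergence([0.5, 0.5], [1.0, 0.0])


class TestJensenShannonDistance:
    def test_identical_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jensen_shannon_distance(p, p) == 0.0

    def test_disjoint_support_is_one(self):
        p = np.array([0.5, 0.5, 0.0, 0.0])
        q = np.array([0.0, 0.0, 0.25, 0.75])
        assert jensen_shannon_distance(p, q) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # M = (0.75, 0.25); divergence = 0.311278 bits; sqrt = 0.557922
        d = jensen_shannon_distance([1.0, 0.0], [0.5, 0.5])
        assert d == pytest.approx(0.5579230452, abs=1e-9)
        div = jensen_shannon_distance([1.0, 0.0], [0.5, 0.5], squared=True)
        assert div == pytest.approx(0.3112781245, abs=1e-9)

    def test_matches_scipy(self, rng):
        from scipy.spatial.distance import jensenshannon

        for _ in range(25):
            p = rng.dirichlet(np.ones(19))
            q = rng.dirichlet(np.ones(19))
            assert jensen_shannon_distance(p, q) == pytest.approx(
                jensenshannon(p, q, base=2.0), abs=1e-9
            )

    @settings(deadline=None, max_examples=60)
    @given(p=prob_vectors(), q=prob_vectors())
    def test_symmetric_and_bounded(self, p, q):
        d = jensen_shannon_distance(p, q)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(jensen_shannon_distance(q, p))

    @settings(deadline=None, max_examples=40)
    @given(p=prob_vectors(8), q=prob_vectors(8), r=prob_vectors(8))
    def test_triangle_inequality(self, p, q, r):
        dpq = jensen_shannon_distance(p, q)
        dqr = jensen_shannon_distance(q, r)
        dpr = jensen_shannon_distance(p, r)
        assert dpr <= dpq + dqr + 1e-12


def _normed(label, a_rel, p=None):
    panel = DEFAULT_PANEL
    vec = np.asarray(p, dtype=float) if p is not None else np.zeros(len(panel))
    profile = VariantProfile(
        variant=parse_variant_label(label), batch_id="B1",
        conc_mean=np.maximum(vec * max(a_rel, 0.0), 0.0) if vec.sum() else np.zeros(len(panel)),
        n_replicates=1, panel=panel,
    )
    return NormalizedVariant(
        profile=profile, a_rel=a_rel, p=vec,
        below_floor=a_rel < 0.01, below_trace=False,
    )


class TestEligibility:
    def test_boundaries(self):
        assert eligibility_1pct(_normed("G728M", 0.02))
        assert eligibility_1pct(_normed("G728M", 0.01))  # inclusive at 1%
        assert not eligibility_1pct(_normed("G728M", 0.0))
        assert not eligibility_1pct(_normed("G728M", 0.0099))


class TestWtNullThreshold:
    def _wt_profiles(self, totals_and_shifts):
        panel = DEFAULT_PANEL
        out = []
        for total, shift in totals_and_shifts:
            conc = np.zeros(len(panel))
            conc[0] = total * (0.5 + shift)
            conc[1] = total * (0.5 - shift)
            out.append(
                VariantProfile(
                    variant=parse_variant_label("WT"), batch_id="B1",
                    conc_mean=conc, n_replicates=1, panel=panel,
                )
            )
        return out

    def test_identical_replicates_give_zero(self):
        profiles = self._wt_profiles([(10, 0.1)] * 4)
        assert wt_null_threshold(profiles) == 0.0

    def test_matches_brute_force_pairs(self):
        profiles = self._wt_profiles([(10, 0.0), (10, 0.1), (10, 0.2), (10, 0.3)])
        from hamascreen.normalize import substrate_fractions

        fracs = [substrate_fractions(p) for p in profiles]
        pair_jsds = [
            jensen_shannon_distance(a, b) for a, b in combinations(fracs, 2)
        ]
        assert len(pair_jsds) == 6
        assert wt_null_threshold(profiles) == pytest.approx(
            np.percentile(pair_jsds, 95)
        )

    def test_order_invariant(self, rng):
        profiles = self._wt_profiles([(10, s) for s in rng.uniform(0, 0.4, 5)])
        t1 = wt_null_threshold(profiles)
        t2 = wt_null_threshold(list(reversed(profiles)))
        assert t1 == pytest.approx(t2)

    def test_insufficient_null(self):
        with pytest.raises(ValueError):
            wt_null_threshold(self._wt_profiles([(10, 0.1)]))


class TestPositionTop3:
    def _results(self, jsds, eligible=None):
        eligible = eligible or [True] * len(jsds)
        return [
            DivergenceResult(
                variant=parse_variant_label(f"G728{m}"), jsd_to_wt=j,
                passed_1pct=e, significant=False, threshold_used=0.2,
            )
            for m, j, e in zip("ACDEFHIKLMNPQRSTVWY", jsds, eligible)
        ]

    def test_mean_of_top_three(self):
        mean, top, insufficient = position_top3(self._results([0.1, 0.2, 0.3, 0.4]))
        assert mean == pytest.approx(0.3)
        assert not insufficient
        assert {v.label for v in top} == {"G728D", "G728E", "G728C"}

    def test_exactly_three(self):
        mean, _, insufficient = position_top3(self._results([0.1, 0.2, 0.3]))
        assert mean == pytest.approx(0.2) and not insufficient

    def test_two_eligible_flagged(self):
        mean, _, insufficient = position_top3(
            self._results([0.2, 0.4, 0.9], eligible=[True, True, False])
        )
        assert mean == pytest.approx(0.3) and insufficient

    def test_zero_eligible_is_nan_not_error(self):
        mean, top, insufficient = position_top3(
            self._results([0.2], eligible=[False])
        )
        assert math.isnan(mean) and top == () and insufficient


class TestActivityEntropy:
    def test_single_bin_zero(self):
        assert activity_entropy([1.0] * 20) == 0.0

    def test_uniform_over_bins(self):
        # one value per bin midpoint over the default range [-3, 1]
        mids = np.linspace(-2.8, 0.8, 10)
        assert activity_entropy(10.0**mids) == pytest.approx(math.log(10))

    def test_matches_hand_binned_histogram(self, rng):
        a = rng.uniform(0.001, 10.0, 20)
        x = np.clip(np.log10(a), -3, 1)
        counts, _ = np.histogram(x, bins=10, range=(-3, 1))
        freq = counts[counts > 0] / counts.sum()
        expected = -(freq * np.log(freq)).sum()
        assert activity_entropy(a) == pytest.approx(expected)

    def test_zeros_land_in_lowest_bin(self):
        assert activity_entropy([0.0, 0.0, 0.0]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            activity_entropy([])


class TestBlosum:
    @pytest.mark.parametrize(
        "wt,mut,score", [("V", "W", -3), ("L", "I", 2), ("A", "A", 4)]
    )
    def test_blosum62_lookups(self, wt, mut, score):
        assert blosum_score(wt, mut) == score
        assert blosum_score(mut, wt) == score  # symmetric

    def test_unknown_residue(self):
        with pytest.raises(ValueError):
            blosum_score("V", "Z")


class TestDesignabilityTable:
    def _div(self, pos, mut, jsd, eligible=True):
        return DivergenceResult(
            variant=parse_variant_label(f"G{pos}{mut}"), jsd_to_wt=jsd,
            passed_1pct=eligible, significant=False, threshold_used=0.2,
        )

    def test_counts_shells_and_sorting(self):
        divergences = {
            660: [self._div(660, m, j) for m, j in zip("AMS", [0.1, 0.2, 0.3])],
            654: [self._div(654, m, j) for m, j in zip("AMS", [0.5, 0.6, 0.7])],
        }
        activities = {660: [1.0, 0.5, 0.1], 654: [1.0, 1.0, 1.0]}
        table = designability_table(divergences, activities, threshold=0.25)
        assert len(table) == 2
        assert table[0].position == 654  # higher top3 mean first
        assert table[0].shell == "second" and table[1].shell == "first"
        assert table[0].significant and not table[1].significant

    def test_planted_switch_ranks_first(self, rng):
        """A position with one strongly divergent mutant tops the table."""
        divergences = {}
        for pos in sorted(FIRST_SHELL_POSITIONS):
            jsds = rng.uniform(0.0, 0.2, 5)
            divergences[pos] = [
                self._div(pos, m, float(j)) for m, j in zip("AMSCD", jsds)
            ]
        divergences[728].append(self._div(728, "W", 0.95))
        activities = {pos: list(rng.uniform(0.1, 1, 5)) for pos in divergences}
        table = designability_table(divergences, activities, threshold=0.3)
        assert table[0].position == 728
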