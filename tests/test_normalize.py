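"""Replicate averaging, wild-type normalization, floors and fractions."""

import numpy as np
import pytest

from hamascreen import (
    apply_activity_floor,
    average_replicates,
    merge_identical,
    relative_activity,
    substrate_fractions,
    trace_filter,
    wt_reference,
)
from hamascreen.normalize import MissingReferenceError, VariantProfile
from hamascreen.io import VariantId, parse_variant_label


def profile(panel, label, conc, batch="B1", n=1):
    vec = np.zeros(len(panel))
    for sub, value in conc.items():
        vec[panel.index(sub)] = value
    return VariantProfile(
        variant=parse_variant_label(label), batch_id=batch,
        conc_mean=vec, n_replicates=n, panel=panel,
    )


class TestAverageReplicates:
    def test_mean_of_three_replicates(self, make_well):
        wells = [
            make_well("G728M", {"l-Ala": t}, replicate=i + 1)
            for i, t in enumerate([9.0, 10.0, 11.0])
        ]
        profiles = average_replicates(wells)
        assert len(profiles) == 1
        assert profiles[0].total_activity == pytest.approx(10.0)
        assert profiles[0].n_replicates == 3

    def test_single_replicate_identity(self, make_well):
        w = make_well("G728M", {"l-Ala": 3.0, "l-Met": 1.0})
        (p,) = average_replicates([w])
        np.testing.assert_array_equal(p.conc_mean, w.conc)

    def test_grouping_matches_brute_force(self, make_well, rng):
        labels = ["G728M", "G728A", "WT"]
        batches = ["B1", "B2"]
        wells = []
        for _ in range(40):
            wells.append(
                make_well(
                    labels[rng.integers(3)],
                    {"l-Ala": float(rng.uniform(0.1, 5))},
                    batch_id=batches[rng.integers(2)],
                )
            )
        profiles = average_replicates(wells)
        # brute-force (variant, batch) enumeration
        expected_keys = {
            (parse_variant_label(w.variant_label), w.batch_id) for w in wells
        }
        assert {(p.variant, p.batch_id) for p in profiles} == expected_keys
        for p in profiles:
            members = [
                w.conc for w in wells
                if parse_variant_label(w.variant_label) == p.variant
                and w.batch_id == p.batch_id
            ]
            np.testing.assert_allclose(p.conc_mean, np.mean(members, axis=0))

    def test_neg_wells_skipped_and_empty_ok(self, make_well):
        assert average_replicates([]) == []
        profiles = average_replicates([make_well("NEG", {"l-Ala": 1.0})])
        assert profiles == []


class TestMergeIdentical:
    def test_replicate_weighted_mean(self, panel):
        a = profile(panel, "G728M", {"l-Ala": 2.0}, batch="B1", n=2)
        b = profile(panel, "G728M", {"l-Ala": 5.0}, batch="B2", n=4)
        (m,) = merge_identical([a, b])
        # weighted mean: (2*2 + 5*4)/6 = 4
        assert m.conc_mean[panel.index("l-Ala")] == pytest.approx(4.0)
        assert m.n_replicates == 6

    def test_distinct_unchanged(self, panel):
        ps = [profile(panel, lab, {"l-Ala": 1.0}) for lab in ["G728M", "G728A"]]
        assert merge_identical(ps) == ps

    def test_order_independent(self, panel, rng):
        ps = [
            profile(panel, "G728M", {"l-Ala": float(rng.uniform(1, 5))},
                    batch=f"B{i}", n=int(rng.integers(1, 5)))
            for i in range(5)
        ] + [profile(panel, "V660W", {"l-Met": 2.0})]
        merged = {m.variant: m.conc_mean for m in merge_identical(ps)}
        perm = [ps[i] for i in rng.permutation(len(ps))]
        merged_perm = {m.variant: m.conc_mean for m in merge_identical(perm)}
        for v in merged:
            np.testing.assert_allclose(merged[v], merged_perm[v])


class TestWtReference:
    def test_mean_of_four_wells(self, panel):
        ps = [
            profile(panel, "WT", {"l-Leu-d7": t}) for t in [8.0, 9.0, 11.0, 12.0]
        ] + [profile(panel, "G728M", {"l-Ala": 1.0})]
        ref = wt_reference(ps, "B1")
        assert ref.total_activity == pytest.approx(10.0)
        assert ref.variant.is_wildtype

    def test_single_well_identity(self, panel):
        (ref,) = [wt_reference([profile(panel, "WT", {"l-Leu-d7": 7.0})], "B1")]
        assert ref.total_activity == pytest.approx(7.0)

    def test_missing_wt_raises_naming_batch(self, panel):
        with pytest.raises(MissingReferenceError, match="B9"):
            wt_reference([profile(panel, "G728M", {"l-Ala": 1.0})], "B9")

    def test_median_option(self, panel):
        ps = [profile(panel, "WT", {"l-Leu-d7": t}) for t in [1.0, 2.0, 30.0]]
        assert wt_reference(ps, "B1", aggregate="median").total_activity == 2.0


class TestRelativeActivityAndFractions:
    def test_identity_zero_and_ratio(self, panel):
        wt = profile(panel, "WT", {"l-Leu-d7": 10.0})
        assert relative_activity(wt, wt) == pytest.approx(1.0)
        zero = profile(panel, "G728M", {})
        assert relative_activity(zero, wt) == 0.0
        half = profile(panel, "G728A", {"l-Ala": 5.0})
        assert relative_activity(half, wt) == pytest.approx(0.5)

    def test_zero_wt_rejected(self, panel):
        wt = profile(panel, "WT", {})
        with pytest.raises(MissingReferenceError):
            relative_activity(wt, wt)

    def test_fractions(self, panel):
        p = substrate_fractions(profile(panel, "G728M", {"l-Ala": 3.0, "l-Arg": 1.0}))
        assert p[panel.index("l-Ala")] == pytest.approx(0.75)
        assert p[panel.index("l-Arg")] == pytest.approx(0.25)
        assert p.sum() == pytest.approx(1.0)
        # indicator and uniform cases
        single = substrate_fractions(profile(panel, "G728A", {"l-Met": 2.0}))
        assert single[panel.index("l-Met")] == 1.0
        uniform = substrate_fractions(
            profile(panel, "G728S", {s: 1.0 for s in panel.ids})
        )
        np.testing.assert_allclose(uniform, 1.0 / len(panel))
        # inactive
        assert substrate_fractions(profile(panel, "G728C", {})).sum() == 0.0


class TestFloorsAndFilters:
    def test_activity_floor(self, panel):
        wt = profile(panel, "WT", {"l-Leu-d7": 10.0})
        weak = profile(panel, "G728M", {"l-Ala": 0.05})
        ok = profile(panel, "G728A", {"l-Ala": 0.2})
        normed = apply_activity_floor([weak, ok], wt)
        assert normed[0].below_floor and normed[0].p.sum() == 0.0
        assert not normed[1].below_floor
        assert normed[1].p.sum() == pytest.approx(1.0)

    def test_floor_frac_one_boundary(self, panel):
        wt = profile(panel, "WT", {"l-Leu-d7": 10.0})
        weaker = profile(panel, "G728M", {"l-Ala": 9.0})
        (n,) = apply_activity_floor([weaker], wt, frac=1.0)
        assert n.below_floor
        with pytest.raises(ValueError):
            apply_activity_floor([weaker], wt, frac=0.0)

    def test_trace_filter_inclusive_boundary(self, panel):
        ps = [
            profile(panel, "G728M", {"l-Ala": 0.1}),
            profile(panel, "G728A", {"l-Ala": 0.2}),
            profile(panel, "G728S", {"l-Ala": 5.0}),
        ]
        kept, excluded = trace_filter(ps)
        assert [p.total_activity for p in kept] == pytest.approx([0.2, 5.0])
        assert [p.total_activity for p in excluded] == pytest.approx([0.1])
        kept_all, none = trace_filter(ps, min_total=0.0)
        assert len(kept_all) == 3 and not none
        assert trace_filter([]) == ([], [])
        with pytest.raises(ValueError):
            trace_filter(ps, min_total=-1.0)


class TestInvariants:
    def test_scale_equivariance_of_relative_activity(self, panel, rng):
        """Multiplying a batch by c > 0 leaves every A_rel unchanged."""
        wt = profile(panel, "WT", {"l-Leu-d7": 10.0, "l-Met": 2.0})
        muts = [
            profile(panel, f"G728{m}", {"l-Ala": float(rng.uniform(0.1, 20))})
            for m in "AMSC"
        ]
        c = 3.7
        scaled_wt = profile(panel, "WT", {"l-Leu-d7": 10.0 * c, "l-Met": 2.0 * c})
        for m in muts:
            scaled = VariantProfile(
                variant=m.variant, batch_id=m.batch_id,
                conc_mean=m.conc_mean * c, n_replicates=1, panel=panel,
            )
            assert relative_activity(scaled, scaled_wt) == pytest.approx(
                relative_activity(m, wt)
            )

    def test_floor_then_fractions_idempotent(self, panel, rng):
        wt = profile(panel, "WT", {"l-Leu-d7": 10.0})
        muts = [
            profile(panel, f"G728{m}",
                    {s: float(rng.uniform(0, 1)) for s in panel.ids[:5]})
            for m in "AMS"
        ]
        normed = apply_activity_floor(muts, wt)
        for n in normed:
            if n.p.sum() == 0:
                continue
            renormed = VariantProfile(
                variant=n.variant, batch_id="B1", conc_mean=n.p,
                n_replicates=1, panel=panel,
            )
            np.testing.assert_allclose(substrate_fractions(renormed), n.p)
            assert n.p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all((n.p >= 0) & (n.p <= 1))
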