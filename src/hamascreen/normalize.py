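"""Replicate aggregation, wild-type normalization and substrate fractions.

Plate screens of enzyme variants suffer from batch-to-batch variation in
protein expression, so absolute hydroxamate totals are only meaningful
relative to the wild-type control measured in the same batch.  The steps
here implement that normalization chain:

1. average technical replicates within each batch;
2. divide each mutant's total hydroxamate output by the batch wild-type
   total, giving the relative activity ``A_rel``;
3. convert each profile into substrate fractions ``p_i`` (the probability
   that the enzyme converts substrate *i*), which feed the promiscuity and
   divergence statistics;
4. apply the activity floor (mutants below 1% of wild type are zeroed) and
   the trace filter (mutants below 0.2 µM total hydroxamates are excluded
   from promiscuity ranking).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .io import PanelMismatchError, VariantId, WellMeasurement, parse_variant_label
from .panel import SubstratePanel


class MissingReferenceError(ValueError):
    """Raised when a batch has no wild-type control to normalize against."""


@dataclass(frozen=True)
class VariantProfile:
    """Replicate-averaged concentration profile of one variant in one batch."""

    variant: VariantId
    batch_id: str
    conc_mean: np.ndarray
    n_replicates: int
    panel: SubstratePanel

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc_mean, dtype=float)
        object.__setattr__(self, "conc_mean", conc)
        if conc.shape != (len(self.panel),):
            raise PanelMismatchError("profile length does not match panel")
        if np.any(conc < 0):
            raise ValueError("negative mean concentration")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def total_activity(self) -> float:
        """Sum of the mean hydroxamate concentrations (µM)."""
        return float(self.conc_mean.sum())


@dataclass(frozen=True)
class NormalizedVariant:
    """A variant profile after wild-type normalization and activity floors.

    ``p`` is the substrate-fraction (probability) vector; it is all zero,
    with ``below_floor`` set, for variants whose total hydroxamate output
    falls below the stated fraction of the wild type.
    """

    profile: VariantProfile
    a_rel: float
    p: np.ndarray
    below_floor: bool
    below_trace: bool

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)

    @property
    def variant(self) -> VariantId:
        return self.profile.variant


def well_profiles(wells: Iterable[WellMeasurement]) -> list[VariantProfile]:
    """One single-replicate profile per well (no averaging).

    Used where per-well resolution matters, e.g. the wild-type null
    distribution of the divergence statistics.
    """
    return [
        VariantProfile(
            variant=parse_variant_label(w.variant_label),
            batch_id=w.batch_id,
            conc_mean=w.conc.copy(),
            n_replicates=1,
            panel=w.panel,
        )
        for w in wells
        if not w.is_neg_control
    ]


def average_replicates(wells: Sequence[WellMeasurement]) -> list[VariantProfile]:
    """Average hydroxamate concentrations over replicates within each batch.

    Returns one profile per (variant, batch) pair, in first-appearance
    order.  Negative-control wells are skipped; wild-type control wells
    become ``WT`` profiles.
    """
    wells = list(wells)
    if not wells:
        return []
    panel = wells[0].panel
    groups: dict[tuple[VariantId, str], list[WellMeasurement]] = {}
    for w in wells:
        if w.panel.ids != panel.ids:
            raise PanelMismatchError("wells from different panels")
        if w.is_neg_control:
            continue
        key = (parse_variant_label(w.variant_label), w.batch_id)
        groups.setdefault(key, []).append(w)
    return [
        VariantProfile(
            variant=variant,
            batch_id=batch,
            conc_mean=np.mean([w.conc for w in ws], axis=0),
            n_replicates=len(ws),
            panel=panel,
        )
        for (variant, batch), ws in groups.items()
    ]


def merge_identical(profiles: Sequence[VariantProfile]) -> list[VariantProfile]:
    """Merge profiles of the same variant across batches/libraries.

    Identical mutants that were screened more than once (e.g. in two
    libraries) are combined by a replicate-weighted mean, so the merged
    profile equals the plain mean over all underlying wells.  Output order
    follows the first appearance of each variant; the operation is
    invariant to the input ordering up to that.
    """
    groups: dict[VariantId, list[VariantProfile]] = {}
    for p in profiles:
        groups.setdefault(p.variant, []).append(p)
    merged = []
    for variant, ps in groups.items():
        if len(ps) == 1:
            merged.append(ps[0])
            continue
        weights = np.array([p.n_replicates for p in ps], dtype=float)
        conc = np.average([p.conc_mean for p in ps], axis=0, weights=weights)
        batches = sorted({p.batch_id for p in ps})
        merged.append(
            VariantProfile(
                variant=variant,
                batch_id="+".join(batches),
                conc_mean=conc,
                n_replicates=int(weights.sum()),
                panel=ps[0].panel,
            )
        )
    return merged


def wt_reference(
    profiles: Sequence[VariantProfile],
    batch_id: str | None = None,
    aggregate: Literal["mean", "median"] = "mean",
) -> VariantProfile:
    """Aggregate wild-type control profiles into the normalization reference.

    Parameters
    ----------
    profiles:
        Candidate profiles; only wild-type entries (optionally restricted
        to ``batch_id``) are used.
    aggregate:
        ``"mean"`` (default) or ``"median"`` per substrate, the latter for
        robustness against a single failed control well.
    """
    wt = [p for p in profiles if p.variant.is_wildtype]
    if batch_id is not None:
        wt = [p for p in wt if p.batch_id == batch_id]
    if not wt:
        where = f"batch {batch_id!r}" if batch_id is not None else "input"
        raise MissingReferenceError(f"no wild-type control in {where}")
    stack = np.array([p.conc_mean for p in wt])
    if aggregate == "mean":
        weights = np.array([p.n_replicates for p in wt], dtype=float)
        conc = np.average(stack, axis=0, weights=weights)
    elif aggregate == "median":
        conc = np.median(stack, axis=0)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return VariantProfile(
        variant=VariantId.wildtype(),
        batch_id=batch_id if batch_id is not None else "all",
        conc_mean=conc,
        n_replicates=sum(p.n_replicates for p in wt),
        panel=wt[0].panel,
    )


def relative_activity(variant: VariantProfile, wt: VariantProfile) -> float:
    """Total activity of the variant divided by the wild-type total (A_rel).

    Because both totals come from the same batch, systematic batch effects
    (variable protein expression) cancel.
    """
    if wt.total_activity <= 0:
        raise MissingReferenceError(
            f"wild-type reference of batch {wt.batch_id!r} has zero total activity"
        )
    return variant.total_activity / wt.total_activity


def substrate_fractions(profile: VariantProfile) -> np.ndarray:
    """Per-substrate fractions p_i = conc_i / total.

    An inactive profile (total 0) yields the all-zero vector.
    """
    total = profile.total_activity
    if total <= 0:
        return np.zeros(len(profile.panel))
    return profile.conc_mean / total


def apply_activity_floor(
    variants: Sequence[VariantProfile],
    wt: VariantProfile,
    frac: float = 0.01,
    trace_min_uM: float = 0.2,
) -> list[NormalizedVariant]:
    """Normalize profiles and zero those below ``frac`` of the wild type.

    A variant whose summed hydroxamates fall below ``frac`` (default 1%)
    of the wild-type total is flagged ``below_floor`` and its fraction
    vector set to zero; every other variant carries a unit-sum fraction
    vector.  ``below_trace`` additionally marks variants under the
    absolute ``trace_min_uM`` detection floor (default 0.2 µM), which are
    excluded from promiscuity ranking downstream.
    """
    if not (0 < frac <= 1):
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    if trace_min_uM < 0:
        raise ValueError(f"trace_min_uM must be >= 0, got {trace_min_uM}")
    floor = frac * wt.total_activity
    if wt.total_activity <= 0:
        raise MissingReferenceError("wild-type reference has zero total activity")
    out = []
    for v in variants:
        a_rel = relative_activity(v, wt)
        below_floor = v.total_activity < floor
        p = np.zeros(len(v.panel)) if below_floor else substrate_fractions(v)
        out.append(
            NormalizedVariant(
                profile=v,
                a_rel=a_rel,
                p=p,
                below_floor=below_floor,
                below_trace=v.total_activity < trace_min_uM,
            )
        )
    return out


def trace_filter(
    variants: Sequence[VariantProfile],
    min_total: float = 0.2,
) -> tuple[list[VariantProfile], list[VariantProfile]]:
    """Partition profiles at the absolute detection floor (default 0.2 µM).

    Variants accumulating less than ``min_total`` µM hydroxamates are
    excluded (second element); they are too close to the detection limit
    for a meaningful promiscuity estimate.  The boundary is inclusive on
    the kept side.
    """
    if min_total < 0:
        raise ValueError(f"min_total must be >= 0, got {min_total}")
    kept = [v for v in variants if v.total_activity >= min_total]
    excluded = [v for v in variants if v.total_activity < min_total]
    return kept, excluded


def subtract_background(
    wells: Sequence[WellMeasurement],
) -> list[WellMeasurement]:
    """Optional background subtraction using negative-control wells.

    Subtracts, per batch and substrate, the mean signal of the NEG wells
    (disrupted adenylation domain) from every other well, floored at 0.
    Off by default in the pipeline; useful when carry-over or chemical
    background is suspected.
    """
    neg_by_batch: dict[str, list[np.ndarray]] = {}
    for w in wells:
        if w.is_neg_control:
            neg_by_batch.setdefault(w.batch_id, []).append(w.conc)
    out = []
    for w in wells:
        if w.is_neg_control:
            out.append(w)
            continue
        negs = neg_by_batch.get(w.batch_id)
        if not negs:
            out.append(w)
            continue
        bg = np.mean(negs, axis=0)
        out.append(replace(w, conc=np.maximum(w.conc - bg, 0.0)))
    return out
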