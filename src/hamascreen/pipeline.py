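"""End-to-end analysis: plate table -> variant metrics -> designability.

The stages follow the normalization chain of a batch-controlled plate
screen: replicates are averaged within each batch, totals are divided by
the batch wild-type total, identical mutants from different libraries are
merged by a replicate-weighted mean, and the promiscuity and divergence
statistics are computed on the merged substrate-fraction profiles.
Significance of a specificity change is judged against the per-plate
wild-type null (95th percentile of JSDs among wild-type wells), pooled
conservatively by taking the maximum across plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import divergence as dv
from . import normalize as nm
from . import promiscuity as pm
from .io import VariantMetrics, WellMeasurement
from .panel import SubstratePanel


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline."""

    activity_floor_frac: float = 0.01   # zero profiles below this fraction of WT
    trace_min_uM: float = 0.2           # exclude from promiscuity ranking below this
    wt_aggregate: str = "mean"          # "mean" or "median" over WT control wells
    neg_subtract: bool = False          # subtract mean NEG background per batch
    null_percentile: float = 95.0       # WT-null percentile for significance
    jsd_squared: bool = False           # report JS divergence instead of distance
    hist_bins: int = 10                 # activity-entropy histogram bins
    hist_range: tuple[float, float] = (-3.0, 1.0)  # log10(A_rel) clip range
    blosum: str = "BLOSUM62"
    first_shell: frozenset[int] = field(default=dv.FIRST_SHELL_POSITIONS)


@dataclass
class AnalysisResult:
    """Outputs of one pipeline run."""

    metrics: list[VariantMetrics]
    promiscuity_ranking: list[pm.PromiscuityResult]
    divergences: list[dv.DivergenceResult]
    positions: list[dv.PositionSummary]
    null_thresholds: dict[str, float]  # per plate
    global_threshold: float
    wt_p: np.ndarray
    config: AnalysisConfig

    def metrics_frame(self) -> pd.DataFrame:
        cols = [
            "variant_label", "n_replicates", "total_uM", "a_rel", "entropy_P",
            "index_I", "index_I_rel", "jsd_to_wt", "below_floor",
            "below_trace", "significant",
        ]
        return pd.DataFrame(
            [{c: getattr(m, c) for c in cols} for m in self.metrics],
            columns=cols,
        )

    def positions_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.positions:
            rows.append(
                {
                    "position": s.position,
                    "shell": s.shell,
                    "top3_mean_jsd": s.top3_mean_jsd,
                    "top3_variants": ";".join(v.label for v in s.top3_variants),
                    "activity_entropy": s.activity_entropy,
                    "n_eligible": s.n_eligible,
                    "insufficient": s.insufficient,
                    "significant": s.significant,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "position", "shell", "top3_mean_jsd", "top3_variants",
                "activity_entropy", "n_eligible", "insufficient", "significant",
            ],
        )


def analyze_wells(
    wells: Sequence[WellMeasurement],
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisResult:
    """Run the full analysis on a plate table."""
    if not wells:
        raise ValueError("no wells to analyze")
    panel: SubstratePanel = wells[0].panel
    jsd_kwargs = {"squared": config.jsd_squared}

    if config.neg_subtract:
        wells = nm.subtract_background(wells)

    # per-plate WT null thresholds from individual WT wells
    wt_wells_by_plate: dict[str, list[WellMeasurement]] = {}
    for w in wells:
        if w.is_wt_control:
            wt_wells_by_plate.setdefault(w.plate_id, []).append(w)
    null_thresholds: dict[str, float] = {}
    for plate_id, pw in sorted(wt_wells_by_plate.items()):
        if len(pw) >= 2:
            null_thresholds[plate_id] = dv.wt_null_threshold(
                nm.well_profiles(pw),
                percentile=config.null_percentile,
                **jsd_kwargs,
            )
    if not null_thresholds:
        raise ValueError("no plate has >= 2 wild-type wells for the null threshold")
    # conservative pooling: a mutant must beat the noisiest plate's null
    global_threshold = max(null_thresholds.values())

    # batch averaging and per-batch WT normalization
    profiles = nm.average_replicates(wells)
    batches = sorted({p.batch_id for p in profiles})
    scaled: list[nm.VariantProfile] = []
    wt_totals_uM: list[float] = []
    for batch in batches:
        batch_profiles = [p for p in profiles if p.batch_id == batch]
        wt = nm.wt_reference(batch_profiles, batch, aggregate=config.wt_aggregate)
        wt_totals_uM.append(wt.total_activity)
        for p in batch_profiles:
            # rescale to wild-type-relative units so batch effects cancel
            # before identical mutants are merged across batches
            scaled.append(
                nm.VariantProfile(
                    variant=p.variant,
                    batch_id=p.batch_id,
                    conc_mean=p.conc_mean / wt.total_activity,
                    n_replicates=p.n_replicates,
                    panel=p.panel,
                )
            )

    merged = nm.merge_identical(scaled)
    wt_merged = nm.wt_reference(merged)
    mutants = [p for p in merged if not p.variant.is_wildtype]

    # mean WT total in µM, for the absolute trace filter on merged records
    mean_wt_total_uM = float(np.mean(wt_totals_uM))
    normed = nm.apply_activity_floor(
        mutants,
        wt_merged,
        frac=config.activity_floor_frac,
        trace_min_uM=config.trace_min_uM / mean_wt_total_uM,
    )
    wt_normed = nm.apply_activity_floor(
        [wt_merged], wt_merged, frac=config.activity_floor_frac,
        trace_min_uM=config.trace_min_uM / mean_wt_total_uM,
    )[0]
    wt_p = wt_normed.p

    # promiscuity
    wt_I = pm.promiscuity_index(pm.shannon_entropy(wt_p), len(panel))
    prom_results = []
    for v in normed:
        if v.p.sum() <= 0:
            prom_results.append(
                pm.PromiscuityResult(
                    variant=v.variant, entropy_P=0.0, index_I=0.0,
                    index_I_rel=0.0,
                    total_uM=v.profile.total_activity * mean_wt_total_uM,
                    excluded_trace=True,
                )
            )
            continue
        prom_results.append(
            pm.promiscuity_result(
                v.variant, v.p,
                total_uM=v.profile.total_activity * mean_wt_total_uM,
                I_wt=wt_I,
                excluded_trace=v.below_trace,
            )
        )
    ranking = pm.rank_by_promiscuity(prom_results)

    # divergence vs wild type
    div_results = [
        dv.divergence_result(
            v, wt_p, global_threshold, frac=config.activity_floor_frac,
            **jsd_kwargs,
        )
        for v in normed
    ]

    # per-position designability
    by_position: dict[int, list[dv.DivergenceResult]] = {}
    activities: dict[int, list[float]] = {}
    for v, d in zip(normed, div_results):
        if v.variant.is_wildtype or v.variant.is_stop:
            continue
        pos = v.variant.position
        by_position.setdefault(pos, []).append(d)
        activities.setdefault(pos, []).append(v.a_rel)
    positions = dv.designability_table(
        by_position, activities, global_threshold,
        first_shell=config.first_shell,
        hist_bins=config.hist_bins, hist_range=config.hist_range,
    )

    # assemble per-variant metrics rows
    prom_by_variant = {r.variant: r for r in prom_results}
    metrics = []
    for v, d in zip(normed, div_results):
        r = prom_by_variant[v.variant]
        metrics.append(
            VariantMetrics(
                variant_label=v.variant.label,
                n_replicates=v.profile.n_replicates,
                total_uM=v.profile.total_activity * mean_wt_total_uM,
                a_rel=v.a_rel,
                entropy_P=r.entropy_P,
                index_I=r.index_I,
                index_I_rel=r.index_I_rel,
                jsd_to_wt=d.jsd_to_wt,
                below_floor=v.below_floor,
                below_trace=v.below_trace,
                significant=d.significant,
                panel=panel,
            )
        )

    return AnalysisResult(
        metrics=metrics,
        promiscuity_ranking=ranking,
        divergences=div_results,
        positions=positions,
        null_thresholds=null_thresholds,
        global_threshold=global_threshold,
        wt_p=wt_p,
        config=config,
    )


@dataclass
class RecoveryReport:
    """How well the pipeline recovered a simulation's ground truth."""

    planted_position_ranks: dict[int, int]       # 1 = most designable
    planted_jsd: list[tuple[str, float, float]]  # (label, true, estimated)
    null_significant_fraction: float             # among eligible null mutants
    n_null_eligible: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.planted_jsd, columns=["variant", "true_jsd", "estimated_jsd"]
        )


def recovery_report(truth, result: AnalysisResult) -> RecoveryReport:
    """Compare pipeline output against the simulation ground truth.

    Reports the designability rank of every planted switch position, the
    estimated vs true JSD of each planted mutant, and the fraction of
    eligible *null* mutants (no planted effect) called significant.
    """
    from .divergence import jensen_shannon_distance

    planted_positions = {sw.position for sw in truth.config.planted_switches}
    planted_labels = {}
    for sw in truth.config.planted_switches:
        parent = truth.config.parent_residues[sw.position]
        planted_labels[f"{parent}{sw.position}{sw.mut_residue}"] = sw

    rank_of = {
        s.position: i + 1 for i, s in enumerate(result.positions)
    }
    position_ranks = {
        pos: rank_of.get(pos, -1) for pos in sorted(planted_positions)
    }

    jsd_rows = []
    wt_p = truth.wt_profile
    est_by_label = {d.variant.label: d for d in result.divergences}
    for label, sw in sorted(planted_labels.items()):
        true_jsd = jensen_shannon_distance(sw.profile / sw.profile.sum(), wt_p)
        est = est_by_label.get(label)
        jsd_rows.append(
            (label, true_jsd, est.jsd_to_wt if est is not None else float("nan"))
        )

    null_eligible = [
        d for d in result.divergences
        if d.passed_1pct
        and d.variant.label not in planted_labels
        and d.variant.position not in planted_positions
    ]
    n_sig = sum(d.significant for d in null_eligible)
    frac = n_sig / len(null_eligible) if null_eligible else float("nan")

    return RecoveryReport(
        planted_position_ranks=position_ranks,
        planted_jsd=jsd_rows,
        null_significant_fraction=frac,
        n_null_eligible=len(null_eligible),
    )
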