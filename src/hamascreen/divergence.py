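"""Specificity divergence, significance and position designability.

The change in a mutant's substrate profile relative to the wild type is
quantified by the Jensen-Shannon distance (JSD).  Given two probability
vectors ``P`` and ``Q`` on the substrate panel, the average distribution
is ``M = (P + Q) / 2`` and

    JSD(P, Q) = sqrt( D(P|M)/2 + D(Q|M)/2 )

where ``D(X|Y) = sum_i X_i log2(X_i / Y_i)`` is the Kullback-Leibler
divergence.  With base-2 logarithms the distance is symmetric, bounded in
[0, 1] (1 is attained for profiles with disjoint support), and a metric.

Significance is judged against an empirical wild-type null: the 95th
percentile of JSDs between wild-type control wells on the same plate.
A mutant must also retain at least 1% of the wild-type total activity to
be considered at all, to keep near-detection-limit profiles from
producing spurious divergences.

Positions are ranked for "designability" by the mean JSD of their top
three mutants, displayed against the entropy of the activity distribution
at that position (high entropy = activity tolerant to mutation).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .io import AMINO_ACIDS, VariantId
from .normalize import NormalizedVariant, VariantProfile, substrate_fractions

#: canonical specificity-code (first shell) positions of the SrfAC
#: adenylation domain binding pocket
FIRST_SHELL_POSITIONS = frozenset({660, 663, 702, 726, 728, 752, 760, 761})

#: the 15 binding-pocket positions of the saturation-mutagenesis screen,
#: mapped to the parent (VSA) residue at each
SCREEN_PARENT_RESIDUES: dict[int, str] = {
    654: "S", 658: "F", 660: "V", 661: "F", 663: "F", 664: "D", 702: "S",
    703: "A", 726: "L", 727: "F", 728: "G", 752: "A", 759: "T", 760: "V",
    761: "F",
}


class DivergenceUndefinedError(ValueError):
    """Raised when D(P|Q) is requested with Q_i = 0 on the support of P."""


def kl_divergence(
    P: Sequence[float] | np.ndarray,
    Q: Sequence[float] | np.ndarray,
    base: float = 2.0,
) -> float:
    """Kullback-Leibler divergence D(P|Q) = sum_{P_i>0} P_i log(P_i/Q_i).

    Defined only where Q puts mass on the support of P; inside the JSD the
    mixture M = (P+Q)/2 always satisfies this.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("distributions have different lengths")
    support = P > 0
    if np.any(Q[support] <= 0):
        raise DivergenceUndefinedError(
            "D(P|Q) undefined: Q has zero mass on the support of P"
        )
    return float(
        (P[support] * (np.log(P[support] / Q[support]) / np.log(base))).sum()
    )


def jensen_shannon_distance(
    P: Sequence[float] | np.ndarray,
    Q: Sequence[float] | np.ndarray,
    *,
    base: float = 2.0,
    squared: bool = False,
) -> float:
    """Jensen-Shannon distance between two profiles on the same panel.

    Returns the metric form sqrt(divergence) by default; ``squared=True``
    returns the divergence itself.  With ``base=2`` both lie in [0, 1].
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("profiles are on different panels")
    M = (P + Q) / 2.0
    div = 0.5 * kl_divergence(P, M, base=base) + 0.5 * kl_divergence(Q, M, base=base)
    div = min(max(div, 0.0), 1.0)  # clip float round-off at the bounds
    return div if squared else float(np.sqrt(div))


def eligibility_1pct(variant: NormalizedVariant, frac: float = 0.01) -> bool:
    """Whether a variant retains enough activity for JSD analysis.

    The total activity must be at least ``frac`` (default 1%) of the
    wild-type production; the boundary is inclusive.
    """
    return variant.a_rel >= frac


def wt_null_threshold(
    wt_profiles: Sequence[VariantProfile],
    percentile: float = 95.0,
    **jsd_kwargs,
) -> float:
    """Null JSD threshold from wild-type replicates on one plate.

    Computes the JSD for every unordered pair of wild-type profiles and
    returns the requested percentile (default 95th).  Mutant JSDs above
    this level diverge more than wild-type replicates do among themselves
    and are called significant.
    """
    if len(wt_profiles) < 2:
        raise ValueError(
            f"need at least 2 wild-type profiles for a null, got {len(wt_profiles)}"
        )
    fracs = [substrate_fractions(p) for p in wt_profiles]
    pair_jsds = [
        jensen_shannon_distance(a, b, **jsd_kwargs)
        for a, b in combinations(fracs, 2)
    ]
    return float(np.percentile(pair_jsds, percentile))


@dataclass(frozen=True)
class DivergenceResult:
    """JSD of one variant against the wild-type profile."""

    variant: VariantId
    jsd_to_wt: float
    passed_1pct: bool
    significant: bool
    threshold_used: float


def divergence_result(
    variant: NormalizedVariant,
    wt_p: np.ndarray,
    threshold: float,
    frac: float = 0.01,
    **jsd_kwargs,
) -> DivergenceResult:
    """JSD to wild type with the 1% eligibility rule and significance call."""
    eligible = eligibility_1pct(variant, frac)
    if eligible and variant.p.sum() > 0:
        jsd = jensen_shannon_distance(variant.p, wt_p, **jsd_kwargs)
    else:
        jsd = float("nan")
        eligible = False
    significant = eligible and jsd > threshold
    return DivergenceResult(
        variant=variant.variant,
        jsd_to_wt=jsd,
        passed_1pct=eligible,
        significant=significant,
        threshold_used=threshold,
    )


@dataclass(frozen=True)
class PositionSummary:
    """Designability summary of one mutated position."""

    position: int
    shell: str  # "first" or "second"
    top3_mean_jsd: float
    top3_variants: tuple[VariantId, ...]
    activity_entropy: float
    n_eligible: int
    insufficient: bool  # fewer than 3 eligible mutants at the position
    significant: bool


def position_top3(
    results: Sequence[DivergenceResult],
) -> tuple[float, tuple[VariantId, ...], bool]:
    """Mean JSD of the (up to) three most divergent eligible mutants.

    Returns ``(mean, contributing variants, insufficient_flag)``; with no
    eligible mutant the mean is NaN and the flag is set.
    """
    eligible = [r for r in results if r.passed_1pct and np.isfinite(r.jsd_to_wt)]
    eligible.sort(key=lambda r: (-r.jsd_to_wt, r.variant.label))
    top = eligible[:3]
    if not top:
        return float("nan"), (), True
    mean = float(np.mean([r.jsd_to_wt for r in top]))
    return mean, tuple(r.variant for r in top), len(top) < 3


def activity_entropy(
    a_rels: Sequence[float],
    bins: int = 10,
    log_range: tuple[float, float] = (-3.0, 1.0),
) -> float:
    """Entropy (nats) of the histogram of relative activities at a position.

    Activities are binned on log10(A_rel), clipped to ``log_range``
    (default 10^-3 to 10; zeros land in the lowest bin), with ``bins``
    equal-width bins.  High entropy means mutations spread activity
    broadly (tolerant position); low entropy means most mutations share a
    fate, typically inactivation.
    """
    a = np.asarray(a_rels, dtype=float)
    if a.size == 0:
        raise ValueError("activity entropy undefined for empty input")
    lo, hi = log_range
    with np.errstate(divide="ignore"):
        x = np.clip(np.log10(np.maximum(a, 0.0)), lo, hi)
    counts, _ = np.histogram(x, bins=bins, range=log_range)
    freq = counts[counts > 0] / counts.sum()
    return float(-(freq * np.log(freq)).sum())


def blosum_score(wt: str, mut: str, matrix: str = "BLOSUM62") -> int:
    """Substitution score of a mutation in a BLOSUM matrix.

    More negative scores mark chemically more drastic exchanges.
    """
    if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
        raise ValueError(f"residues must be amino acids, got {wt!r}->{mut!r}")
    m = substitution_matrices.load(matrix)
    return int(m[wt, mut])


def designability_table(
    divergences: Mapping[int, Sequence[DivergenceResult]],
    activities: Mapping[int, Sequence[float]],
    threshold: float,
    first_shell: frozenset[int] = FIRST_SHELL_POSITIONS,
    hist_bins: int = 10,
    hist_range: tuple[float, float] = (-3.0, 1.0),
) -> list[PositionSummary]:
    """Per-position designability ranking.

    Combines, for every position, the top-3 mean JSD, the entropy of the
    activity distribution, the binding-pocket shell, and significance
    against the wild-type null threshold.  Sorted by top-3 mean JSD
    descending (NaN last); the most designable positions come first.
    """
    summaries = []
    for pos, results in divergences.items():
        mean, top, insufficient = position_top3(results)
        n_eligible = sum(r.passed_1pct for r in results)
        a_rels = activities.get(pos, [])
        ent = (
            activity_entropy(a_rels, bins=hist_bins, log_range=hist_range)
            if len(a_rels) > 0
            else float("nan")
        )
        summaries.append(
            PositionSummary(
                position=pos,
                shell="first" if pos in first_shell else "second",
                top3_mean_jsd=mean,
                top3_variants=top,
                activity_entropy=ent,
                n_eligible=n_eligible,
                insufficient=insufficient,
                significant=bool(np.isfinite(mean) and mean > threshold),
            )
        )
    summaries.sort(
        key=lambda s: (
            not np.isfinite(s.top3_mean_jsd),
            -(s.top3_mean_jsd if np.isfinite(s.top3_mean_jsd) else 0.0),
            s.position,
        )
    )
    return summaries
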