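"""Shannon-entropy promiscuity metrics for substrate-specificity profiles.

A variant's specificity profile is a probability vector ``p`` over the
``N`` assayed substrates.  Its promiscuity is measured by the Shannon
entropy

    P = -sum_i p_i ln p_i          (nats, 0 * ln 0 := 0)

and summarized by the promiscuity index

    I = P / ln N

which maps the entropy onto [0, 1]: ``I = 0`` for a perfectly specific
enzyme (all signal in one substrate channel) and ``I = 1`` for a perfectly
promiscuous one (uniform over the panel).  The relative index
``I_rel = I_mutant / I_wildtype`` is > 1 for mutants more promiscuous than
the wild type and < 1 for more specific ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import VariantId


class NormalizationError(ValueError):
    """Raised when an input vector is not a probability distribution."""


def shannon_entropy(p: Sequence[float] | np.ndarray, tol: float = 1e-6) -> float:
    """Shannon entropy in nats of a probability vector.

    Raises :class:`NormalizationError` if entries are negative or the sum
    deviates from 1 by more than ``tol``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise NormalizationError("probability vector has negative entries")
    total = p.sum()
    if abs(total - 1.0) > tol:
        raise NormalizationError(f"probability vector sums to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum()) + 0.0  # +0.0 normalizes -0.0


def promiscuity_index(P: float, N: int) -> float:
    """Promiscuity index I in [0, 1] from entropy ``P`` over ``N`` substrates.

    Implemented as the normalized entropy I = P / ln N, which takes the
    value 0 for a perfectly specific and 1 for a perfectly promiscuous
    enzyme.  (The logarithm base cancels in this normalization.)
    """
    if N < 2:
        raise ValueError(f"need at least 2 substrates, got N={N}")
    ln_n = math.log(N)
    if P < -1e-12 or P > ln_n + 1e-9:
        raise ValueError(f"entropy {P} outside [0, ln {N}]")
    return min(max(P / ln_n, 0.0), 1.0) + 0.0  # +0.0 normalizes -0.0


def relative_promiscuity(I_m: float, I_wt: float) -> float:
    """I_rel = I_mutant / I_wildtype.

    Values above 1 mark mutants more promiscuous than the wild type,
    below 1 more specific ones.
    """
    if I_wt <= 0:
        raise ZeroDivisionError(
            "wild type is perfectly specific (I = 0); relative promiscuity undefined"
        )
    return I_m / I_wt


@dataclass(frozen=True)
class PromiscuityResult:
    """Promiscuity metrics of one variant."""

    variant: VariantId
    entropy_P: float
    index_I: float
    index_I_rel: float
    total_uM: float
    excluded_trace: bool = False


def promiscuity_result(
    variant: VariantId,
    p: np.ndarray,
    total_uM: float,
    I_wt: float,
    excluded_trace: bool = False,
) -> PromiscuityResult:
    """Compute entropy, index and relative index for one fraction vector."""
    P = shannon_entropy(p)
    I = promiscuity_index(P, len(p))
    return PromiscuityResult(
        variant=variant,
        entropy_P=P,
        index_I=I,
        index_I_rel=relative_promiscuity(I, I_wt),
        total_uM=total_uM,
        excluded_trace=excluded_trace,
    )


def rank_by_promiscuity(
    results: Sequence[PromiscuityResult],
) -> list[PromiscuityResult]:
    """Rank variants by promiscuity index, most promiscuous first.

    Variants flagged ``excluded_trace`` (below the 0.2 µM detection floor)
    are dropped.  Ties are broken by higher total activity, then by
    variant label, so the order is deterministic.
    """
    eligible = [r for r in results if not r.excluded_trace]
    return sorted(
        eligible,
        key=lambda r: (-r.index_I, -r.total_uM, r.variant.label),
    )
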