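"""Degenerate-codon arithmetic and mutant-library statistics.

Site-saturation libraries are built from degenerate codons such as NNK
(N = A/C/G/T, K = G/T), which encodes all 20 amino acids in 32 codons with
a single stop (TAG).  This module expands IUPAC triplets against the
standard genetic code, computes combinatorial library sizes, oligo mixing
ratios, and colony-coverage statistics for deciding how many colonies to
screen per library.

Two notions of "coverage" at n screened colonies are exposed:

- :func:`coverage` — the expected fraction of the amino acids observed,
  mean over residues a of 1 - (1 - k_a/32)^n (the usual screening
  heuristic; ~96.7% for NNK at n = 92);
- :func:`complete_coverage_probability` — the probability that *every*
  amino acid is observed, which is considerably lower at the same n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import comb
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Data.IUPACData import ambiguous_dna_values

STANDARD_CODE = unambiguous_dna_by_id[1]
STOP = "*"


@dataclass(frozen=True)
class DegenerateCodon:
    """A degenerate (IUPAC) codon and its expansion.

    ``aa_counts`` maps each encoded amino acid (or ``"*"`` for stop) to
    the number of codons encoding it; the counts sum to the size of the
    codon set.
    """

    triplet: str
    codon_set: tuple[str, ...]
    aa_counts: dict[str, int]

    @property
    def n_codons(self) -> int:
        return len(self.codon_set)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(a for a in self.aa_counts if a != STOP))

    @property
    def n_stop_codons(self) -> int:
        return self.aa_counts.get(STOP, 0)


def expand_degenerate(triplet: str, code=STANDARD_CODE) -> DegenerateCodon:
    """Expand an IUPAC triplet into codons and translate them.

    >>> nnk = expand_degenerate("NNK")
    >>> nnk.n_codons, len(nnk.amino_acids), nnk.n_stop_codons
    (32, 20, 1)
    """
    triplet = triplet.strip().upper()
    if len(triplet) != 3:
        raise ValueError(f"codon must have 3 letters, got {triplet!r}")
    expansions = []
    for letter in triplet:
        if letter not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC nucleotide {letter!r} in {triplet!r}")
        expansions.append(ambiguous_dna_values[letter])
    codons = tuple("".join(bases) for bases in product(*expansions))
    counts: dict[str, int] = {}
    for codon in codons:
        aa = STOP if codon in code.stop_codons else code.forward_table[codon]
        counts[aa] = counts.get(aa, 0) + 1
    return DegenerateCodon(triplet=triplet, codon_set=codons, aa_counts=counts)


NNK = expand_degenerate("NNK")


@dataclass(frozen=True)
class LibrarySite:
    """One randomized position with its allowed residue set."""

    position: int
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"position {self.position}: empty residue set")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError(f"position {self.position}: duplicate residues")


@dataclass(frozen=True)
class LibraryDesign:
    """A multi-site combinatorial library of protein variants."""

    sites: tuple[LibrarySite, ...]

    @property
    def size(self) -> int:
        return library_size(self)


def library_size(design: LibraryDesign) -> int:
    """Number of distinct protein variants: product of residue-set sizes.

    E.g. residue sets of sizes 5, 6 and 7 at three positions combine to a
    library of 210 triple mutants.
    """
    if not design.sites:
        raise ValueError("design has no sites")
    size = 1
    for site in design.sites:
        size *= len(site.residues)
    return size


def count_point_mutants(n_positions: int, alphabet: int = 20) -> int:
    """Number of single point mutants over ``n_positions`` saturated sites.

    Each position admits ``alphabet - 1`` substitutions, so full
    saturation of 15 positions yields 15 x 19 = 285 point mutations.
    """
    if n_positions < 1:
        raise ValueError("need at least one position")
    return n_positions * (alphabet - 1)


def mix_ratios(oligos: Sequence[tuple[str, int]]) -> list[tuple[str, float]]:
    """Mixing fractions of degenerate oligos, proportional to codon counts.

    When a residue set is covered by several degenerate oligos, combining
    them in ratios reflecting the number of codons each contributes keeps
    every codon equiprobable in the pooled library.
    """
    for oid, count in oligos:
        if count < 1:
            raise ValueError(f"oligo {oid!r}: codon count must be >= 1")
    total = sum(count for _, count in oligos)
    return [(oid, count / total) for oid, count in oligos]


def coverage(
    n_colonies: int,
    codon: DegenerateCodon = NNK,
    mode: str = "analytic",
    reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Expected fraction of amino acids observed among ``n_colonies``.

    Colonies are drawn uniformly over the codon set; stop-codon draws
    consume a colony but cover no amino acid.  Analytic mode evaluates
    mean_a [1 - (1 - k_a/m)^n]; simulate mode averages the observed
    fraction over ``reps`` Monte-Carlo screens.
    """
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    aa_counts = {a: c for a, c in codon.aa_counts.items() if a != STOP}
    m = codon.n_codons
    if mode == "analytic":
        probs = [1.0 - (1.0 - k / m) ** n_colonies for k in aa_counts.values()]
        return float(np.mean(probs))
    if mode == "simulate":
        if reps < 1:
            raise ValueError("reps must be >= 1 in simulate mode")
        rng = np.random.default_rng(seed)
        aa_list = sorted(aa_counts)
        if not aa_list:
            return 0.0
        aa_index = {a: i for i, a in enumerate(aa_list)}
        # codon -> amino-acid index lookup table; stops map to -1
        lut = np.array(
            [aa_index.get(_aa(c, codon), -1) for c in codon.codon_set]
        )
        draws = lut[rng.integers(0, m, size=(reps, n_colonies))]
        seen = np.zeros((reps, len(aa_list)), dtype=bool)
        rows = np.repeat(np.arange(reps), n_colonies)
        flat = draws.ravel()
        keep = flat >= 0
        seen[rows[keep], flat[keep]] = True
        return float(seen.mean(axis=1).mean())
    raise ValueError(f"unknown mode {mode!r}")


def _aa(codon_str: str, codon: DegenerateCodon) -> str:
    if codon_str in STANDARD_CODE.stop_codons:
        return STOP
    return STANDARD_CODE.forward_table[codon_str]


def complete_coverage_probability(
    n_colonies: int, codon: DegenerateCodon = NNK
) -> float:
    """Probability that all amino acids of the codon are seen in n colonies.

    Computed by inclusion-exclusion over the missed amino acids, grouping
    residues by their codon multiplicity so the sum stays small.
    """
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    m = codon.n_codons
    # group amino acids by codon count: {count: number of amino acids}
    groups: dict[int, int] = {}
    for a, k in codon.aa_counts.items():
        if a == STOP:
            continue
        groups[k] = groups.get(k, 0) + 1
    counts = sorted(groups)
    sizes = [groups[k] for k in counts]
    prob = 0.0
    for chosen in product(*[range(s + 1) for s in sizes]):
        sign = (-1) ** sum(chosen)
        ways = 1
        missed_codons = 0
        for j, c in enumerate(chosen):
            ways *= comb(sizes[j], c)
            missed_codons += c * counts[j]
        prob += sign * ways * (1.0 - missed_codons / m) ** n_colonies
    return float(min(max(prob, 0.0), 1.0))


def coverage_curve(
    n_max: int,
    codon: DegenerateCodon = NNK,
) -> list[tuple[int, float, float]]:
    """(n, expected coverage, complete-coverage probability) for n = 0..n_max."""
    return [
        (n, coverage(n, codon), complete_coverage_probability(n, codon))
        for n in range(n_max + 1)
    ]
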