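"""Synthetic HAMA screens with known ground truth.

Emulates the statistical structure of a plate-based saturation-mutagenesis
specificity screen so that every analysis stage can be exercised against a
known answer:

- colonies are drawn per library by NNK codon sampling, so replicate
  counts per mutant are multinomial and stop codons yield inactive wells;
- each mutant's true substrate profile is drawn from a Dirichlet
  distribution centred on the parent (wild-type) profile; planted
  "specificity switch" mutants override this with a target profile;
- true total activity is lognormal around the wild-type total, with a
  configurable fraction of completely inactive mutants;
- observed concentrations carry a multiplicative per-batch (plate) effect,
  multiplicative per-channel measurement noise, and detection-limit
  censoring (sub-LOD channels report 0, as MRM quantification does);
- each 96-well plate holds 88 library wells plus 4 wild-type and 4
  negative-control wells.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .divergence import SCREEN_PARENT_RESIDUES
from .io import NEG_TOKEN, WT_TOKEN, VariantId, WellMeasurement
from .libdesign import NNK, STANDARD_CODE, STOP
from .panel import DEFAULT_PANEL, SubstratePanel


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


#: default parent (VSA-like) substrate profile: a multispecific enzyme
#: with major activities for Phe, Met and Leu and high side activities
#: for Trp and Tyr; minor channels keep the profile strictly positive.
_DEFAULT_WT_WEIGHTS = {
    "l-Phe-d5": 0.30,
    "l-Met": 0.24,
    "l-Leu-d7": 0.20,
    "l-Trp": 0.12,
    "l-Tyr": 0.08,
    "l-Cys": 0.03,
    "l-Ile": 0.02,
    "d-Phe": 0.01,
}
_WT_PROFILE_FLOOR = 1e-4


def default_wt_profile(panel: SubstratePanel = DEFAULT_PANEL) -> np.ndarray:
    """Multispecific parent profile on the given panel (unit sum)."""
    p = np.full(len(panel), _WT_PROFILE_FLOOR)
    for sub, w in _DEFAULT_WT_WEIGHTS.items():
        if sub in panel:
            p[panel.index(sub)] = w
    return p / p.sum()


@dataclass(frozen=True)
class PlantedSwitch:
    """A mutant planted with a known specificity change."""

    position: int
    mut_residue: str
    profile: np.ndarray  # true substrate-fraction vector
    activity_multiplier: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "profile", np.asarray(self.profile, dtype=float))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a simulated saturation-mutagenesis screen.

    Defaults mirror the screening format the analysis is built for: 15
    randomized binding-pocket positions, 92 colonies per NNK library
    (expected amino-acid coverage ~97%), 96-well plates with 4 positive
    and 4 negative control wells each, and per-batch wild-type
    normalization.

    Parameters
    ----------
    dirichlet_alpha:
        Total concentration of the Dirichlet from which non-planted
        mutant profiles are drawn (``alpha_i = dirichlet_alpha * wt_i``).
        The default 50 keeps most mutants close to the parent profile,
        matching the observation that most single substitutions leave
        specificity broadly unchanged.
    activity_lognormal_sigma:
        Log-scale spread of true mutant totals around the wild type;
        1.0 spans roughly two orders of magnitude, as point mutations in
        a binding pocket commonly do.
    noise_cv:
        Coefficient of variation of the per-channel multiplicative
        measurement noise (0.2 = 20%, a typical plate-assay technical CV).
    batch_sigma:
        Log-scale spread of the per-plate expression/batch multiplier.
    lod_uM:
        Detection limit; observed channels below it report 0 µM.
    inactive_prob:
        Probability that a (non-planted) mutant is completely inactive,
        in addition to stop codons; 0.3 reproduces the roughly one third
        of point mutants falling below 1% of wild-type activity.
    """

    seed: int = 0
    panel: SubstratePanel = field(default_factory=SubstratePanel.default)
    positions: tuple[int, ...] = tuple(sorted(SCREEN_PARENT_RESIDUES))
    parent_residues: dict[int, str] = field(
        default_factory=lambda: dict(SCREEN_PARENT_RESIDUES)
    )
    n_colonies_per_library: int = 92
    wt_profile: np.ndarray | None = None
    wt_total_uM: float = 10.0
    dirichlet_alpha: float = 50.0
    activity_lognormal_sigma: float = 1.0
    noise_cv: float = 0.2
    batch_sigma: float = 0.3
    lod_uM: float = 0.02
    inactive_prob: float = 0.3
    planted_switches: tuple[PlantedSwitch, ...] = ()
    wells_per_plate: int = 96
    n_wt_controls: int = 4
    n_neg_controls: int = 4

    def resolved_wt_profile(self) -> np.ndarray:
        if self.wt_profile is not None:
            p = np.asarray(self.wt_profile, dtype=float)
            return p / p.sum()
        return default_wt_profile(self.panel)

    def validate(self) -> None:
        problems = []
        if self.n_colonies_per_library < 1:
            problems.append("n_colonies_per_library must be >= 1")
        if not self.positions:
            problems.append("positions must be non-empty")
        for pos in self.positions:
            if pos not in self.parent_residues:
                problems.append(f"no parent residue for position {pos}")
        if self.wt_total_uM <= 0:
            problems.append("wt_total_uM must be > 0")
        for name in ("dirichlet_alpha", "activity_lognormal_sigma"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        for name in ("noise_cv", "batch_sigma", "lod_uM"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not (0 <= self.inactive_prob <= 1):
            problems.append("inactive_prob must be in [0, 1]")
        wt_p = self.resolved_wt_profile()
        if np.any(wt_p < 0):
            problems.append("wt_profile must be non-negative")
        if len(wt_p) != len(self.panel):
            problems.append("wt_profile length does not match panel")
        for sw in self.planted_switches:
            if sw.position not in self.positions:
                problems.append(f"planted switch at unscreened position {sw.position}")
            if len(sw.profile) != len(self.panel):
                problems.append(
                    f"planted profile at {sw.position}{sw.mut_residue} has wrong length"
                )
            if sw.activity_multiplier <= 0:
                problems.append("planted activity_multiplier must be > 0")
        if self.n_wt_controls < 0 or self.n_neg_controls < 0:
            problems.append("control well counts must be >= 0")
        if self.wells_per_plate <= self.n_wt_controls + self.n_neg_controls:
            problems.append("plate too small for the control wells")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one simulated well."""

    plate_id: str
    well: str
    variant_label: str
    position: int | None  # None for control wells
    codon: str | None
    true_p: np.ndarray
    true_total_uM: float
    activity_multiplier: float
    inactive: bool


@dataclass
class GroundTruth:
    """All ground-truth records of one simulated screen."""

    records: list[TruthRecord]
    wt_profile: np.ndarray
    wt_total_uM: float
    config: SyntheticConfig

    def variant_truth(self) -> dict[str, TruthRecord]:
        """First truth record per variant label (identical across wells)."""
        out: dict[str, TruthRecord] = {}
        for r in self.records:
            out.setdefault(r.variant_label, r)
        return out

    def replicate_counts(self) -> dict[str, int]:
        """Number of library wells per variant label (controls excluded)."""
        counts: dict[str, int] = {}
        for r in self.records:
            if r.position is not None:
                counts[r.variant_label] = counts.get(r.variant_label, 0) + 1
        return counts


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGH"
    names = [f"{r}{c}" for r in rows for c in range(1, 13)]
    if n > len(names):  # plates beyond 96 wells: synthesize extra names
        names = [f"{r}{c}" for r in rows for c in range(1, n // 8 + 2)]
    return names[:n]


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def simulate_screen(
    config: SyntheticConfig,
) -> tuple[list[WellMeasurement], GroundTruth]:
    """Simulate a full multi-plate NNK screen.

    Returns the plate table (list of wells) and the ground truth for every
    well.  Colonies of each library are laid out sequentially over plates
    of 88 library wells; each plate also carries its own wild-type and
    negative-control wells and acts as one batch.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    wt_p = config.resolved_wt_profile()
    n_sub = len(panel)

    planted = {
        (sw.position, sw.mut_residue): sw for sw in config.planted_switches
    }

    # -- draw per-variant ground truth lazily as variants appear ----------
    variant_truth: dict[str, tuple[np.ndarray, float, float, bool]] = {}

    def truth_for(label: str, position: int, aa: str):
        if label in variant_truth:
            return variant_truth[label]
        if aa == STOP:
            p = np.zeros(n_sub)
            t = (p, 0.0, 0.0, True)
        elif label == WT_TOKEN:
            t = (wt_p.copy(), config.wt_total_uM, 1.0, False)
        elif (position, aa) in planted:
            sw = planted[(position, aa)]
            prof = sw.profile / sw.profile.sum()
            t = (prof, config.wt_total_uM * sw.activity_multiplier,
                 sw.activity_multiplier, False)
        else:
            alpha = config.dirichlet_alpha * wt_p
            prof = rng.dirichlet(alpha)
            if rng.random() < config.inactive_prob:
                t = (np.zeros(n_sub), 0.0, 0.0, True)
            else:
                mult = float(
                    rng.lognormal(mean=0.0, sigma=config.activity_lognormal_sigma)
                )
                t = (prof, config.wt_total_uM * mult, mult, False)
        variant_truth[label] = t
        return t

    # -- draw the colony sequence (library wells) -------------------------
    codon_list = NNK.codon_set
    library_colonies: list[tuple[int, str, str]] = []  # (position, codon, label)
    for pos in config.positions:
        parent = config.parent_residues[pos]
        for _ in range(config.n_colonies_per_library):
            codon = codon_list[rng.integers(0, len(codon_list))]
            aa = STOP if codon in STANDARD_CODE.stop_codons else (
                STANDARD_CODE.forward_table[codon]
            )
            if aa == parent:
                label = WT_TOKEN  # synonymous clone: parent enzyme
            elif aa == STOP:
                label = f"{parent}{pos}*"
            else:
                label = str(VariantId(position=pos, wt_residue=parent, mut_residue=aa))
            library_colonies.append((pos, codon, label))

    # -- lay out plates ----------------------------------------------------
    n_library_wells = (
        config.wells_per_plate - config.n_wt_controls - config.n_neg_controls
    )
    wells: list[WellMeasurement] = []
    truth_records: list[TruthRecord] = []
    n_plates = max(1, int(np.ceil(len(library_colonies) / n_library_wells)))

    colony_iter = iter(library_colonies)
    for plate_idx in range(n_plates):
        plate_id = f"P{plate_idx + 1:02d}"
        batch_mult = float(rng.lognormal(mean=0.0, sigma=config.batch_sigma))
        names = _well_names(config.wells_per_plate)
        plate_slots: list[tuple[str, str, int | None, str | None]] = []
        for i in range(config.n_wt_controls):
            plate_slots.append((names[i], WT_TOKEN, None, None))
        body = names[config.n_wt_controls:
                     config.n_wt_controls + n_library_wells]
        for name in body:
            try:
                pos, codon, label = next(colony_iter)
            except StopIteration:
                break
            plate_slots.append((name, label, pos, codon))
        for i in range(config.n_neg_controls):
            plate_slots.append(
                (names[config.wells_per_plate - config.n_neg_controls + i],
                 NEG_TOKEN, None, None)
            )

        rep_counter: dict[str, int] = {}
        for name, label, pos, codon in plate_slots:
            if label == NEG_TOKEN:
                true_p = np.zeros(n_sub)
                true_total, mult, inactive = 0.0, 0.0, True
            else:
                aa = None
                if codon is not None:
                    aa = STOP if codon in STANDARD_CODE.stop_codons else (
                        STANDARD_CODE.forward_table[codon]
                    )
                true_p, true_total, mult, inactive = truth_for(
                    label, pos if pos is not None else -1,
                    aa if aa is not None else label,
                )
            conc_true = true_p * true_total
            noise = _lognormal_noise(rng, config.noise_cv, n_sub)
            conc_obs = conc_true * batch_mult * noise
            conc_obs = np.where(conc_obs < config.lod_uM, 0.0, conc_obs)
            rep_counter[label] = rep_counter.get(label, 0) + 1
            wells.append(
                WellMeasurement(
                    plate_id=plate_id,
                    well=name,
                    variant_label=label,
                    batch_id=plate_id,
                    replicate=rep_counter[label],
                    conc=conc_obs,
                    panel=panel,
                )
            )
            truth_records.append(
                TruthRecord(
                    plate_id=plate_id,
                    well=name,
                    variant_label=label,
                    position=pos,
                    codon=codon,
                    true_p=true_p,
                    true_total_uM=true_total,
                    activity_multiplier=mult,
                    inactive=inactive,
                )
            )

    truth = GroundTruth(
        records=truth_records,
        wt_profile=wt_p,
        wt_total_uM=config.wt_total_uM,
        config=config,
    )
    return wells, truth
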