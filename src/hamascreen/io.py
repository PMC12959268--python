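"""Plate-table I/O and variant nomenclature for HAMA screens.

Screens are recorded as delimited tables with one concentration column per
panel substrate (wide layout) or one row per well x substrate (long
layout).  Variants are labelled with the usual substitution nomenclature
``<wt><position><mut>`` (e.g. ``G728M``); the reserved tokens ``WT`` and
``NEG`` mark positive (parent enzyme) and negative (disrupted adenylation
domain) control wells.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import SubstratePanel

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residue codes accepted in mutant labels; '*' marks an amber stop codon
#: picked up when sequencing NNK libraries (such clones make no protein)
MUTANT_RESIDUES = AMINO_ACIDS | {"*"}

WT_TOKEN = "WT"
NEG_TOKEN = "NEG"

METADATA_COLUMNS = ("plate_id", "well", "variant_label", "batch_id", "replicate")
LONG_COLUMNS = METADATA_COLUMNS + ("substrate", "conc_uM")

_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z*])$")


class VariantLabelError(ValueError):
    """Raised for malformed or non-amino-acid variant labels."""


class SchemaError(ValueError):
    """Raised when a plate table's columns do not match the panel."""


class PanelMismatchError(ValueError):
    """Raised when records from different panels are mixed."""


@dataclass(frozen=True, order=True)
class VariantId:
    """Structured identity of a point mutant (or the wild type)."""

    position: int
    wt_residue: str
    mut_residue: str
    is_wildtype: bool = False

    def __post_init__(self) -> None:
        if self.is_wildtype:
            return
        if self.wt_residue not in AMINO_ACIDS:
            raise VariantLabelError(f"unknown wild-type residue {self.wt_residue!r}")
        if self.mut_residue not in MUTANT_RESIDUES:
            raise VariantLabelError(f"unknown mutant residue {self.mut_residue!r}")
        if self.position < 1:
            raise VariantLabelError(f"position must be positive, got {self.position}")
        if self.wt_residue == self.mut_residue:
            raise VariantLabelError(
                f"synonymous label {self.wt_residue}{self.position}{self.mut_residue}: "
                "use 'WT' for the parent enzyme"
            )

    @classmethod
    def wildtype(cls) -> "VariantId":
        return cls(position=0, wt_residue="", mut_residue="", is_wildtype=True)

    @property
    def is_stop(self) -> bool:
        return self.mut_residue == "*"

    @property
    def label(self) -> str:
        if self.is_wildtype:
            return WT_TOKEN
        return f"{self.wt_residue}{self.position}{self.mut_residue}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_variant_label(label: str) -> VariantId:
    """Parse ``"G728M"``-style labels; ``"WT"`` maps to the wild-type sentinel.

    Raises
    ------
    VariantLabelError
        If the label is malformed or uses a letter outside the 20-residue
        alphabet (plus ``*`` for stop codons on the mutant side).
    """
    token = label.strip()
    if token.upper() == WT_TOKEN:
        return VariantId.wildtype()
    m = _LABEL_RE.match(token)
    if m is None:
        raise VariantLabelError(f"malformed variant label {label!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return VariantId(position=pos, wt_residue=wt, mut_residue=mut)


def format_variant_label(variant: VariantId) -> str:
    """Inverse of :func:`parse_variant_label`."""
    return variant.label


@dataclass(frozen=True)
class WellMeasurement:
    """Raw hydroxamate concentrations of one well.

    ``conc`` is a µM vector aligned to ``panel``; entries are >= 0 (a zero
    means no signal, i.e. below the detection limit of the LC-MS/MS
    method).
    """

    plate_id: str
    well: str
    variant_label: str
    batch_id: str
    replicate: int
    conc: np.ndarray
    panel: SubstratePanel

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        object.__setattr__(self, "conc", conc)
        if conc.shape != (len(self.panel),):
            raise PanelMismatchError(
                f"well {self.well}: {conc.shape[0]} concentrations for a "
                f"{len(self.panel)}-substrate panel"
            )
        if np.any(conc < 0):
            raise ValueError(f"well {self.well}: negative concentration")
        if self.replicate < 1:
            raise ValueError(f"well {self.well}: replicate must be >= 1")

    @property
    def is_wt_control(self) -> bool:
        return self.variant_label.strip().upper() == WT_TOKEN

    @property
    def is_neg_control(self) -> bool:
        return self.variant_label.strip().upper() == NEG_TOKEN

    @property
    def total(self) -> float:
        return float(self.conc.sum())


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _wells_from_wide(
    df: pd.DataFrame, panel: SubstratePanel, strict: bool, source: str
) -> list[WellMeasurement]:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing metadata columns {missing}")
    extra = [c for c in df.columns if c not in METADATA_COLUMNS and c not in panel.ids]
    if extra:
        raise SchemaError(f"{source}: unknown substrate columns {extra}")
    missing_sub = [s for s in panel.ids if s not in df.columns]
    if missing_sub:
        raise SchemaError(f"{source}: missing substrate columns {missing_sub}")

    wells: list[WellMeasurement] = []
    for idx, row in df.iterrows():
        conc = np.array([row[s] for s in panel.ids], dtype=float)
        nan = np.isnan(conc)
        if nan.any():
            if strict:
                raise ValueError(f"{source}: missing concentration in row {idx}")
            logger.warning(
                "%s: row %s has %d missing concentrations, read as 0 uM "
                "(below detection limit)", source, idx, int(nan.sum())
            )
            conc = np.where(nan, 0.0, conc)
        if np.any(conc < 0):
            raise ValueError(f"{source}: negative concentration in row {idx}")
        wells.append(
            WellMeasurement(
                plate_id=str(row["plate_id"]),
                well=str(row["well"]),
                variant_label=str(row["variant_label"]),
                batch_id=str(row["batch_id"]),
                replicate=int(row["replicate"]),
                conc=conc,
                panel=panel,
            )
        )
    return wells


def _wells_from_long(
    df: pd.DataFrame, panel: SubstratePanel, strict: bool, source: str
) -> list[WellMeasurement]:
    unknown = sorted(set(df["substrate"]) - set(panel.ids))
    if unknown:
        raise SchemaError(f"{source}: unknown substrates {unknown}")
    key_cols = list(METADATA_COLUMNS)
    wide = df.pivot_table(
        index=key_cols, columns="substrate", values="conc_uM", aggfunc="first",
        sort=False,
    ).reset_index()
    for s in panel.ids:
        if s not in wide.columns:
            wide[s] = np.nan
    return _wells_from_wide(wide[key_cols + list(panel.ids)], panel, strict, source)


def read_plate_table(
    path: str | Path,
    panel: SubstratePanel,
    *,
    strict: bool = False,
    exclude_wells: Iterable[tuple[str, str]] | None = None,
) -> list[WellMeasurement]:
    """Read a plate table (CSV or TSV, wide or long layout auto-detected).

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    panel:
        Substrate panel the concentration columns must match.
    strict:
        If true, missing concentration cells raise instead of being read
        as 0 µM (no signal).
    exclude_wells:
        Optional ``(plate_id, well)`` pairs to drop, e.g. wells that
        failed sequencing.
    """
    df = _read_delimited(path)
    source = str(path)
    if "substrate" in df.columns and "conc_uM" in df.columns:
        wells = _wells_from_long(df, panel, strict, source)
    else:
        wells = _wells_from_wide(df, panel, strict, source)
    if exclude_wells:
        drop = {(str(p), str(w)) for p, w in exclude_wells}
        wells = [w for w in wells if (w.plate_id, w.well) not in drop]
    return wells


def write_plate_table(wells: Sequence[WellMeasurement], path: str | Path) -> None:
    """Write wells as a wide-layout CSV (the inverse of :func:`read_plate_table`)."""
    if not wells:
        raise ValueError("no wells to write")
    panel = wells[0].panel
    for w in wells:
        if w.panel.ids != panel.ids:
            raise PanelMismatchError("wells from different panels")
    rows = []
    for w in wells:
        row = {
            "plate_id": w.plate_id,
            "well": w.well,
            "variant_label": w.variant_label,
            "batch_id": w.batch_id,
            "replicate": w.replicate,
        }
        row.update(dict(zip(panel.ids, w.conc)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class VariantMetrics:
    """Per-variant summary row of the analysis pipeline.

    Column dictionary (CSV output):

    - ``variant_label``: substitution label or ``WT``
    - ``n_replicates``: wells averaged into the profile
    - ``total_uM``: mean total hydroxamate concentration (µM)
    - ``a_rel``: total activity relative to the batch wild type
    - ``entropy_P``: Shannon entropy of the substrate profile (nats)
    - ``index_I``: promiscuity index in [0, 1]
    - ``index_I_rel``: promiscuity relative to the wild type
    - ``jsd_to_wt``: Jensen-Shannon distance to the wild-type profile
    - ``below_floor``: total activity < 1% of wild type
    - ``below_trace``: total hydroxamates < 0.2 µM
    - ``significant``: JSD above the wild-type null threshold
    """

    variant_label: str
    n_replicates: int
    total_uM: float
    a_rel: float
    entropy_P: float
    index_I: float
    index_I_rel: float
    jsd_to_wt: float
    below_floor: bool
    below_trace: bool
    significant: bool
    panel: SubstratePanel = field(default_factory=SubstratePanel.default, compare=False)


_METRIC_COLUMNS = [
    "variant_label", "n_replicates", "total_uM", "a_rel", "entropy_P",
    "index_I", "index_I_rel", "jsd_to_wt", "below_floor", "below_trace",
    "significant",
]


def write_metrics_table(records: Sequence[VariantMetrics], path: str | Path) -> None:
    """Write variant metrics as CSV, one row per variant.

    Floats are written with 17 significant digits, so reading the file
    back reproduces the exact binary values.
    """
    panels = {r.panel.ids for r in records}
    if len(panels) > 1:
        raise PanelMismatchError("metrics records come from different panels")
    rows = [{c: getattr(r, c) for c in _METRIC_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=_METRIC_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_metrics_table(
    path: str | Path, panel: SubstratePanel | None = None
) -> list[VariantMetrics]:
    """Read back a metrics CSV written by :func:`write_metrics_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    panel = panel or SubstratePanel.default()
    records = []
    for _, row in df.iterrows():
        records.append(
            VariantMetrics(
                variant_label=str(row["variant_label"]),
                n_replicates=int(row["n_replicates"]),
                total_uM=float(row["total_uM"]),
                a_rel=float(row["a_rel"]),
                entropy_P=float(row["entropy_P"]),
                index_I=float(row["index_I"]),
                index_I_rel=float(row["index_I_rel"]),
                jsd_to_wt=float(row["jsd_to_wt"]),
                below_floor=bool(row["below_floor"]),
                below_trace=bool(row["below_trace"]),
                significant=bool(row["significant"]),
                panel=panel,
            )
        )
    return records
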