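"""Substrate panel definition for hydroxamate (HAMA) specificity assays.

A HAMA reaction presents a mixture of amino-acid substrates to an
adenylation domain and quantifies the hydroxamate formed from every
substrate at once.  The panel fixes the identity and order of the assayed
substrates; every concentration vector in a run is aligned to it.

The default panel holds the 19 substrates of the standard competition mix:
17 proteinogenic amino acids plus the two D-configured substrates d-Phe and
d-Val.  Three substrates are supplied as deuterated standards (l-Leu-d7,
l-Phe-d5, l-Val-d8) so that they can be distinguished by mass from their
isobaric or enantiomeric counterparts (l-Ile, d-Phe, d-Val).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Substrate:
    """One assayed amino-acid substrate.

    Attributes
    ----------
    id:
        Panel identifier, e.g. ``"l-Leu-d7"``.
    letter:
        One-letter code of the amino acid backbone (stereochemistry and
        isotope label ignored), e.g. ``"L"``.
    enantiomer:
        ``"L"`` or ``"D"``.
    isotope:
        Deuterium label (``""``, ``"d5"``, ``"d7"`` or ``"d8"``).
    """

    id: str
    letter: str
    enantiomer: str = "L"
    isotope: str = ""

    def __post_init__(self) -> None:
        if self.enantiomer not in ("L", "D"):
            raise ValueError(f"enantiomer must be 'L' or 'D', got {self.enantiomer!r}")


_DEFAULT_SUBSTRATES = (
    Substrate("l-Ala", "A"),
    Substrate("l-Arg", "R"),
    Substrate("l-Asp", "D"),
    Substrate("l-Cys", "C"),
    Substrate("l-Glu", "E"),
    Substrate("l-Gly", "G"),
    Substrate("l-His", "H"),
    Substrate("l-Ile", "I"),
    Substrate("l-Lys", "K"),
    Substrate("l-Met", "M"),
    Substrate("d-Phe", "F", enantiomer="D"),
    Substrate("l-Pro", "P"),
    Substrate("l-Thr", "T"),
    Substrate("l-Trp", "W"),
    Substrate("l-Tyr", "Y"),
    Substrate("d-Val", "V", enantiomer="D"),
    Substrate("l-Val-d8", "V", isotope="d8"),
    Substrate("l-Phe-d5", "F", isotope="d5"),
    Substrate("l-Leu-d7", "L", isotope="d7"),
)


@dataclass(frozen=True)
class SubstratePanel:
    """Ordered, immutable list of assayed substrates.

    The panel length ``N`` is the number of measured hydroxamates; the
    default panel has ``N = 19``.
    """

    substrates: tuple[Substrate, ...] = field(default=_DEFAULT_SUBSTRATES)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.substrates]
        if len(set(ids)) != len(ids):
            raise ValueError("substrate ids must be unique")
        if not ids:
            raise ValueError("panel must contain at least one substrate")

    @classmethod
    def default(cls) -> "SubstratePanel":
        """The standard 19-substrate competition panel."""
        return cls()

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.substrates)

    def __len__(self) -> int:
        return len(self.substrates)

    def index(self, substrate_id: str) -> int:
        """Position of ``substrate_id`` in the panel order."""
        try:
            return self.ids.index(substrate_id)
        except ValueError:
            raise KeyError(f"substrate {substrate_id!r} not in panel") from None

    def __contains__(self, substrate_id: str) -> bool:
        return substrate_id in self.ids


DEFAULT_PANEL = SubstratePanel.default()
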