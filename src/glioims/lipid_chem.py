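"""Sum-composition lipid chemistry: formulas, monoisotopic masses, adduct m/z,
and ppm-tolerance annotation of observed peaks against a lipid panel.

Species are identified at the sum-composition level (class plus total chain
carbons:double bonds, e.g. ``PI 38:4``), which is the resolution MALDI imaging
provides without on-tissue fragmentation. Plasmalogen PE (``PE P-``) is its
own class carrying the sn-1 vinyl-ether linkage; the double-bond count in the
shorthand excludes that vinyl ether, following common usage. Sphingolipids
carry a ``d``/``t`` prefix for di-/tri-hydroxylated sphingoid bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import (
    MONOISOTOPIC_MASS,
    POTASSIUM_CATION_MASS,
    PROTON_MASS,
    SODIUM_CATION_MASS,
)

__all__ = [
    "LipidClass",
    "Hydroxylation",
    "LipidSpecies",
    "Adduct",
    "Annotation",
    "Panel",
    "PanelEntry",
    "UnsupportedSpeciesError",
    "formula_of",
    "monoisotopic_mass",
    "theoretical_mz",
    "parse_shorthand",
    "build_panel",
    "load_panel",
    "default_panel",
    "annotate",
    "annotations_to_table",
]


class UnsupportedSpeciesError(ValueError):
    """Raised for class/hydroxylation/chain combinations with no formula rule."""


class LipidClass(str, Enum):
    PE = "PE"
    PE_P = "PE P-"
    PC = "PC"
    PI = "PI"
    PS = "PS"
    PG = "PG"
    SM = "SM"
    SULF = "Sulf"
    HEXCER = "HexCer"
    CER = "Cer"
    DG = "DG"
    TG = "TG"


class Hydroxylation(str, Enum):
    NONE = "none"
    D = "d"     # dihydroxy sphingoid base
    T = "t"     # trihydroxy sphingoid base


SPHINGOLIPID_CLASSES = frozenset(
    {LipidClass.SM, LipidClass.SULF, LipidClass.HEXCER, LipidClass.CER}
)

# classes detected in negative-ion mode as [M-H]-; the rest are positive-mode
NEGATIVE_MODE_CLASSES = frozenset(
    {LipidClass.PE, LipidClass.PE_P, LipidClass.PI, LipidClass.PS,
     LipidClass.PG, LipidClass.SULF}
)
POSITIVE_MODE_CLASSES = frozenset(LipidClass) - NEGATIVE_MODE_CLASSES

MIN_TOTAL_CARBONS = 20

# Closed-form sum-composition arithmetic per class. With total chain carbons C
# and chain double bonds D, the neutral molecule is
#   C_{C + carbon_offset} H_{2C - 2D + h_offset} + fixed heteroatoms.
# Derived by condensing the backbone (glycerophosphate + head group, or a
# sphingoid base) with the chains; the PE P- rule reflects the vinyl-ether
# sn-1 linkage (one ester oxygen fewer, two H more than the diacyl isobar).
# Sphingolipid D counts the sphingoid 4,5-ene; `t` bases add one oxygen.
_FORMULA_RULES: dict[LipidClass, tuple[int, int, dict[str, int]]] = {
    LipidClass.PC: (8, 16, {"N": 1, "O": 8, "P": 1}),
    LipidClass.PE: (5, 10, {"N": 1, "O": 8, "P": 1}),
    LipidClass.PE_P: (5, 10, {"N": 1, "O": 7, "P": 1}),
    LipidClass.PI: (9, 15, {"O": 13, "P": 1}),
    LipidClass.PS: (6, 10, {"N": 1, "O": 10, "P": 1}),
    LipidClass.PG: (6, 11, {"O": 10, "P": 1}),
    LipidClass.SM: (5, 13, {"N": 2, "O": 6, "P": 1}),
    LipidClass.CER: (0, 1, {"N": 1, "O": 3}),
    LipidClass.HEXCER: (6, 11, {"N": 1, "O": 8}),
    LipidClass.SULF: (6, 11, {"N": 1, "O": 11, "S": 1}),
    LipidClass.DG: (3, 4, {"O": 5}),
    LipidClass.TG: (3, 2, {"O": 6}),
}


@dataclass(frozen=True, order=True)
class LipidSpecies:
    """A sum-composition lipid species (no sn-1/sn-2 chain resolution)."""

    lipid_class: LipidClass
    total_carbons: int
    double_bonds: int
    hydroxylation: Hydroxylation = Hydroxylation.NONE

    def __post_init__(self) -> None:
        cls = self.lipid_class
        if self.total_carbons < MIN_TOTAL_CARBONS:
            raise UnsupportedSpeciesError(
                f"{cls.value} {self.total_carbons}:{self.double_bonds}: "
                f"total carbons below the supported minimum "
                f"({MIN_TOTAL_CARBONS})"
            )
        if not 0 <= self.double_bonds <= self.total_carbons // 2:
            raise UnsupportedSpeciesError(
                f"{cls.value}: double bonds {self.double_bonds} outside "
                f"[0, {self.total_carbons // 2}]"
            )
        if cls in SPHINGOLIPID_CLASSES:
            if self.hydroxylation is Hydroxylation.NONE:
                raise UnsupportedSpeciesError(
                    f"{cls.value}: sphingolipids require a d or t sphingoid "
                    f"base hydroxylation"
                )
        elif self.hydroxylation is not Hydroxylation.NONE:
            raise UnsupportedSpeciesError(
                f"{cls.value}: hydroxylation only applies to sphingolipids"
            )

    @property
    def shorthand(self) -> str:
        prefix = (
            self.hydroxylation.value
            if self.hydroxylation is not Hydroxylation.NONE
            else ""
        )
        return (
            f"{self.lipid_class.value}"
            f"{'' if self.lipid_class is LipidClass.PE_P else ' '}"
            f"{prefix}{self.total_carbons}:{self.double_bonds}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.shorthand


_SHORTHAND_RE = re.compile(
    r"^(?P<cls>PE P-|PE|PC|PI|PS|PG|SM|Sulf|HexCer|Cer|DG|TG)\s*"
    r"(?P<hydroxy>[dt]?)(?P<c>\d+):(?P<db>\d+)$"
)


def parse_shorthand(text: str) -> LipidSpecies:
    """Parse shorthand such as ``"PI 38:4"``, ``"PE P-36:2"``, ``"SM d36:1"``."""
    m = _SHORTHAND_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse lipid shorthand {text!r}")
    return LipidSpecies(
        lipid_class=LipidClass(m.group("cls")),
        total_carbons=int(m.group("c")),
        double_bonds=int(m.group("db")),
        hydroxylation=Hydroxylation(m.group("hydroxy") or "none"),
    )


class Adduct(Enum):
    """Adduct ion with its exact m/z shift relative to the neutral molecule."""

    M_MINUS_H = ("[M-H]-", "negative", -PROTON_MASS)
    M_PLUS_H = ("[M+H]+", "positive", PROTON_MASS)
    M_PLUS_NA = ("[M+Na]+", "positive", SODIUM_CATION_MASS)
    M_PLUS_K = ("[M+K]+", "positive", POTASSIUM_CATION_MASS)

    def __init__(self, label: str, polarity: str, mass_shift: float):
        self.label = label
        self.polarity = polarity
        self.mass_shift = mass_shift

    @classmethod
    def from_label(cls, label: str) -> "Adduct":
        for a in cls:
            if a.label == label:
                return a
        raise ValueError(f"unknown adduct {label!r}")


def formula_of(species: LipidSpecies) -> dict[str, int]:
    """Neutral-molecule elemental formula (element -> count over C,H,O,N,P,S)."""
    c_off, h_off, hetero = _FORMULA_RULES[species.lipid_class]
    formula = {
        "C": species.total_carbons + c_off,
        "H": 2 * species.total_carbons - 2 * species.double_bonds + h_off,
    }
    formula.update(hetero)
    if species.hydroxylation is Hydroxylation.T:
        formula["O"] += 1
    if formula["H"] <= 0:
        raise UnsupportedSpeciesError(f"{species.shorthand}: negative H count")
    return formula


def formula_string(formula: Mapping[str, int]) -> str:
    """Hill-ish string form, e.g. ``C47H83O13P`` (count 1 left implicit)."""
    parts = []
    for el in ("C", "H", "N", "O", "P", "S"):
        n = formula.get(el, 0)
        if n:
            parts.append(f"{el}{n if n > 1 else ''}")
    return "".join(parts)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da of an elemental formula."""
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.items()))


def theoretical_mz(species: LipidSpecies, adduct: Adduct) -> float:
    """Monoisotopic m/z of the given adduct ion of a sum-composition species."""
    expected = (
        "negative" if species.lipid_class in NEGATIVE_MODE_CLASSES else "positive"
    )
    if adduct.polarity != expected:
        raise ValueError(
            f"{species.shorthand} is detected in {expected}-ion mode; "
            f"adduct {adduct.label} is {adduct.polarity}"
        )
    return monoisotopic_mass(formula_of(species)) + adduct.mass_shift


@dataclass(frozen=True)
class PanelEntry:
    species: LipidSpecies
    adduct: Adduct
    mz: float


class Panel:
    """An m/z-sorted list of (species, adduct) targets for annotation."""

    def __init__(self, entries: Sequence[PanelEntry]):
        seen: set[tuple[LipidSpecies, Adduct]] = set()
        for e in entries:
            key = (e.species, e.adduct)
            if key in seen:
                raise ValueError(
                    f"duplicate panel entry {e.species.shorthand} {e.adduct.label}"
                )
            seen.add(key)
        self.entries: list[PanelEntry] = sorted(entries, key=lambda e: e.mz)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def species(self) -> list[LipidSpecies]:
        return [e.species for e in self.entries]

    @property
    def classes(self) -> list[LipidClass]:
        return sorted({e.species.lipid_class for e in self.entries},
                      key=lambda c: c.value)

    @property
    def mzs(self) -> np.ndarray:
        return np.array([e.mz for e in self.entries])

    def subset(self, polarity: str) -> "Panel":
        return Panel([e for e in self.entries if e.adduct.polarity == polarity])

    def by_class(self, lipid_class: LipidClass) -> list[PanelEntry]:
        return [e for e in self.entries if e.species.lipid_class is lipid_class]


@dataclass(frozen=True)
class Annotation:
    """Assignment of an observed m/z to the nearest in-tolerance panel entry."""

    observed_mz: float
    species: LipidSpecies
    adduct: Adduct
    theoretical_mz: float
    ppm_error: float
    ambiguous: bool

    @property
    def key(self) -> tuple[LipidSpecies, Adduct]:
        return (self.species, self.adduct)


def build_panel(config: Mapping) -> Panel:
    """Build a panel from a config mapping.

    Expected layout::

        classes:
          PI:  {adduct: "[M-H]-", species: ["34:1", "38:4", ...]}
          SM:  {adduct: "[M+H]+", species: ["d34:1", ...]}

    An empty/missing ``classes`` mapping yields an empty panel.
    """
    entries: list[PanelEntry] = []
    for cls_name, block in (config.get("classes") or {}).items():
        lipid_cls = LipidClass(cls_name)
        adducts = block.get("adducts") or [block["adduct"]]
        for chain in block["species"]:
            sp = parse_shorthand(f"{lipid_cls.value}{'' if lipid_cls is LipidClass.PE_P else ' '}{chain}")
            for adduct_label in adducts:
                adduct = Adduct.from_label(adduct_label)
                entries.append(PanelEntry(sp, adduct, theoretical_mz(sp, adduct)))
    return Panel(entries)


def load_panel(path: str | Path | None = None) -> Panel:
    """Load a panel YAML; with no path, load the packaged default brain panel."""
    if path is None:
        text = (resources.files("glioims.data") / "panel_default.yaml").read_text()
    else:
        text = Path(path).read_text()
    return build_panel(yaml.safe_load(text) or {})


def default_panel() -> Panel:
    return load_panel()


def annotate(
    mz_list: Iterable[float], panel: Panel, tol_ppm: float = 9.0
) -> list[Annotation | None]:
    """Annotate each observed m/z with the candidate minimising \\|ppm error\\|.

    Returns ``None`` where no panel entry lies within ``tol_ppm``. When more
    than one candidate is in tolerance the nearest wins and the annotation is
    flagged ``ambiguous`` (the printed-output stand-in for on-tissue MS/MS
    disambiguation).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    panel_mz = panel.mzs
    out: list[Annotation | None] = []
    for mz in mz_list:
        if mz <= 0:
            raise ValueError(f"non-positive m/z {mz}")
        ppm = (mz - panel_mz) / panel_mz * 1e6
        in_tol = np.flatnonzero(np.abs(ppm) <= tol_ppm)
        if in_tol.size == 0:
            out.append(None)
            continue
        best = in_tol[np.argmin(np.abs(ppm[in_tol]))]
        entry = panel.entries[best]
        out.append(
            Annotation(
                observed_mz=float(mz),
                species=entry.species,
                adduct=entry.adduct,
                theoretical_mz=entry.mz,
                ppm_error=float(ppm[best]),
                ambiguous=bool(in_tol.size > 1),
            )
        )
    return out


def annotations_to_table(annotations: Sequence[Annotation | None]) -> pd.DataFrame:
    """Tabulate annotations (one row per observed peak, unannotated included)."""
    rows = []
    for ann in annotations:
        if ann is None:
            rows.append({"observed_mz": np.nan, "class": None, "species": None,
                         "adduct": None, "theoretical_mz": np.nan,
                         "ppm_error": np.nan, "ambiguous": False})
        else:
            rows.append({
                "observed_mz": ann.observed_mz,
                "class": ann.species.lipid_class.value,
                "species": ann.species.shorthand,
                "adduct": ann.adduct.label,
                "theoretical_mz": ann.theoretical_mz,
                "ppm_error": ann.ppm_error,
                "ambiguous": ann.ambiguous,
            })
    return pd.DataFrame(rows)
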