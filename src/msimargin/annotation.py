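"""Tentative metabolite annotation by mass-tolerance lookup.

Discriminant m/z values from segmentation are matched against a local,
user-extendable table of compound formulas by computing each candidate's
monoisotopic mass, forming the common MALDI adduct ions, and accepting
matches within a +/-0.1 Da tolerance (the scale of low-resolution TOF
accuracy in this mass range).

All annotations are *tentative*: MS1 mass matching alone cannot identify
a molecular species, it can only shortlist candidates of compatible
elemental composition and polarity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "AnnotationEntry",
    "AnnotationHit",
    "MONOISOTOPIC_MASS",
    "ADDUCTS",
    "monoisotopic_mass",
    "theoretical_mz",
    "annotate",
    "load_table",
]

#: IUPAC/CODATA monoisotopic atomic masses, Da.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

#: Supported adducts: mass shift (Da, electron-adjusted) and polarity.
ADDUCTS = {
    "[M+H]+": (1.007276, "positive"),
    "[M-H]-": (-1.007276, "negative"),
    "[M+Na]+": (22.989218, "positive"),
    "[M+K]+": (38.963158, "positive"),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class AnnotationEntry:
    name: str
    formula: str
    compound_class: str = ""


@dataclass(frozen=True)
class AnnotationHit:
    query_mz: float
    entry: AnnotationEntry
    adduct: str
    theoretical_mz: float
    delta: float  # |query - theoretical|, Da
    tentative: bool = True


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula (C, H, N, O, P, S, Na, K)."""
    if not formula or not formula.strip():
        raise ValueError("empty elemental formula")
    pos = 0
    total = 0.0
    for m in _FORMULA_RE.finditer(formula.strip()):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        element, count = m.group(1), int(m.group(2) or 1)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        total += MONOISOTOPIC_MASS[element] * count
    if pos != len(formula.strip()):
        raise ValueError(f"cannot parse formula {formula!r}")
    return total


def theoretical_mz(mass: float, adduct: str) -> float:
    """m/z of the singly charged *adduct* ion of a neutral of mass *mass*."""
    if mass <= 0:
        raise ValueError("neutral mass must be positive")
    if adduct not in ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; choose from {sorted(ADDUCTS)}")
    return mass + ADDUCTS[adduct][0]


def load_table(path: str | Path | None = None) -> list[AnnotationEntry]:
    """Load an annotation table (TSV: name, formula, class).

    With no path, the curated built-in table shipped with the package is
    used (nucleotides, common membrane lipids, sugars and fatty acids in
    the 200-1000 Da range).
    """
    if path is None:
        text = (resources.files("msimargin") / "data" / "annotation_table.tsv").read_text()
    else:
        text = Path(path).read_text()
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"bad annotation table line: {line!r}")
        name, formula = parts[0], parts[1]
        cls = parts[2] if len(parts) > 2 else ""
        monoisotopic_mass(formula)  # validate eagerly
        entries.append(AnnotationEntry(name=name, formula=formula, compound_class=cls))
    return entries


def annotate(query_mz: float, mode: str,
             table: list[AnnotationEntry] | None = None,
             tolerance: float = 0.1) -> list[AnnotationHit]:
    """All (entry, adduct) matches within *tolerance* Da, nearest first.

    Only adducts whose polarity matches the query's ionization mode are
    considered; an empty list is a valid (and common) result.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if mode not in ("positive", "negative"):
        raise ValueError(f"mode must be positive/negative, got {mode!r}")
    if table is None:
        table = load_table()
    hits = []
    for entry in table:
        mass = monoisotopic_mass(entry.formula)
        for adduct, (_, polarity) in ADDUCTS.items():
            if polarity != mode:
                continue
            tmz = theoretical_mz(mass, adduct)
            delta = abs(query_mz - tmz)
            if delta <= tolerance:
                hits.append(AnnotationHit(query_mz=query_mz, entry=entry,
                                          adduct=adduct, theoretical_mz=tmz,
                                          delta=delta))
    hits.sort(key=lambda h: (h.delta, h.entry.name, h.adduct))
    return hits
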