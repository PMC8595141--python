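"""Compound-characterization table handling for UPLC-HRMS annotation.

A characterization table lists, per detected compound, the retention time,
the observed adduct ion, measured and theoretical (expected) m/z, the signed
ppm mass error, the molecular formula, neutral monoisotopic mass, compound
name and herb source.  This module parses molecular formulas, computes
monoisotopic masses and adduct m/z values, recomputes ppm errors, and
produces a QC report that flags rows whose printed derived columns are
inconsistent with their own inputs.  Printed values are treated as
authoritative: QC flags, it never corrects.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "MolecularFormula",
    "AdductSpec",
    "ADDUCT_REGISTRY",
    "CompoundRecord",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "round_half_away",
    "read_compound_table",
    "write_compound_table",
    "validate_compound_table",
    "nfpx_compound_table_path",
]

# Monoisotopic atomic masses (Da).  Carbon-12 defines the scale.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "Na": 22.98976928,
    "S": 31.97207117,
    "P": 30.97376200,
}

PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.00054858

# Formic acid CH2O2, monoisotopic.
_FORMIC_ACID_MASS = (
    MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["H"] + 2 * MONOISOTOPIC_MASS["O"]
)


class FormulaError(ValueError):
    """Raised for malformed molecular formulas or unknown elements/adducts."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element composition of a neutral molecule or an intrinsic cation."""

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise FormulaError("empty formula")
        for sym, n in self.element_counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if n < 1:
                raise FormulaError(f"element {sym} has non-positive count {n}")
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    def __format__(self, spec: str) -> str:
        return str(self)

    def __str__(self) -> str:
        # Hill order: C first, then H, then the rest alphabetically.
        counts = dict(self.element_counts)
        order = [s for s in ("C", "H") if s in counts]
        order += sorted(s for s in counts if s not in ("C", "H"))
        return "".join(f"{s}{counts[s] if counts[s] != 1 else ''}" for s in order)


_TOKEN = re.compile(r"([A-Z][a-z]?)_?(\d*)_?")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a molecular formula such as ``C15H22O10`` or ``C_15_H_22_O_10_``.

    A symbol without a following count has implicit count 1.  Repeated
    symbols accumulate.  Unknown elements, explicit zero counts and empty
    strings raise :class:`FormulaError`.
    """
    s = text.strip()
    if not s:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m or m.end() == pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"explicit zero count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da: sum of count x atomic monoisotopic mass."""
    return sum(n * MONOISOTOPIC_MASS[sym] for sym, n in f.element_counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """An observed ion species.

    ``mass_delta`` is added to the neutral monoisotopic mass to obtain m/z
    (all registered species are singly charged).  For an intrinsic cation
    (``[M]+``) the formula already describes the charged species and the
    m/z is the formula mass minus one electron.
    """

    name: str
    mass_delta: float
    charge_sign: int
    intrinsic_cation: bool = False


ADDUCT_REGISTRY: dict[str, AdductSpec] = {
    a.name: a
    for a in [
        AdductSpec("[M+H]+", PROTON_MASS, +1),
        AdductSpec("[M-H]-", -PROTON_MASS, -1),
        AdductSpec("[M+Na]+", MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, +1),
        AdductSpec("[M+FA-H]-", _FORMIC_ACID_MASS - PROTON_MASS, -1),
        AdductSpec("[M]+", -ELECTRON_MASS, +1, intrinsic_cation=True),
    ]
}


def _normalize_adduct_name(name: str) -> str:
    # Unicode minus / en-dash and superscript markers normalised away.
    return name.replace("−", "-").replace("–", "-").replace("^", "").strip()


def adduct_mz(f: MolecularFormula, adduct: str | AdductSpec) -> float:
    """Theoretical m/z of ``f`` observed as ``adduct``.

    For ordinary adducts this is the neutral mass plus the adduct's mass
    delta; for intrinsic cations the formula mass minus the electron mass.
    """
    if isinstance(adduct, str):
        key = _normalize_adduct_name(adduct)
        try:
            adduct = ADDUCT_REGISTRY[key]
        except KeyError:
            raise FormulaError(f"unregistered adduct: {key!r}") from None
    return monoisotopic_mass(f) + adduct.mass_delta


def ppm_error(measured: float, expected: float) -> float:
    """Signed relative mass error in parts per million."""
    if expected <= 0:
        raise ValueError(f"expected m/z must be positive, got {expected}")
    return (measured - expected) / expected * 1e6


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed MS tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class CompoundRecord:
    """One row of a compound-characterization table."""

    index: int
    rt_min: float
    adduct: str
    measured_mz: float
    expected_mz: float
    ppm: float
    formula: MolecularFormula
    mw: float
    name: str
    herb_source: str

    def __post_init__(self) -> None:
        if self.measured_mz <= 0 or self.expected_mz <= 0 or self.mw <= 0:
            raise ValueError(f"row {self.index}: masses must be positive")
        if self.rt_min < 0:
            raise ValueError(f"row {self.index}: negative retention time")


_REQUIRED_COLUMNS = [
    "No",
    "RT_min",
    "Adduct",
    "Measured_mz",
    "Expected_mz",
    "ppm",
    "Formula",
    "MW",
    "Name",
    "Source",
]


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a characterization TSV into records, preserving row order.

    The reader normalises Unicode minus signs to ASCII hyphens so that
    tables copied from typeset sources parse cleanly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"compound table missing required columns: {missing}")
    records = []
    for i, row in df.iterrows():
        def num(col: str) -> float:
            raw = str(row[col]).replace("−", "-").strip()
            try:
                return float(raw)
            except ValueError:
                raise ValueError(
                    f"unparseable numeric cell in row {i + 1}, column {col!r}: {raw!r}"
                ) from None

        records.append(
            CompoundRecord(
                index=int(num("No")),
                rt_min=num("RT_min"),
                adduct=_normalize_adduct_name(str(row["Adduct"])),
                measured_mz=num("Measured_mz"),
                expected_mz=num("Expected_mz"),
                ppm=num("ppm"),
                formula=parse_formula(str(row["Formula"])),
                mw=num("MW"),
                name=str(row["Name"]).strip(),
                herb_source=str(row["Source"]).strip(),
            )
        )
    return records


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write records back to the TSV layout accepted by :func:`read_compound_table`."""
    rows = [
        {
            "No": r.index,
            "RT_min": r.rt_min,
            "Adduct": r.adduct,
            "Measured_mz": r.measured_mz,
            "Expected_mz": r.expected_mz,
            "ppm": r.ppm,
            "Formula": str(r.formula),
            "MW": r.mw,
            "Name": r.name,
            "Source": r.herb_source,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_REQUIRED_COLUMNS).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def validate_compound_table(
    records: Iterable[CompoundRecord],
    tol_ppm: float = 0.15,
    tol_mz: float = 0.0005,
) -> pd.DataFrame:
    """Recompute the derived columns of a characterization table and flag drift.

    Per row, two independent checks:

    * ``ppm`` recomputed from the printed (measured, expected) m/z pair;
      flagged when it deviates from the printed ppm by more than ``tol_ppm``.
    * ``expected m/z`` recomputed from the formula and adduct; flagged when
      it deviates from the printed expected m/z by more than ``tol_mz``.

    Printed values are never altered; the report only records deviations.
    """
    rows = []
    for r in records:
        recomputed_ppm = ppm_error(r.measured_mz, r.expected_mz)
        theoretical_mz = adduct_mz(r.formula, r.adduct)
        ppm_dev = abs(recomputed_ppm - r.ppm)
        mz_dev = abs(theoretical_mz - r.expected_mz)
        rows.append(
            {
                "No": r.index,
                "Name": r.name,
                "printed_ppm": r.ppm,
                "recomputed_ppm": recomputed_ppm,
                "ppm_deviation": ppm_dev,
                "ppm_flag": ppm_dev > tol_ppm,
                "printed_expected_mz": r.expected_mz,
                "theoretical_mz": round_half_away(theoretical_mz, 4),
                "mz_deviation": mz_dev,
                "mz_flag": mz_dev > tol_mz,
            }
        )
    cols = [
        "No",
        "Name",
        "printed_ppm",
        "recomputed_ppm",
        "ppm_deviation",
        "ppm_flag",
        "printed_expected_mz",
        "theoretical_mz",
        "mz_deviation",
        "mz_flag",
    ]
    return pd.DataFrame(rows, columns=cols)


def nfpx_compound_table_path() -> Path:
    """Path of the packaged NFPX compound-characterization table (150 rows)."""
    return Path(resources.files("gmpnet").joinpath("data/nfpx_compounds.tsv"))
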