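"""Core typed representation of nuclei, conformers and candidate stereoisomers.

The pipeline never sees 3-D structure: a nucleus is a label plus metadata
(element, carbon hybridization, carbon class, exchangeability, equivalence
group) and an experimental chemical shift; a candidate stereoisomer is a
configuration bit-vector over stereocenters plus a conformer ensemble of
computed isotropic shieldings.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

ELEMENTS = ("H", "C")
HYBRIDIZATIONS = ("sp2", "sp3")
CARBON_CLASSES = ("quaternary", "methine", "methylene", "methyl", "n/a")

#: transliteration for primes / Greek marks used in nucleus labels
_ASCII_MAP = {
    "′": "'",      # prime
    "″": "''",     # double prime
    "‴": "'''",    # triple prime
    "α": "a",      # alpha
    "β": "b",      # beta
    "γ": "g",      # gamma
}


def ascii_label(label: str) -> str:
    """Transliterate primes and Greek letters for ASCII-only downstream tools."""
    out = label
    for src, dst in _ASCII_MAP.items():
        out = out.replace(src, dst)
    return out


class FormulaParseError(ValueError):
    """Raised when a molecular-formula string does not match the grammar."""


@dataclass(frozen=True)
class NucleusRecord:
    """One assignable nucleus.

    For H nuclei ``hybridization`` is that of the bonded carbon and
    ``carbon_class`` is ``"n/a"``. Exchangeable (N–H / O–H) protons are
    flagged and excluded from every statistic downstream.
    """

    label: str
    element: str
    hybridization: str
    delta_exp: float
    carbon_class: str = "n/a"
    exchangeable: bool = False
    equivalence_group: str | None = None

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"nucleus {self.label!r}: element must be one of {ELEMENTS}, got {self.element!r}")
        if self.hybridization not in HYBRIDIZATIONS:
            raise ValueError(f"nucleus {self.label!r}: hybridization must be one of {HYBRIDIZATIONS}")
        if self.carbon_class not in CARBON_CLASSES:
            raise ValueError(f"nucleus {self.label!r}: unknown carbon_class {self.carbon_class!r}")
        if not math.isfinite(self.delta_exp):
            raise ValueError(f"nucleus {self.label!r}: delta_exp must be finite")


@dataclass(frozen=True)
class ConformerRecord:
    """One conformer: relative Gibbs free energy (kcal/mol) and its shieldings."""

    conformer_id: str
    delta_g: float
    shieldings: Mapping[str, float]

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_g):
            raise ValueError(f"conformer {self.conformer_id!r}: delta_g must be finite")


@dataclass(frozen=True)
class CandidateStructure:
    """A stereoisomer hypothesis: configuration bits over stereocenters + ensemble."""

    candidate_id: str
    configuration: tuple[int, ...]
    conformers: tuple[ConformerRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "configuration", tuple(int(b) for b in self.configuration))
        object.__setattr__(self, "conformers", tuple(self.conformers))
        if not self.conformers:
            raise ValueError(f"candidate {self.candidate_id!r}: at least one conformer required")
        if any(b not in (0, 1) for b in self.configuration):
            raise ValueError(f"candidate {self.candidate_id!r}: configuration bits must be 0/1")
        labels = set(self.conformers[0].shieldings)
        for conf in self.conformers[1:]:
            if set(conf.shieldings) != labels:
                missing = labels.symmetric_difference(conf.shieldings)
                raise ValueError(
                    f"candidate {self.candidate_id!r}: conformer {conf.conformer_id!r} "
                    f"shielding labels differ: {sorted(missing)}"
                )

    @property
    def nucleus_labels(self) -> frozenset[str]:
        return frozenset(self.conformers[0].shieldings)


def config_id(configuration: Sequence[int]) -> str:
    """Canonical candidate id: the flip bitstring relative to the base ('000…')."""
    return "".join(str(int(b)) for b in configuration)


# ---------------------------------------------------------------------------
# Molecular-formula bookkeeping
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementCounts:
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            n = int(n)
            if n < 0:
                raise ValueError(f"element {el!r}: negative count {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", dict(clean))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def to_hill(self) -> str:
        """Canonical Hill-notation string (C first, then H, then alphabetical)."""
        order: list[str] = []
        if "C" in self.counts:
            order.append("C")
            if "H" in self.counts:
                order.append("H")
            order += sorted(el for el in self.counts if el not in ("C", "H"))
        else:
            order = sorted(self.counts)
        return "".join(f"{el}{self.counts[el] if self.counts[el] != 1 else ''}" for el in order)


def parse_molecular_formula(formula: str) -> ElementCounts:
    """Parse a Hill-notation formula string (e.g. ``"C84H91N8O12"``)."""
    if not formula:
        raise FormulaParseError("empty formula string")
    counts: Counter[str] = Counter()
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.end() == pos:
            raise FormulaParseError(f"malformed formula at position {pos}: {formula[pos:]!r}")
        element, digits = m.groups()
        counts[element] += int(digits) if digits else 1
        pos = m.end()
    return ElementCounts(counts)


# ---------------------------------------------------------------------------
# Inventory summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InventorySummary:
    """Counts per (element, hybridization, carbon_class) cell plus totals."""

    cells: Mapping[tuple[str, str, str], int]
    total_carbons: int
    total_hydrogens: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"element": el, "hybridization": hyb, "carbon_class": cls, "count": n}
            for (el, hyb, cls), n in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["element", "hybridization", "carbon_class", "count"])


def summarize_inventory(nuclei: Sequence[NucleusRecord]) -> InventorySummary:
    """Tabulate nuclei per (element, hybridization, carbon class)."""
    if not nuclei:
        raise ValueError("empty nucleus list")
    cells: Counter[tuple[str, str, str]] = Counter()
    for nuc in nuclei:
        cells[(nuc.element, nuc.hybridization, nuc.carbon_class)] += 1
    total_c = sum(n for (el, _, _), n in cells.items() if el == "C")
    total_h = sum(n for (el, _, _), n in cells.items() if el == "H")
    return InventorySummary(dict(cells), total_c, total_h)


@dataclass(frozen=True)
class FormulaCheck:
    passed: bool
    carbon_inventory: int
    carbon_formula: int
    carbon_deficit: int
    hydrogen_inventory: int
    hydrogen_formula: int
    message: str


def validate_against_formula(
    inventory: InventorySummary | Sequence[NucleusRecord],
    formula_counts: ElementCounts,
) -> FormulaCheck:
    """Check inventory carbon total against the molecular formula.

    Hydrogen totals are reported informationally only: exchangeable or
    unobserved protons are legitimately absent from an assignment table.
    An empty nucleus list counts as zero of everything.
    """
    if not isinstance(inventory, InventorySummary):
        if len(inventory) == 0:
            inventory = InventorySummary({}, 0, 0)
        else:
            inventory = summarize_inventory(inventory)
    c_inv, c_form = inventory.total_carbons, formula_counts["C"]
    deficit = c_form - c_inv
    passed = deficit == 0
    msg = (
        "carbon inventory matches formula"
        if passed
        else f"carbon inventory {c_inv} != formula {c_form} (deficit {deficit})"
    )
    return FormulaCheck(
        passed=passed,
        carbon_inventory=c_inv,
        carbon_formula=c_form,
        carbon_deficit=deficit,
        hydrogen_inventory=inventory.total_hydrogens,
        hydrogen_formula=formula_counts["H"],
        message=msg,
    )
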