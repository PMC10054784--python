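"""Free-energy filtering of conformer/candidate ensembles and Boltzmann averaging.

Shieldings are Boltzmann-averaged over the conformer ensemble before any
scaling or statistics, giving one averaged shielding vector per candidate.
Energies are relative Gibbs free energies in kcal/mol; weights use
w_i ∝ exp(−ΔG_i / RT) after shifting the ensemble minimum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import ConformerRecord

#: molar gas constant, kcal mol^-1 K^-1
R_KCAL_PER_MOL_K = 1.98720425864083e-3

DEFAULT_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class BoltzmannWeights:
    weights: Mapping[str, float]
    temperature: float

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, not 1")

    def __getitem__(self, conformer_id: str) -> float:
        return self.weights[conformer_id]


def boltzmann_weights(
    conformers: Sequence[ConformerRecord],
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> BoltzmannWeights:
    """Normalized Boltzmann weights over a conformer ensemble."""
    if not conformers:
        raise ValueError("empty conformer ensemble")
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    dg = np.array([c.delta_g for c in conformers], dtype=float)
    dg = dg - dg.min()  # invariant under a common offset
    w = np.exp(-dg / (R_KCAL_PER_MOL_K * temperature))
    w /= w.sum()
    return BoltzmannWeights(
        {c.conformer_id: float(wi) for c, wi in zip(conformers, w)}, temperature
    )


@dataclass(frozen=True)
class DiscardReport:
    """Ids and relative energies of ensemble members outside the energy window."""

    discarded: tuple[tuple[str, float], ...]
    threshold: float

    def __bool__(self) -> bool:
        return bool(self.discarded)


def _entry_id(entry) -> str:
    for attr in ("conformer_id", "candidate_id"):
        if hasattr(entry, attr):
            return str(getattr(entry, attr))
    return repr(entry)


def filter_energy_window(entries: Sequence, threshold: float):
    """Retain entries with ΔG ≤ threshold above the ensemble minimum.

    Works on anything carrying a ``delta_g`` attribute (conformers or
    candidate stereoisomers). The minimum-energy entry is retained by
    construction. Returns ``(retained, DiscardReport)``.
    """
    if threshold <= 0:
        raise ValueError(f"energy window must be > 0 kcal/mol, got {threshold}")
    if not entries:
        raise ValueError("nothing to filter: empty list")
    dg = np.array([e.delta_g for e in entries], dtype=float)
    rel = dg - dg.min()
    keep = rel <= threshold
    retained = [e for e, k in zip(entries, keep) if k]
    discarded = tuple(
        (_entry_id(e), float(r)) for e, r, k in zip(entries, rel, keep) if not k
    )
    assert retained, "minimum-energy entry must always be retained"
    return retained, DiscardReport(discarded, threshold)


def ensemble_average_shieldings(
    conformers: Sequence[ConformerRecord],
    weights: BoltzmannWeights,
) -> dict[str, float]:
    """Boltzmann-weighted mean shielding per nucleus: σ̄(k) = Σ_i w_i σ_i(k)."""
    missing = {c.conformer_id for c in conformers} ^ set(weights.weights)
    if missing:
        raise ValueError(f"conformer ids do not match weights: {sorted(missing)}")
    labels = set(conformers[0].shieldings)
    for conf in conformers[1:]:
        if set(conf.shieldings) != labels:
            raise ValueError(
                "shielding labels differ across conformers: "
                f"{sorted(labels.symmetric_difference(conf.shieldings))}"
            )
    avg: dict[str, float] = {}
    for label in conformers[0].shieldings:
        avg[label] = float(
            sum(weights[c.conformer_id] * c.shieldings[label] for c in conformers)
        )
    return avg
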