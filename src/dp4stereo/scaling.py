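"""Linear scaling of shieldings to the shift scale and error descriptors.

Systematic error in computed shieldings is removed by regressing the
shielding σ_calc on the experimental shift δ_exp, σ = a·δ + b (slope a is
near −1 because shielding decreases as shift grows), and inverting:
δ_s = (σ − b)/a. Descriptors over the resulting per-nucleus errors
e = δ_calc − δ_exp:

* MAE   — mean |e|
* CMAE  — mean |residual| after the internal scaling fit
* RMSD  — √(mean e²)
* r     — Pearson correlation of δ_calc with δ_exp

plus the normalized descriptor N(D) = D / range(D) × 100 % across
candidates (a min-shifted min-max variant is available).

Fits are always per element (¹H and ¹³C separately) and per candidate.
Exchangeable nuclei are dropped and equivalence groups (e.g. the three
protons of a methyl) are averaged — experimental and computed values alike —
before any statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import NucleusRecord

MIN_FIT_POINTS = 3


class DegenerateFitError(ValueError):
    """Raised when a scaling fit is not identifiable (too few or constant points)."""


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares line σ_calc = a·δ_exp + b with Pearson r of the fit."""

    a: float
    b: float
    r: float
    n_points: int
    a_stderr: float = float("nan")

    def __post_init__(self) -> None:
        if self.a == 0:
            raise DegenerateFitError("zero slope: scaling is not invertible")


def _as_arrays(x, y, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return x, y


def fit_scaling(sigma_calc, delta_exp) -> ScalingFit:
    """OLS of computed shieldings on experimental shifts."""
    delta, sigma = _as_arrays(delta_exp, sigma_calc, MIN_FIT_POINTS)
    if np.ptp(delta) == 0:
        raise DegenerateFitError("experimental shifts are constant; fit is degenerate")
    res = stats.linregress(delta, sigma)
    return ScalingFit(a=float(res.slope), b=float(res.intercept),
                      r=float(res.rvalue), n_points=delta.size,
                      a_stderr=float(res.stderr))


def scale_shifts(sigma_calc, fit: ScalingFit) -> np.ndarray:
    """Invert the scaling line: δ_s = (σ_calc − b)/a."""
    sigma = np.asarray(sigma_calc, dtype=float)
    return (sigma - fit.b) / fit.a


def unscaled_shifts(sigma_calc, sigma_reference: float) -> np.ndarray:
    """Reference-compound conversion: δ_u = σ_ref − σ_calc."""
    return float(sigma_reference) - np.asarray(sigma_calc, dtype=float)


def mae(errors) -> float:
    """Mean absolute error of a per-nucleus error vector (ppm)."""
    e = np.asarray(errors, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("empty error vector")
    return float(np.mean(np.abs(e)))


def cmae(delta_exp, sigma_calc) -> float:
    """Corrected MAE: fit the scaling internally, then mean |δ_s − δ_exp|."""
    fit = fit_scaling(sigma_calc, delta_exp)
    delta_s = scale_shifts(np.asarray(sigma_calc, dtype=float), fit)
    return mae(delta_s - np.asarray(delta_exp, dtype=float))


def rmsd(delta_exp, delta_calc) -> float:
    """Root-mean-square deviation between calculated and experimental shifts."""
    x, y = _as_arrays(delta_exp, delta_calc, 1)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def pearson_r(delta_exp, delta_calc) -> float:
    """Sample Pearson correlation; errors on constant input (undefined)."""
    x, y = _as_arrays(delta_exp, delta_calc, MIN_FIT_POINTS)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def normalize_descriptors(values, variant: str = "literal") -> np.ndarray:
    """N(D) across candidates, in percent.

    variant="literal":     D / (max − min) × 100
    variant="min_shifted": (D − min) / (max − min) × 100
    """
    d = np.asarray(values, dtype=float).ravel()
    span = np.ptp(d)
    if span == 0:
        raise ValueError("zero range: normalized descriptor undefined")
    if variant == "literal":
        return d / span * 100.0
    if variant == "min_shifted":
        return (d - d.min()) / span * 100.0
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Per-candidate evaluation on a nucleus table
# ---------------------------------------------------------------------------


def comparison_table(
    nuclei: Sequence[NucleusRecord],
    sigma: Mapping[str, float],
) -> pd.DataFrame:
    """Align nuclei with an averaged shielding vector for statistics.

    Drops exchangeable nuclei and collapses equivalence groups by averaging
    both δ_exp and σ over members (members must share element and
    hybridization). One row per effective nucleus.
    """
    rows = []
    groups: dict[str, list[NucleusRecord]] = {}
    for nuc in nuclei:
        if nuc.exchangeable:
            continue
        if nuc.label not in sigma:
            raise ValueError(f"no computed shielding for nucleus {nuc.label!r}")
        if nuc.equivalence_group:
            groups.setdefault(nuc.equivalence_group, []).append(nuc)
        else:
            rows.append(
                (nuc.label, nuc.element, nuc.hybridization, nuc.delta_exp, sigma[nuc.label])
            )
    for gid, members in groups.items():
        if len({(m.element, m.hybridization) for m in members}) != 1:
            raise ValueError(f"equivalence group {gid!r} mixes element/hybridization")
        rows.append(
            (
                gid,
                members[0].element,
                members[0].hybridization,
                float(np.mean([m.delta_exp for m in members])),
                float(np.mean([sigma[m.label] for m in members])),
            )
        )
    df = pd.DataFrame(rows, columns=["label", "element", "hybridization", "delta_exp", "sigma"])
    return df.sort_values("label", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class CandidateEvaluation:
    """Scaled/unscaled shifts and errors for one candidate, per nucleus.

    ``table`` columns: label, element, hybridization, delta_exp, sigma,
    delta_scaled, e_scaled, and (when a reference shielding is given)
    delta_unscaled, e_unscaled.
    """

    candidate_id: str
    table: pd.DataFrame
    fits: Mapping[str, ScalingFit]

    @property
    def has_unscaled(self) -> bool:
        return "e_unscaled" in self.table.columns


def evaluate_candidate(
    candidate_id: str,
    nuclei: Sequence[NucleusRecord],
    sigma: Mapping[str, float],
    sigma_reference: Mapping[str, float] | None = None,
) -> CandidateEvaluation:
    """Per-element scaling fits plus scaled (and optionally unscaled) errors."""
    df = comparison_table(nuclei, sigma)
    if df.empty:
        raise ValueError("no comparable nuclei (all exchangeable or empty input)")
    fits: dict[str, ScalingFit] = {}
    delta_scaled = np.empty(len(df))
    for element, sub in df.groupby("element"):
        fit = fit_scaling(sub["sigma"].to_numpy(), sub["delta_exp"].to_numpy())
        fits[element] = fit
        delta_scaled[sub.index] = scale_shifts(sub["sigma"].to_numpy(), fit)
    df = df.assign(delta_scaled=delta_scaled, e_scaled=delta_scaled - df["delta_exp"])
    if sigma_reference is not None:
        missing = set(df["element"]) - set(sigma_reference)
        if missing:
            raise ValueError(f"missing reference shielding for element(s) {sorted(missing)}")
        ref = df["element"].map(sigma_reference).to_numpy(dtype=float)
        delta_u = ref - df["sigma"].to_numpy()
        df = df.assign(delta_unscaled=delta_u, e_unscaled=delta_u - df["delta_exp"])
    return CandidateEvaluation(candidate_id, df, fits)


DESCRIPTORS = ("MAE", "CMAE", "RMSD", "r")


def descriptor_table(evaluations: Sequence[CandidateEvaluation]) -> pd.DataFrame:
    """Tidy long-format descriptor table: candidate_id, nucleus_type, descriptor, value.

    MAE/CMAE/RMSD are in ppm on the scaled shifts; r is the Pearson
    correlation of scaled vs experimental shifts.
    """
    rows = []
    for ev in evaluations:
        for element, sub in ev.table.groupby("element"):
            de = sub["delta_exp"].to_numpy()
            ds = sub["delta_scaled"].to_numpy()
            vals = {
                "MAE": mae(ds - de),
                "CMAE": cmae(de, sub["sigma"].to_numpy()),
                "RMSD": rmsd(de, ds),
                "r": pearson_r(de, ds),
            }
            nucleus_type = "1H" if element == "H" else "13C"
            rows += [
                {"candidate_id": ev.candidate_id, "nucleus_type": nucleus_type,
                 "descriptor": k, "value": v}
                for k, v in vals.items()
            ]
    return pd.DataFrame(rows, columns=["candidate_id", "nucleus_type", "descriptor", "value"])


def add_normalized_descriptors(df: pd.DataFrame, variant: str = "literal") -> pd.DataFrame:
    """Append N(D) rows (descriptor name ``"N(<D>)"``) normalized across candidates."""
    extra = []
    for (nucleus_type, descriptor), sub in df.groupby(["nucleus_type", "descriptor"]):
        if descriptor.startswith("N("):
            continue
        vals = sub["value"].to_numpy()
        if np.ptp(vals) == 0:
            continue  # degenerate across candidates; nothing to normalize
        nd = normalize_descriptors(vals, variant=variant)
        for (_, row), v in zip(sub.iterrows(), nd):
            extra.append(
                {"candidate_id": row["candidate_id"], "nucleus_type": nucleus_type,
                 "descriptor": f"N({descriptor})", "value": float(v)}
            )
    return pd.concat([df, pd.DataFrame(extra, columns=df.columns)], ignore_index=True)
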