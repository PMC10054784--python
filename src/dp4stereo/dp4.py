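"""DP4+ probability of candidate stereoisomers from shift errors.

Each candidate's likelihood is a product over nuclei of Student-t tail
terms 1 − T_ν(|e − μ|/σ), one term from the scaled error and one from the
unscaled error, where the unscaled (ν, μ, σ) triplet is chosen by the
carbon hybridization of the nucleus (for protons, of the attached carbon).
Probabilities are the likelihoods normalized over the candidate set,
computed in log space.

The scaled channel uses μ = 0 (scaling removes the systematic bias); the
unscaled channels carry non-zero, hybridization-dependent μ because
unscaled errors are not centered at zero. Parameter sets are editable
profiles keyed by the functional/basis they were calibrated for — nothing
is hard-coded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats
from scipy.special import logsumexp

from .scaling import CandidateEvaluation

_TINY = float(np.finfo(float).tiny)

#: elementary probability channels, then the combined ones
SCALED_CHANNELS = ("1H_scaled", "13C_scaled")
UNSCALED_CHANNELS = ("1H_unscaled", "13C_unscaled")
COMBINED_CHANNELS = ("1H", "13C", "all")
ALL_CHANNELS = SCALED_CHANNELS + UNSCALED_CHANNELS + COMBINED_CHANNELS

_ELEMENT_OF = {"1H": "H", "13C": "C"}


@dataclass(frozen=True)
class TTriplet:
    """Student-t error statistics: degrees of freedom, location, scale (ppm)."""

    nu: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError(f"degrees of freedom must be > 0, got {self.nu}")
        if self.sigma <= 0:
            raise ValueError(f"scale must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class NucleusTypeParameters:
    scaled: TTriplet
    unscaled_sp2: TTriplet
    unscaled_sp3: TTriplet


@dataclass(frozen=True)
class DP4Parameters:
    """Per nucleus type (¹H, ¹³C): scaled + hybridization-split unscaled triplets."""

    proton: NucleusTypeParameters
    carbon: NucleusTypeParameters
    provenance: str = "unspecified"

    def for_element(self, element: str) -> NucleusTypeParameters:
        return self.proton if element == "H" else self.carbon

    def to_dict(self) -> dict:
        def trip(t: TTriplet) -> dict:
            return {"nu": t.nu, "mu": t.mu, "sigma": t.sigma}

        return {
            "provenance": self.provenance,
            "1H": {"scaled": trip(self.proton.scaled),
                   "unscaled_sp2": trip(self.proton.unscaled_sp2),
                   "unscaled_sp3": trip(self.proton.unscaled_sp3)},
            "13C": {"scaled": trip(self.carbon.scaled),
                    "unscaled_sp2": trip(self.carbon.unscaled_sp2),
                    "unscaled_sp3": trip(self.carbon.unscaled_sp3)},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DP4Parameters":
        def block(b: Mapping) -> NucleusTypeParameters:
            return NucleusTypeParameters(
                scaled=TTriplet(**b["scaled"]),
                unscaled_sp2=TTriplet(**b["unscaled_sp2"]),
                unscaled_sp3=TTriplet(**b["unscaled_sp3"]),
            )

        return cls(proton=block(d["1H"]), carbon=block(d["13C"]),
                   provenance=str(d.get("provenance", "unspecified")))


def save_parameters(params: DP4Parameters, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def load_parameters(path) -> DP4Parameters:
    with open(path, encoding="utf-8") as fh:
        return DP4Parameters.from_dict(yaml.safe_load(fh))


def nucleus_likelihood(error: float, triplet: TTriplet) -> float:
    """Tail term 1 − T_ν(|e − μ|/σ) for one nucleus; lies in (0, 0.5]."""
    if not math.isfinite(error):
        raise ValueError(f"non-finite error {error!r}")
    t = abs(error - triplet.mu) / triplet.sigma
    return float(stats.t.sf(t, triplet.nu))


@dataclass(frozen=True)
class DP4Result:
    """Per-channel log-likelihoods and normalized probabilities over candidates."""

    log_likelihoods: Mapping[str, Mapping[str, float]]
    probabilities: Mapping[str, Mapping[str, float]]
    channels: tuple[str, ...]
    warnings: tuple[str, ...] = ()

    def channel(self, name: str) -> Mapping[str, float]:
        if name not in self.probabilities:
            raise KeyError(f"channel {name!r} not computed; have {self.channels}")
        return self.probabilities[name]


def _log_term(error: float, triplet: TTriplet, warn: list[str]) -> float:
    term = nucleus_likelihood(error, triplet)
    if term < _TINY:
        if not warn:
            warn.append("likelihood term underflow: floored at smallest positive normal")
        term = _TINY
    return math.log(term)


def dp4plus_probability(
    evaluations: Sequence[CandidateEvaluation],
    params: DP4Parameters,
    channels: Sequence[str] | None = None,
) -> DP4Result:
    """DP4+ probabilities for a candidate set sharing one compared nucleus set.

    Elementary channels are the scaled and unscaled error sets per nucleus
    type; the combined ¹H, ¹³C and all-data probabilities multiply the
    corresponding elementary likelihoods. Channels without any nucleus of
    the required type (or without unscaled errors when no reference
    shielding was supplied) are omitted with a warning.
    """
    if not evaluations:
        raise ValueError("no candidates")
    label_sets = {frozenset(ev.table["label"]) for ev in evaluations}
    if len(label_sets) != 1:
        raise ValueError("candidates do not share the same compared nucleus set")
    if not evaluations[0].table.shape[0]:
        raise ValueError("empty nucleus set")
    requested = tuple(channels) if channels is not None else ALL_CHANNELS
    unknown = set(requested) - set(ALL_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channel(s) {sorted(unknown)}")

    warn: list[str] = []
    elementary: dict[str, dict[str, float]] = {}
    for chan in SCALED_CHANNELS + UNSCALED_CHANNELS:
        nucleus_type, kind = chan.split("_")
        element = _ELEMENT_OF[nucleus_type]
        loglikes: dict[str, float] = {}
        feasible = True
        for ev in evaluations:
            sub = ev.table[ev.table["element"] == element]
            if sub.empty or (kind == "unscaled" and not ev.has_unscaled):
                feasible = False
                break
            tp = params.for_element(element)
            total = 0.0
            for _, row in sub.iterrows():
                if kind == "scaled":
                    total += _log_term(row["e_scaled"], tp.scaled, warn)
                else:
                    trip = tp.unscaled_sp2 if row["hybridization"] == "sp2" else tp.unscaled_sp3
                    total += _log_term(row["e_unscaled"], trip, warn)
            loglikes[ev.candidate_id] = total
        if feasible:
            elementary[chan] = loglikes
        elif chan in requested:
            warnings.warn(f"channel {chan}: no usable nuclei; omitted", stacklevel=2)
            warn.append(f"channel {chan} omitted (no usable nuclei)")

    combined_parts = {
        "1H": ("1H_scaled", "1H_unscaled"),
        "13C": ("13C_scaled", "13C_unscaled"),
        "all": SCALED_CHANNELS + UNSCALED_CHANNELS,
    }
    loglike_out: dict[str, dict[str, float]] = {}
    prob_out: dict[str, dict[str, float]] = {}
    for chan in requested:
        if chan in combined_parts:
            parts = [p for p in combined_parts[chan] if p in elementary]
            if not parts:
                continue
            ll = {
                ev.candidate_id: sum(elementary[p][ev.candidate_id] for p in parts)
                for ev in evaluations
            }
        elif chan in elementary:
            ll = elementary[chan]
        else:
            continue
        ids = [ev.candidate_id for ev in evaluations]
        arr = np.array([ll[i] for i in ids])
        probs = np.exp(arr - logsumexp(arr))
        loglike_out[chan] = {i: float(v) for i, v in zip(ids, arr)}
        prob_out[chan] = {i: float(p) for i, p in zip(ids, probs)}
    if not prob_out:
        raise ValueError("no computable channel among requested")
    return DP4Result(loglike_out, prob_out, tuple(prob_out), tuple(warn))


@dataclass(frozen=True)
class RankedCandidate:
    candidate_id: str
    probability: float
    tied: bool


def rank_by_probability(result: DP4Result, channel: str = "all",
                        tie_tol: float = 1e-12) -> list[RankedCandidate]:
    """Candidates in descending probability; ties broken lexicographically and flagged."""
    probs = result.channel(channel)
    ordered = sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    for i, (cid, p) in enumerate(ordered):
        tied = any(
            abs(p - q) <= tie_tol
            for j, (_, q) in enumerate(ordered)
            if j != i
        )
        out.append(RankedCandidate(cid, p, tied))
    return out
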