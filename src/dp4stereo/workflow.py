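"""Staged stereochemistry-assignment workflow.

The procedure narrows a 2^n stereoisomer space without ever enumerating it:

1. **Single-flip scan** — flip each of the n stereocenters once, compute the
   error descriptors of every flipped candidate against the base.
2. **Principle-center selection** — keep the centers whose flip degrades the
   combined descriptor least (the data cannot fix them from single flips),
   after removing centers excluded by user-declared constraints (NOESY) or
   by relative Gibbs free energy; cap at m (default 6).
3. **Combinatorial expansion** — build all 2^m candidates over the principle
   centers.
4. **DP4+ ranking** — Boltzmann-average each candidate's conformers, scale,
   compute errors, and rank candidates by DP4+ probability; candidates
   within a near-tie margin of the top are reported together as the key
   configurations.

Configurations are flip-bitstrings relative to the base ("0…0"); R/S labels
are display metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CandidateStructure, NucleusRecord, config_id
from .dp4 import DP4Parameters, DP4Result, dp4plus_probability, rank_by_probability
from .ensemble import DEFAULT_TEMPERATURE_K, boltzmann_weights, ensemble_average_shieldings, filter_energy_window
from .scaling import CandidateEvaluation, cmae, descriptor_table, evaluate_candidate, mae, pearson_r, rmsd

CandidateProvider = Callable[[tuple[int, ...]], CandidateStructure | None]


@dataclass(frozen=True)
class WorkflowConfig:
    """Tunables of the staged workflow (units: K, kcal/mol, percentage points)."""

    temperature: float = DEFAULT_TEMPERATURE_K
    energy_window: float = 20.0
    descriptor: str = "CMAE"
    max_m: int = 6
    threshold_sd: float | None = 1.0
    near_tie_percent: float = 5.0
    sigma_reference: Mapping[str, float] | None = None
    channel: str = "all"
    combination_guard: int = 20


def enumerate_single_flips(base: Sequence[int]) -> list[tuple[int, ...]]:
    """All configurations at Hamming distance 1 from the base, in center order."""
    base = tuple(int(b) for b in base)
    out = []
    for i in range(len(base)):
        cfg = list(base)
        cfg[i] ^= 1
        out.append(tuple(cfg))
    return out


def enumerate_combinations(
    base: Sequence[int],
    center_indices: Sequence[int],
    guard: int = 20,
) -> list[tuple[int, ...]]:
    """All 2^m configurations varying exactly the given centers.

    Binary-counter order with the first listed center as the most
    significant bit; the base configuration is element 0.
    """
    base = tuple(int(b) for b in base)
    m = len(center_indices)
    if len(set(center_indices)) != m:
        raise ValueError("duplicate center indices")
    if m > guard:
        raise ValueError(f"refusing to enumerate 2^{m} candidates (guard {guard})")
    out = []
    for k in range(2 ** m):
        cfg = list(base)
        for j, idx in enumerate(center_indices):
            if (k >> (m - 1 - j)) & 1:
                cfg[idx] ^= 1
        out.append(tuple(cfg))
    return out


def _resolve_provider(
    candidates: Mapping[str, CandidateStructure] | CandidateProvider,
) -> CandidateProvider:
    if callable(candidates):
        return candidates
    mapping = dict(candidates)
    return lambda cfg: mapping.get(config_id(cfg))


def prepare_candidate(
    candidate: CandidateStructure,
    nuclei: Sequence[NucleusRecord],
    config: WorkflowConfig,
) -> CandidateEvaluation:
    """Energy-filter, Boltzmann-average, scale: one evaluation per candidate."""
    conformers, _ = filter_energy_window(candidate.conformers, config.energy_window)
    weights = boltzmann_weights(conformers, config.temperature)
    sigma = ensemble_average_shieldings(conformers, weights)
    return evaluate_candidate(candidate.candidate_id, nuclei, sigma, config.sigma_reference)


# ---------------------------------------------------------------------------
# Stage 1: single-flip scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StereoScanResult:
    """Descriptor table of the base plus every single-flip candidate.

    ``table`` has one row per stereocenter plus the base reference row
    (center ``"(base)"``); descriptor columns are ``<D>_1H`` / ``<D>_13C``.
    """

    table: pd.DataFrame
    base_id: str
    stereocenters: tuple[str, ...]


_SCAN_DESCRIPTORS = ("CMAE", "RMSD", "r")


def _descriptor_row(ev: CandidateEvaluation) -> dict[str, float]:
    out: dict[str, float] = {}
    for element, sub in ev.table.groupby("element"):
        tag = "1H" if element == "H" else "13C"
        de = sub["delta_exp"].to_numpy()
        ds = sub["delta_scaled"].to_numpy()
        out[f"CMAE_{tag}"] = cmae(de, sub["sigma"].to_numpy())
        out[f"RMSD_{tag}"] = rmsd(de, ds)
        out[f"r_{tag}"] = pearson_r(de, ds)
    return out


def single_flip_scan(
    nuclei: Sequence[NucleusRecord],
    stereocenters: Sequence[str],
    candidates: Mapping[str, CandidateStructure] | CandidateProvider,
    config: WorkflowConfig = WorkflowConfig(),
    candidate_delta_g: Mapping[str, float] | None = None,
) -> StereoScanResult:
    """Evaluate the base and every single-flip candidate."""
    provider = _resolve_provider(candidates)
    n = len(stereocenters)
    base = (0,) * n
    rows = []
    configs = [("(base)", base)] + list(zip(stereocenters, enumerate_single_flips(base)))
    dg_map = candidate_delta_g or {}
    for center, cfg in configs:
        cid = config_id(cfg)
        cand = provider(cfg)
        row: dict = {"center": center, "candidate_id": cid,
                     "delta_g": float(dg_map.get(cid, math.nan)),
                     "evaluable": cand is not None}
        if cand is not None:
            row.update(_descriptor_row(prepare_candidate(cand, nuclei, config)))
        rows.append(row)
    cols = ["center", "candidate_id", "delta_g", "evaluable"]
    cols += [f"{d}_{t}" for d in _SCAN_DESCRIPTORS for t in ("1H", "13C")]
    table = pd.DataFrame(rows).reindex(columns=cols)
    return StereoScanResult(table, config_id(base), tuple(stereocenters))


# ---------------------------------------------------------------------------
# Stage 2: principle-center selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CenterSelection:
    centers: tuple[str, ...]
    excluded: Mapping[str, str]
    deviations: pd.DataFrame  # center, combined deviation, selected flag


def select_principle_centers(
    scan: StereoScanResult,
    max_m: int = 6,
    descriptor: str = "CMAE",
    threshold_sd: float | None = 1.0,
    exclusions: Mapping[str, str] | None = None,
    energy_window: float | None = None,
) -> CenterSelection:
    """Centers whose single flip degrades the combined descriptor least.

    Per nucleus type, the deviation of each flip from the base descriptor is
    min-max normalized across the scan; the combined deviation is the mean
    over types. Centers whose combined deviation lies within ``threshold_sd``
    sample standard deviations of the base (deviation 0, normalized) are
    candidates, capped at ``max_m`` by smallest deviation; with
    ``threshold_sd=None`` the threshold is skipped and the ``max_m``
    least-degrading centers are taken. User-declared exclusions (e.g.
    NOESY-violating flips) and centers whose flipped stereoisomer lies above
    ``energy_window`` kcal/mol are removed first, with reasons logged.
    """
    if max_m <= 0:
        raise ValueError(f"max_m must be >= 1, got {max_m}")
    t = scan.table
    base_row = t[t["center"] == "(base)"]
    if base_row.empty:
        raise ValueError("scan has no base reference row")
    flips = t[(t["center"] != "(base)") & t["evaluable"]].copy()
    if flips.empty:
        raise ValueError("scan has no evaluable single-flip rows")

    excluded: dict[str, str] = dict(exclusions or {})
    if energy_window is not None:
        for _, row in flips.iterrows():
            dg = row["delta_g"]
            if math.isfinite(dg) and dg > energy_window and row["center"] not in excluded:
                excluded[row["center"]] = f"energy: ΔG {dg:.1f} kcal/mol above base exceeds window {energy_window:g}"

    types = [tag for tag in ("1H", "13C") if f"{descriptor}_{tag}" in t.columns]
    if not types:
        raise ValueError(f"descriptor {descriptor!r} not present in scan")
    norm_parts, base_parts = [], []
    for tag in types:
        col = f"{descriptor}_{tag}"
        dev = flips[col].to_numpy(dtype=float) - float(base_row[col].iloc[0])
        lo, span = dev.min(), np.ptp(dev)
        if span == 0:
            norm_parts.append(np.zeros_like(dev))
            base_parts.append(0.0)
        else:
            norm_parts.append((dev - lo) / span)
            base_parts.append((0.0 - lo) / span)
    combined = np.mean(norm_parts, axis=0)
    base_combined = float(np.mean(base_parts))

    flips = flips.assign(deviation=combined)
    eligible = flips[~flips["center"].isin(excluded)]
    if eligible.empty:
        raise ValueError("all centers excluded; nothing to select")
    if threshold_sd is None:
        within = eligible
    else:
        sd = float(np.std(combined, ddof=1)) if combined.size > 1 else 0.0
        cutoff = base_combined + threshold_sd * sd
        within = eligible[eligible["deviation"] <= cutoff]
        if within.empty:
            raise ValueError(
                f"threshold selects zero centers (cutoff {cutoff:.3g}); relax threshold_sd"
            )
    chosen = within.sort_values(["deviation", "center"], kind="stable").head(max_m)
    order = {c: i for i, c in enumerate(scan.stereocenters)}
    centers = tuple(sorted(chosen["center"], key=order.__getitem__))
    deviations = flips.assign(selected=flips["center"].isin(centers))[
        ["center", "candidate_id", "deviation", "selected"]
    ].reset_index(drop=True)
    return CenterSelection(centers, excluded, deviations)


# ---------------------------------------------------------------------------
# Stage 3+4: expansion and DP4+ ranking
# ---------------------------------------------------------------------------


def run_full_workflow(
    nuclei: Sequence[NucleusRecord],
    stereocenters: Sequence[str],
    candidates: Mapping[str, CandidateStructure] | CandidateProvider,
    params: DP4Parameters,
    config: WorkflowConfig = WorkflowConfig(),
    exclusions: Mapping[str, str] | None = None,
    candidate_delta_g: Mapping[str, float] | None = None,
) -> dict:
    """Run scan → selection → 2^m expansion → DP4+ ranking; return a report dict.

    Candidates whose shielding tables are missing are listed as not
    evaluable, never silently skipped.
    """
    provider = _resolve_provider(candidates)
    n = len(stereocenters)
    base = (0,) * n

    scan = single_flip_scan(nuclei, stereocenters, provider, config, candidate_delta_g)
    selection = select_principle_centers(
        scan,
        max_m=config.max_m,
        descriptor=config.descriptor,
        threshold_sd=config.threshold_sd,
        exclusions=exclusions,
        energy_window=config.energy_window if candidate_delta_g else None,
    )
    center_idx = [list(stereocenters).index(c) for c in selection.centers]
    combos = enumerate_combinations(base, center_idx, guard=config.combination_guard)

    evaluations: list[CandidateEvaluation] = []
    not_evaluable: list[str] = []
    for cfg in combos:
        cand = provider(cfg)
        cid = config_id(cfg)
        if cand is None:
            not_evaluable.append(cid)
            continue
        evaluations.append(prepare_candidate(cand, nuclei, config))
    if not evaluations:
        raise ValueError("no evaluable combinatorial candidate")

    result = dp4plus_probability(evaluations, params)
    channel = config.channel if config.channel in result.channels else result.channels[-1]
    ranking = rank_by_probability(result, channel)
    top_p = ranking[0].probability
    key_configs = [
        r.candidate_id
        for r in ranking
        if (top_p - r.probability) * 100.0 <= config.near_tie_percent
    ]
    descriptors = descriptor_table(evaluations)

    return {
        "stereocenters": list(stereocenters),
        "base_id": config_id(base),
        "config": {
            "temperature_K": config.temperature,
            "energy_window_kcal_mol": config.energy_window,
            "descriptor": config.descriptor,
            "max_m": config.max_m,
            "threshold_sd": config.threshold_sd,
            "near_tie_percent": config.near_tie_percent,
            "channel": channel,
        },
        "scan": scan.table.to_dict(orient="records"),
        "selected_centers": list(selection.centers),
        "excluded_centers": dict(selection.excluded),
        "n_combinatorial_candidates": len(combos),
        "not_evaluable": not_evaluable,
        "probabilities": {ch: dict(result.probabilities[ch]) for ch in result.channels},
        "ranking": [
            {"candidate_id": r.candidate_id, "probability": r.probability, "tied": r.tied}
            for r in ranking
        ],
        "key_configurations": key_configs,
        "warnings": list(result.warnings),
        "descriptors": descriptors.to_dict(orient="records"),
    }
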