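"""Table readers/writers, run configuration, and deterministic reports.

Formats are plain UTF-8 delimiter-separated tables (CSV; TSV auto-detected
by extension) with explicit headers:

* experimental table — columns ``label, element, hybridization,
  carbon_class, exchangeable, equivalence_group, delta_exp``;
* candidate shieldings — wide table ``label`` + one column per conformer,
  stored as ``<candidate_id>_shieldings.csv`` with an energies sidecar
  ``<candidate_id>_energies.csv`` (columns ``conformer_id, delta_g``).

Readers reject rather than coerce malformed input; error messages carry
file and row context. Nucleus labels keep their Unicode primes/Greek marks;
an ASCII transliteration is available for downstream tools.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .data_model import CandidateStructure, ConformerRecord, NucleusRecord, ascii_label

EXPERIMENTAL_COLUMNS = (
    "label", "element", "hybridization", "carbon_class",
    "exchangeable", "equivalence_group", "delta_exp",
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


class TableFormatError(ValueError):
    """Malformed input table; message carries file and row context."""


def read_experimental_table(path) -> list[NucleusRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    missing = set(EXPERIMENTAL_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    records: list[NucleusRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based incl. header
        label = row["label"]
        if label in seen:
            raise TableFormatError(f"{path}, row {rowno}: duplicate label {label!r}")
        seen.add(label)
        flag = row["exchangeable"].strip().lower()
        if flag not in _TRUE | _FALSE:
            raise TableFormatError(f"{path}, row {rowno}: bad exchangeable flag {row['exchangeable']!r}")
        try:
            delta = float(row["delta_exp"])
        except ValueError:
            raise TableFormatError(
                f"{path}, row {rowno}: non-numeric delta_exp {row['delta_exp']!r}"
            ) from None
        try:
            records.append(
                NucleusRecord(
                    label=label,
                    element=row["element"].strip(),
                    hybridization=row["hybridization"].strip(),
                    carbon_class=row["carbon_class"].strip() or "n/a",
                    exchangeable=flag in _TRUE,
                    equivalence_group=row["equivalence_group"].strip() or None,
                    delta_exp=delta,
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}, row {rowno}: {exc}") from None
    return records


def write_experimental_table(nuclei: Sequence[NucleusRecord], path, ascii_labels: bool = False) -> None:
    path = Path(path)
    tr = ascii_label if ascii_labels else (lambda s: s)
    df = pd.DataFrame(
        [
            {
                "label": tr(n.label),
                "element": n.element,
                "hybridization": n.hybridization,
                "carbon_class": n.carbon_class,
                "exchangeable": str(n.exchangeable).lower(),
                "equivalence_group": tr(n.equivalence_group) if n.equivalence_group else "",
                "delta_exp": repr(n.delta_exp),
            }
            for n in nuclei
        ],
        columns=list(EXPERIMENTAL_COLUMNS),
    )
    df.to_csv(path, sep=_sep(path), index=False)


# ---------------------------------------------------------------------------
# Candidate shielding tables
# ---------------------------------------------------------------------------


def write_candidate_tables(candidate: CandidateStructure, directory, ascii_labels: bool = False) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tr = ascii_label if ascii_labels else (lambda s: s)
    wide = pd.DataFrame({"label": [tr(lab) for lab in candidate.conformers[0].shieldings]})
    for conf in candidate.conformers:
        wide[conf.conformer_id] = [repr(conf.shieldings[lab]) for lab in candidate.conformers[0].shieldings]
    wide.to_csv(directory / f"{candidate.candidate_id}_shieldings.csv", index=False)
    energies = pd.DataFrame(
        {"conformer_id": [c.conformer_id for c in candidate.conformers],
         "delta_g": [repr(c.delta_g) for c in candidate.conformers]}
    )
    energies.to_csv(directory / f"{candidate.candidate_id}_energies.csv", index=False)


def _read_one_candidate(shield_path: Path, expected_labels: set[str] | None) -> CandidateStructure:
    cid = shield_path.name[: -len("_shieldings.csv")]
    energy_path = shield_path.with_name(f"{cid}_energies.csv")
    if not energy_path.exists():
        raise TableFormatError(f"{shield_path}: energies sidecar {energy_path.name} missing")
    wide = pd.read_csv(shield_path, float_precision="round_trip")
    if "label" not in wide.columns or wide.shape[1] < 2:
        raise TableFormatError(f"{shield_path}: need 'label' column plus one column per conformer")
    if wide["label"].duplicated().any():
        dup = wide["label"][wide["label"].duplicated()].iloc[0]
        raise TableFormatError(f"{shield_path}: duplicate nucleus label {dup!r}")
    energies = pd.read_csv(energy_path, float_precision="round_trip")
    if set(energies.columns) < {"conformer_id", "delta_g"}:
        raise TableFormatError(f"{energy_path}: need columns conformer_id, delta_g")
    dg = dict(zip(energies["conformer_id"].astype(str), energies["delta_g"].astype(float)))
    conf_cols = [c for c in wide.columns if c != "label"]
    missing = set(conf_cols) - set(dg)
    if missing:
        raise TableFormatError(f"{energy_path}: no energy for conformer(s) {sorted(missing)}")
    labels = wide["label"].tolist()
    if expected_labels is not None and set(labels) != expected_labels:
        diff = sorted(set(labels) ^ expected_labels)
        raise TableFormatError(
            f"{shield_path}: nucleus labels do not match experimental table: {diff}"
        )
    conformers = tuple(
        ConformerRecord(col, dg[col], dict(zip(labels, wide[col].astype(float))))
        for col in conf_cols
    )
    configuration = tuple(int(b) for b in cid) if set(cid) <= {"0", "1"} else ()
    return CandidateStructure(cid, configuration, conformers)


def read_candidate_shieldings(
    directory, experimental: Sequence[NucleusRecord] | None = None
) -> dict[str, CandidateStructure]:
    """Read every ``*_shieldings.csv`` (+ energies sidecar) in a directory."""
    directory = Path(directory)
    expected = {n.label for n in experimental} if experimental is not None else None
    out: dict[str, CandidateStructure] = {}
    paths = sorted(directory.glob("*_shieldings.csv"))
    if not paths:
        raise TableFormatError(f"{directory}: no *_shieldings.csv files found")
    for p in paths:
        cand = _read_one_candidate(p, expected)
        out[cand.candidate_id] = cand
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Paths plus pipeline tunables for a full workflow run."""

    experimental: str = "experimental.csv"
    candidates_dir: str = "candidates"
    output_dir: str = "out"
    temperature: float = 298.15
    energy_window: float = 20.0
    max_m: int = 6
    threshold_sd: float | None = 1.0
    near_tie_percent: float = 5.0
    descriptor: str = "CMAE"
    channel: str = "all"
    sigma_reference: dict | None = None
    parameters: str | None = None  # DP4 parameter profile path
    seed: int = 0
    verbosity: str = "info"

    def validate(self, base: Path | None = None) -> None:
        root = Path(base) if base else Path(".")
        for name in ("experimental", "candidates_dir"):
            p = root / getattr(self, name)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if not (1.0 <= self.temperature <= 1000.0):
            raise ValueError(f"temperature {self.temperature} K outside [1, 1000]")
        if not (0.0 < self.energy_window <= 100.0):
            raise ValueError(f"energy window {self.energy_window} outside (0, 100] kcal/mol")


def load_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_run_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({k: v for k, v in config.__dict__.items()}, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _round_floats(obj, ndigits: int, prob_digits: int, in_prob: bool = False):
    if isinstance(obj, dict):
        return {
            k: _round_floats(
                v, ndigits, prob_digits,
                in_prob or str(k) in ("probabilities", "probability", "ranking"),
            )
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits, prob_digits, in_prob) for v in obj]
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return round(obj, prob_digits if in_prob else ndigits)
    return obj


def write_report(report: dict, output_dir, stem: str = "report", seed: int | None = None) -> tuple[Path, Path]:
    """Write JSON (machine) and Markdown (human) reports, deterministically.

    Probabilities are fixed at 4 decimals, ppm quantities at 3; keys are
    sorted; a provenance block records the config hash, seed and package
    version so a rerun is byte-identical.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    payload = _round_floats(dict(report), ndigits=3, prob_digits=4)
    cfg_hash = hashlib.sha256(
        json.dumps(payload.get("config", {}), sort_keys=True).encode()
    ).hexdigest()[:16]
    payload["provenance"] = {
        "package": f"dp4stereo {__version__}",
        "config_sha256": cfg_hash,
        "seed": seed,
    }
    json_path = output_dir / f"{stem}.json"
    json_path.write_text(
        json.dumps(payload, indent=1, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    md_path = output_dir / f"{stem}.md"
    md_path.write_text(_markdown_summary(payload), encoding="utf-8")
    return json_path, md_path


def _markdown_summary(report: dict) -> str:
    lines = ["# Stereochemistry assignment report", ""]
    if "selected_centers" in report:
        lines += [
            f"- stereocenters: {len(report.get('stereocenters', []))}",
            f"- principle centers: {', '.join(report['selected_centers']) or '(none)'}",
            f"- combinatorial candidates: {report.get('n_combinatorial_candidates', 0)}",
            "",
        ]
        if report.get("excluded_centers"):
            lines.append("## Excluded centers")
            for center, reason in sorted(report["excluded_centers"].items()):
                lines.append(f"- {center}: {reason}")
            lines.append("")
    ranking = report.get("ranking", [])
    if ranking:
        lines += ["## DP4+ ranking", "", "| candidate | probability | |", "|---|---|---|"]
        for row in ranking[:16]:
            p = row["probability"]
            bar = "█" * max(1, round(p * 20)) if p > 0 else ""
            tie = " (tie)" if row.get("tied") else ""
            lines.append(f"| {row['candidate_id']}{tie} | {p:.4f} | {bar} |")
        lines.append("")
    if report.get("key_configurations"):
        lines += ["## Key configurations", "",
                  ", ".join(report["key_configurations"]), ""]
    if not ranking and "candidates" in report:
        lines.append(f"Candidates evaluated: {len(report['candidates'])}")
    if report.get("ranking") == [] or ("ranking" in report and not report["ranking"]):
        lines.append("No candidates evaluated.")
    prov = report.get("provenance", {})
    lines += ["---", f"{prov.get('package', '')} · config {prov.get('config_sha256', '')} · seed {prov.get('seed')}", ""]
    return "\n".join(lines)
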