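"""Readers, writers and run configuration.

Monitoring records travel as CSV (one row per site/timestamp, columns named
after the ten monitoring variables plus the meteorological fields), the
noise-source decomposition as a companion long-format CSV
``(site, timestamp, source_id, p, d)``, model configuration as YAML and
evaluation reports as JSON. Emitted files embed the package version and a
hash of the resolved configuration for provenance; reruns with identical
configuration and seeds produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assessment import (
    AirSample,
    EnvironmentalRecord,
    RiskAssessment,
    SoilSample,
    WaterSample,
    assess_batch,
    build_default_tree,
    load_tree,
)
from .evaluation import evaluate_city
from .indices import NoiseSourceSet, ThermalInput, default_breakpoints, load_breakpoints
from .synthetic import builtin_profiles, generate_city, load_profile

__all__ = [
    "REQUIRED_COLUMNS",
    "ValidationReport",
    "RunConfig",
    "read_records",
    "write_records",
    "write_assessments",
    "read_assessments",
    "config_hash",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: required record CSV columns, in canonical order
REQUIRED_COLUMNS = (
    "site",
    "timestamp",
    "pm25",
    "no2",
    "pm10",
    "o3",
    "heavy_metal",
    "dissolved_oxygen",
    "ph",
    "organic_matter",
    "n_p_content",
    "noise_level",
    "temperature",
    "wind_speed",
    "relative_humidity",
)

_NUMERIC = REQUIRED_COLUMNS[2:]


@dataclass
class ValidationReport:
    """Row-level validation outcome of a record read."""

    n_total: int = 0
    n_ok: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)

    def reject(self, row: int, reason: str) -> None:
        self.rejected.append((row, reason))


def _noise_sources_map(
    noise_path: str | Path,
) -> dict[tuple[str, str], NoiseSourceSet]:
    frame = pd.read_csv(noise_path, comment="#")
    needed = {"site", "timestamp", "source_id", "p", "d"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValueError(f"{noise_path}: missing noise column(s) {sorted(missing)}")
    out: dict[tuple[str, str], NoiseSourceSet] = {}
    for (site, ts), grp in frame.groupby(["site", "timestamp"], sort=False):
        out[(str(site), str(ts))] = NoiseSourceSet(
            sources=tuple(
                (float(p), float(d)) for p, d in zip(grp["p"], grp["d"])
            )
        )
    return out


def read_records(
    path: str | Path, noise_path: str | Path | None = None
) -> tuple[list[EnvironmentalRecord], ValidationReport]:
    """Read monitoring records; malformed rows are collected, never dropped silently.

    Missing (empty) cells in the ten monitoring variables are kept as NaN so
    that the batch imputation policy can act on them; rows violating hard
    invariants (negative concentrations, pH outside [0, 14], unparseable
    cells, invalid meteorology) are rejected into the validation report.
    """
    frame = pd.read_csv(path, comment="#", dtype={"site": str, "timestamp": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {missing_cols}")
    sources = _noise_sources_map(noise_path) if noise_path else {}
    report = ValidationReport(n_total=len(frame))
    records: list[EnvironmentalRecord] = []
    for i, row in frame.iterrows():
        line = int(i) + 2  # header + 1-based
        vals: dict[str, float] = {}
        bad = False
        for col in _NUMERIC:
            raw = row[col]
            try:
                vals[col] = float(raw) if not pd.isna(raw) else float("nan")
            except (TypeError, ValueError):
                report.reject(line, f"unparseable value {raw!r} in column {col!r}")
                bad = True
                break
        if bad:
            continue
        try:
            rec = EnvironmentalRecord(
                site=str(row["site"]),
                timestamp=str(row["timestamp"]),
                air=AirSample(vals["pm25"], vals["no2"], vals["pm10"], vals["o3"]),
                water=WaterSample(
                    vals["heavy_metal"], vals["dissolved_oxygen"], vals["ph"]
                ),
                soil=SoilSample(vals["organic_matter"], vals["n_p_content"]),
                noise_level=vals["noise_level"],
                thermal=ThermalInput(
                    vals["temperature"], vals["wind_speed"], vals["relative_humidity"]
                ),
                noise_sources=sources.get((str(row["site"]), str(row["timestamp"]))),
            )
        except ValueError as exc:
            report.reject(line, str(exc))
            continue
        records.append(rec)
        report.n_ok += 1
    if report.rejected:
        logger.warning(
            "%s: rejected %d of %d rows", path, len(report.rejected), report.n_total
        )
    return records, report


def _provenance_line(cfg_hash: str | None) -> str:
    tag = f" config={cfg_hash}" if cfg_hash else ""
    return f"# urbanhealth v{__version__}{tag}\n"


def write_records(
    records: Sequence[EnvironmentalRecord],
    path: str | Path,
    noise_path: str | Path | None = None,
    cfg_hash: str | None = None,
) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "site": r.site,
                "timestamp": r.timestamp,
                **r.variables(),
                "temperature": r.thermal.temperature,
                "wind_speed": r.thermal.wind_speed,
                "relative_humidity": r.thermal.relative_humidity,
            }
        )
    frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    with open(path, "w") as fh:
        fh.write(_provenance_line(cfg_hash))
        frame.to_csv(fh, index=False)
    if noise_path is not None:
        noise_rows = []
        for r in records:
            if r.noise_sources is None:
                continue
            for j, (p, d) in enumerate(r.noise_sources.sources):
                noise_rows.append(
                    {
                        "site": r.site,
                        "timestamp": r.timestamp,
                        "source_id": f"src{j}",
                        "p": p,
                        "d": d,
                    }
                )
        with open(noise_path, "w") as fh:
            fh.write(_provenance_line(cfg_hash))
            pd.DataFrame(
                noise_rows, columns=["site", "timestamp", "source_id", "p", "d"]
            ).to_csv(fh, index=False)


ASSESSMENT_COLUMNS = (
    "site",
    "timestamp",
    "risk",
    "air_score",
    "water_score",
    "soil_score",
    "noise_score",
    "iaqi",
    "tci",
    "npi",
    "i_sum",
)


def write_assessments(
    assessments: Sequence[RiskAssessment],
    path: str | Path,
    cfg_hash: str | None = None,
) -> None:
    rows = [
        {
            "site": a.site,
            "timestamp": a.timestamp,
            "risk": a.risk,
            **{f"{m}_score": s for m, s in a.sub_scores.items()},
            **a.indices,
        }
        for a in assessments
    ]
    with open(path, "w") as fh:
        fh.write(_provenance_line(cfg_hash))
        pd.DataFrame(rows, columns=list(ASSESSMENT_COLUMNS)).to_csv(fh, index=False)


def read_assessments(path: str | Path) -> list[RiskAssessment]:
    """Rebuild assessments from CSV (rule traces are not round-tripped)."""
    frame = pd.read_csv(path, comment="#", dtype={"site": str, "timestamp": str})
    missing = [c for c in ASSESSMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing assessment column(s) {missing}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            RiskAssessment(
                site=row["site"],
                timestamp=row["timestamp"],
                risk=float(row["risk"]),
                sub_scores={
                    m: float(row[f"{m}_score"])
                    for m in ("air", "water", "soil", "noise")
                },
                indices={
                    k: float(row[k]) for k in ("iaqi", "tci", "npi", "i_sum")
                },
                trace={},
            )
        )
    return out


def config_hash(config: Mapping) -> str:
    """Stable short hash of a resolved configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration (synth -> assess -> evaluate)."""

    out_dir: str
    profile: str = "B"  # builtin key (B/W/K) or path to a profile YAML
    n: int = 500
    seed: int = 0
    records: str | None = None  # bypass synthesis with an existing CSV
    noise: str | None = None
    observed: str | None = None  # observed-risk CSV; default: planted latent risk
    tree: str | None = None  # tree YAML; default: shipped default tree
    breakpoints: str | None = None
    tci_form: str = "ratio"
    missing: str = "error"
    n_boot: int = 2000
    n_permutations: int = 999
    levels: tuple[float, float] = (0.90, 0.95)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["levels"] = list(self.levels)
        return d


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Synthesize (optional) -> assess -> evaluate; returns artifact paths.

    Writes ``records.csv``/``noise.csv`` (when synthesizing),
    ``assessments.csv`` and ``report.json`` under ``config.out_dir``. All
    stages are logged with the config hash; fixed seeds give byte-identical
    reports across reruns.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config.to_dict())
    logger.info("pipeline start: config=%s seed=%d", cfg_hash, config.seed)

    artifacts: dict[str, Path] = {}
    observed = None
    if config.records:
        records, report = read_records(config.records, config.noise)
        if not records:
            raise RuntimeError(f"stage read: no valid records in {config.records}")
        logger.info("stage read: %d records (%d rejected)", len(records), len(report.rejected))
    else:
        profiles = builtin_profiles()
        profile = (
            profiles[config.profile]
            if config.profile in profiles
            else load_profile(config.profile)
        )
        batch = generate_city(profile, config.n, seed=config.seed)
        records = list(batch.records)
        observed = np.asarray(batch.latent_risk)
        rec_path = out_dir / "records.csv"
        write_records(records, rec_path, out_dir / "noise.csv", cfg_hash)
        artifacts["records"] = rec_path
        artifacts["noise"] = out_dir / "noise.csv"
        logger.info("stage synth: %d records for %s", len(records), profile.name)

    if config.observed:
        obs_frame = pd.read_csv(config.observed, comment="#")
        if "observed_risk" not in obs_frame.columns:
            raise ValueError(f"{config.observed}: needs an 'observed_risk' column")
        observed = obs_frame["observed_risk"].to_numpy(dtype=float)

    tree = load_tree(config.tree) if config.tree else build_default_tree()
    tables = (
        load_breakpoints(config.breakpoints)
        if config.breakpoints
        else default_breakpoints()
    )
    assessments, summary = assess_batch(
        records, tree, tables, tci_form=config.tci_form, missing=config.missing
    )
    assess_path = out_dir / "assessments.csv"
    write_assessments(assessments, assess_path, cfg_hash)
    artifacts["assessments"] = assess_path
    logger.info("stage assess: mean risk %.4f", summary["risk"].mean())

    factors = pd.DataFrame([r.variables() for r in records])
    report = evaluate_city(
        assessments,
        observed,
        factors=factors,
        levels=config.levels,
        n_boot=config.n_boot,
        n_permutations=config.n_permutations,
        seed=config.seed,
    )
    doc = report.to_dict()
    doc["config"]["config_hash"] = cfg_hash
    doc["config"]["package_version"] = __version__
    report_path = out_dir / "report.json"
    tmp = report_path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")
    tmp.replace(report_path)  # no partial report.json on failure
    artifacts["report"] = report_path
    logger.info("pipeline done: %s", report_path)
    return artifacts
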