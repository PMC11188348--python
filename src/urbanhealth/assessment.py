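"""Hierarchical risk assessment: the FIS tree.

Ten monitoring variables in four media (air, water, soil, noise) feed four
per-medium fuzzy systems whose sub-scores in [0, 1] feed a root fuzzy
system producing the comprehensive health risk index in [0, 1]. The
hierarchical decomposition keeps the rule count tractable compared with a
flat ten-input system and mirrors how practitioners reason about media
separately before combining them.

The shipped default tree is an explicit, documented stand-in rule base:
every linguistic variable carries a low / medium / high partition built
from a decreasing sigmoid, a difference-of-sigmoids bump and an increasing
sigmoid (an exact partition of unity), and single-antecedent rules map each
term to risk levels 0.1 / 0.5 / 0.9. Because the partition sums to one, the
defuzzified node output is an exact average of per-variable severity
scores, each strictly monotone in its variable — the tree is monotone by
construction (worse environment never lowers risk). All pipeline code takes
the tree as a parameter so users can substitute their own rule base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fis import (
    FuzzyRule,
    FuzzySystem,
    FuzzyVariable,
    GaussianMF,
    SigmoidDiffMF,
    SigmoidMF,
    evaluate_system,
    system_from_dict,
    system_to_dict,
)
from .indices import (
    BreakpointTable,
    NoiseSourceSet,
    ThermalInput,
    compute_composite_index,
    compute_npi,
    compute_overall_iaqi,
    compute_tci,
)

__all__ = [
    "AirSample",
    "WaterSample",
    "SoilSample",
    "EnvironmentalRecord",
    "FisTree",
    "RiskAssessment",
    "MEDIA_VARIABLES",
    "DEFAULT_UNIVERSES",
    "build_default_tree",
    "assess_record",
    "assess_batch",
    "load_tree",
    "save_tree",
]

# medium -> record variables feeding that medium's leaf system
MEDIA_VARIABLES: dict[str, tuple[str, ...]] = {
    "air": ("pm25", "no2", "pm10", "o3"),
    "water": ("heavy_metal", "dissolved_oxygen", "ph"),
    "soil": ("organic_matter", "n_p_content"),
    "noise": ("noise_level",),
}

ALL_VARIABLES: tuple[str, ...] = tuple(
    v for vars_ in MEDIA_VARIABLES.values() for v in vars_
)

# default closed universes per variable (units as in the record schema)
DEFAULT_UNIVERSES: dict[str, tuple[float, float]] = {
    "pm25": (0.0, 100.0),  # ug/m3
    "no2": (0.0, 80.0),  # ug/m3
    "pm10": (0.0, 150.0),  # ug/m3
    "o3": (0.0, 200.0),  # ug/m3
    "heavy_metal": (0.0, 0.1),  # mg/L
    "dissolved_oxygen": (0.0, 14.0),  # mg/L; higher is better
    "ph": (0.0, 14.0),  # V-shaped risk around the neutral band
    "organic_matter": (0.0, 10.0),  # percent
    "n_p_content": (0.0, 2000.0),  # mg/kg
    "noise_level": (30.0, 90.0),  # dB
}

# variables whose increase lowers risk
BENEFICIAL_VARIABLES = ("dissolved_oxygen",)

# default consequent levels for low / medium / high risk
RISK_LEVELS = {"low": 0.1, "medium": 0.5, "high": 0.9}

# neutral pH band: risk rises when pH leaves [6.5, 8.5]
PH_NEUTRAL_BAND = (6.5, 8.5)
PH_STEEPNESS = 3.0


@dataclass(frozen=True)
class AirSample:
    pm25: float
    no2: float
    pm10: float
    o3: float

    def __post_init__(self) -> None:
        for name in ("pm25", "no2", "pm10", "o3"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class WaterSample:
    heavy_metal: float  # mg/L
    dissolved_oxygen: float  # mg/L
    ph: float

    def __post_init__(self) -> None:
        if not math.isnan(self.heavy_metal) and self.heavy_metal < 0:
            raise ValueError(f"heavy_metal must be >= 0, got {self.heavy_metal}")
        if not math.isnan(self.dissolved_oxygen) and self.dissolved_oxygen < 0:
            raise ValueError(
                f"dissolved_oxygen must be >= 0, got {self.dissolved_oxygen}"
            )
        if not math.isnan(self.ph) and not (0.0 <= self.ph <= 14.0):
            raise ValueError(f"ph must be in [0, 14], got {self.ph}")


@dataclass(frozen=True)
class SoilSample:
    organic_matter: float  # percent
    n_p_content: float  # mg/kg

    def __post_init__(self) -> None:
        for name in ("organic_matter", "n_p_content"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class EnvironmentalRecord:
    """One timestamped multi-media observation at one site."""

    site: str
    timestamp: str  # ISO-8601
    air: AirSample
    water: WaterSample
    soil: SoilSample
    noise_level: float  # dB
    thermal: ThermalInput
    noise_sources: NoiseSourceSet | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.noise_level) and self.noise_level < 0:
            raise ValueError(f"noise_level must be >= 0, got {self.noise_level}")

    def variables(self) -> dict[str, float]:
        """Flat map of the ten monitoring variables."""
        return {
            "pm25": self.air.pm25,
            "no2": self.air.no2,
            "pm10": self.air.pm10,
            "o3": self.air.o3,
            "heavy_metal": self.water.heavy_metal,
            "dissolved_oxygen": self.water.dissolved_oxygen,
            "ph": self.water.ph,
            "organic_matter": self.soil.organic_matter,
            "n_p_content": self.soil.n_p_content,
            "noise_level": self.noise_level,
        }


@dataclass(frozen=True)
class FisTree:
    """Per-medium leaf systems plus a root system over the four sub-scores."""

    leaves: Mapping[str, FuzzySystem]
    root: FuzzySystem

    def __post_init__(self) -> None:
        expected = set(MEDIA_VARIABLES)
        if set(self.leaves) != expected:
            raise ValueError(
                f"leaves must cover media {sorted(expected)}, got {sorted(self.leaves)}"
            )
        root_inputs = {v.name for v in self.root.inputs}
        leaf_outputs = {sys.output.name for sys in self.leaves.values()}
        if root_inputs != leaf_outputs:
            raise ValueError(
                f"root inputs {sorted(root_inputs)} must exactly match leaf "
                f"outputs {sorted(leaf_outputs)}"
            )
        for medium, sys in self.leaves.items():
            if sys.output.universe != (0.0, 1.0):
                raise ValueError(f"{medium}: sub-score universe must be [0, 1]")
        if self.root.output.universe != (0.0, 1.0):
            raise ValueError("risk universe must be [0, 1]")


@dataclass(frozen=True)
class RiskAssessment:
    """Comprehensive health risk index plus per-medium sub-scores and trace."""

    site: str
    timestamp: str
    risk: float
    sub_scores: Mapping[str, float]
    indices: Mapping[str, float]
    trace: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        if not (0.0 <= self.risk <= 1.0):
            raise ValueError(f"risk must be in [0, 1], got {self.risk}")
        for medium, s in self.sub_scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"{medium} sub-score must be in [0, 1], got {s}")


def _lmh_terms(
    lo: float, hi: float
) -> dict[str, SigmoidMF | SigmoidDiffMF]:
    """Low/medium/high partition-of-unity terms over [lo, hi].

    Sigmoid centers at 35% and 65% of the span, steepness 8 per span, so the
    three degrees sum to exactly one everywhere.
    """
    span = hi - lo
    a1 = lo + 0.35 * span
    a2 = lo + 0.65 * span
    c = 8.0 / span
    return {
        "low": SigmoidMF(a=a1, c=-c),
        "medium": SigmoidDiffMF(a_left=a1, a_right=a2, c=c),
        "high": SigmoidMF(a=a2, c=c),
    }


def _ph_terms() -> dict[str, SigmoidMF | SigmoidDiffMF]:
    lo_band, hi_band = PH_NEUTRAL_BAND
    return {
        "acidic": SigmoidMF(a=lo_band, c=-PH_STEEPNESS),
        "neutral": SigmoidDiffMF(a_left=lo_band, a_right=hi_band, c=PH_STEEPNESS),
        "alkaline": SigmoidMF(a=hi_band, c=PH_STEEPNESS),
    }


def _score_output(name: str) -> FuzzyVariable:
    return FuzzyVariable(
        name=name,
        universe=(0.0, 1.0),
        terms={
            label: GaussianMF(b=level, sigma=0.15)
            for label, level in RISK_LEVELS.items()
        },
    )


def _leaf_system(medium: str, universes: Mapping[str, tuple[float, float]]) -> FuzzySystem:
    inputs = []
    rules = []
    for var in MEDIA_VARIABLES[medium]:
        lo, hi = universes[var]
        if var == "ph":
            terms = _ph_terms()
            mapping = {"acidic": "high", "neutral": "low", "alkaline": "high"}
        else:
            terms = _lmh_terms(lo, hi)
            if var in BENEFICIAL_VARIABLES:
                mapping = {"low": "high", "medium": "medium", "high": "low"}
            else:
                mapping = {"low": "low", "medium": "medium", "high": "high"}
        inputs.append(FuzzyVariable(name=var, universe=(lo, hi), terms=terms))
        for label, risk_label in mapping.items():
            rules.append(
                FuzzyRule(antecedent=((var, label),), consequent=risk_label)
            )
    return FuzzySystem(
        inputs=tuple(inputs),
        output=_score_output(f"{medium}_score"),
        rules=tuple(rules),
        and_operator="product",
        consequent_levels=dict(RISK_LEVELS),
    )


def build_default_tree(
    universes: Mapping[str, tuple[float, float]] | None = None,
) -> FisTree:
    """Construct the shipped default FIS tree.

    ``universes`` overrides the default per-variable ranges; missing keys
    fall back to :data:`DEFAULT_UNIVERSES`.
    """
    uni = dict(DEFAULT_UNIVERSES)
    if universes:
        unknown = set(universes) - set(uni)
        if unknown:
            raise ValueError(f"unknown variable(s) in universes: {sorted(unknown)}")
        uni.update({k: (float(v[0]), float(v[1])) for k, v in universes.items()})
    leaves = {medium: _leaf_system(medium, uni) for medium in MEDIA_VARIABLES}
    root_inputs = []
    root_rules = []
    for medium in MEDIA_VARIABLES:
        name = f"{medium}_score"
        root_inputs.append(
            FuzzyVariable(name=name, universe=(0.0, 1.0), terms=_lmh_terms(0.0, 1.0))
        )
        for label in ("low", "medium", "high"):
            root_rules.append(FuzzyRule(antecedent=((name, label),), consequent=label))
    root = FuzzySystem(
        inputs=tuple(root_inputs),
        output=_score_output("risk"),
        rules=tuple(root_rules),
        and_operator="product",
        consequent_levels=dict(RISK_LEVELS),
    )
    return FisTree(leaves=leaves, root=root)


def _record_indices(
    record: EnvironmentalRecord,
    tables: Mapping[str, BreakpointTable],
    tci_form: str,
) -> dict[str, float]:
    panel = {
        "pm25": record.air.pm25,
        "no2": record.air.no2,
        "pm10": record.air.pm10,
        "o3": record.air.o3,
    }
    iaqi, _dominant = compute_overall_iaqi(panel, tables, cap_above_scale=True)
    if record.noise_sources is not None:
        npi = compute_npi(record.noise_sources)
    else:
        # no decomposition available: the measured level is the single source
        npi = compute_npi(NoiseSourceSet(sources=((1.0, record.noise_level),)))
    return {
        "iaqi": iaqi,
        "tci": compute_tci(record.thermal, form=tci_form),
        "npi": npi,
        "i_sum": compute_composite_index(panel, tables),
    }


def assess_record(
    record: EnvironmentalRecord,
    tree: FisTree,
    tables: Mapping[str, BreakpointTable],
    tci_form: str = "ratio",
) -> RiskAssessment:
    """Evaluate the FIS tree on one record.

    Leaf systems run on their medium's variables; the root runs on the four
    sub-scores; the classical indices are attached alongside. Deterministic
    for fixed inputs.
    """
    values = record.variables()
    for name, v in values.items():
        if math.isnan(v):
            raise ValueError(
                f"record {record.site}@{record.timestamp}: missing value for "
                f"{name!r} (use assess_batch with missing='impute')"
            )
    sub_scores: dict[str, float] = {}
    trace: dict[str, dict[str, float]] = {}
    for medium, sys in tree.leaves.items():
        sub = {v: values[v] for v in MEDIA_VARIABLES[medium]}
        score, node_trace = evaluate_system(sys, sub)
        sub_scores[medium] = score
        trace[medium] = node_trace
    root_record = {
        sys.output.name: sub_scores[medium] for medium, sys in tree.leaves.items()
    }
    risk, root_trace = evaluate_system(tree.root, root_record)
    trace["root"] = root_trace
    return RiskAssessment(
        site=record.site,
        timestamp=record.timestamp,
        risk=risk,
        sub_scores=sub_scores,
        indices=_record_indices(record, tables, tci_form),
        trace=trace,
    )


def _impute(records: Sequence[EnvironmentalRecord]) -> list[EnvironmentalRecord]:
    frame = pd.DataFrame([r.variables() for r in records])
    medians = frame.median(skipna=True)
    if frame.isna().all().any():
        cols = sorted(frame.columns[frame.isna().all()])
        raise ValueError(f"cannot impute: variable(s) entirely missing: {cols}")
    out: list[EnvironmentalRecord] = []
    for rec, (_, row) in zip(records, frame.iterrows()):
        if not row.isna().any():
            out.append(rec)
            continue
        v = {k: (medians[k] if math.isnan(row[k]) else row[k]) for k in frame.columns}
        out.append(
            replace(
                rec,
                air=AirSample(v["pm25"], v["no2"], v["pm10"], v["o3"]),
                water=WaterSample(v["heavy_metal"], v["dissolved_oxygen"], v["ph"]),
                soil=SoilSample(v["organic_matter"], v["n_p_content"]),
                noise_level=v["noise_level"],
            )
        )
    return out


def assess_batch(
    records: Sequence[EnvironmentalRecord],
    tree: FisTree,
    tables: Mapping[str, BreakpointTable],
    tci_form: str = "ratio",
    missing: str = "error",
) -> tuple[list[RiskAssessment], pd.DataFrame]:
    """Element-wise assessment of a batch, order-preserving.

    ``missing`` is ``"error"`` (default) or ``"impute"`` (per-variable
    median from the batch, flagged in the log). Returns the assessments and
    a per-site summary table of mean risk and sub-scores.
    """
    if not records:
        raise ValueError("empty record batch")
    if missing == "impute":
        records = _impute(records)
    elif missing != "error":
        raise ValueError(f"missing policy must be 'impute' or 'error', got {missing!r}")
    out: list[RiskAssessment] = []
    for i, rec in enumerate(records):
        try:
            out.append(assess_record(rec, tree, tables, tci_form=tci_form))
        except Exception as exc:
            raise RuntimeError(
                f"record #{i} (site={rec.site}, t={rec.timestamp}): {exc}"
            ) from exc
    rows = [
        {
            "site": a.site,
            "risk": a.risk,
            **{f"{m}_score": s for m, s in a.sub_scores.items()},
        }
        for a in out
    ]
    summary = (
        pd.DataFrame(rows).groupby("site", sort=True).mean().reset_index()
    )
    return out, summary


def load_tree(path: str | Path) -> FisTree:
    """Load a FIS tree from YAML: ``{leaves: {medium: <system>}, root: <system>}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return FisTree(
        leaves={m: system_from_dict(d) for m, d in raw["leaves"].items()},
        root=system_from_dict(raw["root"]),
    )


def save_tree(tree: FisTree, path: str | Path) -> None:
    doc = {
        "leaves": {m: system_to_dict(s) for m, s in tree.leaves.items()},
        "root": system_to_dict(tree.root),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
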