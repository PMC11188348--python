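"""Fuzzy inference engine.

A :class:`FuzzySystem` maps crisp inputs to a crisp output in four steps:

1. fuzzification — each input value is turned into a degree of membership
   in each linguistic term of its variable;
2. rule firing — each rule's antecedent degrees are AND-combined (product
   by default, min optionally) and scaled by the rule weight;
3. consequent resolution — each rule's linguistic consequent is mapped to a
   representative crisp level (the center of the output term's membership
   function), a zero-order Takagi–Sugeno reading;
4. defuzzification — the weighted average of crisp consequent levels by
   firing strength, Output = sum(w_i * Output_i) / sum(w_i).

The output is therefore always a convex combination of the consequent
levels of the rules that fired.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import yaml

__all__ = [
    "SigmoidMF",
    "GaussianMF",
    "TriangularMF",
    "SigmoidDiffMF",
    "FuzzyVariable",
    "FuzzyRule",
    "FuzzySystem",
    "NoRuleFiredError",
    "fuzzify",
    "fire_rules",
    "defuzzify",
    "evaluate_system",
    "system_from_dict",
    "system_to_dict",
    "load_system",
    "save_system",
]

logger = logging.getLogger(__name__)

_EPS = 1e-300  # open-bound clamp for sigmoid saturation


def _sigmoid(z: float) -> float:
    # numerically safe logistic, clamped to the open interval (0, 1)
    if z >= 0:
        v = 1.0 / (1.0 + math.exp(-min(z, 700.0)))
    else:
        e = math.exp(max(z, -700.0))
        v = e / (1.0 + e)
    return min(max(v, _EPS), 1.0 - 1e-16)


@dataclass(frozen=True)
class SigmoidMF:
    """Sigmoid membership mu(x) = 1 / (1 + exp(-c * (x - a) / b)).

    ``a`` is the curve center (mu(a) = 0.5), ``c`` the steepness, ``b`` the
    base of the curve (default 1 so that c alone sets the steepness).
    Increasing when c/b > 0, decreasing when c/b < 0.
    """

    a: float
    c: float
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.b == 0:
            raise ValueError("sigmoid base b must be nonzero")

    def __call__(self, x: float) -> float:
        return _sigmoid(self.c * (x - self.a) / self.b)

    @property
    def center(self) -> float:
        return self.a


@dataclass(frozen=True)
class GaussianMF:
    """Gaussian membership mu(y) = exp(-(y - b)^2 / (2 sigma^2))."""

    b: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def __call__(self, y: float) -> float:
        z = (y - self.b) / self.sigma
        return math.exp(-0.5 * z * z)

    @property
    def center(self) -> float:
        return self.b


@dataclass(frozen=True)
class TriangularMF:
    """Triangular membership: 0 outside [left, right], 1 at peak."""

    left: float
    peak: float
    right: float

    def __post_init__(self) -> None:
        if not (self.left <= self.peak <= self.right):
            raise ValueError(f"need left <= peak <= right, got {self}")

    def __call__(self, y: float) -> float:
        if y <= self.left or y >= self.right:
            # degenerate spikes still return 1 exactly at the peak
            return 1.0 if y == self.peak else 0.0
        if y == self.peak:
            return 1.0
        if y < self.peak:
            return (y - self.left) / (self.peak - self.left)
        return (self.right - y) / (self.right - self.peak)

    @property
    def center(self) -> float:
        return self.peak


@dataclass(frozen=True)
class SigmoidDiffMF:
    """Difference-of-sigmoids membership (the classic ``dsigmf``).

    mu(x) = sigmoid(c*(x - a_left)) - sigmoid(c*(x - a_right)), a bump that
    rises at ``a_left`` and falls at ``a_right``. Together with a decreasing
    sigmoid at ``a_left`` and an increasing sigmoid at ``a_right`` it forms
    an exact partition of unity, which is what makes the default risk tree
    provably monotone.
    """

    a_left: float
    a_right: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a_left < self.a_right):
            raise ValueError("need a_left < a_right")
        if not self.c > 0:
            raise ValueError("steepness c must be > 0")

    def __call__(self, x: float) -> float:
        v = _sigmoid(self.c * (x - self.a_left)) - _sigmoid(self.c * (x - self.a_right))
        return max(v, 0.0)

    @property
    def center(self) -> float:
        return 0.5 * (self.a_left + self.a_right)


MembershipFunction = Union[SigmoidMF, GaussianMF, TriangularMF, SigmoidDiffMF]


@dataclass(frozen=True)
class FuzzyVariable:
    """A named variable with a closed universe and linguistic terms."""

    name: str
    universe: tuple[float, float]
    terms: Mapping[str, MembershipFunction]

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise ValueError(f"{self.name}: universe must satisfy lo < hi")
        if not self.terms:
            raise ValueError(f"{self.name}: at least one term is required")


@dataclass(frozen=True)
class FuzzyRule:
    """IF <conjunction of (variable, label)> THEN <output label or crisp level>."""

    antecedent: tuple[tuple[str, str], ...]
    consequent: Union[str, float]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ValueError("rule needs at least one antecedent conjunct")
        if self.weight < 0:
            raise ValueError(f"rule weight must be >= 0, got {self.weight}")


class NoRuleFiredError(RuntimeError):
    """All rule firing strengths are zero; no defuzzified output exists."""


@dataclass(frozen=True)
class FuzzySystem:
    """One node of a FIS tree: input variables, output variable, rule base.

    ``consequent_levels`` maps each output label to its representative crisp
    level; when omitted, the center of the output term's membership function
    is used. ``and_operator`` is ``"product"`` (default, smooth) or ``"min"``.
    """

    inputs: tuple[FuzzyVariable, ...]
    output: FuzzyVariable
    rules: tuple[FuzzyRule, ...]
    and_operator: str = "product"
    consequent_levels: Mapping[str, float] | None = None
    clamp_inputs: bool = True

    def __post_init__(self) -> None:
        if self.and_operator not in ("product", "min"):
            raise ValueError(f"and_operator must be 'product' or 'min'")
        if not self.rules:
            raise ValueError("a fuzzy system needs at least one rule")
        by_name = {v.name: v for v in self.inputs}
        used: set[str] = set()
        for rule in self.rules:
            for var, label in rule.antecedent:
                if var not in by_name:
                    raise ValueError(f"rule references unknown variable {var!r}")
                if label not in by_name[var].terms:
                    raise ValueError(f"variable {var!r} has no term {label!r}")
                used.add(var)
            if isinstance(rule.consequent, str):
                known = (
                    self.consequent_levels
                    if self.consequent_levels is not None
                    else self.output.terms
                )
                if rule.consequent not in known:
                    raise ValueError(
                        f"unknown consequent label {rule.consequent!r}"
                    )
        unused = set(by_name) - used
        if unused:
            raise ValueError(f"input variable(s) never referenced: {sorted(unused)}")

    def variable(self, name: str) -> FuzzyVariable:
        for v in self.inputs:
            if v.name == name:
                return v
        raise KeyError(name)

    def consequent_level(self, consequent: Union[str, float]) -> float:
        if not isinstance(consequent, str):
            return float(consequent)
        if self.consequent_levels is not None:
            return float(self.consequent_levels[consequent])
        return float(self.output.terms[consequent].center)


def fuzzify(
    value: float, variable: FuzzyVariable, clamp: bool = True
) -> dict[str, float]:
    """Degrees of membership of ``value`` in every term of ``variable``.

    Values outside the universe are clamped with a logged warning by
    default; with ``clamp=False`` they raise instead (strict mode for
    validated pipelines).
    """
    lo, hi = variable.universe
    if value < lo or value > hi:
        if not clamp:
            raise ValueError(
                f"{variable.name}: value {value} outside universe [{lo}, {hi}]"
            )
        logger.warning(
            "%s: value %s outside universe [%s, %s]; clamped",
            variable.name,
            value,
            lo,
            hi,
        )
        value = min(max(value, lo), hi)
    return {label: mf(value) for label, mf in variable.terms.items()}


def fire_rules(
    system: FuzzySystem, degrees: Mapping[str, Mapping[str, float]]
) -> list[tuple[FuzzyRule, float]]:
    """Firing strength per rule: AND-combined antecedent degrees times weight."""
    fired: list[tuple[FuzzyRule, float]] = []
    for rule in system.rules:
        parts = []
        for var, label in rule.antecedent:
            if var not in degrees:
                raise KeyError(
                    f"no fuzzified degrees supplied for variable {var!r}"
                )
            parts.append(degrees[var][label])
        if system.and_operator == "min":
            strength = min(parts)
        else:
            strength = math.prod(parts)
        fired.append((rule, strength * rule.weight))
    return fired


def defuzzify(fired: Sequence[tuple[float, float]]) -> float:
    """Weighted average of crisp consequent levels by firing strength.

    ``fired`` is a sequence of (strength w_i, crisp consequent Output_i);
    returns sum(w_i * Output_i) / sum(w_i). Raises
    :class:`NoRuleFiredError` when the total strength is zero.
    """
    total = sum(w for w, _ in fired)
    if total <= 0.0:
        raise NoRuleFiredError("all firing strengths are zero")
    return sum(w * out for w, out in fired) / total


def evaluate_system(
    system: FuzzySystem, record: Mapping[str, float]
) -> tuple[float, dict[str, float]]:
    """Crisp output of the system for a record of input values, plus a trace.

    The trace maps a human-readable rule key to its firing strength, for
    explainability of individual assessments.
    """
    degrees = {
        v.name: fuzzify(record[v.name], v, clamp=system.clamp_inputs)
        for v in system.inputs
    }
    fired = fire_rules(system, degrees)
    trace: dict[str, float] = {}
    pairs: list[tuple[float, float]] = []
    for i, (rule, strength) in enumerate(fired):
        key = (
            " & ".join(f"{var}={label}" for var, label in rule.antecedent)
            + f" -> {rule.consequent}"
        )
        trace[f"[{i}] {key}"] = strength
        pairs.append((strength, system.consequent_level(rule.consequent)))
    return defuzzify(pairs), trace


# --------------------------------------------------------------------------
# YAML (de)serialization

_MF_TYPES = {
    "sigmoid": SigmoidMF,
    "gaussian": GaussianMF,
    "triangular": TriangularMF,
    "sigmoid_diff": SigmoidDiffMF,
}
_MF_NAMES = {cls: name for name, cls in _MF_TYPES.items()}
_MF_FIELDS = {
    "sigmoid": ("a", "c", "b"),
    "gaussian": ("b", "sigma"),
    "triangular": ("left", "peak", "right"),
    "sigmoid_diff": ("a_left", "a_right", "c"),
}


def _mf_from_dict(d: Mapping) -> MembershipFunction:
    kind = d["type"]
    if kind not in _MF_TYPES:
        raise ValueError(f"unknown membership function type {kind!r}")
    params = {k: float(v) for k, v in d.items() if k != "type"}
    return _MF_TYPES[kind](**params)


def _mf_to_dict(mf: MembershipFunction) -> dict:
    name = _MF_NAMES[type(mf)]
    d: dict = {"type": name}
    for f in _MF_FIELDS[name]:
        d[f] = getattr(mf, f)
    return d


def _variable_from_dict(d: Mapping) -> FuzzyVariable:
    return FuzzyVariable(
        name=d["name"],
        universe=(float(d["universe"][0]), float(d["universe"][1])),
        terms={label: _mf_from_dict(m) for label, m in d["terms"].items()},
    )


def _variable_to_dict(v: FuzzyVariable) -> dict:
    return {
        "name": v.name,
        "universe": [v.universe[0], v.universe[1]],
        "terms": {label: _mf_to_dict(mf) for label, mf in v.terms.items()},
    }


def system_from_dict(d: Mapping) -> FuzzySystem:
    rules = []
    for r in d["rules"]:
        antecedent = tuple(sorted(r["if"].items()))
        consequent = r["then"]
        if not isinstance(consequent, str):
            consequent = float(consequent)
        rules.append(
            FuzzyRule(
                antecedent=antecedent,
                consequent=consequent,
                weight=float(r.get("weight", 1.0)),
            )
        )
    levels = d.get("consequent_levels")
    return FuzzySystem(
        inputs=tuple(_variable_from_dict(v) for v in d["inputs"]),
        output=_variable_from_dict(d["output"]),
        rules=tuple(rules),
        and_operator=d.get("and", "product"),
        consequent_levels=(
            {k: float(v) for k, v in levels.items()} if levels else None
        ),
    )


def system_to_dict(system: FuzzySystem) -> dict:
    return {
        "inputs": [_variable_to_dict(v) for v in system.inputs],
        "output": _variable_to_dict(system.output),
        "rules": [
            {
                "if": {var: label for var, label in r.antecedent},
                "then": r.consequent,
                "weight": r.weight,
            }
            for r in system.rules
        ],
        "and": system.and_operator,
        **(
            {"consequent_levels": dict(system.consequent_levels)}
            if system.consequent_levels is not None
            else {}
        ),
    }


def load_system(path: str | Path) -> FuzzySystem:
    with open(path) as fh:
        return system_from_dict(yaml.safe_load(fh))


def save_system(system: FuzzySystem, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(system_to_dict(system), fh, sort_keys=False)
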