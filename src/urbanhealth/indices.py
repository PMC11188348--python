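"""Formula-defined environmental indices.

Four scalar indices summarise the raw monitoring variables before (and
alongside) the fuzzy risk assessment:

* per-pollutant air-quality sub-index — linear interpolation of a monitored
  concentration between graded breakpoint intervals;
* thermal comfort index (TCI) — temperature, wind speed and relative
  humidity combined into a single comfort scalar (higher = more
  comfortable);
* noise pollution index (NPI) — contribution-weighted average decibel level
  over noise sources;
* composite air-quality index (I_sum) — sum of pollutant concentrations
  normalised by their regulatory secondary standards (larger = heavier
  pollution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "BreakpointRow",
    "BreakpointTable",
    "ThermalInput",
    "NoiseSourceSet",
    "AboveScaleError",
    "DegenerateInputError",
    "compute_iaqi",
    "compute_overall_iaqi",
    "compute_tci",
    "compute_npi",
    "compute_composite_index",
    "load_breakpoints",
    "default_breakpoints",
    "KNOWN_POLLUTANTS",
]

KNOWN_POLLUTANTS = ("so2", "no2", "pm10", "pm25", "co", "o3")

_DATA_DIR = Path(__file__).parent / "data"


class AboveScaleError(ValueError):
    """Concentration exceeds the top breakpoint row.

    Carries ``max_index`` (the scale's top index value) so callers can
    decide whether to cap; the library itself never caps silently.
    """

    def __init__(self, pollutant: str, concentration: float, max_index: float):
        self.pollutant = pollutant
        self.concentration = concentration
        self.max_index = max_index
        super().__init__(
            f"{pollutant} concentration {concentration} is above the top "
            f"breakpoint; scale max index is {max_index}"
        )


class DegenerateInputError(ValueError):
    """Input puts a formula in a numerically degenerate regime."""


@dataclass(frozen=True)
class BreakpointRow:
    c_low: float
    c_high: float
    i_low: float
    i_high: float

    def __post_init__(self) -> None:
        if not (self.c_low < self.c_high):
            raise ValueError(f"c_low must be < c_high, got {self}")
        if not (self.i_low < self.i_high):
            raise ValueError(f"i_low must be < i_high, got {self}")


@dataclass(frozen=True)
class BreakpointTable:
    """Graded concentration→index intervals plus the regulatory standard S_p.

    Rows must be sorted and contiguous: row k's upper concentration/index
    bound is row k+1's lower bound, which guarantees that the interpolated
    sub-index is continuous and non-decreasing in concentration.
    """

    pollutant: str
    rows: tuple[BreakpointRow, ...]
    s_p: float

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.pollutant}: breakpoint table has no rows")
        for a, b in zip(self.rows, self.rows[1:]):
            if a.c_high != b.c_low or a.i_high != b.i_low:
                raise ValueError(
                    f"{self.pollutant}: rows not contiguous at c={a.c_high}"
                )
        if not self.s_p > 0:
            raise ValueError(f"{self.pollutant}: s_p must be > 0, got {self.s_p}")

    @property
    def c_max(self) -> float:
        return self.rows[-1].c_high

    @property
    def i_max(self) -> float:
        return self.rows[-1].i_high


@dataclass(frozen=True)
class ThermalInput:
    """Meteorological fields entering the thermal comfort index."""

    temperature: float  # deg C
    wind_speed: float  # m/s
    relative_humidity: float  # percent, in [0, 100]

    def __post_init__(self) -> None:
        if self.wind_speed < 0:
            raise ValueError(f"wind_speed must be >= 0, got {self.wind_speed}")
        if not (0.0 <= self.relative_humidity <= 100.0):
            raise ValueError(
                f"relative_humidity must be in [0, 100], got {self.relative_humidity}"
            )


@dataclass(frozen=True)
class NoiseSourceSet:
    """Noise-source decomposition: (contribution rate p_i, decibel d_i) pairs."""

    sources: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("at least one noise source is required")
        if any(p < 0 for p, _ in self.sources):
            raise ValueError("contribution rates must be nonnegative")
        if any(d < 0 for _, d in self.sources):
            raise ValueError("decibel levels must be nonnegative")
        if sum(p for p, _ in self.sources) <= 0:
            raise ValueError("total contribution rate must be positive")


def compute_iaqi(concentration: float, table: BreakpointTable) -> float:
    """Per-pollutant air-quality sub-index by linear breakpoint interpolation.

    IAQI = I_low + (I_high - I_low) * (C - C_low) / (C_high - C_low)
    using the row whose concentration interval brackets ``concentration``.
    The top row's upper bound is treated as an inclusive cap.

    Raises
    ------
    ValueError
        If the concentration is negative or below the scale start.
    AboveScaleError
        If the concentration exceeds the top row's upper bound.
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if concentration < table.rows[0].c_low:
        raise ValueError(
            f"{table.pollutant}: concentration {concentration} below scale "
            f"start {table.rows[0].c_low}"
        )
    if concentration > table.c_max:
        raise AboveScaleError(table.pollutant, concentration, table.i_max)
    for row in table.rows:
        if row.c_low <= concentration <= row.c_high:
            frac = (concentration - row.c_low) / (row.c_high - row.c_low)
            return row.i_low + (row.i_high - row.i_low) * frac
    raise AssertionError("unreachable: contiguity guarantees a bracketing row")


def compute_overall_iaqi(
    panel: Mapping[str, float],
    tables: Mapping[str, BreakpointTable],
    cap_above_scale: bool = False,
) -> tuple[float, str]:
    """Aggregate per-pollutant sub-indices: the maximum, plus the dominant pollutant.

    Max-of-sub-indices is the universal AQI aggregation convention. With
    ``cap_above_scale`` a concentration beyond the scale contributes the top
    index value instead of raising.
    """
    if not panel:
        raise ValueError("empty pollutant panel")
    missing = sorted(set(panel) - set(tables))
    if missing:
        raise KeyError(f"no breakpoint table for pollutant(s): {missing}")
    best: tuple[float, str] | None = None
    for pollutant, conc in panel.items():
        try:
            sub = compute_iaqi(conc, tables[pollutant])
        except AboveScaleError as exc:
            if not cap_above_scale:
                raise
            sub = exc.max_index
        if best is None or sub > best[0]:
            best = (sub, pollutant)
    assert best is not None
    return best


def compute_tci(
    thermal: ThermalInput, form: str = "ratio", eps: float = 1e-9
) -> float:
    """Thermal comfort index; higher values indicate greater comfort.

    Two readings of the defining formula are supported:

    * ``"ratio"`` (default): the wind speed corrects the temperature term,
      TCI = (T - 14.3) / (1 + 0.0216 * V * (T - 14.3)) + (1 - 0.01*|70.5 - RH|)
    * ``"additive"``: all three terms are summed,
      TCI = (T - 14.3) + 0.0216 * V * (T - 14.3) + (1 - 0.01*|70.5 - RH|)
    """
    t = thermal.temperature - 14.3
    humidity = 1.0 - 0.01 * abs(70.5 - thermal.relative_humidity)
    if form == "ratio":
        denom = 1.0 + 0.0216 * thermal.wind_speed * t
        if abs(denom) < eps:
            raise DegenerateInputError(
                f"TCI denominator {denom} within {eps} of zero "
                f"(T={thermal.temperature}, V={thermal.wind_speed})"
            )
        return t / denom + humidity
    if form == "additive":
        return t + 0.0216 * thermal.wind_speed * t + humidity
    raise ValueError(f"unknown tci form {form!r}; expected 'ratio' or 'additive'")


def compute_npi(sources: NoiseSourceSet) -> float:
    """Noise pollution index: contribution-weighted average decibel level.

    NPI = sum(p_i * d_i) / sum(p_i); always lies in [min d_i, max d_i].
    """
    total_p = sum(p for p, _ in sources.sources)
    return sum(p * d for p, d in sources.sources) / total_p


def compute_composite_index(
    panel: Mapping[str, float], tables: Mapping[str, BreakpointTable]
) -> float:
    """Composite air-quality index: I_sum = sum_p C_p / S_p.

    Dimensionless; a larger value indicates heavier overall pollution.
    Computed over the pollutants present in ``panel`` (monthly means for
    SO2/NO2/PM10/PM2.5, percentile values for CO/O3).
    """
    if not panel:
        raise ValueError("empty pollutant panel")
    total = 0.0
    for pollutant, conc in panel.items():
        if conc < 0:
            raise ValueError(f"{pollutant}: concentration must be >= 0, got {conc}")
        try:
            s_p = tables[pollutant].s_p
        except KeyError:
            raise KeyError(f"no standard S_p for pollutant {pollutant!r}") from None
        total += conc / s_p
    return total


def _table_from_dict(pollutant: str, entry: Mapping) -> BreakpointTable:
    rows = tuple(BreakpointRow(*map(float, r)) for r in entry["rows"])
    return BreakpointTable(pollutant=pollutant, rows=rows, s_p=float(entry["s_p"]))


def load_breakpoints(path: str | Path) -> dict[str, BreakpointTable]:
    """Load breakpoint tables + standards from the YAML schema.

    Schema: ``{pollutant: {units: str, rows: [[c_low, c_high, i_low, i_high],
    ...], s_p: value}}``. Units are fixed per pollutant and carried through
    as declared; no unit conversion is attempted.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: breakpoint file must be a mapping")
    tables: dict[str, BreakpointTable] = {}
    for pollutant, entry in raw.items():
        if pollutant.startswith("_"):  # metadata keys (_schema, _version)
            continue
        tables[pollutant] = _table_from_dict(pollutant, entry)
    return tables


def default_breakpoints() -> dict[str, BreakpointTable]:
    """The shipped breakpoint tables (modeled on Chinese ambient air quality
    grading, 24-h/8-h averaging) with annual/daily/8-h secondary standards."""
    return load_breakpoints(_DATA_DIR / "breakpoints.yaml")
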