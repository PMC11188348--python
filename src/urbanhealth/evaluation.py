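"""Statistical evaluation protocol for risk assessments.

Three-part protocol:

1. credibility — bootstrap percentile confidence intervals (90% / 95%) on
   the mean risk output, quantifying the stability of the model's output;
2. correlation / significance — Pearson correlation of each environmental
   factor with the risk index, and permutation tests of the association
   between each classical index (IAQI, TCI, NPI) and the risk output, with
   add-one-smoothed p-values;
3. applicability — fit of the model's risk output against an observed risk
   series: RMSE, coefficient of determination R², and the mean absolute
   residual.

Bootstrap and permutation procedures are seed-reproducible and invariant to
the ordering of their inputs (inputs are canonically sorted before the
resampling stream is consumed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CredibilityResult",
    "ApplicabilityMetrics",
    "SignificanceResult",
    "EvaluationReport",
    "DegenerateTestError",
    "credibility_interval",
    "applicability_metrics",
    "correlation_analysis",
    "significance_test",
    "evaluate_city",
]


class DegenerateTestError(ValueError):
    """The test statistic is undefined (e.g. a constant input series)."""


@dataclass(frozen=True)
class CredibilityResult:
    level: float
    lower: float
    upper: float
    point: float
    n_boot: int
    seed: int | None
    method: str = "percentile"

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValueError(
                f"interval must bracket the point estimate: "
                f"{self.lower} <= {self.point} <= {self.upper}"
            )


@dataclass(frozen=True)
class ApplicabilityMetrics:
    rmse: float
    r_squared: float
    mean_abs_residual: float
    mean_residual: float  # signed, emitted for transparency

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.mean_abs_residual < 0:
            raise ValueError("rmse and mean_abs_residual must be >= 0")
        if self.r_squared > 1:
            raise ValueError(f"r_squared must be <= 1, got {self.r_squared}")
        # Jensen: the quadratic mean dominates the arithmetic mean
        if self.mean_abs_residual > self.rmse + 1e-12:
            raise ValueError("mean_abs_residual cannot exceed rmse")


@dataclass(frozen=True)
class SignificanceResult:
    index: str
    statistic: float  # |Pearson r| between index and risk
    p_value: float
    n_permutations: int
    seed: int | None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


def _sorted_array(x: Sequence[float], name: str, min_len: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if len(arr) < min_len:
        raise ValueError(f"{name} needs at least {min_len} values, got {len(arr)}")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def credibility_interval(
    risks: Sequence[float],
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
    method: str = "percentile",
) -> CredibilityResult:
    """Bootstrap confidence interval of the mean risk.

    Percentile method by default: resample with replacement ``n_boot``
    times and take the (alpha/2, 1 - alpha/2) empirical quantiles of the
    resampled means. ``method="bca"`` uses the bias-corrected accelerated
    variant. Reproducible under a fixed seed and invariant to input
    ordering (the sample is sorted before resampling).
    """
    arr = _sorted_array(risks, "risks", 10)
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if n_boot < 200:
        raise ValueError(f"n_boot must be >= 200, got {n_boot}")
    arr = np.sort(arr)
    point = float(arr.mean())
    alpha = 1.0 - level
    if method == "percentile":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(arr), size=(n_boot, len(arr)))
        boot_means = arr[idx].mean(axis=1)
        lower = float(np.quantile(boot_means, alpha / 2))
        upper = float(np.quantile(boot_means, 1 - alpha / 2))
    elif method == "bca":
        if np.ptp(arr) == 0.0:
            lower = upper = point  # degenerate constant sample
        else:
            res = stats.bootstrap(
                (arr,),
                np.mean,
                n_resamples=n_boot,
                confidence_level=level,
                method="BCa",
                random_state=np.random.default_rng(seed),
            )
            lower = float(res.confidence_interval.low)
            upper = float(res.confidence_interval.high)
    else:
        raise ValueError(f"method must be 'percentile' or 'bca', got {method!r}")
    # a constant sample yields a valid zero-width interval
    lower = min(lower, point)
    upper = max(upper, point)
    return CredibilityResult(
        level=level,
        lower=lower,
        upper=upper,
        point=point,
        n_boot=n_boot,
        seed=seed,
        method=method,
    )


def applicability_metrics(
    predicted: Sequence[float], observed: Sequence[float]
) -> ApplicabilityMetrics:
    """RMSE, R² and mean absolute residual of predictions against observations.

    R² = 1 - SS_res / SS_tot against the observed mean; the observations
    must have nonzero variance for R² to be defined.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be 1-d of equal length")
    if len(pred) < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateTestError("observed series has zero variance; R² undefined")
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    return ApplicabilityMetrics(
        rmse=rmse,
        r_squared=1.0 - float(np.sum(resid**2)) / ss_tot,
        mean_abs_residual=float(np.mean(np.abs(resid))),
        mean_residual=float(np.mean(resid)),
    )


def correlation_analysis(
    factors: pd.DataFrame,
    risks: Sequence[float],
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-factor correlation with the risk index.

    Pairwise-complete handling of missing values; a constant factor is
    reported with ``r = NaN`` and ``flag = "constant"`` rather than raised.
    Returns a frame with columns ``factor, r, n, flag``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    risk_arr = np.asarray(risks, dtype=float)
    if len(factors) != len(risk_arr):
        raise ValueError("factors and risks must be aligned")
    rows = []
    for col in factors.columns:
        x = factors[col].to_numpy(dtype=float)
        mask = ~(np.isnan(x) | np.isnan(risk_arr))
        n = int(mask.sum())
        if n < 3:
            rows.append({"factor": col, "r": np.nan, "n": n, "flag": "insufficient"})
            continue
        xs, ys = x[mask], risk_arr[mask]
        if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
            rows.append({"factor": col, "r": np.nan, "n": n, "flag": "constant"})
            continue
        if method == "pearson":
            r = float(stats.pearsonr(xs, ys).statistic)
        else:
            r = float(stats.spearmanr(xs, ys).statistic)
        rows.append({"factor": col, "r": r, "n": n, "flag": ""})
    return pd.DataFrame(rows, columns=["factor", "r", "n", "flag"])


def significance_test(
    index_values: Sequence[float],
    risks: Sequence[float],
    n_permutations: int = 999,
    seed: int | None = None,
    index_name: str = "index",
) -> SignificanceResult:
    """Permutation test of the Pearson association between an index and risk.

    Statistic: |r(index, risk)|. The risk series is permuted
    ``n_permutations`` times and the add-one-smoothed p-value

        p = (1 + #{permuted |r| >= observed |r|}) / (n_permutations + 1)

    is returned, so p is never 0 and has resolution 1/(n_permutations + 1).
    Reproducible under a fixed seed; invariant to input ordering (pairs are
    canonically sorted before the permutation stream is consumed).
    """
    x = _sorted_array(index_values, "index_values", 10)
    y = _sorted_array(risks, "risks", 10)
    if len(x) != len(y):
        raise ValueError("index_values and risks must be aligned")
    if n_permutations < 999:
        raise ValueError(f"n_permutations must be >= 999, got {n_permutations}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateTestError(f"{index_name}: constant series, r undefined")
    # canonical pair order for order-invariance under a fixed seed
    order = np.lexsort((y, x))
    x, y = x[order], y[order]
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    observed = abs(float(xc @ yc / denom))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(yc, (n_permutations, 1)), axis=1)
    perm_stats = np.abs(perms @ xc) / denom
    exceed = int(np.sum(perm_stats >= observed - 1e-12))
    p = (1 + exceed) / (n_permutations + 1)
    return SignificanceResult(
        index=index_name,
        statistic=observed,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def _holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (monotone, capped at 1)."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


@dataclass(frozen=True)
class EvaluationReport:
    """Bundled output of the three-part evaluation protocol."""

    credibility: tuple[CredibilityResult, ...]
    correlation: pd.DataFrame
    significance: tuple[SignificanceResult, ...]
    significance_holm: Mapping[str, float]
    applicability: ApplicabilityMetrics | None
    config: Mapping[str, object]
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "credibility": [asdict(c) for c in self.credibility],
            "correlation": self.correlation.to_dict(orient="records"),
            "significance": [asdict(s) for s in self.significance],
            "significance_holm": dict(self.significance_holm),
            "applicability": (
                asdict(self.applicability) if self.applicability else None
            ),
            "config": dict(self.config),
            "warnings": list(self.warnings),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def evaluate_city(
    assessments: Sequence,
    observed_risk: Sequence[float] | None,
    factors: pd.DataFrame | None = None,
    levels: Sequence[float] = (0.90, 0.95),
    n_boot: int = 2000,
    n_permutations: int = 999,
    seed: int | None = None,
    correlation_method: str = "pearson",
    ci_method: str = "percentile",
) -> EvaluationReport:
    """Run the full evaluation protocol on a city's assessments.

    ``assessments`` are :class:`~urbanhealth.assessment.RiskAssessment`
    objects; ``observed_risk`` is the external risk series the model is
    scored against for the applicability metrics (pass None to skip that
    section); ``factors`` is an optional table of environmental factor
    values aligned with the assessments (defaults to the IAQI/TCI/NPI/I_sum
    columns extracted from the assessments themselves).
    """
    if not len(assessments):
        raise ValueError("no assessments supplied")
    risks = np.array([a.risk for a in assessments])
    warn: list[str] = []

    credibility = tuple(
        credibility_interval(risks, level=lv, n_boot=n_boot, seed=seed, method=ci_method)
        for lv in sorted(levels)
    )

    index_frame = pd.DataFrame(
        {
            "iaqi": [a.indices["iaqi"] for a in assessments],
            "tci": [a.indices["tci"] for a in assessments],
            "npi": [a.indices["npi"] for a in assessments],
            "i_sum": [a.indices["i_sum"] for a in assessments],
        }
    )
    if factors is None or factors.empty:
        if factors is not None and factors.empty:
            warn.append("empty factor table; correlating indices only")
        corr_input = index_frame
    else:
        corr_input = pd.concat(
            [factors.reset_index(drop=True), index_frame], axis=1
        )
    correlation = correlation_analysis(corr_input, risks, method=correlation_method)

    significance = []
    for name in ("iaqi", "tci", "npi"):
        try:
            significance.append(
                significance_test(
                    index_frame[name],
                    risks,
                    n_permutations=n_permutations,
                    seed=seed,
                    index_name=name,
                )
            )
        except DegenerateTestError as exc:
            warn.append(f"significance[{name}]: {exc}")
    holm = {}
    if significance:
        adj = _holm_adjust([s.p_value for s in significance])
        holm = {s.index: a for s, a in zip(significance, adj)}

    applicability = None
    if observed_risk is not None:
        obs = np.asarray(observed_risk, dtype=float)
        if len(obs) != len(risks):
            raise ValueError("observed_risk must be aligned with assessments")
        applicability = applicability_metrics(risks, obs)

    return EvaluationReport(
        credibility=credibility,
        correlation=correlation,
        significance=tuple(significance),
        significance_holm=holm,
        applicability=applicability,
        config={
            "levels": list(sorted(levels)),
            "n_boot": n_boot,
            "n_permutations": n_permutations,
            "seed": seed,
            "correlation_method": correlation_method,
            "ci_method": ci_method,
        },
        warnings=tuple(warn),
    )
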