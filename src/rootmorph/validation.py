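"""Cross-instrument validation statistics.

Certifies a new measurement instrument against a reference instrument from
paired readings of the same samples: sample standard deviations, the
totals-based absolute and signed relative error, an independent-samples
t-test preceded by a Levene variance-homogeneity screen, and the linear
cross-calibration line (gain, offset, coefficient of determination) used
to correct the test instrument's readings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, UndefinedMeasurementError

__all__ = [
    "MeasurementPair",
    "TTestResult",
    "CalibrationFit",
    "ValidationStats",
    "standard_deviation",
    "error_analysis",
    "independent_t_test",
    "calibrate_instruments",
    "validate_pair",
]


@dataclass
class MeasurementPair:
    """Paired readings: ``x`` from the instrument under test, ``y`` from the
    reference instrument, for one morphological parameter."""

    x: np.ndarray
    y: np.ndarray
    parameter_name: str = ""
    units: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ParameterError("measurement sequences must be 1-D")
        if len(self.x) < 2 or len(self.y) < 2:
            raise ParameterError("need at least two readings per instrument")

    def require_paired(self) -> None:
        if len(self.x) != len(self.y):
            raise ParameterError("paired analysis requires equal-length sequences")


def standard_deviation(values: Sequence[float]) -> float:
    """Sample standard deviation with the n − 1 denominator."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("standard deviation needs n >= 2")
    return float(np.std(v, ddof=1))


def error_analysis(pair: MeasurementPair) -> tuple[float, float]:
    """Totals-based error of the test instrument against the reference.

    Returns (Δ, δ): the absolute error Δ = Σxᵢ − Σyᵢ and the signed relative
    error δ = Δ / Σyᵢ × 100 (percent).
    """
    pair.require_paired()
    sx, sy = float(pair.x.sum()), float(pair.y.sum())
    if sy == 0:
        raise UndefinedMeasurementError("reference total is zero; relative error undefined")
    delta = sx - sy
    return delta, delta / sy * 100.0


@dataclass
class TTestResult:
    """Independent-samples t-test with a variance-homogeneity screen.

    Both the pooled (equal-variance) and Welch variants are reported, as
    instrument-comparison tables conventionally list both rows; ``t``,
    ``df`` and ``p_value`` carry the variant selected by the Levene screen.
    """

    t: float
    df: float
    p_value: float
    equal_variance_assumed: bool
    levene_F: float
    levene_p: float
    pooled: tuple[float, float, float]  # (t, df, p)
    welch: tuple[float, float, float]
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def _safe_ttest(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[float, float, float]:
    if np.var(x) == 0 and np.var(y) == 0:
        # Degenerate constant samples: no evidence either way.
        if np.mean(x) == np.mean(y):
            df = len(x) + len(y) - 2 if equal_var else float(len(x) + len(y) - 2)
            return 0.0, float(df), 1.0
        return float("inf"), float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def independent_t_test(
    pair: MeasurementPair, alpha: float = 0.01, levene_alpha: float = 0.05
) -> TTestResult:
    """Two-sample t-test of mean equality between the two instruments.

    A classic Levene screen (mean-centered absolute deviations) first tests
    variance homogeneity at ``levene_alpha``; the pooled-variance t-test is
    used when variances are homogeneous, Welch's otherwise.  p-values are
    two-tailed; the comparison verdict is "no significant difference" when
    p > ``alpha``.
    """
    x, y = pair.x, pair.y
    if np.var(x) == 0 and np.var(y) == 0:
        lev_F, lev_p = 0.0, 1.0
    else:
        lev_F, lev_p = stats.levene(x, y, center="mean")
        lev_F, lev_p = float(lev_F), float(lev_p)
    pooled = _safe_ttest(x, y, equal_var=True)
    welch = _safe_ttest(x, y, equal_var=False)
    equal_var = lev_p > levene_alpha
    t, df, p = pooled if equal_var else welch
    return TTestResult(
        t=t,
        df=df,
        p_value=p,
        equal_variance_assumed=equal_var,
        levene_F=lev_F,
        levene_p=lev_p,
        pooled=pooled,
        welch=welch,
        alpha=alpha,
    )


@dataclass
class CalibrationFit:
    """Least-squares line y ≈ gain · x + offset relating test readings (x)
    to reference readings (y); ``corrected(x)`` maps test values onto the
    reference scale."""

    gain: float
    offset: float
    r_squared: float

    def corrected(self, x):
        return self.gain * np.asarray(x, dtype=float) + self.offset


def calibrate_instruments(pair: MeasurementPair) -> CalibrationFit:
    """Ordinary least squares of reference on test readings."""
    pair.require_paired()
    if len(pair.x) < 3:
        raise ParameterError("calibration needs at least 3 paired readings")
    if np.var(pair.x) == 0:
        raise UndefinedMeasurementError("test readings have zero variance; fit undefined")
    res = stats.linregress(pair.x, pair.y)
    return CalibrationFit(
        gain=float(res.slope),
        offset=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


@dataclass
class ValidationStats:
    """Full per-parameter validation summary."""

    parameter_name: str
    n: int
    s_x: float
    s_y: float
    delta: float
    delta_rel_pct: float
    t_test: TTestResult
    fit: CalibrationFit

    def to_record(self) -> dict:
        return {
            "parameter": self.parameter_name,
            "n": self.n,
            "sd_test": self.s_x,
            "sd_reference": self.s_y,
            "absolute_error": self.delta,
            "relative_error_pct": self.delta_rel_pct,
            "levene_F": self.t_test.levene_F,
            "levene_p": self.t_test.levene_p,
            "t_pooled": self.t_test.pooled[0],
            "df_pooled": self.t_test.pooled[1],
            "p_pooled": self.t_test.pooled[2],
            "t_welch": self.t_test.welch[0],
            "df_welch": self.t_test.welch[1],
            "p_welch": self.t_test.welch[2],
            "equal_variance_assumed": self.t_test.equal_variance_assumed,
            "significant_at_alpha": self.t_test.significant,
            "gain": self.fit.gain,
            "offset": self.fit.offset,
            "r_squared": self.fit.r_squared,
        }


def validate_pair(pair: MeasurementPair, alpha: float = 0.01) -> ValidationStats:
    """Run the complete validation battery on one parameter's paired readings."""
    pair.require_paired()
    delta, delta_rel = error_analysis(pair)
    return ValidationStats(
        parameter_name=pair.parameter_name,
        n=len(pair.x),
        s_x=standard_deviation(pair.x),
        s_y=standard_deviation(pair.y),
        delta=delta,
        delta_rel_pct=delta_rel,
        t_test=independent_t_test(pair, alpha=alpha),
        fit=calibrate_instruments(pair),
    )
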