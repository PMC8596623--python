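"""Linear-vs-logarithmic correlation validation of fixation measures.

Four fixation-force measures are recorded per specimen: resonance frequency
(RF, Hz), implant stability quotient (ISQ, 0–100), peak insertion torque (Nm)
and pull-out force (POF, N). For every measure pair the analysis fits two
best-fit approximations —

* linear:       ``y = a + b * x``
* logarithmic:  ``y = a + b * ln(x)``   (requires ``x > 0``)

— reports the Pearson correlation of the (transformed) predictor with the
response, its two-sided t-test p-value, and prefers the model with the larger
|R| (ties go to the simpler linear model). ``CorrelationStudy`` wraps the six
pairwise comparisons into a fit/results object with a printable summary.

For a simple regression the Pearson |R| equals the square root of the model
R², so "correlation of the fit" and "correlation of the transformed
predictor" coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stability import StrengthClass, classify_strength

__all__ = [
    "SpecimenMeasurements",
    "FitResult",
    "CorrelationCell",
    "CorrelationMatrix",
    "fit_linear",
    "fit_logarithmic",
    "compare_fits",
    "correlation_table",
    "significance_marker",
    "CorrelationStudy",
    "CorrelationStudyResults",
    "MEASURES",
    "MEASURE_COLUMNS",
    "cohort_to_frame",
    "frame_to_cohort",
]

#: Canonical measure order; the later measure in a pair is the predictor, so
#: e.g. RF is regressed on peak torque (the log transform applies to the
#: mechanical force), mirroring how the scatter panels are drawn.
MEASURES: tuple[str, ...] = ("rf", "isq", "peak_torque", "pullout")

#: Measure -> cohort CSV column (units embedded in the header).
MEASURE_COLUMNS: dict[str, str] = {
    "rf": "rf_hz",
    "isq": "isq",
    "peak_torque": "peak_torque_Nm",
    "pullout": "pullout_N",
}


@dataclass(frozen=True)
class SpecimenMeasurements:
    """One specimen's row of the measurement table; missing fields are None."""

    specimen_id: str
    group: str = ""
    peak_torque: float | None = None  # Nm
    pullout: float | None = None  # N
    isq: float | None = None  # dimensionless, 0-100
    rf: float | None = None  # Hz


@dataclass(frozen=True)
class FitResult:
    """One fitted relation y ~ a + b*x or y ~ a + b*ln(x)."""

    model: str  # "linear" | "logarithmic"
    intercept: float
    slope: float
    pearson_r: float
    p_value: float
    n: int
    strength: StrengthClass

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "logarithmic":
            return self.intercept + self.slope * np.log(x)
        return self.intercept + self.slope * x


def _complete_pairs(
    x: Sequence[float], y: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    # canonical (x, y) ordering: fit results are bit-identical under any
    # permutation of the specimens
    order = np.lexsort((y, x))
    return x[order], y[order]


def fit_linear(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Ordinary least squares ``y = a + b*x`` with Pearson R and its p-value.

    Pairs with a missing value are dropped; at least 3 complete pairs are
    required. The p-value is the two-sided t-test on
    ``t = r * sqrt((n-2) / (1-r^2))`` with ``n-2`` degrees of freedom.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; correlation undefined")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; correlation undefined")
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    return FitResult(
        model="linear",
        intercept=float(res.intercept),
        slope=float(res.slope),
        pearson_r=r,
        p_value=float(res.pvalue),
        n=int(n),
        strength=classify_strength(max(min(r, 1.0), -1.0)),
    )


def fit_logarithmic(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Least squares ``y = a + b*ln(x)``; identical to ``fit_linear(ln x, y)``.

    All (complete-pair) x must be strictly positive. Natural log is used; the
    base only rescales the slope and leaves R unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    bad = np.flatnonzero(keep & (x <= 0))  # original specimen indices
    if bad.size:
        raise ValueError(
            f"logarithmic fit requires x > 0; offending specimen index(es) "
            f"{bad.tolist()} with value(s) {x[bad].tolist()} "
            "(is the force in the right units?)"
        )
    lin = fit_linear(np.log(x[keep]), y[keep])
    return FitResult(
        model="logarithmic",
        intercept=lin.intercept,
        slope=lin.slope,
        pearson_r=lin.pearson_r,
        p_value=lin.p_value,
        n=lin.n,
        strength=lin.strength,
    )


def compare_fits(
    x: Sequence[float], y: Sequence[float]
) -> tuple[FitResult, FitResult, str]:
    """Fit both models and name the preferred one.

    Preferred is the larger |Pearson R|; an exact tie goes to the linear
    model (parsimony).
    """
    linear = fit_linear(x, y)
    logarithmic = fit_logarithmic(x, y)
    if abs(logarithmic.pearson_r) > abs(linear.pearson_r):
        preferred = "logarithmic"
    else:
        preferred = "linear"
    return linear, logarithmic, preferred


def significance_marker(p: float) -> str:
    """Three-tier marker used in the correlation table; n.s. above 0.05."""
    if p < 0.001:
        return "p < .001"
    if p < 0.01:
        return "p < .01"
    if p <= 0.05:
        return "p < .05"
    return "n.s."


@dataclass(frozen=True)
class CorrelationCell:
    """One measure-pair entry of the correlation matrix."""

    measure_y: str
    measure_x: str
    available: bool
    model: str | None = None
    pearson_r: float | None = None
    p_value: float | None = None
    n: int | None = None
    strength: StrengthClass | None = None
    marker: str | None = None
    reason: str | None = None  # why unavailable

    def describe(self) -> str:
        if not self.available:
            return f"unavailable ({self.reason})"
        return (
            f"R = {self.pearson_r:.3f} ({self.model}), {self.marker}, "
            f"n = {self.n}, {self.strength.label}"
        )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise best-fit correlations over the four fixation measures.

    Cells are keyed by the unordered measure pair; lookup is symmetric in
    the pair ordering and the diagonal is undefined.
    """

    cells: dict[tuple[str, str], CorrelationCell] = field(default_factory=dict)

    def cell(self, a: str, b: str) -> CorrelationCell:
        if a == b:
            raise KeyError("diagonal cells are undefined")
        key = _pair_key(a, b)
        return self.cells[key]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (y, x), c in self.cells.items():
            rows.append(
                {
                    "measure_y": y,
                    "measure_x": x,
                    "available": c.available,
                    "model": c.model,
                    "pearson_r": c.pearson_r,
                    "p_value": c.p_value,
                    "n": c.n,
                    "strength": c.strength.label if c.strength else None,
                    "marker": c.marker,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {}
        for (y, x), c in self.cells.items():
            out[f"{y}~{x}"] = {
                "available": c.available,
                "model": c.model,
                "pearson_r": c.pearson_r,
                "p_value": c.p_value,
                "n": c.n,
                "strength": c.strength.label if c.strength else None,
                "marker": c.marker,
                "reason": c.reason,
            }
        return out


def _pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (y, x) ordering: the later measure in MEASURES is the predictor."""
    for m in (a, b):
        if m not in MEASURES:
            raise KeyError(f"unknown measure {m!r}; expected one of {MEASURES}")
    ia, ib = MEASURES.index(a), MEASURES.index(b)
    return (a, b) if ia < ib else (b, a)


def _measure_values(
    cohort: Sequence[SpecimenMeasurements], measure: str
) -> np.ndarray:
    vals = [getattr(s, measure) for s in cohort]
    return np.asarray(
        [np.nan if v is None else float(v) for v in vals], dtype=float
    )


def correlation_table(
    cohort: Sequence[SpecimenMeasurements],
) -> CorrelationMatrix:
    """Best-fit correlation for each of the six measure pairs.

    Per cell, both approximations are fitted on pairwise-complete cases and
    the better (larger |R|) reported with its strength class and significance
    marker (.05/.01/.001 tiers; ``n.s.`` above .05). When the logarithmic
    model is undefined (a non-positive predictor value, e.g. ISQ = 0) the
    linear fit alone is reported. A cell with fewer than 3 complete pairs, or
    a degenerate (constant) measure, is marked unavailable, never fabricated.
    """
    cells: dict[tuple[str, str], CorrelationCell] = {}
    for i, a in enumerate(MEASURES):
        for b in MEASURES[i + 1 :]:
            yname, xname = _pair_key(a, b)
            y = _measure_values(cohort, yname)
            x = _measure_values(cohort, xname)
            xs, ys = _complete_pairs(x, y)
            if xs.size < 3:
                cells[(yname, xname)] = CorrelationCell(
                    measure_y=yname,
                    measure_x=xname,
                    available=False,
                    reason=f"only {xs.size} complete pairs (need >= 3)",
                )
                continue
            try:
                best = _best_fit(xs, ys)
            except ValueError as exc:
                cells[(yname, xname)] = CorrelationCell(
                    measure_y=yname,
                    measure_x=xname,
                    available=False,
                    reason=str(exc),
                )
                continue
            cells[(yname, xname)] = CorrelationCell(
                measure_y=yname,
                measure_x=xname,
                available=True,
                model=best.model,
                pearson_r=best.pearson_r,
                p_value=best.p_value,
                n=best.n,
                strength=best.strength,
                marker=significance_marker(best.p_value),
            )
    return CorrelationMatrix(cells=cells)


def _best_fit(x: np.ndarray, y: np.ndarray) -> FitResult:
    """compare_fits with a linear-only fallback when ln(x) is undefined."""
    if np.any(x <= 0):
        return fit_linear(x, y)
    linear, logarithmic, preferred = compare_fits(x, y)
    return logarithmic if preferred == "logarithmic" else linear


# ---------------------------------------------------------------------------
# Model/Results surface
# ---------------------------------------------------------------------------


def cohort_to_frame(cohort: Sequence[SpecimenMeasurements]) -> pd.DataFrame:
    """Measurement table as a DataFrame with unit-bearing column names."""
    return pd.DataFrame(
        {
            "specimen_id": [s.specimen_id for s in cohort],
            "group": [s.group for s in cohort],
            "peak_torque_Nm": _measure_values(cohort, "peak_torque"),
            "pullout_N": _measure_values(cohort, "pullout"),
            "isq": _measure_values(cohort, "isq"),
            "rf_hz": _measure_values(cohort, "rf"),
        }
    )


def frame_to_cohort(df: pd.DataFrame) -> list[SpecimenMeasurements]:
    """Inverse of :func:`cohort_to_frame`; missing columns become None fields."""

    def col(name: str, i: int) -> float | None:
        if name not in df.columns:
            return None
        v = df[name].iloc[i]
        return None if pd.isna(v) else float(v)

    out = []
    for i in range(len(df)):
        out.append(
            SpecimenMeasurements(
                specimen_id=str(df["specimen_id"].iloc[i])
                if "specimen_id" in df.columns
                else str(i),
                group=str(df["group"].iloc[i]) if "group" in df.columns else "",
                peak_torque=col("peak_torque_Nm", i),
                pullout=col("pullout_N", i),
                isq=col("isq", i),
                rf=col("rf_hz", i),
            )
        )
    return out


class CorrelationStudy:
    """Pairwise correlation study over a cohort of specimen measurements.

    Build from a list of :class:`SpecimenMeasurements` or a DataFrame with
    the cohort CSV schema, then call :meth:`fit`.

    Examples
    --------
    >>> study = CorrelationStudy.from_dataframe(df)
    >>> results = study.fit()
    >>> print(results.summary())
    """

    def __init__(self, cohort: Sequence[SpecimenMeasurements]):
        self.cohort = list(cohort)
        if len(self.cohort) < 3:
            raise ValueError("a correlation study needs at least 3 specimens")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CorrelationStudy":
        return cls(frame_to_cohort(df))

    def fit(self) -> "CorrelationStudyResults":
        return CorrelationStudyResults(self, correlation_table(self.cohort))


class CorrelationStudyResults:
    """Fitted correlation study: the matrix plus summary/plot helpers."""

    def __init__(self, model: CorrelationStudy, matrix: CorrelationMatrix):
        self.model = model
        self.matrix = matrix

    @property
    def n_specimens(self) -> int:
        return len(self.model.cohort)

    def to_frame(self) -> pd.DataFrame:
        return self.matrix.to_frame()

    def summary(self) -> str:
        """Plain-text table of the six pairwise best fits."""
        lines = [
            "Fixation-measure correlation study",
            f"specimens: {self.n_specimens}",
            "-" * 78,
            f"{'pair':<24}{'model':<14}{'R':>8}{'p':>12}{'n':>5}  strength",
            "-" * 78,
        ]
        for (yname, xname), c in self.matrix.cells.items():
            pair = f"{yname} ~ {xname}"
            if not c.available:
                lines.append(f"{pair:<24}{'unavailable':<14}{'':>8}{'':>12}")
                continue
            lines.append(
                f"{pair:<24}{c.model:<14}{c.pearson_r:>8.3f}"
                f"{c.p_value:>12.3g}{c.n:>5}  {c.strength.label} ({c.marker})"
            )
        lines.append("-" * 78)
        return "\n".join(lines)

    def plot_pairs(self, path=None):
        """Scatter + fitted-curve grid across measure pairs (see plotting)."""
        from .plotting import plot_pair_grid

        return plot_pair_grid(self.model.cohort, path=path)
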