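"""GM(1,1) grey forecasting for short positive time series.

The model fits the first-order grey differential equation
``dx1/dt + a·x1 = b`` to the accumulated (1-AGO) sequence
``x1(i) = Σ_{j≤i} x0(j)``. The developing coefficient ``a`` and grey
input ``b`` are estimated by least squares on the discretized equation
``x0(k+1) = b − a·z1(k)`` with consecutive-neighbour means
``z1(k) = (x1(k) + x1(k+1))/2``. Fitted and forecast values come from the
time-response function

    x̂1(i) = (x0(1) − b/a)·exp(−a(i−1)) + b/a,   x̂0(i) = x̂1(i) − x̂1(i−1),

with x̂0(1) = x0(1). A positive ``a`` means a decaying series, negative a
growing one. Model adequacy is judged by the mean absolute relative
residual over the fitted points (< 20% is the customary acceptability
bar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GM11Model", "fit_gm11", "forecast", "mean_relative_error",
           "generate_gm_sequence"]

# |a| below this is treated as the a -> 0 linear limit of the response
_A_LIMIT = 1e-12


@dataclass
class GM11Model:
    """Fitted GM(1,1) model.

    Sequence index ``i`` is 1-based with i = 1 the earliest observation;
    when ``years`` is given, index i maps to ``years[0] + (i - 1)``.
    """

    a: float
    b: float
    x0: np.ndarray
    x1: np.ndarray
    fitted: np.ndarray
    years: list[int] | None = None

    @property
    def n(self) -> int:
        return self.x0.size

    def response(self, i) -> np.ndarray:
        """Reconstructed original-series values x̂0 at 1-based indices ``i``
        (i ≥ 2; index 1 returns x0(1) by convention)."""
        i = np.asarray(i, dtype=float)
        c = self.x0[0] - self._b_over_a()
        if abs(self.a) < _A_LIMIT:
            out = np.where(i >= 2, np.full_like(i, self.b), self.x0[0])
        else:
            out = np.where(
                i >= 2,
                c * (1.0 - np.exp(self.a)) * np.exp(-self.a * (i - 1.0)),
                self.x0[0],
            )
        return out if out.ndim else float(out)

    def _b_over_a(self) -> float:
        return self.b / self.a if abs(self.a) >= _A_LIMIT else 0.0

    def forecast(self, horizon: int) -> "pd.Series | np.ndarray":
        """Forecast ``horizon`` steps past the sample; labelled by calendar
        year when the model carries one (last_year + k for step k)."""
        if horizon <= 0:
            raise ValueError("horizon must be a positive integer")
        idx = np.arange(self.n + 1, self.n + horizon + 1)
        values = self.response(idx)
        if self.years is not None:
            import pandas as pd

            years = [self.years[-1] + k for k in range(1, horizon + 1)]
            return pd.Series(values, index=years, name="forecast")
        return values

    def mean_relative_error(self, include_first: bool = False) -> float:
        """Mean absolute relative residual of the fitted values.

        By default the first point is excluded: its residual is
        structurally zero (x̂0(1) ≡ x0(1)) and would only dilute the
        average. Returns a fraction.
        """
        rel = np.abs(self.fitted - self.x0) / self.x0
        return float(rel.mean() if include_first else rel[1:].mean())

    @property
    def acceptable(self) -> bool:
        """Customary adequacy flag: mean relative error below 20%."""
        return self.mean_relative_error() < 0.20

    def class_ratio_bounds(self) -> tuple[float, float]:
        """Admissible class-ratio band (exp(∓2/(n+1))) for diagnostics."""
        return float(np.exp(-2.0 / (self.n + 1))), float(np.exp(2.0 / (self.n + 1)))

    def class_ratios(self) -> np.ndarray:
        """Consecutive ratios x0(k−1)/x0(k) of the original series."""
        return self.x0[:-1] / self.x0[1:]


def fit_gm11(series, years=None) -> GM11Model:
    """Fit GM(1,1) to a positive series of length ≥ 4.

    Builds the 1-AGO sequence, forms the least-squares system from the
    consecutive-neighbour means, solves for (a, b), and reconstructs the
    in-sample fitted values via the time-response function.
    """
    x0 = np.asarray(series, dtype=float)
    if x0.ndim != 1:
        raise ValueError("series must be 1-D")
    n = x0.size
    if n < 4:
        raise ValueError(f"GM(1,1) needs at least 4 observations, got {n}")
    if not (np.isfinite(x0).all() and (x0 > 0).all()):
        raise ValueError("all series values must be finite and positive")
    if years is not None:
        years = [int(y) for y in years]
        if len(years) != n:
            raise ValueError("years must match the series length")

    x1 = np.cumsum(x0)
    z1 = 0.5 * (x1[:-1] + x1[1:])
    P = np.column_stack([-z1, np.ones(n - 1)])
    Q = x0[1:]
    if np.ptp(z1) < _A_LIMIT * max(1.0, abs(z1[0])):
        raise ValueError("degenerate accumulated sequence; normal equations singular")
    (a, b), *_ = np.linalg.lstsq(P, Q, rcond=None)

    model = GM11Model(a=float(a), b=float(b), x0=x0, x1=x1,
                      fitted=np.empty(n), years=years)
    model.fitted = model.response(np.arange(1, n + 1))
    return model


def forecast(model: GM11Model, horizon: int):
    """Functional alias for :meth:`GM11Model.forecast`."""
    return model.forecast(horizon)


def mean_relative_error(model: GM11Model, include_first: bool = False) -> float:
    """Functional alias for :meth:`GM11Model.mean_relative_error`."""
    return model.mean_relative_error(include_first=include_first)


def generate_gm_sequence(a: float, b: float, x_first: float, n: int) -> np.ndarray:
    """Generate a series that satisfies the fitted model's discrete
    equation exactly, so refitting recovers (a, b) at machine precision.

    The recurrence is the trapezoid discretization the estimator solves:
    x1(k+1) = ((1 − a/2)·x1(k) + b) / (1 + a/2), x0 = first differences.
    """
    if n < 4:
        raise ValueError("need n >= 4 to produce a fittable sequence")
    x1 = np.empty(n)
    x1[0] = x_first
    for k in range(n - 1):
        x1[k + 1] = ((1.0 - a / 2.0) * x1[k] + b) / (1.0 + a / 2.0)
    x0 = np.empty(n)
    x0[0] = x_first
    x0[1:] = np.diff(x1)
    return x0
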