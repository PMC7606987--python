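"""T1/T2 estimation and relaxivity fitting.

T1 comes from a magnitude inversion-recovery fit, T2 from a
mono-exponential CPMG fit; relaxation rates are the reciprocals in s^-1;
relaxivities r1 and r2 are the ordinary-least-squares slopes of rate
versus Gd concentration, and their quotient r2/r1 characterises whether an
agent is a positive (T1) or negative (T2) contrast agent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "IRSeries",
    "CpmgSeries",
    "DilutionSeries",
    "RelaxivityFit",
    "FitError",
    "fit_t1_inversion_recovery",
    "fit_t2_cpmg",
    "relaxation_rates",
    "fit_relaxivity",
    "relaxivity_ratio",
]


class FitError(RuntimeError):
    """A relaxation fit failed to converge or hit a degenerate input."""


@dataclass(frozen=True)
class IRSeries:
    """Inversion-recovery magnitudes at increasing inversion times (ms)."""

    inversion_times_ms: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        ti = np.asarray(self.inversion_times_ms, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "inversion_times_ms", ti)
        object.__setattr__(self, "signals", s)
        if ti.shape != s.shape or ti.ndim != 1 or len(ti) < 3:
            raise ValueError("need matched 1D arrays of length >= 3")
        if not (np.all(np.diff(ti) > 0) and ti[0] > 0):
            raise ValueError("inversion times must be positive and strictly increasing")


@dataclass(frozen=True)
class CpmgSeries:
    """CPMG echo-train magnitudes at increasing echo times (ms)."""

    echo_times_ms: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "echo_times_ms", te)
        object.__setattr__(self, "signals", s)
        if te.shape != s.shape or te.ndim != 1 or len(te) < 3:
            raise ValueError("need matched 1D arrays of length >= 3")
        if not np.all(np.diff(te) > 0):
            raise ValueError("echo times must be strictly increasing")


@dataclass(frozen=True)
class DilutionSeries:
    """Concentration (mM) against T1 and/or T2 (ms)."""

    concentrations_mM: np.ndarray
    t1_ms: np.ndarray | None = None
    t2_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_mM, dtype=float)
        object.__setattr__(self, "concentrations_mM", c)
        if len(np.unique(c)) < 2:
            raise ValueError("need at least two distinct concentrations")
        for name in ("t1_ms", "t2_ms"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != c.shape:
                    raise ValueError(f"{name} must match concentrations")
                if np.any(v <= 0):
                    raise ValueError(f"{name} must be positive")
        if self.t1_ms is None and self.t2_ms is None:
            raise ValueError("need at least one of t1_ms / t2_ms")


@dataclass(frozen=True)
class RelaxivityFit:
    """OLS relaxivity estimates with diamagnetic intercepts and fit quality."""

    r1: float | None
    r2: float | None
    intercept_r1_s: float | None
    intercept_r2_s: float | None
    r_squared_r1: float | None
    r_squared_r2: float | None

    @property
    def ratio(self) -> float:
        """r2/r1 — near 1 for an ideal T1 agent, large for a T2 agent."""
        if self.r1 is None or self.r2 is None:
            raise ValueError("both relaxivities are needed for the ratio")
        return relaxivity_ratio(self.r2, self.r1)


def fit_t1_inversion_recovery(series: IRSeries) -> tuple[float, dict]:
    """Fit the two-parameter magnitude model ``|S0 (1 - 2 exp(-TI/T1))|``.

    Initialised from the signal null: at the minimum-magnitude TI,
    ``T1 ~ TI_null / ln 2``.  Returns ``(T1_ms, diagnostics)``.
    """
    ti = series.inversion_times_ms
    s = series.signals
    if np.allclose(s, s[0]):
        raise FitError("all signals equal; inversion recovery curve is degenerate")

    def model(t, s0, t1):
        return np.abs(s0 * (1.0 - 2.0 * np.exp(-t / t1)))

    t1_init = max(ti[int(np.argmin(s))] / np.log(2.0), ti[0])
    s0_init = float(np.max(s))
    try:
        popt, pcov = optimize.curve_fit(
            model, ti, s, p0=[s0_init, t1_init], maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"inversion-recovery fit did not converge: {exc}") from exc
    s0, t1 = popt
    if t1 <= 0:
        raise FitError(f"non-physical fitted T1 = {t1:.3g} ms")
    resid = s - model(ti, *popt)
    diag = {
        "s0": float(s0),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "covariance": pcov,
    }
    return float(t1), diag


def fit_t2_cpmg(series: CpmgSeries) -> tuple[float, dict]:
    """Fit ``S0 exp(-t/T2)``; log-linear initialisation, nonlinear refinement."""
    te = series.echo_times_ms
    s = series.signals
    if np.allclose(s, s[0]):
        raise FitError("all signals equal; CPMG decay is degenerate")
    pos = s > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(te[pos], np.log(s[pos]), 1)
        t2_init = -1.0 / slope if slope < 0 else float(te[-1])
        s0_init = float(np.exp(intercept))
    else:
        t2_init, s0_init = float(te[-1]), float(np.max(s))

    def model(t, s0, t2):
        return s0 * np.exp(-t / t2)

    try:
        popt, pcov = optimize.curve_fit(
            model, te, s, p0=[s0_init, max(t2_init, te[0])], maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"CPMG fit did not converge: {exc}") from exc
    s0, t2 = popt
    if t2 <= 0:
        raise FitError(f"non-physical fitted T2 = {t2:.3g} ms")
    resid = s - model(te, *popt)
    return float(t2), {"s0": float(s0), "rmse": float(np.sqrt(np.mean(resid**2))), "covariance": pcov}


def relaxation_rates(t1_ms: float, t2_ms: float) -> tuple[float, float]:
    """Convert relaxation times (ms) to rates (s^-1): ``R = 1000 / T``."""
    if t1_ms <= 0 or t2_ms <= 0:
        raise ValueError("relaxation times must be positive")
    return 1000.0 / t1_ms, 1000.0 / t2_ms


def _ols_rate_fit(conc: np.ndarray, rates: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(conc, rates)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_relaxivity(series: DilutionSeries) -> RelaxivityFit:
    """OLS slope of relaxation rate against concentration, per channel.

    The intercept is left free (the diamagnetic baseline rate of the
    solvent); exact on collinear input.
    """
    conc = series.concentrations_mM
    out: dict[str, tuple[float, float, float] | None] = {"r1": None, "r2": None}
    if series.t1_ms is not None:
        out["r1"] = _ols_rate_fit(conc, 1000.0 / series.t1_ms)
    if series.t2_ms is not None:
        out["r2"] = _ols_rate_fit(conc, 1000.0 / series.t2_ms)
    f1, f2 = out["r1"], out["r2"]
    return RelaxivityFit(
        r1=f1[0] if f1 else None,
        r2=f2[0] if f2 else None,
        intercept_r1_s=f1[1] if f1 else None,
        intercept_r2_s=f2[1] if f2 else None,
        r_squared_r1=f1[2] if f1 else None,
        r_squared_r2=f2[2] if f2 else None,
    )


def relaxivity_ratio(r2: float, r1: float) -> float:
    """The r2/r1 quotient; requires r1 > 0."""
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    return r2 / r1
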