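"""Closed-form batch fermentation kinetics and nonlinear least-squares fitting.

Three unstructured models describe a batch culture growing on cheese whey:

* **Biomass** follows logistic growth
  ``dX/dt = mu X (1 - X/Xm)``, whose closed form is the sigmoid
  ``X(t) = X0 Xm e^{mu t} / (Xm - X0 + X0 e^{mu t})``.
* **Lactose** obeys a yield-plus-maintenance mass balance
  ``-dS/dt = (1/Y_XS) dX/dt + mC X``; integrating against the logistic
  biomass gives a closed form with a logarithmic maintenance term.
* **Product** (beta-cryptoxanthin) follows Luedeking–Piret kinetics
  ``dP/dt = alpha dX/dt + beta X`` with a delay ``delta_t`` of production
  relative to growth, so the integrated curve evaluates the biomass
  trajectory at ``t - delta_t`` and is exactly zero at ``t = 0``.

Fitting is two-stage, mirroring how such data are analysed: growth
parameters first, then substrate and product parameters conditional on the
fitted growth curve. Each fit is a multi-start trust-region least-squares
minimization of the residual sum of squares; goodness statistics (SS, R²,
observed-series sigma, residual standard deviation S_y.x and MSE% = 100·SS/n)
are the ones conventionally reported alongside such fits.

All exponentials are evaluated through ``e^{-mu t}`` forms so trajectories
stay finite for arbitrarily large ``mu·t``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = [
    "GrowthParams",
    "SubstrateParams",
    "ProductParams",
    "TimeCourse",
    "FitQuality",
    "logistic_X",
    "substrate_SL",
    "product_P",
    "fit_growth",
    "fit_substrate",
    "fit_product",
    "goodness",
    "FitError",
]


class FitError(RuntimeError):
    """Nonlinear fit failed from every start; carries the best partial result."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth parameters: inoculum X0, carrying capacity Xm (g/l),
    specific growth rate mu (1/h); requires 0 < X0 < Xm and mu > 0."""

    X0: float
    Xm: float
    mu: float

    def __post_init__(self):
        if not (0 < self.X0 < self.Xm):
            raise ValueError(f"need 0 < X0 < Xm, got X0={self.X0}, Xm={self.Xm}")
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")


@dataclass(frozen=True)
class SubstrateParams:
    """Lactose balance parameters: initial lactose SL0 (g/l), yield
    coefficient Y_XS (g biomass per g lactose) and maintenance coefficient
    mC (g lactose per g biomass per h)."""

    SL0: float
    Y_XS: float
    mC: float

    def __post_init__(self):
        if not self.SL0 > 0:
            raise ValueError(f"SL0 must be > 0, got {self.SL0}")
        if not self.Y_XS > 0:
            raise ValueError(f"Y_XS must be > 0, got {self.Y_XS}")
        if self.mC < 0:
            raise ValueError(f"mC must be >= 0, got {self.mC}")


@dataclass(frozen=True)
class ProductParams:
    """Luedeking–Piret parameters: growth-associated alpha (mg product per g
    biomass), non-growth beta (mg per g per h) and production delay delta_t (h)."""

    alpha: float
    beta: float
    delta_t: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.delta_t < 0:
            raise ValueError("alpha, beta and delta_t must be non-negative")


@dataclass
class TimeCourse:
    """One batch time course. Channels may be missing (None) or carry NaN at
    unsampled times; times are hours, ascending, starting at or after 0."""

    t: np.ndarray
    X: np.ndarray | None = None
    SL: np.ndarray | None = None
    P: np.ndarray | None = None
    condition: float | None = None  # cheese whey dose, % v/v

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size and (np.any(np.diff(self.t) < 0) or self.t[0] < 0):
            raise ValueError("t must be ascending and start at >= 0")
        for ch in ("X", "SL", "P"):
            v = getattr(self, ch)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.t.shape:
                    raise ValueError(f"channel {ch} length mismatch")
                if np.any(v[np.isfinite(v)] < 0):
                    raise ValueError(f"channel {ch} has negative concentrations")
                setattr(self, ch, v)

    def channel(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (t, values) with missing entries dropped."""
        v = getattr(self, name)
        if v is None:
            raise ValueError(f"time course has no {name} channel")
        ok = np.isfinite(v)
        return self.t[ok], v[ok]


@dataclass(frozen=True)
class FitQuality:
    """Goodness-of-fit summary: SS = sum of squared residuals, r2, sigma =
    sample standard deviation of the observations, Syx = sqrt(SS/df) with
    df = n - n_params, MSEpct = 100·SS/n."""

    SS: float
    r2: float
    sigma: float
    Syx: float
    MSEpct: float
    n: int
    df: int


def _log_denom_ratio(t, g: GrowthParams):
    """log[(Xm - X0 + X0 e^{mu t}) / Xm], overflow-safe for large mu*t."""
    t = np.asarray(t, dtype=float)
    # = mu*t + log[(X0 + (Xm - X0) e^{-mu t}) / Xm]
    return g.mu * t + np.log((g.X0 + (g.Xm - g.X0) * np.exp(-g.mu * t)) / g.Xm)


def logistic_X(t, g: GrowthParams):
    """Logistic biomass trajectory; X(0) = X0, X(inf) = Xm."""
    t = np.asarray(t, dtype=float)
    return g.Xm / (1.0 + ((g.Xm - g.X0) / g.X0) * np.exp(-g.mu * t))


def substrate_SL(t, g: GrowthParams, s: SubstrateParams, warn_negative: bool = False):
    """Closed-form lactose trajectory under the yield + maintenance balance.

    The model curve may cross zero at long times (the maintenance term is
    unbounded); the raw value is returned so the fitted curve matches the
    closed form, with ``warn_negative=True`` attaching a flag array instead.
    """
    X = logistic_X(t, g)
    out = (
        s.SL0
        - (X - g.X0) / s.Y_XS
        - (g.Xm * s.mC / g.mu) * _log_denom_ratio(t, g)
    )
    if warn_negative:
        return out, out < 0
    return out


def product_P(t, g: GrowthParams, p: ProductParams):
    """Delayed Luedeking–Piret product trajectory; identically 0 at t = 0."""
    t = np.asarray(t, dtype=float)
    shifted = t - p.delta_t
    ref = -p.delta_t
    growth_part = logistic_X(shifted, g) - logistic_X(ref, g)
    nongrowth_part = _log_denom_ratio(shifted, g) - _log_denom_ratio(ref, g)
    return p.alpha * growth_part + (g.Xm * p.beta / g.mu) * nongrowth_part


def goodness(observed, predicted, n_params: int) -> FitQuality:
    """Fit statistics for an observed/predicted pair of equal-length series."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed/predicted length mismatch")
    n = observed.size
    df = n - n_params
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, params={n_params})")
    resid = observed - predicted
    ss = float(resid @ resid)
    sst = float(((observed - observed.mean()) ** 2).sum())
    return FitQuality(
        SS=ss,
        r2=1.0 - ss / sst if sst > 0 else np.nan,
        sigma=float(np.std(observed, ddof=1)),
        Syx=float(np.sqrt(ss / df)),
        MSEpct=100.0 * ss / n,
        n=n,
        df=df,
    )


def _multistart_ls(residual, starts, bounds, x_scale=None):
    """Run trust-region least squares from each start; keep the lowest SS.

    Ties (within 1e-10 relative) break toward the smaller parameter norm.
    Raises :class:`FitError` when no start converges.
    """
    best = None
    best_cost = np.inf
    n_ok = 0
    for x0 in starts:
        try:
            res = least_squares(
                residual,
                x0,
                bounds=bounds,
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                x_scale=x_scale if x_scale is not None else "jac",
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        n_ok += 1
        better = res.cost < best_cost * (1 - 1e-10)
        tied = abs(res.cost - best_cost) <= 1e-10 * max(best_cost, 1e-300)
        if best is None or better or (
            tied and np.linalg.norm(res.x) < np.linalg.norm(best.x)
        ):
            best, best_cost = res, res.cost
    if best is None:
        raise FitError("no start converged", best=None)
    return best


def _lhs_starts(lo, hi, n_starts, seed):
    sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
    u = sampler.random(n_starts)
    return qmc.scale(u, lo, hi)


def fit_growth(
    tc: TimeCourse, starts=None, n_starts: int = 16, seed: int = 0
) -> tuple[GrowthParams, FitQuality]:
    """Fit the logistic model to the biomass channel.

    Multi-start least squares with Latin-hypercube starts over
    X0 in (1e-3, 0.2), Xm in (0.5, 2)·max(X) and mu in (0.01, 1); three
    parameters are charged to the degrees of freedom.
    """
    t, X = tc.channel("X")
    if t.size < 4:
        raise ValueError("need at least 4 biomass points")
    if np.ptp(X) <= 1e-12 * max(abs(X).max(), 1.0):
        raise FitError("biomass series is constant: growth rate unidentifiable")
    xmax = X.max()

    def residual(theta):
        x0, xm, mu = theta
        g = GrowthParams(min(x0, xm * (1 - 1e-9)), xm, mu)
        return logistic_X(t, g) - X

    lo = np.array([1e-3, 0.5 * xmax, 0.01])
    hi = np.array([0.2, 2.0 * xmax, 1.0])
    if starts is None:
        starts = _lhs_starts(lo, hi, n_starts, seed)
    bounds = (np.array([1e-6, 1e-6, 1e-4]), np.array([np.inf, np.inf, 10.0]))
    best = _multistart_ls(residual, starts, bounds)
    g = GrowthParams(*best.x)
    return g, goodness(X, logistic_X(t, g), n_params=3)


def fit_substrate(
    tc: TimeCourse, g: GrowthParams, n_starts: int = 16, seed: int = 0
) -> tuple[SubstrateParams, FitQuality]:
    """Fit SL0, Y_XS and mC to the lactose channel, conditional on a fitted
    growth curve (two-stage estimation)."""
    t, SL = tc.channel("SL")
    if t.size < 3:
        raise ValueError("need at least 3 lactose points")
    smax = SL.max()
    dX = g.Xm - g.X0

    def residual(theta):
        sl0, y, mc = theta
        return substrate_SL(t, g, SubstrateParams(sl0, y, mc)) - SL

    # yield bracket from the no-maintenance mass balance dX = Y * dS
    y_guess = dX / max(smax * 0.9, 1e-6)
    lo = np.array([0.5 * smax, 0.2 * y_guess, 0.0])
    hi = np.array([1.5 * smax, 20.0 * y_guess, 0.1])
    starts = _lhs_starts(lo, hi, n_starts, seed)
    bounds = (np.array([1e-6, 1e-6, 0.0]), np.array([np.inf, np.inf, np.inf]))
    best = _multistart_ls(residual, starts, bounds)
    s = SubstrateParams(*best.x)
    return s, goodness(SL, substrate_SL(t, g, s), n_params=3)


def fit_product(
    tc: TimeCourse, g: GrowthParams, n_starts: int = 16, seed: int = 0,
    delay_bounds: tuple[float, float] = (0.0, 12.0),
) -> tuple[ProductParams, FitQuality]:
    """Fit alpha, beta and the production delay to the product channel,
    conditional on a fitted growth curve. The delay is box-bounded (default
    0–12 h, a small fraction of a batch)."""
    t, P = tc.channel("P")
    if t.size < 3:
        raise ValueError("need at least 3 product points")
    pmax = max(P.max(), 1e-6)
    dX = g.Xm - g.X0

    def residual(theta):
        a, b, dt_ = theta
        return product_P(t, g, ProductParams(a, b, dt_)) - P

    a_guess = pmax / dX
    lo = np.array([0.0, 0.0, delay_bounds[0]])
    hi = np.array([5.0 * a_guess, 0.2 * a_guess, delay_bounds[1]])
    starts = _lhs_starts(lo, hi, n_starts, seed)
    bounds = (
        np.array([0.0, 0.0, delay_bounds[0]]),
        np.array([np.inf, np.inf, delay_bounds[1]]),
    )
    best = _multistart_ls(residual, starts, bounds)
    p = ProductParams(*best.x)
    return p, goodness(P, product_P(t, g, p), n_params=3)
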