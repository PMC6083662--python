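"""Substrate-inhibition models for the specific growth rate mu(S).

When the specific growth rate of a batch culture first rises and then falls
with the initial substrate dose, plain Monod saturation cannot describe the
data and an inhibition term is needed. This module ships the standard
comparison set — Monod, Andrews (Haldane), Aiba, Webb, Luong and
Han–Levenspiel — fits any of them to (S, mu) data by multi-start nonlinear
least squares, and ranks them on the usual goodness statistics.

The Han–Levenspiel form

    mu = mu_max (1 - S/Sm)^n · S / (S + Ks (1 - S/Sm)^m)

generalizes Monod with a critical substrate concentration ``Sm`` above which
growth ceases; with both exponents zero it reduces exactly to Monod. S is
expressed here in % (v/v) cheese whey, the dose actually varied in the
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .kinetics import FitError, FitQuality, goodness, _multistart_ls

__all__ = [
    "MuDataset",
    "InhibitionFit",
    "MODELS",
    "mu_model",
    "fit_inhibition",
    "compare_models",
]


@dataclass
class MuDataset:
    """Paired (S, mu) observations: initial substrate dose (% v/v) against the
    specific growth rate (1/h) estimated from each batch."""

    S: np.ndarray
    mu: np.ndarray

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.S.shape != self.mu.shape or self.S.size < 4:
            raise ValueError("need >= 4 paired (S, mu) points")
        if np.any(self.S < 0) or np.any(self.mu < 0):
            raise ValueError("S and mu must be non-negative")
        if np.unique(self.S).size != self.S.size:
            raise ValueError("S values must be distinct")


def _monod(S, p):
    return p["mu_max"] * S / (p["Ks"] + S)


def _andrews(S, p):  # Haldane
    return p["mu_max"] * S / (p["Ks"] + S + S**2 / p["Ki"])


def _aiba(S, p):
    return p["mu_max"] * S / (p["Ks"] + S) * np.exp(-S / p["Ki"])


def _webb(S, p):
    return p["mu_max"] * S * (1 + S / p["K"]) / (p["Ks"] + S + S**2 / p["Ki"])


def _bounded_factor(S, Sm, expnt):
    """(1 - S/Sm)^expnt, defined as 0 beyond the critical dose Sm."""
    frac = 1.0 - np.asarray(S, dtype=float) / Sm
    return np.where(frac > 0, np.power(np.clip(frac, 0, None), expnt), 0.0)


def _luong(S, p):
    return p["mu_max"] * S / (p["Ks"] + S) * _bounded_factor(S, p["Sm"], p["exp_n"])


def _han_levenspiel(S, p):
    num = p["mu_max"] * _bounded_factor(S, p["Sm"], p["exp_n"]) * S
    den = S + p["Ks"] * _bounded_factor(S, p["Sm"], p["exp_m"])
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


@dataclass(frozen=True)
class _ModelSpec:
    fn: object
    params: tuple[str, ...]
    # per-parameter multi-start bracket builders, given the data
    bracket: object


def _smax_brackets(extra):
    def build(data: MuDataset):
        smax = data.S.max()
        mumax = data.mu.max()
        base = {
            "mu_max": (0.5 * mumax, 5.0 * mumax),
            "Ks": (0.1, 5.0 * smax),
            "Ki": (0.1, 10.0 * smax),
            "K": (0.1, 10.0 * smax),
            "Sm": (smax * 1.01, 3.0 * smax),
            "exp_n": (0.05, 5.0),
            "exp_m": (0.05, 5.0),
        }
        base.update(extra)
        return base

    return build


MODELS: dict[str, _ModelSpec] = {
    "monod": _ModelSpec(_monod, ("mu_max", "Ks"), _smax_brackets({})),
    "andrews": _ModelSpec(_andrews, ("mu_max", "Ks", "Ki"), _smax_brackets({})),
    "aiba": _ModelSpec(_aiba, ("mu_max", "Ks", "Ki"), _smax_brackets({})),
    "webb": _ModelSpec(_webb, ("mu_max", "Ks", "Ki", "K"), _smax_brackets({})),
    "luong": _ModelSpec(_luong, ("mu_max", "Ks", "Sm", "exp_n"), _smax_brackets({})),
    "han_levenspiel": _ModelSpec(
        _han_levenspiel,
        ("mu_max", "Ks", "Sm", "exp_n", "exp_m"),
        _smax_brackets({}),
    ),
}


def mu_model(S, model: str, params: dict) -> np.ndarray:
    """Evaluate a named mu(S) model; bounded models return 0 beyond Sm."""
    if model not in MODELS:
        raise KeyError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    spec = MODELS[model]
    missing = set(spec.params) - set(params)
    if missing:
        raise ValueError(f"model {model!r} missing parameters {sorted(missing)}")
    S_arr = np.asarray(S, dtype=float)
    out = spec.fn(S_arr, params)
    return out if np.ndim(S) else float(out)


@dataclass
class InhibitionFit:
    """One fitted mu(S) model with its parameters, fit quality and the
    multi-start provenance (number of starts, winning start index)."""

    model: str
    params: dict[str, float]
    quality: FitQuality
    n_starts: int
    seed: int

    def predict(self, S):
        return mu_model(S, self.model, self.params)


def fit_inhibition(
    data: MuDataset, model: str, n_starts: int = 200, seed: int = 0
) -> InhibitionFit:
    """Fit one named model to (S, mu) data by multi-start least squares.

    Starts come from a Latin hypercube over data-scaled parameter brackets
    (for bounded models the critical dose Sm starts above max S so the whole
    dataset is inside the growth domain); the lowest-SS solution is kept.
    """
    if model not in MODELS:
        raise KeyError(f"unknown model {model!r}")
    spec = MODELS[model]
    if data.S.size <= len(spec.params):
        raise ValueError(
            f"need more points than parameters ({len(spec.params)}) for {model!r}"
        )
    brackets = spec.bracket(data)
    lo = np.array([brackets[p][0] for p in spec.params])
    hi = np.array([brackets[p][1] for p in spec.params])
    sampler = qmc.LatinHypercube(d=lo.size, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lo, hi)

    def residual(theta):
        p = dict(zip(spec.params, theta))
        return spec.fn(data.S, p) - data.mu

    # fit inside the same interpretable regime the starts cover: without the
    # upper bounds the flexible forms drift to degenerate parameter ridges
    # (Sm and the exponents growing together) with no gain in meaning
    lower = np.full(lo.size, 1e-8)
    upper = hi.copy()
    if "Sm" in spec.params:
        # keep every observation inside the growth domain during fitting
        lower[spec.params.index("Sm")] = data.S.max() * (1 + 1e-6)
    best = _multistart_ls(residual, starts, (lower, upper), x_scale=np.maximum(hi, 1e-3))
    params = dict(zip(spec.params, (float(v) for v in best.x)))
    q = goodness(data.mu, mu_model(data.S, model, params), n_params=len(spec.params))
    return InhibitionFit(model=model, params=params, quality=q,
                         n_starts=n_starts, seed=seed)


def compare_models(
    data: MuDataset, models: list[str] | None = None,
    n_starts: int = 200, seed: int = 0,
) -> pd.DataFrame:
    """Fit several models and rank them by R² (descending).

    Returns one row per model with all goodness columns plus the fitted
    parameters; the first row is the winning model. Ties in R² break by SS.
    """
    if models is None:
        models = list(MODELS)
    if len(models) < 1:
        raise ValueError("need at least one model")
    rows = []
    for m in models:
        try:
            fit = fit_inhibition(data, m, n_starts=n_starts, seed=seed)
        except FitError:
            continue
        q = fit.quality
        rows.append(
            {
                "model": m,
                "R2": q.r2,
                "sigma": q.sigma,
                "SS": q.SS,
                "Syx": q.Syx,
                "MSEpct": q.MSEpct,
                "n_params": len(MODELS[m].params),
                "params": fit.params,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["R2", "SS"], ascending=[False, True], kind="mergesort"
    )
    return table.reset_index(drop=True)
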