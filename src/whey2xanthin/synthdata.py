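"""Synthetic data generation and packaged study fixtures.

The raw batch time courses behind the published figures were never
deposited, so every test and simulation here runs on data generated from the
closed-form models themselves: noisy biomass/lactose/product trajectories
from the kinetic equations, designed-experiment response tables from a known
quadratic surface, and mu-versus-substrate datasets from a chosen inhibition
model. Noise is additive Gaussian per channel (the simplest defensible error
model for spectrophotometric and gravimetric assays); all draws go through
``numpy.random.default_rng`` so a spec plus a seed reproduces bit-identical
tables on any platform.

The module also exposes the two printed data tables as packaged fixtures:
the 30-run central composite design with both responses, and the kinetic
parameter sets at seven cheese-whey doses (whose mu row doubles as the
substrate-inhibition dataset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .inhibition import MuDataset, mu_model
from .kinetics import (
    GrowthParams,
    ProductParams,
    SubstrateParams,
    TimeCourse,
    logistic_X,
    product_P,
    substrate_SL,
)
from .rsm import DEFAULT_FACTORS, Design, QuadraticSurface, build_ccd, predict

__all__ = [
    "SynthSpec",
    "gen_timecourse",
    "gen_ccd_responses",
    "gen_mu_dataset",
    "fixtures",
    "table1_design",
    "table3_params",
    "mu_row",
    "DEFAULT_TIME_GRID",
    "DEFAULT_LACTOSE_GRID",
    "DEFAULT_NOISE_SD",
]

#: Default sampling grid for simulated batches: 0-120 h every 2 h (61 points),
#: the density consistent with the published per-curve fit statistics.
DEFAULT_TIME_GRID = np.arange(0.0, 121.0, 2.0)

#: Lactose is assayed more sparsely than biomass; 11 points over the batch.
DEFAULT_LACTOSE_GRID = np.arange(0.0, 121.0, 12.0)

#: Default per-channel noise (sd of the additive Gaussian), chosen so that
#: simulated fit statistics resemble the magnitudes reported for the real
#: curves: biomass ~0.17 g/l, lactose ~0.07 g/l, product ~0.08 mg/l.
DEFAULT_NOISE_SD = {"X": 0.17, "SL": 0.07, "P": 0.08}


@dataclass
class SynthSpec:
    """Declarative recipe for one synthetic dataset.

    ``kind`` selects the generator; ``params`` carries the generating model
    parameters; ``noise`` maps channel names to Gaussian sds; ``grid`` is the
    sampling grid (time in hours, or substrate doses). The same spec and seed
    always produce the same output.
    """

    kind: str  # 'timecourse' | 'ccd' | 'mu_vs_s'
    params: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    grid: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        for sd in self.noise.values():
            if sd < 0:
                raise ValueError("noise sd must be >= 0")
        if self.grid is not None:
            self.grid = np.asarray(self.grid, dtype=float)
            if self.grid.size == 0:
                raise ValueError("grid must be non-empty")


def gen_timecourse(
    g: GrowthParams,
    s: SubstrateParams | None = None,
    p: ProductParams | None = None,
    t=None,
    t_lactose=None,
    noise_sd: dict | None = None,
    seed: int = 0,
    condition: float | None = None,
) -> TimeCourse:
    """Simulate one noisy batch from the closed-form kinetic models.

    Biomass and product are sampled on ``t`` (default 61 points over 120 h),
    lactose on its own sparser grid aligned into ``t`` (other entries NaN).
    Noise is added to the closed-form mean curve and the noisy values are
    clipped at zero — real assays cannot report negative concentrations —
    while the mean curves themselves are never clipped.
    """
    rng = np.random.default_rng(seed)
    t = DEFAULT_TIME_GRID.copy() if t is None else np.asarray(t, dtype=float)
    sd = dict(DEFAULT_NOISE_SD if noise_sd is None else noise_sd)

    X = logistic_X(t, g)
    X_obs = np.clip(X + rng.normal(0, sd.get("X", 0.0), t.size), 0, None) \
        if sd.get("X", 0.0) > 0 else X.copy()

    SL_obs = None
    if s is not None:
        tl = DEFAULT_LACTOSE_GRID.copy() if t_lactose is None \
            else np.asarray(t_lactose, dtype=float)
        SL_obs = np.full(t.size, np.nan)
        mask = np.isin(t, tl)
        if not mask.any():  # lactose grid disjoint from t: append it
            raise ValueError("lactose grid must be a subset of the time grid")
        mean = substrate_SL(t[mask], g, s)
        vals = mean + rng.normal(0, sd.get("SL", 0.0), mean.size) \
            if sd.get("SL", 0.0) > 0 else mean
        SL_obs[mask] = np.clip(vals, 0, None)

    P_obs = None
    if p is not None:
        mean = product_P(t, g, p)
        vals = mean + rng.normal(0, sd.get("P", 0.0), t.size) \
            if sd.get("P", 0.0) > 0 else mean
        P_obs = np.clip(vals, 0, None)

    return TimeCourse(t=t, X=X_obs, SL=SL_obs, P=P_obs, condition=condition)


def gen_ccd_responses(
    surfaces: list[QuadraticSurface],
    n_center: int = 6,
    noise_sd: float | dict = 0.0,
    seed: int = 0,
    factors=None,
) -> Design:
    """Build a CCD and fill its response columns from known surfaces + noise.

    Enables parameter-recovery tests for the response-surface fitter: with
    ``noise_sd=0`` a refit returns the generating coefficients to machine
    precision; with noise, replicate centre points estimate the injected
    variance as pure error.
    """
    factors = list(DEFAULT_FACTORS) if factors is None else list(factors)
    rng = np.random.default_rng(seed)
    design = build_ccd(factors, n_center=n_center)
    for surf in surfaces:
        sd = noise_sd.get(surf.response_name, 0.0) if isinstance(noise_sd, dict) \
            else float(noise_sd)
        mean = predict(surf, design.runs)
        design.responses[surf.response_name] = mean + rng.normal(0, sd, design.n_runs) \
            if sd > 0 else np.asarray(mean, dtype=float)
    return design


def gen_mu_dataset(
    model: str, params: dict, S, noise_sd: float = 0.0, seed: int = 0
) -> MuDataset:
    """Generate a (S, mu) dataset from a named inhibition model plus noise.

    Noisy rates are clipped at zero (a growth rate cannot be negative)."""
    rng = np.random.default_rng(seed)
    S = np.asarray(S, dtype=float)
    mu = np.asarray(mu_model(S, model, params), dtype=float)
    if noise_sd > 0:
        mu = np.clip(mu + rng.normal(0, noise_sd, S.size), 0, None)
    return MuDataset(S=S, mu=mu)


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("whey2xanthin.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def table1_design() -> Design:
    """The packaged 30-run central composite design with both responses.

    16 factorial corners at ±1, 8 axial points at ±2 and 6 centre replicates
    over yeast extract, peptone, cheese whey and initial pH, with the product
    yield (mg/l) and biomass (g/l) measured in each run.
    """
    df = _load_csv("table1_ccd.csv")
    factors = list(DEFAULT_FACTORS)
    actual = df[[f.name for f in factors]].to_numpy(float)
    runs = np.column_stack(
        [f.code(actual[:, j]) for j, f in enumerate(factors)]
    )
    return Design(
        factors=factors,
        runs=runs,
        n_center=int(np.all(runs == 0, axis=1).sum()),
        responses={
            "bcrx_mg_l": df["bcrx_mg_l"].to_numpy(float),
            "biomass_g_l": df["biomass_g_l"].to_numpy(float),
        },
    )


def table3_params() -> dict[float, dict]:
    """Published kinetic parameter sets, one per cheese-whey dose (% v/v).

    Each entry carries the growth, substrate and product parameter objects
    fitted to that batch.
    """
    df = _load_csv("table3_kinetics.csv")
    out = {}
    for _, r in df.iterrows():
        out[float(r["cheese_whey_pct_v_v"])] = {
            "growth": GrowthParams(r["X0_g_l"], r["Xm_g_l"], r["mu_per_h"]),
            "substrate": SubstrateParams(r["SL0_g_l"], r["Y_XS_g_g"], r["mC_g_g_h"]),
            "product": ProductParams(r["alpha_mg_g"], r["beta_mg_g_h"], r["delta_t_h"]),
        }
    return out


def mu_row() -> MuDataset:
    """The seven (cheese-whey dose, specific growth rate) pairs used for
    substrate-inhibition model comparison."""
    df = _load_csv("mu_vs_whey.csv")
    return MuDataset(S=df["substrate_pct_v_v"].to_numpy(float),
                     mu=df["mu_per_h"].to_numpy(float))


def fixtures() -> dict:
    """All packaged fixtures: {'table1': Design, 'table3': params, 'mu': MuDataset}."""
    return {"table1": table1_design(), "table3": table3_params(), "mu": mu_row()}
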