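"""Central composite designs and second-order response surfaces.

This module covers the design-of-experiments arm of the pipeline: building a
rotatable central composite design (CCD) in coded units, converting between
actual and coded factor levels, fitting the full quadratic response surface by
ordinary least squares, producing a Design-Expert-style ANOVA (partial
type-III sums of squares, lack of fit against pure error, PRESS/predicted R²,
adequate precision, standardized effects) and locating single- or
multi-response optima over the coded box via Derringer–Suich desirability.

All model fitting happens in coded units ``z = (x - center) / step`` so that
the design is symmetric about the origin and coefficient magnitudes are
directly comparable across factors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize as sp_optimize
from scipy import stats as sp_stats

__all__ = [
    "Factor",
    "Design",
    "QuadraticSurface",
    "AnovaReport",
    "OptimizationResult",
    "build_ccd",
    "code_point",
    "decode_point",
    "fit_quadratic",
    "anova",
    "predict",
    "optimize",
    "standardized_effects",
]


@dataclass(frozen=True)
class Factor:
    """One design factor with its coding transform.

    The coded level of an actual value ``x`` is ``(x - center) / step``;
    ``step`` is the actual-unit width of one coded unit and must be positive.
    """

    name: str
    center: float
    step: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0, got {self.step}")

    def code(self, x):
        return (np.asarray(x, dtype=float) - self.center) / self.step

    def decode(self, z):
        return np.asarray(z, dtype=float) * self.step + self.center


@dataclass
class Design:
    """A coded experimental design plus response columns.

    ``runs`` holds the design points in coded units, one row per run, columns
    ordered as ``factors``. Responses are named columns with one value per
    run. ``center_mask`` marks the replicated all-zero centre runs used for
    the pure-error partition.
    """

    factors: list[Factor]
    runs: np.ndarray
    n_center: int
    responses: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.runs = np.atleast_2d(np.asarray(self.runs, dtype=float))
        if self.runs.shape[1] != len(self.factors):
            raise ValueError("runs/factors dimension mismatch")
        for name, col in list(self.responses.items()):
            col = np.asarray(col, dtype=float)
            if col.shape != (self.n_runs,):
                raise ValueError(
                    f"response {name!r} has {col.size} entries, expected {self.n_runs}"
                )
            self.responses[name] = col

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def center_mask(self) -> np.ndarray:
        return np.all(self.runs == 0.0, axis=1)

    def actual(self) -> np.ndarray:
        """Design points in actual (uncoded) units."""
        return np.column_stack(
            [f.decode(self.runs[:, j]) for j, f in enumerate(self.factors)]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.actual(), columns=[f.name for f in self.factors])
        for name, col in self.responses.items():
            df[name] = col
        return df


def _term_names(factor_names: list[str]) -> list[str]:
    """Quadratic model terms: intercept, linear, pairwise interactions, squares."""
    n = len(factor_names)
    names = ["Intercept"] + list(factor_names)
    names += [
        f"{factor_names[i]}:{factor_names[j]}"
        for i, j in itertools.combinations(range(n), 2)
    ]
    names += [f"{f}^2" for f in factor_names]
    return names


def _model_matrix(Z: np.ndarray) -> np.ndarray:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[1]
    cols = [np.ones(Z.shape[0])]
    cols += [Z[:, j] for j in range(n)]
    cols += [Z[:, i] * Z[:, j] for i, j in itertools.combinations(range(n), 2)]
    cols += [Z[:, j] ** 2 for j in range(n)]
    return np.column_stack(cols)


@dataclass
class QuadraticSurface:
    """Full second-order polynomial in coded units.

    ``interaction`` is keyed by factor-name pairs in the combinatorial order
    of the model matrix. Prediction is a pure polynomial evaluation; the
    surface knows nothing about the data it was fitted to.
    """

    response_name: str
    factor_names: list[str]
    intercept: float
    linear: np.ndarray
    interaction: dict[tuple[str, str], float]
    quadratic: np.ndarray

    @property
    def n_terms(self) -> int:
        n = len(self.factor_names)
        return 1 + 2 * n + n * (n - 1) // 2

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficient vector in model-matrix order."""
        inter = [
            self.interaction[(self.factor_names[i], self.factor_names[j])]
            for i, j in itertools.combinations(range(len(self.factor_names)), 2)
        ]
        return np.concatenate(
            [[self.intercept], self.linear, inter, self.quadratic]
        )

    @classmethod
    def from_coefficients(
        cls, response_name: str, factor_names: list[str], beta: np.ndarray
    ) -> "QuadraticSurface":
        n = len(factor_names)
        beta = np.asarray(beta, dtype=float)
        expected = 1 + 2 * n + n * (n - 1) // 2
        if beta.size != expected:
            raise ValueError(f"expected {expected} coefficients, got {beta.size}")
        pairs = list(itertools.combinations(range(n), 2))
        return cls(
            response_name=response_name,
            factor_names=list(factor_names),
            intercept=float(beta[0]),
            linear=beta[1 : 1 + n].copy(),
            interaction={
                (factor_names[i], factor_names[j]): float(beta[1 + n + k])
                for k, (i, j) in enumerate(pairs)
            },
            quadratic=beta[1 + n + len(pairs) :].copy(),
        )


@dataclass
class AnovaReport:
    """Design-Expert-style ANOVA for a fitted quadratic surface.

    ``table`` rows: the model, each term (partial type-III SS), residual,
    lack-of-fit, pure-error and corrected-total entries with SS/df/MS/F/p.
    Pure error comes from the replicated centre points; lack of fit is the
    remainder of the residual. ``standardized_effects`` are per-term
    |t|-values (t² equals the term's partial F); ``t_critical`` is the
    two-sided 5% threshold at the residual df drawn in the Pareto chart.
    """

    response_name: str
    table: pd.DataFrame
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    adeq_precision: float
    standardized_effects: pd.Series
    t_critical: float


def build_ccd(factors: list[Factor], n_center: int) -> Design:
    """Build a full central composite design in coded units.

    The design has ``2^n`` factorial corners at ±1, ``2n`` axial points at
    ±alpha on one axis at a time, and ``n_center`` all-zero centre
    replicates, for ``N = 2^n + 2n + n_center`` runs. The axial distance is
    the rotatable ``alpha = 2^(n/4)`` rounded to two decimals, which gives
    the conventional alpha = 2 for four factors.
    """
    n = len(factors)
    if not 2 <= n <= 6:
        raise ValueError(f"need between 2 and 6 factors, got {n}")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    alpha = round(2.0 ** (n / 4.0), 2)
    factorial = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
    axial = np.zeros((2 * n, n))
    for j in range(n):
        axial[2 * j, j] = -alpha
        axial[2 * j + 1, j] = alpha
    center = np.zeros((n_center, n))
    return Design(
        factors=list(factors),
        runs=np.vstack([factorial, axial, center]),
        n_center=n_center,
    )


def code_point(factors: list[Factor], actual) -> np.ndarray:
    """Convert a point (or array of points) from actual to coded units."""
    actual = np.asarray(actual, dtype=float)
    if actual.shape[-1] != len(factors):
        raise ValueError(
            f"point has {actual.shape[-1]} coordinates, expected {len(factors)}"
        )
    return np.stack(
        [f.code(np.take(actual, j, axis=-1)) for j, f in enumerate(factors)], axis=-1
    )


def decode_point(factors: list[Factor], coded) -> np.ndarray:
    """Inverse of :func:`code_point`."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != len(factors):
        raise ValueError(
            f"point has {coded.shape[-1]} coordinates, expected {len(factors)}"
        )
    return np.stack(
        [f.decode(np.take(coded, j, axis=-1)) for j, f in enumerate(factors)], axis=-1
    )


def fit_quadratic(design: Design, response_name: str) -> QuadraticSurface:
    """Fit the full quadratic surface to one response by ordinary least squares.

    Raises a rank error when the design cannot support the 15-term model for
    four factors (e.g. axial points missing, so the pure quadratic columns are
    confounded).
    """
    if response_name not in design.responses:
        raise KeyError(f"response {response_name!r} not in design")
    y = design.responses[response_name]
    if np.any(~np.isfinite(y)):
        raise ValueError(f"response {response_name!r} has missing values")
    X = _model_matrix(design.runs)
    if design.n_runs < X.shape[1]:
        raise ValueError(
            f"need at least {X.shape[1]} runs for the quadratic model, "
            f"got {design.n_runs}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient ({rank} < {X.shape[1]}); "
            "the design does not identify the full quadratic model"
        )
    res = sm.OLS(y, X).fit()
    return QuadraticSurface.from_coefficients(
        response_name, [f.name for f in design.factors], res.params
    )


def predict(surface: QuadraticSurface, coded_point) -> np.ndarray | float:
    """Evaluate the polynomial at one or many coded points."""
    pt = np.asarray(coded_point, dtype=float)
    single = pt.ndim == 1
    X = _model_matrix(np.atleast_2d(pt))
    out = X @ surface.coefficients
    return float(out[0]) if single else out


def anova(design: Design, surface: QuadraticSurface) -> AnovaReport:
    """ANOVA and regression diagnostics for a fitted surface.

    Per-term sums of squares are partial (type III): ``SS_j = b_j² / c_jj``
    with ``c_jj`` the j-th diagonal of ``(X'X)⁻¹``, each tested against the
    residual mean square on (1, df_res). The residual splits into pure error
    (centre replicates about their mean) and lack of fit. PRESS uses the
    leave-one-out hat-matrix identity; adequate precision is the spread of
    fitted values over the design divided by the average prediction standard
    error ``sqrt(p · MS_res / N)``.
    """
    y = design.responses[surface.response_name]
    X = _model_matrix(design.runs)
    beta = surface.coefficients
    fitted = X @ beta
    resid = y - fitted
    N, p = X.shape
    df_res = N - p
    if df_res < 1:
        raise ValueError("saturated model: no residual degrees of freedom")

    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_model = ss_tot - ss_res
    ms_res = ss_res / df_res

    XtX_inv = np.linalg.inv(X.T @ X)
    c_jj = np.diag(XtX_inv)
    term_names = _term_names(surface.factor_names)
    ss_terms = beta**2 / c_jj  # partial (type III) SS, one df each
    f_terms = ss_terms / ms_res
    p_terms = sp_stats.f.sf(f_terms, 1, df_res)

    df_model = p - 1
    f_model = (ss_model / df_model) / ms_res
    p_model = sp_stats.f.sf(f_model, df_model, df_res)

    rows = [("model", ss_model, df_model, ss_model / df_model, f_model, p_model)]
    for j in range(1, p):  # skip the intercept row, as Design-Expert does
        rows.append(
            (term_names[j], ss_terms[j], 1, ss_terms[j], f_terms[j], p_terms[j])
        )
    rows.append(("residual", ss_res, df_res, ms_res, np.nan, np.nan))

    center = design.center_mask
    n_center = int(center.sum())
    if n_center >= 2:
        yc = y[center]
        ss_pe = float(((yc - yc.mean()) ** 2).sum())
        df_pe = n_center - 1
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        if df_lof > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = sp_stats.f.sf(f_lof, df_lof, df_pe)
        else:
            f_lof, p_lof = np.nan, np.nan
        rows.append(("lack of fit", ss_lof, df_lof, ss_lof / max(df_lof, 1), f_lof, p_lof))
        rows.append(("pure error", ss_pe, df_pe, ss_pe / df_pe, np.nan, np.nan))
    else:
        warnings.warn(
            "no replicated centre points: pure-error/lack-of-fit rows omitted",
            stacklevel=2,
        )
    rows.append(("cor total", ss_tot, N - 1, np.nan, np.nan, np.nan))

    table = pd.DataFrame(
        rows, columns=["source", "SS", "df", "MS", "F", "p"]
    ).set_index("source")

    hat = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    press = float((((resid) / (1.0 - hat)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (ss_res / df_res) / (ss_tot / (N - 1))
    pred_r2 = 1.0 - press / ss_tot
    adeq = float((fitted.max() - fitted.min()) / np.sqrt(p * ms_res / N))

    se = np.sqrt(ms_res * c_jj)
    t_vals = pd.Series(np.abs(beta) / se, index=term_names)
    t_crit = float(sp_stats.t.ppf(0.975, df_res))

    return AnovaReport(
        response_name=surface.response_name,
        table=table,
        r2=r2,
        adj_r2=adj_r2,
        pred_r2=pred_r2,
        press=press,
        adeq_precision=adeq,
        standardized_effects=t_vals.drop("Intercept"),
        t_critical=t_crit,
    )


def standardized_effects(
    design: Design, surface: QuadraticSurface
) -> tuple[pd.Series, float]:
    """Per-term |t| statistics and the 5% two-sided critical value.

    These are the bar lengths and reference line of a standardized Pareto
    chart; each t² equals the term's partial F from :func:`anova`.
    """
    report = anova(design, surface)
    return report.standardized_effects.sort_values(ascending=False), report.t_critical


@dataclass
class OptimizationResult:
    """Outcome of a box-constrained (multi-)response optimization."""

    coded_point: np.ndarray
    actual_point: np.ndarray
    predicted: dict[str, float]
    desirability: float
    bounds_used: np.ndarray
    flat_warning: bool = False


def _box_extremum(surface: QuadraticSurface, bounds: np.ndarray, sign: float) -> float:
    """Exact min (sign=+1) or max (sign=-1) of the polynomial over the box,
    by multi-start L-BFGS-B from a 3-per-axis grid."""
    starts = np.array(
        list(itertools.product(*[np.linspace(lo, hi, 3) for lo, hi in bounds]))
    )
    best = np.inf
    for z0 in starts:
        res = sp_optimize.minimize(
            lambda z: sign * predict(surface, z), z0, method="L-BFGS-B", bounds=bounds
        )
        best = min(best, res.fun)
    return sign * best


def _desirability_ranges(
    surfaces: list[QuadraticSurface], bounds: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Per-response min/max over the box: the Derringer–Suich ramp anchors.

    Using the exact extrema (not a grid scan) keeps the maximize-ramps
    strictly below 1 away from each response's own argmax, so the joint
    desirability has a well-defined interior maximum."""
    return {
        s.response_name: (
            _box_extremum(s, bounds, +1.0),
            _box_extremum(s, bounds, -1.0),
        )
        for s in surfaces
    }


def optimize(
    surfaces: list[QuadraticSurface],
    bounds=None,
    mode: str = "desirability",
    factors: list[Factor] | None = None,
) -> OptimizationResult:
    """Maximize one surface or the joint desirability of several.

    In ``desirability`` mode the objective is the geometric mean of
    Derringer–Suich maximize-ramps, one per response, each anchored at the
    min/max of that surface's predictions over the box (equal weights,
    linear ramps). ``single`` mode maximizes the first surface directly.
    A multi-start local search (L-BFGS-B from a 3-per-axis grid) makes the
    result deterministic; ties go to the first-found optimum.
    """
    if not surfaces:
        raise ValueError("need at least one surface")
    n = len(surfaces[0].factor_names)
    if bounds is None:
        bounds = np.array([[-1.0, 1.0]] * n)
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (n, 2) or np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("bounds must be (n, 2) with lo <= hi")

    if mode == "single":
        surfaces = surfaces[:1]

    ranges = _desirability_ranges(surfaces, bounds)

    def objective(z: np.ndarray) -> float:
        if mode == "single":
            return -predict(surfaces[0], z)
        d = 1.0
        for s in surfaces:
            lo, hi = ranges[s.response_name]
            if hi - lo < 1e-12:
                ramp = 1.0  # flat response: everything equally desirable
            else:
                ramp = np.clip((predict(s, z) - lo) / (hi - lo), 0.0, 1.0)
            d *= ramp
        return -(d ** (1.0 / len(surfaces)))

    starts = np.array(
        list(itertools.product(*[np.linspace(lo, hi, 3) for lo, hi in bounds]))
    )
    best = None
    for z0 in starts:
        res = sp_optimize.minimize(
            objective, z0, method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    z_opt = np.clip(best.x, bounds[:, 0], bounds[:, 1])

    predicted = {s.response_name: float(predict(s, z_opt)) for s in surfaces}
    flat = abs(objective(bounds[:, 0]) - best.fun) < 1e-12 and np.allclose(
        [objective(x) for x in starts], best.fun
    )
    if mode == "single":
        lo, hi = ranges[surfaces[0].response_name]
        val = predicted[surfaces[0].response_name]
        desirability = float(np.clip((val - lo) / (hi - lo), 0, 1)) if hi > lo else 1.0
    else:
        desirability = float(-best.fun)
    if factors is not None:
        actual = decode_point(factors, z_opt)
    else:
        actual = z_opt.copy()
    return OptimizationResult(
        coded_point=z_opt,
        actual_point=actual,
        predicted=predicted,
        desirability=desirability,
        bounds_used=bounds,
        flat_warning=bool(flat),
    )


#: Factor table for the published four-factor screen of the cheese-whey medium:
#: yeast extract, peptone, cheese whey dose and initial pH, centred on the
#: centre-point recipe with one coded unit per half the factorial spread.
DEFAULT_FACTORS = [
    Factor("yeast_extract_g_l", center=10.0, step=5.0, unit="g/l"),
    Factor("peptone_g_l", center=5.0, step=2.5, unit="g/l"),
    Factor("cheese_whey_pct_v_v", center=10.0, step=5.0, unit="% v/v"),
    Factor("ph", center=7.75, step=0.75, unit="pH"),
]
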