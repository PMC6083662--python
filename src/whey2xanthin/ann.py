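"""Feed-forward neural surrogate trained by Levenberg–Marquardt.

A single-hidden-layer network (sigmoid hidden units, linear outputs) maps the
four medium factors, in coded units, to the two responses (product yield and
biomass). The reference topology is 4-9-2. Training minimizes the mean
squared error on a train split by Levenberg–Marquardt — Gauss–Newton steps
with an adaptive damping factor — with early stopping on a validation split:
after ``patience`` consecutive epochs of rising validation MSE the loop stops
and the weights with the lowest validation MSE ever seen are restored.

Inputs and outputs are affinely mapped to [-1, 1] per channel before
training (the usual conditioning for sigmoid nets); predictions are mapped
back, so the model is scale-consistent by construction.

The training set is the designed experiment augmented with points generated
from the fitted quadratic surfaces, which densifies the 30-run design into a
few hundred samples — enough for a 65-weight network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rsm import Design, QuadraticSurface, predict as surface_predict

__all__ = [
    "Scaler",
    "AnnModel",
    "TrainingRecord",
    "AugmentedDataset",
    "augment_dataset",
    "train",
    "predict",
    "neuron_sweep",
]


@dataclass(frozen=True)
class Scaler:
    """Per-channel affine map onto [-1, 1]: scaled = 2(x - lo)/(hi - lo) - 1."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        hi = np.where(hi > lo, hi, lo + 1.0)  # constant channel: avoid 0 span
        return cls(lo=lo, hi=hi)

    def transform(self, X):
        return 2.0 * (np.asarray(X, dtype=float) - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, Xs):
        return (np.asarray(Xs, dtype=float) + 1.0) * (self.hi - self.lo) / 2.0 + self.lo


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class AnnModel:
    """Trained network: hidden weights (H, n_in) + biases (H,), output weights
    (n_out, H) + biases (n_out,), and the input/output scalers."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    input_scaler: Scaler
    output_scaler: Scaler

    @property
    def topology(self) -> tuple[int, int, int]:
        return (self.W1.shape[1], self.W1.shape[0], self.W2.shape[0])

    def forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        """Forward pass in scaled space (rows = samples)."""
        H = _sigmoid(Xs @ self.W1.T + self.b1)
        return H @ self.W2.T + self.b2


@dataclass
class TrainingRecord:
    """Per-epoch train/validation/test MSE (scaled space), the stopping epoch
    (index of the best-validation weights) and reason, and the seed."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""
    seed: int = 0


@dataclass
class AugmentedDataset:
    """Inputs (coded units) and outputs for surrogate training, with a
    provenance flag per row ('ccd' or 'generated') and a train/val/test
    split assignment."""

    X: np.ndarray
    Y: np.ndarray
    provenance: np.ndarray
    split: np.ndarray  # 'train' | 'val' | 'test'
    response_names: list[str]

    def part(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == which
        return self.X[m], self.Y[m]


def augment_dataset(
    design: Design,
    surfaces: list[QuadraticSurface],
    n_extra: int = 200,
    domain: float = 1.0,
    seed: int = 0,
    split_sizes: tuple[int, int, int] = (160, 35, 35),
) -> AugmentedDataset:
    """Stack the designed runs with surface-generated points and assign splits.

    Extra inputs are sampled uniformly over the coded box [-domain, domain]^n
    and their outputs are noise-free surface predictions. The split is random
    per seed with exact sizes, stratified so every centre replicate lands in
    the training part (the replicates carry the only pure-error information).
    """
    rng = np.random.default_rng(seed)
    names = [s.response_name for s in surfaces]
    X_ccd = design.runs
    Y_ccd = np.column_stack([design.responses[n] for n in names])
    n = design.n_factors
    if n_extra < 0:
        raise ValueError("n_extra must be >= 0")
    if domain <= 0:
        raise ValueError("domain must be positive")
    X_gen = rng.uniform(-domain, domain, size=(n_extra, n))
    Y_gen = np.column_stack([surface_predict(s, X_gen) for s in surfaces]) \
        if n_extra else np.empty((0, len(names)))
    X = np.vstack([X_ccd, X_gen])
    Y = np.vstack([Y_ccd, Y_gen])
    prov = np.array(["ccd"] * design.n_runs + ["generated"] * n_extra)

    n_total = X.shape[0]
    n_train, n_val, n_test = split_sizes
    if n_train + n_val + n_test != n_total:
        raise ValueError(
            f"split sizes {split_sizes} do not sum to {n_total} rows"
        )
    split = np.empty(n_total, dtype=object)
    center_idx = np.flatnonzero(np.all(X_ccd == 0.0, axis=1))
    others = np.setdiff1d(np.arange(n_total), center_idx)
    rng.shuffle(others)
    n_train_rest = n_train - center_idx.size
    if n_train_rest < 0:
        raise ValueError("training split smaller than the number of centre runs")
    split[center_idx] = "train"
    split[others[:n_train_rest]] = "train"
    split[others[n_train_rest : n_train_rest + n_val]] = "val"
    split[others[n_train_rest + n_val :]] = "test"
    return AugmentedDataset(X=X, Y=Y, provenance=prov, split=split,
                            response_names=names)


def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(theta, n_in, n_hidden, n_out):
    i = 0
    W1 = theta[i : i + n_hidden * n_in].reshape(n_hidden, n_in); i += n_hidden * n_in
    b1 = theta[i : i + n_hidden]; i += n_hidden
    W2 = theta[i : i + n_out * n_hidden].reshape(n_out, n_hidden); i += n_out * n_hidden
    b2 = theta[i : i + n_out]
    return W1, b1, W2, b2


def _residual_and_jac(theta, Xs, Ys, n_in, n_hidden, n_out):
    """Residual vector (N·n_out,) and its analytic Jacobian w.r.t. theta."""
    W1, b1, W2, b2 = _unpack(theta, n_in, n_hidden, n_out)
    A = Xs @ W1.T + b1          # (N, H)
    H = _sigmoid(A)
    out = H @ W2.T + b2         # (N, O)
    R = out - Ys
    N = Xs.shape[0]
    dH = H * (1 - H)            # sigmoid derivative (N, H)
    J = np.zeros((N * n_out, theta.size))
    nW1 = n_hidden * n_in
    for o in range(n_out):
        rows = slice(o * N, (o + 1) * N)
        # d out_o / d W1[h, i] = W2[o, h] * dH[:, h] * Xs[:, i]
        G = (W2[o] * dH)        # (N, H)
        J[rows, :nW1] = (G[:, :, None] * Xs[:, None, :]).reshape(N, nW1)
        J[rows, nW1 : nW1 + n_hidden] = G
        J[rows, nW1 + n_hidden + o * n_hidden : nW1 + n_hidden + (o + 1) * n_hidden] = H
        J[rows, nW1 + n_hidden + n_out * n_hidden + o] = 1.0
    # residuals stacked output-major to match the Jacobian layout
    r = R.T.ravel()
    return r, J


def _mse(model_theta, Xs, Ys, n_in, n_hidden, n_out):
    W1, b1, W2, b2 = _unpack(model_theta, n_in, n_hidden, n_out)
    out = _sigmoid(Xs @ W1.T + b1) @ W2.T + b2
    return float(np.mean((out - Ys) ** 2))


def train(
    dataset: AugmentedDataset,
    n_hidden: int = 9,
    seed: int = 0,
    max_epochs: int = 1000,
    patience: int = 6,
    mu0: float = 1e-3,
    mu_max: float = 1e10,
) -> tuple[AnnModel, TrainingRecord]:
    """Train the surrogate by Levenberg–Marquardt with validation early stop.

    Each epoch solves ``(J'J + mu·I) d = -J'r`` on the training residuals;
    the damping ``mu`` divides by 10 after a successful step and multiplies
    by 10 (retrying) otherwise, which blends Gauss–Newton with gradient
    descent and rides through near-singular Jacobians. Training stops when
    validation MSE has risen for ``patience`` consecutive epochs, damping
    saturates, or ``max_epochs`` is hit; the returned weights are those with
    the lowest validation MSE observed.
    """
    if n_hidden < 1:
        raise ValueError("need at least one hidden neuron")
    rng = np.random.default_rng(seed)
    Xtr, Ytr = dataset.part("train")
    Xva, Yva = dataset.part("val")
    Xte, Yte = dataset.part("test")
    in_scaler = Scaler.fit(dataset.X)
    out_scaler = Scaler.fit(dataset.Y)
    Xs, Ys = in_scaler.transform(Xtr), out_scaler.transform(Ytr)
    Vs, Wy = in_scaler.transform(Xva), out_scaler.transform(Yva)
    Ts, Ty = in_scaler.transform(Xte), out_scaler.transform(Yte)
    n_in, n_out = Xs.shape[1], Ys.shape[1]

    theta = rng.uniform(-0.5, 0.5, size=n_hidden * n_in + n_hidden
                        + n_out * n_hidden + n_out)
    record = TrainingRecord(seed=seed)
    mu = mu0
    best_theta = theta.copy()
    best_val = np.inf
    fails = 0
    reason = "max_epochs"
    r, J = _residual_and_jac(theta, Xs, Ys, n_in, n_hidden, n_out)
    sse = r @ r
    eye = np.eye(theta.size)
    for epoch in range(max_epochs):
        stepped = False
        while mu <= mu_max:
            try:
                d = np.linalg.solve(J.T @ J + mu * eye, -J.T @ r)
            except np.linalg.LinAlgError:
                mu *= 10
                continue
            cand = theta + d
            r_new, J_new = _residual_and_jac(cand, Xs, Ys, n_in, n_hidden, n_out)
            sse_new = r_new @ r_new
            if sse_new < sse:
                theta, r, J, sse = cand, r_new, J_new, sse_new
                mu = max(mu / 10, 1e-20)
                stepped = True
                break
            mu *= 10
        record.train_mse.append(sse / r.size)
        val = _mse(theta, Vs, Wy, n_in, n_hidden, n_out) if len(Vs) else np.nan
        test = _mse(theta, Ts, Ty, n_in, n_hidden, n_out) if len(Ts) else np.nan
        record.val_mse.append(val)
        record.test_mse.append(test)
        if len(Vs) and val < best_val:
            best_val = val
            best_theta = theta.copy()
            record.stop_epoch = epoch
            fails = 0
        elif len(Vs):
            fails += 1
            if fails >= patience:
                reason = "validation_stop"
                break
        if not stepped:
            reason = "damping_saturated"
            break
    else:
        reason = "max_epochs"
    record.stop_reason = reason
    if not len(Vs):
        best_theta = theta
        record.stop_epoch = len(record.train_mse) - 1
    W1, b1, W2, b2 = _unpack(best_theta, n_in, n_hidden, n_out)
    model = AnnModel(W1=W1.copy(), b1=b1.copy(), W2=W2.copy(), b2=b2.copy(),
                     input_scaler=in_scaler, output_scaler=out_scaler)
    return model, record


def predict(model: AnnModel, x, warn_domain: float = 2.0):
    """Forward pass at one or many coded points, in original output units.

    Points beyond ``warn_domain`` coded units on any axis trigger an
    extrapolation warning (the surrogate is only trusted on the design region).
    """
    pt = np.asarray(x, dtype=float)
    single = pt.ndim == 1
    P = np.atleast_2d(pt)
    if np.any(np.abs(P) > warn_domain):
        import warnings

        warnings.warn(
            f"input beyond ±{warn_domain} coded units: surrogate extrapolation",
            stacklevel=2,
        )
    out = model.output_scaler.inverse(model.forward_scaled(model.input_scaler.transform(P)))
    return out[0] if single else out


def neuron_sweep(
    design: Design,
    surfaces: list[QuadraticSurface],
    hidden_range=range(2, 13),
    seeds=range(10),
    n_extra: int = 200,
    **train_kw,
):
    """Seed-averaged validation/test MSE and R² per hidden-layer width.

    Returns a DataFrame with one row per width and the width minimizing the
    mean validation MSE. Dataset draws and weight initialization both vary
    with the seed, so the average reflects the whole training pipeline.
    """
    import pandas as pd

    hidden_range = list(hidden_range)
    if not hidden_range:
        raise ValueError("hidden_range must be non-empty")
    rows = []
    for h in hidden_range:
        vals, tests, r2s = [], [], []
        for s in seeds:
            ds = augment_dataset(design, surfaces, n_extra=n_extra, seed=s)
            model, rec = train(ds, n_hidden=h, seed=s, **train_kw)
            vals.append(min(rec.val_mse))
            tests.append(rec.test_mse[rec.stop_epoch])
            Xte, Yte = ds.part("test")
            pred = predict(model, Xte)
            sst = ((Yte - Yte.mean(axis=0)) ** 2).sum()
            r2s.append(1 - ((Yte - pred) ** 2).sum() / sst)
        rows.append(
            {"hidden": h, "mean_val_mse": np.mean(vals),
             "mean_test_mse": np.mean(tests), "mean_r2": np.mean(r2s)}
        )
    table = pd.DataFrame(rows)
    best = int(table.loc[table["mean_val_mse"].idxmin(), "hidden"])
    table.attrs["best_hidden"] = best
    return table
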