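"""Neural displacement surrogate of the mechanical model.

The surrogate maps ``(x, y, z, p, c1, c2)`` - a material point of the wall in
its reference configuration, the intra-ventricular pressure and the two free
constitutive parameters - to the 3-D displacement of that point, and exposes
exact gradients of any scalar function of its outputs with respect to its
inputs.  The inverse estimators freeze the trained weights and optimise a
subset of the inputs through these gradients.

Training minimises the boundary-penalised squared displacement error

    l(B) = sum_{d in B_d} ||u_d - u~_d||^2 + alpha * sum_{b in B_b} ||u_b - u~_b||^2

where ``B_b`` are samples on the endo-/epicardial surfaces (where the
pressure boundary condition acts), ``B_d`` interior samples, and
``alpha = 4.5`` the boundary penalty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import mechanics
from .mechanics import (C1_RANGE, C2_RANGE, PRESSURE_RANGE, GeometryParams,
                        MaterialParams)
from .nn import MLP, Adam

__all__ = [
    "TrainingSet",
    "build_training_set",
    "DisplacementSurrogate",
    "training_loss",
    "evaluate_surrogate",
    "save_model",
    "load_model",
]

INPUT_NAMES = ("x", "y", "z", "p", "c1", "c2")


@dataclass
class TrainingSet:
    """Flat sample arrays: inputs ``X`` (n, 6), targets ``U`` (n, 3) mm and a
    boundary mask marking samples on the endo-/epicardial surfaces."""

    X: np.ndarray
    U: np.ndarray
    boundary: np.ndarray
    geometry: GeometryParams

    def __len__(self) -> int:
        return len(self.X)


def _check_ranges(p, c1, c2) -> None:
    for value, (lo, hi), name in ((p, PRESSURE_RANGE, "p"), (c1, C1_RANGE, "c1"),
                                  (c2, C2_RANGE, "c2")):
        v = np.asarray(value, dtype=float)
        if np.any(v < lo - 1e-9) or np.any(v > hi + 1e-9):
            raise ValueError(f"{name} outside training range [{lo}, {hi}]")


def build_training_set(geometry: GeometryParams = GeometryParams(),
                       param_grid=None, pressure_grid=None,
                       n_interior: int = 50, n_boundary: int = 12,
                       seed: int = 0, n_theta: int = 120, n_edge: int = 72,
                       pressures_per_theta: int = 5) -> TrainingSet:
    """Sample the forward model over the training ranges.

    ``param_grid`` (pairs of (c1, c2)) and ``pressure_grid`` may be given
    explicitly and are crossed Cartesian-style.  By default ``n_theta``
    (c1, c2) pairs are drawn by Latin-hypercube sampling, ``n_edge`` further
    pairs are spread along the four edges of the (c1, c2) window (plus its
    corners), and each pair is crossed with ``pressures_per_theta`` stratified
    pressures.  The estimators read the surrogate along pressure traces and
    are evaluated across the whole window including its edges, so pressure
    resolution per material and edge coverage matter more than isotropic
    coverage of the (p, c1, c2) box.  Each combination receives fresh seeded
    interior and surface points; targets come from the incompressible-shell
    solution.
    """
    if (param_grid is None) != (pressure_grid is None):
        raise ValueError("give both param_grid and pressure_grid, or neither")
    if param_grid is not None:
        thetas = np.array([(p, c1, c2) for p in np.atleast_1d(pressure_grid)
                           for (c1, c2) in param_grid], dtype=float)
    else:
        rng = np.random.default_rng(seed)
        sampler = qmc.LatinHypercube(d=2, seed=seed)
        lo = np.array([C1_RANGE[0], C2_RANGE[0]])
        hi = np.array([C1_RANGE[1], C2_RANGE[1]])
        pairs = lo + sampler.random(n_theta) * (hi - lo)
        per_edge = n_edge // 4
        ticks = (np.arange(per_edge) + rng.random((4, per_edge))) / per_edge
        c1s = C1_RANGE[0] + ticks[:2] * (C1_RANGE[1] - C1_RANGE[0])
        c2s = C2_RANGE[0] + ticks[2:] * (C2_RANGE[1] - C2_RANGE[0])
        edges = np.concatenate([
            np.column_stack([c1s[0], np.full(per_edge, C2_RANGE[0])]),
            np.column_stack([c1s[1], np.full(per_edge, C2_RANGE[1])]),
            np.column_stack([np.full(per_edge, C1_RANGE[0]), c2s[0]]),
            np.column_stack([np.full(per_edge, C1_RANGE[1]), c2s[1]]),
        ])
        pairs = np.vstack([pairs, edges,
                           [(c1, c2) for c1 in C1_RANGE for c2 in C2_RANGE]])
        p_lo, p_hi = PRESSURE_RANGE
        k = pressures_per_theta
        strata = (np.arange(k) + rng.random((len(pairs), k))) / k
        pressures = p_lo + strata * (p_hi - p_lo)
        thetas = np.column_stack([
            pressures.ravel(),
            np.repeat(pairs[:, 0], k),
            np.repeat(pairs[:, 1], k),
        ])
    _check_ranges(thetas[:, 0], thetas[:, 1], thetas[:, 2])

    n_endo = n_boundary // 2
    n_epi = n_boundary - n_endo
    seeds = np.random.SeedSequence(seed).spawn(len(thetas))
    X_parts, U_parts, b_parts = [], [], []
    for (p, c1, c2), ss in zip(thetas, seeds):
        child = ss.spawn(3)
        material = MaterialParams(c1=c1, c2=c2)
        pts = [mechanics.sample_wall_points(
            geometry, n_interior, np.random.default_rng(child[0]))]
        if n_endo:
            pts.append(mechanics.sample_surface(
                geometry, "endo", n_endo, np.random.default_rng(child[1])).points)
        if n_epi:
            pts.append(mechanics.sample_surface(
                geometry, "epi", n_epi, np.random.default_rng(child[2])).points)
        pts = np.vstack(pts)
        disp = mechanics.displacement_field(geometry, material, p, pts)
        theta_cols = np.broadcast_to([p, c1, c2], (len(pts), 3))
        X_parts.append(np.hstack([pts, theta_cols]))
        U_parts.append(disp.vectors)
        b_parts.append(np.concatenate(
            [np.zeros(n_interior, bool), np.ones(n_endo + n_epi, bool)]))
    return TrainingSet(X=np.vstack(X_parts), U=np.vstack(U_parts),
                       boundary=np.concatenate(b_parts), geometry=geometry)


class DisplacementSurrogate(BaseEstimator, RegressorMixin):
    """Trainable displacement surrogate ``(x, y, z, p, c1, c2) -> u`` (mm).

    Parameters
    ----------
    hidden_layer_sizes : widths of the tanh hidden layers.
    alpha : boundary penalty of the training loss (default 4.5).
    radius_feature : append the reference radius ``|x|`` as an auxiliary input
        feature; the geometry is parameterised radially, so this conditions
        training without changing the differentiable input surface.
    max_epochs, batch_size, learning_rate, lr_decay : stochastic-gradient
        training schedule (Adam; ``lr_i = learning_rate * lr_decay**i``).
    test_size : held-out fraction for the per-epoch test loss; the returned
        weights are the best-by-test-loss snapshot.
    patience : stop early after this many epochs without test improvement.
    random_state : seed controlling initialisation, split and batching.
    """

    def __init__(self, hidden_layer_sizes=(48, 48), alpha=4.5,
                 radius_feature=True, max_epochs=3500, batch_size=4096,
                 learning_rate=0.02, lr_decay=0.99829, test_size=0.1,
                 patience=900, random_state=0, verbose=False):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.alpha = alpha
        self.radius_feature = radius_feature
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.test_size = test_size
        self.patience = patience
        self.random_state = random_state
        self.verbose = verbose

    # -- feature pipeline ---------------------------------------------------

    def _features(self, X: np.ndarray) -> np.ndarray:
        Xn = (X - self.input_center_) / self.input_halfwidth_
        if self.radius_feature:
            r = np.linalg.norm(X[:, :3], axis=1)
            rn = (r - self.radius_center_) / self.radius_halfwidth_
            Xn = np.hstack([Xn, rn[:, None]])
        return Xn

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y, boundary=None, input_ranges=None):
        """Train on inputs ``X`` (n, 6) and displacement targets ``y`` (n, 3).

        ``boundary`` is a boolean mask of surface samples receiving the
        ``alpha`` penalty weight.  ``input_ranges`` (6, 2) optionally fixes the
        normalisation ranges; by default the data range of each column is used.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 6 or y.shape != (len(X), 3):
            raise ValueError("X must be (n, 6) and y (n, 3)")
        if boundary is None:
            boundary = np.zeros(len(X), dtype=bool)
        boundary = np.asarray(boundary, dtype=bool)

        if input_ranges is None:
            lo, hi = X.min(axis=0), X.max(axis=0)
        else:
            ranges = np.asarray(input_ranges, dtype=float)
            lo, hi = ranges[:, 0], ranges[:, 1]
        span = np.maximum(hi - lo, 1e-12)
        self.input_center_ = (hi + lo) / 2.0
        self.input_halfwidth_ = span / 2.0
        r = np.linalg.norm(X[:, :3], axis=1)
        r_lo, r_hi = float(r.min()), float(r.max())
        self.radius_center_ = (r_hi + r_lo) / 2.0
        self.radius_halfwidth_ = max((r_hi - r_lo) / 2.0, 1e-12)
        self.y_scale_ = max(float(np.std(y)), 1e-12)

        rng = np.random.default_rng(self.random_state)
        n = len(X)
        n_test = max(1, int(round(self.test_size * n)))
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        self.test_indices_ = test_idx.copy()

        Xn = self._features(X)
        yn = y / self.y_scale_
        w = np.where(boundary, float(self.alpha), 1.0)[:, None]
        Xtr, ytr, wtr = Xn[train_idx], yn[train_idx], w[train_idx]
        Xte, yte = Xn[test_idx], yn[test_idx]
        yte_mm = y[test_idx]

        n_feat = Xn.shape[1]
        net = MLP((n_feat, *self.hidden_layer_sizes, 3),
                  seed=rng.integers(2 ** 31))
        # train in float32 (the gradient noise of SGD dwarfs the round-off);
        # the published weights are cast back to float64 below
        net.set_parameters([p.astype(np.float32) for p in net.parameters])
        Xtr, ytr, wtr = (a.astype(np.float32) for a in (Xtr, ytr, wtr))
        Xte = Xte.astype(np.float32)
        opt = Adam(net.parameters)
        n_tr = len(Xtr)
        batch = min(self.batch_size, n_tr)
        best = (np.inf, None)
        history = {"train": [], "test": []}
        stale = 0
        for epoch in range(self.max_epochs):
            lr = self.learning_rate * self.lr_decay ** epoch
            order = rng.permutation(n_tr)
            sq_sum = 0.0
            for start in range(0, n_tr, batch):
                idx = order[start:start + batch]
                out, acts = net.forward(Xtr[idx], cache=True)
                err = out - ytr[idx]
                sq_sum += float(np.sum(err ** 2))
                cot = (2.0 / len(idx)) * wtr[idx] * err
                params = net.parameters
                opt.step(params, net.grads(acts, cot), lr)
                net.set_parameters(params)
            train_mse = sq_sum / (3.0 * n_tr) * self.y_scale_ ** 2
            pred_te = net.forward(Xte) * self.y_scale_
            test_mse = float(np.mean((pred_te - yte_mm) ** 2))
            history["train"].append(train_mse)
            history["test"].append(test_mse)
            if not np.isfinite(train_mse) or not np.isfinite(test_mse):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            if test_mse < best[0]:
                best = (test_mse, [p.copy() for p in net.parameters])
                stale = 0
            else:
                stale += 1
                if stale > self.patience:
                    break
            if self.verbose and epoch % 100 == 0:
                print(f"epoch {epoch}: train {train_mse:.3e} test {test_mse:.3e} mm^2")
        net.set_parameters([p.astype(float) for p in best[1]])
        self.net_ = net
        self.history_ = {k: np.asarray(v) for k, v in history.items()}
        self.best_test_mse_ = best[0]
        self.n_features_in_ = 6
        return self

    def predict(self, X):
        """Displacements (n, 3) in mm; deterministic given the weights."""
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        out = self.net_.forward(self._features(X)) * self.y_scale_
        return out[0] if single else out

    # -- differentiable evaluation for the inverse estimators ---------------

    def forward_cached(self, X):
        """Predict and keep the activation cache for a later input-VJP."""
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        out, acts = self.net_.forward(self._features(X), cache=True)
        return out * self.y_scale_, (X, acts)

    def vjp_inputs(self, cache, cotangent):
        """Gradient of ``sum(cotangent * u)`` w.r.t. the native inputs (n, 6).

        The network weights are read-only along this path.
        """
        X, acts = cache
        g = self.net_.vjp_inputs(acts, np.asarray(cotangent) * self.y_scale_)
        gx = g[:, :6] / self.input_halfwidth_
        if self.radius_feature:
            r = np.linalg.norm(X[:, :3], axis=1, keepdims=True)
            gr = (g[:, 6:7] / self.radius_halfwidth_)
            gx = gx.copy()
            gx[:, :3] += gr * X[:, :3] / np.maximum(r, 1e-12)
        return gx

    def input_gradient(self, x, theta):
        """Jacobian (3, 3) of the displacement at point ``x`` w.r.t. (p, c1, c2)."""
        X = np.array([[*np.asarray(x, float), *np.asarray(theta, float)]])
        _, cache = self.forward_cached(X)
        rows = []
        for k in range(3):
            cot = np.zeros((1, 3))
            cot[0, k] = 1.0
            rows.append(self.vjp_inputs(cache, cot)[0, 3:])
        return np.vstack(rows)

    def theta_normalisation(self):
        """(center, halfwidth) arrays for the (p, c1, c2) input columns."""
        check_is_fitted(self, "net_")
        return self.input_center_[3:].copy(), self.input_halfwidth_[3:].copy()


def training_loss(model: DisplacementSurrogate, X, U_target, boundary,
                  alpha: float = 4.5) -> float:
    """Boundary-penalised squared displacement error (mm^2), summed over the
    batch: interior terms weigh 1, boundary terms weigh ``alpha``."""
    X = np.asarray(X, dtype=float)
    U_target = np.asarray(U_target, dtype=float)
    if len(X) == 0:
        raise ValueError("empty batch")
    boundary = np.asarray(boundary, dtype=bool)
    err_sq = np.sum((model.predict(X) - U_target) ** 2, axis=1)
    w = np.where(boundary, alpha, 1.0)
    return float(np.sum(w * err_sq))


def evaluate_surrogate(model: DisplacementSurrogate, X, U_target,
                       boundary=None) -> dict:
    """Displacement-error report: MAE = mean ``|u - u~|`` (mm) and MSE = mean
    squared per-component error (mm^2), plus a boundary/interior breakdown."""
    X = np.asarray(X, dtype=float)
    U_target = np.asarray(U_target, dtype=float)
    pred = model.predict(X)
    err = pred - U_target
    norms = np.linalg.norm(err, axis=1)
    report = {
        "mae": float(norms.mean()),
        "mae_std": float(norms.std()),
        "mse": float(np.mean(err ** 2)),
        "n": len(X),
    }
    if boundary is not None:
        boundary = np.asarray(boundary, dtype=bool)
        for name, mask in (("boundary", boundary), ("interior", ~boundary)):
            if mask.any():
                report[f"mae_{name}"] = float(norms[mask].mean())
                report[f"mse_{name}"] = float(np.mean(err[mask] ** 2))
    return report


def save_model(model: DisplacementSurrogate, path) -> None:
    """Serialise a fitted surrogate (weights, normalisation, config, history)
    into a single ``.npz`` archive."""
    check_is_fitted(model, "net_")
    payload = {
        "config": json.dumps(model.get_params()),
        "layer_sizes": np.asarray(model.net_.layer_sizes),
        "input_center": model.input_center_,
        "input_halfwidth": model.input_halfwidth_,
        "radius_center": model.radius_center_,
        "radius_halfwidth": model.radius_halfwidth_,
        "y_scale": model.y_scale_,
        "history_train": model.history_["train"],
        "history_test": model.history_["test"],
        "test_indices": model.test_indices_,
    }
    for i, w in enumerate(model.net_.weights):
        payload[f"w{i}"] = w
    for i, b in enumerate(model.net_.biases):
        payload[f"b{i}"] = b
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_model(path) -> DisplacementSurrogate:
    """Restore a surrogate saved by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as data:
        model = DisplacementSurrogate(**json.loads(str(data["config"])))
        sizes = tuple(int(s) for s in data["layer_sizes"])
        net = MLP(sizes, seed=0)
        net.weights = [data[f"w{i}"] for i in range(len(sizes) - 1)]
        net.biases = [data[f"b{i}"] for i in range(len(sizes) - 1)]
        model.net_ = net
        model.input_center_ = data["input_center"]
        model.input_halfwidth_ = data["input_halfwidth"]
        model.radius_center_ = float(data["radius_center"])
        model.radius_halfwidth_ = float(data["radius_halfwidth"])
        model.y_scale_ = float(data["y_scale"])
        model.history_ = {"train": data["history_train"],
                          "test": data["history_test"]}
        if "test_indices" in data:
            model.test_indices_ = data["test_indices"]
        model.best_test_mse_ = float(data["history_test"].min()) \
            if len(data["history_test"]) else float("nan")
        model.n_features_in_ = 6
    return model
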