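"""Gaussian-process fitting and prediction for threshold maps.

The model treats the (transformed) threshold map as a draw from a zero-mean
Gaussian process over electrode positions.  Thresholds span orders of
magnitude and the hyperparameter bounds (signal variance 0.1-10) presuppose
unit-scale targets, so the default target transform is log10 followed by
standardization over the training electrodes; predictions are mapped back to
microamps by the exact inverse.

Hyperparameters are chosen by maximizing the log marginal likelihood (LML)

    log p(y | X, theta) = -1/2 y^T K^-1 y - 1/2 log |K| - N/2 log 2 pi,

with ``K`` the training covariance including the diagonal noise term, via
multi-start L-BFGS-B over the bounded box (length scales and variances are
optimized in log10 space; the hybrid mix weight linearly in [0, 1]).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .grid import ElectrodeGrid, ThresholdMap
from .kernels import DEFAULT_BOUNDS, KernelSpec, kernel_matrix

__all__ = [
    "TargetTransform",
    "GPConfig",
    "GPFit",
    "Prediction",
    "transform_targets",
    "log_marginal_likelihood",
    "fit",
    "predict",
]

#: Diagonal jitter added before Cholesky factorization.
JITTER = 1e-10


class GPFitError(RuntimeError):
    """All optimizer restarts failed numerically; carries diagnostics."""


@dataclass(frozen=True)
class TargetTransform:
    """Invertible map from microamp thresholds to GP target space.

    ``forward`` applies log10 (optionally) then standardizes with the stored
    mean/scale; ``inverse`` undoes both exactly.  A zero spread across the
    training targets clamps the scale to 1 and sets ``scale_clamped``.
    """

    use_log: bool = True
    mean: float = 0.0
    scale: float = 1.0
    scale_clamped: bool = False

    def forward(self, values_uA: np.ndarray) -> np.ndarray:
        v = np.asarray(values_uA, dtype=float)
        if self.use_log:
            v = np.log10(v)
        return (v - self.mean) / self.scale

    def inverse(self, transformed: np.ndarray) -> np.ndarray:
        v = np.asarray(transformed, dtype=float) * self.scale + self.mean
        return 10.0 ** v if self.use_log else v

    def to_dict(self) -> dict:
        return {
            "use_log": self.use_log,
            "mean": self.mean,
            "scale": self.scale,
            "scale_clamped": self.scale_clamped,
        }


def transform_targets(
    tmap: ThresholdMap, ids: Sequence[int], use_log: bool = True
) -> tuple[np.ndarray, TargetTransform]:
    """Standardized (optionally log10) targets for the given training ids."""
    ids = np.asarray(ids, dtype=int)
    raw = tmap.thresholds_uA[ids]
    if np.isnan(raw).any():
        raise ValueError("training ids must refer to measured (active) electrodes")
    v = np.log10(raw) if use_log else raw.copy()
    mean = float(v.mean())
    sd = float(v.std())  # population sd: (1, 3) -> mean 2, sd 1
    clamped = sd < 1e-12
    scale = 1.0 if clamped else sd
    if clamped:
        warnings.warn(
            "zero spread across training targets; standardization scale "
            "clamped to 1",
            stacklevel=2,
        )
    tr = TargetTransform(use_log=use_log, mean=mean, scale=scale, scale_clamped=clamped)
    return tr.forward(raw), tr


def _chol_with_jitter(K: np.ndarray):
    return cho_factor(K + JITTER * np.eye(K.shape[0]), lower=True)


def log_marginal_likelihood(
    spec: KernelSpec, X: np.ndarray, y: np.ndarray
) -> float:
    """LML of the transformed targets under the kernel (noise term included)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if X.shape[0] != n or n < 1:
        raise ValueError("X and y must have matching, non-zero length")
    K = kernel_matrix(spec, X, include_noise=True)
    try:
        c = _chol_with_jitter(K)
    except np.linalg.LinAlgError as exc:
        raise FloatingPointError(
            f"covariance not positive definite for {spec.to_dict()}"
        ) from exc
    alpha = cho_solve(c, y)
    log_det = 2.0 * np.log(np.diag(c[0])).sum()
    return float(-0.5 * y @ alpha - 0.5 * log_det - 0.5 * n * np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GPConfig:
    """Fit options.

    Attributes
    ----------
    use_log : apply log10 before standardizing targets.
    n_restarts : number of L-BFGS-B starts; the first uses the default
        initial point, the rest are drawn within the bounds from the seed.
    optimize : when False the kernel keeps ``init_params`` untouched
        (used e.g. to freeze hyperparameters during adaptive sampling).
    init_params : overrides for the first start / the frozen kernel.
    bounds : per-parameter (lower, upper) overrides.
    """

    use_log: bool = True
    n_restarts: int = 10
    optimize: bool = True
    init_params: dict | None = None
    bounds: dict | None = None


@dataclass(frozen=True)
class GPFit:
    """A fitted GP: optimized kernel, target transform, and training data."""

    kernel_spec: KernelSpec
    transform: TargetTransform
    training_ids: np.ndarray
    X_train: np.ndarray
    y_train: np.ndarray
    lml: float
    n_restarts: int
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kernel_spec": self.kernel_spec.to_dict(),
            "transform": self.transform.to_dict(),
            "training_ids": [int(i) for i in self.training_ids],
            "X_train": np.asarray(self.X_train).tolist(),
            "y_train": np.asarray(self.y_train).tolist(),
            "lml": self.lml,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GPFit":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            kernel_spec=KernelSpec.from_dict(d["kernel_spec"]),
            transform=TargetTransform(**d["transform"]),
            training_ids=np.asarray(d["training_ids"], dtype=int),
            X_train=np.asarray(d["X_train"], dtype=float),
            y_train=np.asarray(d["y_train"], dtype=float),
            lml=float(d["lml"]),
            n_restarts=int(d["n_restarts"]),
            seed=int(d["seed"]),
        )


@dataclass(frozen=True)
class Prediction:
    """Posterior summary per queried electrode.

    ``mean_uA`` is the inverse-transformed posterior mean (always positive
    when the log transform is on); ``std_transformed`` is the posterior
    standard deviation in transformed space, the acquisition signal for
    adaptive sampling.
    """

    electrode_ids: np.ndarray
    mean_uA: np.ndarray
    mean_transformed: np.ndarray
    std_transformed: np.ndarray


def _make_spec(family: str, params: dict, bounds: dict) -> KernelSpec:
    return KernelSpec(family=family, bounds=bounds, **params)


def _pack(spec: KernelSpec) -> np.ndarray:
    """Kernel parameters -> optimizer coordinates (log10 except mix weight)."""
    out = []
    for name in spec.param_names():
        v = getattr(spec, name)
        out.append(v if name == "mix_weight" else np.log10(v))
    return np.asarray(out)


def _unpack(spec: KernelSpec, theta: np.ndarray) -> KernelSpec:
    params = {}
    for name, t in zip(spec.param_names(), theta):
        params[name] = float(t) if name == "mix_weight" else float(10.0 ** t)
    return spec.with_params(**params)


def _theta_bounds(spec: KernelSpec) -> list[tuple[float, float]]:
    out = []
    for name in spec.param_names():
        lo, hi = spec.bounds[name]
        if name == "mix_weight":
            out.append((lo, hi))
        else:
            out.append((np.log10(lo), np.log10(hi)))
    return out


_DEFAULT_INIT = {
    "signal_variance": 1.0,
    "length_scale": 5.0,
    "length_scale_rbf": 5.0,
    "length_scale_matern": 5.0,
    "mix_weight": 0.5,
    "noise_variance": 0.1,
}


def fit(
    tmap: ThresholdMap,
    train_ids: Sequence[int],
    family: str,
    config: GPConfig = GPConfig(),
    seed: int = 0,
) -> GPFit:
    """Fit a GP to the thresholds at ``train_ids`` by LML maximization.

    A single training electrode is permitted (the posterior mostly reverts
    to the prior) but flagged with a warning.
    """
    train_ids = np.asarray(train_ids, dtype=int)
    if train_ids.size < 1:
        raise ValueError("need at least one training electrode")
    if train_ids.size < 2:
        warnings.warn("fitting a GP to a single electrode", stacklevel=2)
    if np.unique(train_ids).size != train_ids.size:
        raise ValueError("training ids must be unique")

    y, transform = transform_targets(tmap, train_ids, use_log=config.use_log)
    X = tmap.grid.positions_of(train_ids)

    bounds = dict(DEFAULT_BOUNDS)
    if config.bounds:
        bounds.update({k: tuple(v) for k, v in config.bounds.items()})
    init = dict(_DEFAULT_INIT)
    if config.init_params:
        init.update(config.init_params)
    base = KernelSpec(family=family, bounds=bounds)
    init_params = {k: init[k] for k in base.param_names()}
    spec0 = _make_spec(family, init_params, bounds)

    if not config.optimize:
        lml = log_marginal_likelihood(spec0, X, y)
        return GPFit(spec0, transform, train_ids, X, y, lml, 0, seed)

    theta_bounds = _theta_bounds(spec0)
    rng = np.random.default_rng(seed)

    def neg_lml(theta: np.ndarray) -> float:
        try:
            return -log_marginal_likelihood(_unpack(spec0, theta), X, y)
        except FloatingPointError:
            return np.inf

    starts = [_pack(spec0)]
    lo = np.array([b[0] for b in theta_bounds])
    hi = np.array([b[1] for b in theta_bounds])
    for _ in range(max(0, config.n_restarts - 1)):
        starts.append(rng.uniform(lo, hi))

    best_theta, best_val = None, np.inf
    failures = []
    for theta0 in starts:
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = optimize.minimize(
                neg_lml, theta0, method="L-BFGS-B", bounds=theta_bounds
            )
        except Exception as exc:  # pragma: no cover - optimizer internals
            failures.append(repr(exc))
            continue
        # never accept a point worse than its own start
        val = min(res.fun, neg_lml(theta0))
        cand = res.x if res.fun <= neg_lml(theta0) else theta0
        if np.isfinite(val) and val < best_val:
            best_theta, best_val = cand, val
    if best_theta is None:
        raise GPFitError(
            f"all {len(starts)} restarts failed for family={family}; "
            f"errors: {failures}"
        )
    spec = _unpack(spec0, best_theta)
    return GPFit(
        spec, transform, train_ids, X, y, -best_val, config.n_restarts, seed
    )


def predict(
    gp: GPFit, grid: ElectrodeGrid, query_ids: Sequence[int]
) -> Prediction:
    """Posterior mean and standard deviation at the queried electrodes.

    Inactive electrodes may be queried -- predicting them is the point of the
    tool.  Variances are clamped at zero (tolerance 1e-10 for round-off).
    """
    query_ids = np.asarray(query_ids, dtype=int)
    if query_ids.size == 0:
        empty = np.empty(0)
        return Prediction(query_ids, empty, empty.copy(), empty.copy())
    Xq = grid.positions_of(query_ids)
    spec = gp.kernel_spec
    K = kernel_matrix(spec, gp.X_train, include_noise=True)
    c = _chol_with_jitter(K)
    alpha = cho_solve(c, gp.y_train)
    Ks = kernel_matrix(spec, gp.X_train, Xq)  # (n_train, n_query)
    mean_t = Ks.T @ alpha
    v = cho_solve(c, Ks)
    var = spec.signal_variance - np.einsum("ij,ij->j", Ks, v)
    if (var < -1e-10).any():
        warnings.warn("posterior variance clipped below -1e-10", stacklevel=2)
    std_t = np.sqrt(np.clip(var, 0.0, None))
    return Prediction(
        electrode_ids=query_ids,
        mean_uA=gp.transform.inverse(mean_t),
        mean_transformed=mean_t,
        std_transformed=std_t,
    )
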