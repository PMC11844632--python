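"""Stationary covariance functions for threshold-map Gaussian processes.

Three kernel families are supported, all functions of the Euclidean distance
``d`` between electrode positions (in pitch units):

* ``rbf`` -- squared-exponential, ``sigma2 * exp(-d^2 / (2 l^2))``; assumes
  thresholds vary smoothly across the array.
* ``matern15`` -- Matern with smoothness nu = 1.5,
  ``sigma2 * (1 + sqrt(3) d / l) * exp(-sqrt(3) d / l)``; tolerates sharper
  spatial transitions, e.g. at scars or poorly coupled electrodes.
* ``hybrid`` -- a convex mix ``sigma2 * [alpha * RBF_unit(l1)
  + (1 - alpha) * Matern_unit(l2)]`` of the two unit-variance components,
  with a single shared signal variance and separate length scales.

An independent observation-noise term ``sigma_n^2 * delta_ij`` is added on
the diagonal of training covariance matrices (see :func:`kernel_matrix`), not
inside the point-wise kernel value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["KernelSpec", "kernel_value", "kernel_matrix", "KERNEL_FAMILIES"]

KERNEL_FAMILIES = ("rbf", "matern15", "hybrid")

_SQRT3 = np.sqrt(3.0)

#: Optimization bounds: signal variance in (0.1, 10) and length scales in
#: (1, 50) pitch units; noise variance strictly positive for stable solves;
#: mix weight alpha confined to [0, 1].
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "signal_variance": (0.1, 10.0),
    "length_scale": (1.0, 50.0),
    "length_scale_rbf": (1.0, 50.0),
    "length_scale_matern": (1.0, 50.0),
    "mix_weight": (0.0, 1.0),
    "noise_variance": (1e-5, 1.0),
}


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its hyperparameters and optimization bounds.

    ``length_scale`` applies to the single-component families; the hybrid
    family uses ``length_scale_rbf`` / ``length_scale_matern`` and the mix
    weight ``mix_weight`` (alpha = 1 is pure RBF, alpha = 0 pure Matern).
    """

    family: str
    signal_variance: float = 1.0
    length_scale: float = 5.0
    length_scale_rbf: float = 5.0
    length_scale_matern: float = 5.0
    mix_weight: float = 0.5
    noise_variance: float = 0.1
    bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; expected one of "
                f"{KERNEL_FAMILIES}"
            )
        for name in (
            "signal_variance",
            "length_scale",
            "length_scale_rbf",
            "length_scale_matern",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")
        if not 0.0 <= self.mix_weight <= 1.0:
            raise ValueError("mix_weight must lie in [0, 1]")

    def param_names(self) -> Tuple[str, ...]:
        """Free hyperparameters of this family, in canonical order."""
        if self.family == "hybrid":
            return (
                "signal_variance",
                "length_scale_rbf",
                "length_scale_matern",
                "mix_weight",
                "noise_variance",
            )
        return ("signal_variance", "length_scale", "noise_variance")

    def with_params(self, **params: float) -> "KernelSpec":
        return replace(self, **params)

    def to_dict(self) -> dict:
        d = {"family": self.family}
        for name in self.param_names():
            d[name] = float(getattr(self, name))
        d["bounds"] = {k: list(v) for k, v in self.bounds.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        d = dict(d)
        bounds = d.pop("bounds", None)
        if bounds is not None:
            d["bounds"] = {k: tuple(v) for k, v in bounds.items()}
        return cls(**d)


def _rbf_unit(d: np.ndarray, length_scale: float) -> np.ndarray:
    return np.exp(-0.5 * (d / length_scale) ** 2)


def _matern15_unit(d: np.ndarray, length_scale: float) -> np.ndarray:
    s = _SQRT3 * d / length_scale
    return (1.0 + s) * np.exp(-s)


def kernel_value(spec: KernelSpec, d) -> np.ndarray:
    """Evaluate the covariance at distance(s) ``d >= 0``.

    The observation-noise term is *not* included; it lives on the diagonal of
    the training covariance matrix only (see :func:`kernel_matrix`).
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if spec.family == "rbf":
        unit = _rbf_unit(d, spec.length_scale)
    elif spec.family == "matern15":
        unit = _matern15_unit(d, spec.length_scale)
    else:
        a = spec.mix_weight
        unit = a * _rbf_unit(d, spec.length_scale_rbf) + (1.0 - a) * _matern15_unit(
            d, spec.length_scale_matern
        )
    return spec.signal_variance * unit


def kernel_matrix(
    spec: KernelSpec,
    X1: np.ndarray,
    X2: np.ndarray | None = None,
    include_noise: bool = False,
) -> np.ndarray:
    """Covariance matrix between two position sets.

    Parameters
    ----------
    X1, X2 : (n, 2) position arrays; ``X2 = None`` means ``X2 = X1``.
    include_noise : bool
        Add ``noise_variance`` on the diagonal (the sigma_n^2 delta_ij term).
        Only meaningful when X1 and X2 index the same points.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = X1 if X2 is None else np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"position dimensionality mismatch: {X1.shape[1]} vs {X2.shape[1]}"
        )
    K = kernel_value(spec, cdist(X1, X2))
    if include_noise:
        if K.shape[0] != K.shape[1]:
            raise ValueError("include_noise requires a square (training) matrix")
        K = K + spec.noise_variance * np.eye(K.shape[0])
    return K
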