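"""Multimodal von Mises mixture utilities for torsion-angle distributions.

A mixture has up to five components (w_i, mu_i, kappa_i) per angle, with
density

    p(theta) = sum_i w_i exp(kappa_i cos(theta - mu_i)) / (2 pi I0(kappa_i))

per radian, where I0 is the modified Bessel function of the first kind and
order 0. Means live in [-180, 180] degrees, concentrations in [0, 10].
The module provides the density, the mean negative log-likelihood a
trainer would minimize, the constrained parameterization (tanh means,
clamped softplus concentrations, softmax weights), seeded sampling,
best-component angular RMSE, and circular mean/median lookup baselines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import i0, softmax

MAX_COMPONENTS = 5
KAPPA_MAX = 10.0
NLL_FLOOR = 1e-12


class MixtureError(ValueError):
    pass


@dataclass
class VonMisesMixture:
    weights: np.ndarray
    means_deg: np.ndarray
    kappas: np.ndarray

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.means_deg = np.atleast_1d(np.asarray(self.means_deg, dtype=float))
        self.kappas = np.atleast_1d(np.asarray(self.kappas, dtype=float))
        k = len(self.weights)
        if not (len(self.means_deg) == len(self.kappas) == k):
            raise MixtureError("weights, means and kappas must have equal length")
        if k < 1 or k > MAX_COMPONENTS:
            raise MixtureError(f"1..{MAX_COMPONENTS} components allowed, got {k}")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise MixtureError("weights must be non-negative and sum to 1")
        if np.any(self.kappas < 0) or np.any(self.kappas > KAPPA_MAX):
            raise MixtureError(f"kappas must lie in [0, {KAPPA_MAX}]")
        if np.any(np.abs(self.means_deg) > 180.0):
            raise MixtureError("means must lie in [-180, 180] degrees")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def to_json(self) -> str:
        return json.dumps(
            {"weights": self.weights.tolist(), "means_deg": self.means_deg.tolist(),
             "kappas": self.kappas.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "VonMisesMixture":
        d = json.loads(text)
        return cls(np.array(d["weights"]), np.array(d["means_deg"]), np.array(d["kappas"]))


def vm_density(theta_deg, mix: VonMisesMixture) -> np.ndarray | float:
    """Mixture density per radian at angle(s) in degrees."""
    theta = np.radians(np.atleast_1d(np.asarray(theta_deg, dtype=float)))
    mu = np.radians(mix.means_deg)
    dens = np.zeros_like(theta)
    for w, m, k in zip(mix.weights, mu, mix.kappas):
        dens += w * np.exp(k * np.cos(theta - m)) / (2.0 * math.pi * i0(k))
    return float(dens[0]) if np.isscalar(theta_deg) else dens


def vm_nll(observed_deg, mix: VonMisesMixture, weights=None, floor: float = NLL_FLOOR) -> float:
    """Weighted mean negative log density of observed angles (degrees)."""
    obs = np.atleast_1d(np.asarray(observed_deg, dtype=float))
    if not np.all(np.isfinite(obs)):
        raise MixtureError("observations must be finite")
    w = np.full(obs.size, 1.0 / obs.size) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    dens = np.asarray(vm_density(obs, mix))
    if np.any(dens < floor):
        from .model import warn

        warn("density underflow floored in NLL")
        dens = np.maximum(dens, floor)
    return float(-(w * np.log(dens)).sum())


def softplus(x):
    return np.logaddexp(0.0, np.asarray(x, dtype=float))


def constrain_parameters(raw_weights, raw_means, raw_kappas) -> VonMisesMixture:
    """Map unconstrained parameter streams onto a valid mixture.

    Means are bounded to +-180 deg via tanh, concentrations via softplus
    clamped at kappa <= 10, and weights via softmax.
    """
    rw = np.atleast_1d(np.asarray(raw_weights, dtype=float))
    rm = np.atleast_1d(np.asarray(raw_means, dtype=float))
    rk = np.atleast_1d(np.asarray(raw_kappas, dtype=float))
    if len(rw) > MAX_COMPONENTS:
        raise MixtureError(f"more than {MAX_COMPONENTS} components")
    if not (np.all(np.isfinite(rw)) and np.all(np.isfinite(rm)) and np.all(np.isfinite(rk))):
        raise MixtureError("raw parameters must be finite")
    return VonMisesMixture(
        weights=softmax(rw),
        means_deg=180.0 * np.tanh(rm),
        kappas=np.minimum(softplus(rk), KAPPA_MAX),
    )


def vm_sample(mix: VonMisesMixture, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """n angles (degrees in (-180, 180]) sampled from the mixture, seeded.

    A component is chosen by weight, then a von Mises variate is drawn
    (uniform in the kappa = 0 limit).
    """
    if n < 1:
        raise MixtureError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = rng.choice(mix.n_components, size=n, p=mix.weights)
    out = np.empty(n)
    for i in range(mix.n_components):
        mask = comp == i
        k = mix.kappas[i]
        mu = math.radians(mix.means_deg[i])
        if not mask.any():
            continue
        if k < 1e-12:
            draws = rng.uniform(-math.pi, math.pi, mask.sum())
        else:
            draws = rng.vonmises(mu, k, mask.sum())
        out[mask] = draws
    deg = np.degrees((out + math.pi) % (2 * math.pi) - math.pi)
    deg[deg == -180.0] = 180.0
    return deg


def circular_error_deg(a_deg, b_deg) -> np.ndarray:
    """Smallest absolute angular difference in degrees (wraps at +-180)."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float) + 180.0) % 360.0 - 180.0
    return np.abs(d)


def angular_rmse_best_component(observed_deg, mix: VonMisesMixture) -> float:
    """RMSE of each observation's circular error to its nearest component mean."""
    obs = np.atleast_1d(np.asarray(observed_deg, dtype=float))
    if obs.size == 0:
        raise MixtureError("no observations")
    errs = np.min(
        [circular_error_deg(obs, m) for m in mix.means_deg], axis=0
    )
    return float(np.sqrt(np.mean(errs**2)))


# ---------------------------------------------------------------------------
# mean/median lookup baselines


def circular_mean_deg(angles_deg, weights=None) -> float:
    theta = np.radians(np.asarray(angles_deg, dtype=float))
    w = np.ones(theta.size) if weights is None else np.asarray(weights, float)
    m = math.degrees(math.atan2(float((w * np.sin(theta)).sum()), float((w * np.cos(theta)).sum())))
    return 180.0 if m == -180.0 else m


def circular_median_deg(angles_deg) -> float:
    """Angle among the observations minimizing the summed circular distance."""
    a = np.asarray(angles_deg, dtype=float)
    costs = [circular_error_deg(a, x).sum() for x in a]
    return float(a[int(np.argmin(costs))])


class BaselinePredictor:
    """Lookup predictor keyed by mono- or disaccharide.

    Returns the per-key mean/median of the training values (circular
    statistics for angular targets); unseen keys fall back to the global
    statistic, flagged in :meth:`predict_with_flag`.
    """

    def __init__(self, table: pd.DataFrame, statistic: str = "mean", circular: bool = False,
                 key: str = "key", value: str = "value"):
        if table.empty:
            raise MixtureError("empty baseline training table")
        if statistic not in ("mean", "median"):
            raise MixtureError(f"unknown statistic {statistic!r}")
        self.statistic = statistic
        self.circular = circular

        def _stat(vals: np.ndarray) -> float:
            if circular:
                return circular_mean_deg(vals) if statistic == "mean" else circular_median_deg(vals)
            return float(np.mean(vals)) if statistic == "mean" else float(np.median(vals))

        self.lookup = {k: _stat(g[value].to_numpy()) for k, g in table.groupby(key)}
        self.global_value = _stat(table[value].to_numpy())

    def predict_with_flag(self, key: str) -> tuple[float, bool]:
        if key in self.lookup:
            return self.lookup[key], False
        return self.global_value, True

    def predict(self, key: str) -> float:
        return self.predict_with_flag(key)[0]


def baseline_predictor(table: pd.DataFrame, statistic: str = "mean", circular: bool = False,
                       **kwargs) -> BaselinePredictor:
    return BaselinePredictor(table, statistic=statistic, circular=circular, **kwargs)
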