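"""Core cRBM probability model.

A compositional restricted Boltzmann machine couples N binary visible
units (neurons) to M real-valued hidden units (assemblies) through a
weight matrix ``w`` (N x M).  The joint energy is

    E(v, h) = -sum_i g_i v_i + sum_mu U_mu(h_mu) - sum_{i,mu} w_{i,mu} v_i h_mu

with ``U`` the dReLU potential of :mod:`crbm.drelu`.  Because the graph
is bipartite, both conditionals factorise: ``p(h | v)`` is a product of
truncated-Gaussian mixtures driven by the inputs ``I_mu = w_mu^T v`` and
``p(v | h)`` is a product of Bernoullis with logits ``g + w h``.
Integrating the hidden layer out in closed form gives the unnormalised
marginal ``log P(v) + log Z = g^T v + sum_mu Gamma_mu(I_mu(v))``.

For systems with N <= 20 visible units, this module also provides exact
enumeration over all 2^N configurations (partition function, exact
distribution, exact moments, exact log-likelihood), used throughout the
test suite as an independent oracle for the samplers and the training
gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import h5py
import numpy as np
from scipy.special import expit, logsumexp

from . import drelu

__all__ = [
    "CRBMParams",
    "energy",
    "hidden_input",
    "sample_h_given_v",
    "mean_h_given_v",
    "hidden_moments",
    "sample_v_given_h",
    "mean_v_given_h",
    "marginal_log_unnormalized",
    "all_visible_configs",
    "exact_log_partition",
    "exact_visible_distribution",
    "exact_moments",
    "exact_log_likelihood",
    "sign_swap",
]

ENUMERATION_MAX_N = 20
PARAMS_FORMAT_VERSION = 1


@dataclass
class CRBMParams:
    """All parameters of a cRBM.

    Attributes
    ----------
    weights
        Coupling matrix of shape ``(n_visible, n_hidden)``.
    g
        Visible fields, shape ``(n_visible,)``.
    gamma_plus, gamma_minus
        Positive curvatures of the dReLU branches, shape ``(n_hidden,)``.
    theta_plus, theta_minus
        Branch offsets of the dReLU potential, shape ``(n_hidden,)``.
    """

    weights: np.ndarray
    g: np.ndarray
    gamma_plus: np.ndarray
    gamma_minus: np.ndarray
    theta_plus: np.ndarray
    theta_minus: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.array(self.weights, dtype=float)
        self.g = np.array(self.g, dtype=float)
        for name in ("gamma_plus", "gamma_minus", "theta_plus", "theta_minus"):
            setattr(self, name, np.atleast_1d(np.array(getattr(self, name), dtype=float)))
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D (n_visible, n_hidden) array")
        n, m = self.weights.shape
        if self.g.shape != (n,):
            raise ValueError(f"g has shape {self.g.shape}, expected ({n},)")
        for name in ("gamma_plus", "gamma_minus", "theta_plus", "theta_minus"):
            arr = getattr(self, name)
            if arr.shape != (m,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({m},)")
        for name in ("weights", "g", "gamma_plus", "gamma_minus", "theta_plus", "theta_minus"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.gamma_plus <= 0) or np.any(self.gamma_minus <= 0):
            raise ValueError("gamma_plus and gamma_minus must be strictly positive")

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "CRBMParams":
        return CRBMParams(
            weights=self.weights.copy(),
            g=self.g.copy(),
            gamma_plus=self.gamma_plus.copy(),
            gamma_minus=self.gamma_minus.copy(),
            theta_plus=self.theta_plus.copy(),
            theta_minus=self.theta_minus.copy(),
        )

    def save(self, path) -> None:
        """Write parameters to a single HDF5 file."""
        with h5py.File(path, "w") as f:
            f.create_dataset("weights", data=self.weights)
            f.create_dataset("g", data=self.g)
            f.create_dataset("gamma_plus", data=self.gamma_plus)
            f.create_dataset("gamma_minus", data=self.gamma_minus)
            f.create_dataset("theta_plus", data=self.theta_plus)
            f.create_dataset("theta_minus", data=self.theta_minus)
            f.attrs["n_visible"] = self.n_visible
            f.attrs["n_hidden"] = self.n_hidden
            f.attrs["format_version"] = PARAMS_FORMAT_VERSION

    @classmethod
    def load(cls, path) -> "CRBMParams":
        with h5py.File(path, "r") as f:
            return cls(
                weights=f["weights"][...],
                g=f["g"][...],
                gamma_plus=f["gamma_plus"][...],
                gamma_minus=f["gamma_minus"][...],
                theta_plus=f["theta_plus"][...],
                theta_minus=f["theta_minus"][...],
            )


def _check_binary(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValueError("visible configurations must be binary (entries in {0, 1})")
    return v.astype(float)


def energy(v, h, params: CRBMParams) -> np.ndarray:
    """Joint energy E(v, h); batched over leading axes of v and h."""
    v = _check_binary(v)
    h = np.asarray(h, dtype=float)
    if v.shape[-1] != params.n_visible:
        raise ValueError(
            f"v has {v.shape[-1]} entries, model expects {params.n_visible}"
        )
    if h.shape[-1] != params.n_hidden:
        raise ValueError(
            f"h has {h.shape[-1]} entries, model expects {params.n_hidden}"
        )
    field_term = v @ params.g
    potential = drelu.drelu_potential(
        h, params.gamma_plus, params.gamma_minus, params.theta_plus, params.theta_minus
    ).sum(axis=-1)
    coupling = np.einsum("...i,im,...m->...", v, params.weights, h)
    return -field_term + potential - coupling


def hidden_input(v, params: CRBMParams) -> np.ndarray:
    """Inputs I_mu(v) = w_mu^T v to every hidden unit."""
    v = _check_binary(v)
    return v @ params.weights


def hidden_moments(v, params: CRBMParams) -> drelu.DReLUMoments:
    """Conditional moments of every hidden unit given v."""
    I = hidden_input(v, params)
    return drelu.moments(
        I, params.gamma_plus, params.gamma_minus, params.theta_plus, params.theta_minus
    )


def mean_h_given_v(v, params: CRBMParams) -> np.ndarray:
    """Conditional means <h_mu | v> = Gamma'_mu(I_mu(v)).

    This linear-nonlinear transform is the convention used everywhere a
    hidden trace is computed from recorded activity.
    """
    return hidden_moments(v, params).mean


def sample_h_given_v(v, params: CRBMParams, rng: np.random.Generator) -> np.ndarray:
    """Exact sample from p(h | v)."""
    I = hidden_input(v, params)
    return drelu.sample(
        I,
        params.gamma_plus,
        params.gamma_minus,
        params.theta_plus,
        params.theta_minus,
        rng,
    )


def mean_v_given_h(h, params: CRBMParams) -> np.ndarray:
    """Bernoulli means <v_i | h> = sigmoid(g_i + w_i^T h)."""
    h = np.asarray(h, dtype=float)
    return expit(params.g + h @ params.weights.T)


def sample_v_given_h(h, params: CRBMParams, rng: np.random.Generator) -> np.ndarray:
    """Sample from p(v | h): independent Bernoullis."""
    p = mean_v_given_h(h, params)
    return (rng.random(size=p.shape) < p).astype(np.uint8)


def marginal_log_unnormalized(v, params: CRBMParams) -> np.ndarray:
    """log P(v) + log Z = g^T v + sum_mu Gamma_mu(I_mu(v))."""
    v = _check_binary(v)
    I = v @ params.weights
    gam = drelu.cumulant(
        I, params.gamma_plus, params.gamma_minus, params.theta_plus, params.theta_minus
    )
    return v @ params.g + gam.sum(axis=-1)


def all_visible_configs(n: int) -> np.ndarray:
    """All 2^n binary configurations as a (2^n, n) uint8 array."""
    if n > ENUMERATION_MAX_N:
        raise ValueError(
            f"enumeration limited to n_visible <= {ENUMERATION_MAX_N}, got {n}"
        )
    idx = np.arange(2**n, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(np.uint8)


def exact_log_partition(params: CRBMParams) -> float:
    """log Z by exhaustive enumeration of the visible layer (N <= 20)."""
    if params.n_visible > ENUMERATION_MAX_N:
        raise ValueError(
            "exact_log_partition enumerates 2^N configurations and refuses "
            f"N > {ENUMERATION_MAX_N} (got N = {params.n_visible})"
        )
    configs = all_visible_configs(params.n_visible)
    return float(logsumexp(marginal_log_unnormalized(configs, params)))


def exact_visible_distribution(params: CRBMParams) -> tuple[np.ndarray, np.ndarray]:
    """All configurations and their exact probabilities P(v)."""
    configs = all_visible_configs(params.n_visible)
    logp = marginal_log_unnormalized(configs, params)
    logp = logp - logsumexp(logp)
    return configs, np.exp(logp)


def exact_moments(params: CRBMParams) -> dict[str, np.ndarray]:
    """Exact model-side moments by enumeration (N <= 20).

    Hidden-unit statistics are computed by conditioning on v (law of
    total expectation), i.e. ``<v_i h_mu> = sum_v P(v) v_i Gamma'_mu``.
    Keys mirror the sufficient statistics of the likelihood gradients.
    """
    configs, probs = exact_visible_distribution(params)
    v = configs.astype(float)
    mom = hidden_moments(configs, params)
    return {
        "v": probs @ v,
        "vv": (v * probs[:, None]).T @ v,
        "h": probs @ mom.mean,
        "vh": (v * probs[:, None]).T @ mom.mean,
        "hp": probs @ mom.hp_mean,
        "hm": probs @ mom.hm_mean,
        "hp_sq": probs @ mom.hp_sq_mean,
        "hm_sq": probs @ mom.hm_sq_mean,
    }


def exact_log_likelihood(v, params: CRBMParams) -> float:
    """Mean log-likelihood of data frames under the exactly normalised model."""
    log_z = exact_log_partition(params)
    return float(np.mean(marginal_log_unnormalized(v, params)) - log_z)


def sign_swap(params: CRBMParams, units: Iterable[int] | None = None) -> CRBMParams:
    """Apply the sign-swap gauge transformation to selected hidden units.

    The transformation realises ``h_mu -> -h_mu``: it negates the unit's
    weight column and exchanges the dReLU branches.  With the potential
    written as ``... + theta_+ h_+ + theta_- h_-`` (both linear terms
    entering with a plus sign), exchanging the branches must also negate
    the offsets, ``(gamma_+, theta_+) <- (gamma_-, -theta_-)`` and vice
    versa, for the marginal P(v) to be exactly invariant.  With
    ``units=None`` the conventional post-training choice is applied:
    every unit whose summed weights are negative is flipped, so
    assemblies activate their units positively.
    """
    out = params.copy()
    if units is None:
        units = np.flatnonzero(out.weights.sum(axis=0) < 0)
    units = np.asarray(list(units), dtype=int)
    if units.size == 0:
        return out
    out.weights[:, units] *= -1.0
    gp = out.gamma_plus[units].copy()
    tp = out.theta_plus[units].copy()
    out.gamma_plus[units] = out.gamma_minus[units]
    out.theta_plus[units] = -out.theta_minus[units]
    out.gamma_minus[units] = gp
    out.theta_minus[units] = -tp
    return out
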