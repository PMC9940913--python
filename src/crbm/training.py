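"""Fitting a cRBM by persistent contrastive divergence (PCD).

The likelihood gradient of an RBM is a difference of sufficient
statistics, ``<f>_data - <f>_model``.  Data-side hidden statistics are
computed as conditional expectations given the observed frames
(Rao-Blackwellised, which removes all sampling noise from that side);
model-side statistics come from persistent Gibbs chains that are
advanced a fixed number of alternating steps between parameter updates.
Updates use RMSprop (adaptive per-parameter learning rates, no
momentum), an L1 penalty on the weights promotes sparse assemblies, and
the learning rate decays geometrically over the last part of training.

Two stabilising devices are applied during training:

* hidden-unit normalisation: each unit is periodically reparameterised
  (an exact gauge transformation of the dReLU family) so its activity
  has unit variance, plus a damped offset adjustment driving its mean
  towards zero.  This keeps all units comparably scaled and prevents
  single units from dominating or disconnecting.
* divergence recovery: if the weight spread explodes the run restarts
  from scratch with a halved learning rate, a bounded number of times.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.special import logit

from . import drelu, model as model_mod
from .io import BinarySpikeMatrix
from .model import CRBMParams

__all__ = [
    "TrainingConfig",
    "TrainingState",
    "TrainingDiverged",
    "data_moments",
    "model_moments",
    "gradients",
    "gradient_step",
    "hu_normalization",
    "fit",
    "convergence_check",
]


class TrainingDiverged(RuntimeError):
    """Raised when training diverges beyond recovery.

    Carries a ``snapshot`` dict with the offending state for diagnosis.
    """

    def __init__(self, message: str, snapshot: dict | None = None):
        super().__init__(message)
        self.snapshot = snapshot or {}


@dataclass
class TrainingConfig:
    """Hyperparameters of a cRBM fit.

    Defaults follow the reference protocol for this model family
    (15 Gibbs steps per update, 100 persistent chains, RMSprop with
    beta2 = 0.999 and eps = 1e-6, geometric learning-rate decay to 1e-5
    starting after 25% of the updates, L1 sparsity 0.02), with the
    number of updates set to a desk-scale 20,000 (the full-scale
    protocol uses 200,000; override ``n_updates`` to match it).
    """

    n_hidden: int = 10
    sparsity: float = 0.02
    batch_size: int = 100
    n_chains: int = 100
    n_updates: int = 20_000
    mc_steps_per_update: int = 15
    lr_initial: float = 5e-3
    lr_final: float = 1e-5
    anneal_start_fraction: float = 0.25
    sparsity_warmup_fraction: float = 0.25
    rmsprop_beta2: float = 0.999
    rmsprop_epsilon: float = 1e-6
    seed: int = 0
    normalize_hu: bool = True
    hu_norm_ema: float = 0.99
    hu_mean_damping: float = 0.05
    gamma_min: float = 0.05
    divergence_weight_std: float = 1.0
    max_restarts: int = 3
    log_every: int = 200

    def __post_init__(self) -> None:
        for name in ("n_hidden", "batch_size", "n_chains", "n_updates",
                     "mc_steps_per_update"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sparsity < 0:
            raise ValueError("sparsity (L1 coefficient) must be >= 0")
        if not (0 < self.lr_final <= self.lr_initial):
            raise ValueError("require 0 < lr_final <= lr_initial")
        if not (0 <= self.anneal_start_fraction <= 1):
            raise ValueError("anneal_start_fraction must lie in [0, 1]")

    @classmethod
    def from_file(cls, path) -> "TrainingConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def sparsity_at(self, update: int) -> float:
        """L1 coefficient schedule: linear warm-up to the nominal value.

        The zero-weight configuration is a stable fixed point of the L1
        subgradient whenever the correlation-driven gradient is smaller
        than the penalty, so switching the full penalty on from a small
        random initialisation freezes the model at w = 0.  Ramping the
        penalty over the first ``sparsity_warmup_fraction`` of the run
        lets the assemblies break symmetry first and sparsifies them
        afterwards.
        """
        t0 = int(self.sparsity_warmup_fraction * self.n_updates)
        if update >= t0 or t0 == 0:
            return self.sparsity
        return self.sparsity * update / t0

    def learning_rate(self, update: int) -> float:
        """Constant then geometrically decaying schedule."""
        t0 = int(self.anneal_start_fraction * self.n_updates)
        if update <= t0 or self.n_updates <= t0:
            return self.lr_initial
        frac = (update - t0) / (self.n_updates - t0)
        return float(self.lr_initial * (self.lr_final / self.lr_initial) ** frac)


@dataclass
class TrainingState:
    """Mutable state of a PCD run: parameters, fantasy chains, RMSprop
    second-moment accumulators, hidden-unit activity trackers and the
    per-checkpoint history."""

    params: CRBMParams
    chains_v: np.ndarray
    rms: dict[str, np.ndarray]
    rng: np.random.Generator
    update_counter: int = 0
    h_mean_ema: np.ndarray | None = None
    h_var_ema: np.ndarray | None = None
    history: list[dict[str, Any]] = field(default_factory=list)
    _ema_beta: float = 0.99
    _mean_damping: float = 0.05

    @classmethod
    def initialize(cls, frames: np.ndarray, config: TrainingConfig,
                   rng: np.random.Generator) -> "TrainingState":
        """Fresh state: small random weights, fields at the logit of the
        empirical rates, unit curvatures, chains on random data frames."""
        n_frames, n = frames.shape
        m = config.n_hidden
        w = rng.normal(0.0, 0.01 / np.sqrt(n), size=(n, m))
        rate = frames.mean(axis=0)
        rate = np.clip(rate, 1.0 / (2 * n_frames), 1 - 1.0 / (2 * n_frames))
        g = np.clip(logit(rate), -10.0, 10.0)
        params = CRBMParams(
            weights=w,
            g=g,
            gamma_plus=np.ones(m),
            gamma_minus=np.ones(m),
            theta_plus=np.zeros(m),
            theta_minus=np.zeros(m),
        )
        chains = frames[rng.integers(0, n_frames, size=config.n_chains)].astype(np.uint8)
        rms = {k: np.zeros_like(v) for k, v in _param_arrays(params).items()}
        return cls(params=params, chains_v=chains, rms=rms, rng=rng,
                   _ema_beta=config.hu_norm_ema,
                   _mean_damping=config.hu_mean_damping)


def _param_arrays(params: CRBMParams) -> dict[str, np.ndarray]:
    return {
        "g": params.g,
        "weights": params.weights,
        "theta_plus": params.theta_plus,
        "theta_minus": params.theta_minus,
        "gamma_plus": params.gamma_plus,
        "gamma_minus": params.gamma_minus,
    }


def data_moments(frames: np.ndarray, params: CRBMParams) -> dict[str, np.ndarray]:
    """Sufficient statistics of a batch with hidden units integrated out.

    Hidden values never get sampled on the data side: every hidden
    moment is the conditional expectation given the frame.
    """
    frames = np.asarray(frames, dtype=float)
    mom = model_mod.hidden_moments(frames, params)
    b = frames.shape[0]
    return {
        "v": frames.mean(axis=0),
        "h": mom.mean.mean(axis=0),
        "vh": frames.T @ mom.mean / b,
        "hp": mom.hp_mean.mean(axis=0),
        "hm": mom.hm_mean.mean(axis=0),
        "hp_sq": mom.hp_sq_mean.mean(axis=0),
        "hm_sq": mom.hm_sq_mean.mean(axis=0),
        "_h_frame_means": mom.mean,
        "_h_frame_vars": mom.var,
    }


def model_moments(chains_v: np.ndarray, params: CRBMParams) -> dict[str, np.ndarray]:
    """Model-side statistics from the persistent chains' visible states
    (hidden moments again Rao-Blackwellised given each chain state)."""
    return data_moments(chains_v.astype(float), params)


def gradients(data_m: dict, model_m: dict, params: CRBMParams,
              sparsity: float) -> dict[str, np.ndarray]:
    """Log-likelihood ascent directions for every parameter group.

    ``d/dg = <v>_d - <v>_m``; ``d/dw = <v h>_d - <v h>_m - lambda sign(w)``;
    ``d/dtheta± = -<h±>_d + <h±>_m``; ``d/dgamma± = -(<h±²>_d - <h±²>_m)/2``.
    """
    grad_w = data_m["vh"] - model_m["vh"]
    if sparsity > 0:
        grad_w = grad_w - sparsity * np.sign(params.weights)
    return {
        "g": data_m["v"] - model_m["v"],
        "weights": grad_w,
        "theta_plus": -(data_m["hp"] - model_m["hp"]),
        "theta_minus": -(data_m["hm"] - model_m["hm"]),
        "gamma_plus": -0.5 * (data_m["hp_sq"] - model_m["hp_sq"]),
        "gamma_minus": -0.5 * (data_m["hm_sq"] - model_m["hm_sq"]),
    }


def advance_chains(state: TrainingState, n_steps: int) -> None:
    """Run ``n_steps`` of alternating Gibbs sampling on the fantasy chains."""
    v = state.chains_v
    for _ in range(n_steps):
        h = model_mod.sample_h_given_v(v, state.params, state.rng)
        v = model_mod.sample_v_given_h(h, state.params, state.rng)
    state.chains_v = v


def hu_normalization(state: TrainingState, batch_moments: dict) -> None:
    """Gauge-fix each hidden unit towards unit variance and zero mean.

    Variance: the map ``h -> h / s`` is an exact reparameterisation of
    the dReLU family (``w -> s w``, ``gamma± -> s² gamma±``,
    ``theta± -> s theta±``) leaving P(v) untouched, so the full
    correction is applied each call using an EMA estimate of Var(h).
    Mean: a damped shift of theta± nudges <h> towards 0 (this one does
    move within the family, hence the damping).  RMSprop accumulators
    are rescaled consistently with the gauge change.  Units with
    degenerate (near-zero) variance estimates are left untouched.
    """
    h_means = batch_moments["_h_frame_means"]
    h_vars = batch_moments["_h_frame_vars"]
    batch_mean = h_means.mean(axis=0)
    batch_var = h_vars.mean(axis=0) + h_means.var(axis=0)

    if state.h_mean_ema is None:
        state.h_mean_ema = batch_mean.copy()
        state.h_var_ema = batch_var.copy()
    else:
        b = state._ema_beta
        state.h_mean_ema = b * state.h_mean_ema + (1 - b) * batch_mean
        state.h_var_ema = b * state.h_var_ema + (1 - b) * batch_var

    ok = state.h_var_ema > 1e-8
    if not ok.all():
        warnings.warn("hidden unit(s) with degenerate variance left unnormalised")
    s = np.where(ok, np.sqrt(state.h_var_ema), 1.0)

    p = state.params
    p.weights *= s
    p.gamma_plus *= s**2
    p.gamma_minus *= s**2
    p.theta_plus *= s
    p.theta_minus *= s
    state.rms["weights"] /= s**2
    state.rms["theta_plus"] /= s**2
    state.rms["theta_minus"] /= s**2
    state.rms["gamma_plus"] /= s**4
    state.rms["gamma_minus"] /= s**4
    state.h_var_ema = np.where(ok, 1.0, state.h_var_ema)
    state.h_mean_ema = state.h_mean_ema / s

    shift = state._mean_damping * state.h_mean_ema
    p.theta_plus += shift * p.gamma_plus
    p.theta_minus += shift * p.gamma_minus


def gradient_step(batch: np.ndarray, state: TrainingState,
                  config: TrainingConfig) -> TrainingState:
    """One PCD update: advance chains, compare moments, RMSprop step.

    Mutates and returns ``state``.  Raises :class:`TrainingDiverged`
    with a diagnostic snapshot if any gradient contains NaN.
    """
    advance_chains(state, config.mc_steps_per_update)
    data_m = data_moments(batch, state.params)
    model_m = model_moments(state.chains_v, state.params)
    grads = gradients(data_m, model_m, state.params,
                      config.sparsity_at(state.update_counter))

    for name, grad in grads.items():
        if not np.all(np.isfinite(grad)):
            raise TrainingDiverged(
                f"non-finite gradient for {name} at update {state.update_counter}",
                snapshot={
                    "update": state.update_counter,
                    "param": name,
                    "weight_std": float(np.std(state.params.weights)),
                    "grads": grads,
                },
            )

    lr = config.learning_rate(state.update_counter)
    t = state.update_counter + 1
    bias_corr = 1.0 - config.rmsprop_beta2**t
    arrays = _param_arrays(state.params)
    for name, grad in grads.items():
        acc = state.rms[name]
        acc *= config.rmsprop_beta2
        acc += (1 - config.rmsprop_beta2) * grad**2
        step = lr * grad / (np.sqrt(acc / bias_corr) + config.rmsprop_epsilon)
        arrays[name] += step

    np.clip(state.params.gamma_plus, config.gamma_min, None,
            out=state.params.gamma_plus)
    np.clip(state.params.gamma_minus, config.gamma_min, None,
            out=state.params.gamma_minus)

    if config.normalize_hu:
        hu_normalization(state, data_m)

    state.update_counter = t
    if t % config.log_every == 0 or t == config.n_updates:
        state.history.append({
            "update": t,
            "lr": lr,
            "weight_std": float(np.std(state.params.weights)),
            "err_v": float(np.sqrt(np.mean((data_m["v"] - model_m["v"]) ** 2))),
            "err_h": float(np.sqrt(np.mean((data_m["h"] - model_m["h"]) ** 2))),
            "err_vh": float(np.sqrt(np.mean((data_m["vh"] - model_m["vh"]) ** 2))),
            "mean_h": float(np.mean(data_m["h"])),
            "var_h": float(np.mean(data_m["_h_frame_vars"])
                           + np.mean(np.var(data_m["_h_frame_means"], axis=0))),
        })
    return state


def _run_once(frames: np.ndarray, config: TrainingConfig,
              rng: np.random.Generator) -> TrainingState:
    state = TrainingState.initialize(frames, config, rng)
    n_frames = frames.shape[0]
    order = rng.permutation(n_frames)
    pos = 0
    while state.update_counter < config.n_updates:
        if pos + config.batch_size > n_frames:
            order = rng.permutation(n_frames)
            pos = 0
        batch = frames[order[pos:pos + config.batch_size]]
        pos += config.batch_size
        gradient_step(batch, state, config)
        if state.update_counter % 50 == 0:
            wstd = float(np.std(state.params.weights))
            if not np.isfinite(wstd) or wstd > config.divergence_weight_std:
                raise TrainingDiverged(
                    f"weight std {wstd:.3g} exceeded "
                    f"{config.divergence_weight_std} at update "
                    f"{state.update_counter}",
                    snapshot={"update": state.update_counter, "weight_std": wstd},
                )
    return state


def fit(data, config: TrainingConfig) -> tuple[CRBMParams, pd.DataFrame]:
    """Train a cRBM on binary activity.

    ``data`` is a :class:`~crbm.io.BinarySpikeMatrix` or an ``(N, T)``
    binary array.  Runs ``config.n_updates`` PCD updates over shuffled
    minibatches; on divergence the run restarts with a halved initial
    learning rate (up to ``max_restarts`` times) before failing.  The
    returned parameters have the sign-swap convention applied (all
    hidden units predominantly positive-weighted).  Deterministic given
    ``config.seed``.
    """
    if isinstance(data, BinarySpikeMatrix):
        frames = data.frames()
    else:
        frames = BinarySpikeMatrix(values=np.asarray(data)).frames()
    if frames.shape[0] < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} frames, "
            f"got {frames.shape[0]}"
        )

    config_try = config
    last_error: TrainingDiverged | None = None
    for attempt in range(config.max_restarts + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % 2**31, attempt])
        )
        try:
            state = _run_once(frames, config_try, rng)
            break
        except TrainingDiverged as err:
            last_error = err
            warnings.warn(
                f"training diverged ({err}); restarting with halved learning rate"
            )
            config_try = dataclasses.replace(
                config_try,
                lr_initial=config_try.lr_initial / 2,
                lr_final=min(config_try.lr_final, config_try.lr_initial / 2),
            )
    else:
        raise TrainingDiverged(
            f"training failed after {config.max_restarts} restarts: {last_error}",
            snapshot=getattr(last_error, "snapshot", {}),
        )

    params = model_mod.sign_swap(state.params)
    history = pd.DataFrame(state.history)
    return params, history


def convergence_check(params: CRBMParams, lower: float = 0.01,
                      upper: float = 0.1) -> tuple[bool, float]:
    """Post-hoc convergence screen on the spread of the weights.

    A trained model passes when ``lower < std(w) < upper`` over all
    weight entries: collapsed models (near-zero spread) and diverged
    models both fail.
    """
    wstd = float(np.std(params.weights))
    return (lower < wstd < upper), wstd
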