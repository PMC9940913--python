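"""Sampling synthetic activity from a fitted cRBM.

Alternating Gibbs sampling between p(h | v) and p(v | h) converges to
the joint distribution; thinned chains provide the "model statistics"
datasets against which data statistics are compared.  The fixed
reference protocol for those datasets is: 300 chains initialised on
random training frames, 100 effective burn-in configurations, then 50
configurations saved per chain with 20 Gibbs steps between saves (an
"effective configuration" is one save interval, so the default burn-in
is 100 x 20 raw steps).  All counts are configurable.
"""

from __future__ import annotations

import h5py
import numpy as np

from . import model as model_mod
from .io import BinarySpikeMatrix
from .model import CRBMParams

__all__ = ["gibbs_chain", "generate_model_statistics_dataset", "write_samples"]


def gibbs_chain(params: CRBMParams, v0, n_steps: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Run an alternating Gibbs chain and return its full trajectory.

    ``v0`` may be a single configuration ``(N,)`` or a stack of chains
    ``(C, N)``.  Each step samples h from p(h | v) then v from p(v | h);
    the returned arrays have shapes ``(n_steps, ..., N)`` and
    ``(n_steps, ..., M)``.
    """
    v0 = np.asarray(v0)
    if not np.isin(v0, (0, 1)).all():
        raise ValueError("initial configuration must be binary")
    v = v0.astype(np.uint8)
    vs = np.empty((n_steps,) + v.shape, dtype=np.uint8)
    hs = np.empty((n_steps,) + v.shape[:-1] + (params.n_hidden,))
    for t in range(n_steps):
        h = model_mod.sample_h_given_v(v, params, rng)
        v = model_mod.sample_v_given_h(h, params, rng)
        vs[t] = v
        hs[t] = h
    return vs, hs


def generate_model_statistics_dataset(
    params: CRBMParams,
    train_data,
    rng: np.random.Generator,
    n_chains: int = 300,
    n_saved: int = 50,
    steps_between: int = 20,
    burn_in_configs: int = 100,
    burn_in_raw_steps: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Thinned Gibbs samples following the fixed evaluation protocol.

    Chains start on random training frames; after the burn-in
    (``burn_in_configs * steps_between`` raw steps unless
    ``burn_in_raw_steps`` overrides the reading), ``n_saved``
    configurations per chain are kept, ``steps_between`` steps apart.
    Returns ``(v, h)`` with ``n_chains * n_saved`` rows each.
    """
    if isinstance(train_data, BinarySpikeMatrix):
        frames = train_data.values.T
    else:
        # accept a neuron-major (N, T) array like BinarySpikeMatrix stores
        frames = BinarySpikeMatrix(values=np.asarray(train_data)).values.T
    if frames.shape[0] == 0:
        raise ValueError("train_data must contain at least one frame")
    if frames.shape[1] != params.n_visible:
        raise ValueError("train_data neuron count does not match the model")

    v = frames[rng.integers(0, frames.shape[0], size=n_chains)].astype(np.uint8)
    burn = (burn_in_configs * steps_between
            if burn_in_raw_steps is None else burn_in_raw_steps)
    for _ in range(burn):
        h = model_mod.sample_h_given_v(v, params, rng)
        v = model_mod.sample_v_given_h(h, params, rng)

    vs = np.empty((n_saved, n_chains, params.n_visible), dtype=np.uint8)
    hs = np.empty((n_saved, n_chains, params.n_hidden))
    for k in range(n_saved):
        h = None
        for _ in range(steps_between):
            h = model_mod.sample_h_given_v(v, params, rng)
            v = model_mod.sample_v_given_h(h, params, rng)
        vs[k] = v
        hs[k] = h
    return (vs.reshape(-1, params.n_visible),
            hs.reshape(-1, params.n_hidden))


def write_samples(path, v: np.ndarray, h: np.ndarray) -> None:
    """Store generated (v, h) samples in HDF5 (datasets /v and /h)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("v", data=np.asarray(v, dtype=np.uint8), compression="gzip")
        f.create_dataset("h", data=np.asarray(h), compression="gzip")
        f.attrs["format_version"] = 1
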