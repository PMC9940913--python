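"""Goodness-of-fit suite for trained cRBMs.

The log-likelihood of an RBM is intractable at scale, so model quality
is assessed by comparing moment statistics between three sources —
training data, withheld test data and model-generated samples — plus a
reconstruction likelihood, a logistic-regression baseline, and
diagnostics of the latent dynamics (compositionality, bimodality, time
constants, hidden-unit ordering).

Five moment sets are tracked: ``<v_i>``, ``<h_mu>``, ``<v_i h_mu>`` and
the mean-corrected pairwise moments ``<v_i v_j> - <v_i><v_j>`` and
``<h_mu h_nu> - <h_mu><h_nu>``.  Hidden traces are always the
conditional means ``Gamma'(I(v))`` — recordings contain no hidden data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture

from . import model as model_mod
from .io import BinarySpikeMatrix
from .model import CRBMParams

__all__ = [
    "StatisticsBundle",
    "SplitPlan",
    "compute_statistics",
    "split_train_test",
    "rmse",
    "nrmse",
    "sparsity_corrected_vh",
    "bernoulli_llh",
    "normalized_llh",
    "reconstruction_llh",
    "glm_baseline",
    "participation_ratio",
    "compositional_m",
    "bimodality_points",
    "time_constants",
    "sort_hus",
    "upper_triangle",
]

LLH_CLIP = 1e-7


def _as_activity(v) -> np.ndarray:
    """Coerce to a neuron-major (N, T) binary float array."""
    if isinstance(v, BinarySpikeMatrix):
        return v.values.astype(float)
    return BinarySpikeMatrix(values=np.asarray(v)).values.astype(float)


def upper_triangle(mat: np.ndarray) -> np.ndarray:
    """Strictly-upper-triangle entries of a square matrix, flattened."""
    mat = np.asarray(mat)
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


@dataclass
class StatisticsBundle:
    """The five moment sets of one data source.

    Pairwise matrices are stored in full (symmetric); use
    :func:`upper_triangle` to vectorise them without duplicates.
    """

    mean_v: np.ndarray
    mean_h: np.ndarray | None
    vh: np.ndarray | None
    vv_centered: np.ndarray
    hh_centered: np.ndarray | None
    source: str = "data"


def compute_statistics(v, params: CRBMParams | None = None,
                       h: np.ndarray | None = None,
                       source: str = "data") -> StatisticsBundle:
    """Moment statistics of an activity matrix.

    ``v`` is neuron-major ``(N, T)``.  Hidden traces are derived from
    ``params`` as conditional means ``Gamma'(I_mu(v_t))`` unless an
    explicit ``(M, T)`` trace ``h`` is supplied.  With neither, only the
    visible statistics are filled in.
    """
    act = _as_activity(v)
    n, t = act.shape
    frames = act.T
    mean_v = act.mean(axis=1)
    vv = act @ act.T / t - np.outer(mean_v, mean_v)

    if h is None and params is not None:
        h = model_mod.mean_h_given_v(frames, params).T
    if h is None:
        return StatisticsBundle(mean_v=mean_v, mean_h=None, vh=None,
                                vv_centered=vv, hh_centered=None, source=source)
    h = np.asarray(h, dtype=float)
    if h.shape[1] != t:
        raise ValueError("hidden trace and activity disagree on frame count")
    mean_h = h.mean(axis=1)
    vh = act @ h.T / t
    hh = h @ h.T / t - np.outer(mean_h, mean_h)
    return StatisticsBundle(mean_v=mean_v, mean_h=mean_h, vh=vh,
                            vv_centered=vv, hh_centered=hh, source=source)


# ---------------------------------------------------------------------------
# train / test splitting


@dataclass
class SplitPlan:
    """A chronological train/test split and its rank among candidates.

    The recording is cut into ``n_segments`` equal chronological chunks
    (half-open frame ranges); ``test_segments`` lists the chunks held
    out.  ``rank`` is the 0-based position of this split when all
    candidates are ordered by train-vs-test statistic RMSE.
    """

    n_frames: int
    boundaries: list[tuple[int, int]]
    test_segments: tuple[int, ...]
    rank: int
    rmse: float
    candidate_rmse: np.ndarray

    def test_indices(self) -> np.ndarray:
        parts = [np.arange(*self.boundaries[s]) for s in self.test_segments]
        return np.concatenate(parts)

    def train_indices(self) -> np.ndarray:
        test = set(self.test_indices().tolist())
        return np.array([t for t in range(self.n_frames) if t not in test])


def rmse(x1, x2) -> float:
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return float(np.sqrt(np.mean((x1 - x2) ** 2)))


def _split_statistic_vector(sum_v, sum_vv, n_frames) -> np.ndarray:
    mean_v = sum_v / n_frames
    vv = sum_vv / n_frames - np.outer(mean_v, mean_v)
    return np.concatenate([mean_v, upper_triangle(vv)])


def split_train_test(data, n_segments: int = 10, n_test: int = 3,
                     percentile: float = 10.0) -> SplitPlan:
    """Choose a chronological train/test split at a target quality rank.

    All C(n_segments, n_test) assignments of test segments are scored by
    the RMSE between train and test over the concatenated mean-activity
    and mean-corrected pairwise-correlation statistics, ranked ascending
    (best split first), and the split at the requested percentile rank
    (``floor(percentile/100 * n_candidates)``, 0-based) is returned —
    a near-best split that does not overfit the selection to the single
    luckiest candidate.
    """
    act = _as_activity(data)
    n, t = act.shape
    if t < n_segments:
        raise ValueError(f"need at least {n_segments} frames, got {t}")

    edges = np.linspace(0, t, n_segments + 1).astype(int)
    boundaries = [(int(edges[s]), int(edges[s + 1])) for s in range(n_segments)]
    seg_counts = np.array([b - a for a, b in boundaries])
    seg_sum_v = np.stack([act[:, a:b].sum(axis=1) for a, b in boundaries])
    seg_sum_vv = np.stack([act[:, a:b] @ act[:, a:b].T for a, b in boundaries])

    candidates = list(combinations(range(n_segments), n_test))
    scores = np.empty(len(candidates))
    total_v = seg_sum_v.sum(axis=0)
    total_vv = seg_sum_vv.sum(axis=0)
    for k, test_segs in enumerate(candidates):
        idx = list(test_segs)
        test_v = seg_sum_v[idx].sum(axis=0)
        test_vv = seg_sum_vv[idx].sum(axis=0)
        t_test = int(seg_counts[idx].sum())
        stat_test = _split_statistic_vector(test_v, test_vv, t_test)
        stat_train = _split_statistic_vector(
            total_v - test_v, total_vv - test_vv, t - t_test
        )
        scores[k] = rmse(stat_train, stat_test)

    order = np.argsort(scores, kind="stable")
    rank = min(int(math.floor(percentile / 100.0 * len(candidates))),
               len(candidates) - 1)
    chosen = candidates[order[rank]]
    return SplitPlan(
        n_frames=t,
        boundaries=boundaries,
        test_segments=tuple(chosen),
        rank=rank,
        rmse=float(scores[order[rank]]),
        candidate_rmse=scores,
    )


# ---------------------------------------------------------------------------
# normalized RMSE


def nrmse(model_stat, test_stat, train_stat, rng: np.random.Generator | None = None,
          rmse_shuffled: float | None = None) -> float:
    """Normalized RMSE between model and test statistics.

    ``nRMSE = 1 - (RMSE(model, test) - RMSE_shuffled) /
    (RMSE(train, test) - RMSE_shuffled)``: 0 means the model matches the
    test statistics as well as the training data does (the best
    achievable reference), 1 means no better than chance.  Values below
    0 are legal (model closer to test than train is).

    The chance reference permutes the model statistics against the test
    statistics.  A joint permutation of both vectors leaves the RMSE
    unchanged, so permuting one side is fully equivalent to permuting
    both independently.  Pass ``rmse_shuffled`` to reuse a precomputed
    reference (e.g. when evaluating the shuffled statistics themselves).
    """
    model_stat = np.asarray(model_stat, dtype=float)
    test_stat = np.asarray(test_stat, dtype=float)
    train_stat = np.asarray(train_stat, dtype=float)
    if not (model_stat.shape == test_stat.shape == train_stat.shape):
        raise ValueError("statistic vectors must share a shape")
    if model_stat.size < 2:
        raise ValueError("need at least 2 entries to shuffle")

    if rmse_shuffled is None:
        if rng is None:
            rng = np.random.default_rng(0)
        perm = rng.permutation(model_stat.size)
        rmse_shuffled = rmse(model_stat.ravel()[perm], test_stat.ravel())

    rmse_ordinary = rmse(model_stat, test_stat)
    rmse_optimal = rmse(train_stat, test_stat)
    denom = rmse_optimal - rmse_shuffled
    if denom == 0:
        raise ValueError(
            "degenerate nRMSE normalization: train/test RMSE equals the "
            "shuffled RMSE"
        )
    return float(1.0 - (rmse_ordinary - rmse_shuffled) / denom)


def sparsity_corrected_vh(model_vh: np.ndarray, params: CRBMParams,
                          sparsity: float) -> np.ma.MaskedArray:
    """Correct model <v h> moments for the L1 training penalty.

    At the trained optimum the weight gradient balances the penalty, so
    the model statistic is offset by ``lambda * sign(w)``; entries whose
    weight is exactly zero (subgradient interval) are masked out of any
    downstream comparison.
    """
    model_vh = np.asarray(model_vh, dtype=float)
    if model_vh.shape != params.weights.shape:
        raise ValueError("model_vh must have the weight matrix shape")
    corrected = model_vh + sparsity * np.sign(params.weights)
    return np.ma.MaskedArray(corrected, mask=(params.weights == 0))


# ---------------------------------------------------------------------------
# reconstruction likelihood


def bernoulli_llh(v, p) -> np.ndarray:
    """Per-neuron mean Bernoulli log-likelihood of binary traces.

    ``v`` and ``p`` are (N, T); returns length-N.  The probability
    assigned to each observed symbol is floored at 1e-7 (a perfect
    prediction scores exactly 0).
    """
    v = np.asarray(v, dtype=float)
    p = np.asarray(p, dtype=float)
    obs = p * v + (1.0 - p) * (1.0 - v)
    return np.log(np.maximum(obs, LLH_CLIP)).mean(axis=-1)


def normalized_llh(v, recon) -> pd.DataFrame:
    """Normalize reconstruction likelihoods against the independent model.

    ``nLLH = (LLH - LLH_indep) / (0 - LLH_indep)`` where the independent
    model predicts each neuron's empirical mean at every frame: 0 means
    no better than the rate model, 1 means a perfect reconstruction.
    Constant neurons (LLH_indep exactly 0) get nLLH 0 and a flag.
    """
    v = np.asarray(v, dtype=float)
    recon = np.asarray(recon, dtype=float)
    llh = bernoulli_llh(v, recon)
    mean_v = v.mean(axis=-1, keepdims=True)
    llh_indep = bernoulli_llh(v, np.broadcast_to(mean_v, v.shape))
    constant = llh_indep == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        nllh = np.where(constant, 0.0, (llh - llh_indep) / (-llh_indep))
    return pd.DataFrame({
        "llh": llh,
        "llh_indep": llh_indep,
        "nllh": nllh,
        "constant_neuron": constant,
    })


def reconstruction_llh(v, params: CRBMParams) -> pd.DataFrame:
    """Round-trip reconstruction quality of a cRBM on binary activity.

    Each frame is pushed through the deterministic round trip
    ``v -> <h|v> -> <v|h>`` and the resulting Bernoulli probabilities
    are scored per neuron with :func:`normalized_llh`.  The median of
    the ``nllh`` column is the headline number.
    """
    act = _as_activity(v)
    frames = act.T
    h = model_mod.mean_h_given_v(frames, params)
    recon = model_mod.mean_v_given_h(h, params).T  # (N, T)
    return normalized_llh(act, recon)


def glm_baseline(train, test, l2_strength: float = 1000.0,
                 neurons=None, max_iter: int = 500) -> pd.DataFrame:
    """Fully connected logistic-regression reconstruction baseline.

    For each target neuron an L2-penalised logistic regression predicts
    its activity from all other neurons in the same frame; the held-out
    prediction is scored exactly like the cRBM reconstruction.  The
    penalty is quoted as a regularisation strength ``lambda`` (the
    scikit-learn ``C`` is its inverse, ``C = 1/lambda``); the reference
    value is ``lambda = 1000``.  An intercept is included so the
    baseline nests the independent (rate) model.  Constant training
    targets get nLLH 0 and a flag.
    """
    train = _as_activity(train)
    test = _as_activity(test)
    if train.shape[0] != test.shape[0]:
        raise ValueError("train and test must share the neuron set")
    n = train.shape[0]
    if neurons is None:
        neurons = range(n)

    rows = []
    for i in neurons:
        others = np.delete(np.arange(n), i)
        y_train = train[i]
        if y_train.min() == y_train.max():
            rows.append({"neuron": i, "llh": 0.0, "llh_indep": 0.0,
                         "nllh": 0.0, "constant_neuron": True})
            continue
        # L2 penalty (scikit-learn default) with C = 1/lambda
        clf = LogisticRegression(
            C=1.0 / l2_strength, solver="lbfgs",
            max_iter=max_iter, fit_intercept=True,
        )
        clf.fit(train[others].T, y_train)
        p = clf.predict_proba(test[others].T)[:, 1]
        res = normalized_llh(test[i][None, :], p[None, :]).iloc[0]
        rows.append({"neuron": i, "llh": res["llh"],
                     "llh_indep": res["llh_indep"], "nllh": res["nllh"],
                     "constant_neuron": bool(res["constant_neuron"])})
    return pd.DataFrame(rows).set_index("neuron")


# ---------------------------------------------------------------------------
# latent-dynamics diagnostics


def participation_ratio(x, normalized: bool = False) -> float:
    """PR(x) = (sum x_i^2)^2 / sum x_i^4.

    An effective count of the nonzero components of ``x``: 1 for a
    one-hot vector, n for a constant one.  ``normalized=True`` divides
    by the length, mapping the range to (0, 1].
    """
    x = np.asarray(x, dtype=float)
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("participation ratio undefined for the all-zero vector")
    x = x / peak  # scale invariance, and no under/overflow in the powers
    pr = np.sum(x**2) ** 2 / np.sum(x**4)
    return float(pr / x.size) if normalized else float(pr)


def compositional_m(h_traj: np.ndarray,
                    inactive_peaks: np.ndarray) -> tuple[np.ndarray, float]:
    """Effective number of active hidden units per frame.

    ``h_traj`` is (T, M).  Each unit's inactive peak is subtracted and
    the excursion rectified at zero (the participation ratio treats
    inactive entries as zeros), then
    ``m(t) = PR(h_+(t)) / M * M = normalized-PR x M`` so that k equally
    active units give m = k.  Frames with no active unit give m = 0.
    Returns the trace and its median.
    """
    h_traj = np.asarray(h_traj, dtype=float)
    peaks = np.asarray(inactive_peaks, dtype=float)
    if h_traj.ndim != 2 or h_traj.shape[1] != peaks.size:
        raise ValueError("h_traj must be (T, M) with one inactive peak per unit")
    m_units = h_traj.shape[1]
    h_plus = np.clip(h_traj - peaks, 0.0, None)
    s2 = (h_plus**2).sum(axis=1)
    s4 = (h_plus**4).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(s2 > 0, s2**2 / np.where(s4 > 0, s4, 1.0), 0.0)
    return m, float(np.median(m))


def bimodality_points(h_traj: np.ndarray, random_state: int = 0,
                      n_init: int = 10) -> pd.DataFrame:
    """Two-Gaussian mixture decomposition of each hidden unit's activity.

    Returns per unit the two component means (``inactive_peak`` is the
    lower one), the ``transition_point`` halfway between them, and a
    ``unimodal`` flag raised when the components merge (or the trace is
    constant), in which case the transition point is the single mean.
    """
    h_traj = np.asarray(h_traj, dtype=float)
    if h_traj.ndim != 2:
        raise ValueError("h_traj must be (T, M)")
    t = h_traj.shape[0]
    if t < 100:
        raise ValueError(f"need >= 100 frames to fit mixtures, got {t}")

    rows = []
    for mu in range(h_traj.shape[1]):
        trace = h_traj[:, mu]
        spread = trace.std()
        if spread <= 1e-12 * (1.0 + abs(trace.mean())):
            rows.append({"unit": mu, "inactive_peak": trace[0],
                         "active_peak": trace[0], "transition_point": trace[0],
                         "unimodal": True})
            continue
        gmm = GaussianMixture(n_components=2, n_init=n_init,
                              random_state=random_state)
        gmm.fit(trace[:, None])
        means = np.sort(gmm.means_.ravel())
        merged = (means[1] - means[0]) < 1e-3 * spread
        transition = means.mean() if not merged else float(trace.mean())
        rows.append({
            "unit": mu,
            "inactive_peak": float(means[0]),
            "active_peak": float(means[1]),
            "transition_point": float(transition),
            "unimodal": bool(merged),
        })
    return pd.DataFrame(rows).set_index("unit")


def _run_lengths(binary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and lengths of maximal constant runs of a 1-D array."""
    change = np.flatnonzero(np.diff(binary) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [binary.size]])
    return binary[starts], ends - starts


def time_constants(traces: np.ndarray, frame_rate: float,
                   kind: str = "hidden") -> np.ndarray:
    """Median two-state oscillation period of each trace, in seconds.

    ``traces`` is (T, K).  For ``kind='hidden'`` the traces must already
    be transition-point subtracted and an oscillation is one maximal
    negative run followed by one positive run; for ``kind='neuron'`` the
    traces are binary and an oscillation is one inter-spike interval
    followed by one spike interval.  Units without a single complete
    oscillation get NaN.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("traces must be (T, K)")
    if kind not in ("hidden", "neuron"):
        raise ValueError("kind must be 'hidden' or 'neuron'")
    out = np.full(traces.shape[1], np.nan)
    for k in range(traces.shape[1]):
        if kind == "hidden":
            state = (traces[:, k] > 0).astype(int)
        else:
            vals = traces[:, k]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("neuron traces must be binary")
            state = vals.astype(int)
        values, lengths = _run_lengths(state)
        periods = [
            (lengths[j] + lengths[j + 1]) / frame_rate
            for j in range(len(values) - 1)
            if values[j] == 0 and values[j + 1] == 1
        ]
        if periods:
            out[k] = float(np.median(periods))
    return out


def sort_hus(h_traj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order hidden units by Ward clustering of their activity correlations.

    Returns the leaf order and the linkage matrix.  Distances are
    ``1 - r`` on the Pearson correlation of the (T, M) traces; constant
    traces are assigned zero correlation with everything and flagged.
    """
    h_traj = np.asarray(h_traj, dtype=float)
    if h_traj.ndim != 2 or h_traj.shape[1] < 2:
        raise ValueError("need at least two hidden-unit traces")
    stds = h_traj.std(axis=0)
    if np.any(stds == 0):
        warnings.warn("constant hidden trace(s); correlation with them set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(h_traj.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    iu = np.triu_indices(dist.shape[0], k=1)
    link = linkage(dist[iu], method="ward")
    return leaves_list(link), link
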