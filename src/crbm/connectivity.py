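"""Functional and structural connectivity estimators.

A generative model of the whole population permits in-silico
perturbation: the effective coupling between neurons i and j in the
context of a configuration v is the change in the log-odds of neuron i
spiking when neuron j is flipped,

    J_ij(v) = [log-odds of v_i = 1 with v_j = 1] - [same with v_j = 0],

which is symmetric in (i, j) and vanishes for an independent model.
Averaged over data configurations this yields the neuron-level coupling
matrix; a second-order expansion of the hidden cumulants gives the fast
estimator ``J_ij = sum_mu w_i_mu w_j_mu <Var(h_mu | v)>`` (exact for
quadratic hidden potentials, where both coincide with the pairwise
Hopfield coupling ``sum_mu w_i w_j / gamma_mu``).

Neuron-level couplings are aggregated to anatomical regions by the
normalised L1 norm over region blocks, averaged across specimens with
sampling-aware weights, and compared against covariance/correlation
baselines and a morphology-derived structural estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import model as model_mod
from .evaluation import participation_ratio
from .io import BinarySpikeMatrix, MorphologySet, RegionAnnotation
from .model import CRBMParams

__all__ = [
    "ConnectivityMatrix",
    "local_coupling",
    "coupling_matrix_exact",
    "coupling_matrix_fast",
    "region_aggregate",
    "specimen_average",
    "baseline_matrices",
    "structural_estimator",
    "regional_occupancy",
    "compare_matrices",
]

EXACT_COUPLING_BUDGET = 2_000_000_000  # N^2 * M * T operations


@dataclass
class ConnectivityMatrix:
    """A symmetric coupling matrix at neuron or region level.

    Masked (undefined) entries are NaN.  ``provenance`` records the
    estimator: crbm_fast | crbm_exact | covariance | correlation |
    structural.
    """

    values: np.ndarray
    level: str
    labels: list[str]
    provenance: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.level not in ("neuron", "region"):
            raise ValueError("level must be 'neuron' or 'region'")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per row is required")
        finite = np.isfinite(self.values)
        if not np.array_equal(finite, finite.T):
            raise ValueError("mask must be symmetric")
        vals = np.where(finite, self.values, 0.0)
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _as_frames(data) -> np.ndarray:
    if isinstance(data, BinarySpikeMatrix):
        return data.frames()
    return BinarySpikeMatrix(values=np.asarray(data)).frames()


def local_coupling(v, i: int, j: int, params: CRBMParams) -> float:
    """Effective coupling J_ij(v) by in-silico perturbation.

    Evaluates the four conditional log-probabilities implied by the
    marginal P(v) with all entries but i, j clamped.  The visible-field
    contributions cancel, leaving a difference of hidden cumulant sums.
    """
    if i == j:
        raise ValueError("local coupling is defined for distinct neurons only")
    v = np.asarray(v, dtype=float)
    from .drelu import cumulant

    w = params.weights
    base = v @ w - v[i] * w[i] - v[j] * w[j]

    def gamma_sum(di, dj):
        I = base + di * w[i] + dj * w[j]
        return cumulant(I, params.gamma_plus, params.gamma_minus,
                        params.theta_plus, params.theta_minus).sum()

    return float(gamma_sum(1, 1) - gamma_sum(0, 1) - gamma_sum(1, 0) + gamma_sum(0, 0))


def coupling_matrix_exact(data, params: CRBMParams,
                          budget: int = EXACT_COUPLING_BUDGET) -> ConnectivityMatrix:
    """Data-averaged in-silico perturbation couplings <J_ij(v)>_data.

    Cost is O(N^2 M T); a guard refuses problems beyond ``budget``
    operations.  Diagonal is 0 (self-coupling is meaningless).
    """
    frames = _as_frames(data)
    t, n = frames.shape
    m = params.n_hidden
    if n * n * m * t > budget:
        raise ValueError(
            f"exact coupling cost N^2*M*T = {n * n * m * t:,} exceeds the "
            f"budget {budget:,}; use coupling_matrix_fast"
        )
    from .drelu import cumulant

    def gam(I):
        return cumulant(I, params.gamma_plus, params.gamma_minus,
                        params.theta_plus, params.theta_minus).sum(axis=-1)

    w = params.weights
    iu, ju = np.triu_indices(n, k=1)
    J = np.zeros((n, n))
    for frame in frames:
        base_all = frame @ w
        # inputs with neurons i and j silenced, for every pair (P, M)
        base = base_all[None, :] - frame[iu, None] * w[iu] - frame[ju, None] * w[ju]
        g00 = gam(base)
        g10 = gam(base + w[iu])
        g01 = gam(base + w[ju])
        g11 = gam(base + w[iu] + w[ju])
        J[iu, ju] += g11 - g01 - g10 + g00
    J[iu, ju] /= t
    J = J + J.T
    labels = [str(k) for k in range(n)]
    return ConnectivityMatrix(values=J, level="neuron", labels=labels,
                              provenance="crbm_exact")


def coupling_matrix_fast(data, params: CRBMParams) -> ConnectivityMatrix:
    """Second-order coupling estimator sum_mu w_i w_j <Var(h_mu | v)>.

    Exact for quadratic hidden potentials; in general a fast proxy for
    :func:`coupling_matrix_exact`.  Diagonal set to 0.
    """
    frames = _as_frames(data)
    mom = model_mod.hidden_moments(frames, params)
    var_bar = mom.var.mean(axis=0)
    J = (params.weights * var_bar) @ params.weights.T
    np.fill_diagonal(J, 0.0)
    labels = [str(k) for k in range(params.n_visible)]
    return ConnectivityMatrix(values=J, level="neuron", labels=labels,
                              provenance="crbm_fast")


def region_aggregate(J: ConnectivityMatrix, ann: RegionAnnotation,
                     min_neurons: int = 5) -> ConnectivityMatrix:
    """Aggregate neuron couplings to region level by normalised L1 norm.

    Entry (r, s) is the mean of |J_ij| over neuron pairs with i in r and
    j in s; within-region entries exclude the i = j diagonal from both
    numerator and denominator.  Regions hosting fewer than
    ``min_neurons`` neurons are dropped.
    """
    if J.level != "neuron":
        raise ValueError("region_aggregate expects a neuron-level matrix")
    if ann.n_neurons != J.n:
        raise ValueError("annotation does not cover the neuron set")
    counts = ann.counts()
    keep = np.flatnonzero(counts >= min_neurons)
    if keep.size == 0:
        raise ValueError(
            f"no region has >= {min_neurons} neurons; nothing to aggregate"
        )
    L = ann.membership[keep].astype(float)
    counts = counts[keep].astype(float)
    absJ = np.abs(J.values)
    block_sums = L @ absJ @ L.T
    denom = np.outer(counts, counts)
    np.fill_diagonal(denom, counts * (counts - 1.0))
    values = block_sums / denom
    values = 0.5 * (values + values.T)  # remove float asymmetry
    names = [ann.region_names[r] for r in keep]
    return ConnectivityMatrix(values=values, level="region", labels=names,
                              provenance=J.provenance)


def specimen_average(matrices: list[ConnectivityMatrix],
                     recording_lengths,
                     region_counts) -> ConnectivityMatrix:
    """Sampling-aware average of region matrices across specimens.

    Each specimen's entry (r, s) receives weight
    ``T_F * (N_r + N_s) / 2`` — recording length times the mean number
    of neurons sampled in the two regions.  ``region_counts`` is one
    ``{region: count}`` mapping (or array aligned with the matrix
    labels) per specimen.  Pairs missing (NaN) in a specimen are skipped
    there; pairs valid nowhere stay NaN.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    universe = sorted({r for mat in matrices for r in mat.labels})
    r_index = {r: k for k, r in enumerate(universe)}
    nr = len(universe)
    num = np.zeros((nr, nr))
    den = np.zeros((nr, nr))

    for mat, t_f, counts in zip(matrices, recording_lengths, region_counts):
        if isinstance(counts, dict):
            count_vec = np.array([counts.get(r, 0) for r in mat.labels], float)
        else:
            count_vec = np.asarray(counts, dtype=float)
            if count_vec.shape != (mat.n,):
                raise ValueError("region_counts must align with matrix labels")
        idx = np.array([r_index[r] for r in mat.labels])
        w = t_f * (count_vec[:, None] + count_vec[None, :]) / 2.0
        valid = np.isfinite(mat.values)
        vals = np.where(valid, mat.values, 0.0)
        num[np.ix_(idx, idx)] += np.where(valid, w * vals, 0.0)
        den[np.ix_(idx, idx)] += np.where(valid, w, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(den > 0, num / den, np.nan)
    return ConnectivityMatrix(values=avg, level="region", labels=universe,
                              provenance=matrices[0].provenance)


def baseline_matrices(data) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Covariance and Pearson-correlation baselines across time.

    Diagonals are zeroed (self-coupling is not a connection); neurons
    with zero variance get zero correlation rows.  Sign is kept — the
    L1 region aggregation takes absolute values downstream.
    """
    act = _as_frames(data).T  # (N, T)
    if act.shape[1] < 2:
        raise ValueError("need at least two frames")
    cov = np.cov(act)
    stds = act.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(act)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(cov, 0.0)
    np.fill_diagonal(corr, 0.0)
    labels = [str(k) for k in range(act.shape[0])]
    return (
        ConnectivityMatrix(values=cov, level="neuron", labels=labels,
                           provenance="covariance"),
        ConnectivityMatrix(values=corr, level="neuron", labels=labels,
                           provenance="correlation"),
    )


def structural_estimator(morph: MorphologySet,
                         variant: str = "direct") -> ConnectivityMatrix:
    """Region-level structural connectivity from single-neuron morphology.

    ``variant='direct'``: the directed strength from r to r' is the mean
    over neurons with soma in r of their neurite length inside r',
    normalised by the volume of r'; the matrix is then symmetrised by
    averaging the two directions.  Somata-free regions have an undefined
    outgoing direction — the defined direction is used alone, and pairs
    undefined both ways are NaN.  The diagonal (within-region) is well
    defined.  Only direct (soma-to-neurite) overlap counts: a neuron
    passing through two regions with its soma in a third contributes
    nothing to their connection.

    ``variant='legacy'``: the earlier symmetric formula
    ``sum_n (l_n(r) + l_n(r')) / (N (V_r + V_r'))``, which does credit
    such indirect pass-through neurons.
    """
    lengths = morph.neurite_length
    vols = morph.volumes
    nr = morph.n_regions
    if variant == "legacy":
        tot = lengths.sum(axis=0)  # per region
        values = (tot[:, None] + tot[None, :]) / (
            morph.n_neurons * (vols[:, None] + vols[None, :])
        )
        return ConnectivityMatrix(values=values, level="region",
                                  labels=morph.region_names,
                                  provenance="structural")
    if variant != "direct":
        raise ValueError("variant must be 'direct' or 'legacy'")

    soma_counts = np.bincount(morph.soma_region, minlength=nr).astype(float)
    directed = np.full((nr, nr), np.nan)
    for r in range(nr):
        if soma_counts[r] == 0:
            continue
        resident = morph.soma_region == r
        directed[r] = lengths[resident].sum(axis=0) / vols / soma_counts[r]
    defined = np.isfinite(directed)
    both = defined & defined.T
    either = defined | defined.T
    d0 = np.where(defined, directed, 0.0)
    values = np.full((nr, nr), np.nan)
    values[both] = (0.5 * (d0 + d0.T))[both]
    only = either & ~both
    values[only] = (d0 + d0.T)[only]
    return ConnectivityMatrix(values=values, level="region",
                              labels=morph.region_names,
                              provenance="structural")


def regional_occupancy(params: CRBMParams, ann: RegionAnnotation,
                       weight_threshold: float = 0.15):
    """Anatomical footprint of every assembly.

    For each hidden unit the weighted region vector is ``L |w_mu|``
    (absolute weights: membership strength regardless of sign).  The
    effective number of occupied regions is the normalised participation
    ratio of that vector times the region count; additionally the number
    of regions containing at least one strongly weighted neuron
    (|w| >= ``weight_threshold``) is reported.  Returns the
    (n_regions, M) occupancy matrix and a per-unit summary table.
    """
    import pandas as pd

    if ann.n_neurons != params.n_visible:
        raise ValueError("annotation does not cover the model's neurons")
    L = ann.membership.astype(float)
    occupancy = L @ np.abs(params.weights)  # (R, M)
    nr = ann.n_regions
    rows = []
    member = np.abs(params.weights) > weight_threshold
    for mu in range(params.n_hidden):
        vec = occupancy[:, mu]
        if not np.any(vec > 0):
            rows.append({"unit": mu, "effective_regions": np.nan,
                         "regions_overlapped": 0, "disconnected": True})
            continue
        eff = participation_ratio(vec, normalized=True) * nr
        overlapped = int(np.count_nonzero(L @ member[:, mu]))
        rows.append({"unit": mu, "effective_regions": eff,
                     "regions_overlapped": overlapped, "disconnected": False})
    return occupancy, pd.DataFrame(rows).set_index("unit")


def compare_matrices(a: ConnectivityMatrix, b: ConnectivityMatrix,
                     method: str = "pearson", log10_a: bool = False,
                     log10_b: bool = False,
                     exclude_zeros_in_b: bool = False) -> tuple[float, float]:
    """Correlate two connectivity matrices over shared region pairs.

    Only the strictly-upper triangle is used (the matrices are
    symmetric); entries masked in either matrix are dropped, as are
    pairs whose value in ``b`` is exactly zero when
    ``exclude_zeros_in_b`` is set (the convention when ``b`` is a
    structural matrix with absent connections).  Optional log10
    transforms apply to functional matrices under Pearson comparison.
    Returns (correlation, p-value).
    """
    shared = sorted(set(a.labels) & set(b.labels))
    if len(shared) < 2:
        raise ValueError("matrices share fewer than two regions")
    ia = [a.labels.index(r) for r in shared]
    ib = [b.labels.index(r) for r in shared]
    va = a.values[np.ix_(ia, ia)]
    vb = b.values[np.ix_(ib, ib)]
    xa = va[np.triu_indices(len(shared), k=1)]
    xb = vb[np.triu_indices(len(shared), k=1)]
    valid = np.isfinite(xa) & np.isfinite(xb)
    if exclude_zeros_in_b:
        valid &= xb != 0
    xa, xb = xa[valid], xb[valid]
    if log10_a:
        xa = np.log10(xa)
    if log10_b:
        xb = np.log10(xb)
    if xa.size < 3:
        raise ValueError("fewer than 3 valid region pairs to correlate")
    if method == "pearson":
        r, p = stats.pearsonr(xa, xb)
    elif method == "spearman":
        r, p = stats.spearmanr(xa, xb)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)
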