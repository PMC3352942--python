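"""Synchronization likelihood (SL) between channel pairs.

SL measures generalized synchronization: a signal's instantaneous state is
represented by a time-delay embedding vector, recurrences of that state are
found within the signal, and SL between two signals is the proportion of
those recurrences that coincide with recurrences of the second signal at the
same pair of time points. It is a number in [0, 1]: p_ref for independent
signals (by construction of the recurrence threshold) and 1 for identical
ones.

Definitions used throughout (shared with the brute-force test oracle):

* signals are z-scored per channel before embedding, so gain differences do
  not drive the critical distance;
* for reference time i the candidate set is {j : w1 < |i - j| < w2} (strict
  inequalities, two-sided, truncated at the epoch edges);
* the critical distance eps_i is the k-th smallest candidate distance with
  k = ceil(p_ref * n_candidates) (at least 1); recurrences are all candidates
  with distance <= eps_i, so ties can push the achieved fraction above p_ref;
* SL(x->y) at time i is |R_x(i) ∩ R_y(i)| / |R_x(i)| and the per-direction SL
  is its average over i; the reported pairwise value is the mean of both
  directions, which is symmetric by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import BandDefinition
from .recording import ConfigurationError, LengthError, Recording, WindowError


@dataclass(frozen=True)
class SLParams:
    """Embedding and recurrence settings for the SL computation.

    m : embedding dimension (samples per state vector)
    l : embedding lag in samples
    p_ref : target proportion of candidate comparisons declared recurrent
    w1 : inner Theiler window (samples) excluding autocorrelated neighbours
    w2 : outer window (samples) bounding how far recurrences are sought
    global_eps : use one critical distance per signal (pooled over all
        reference times) instead of the default per-reference adaptive one;
        sensitivity-analysis variant
    """

    m: int
    l: int
    p_ref: float = 0.02
    w1: int = 0
    w2: int = 10**9
    global_eps: bool = False

    def __post_init__(self) -> None:
        if self.m < 1 or self.l < 1:
            raise ConfigurationError("embedding needs m >= 1 and l >= 1")
        if not 0 < self.p_ref < 1:
            raise ConfigurationError("p_ref must lie in (0, 1)")
        if not 0 <= self.w1 < self.w2:
            raise ConfigurationError("need 0 <= w1 < w2")


@dataclass
class ConnectivityMatrix:
    """Symmetric pairwise SL values for one epoch or recording."""

    values: np.ndarray
    labels: list[str]
    params: SLParams

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ConfigurationError("connectivity matrix / label size mismatch")
        if not np.allclose(v, v.T):
            raise ConfigurationError("connectivity matrix must be symmetric")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1 + 1e-12):
            raise ConfigurationError("SL values must lie in [0, 1]")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def mean_sl(self) -> float:
        """Average SL over all distinct channel pairs."""
        iu = np.triu_indices(self.n_channels, k=1)
        return float(self.values[iu].mean())


def montez_params(fs: float, band: BandDefinition, epoch_len: int,
                  p_ref: float = 0.02) -> SLParams:
    """Frequency-adapted SL settings following the published recommendation
    for band-limited signals.

    lag        l  = round(fs / (3 * f_high)), at least 1
               (about three state-vector samples per cycle of the fastest
               in-band component);
    dimension  m  = ceil(3 * f_high / f_low)
               (the vector spans ~one cycle of the slowest component);
    inner win  w1 = 2 * l * (m - 1)  (twice the vector span, excluding
               autocorrelation-driven recurrences);
    outer win  w2 = w1 + floor(10 / p_ref)  (sized so p_ref yields on the
               order of ten recurrences per side).
    """
    band.validate_against(fs)
    l = max(1, round(fs / (3.0 * band.high)))
    m = max(2, math.ceil(3.0 * band.high / band.low))
    w1 = 2 * l * (m - 1)
    w2 = w1 + int(10 / p_ref)
    n_vec = epoch_len - (m - 1) * l
    if n_vec < w1 + 2:
        need = w1 + 2 + (m - 1) * l
        raise LengthError(
            f"epoch of {epoch_len} samples too short for embedding "
            f"(m={m}, l={l}, w1={w1}); need at least {need} samples"
        )
    return SLParams(m=m, l=l, p_ref=p_ref, w1=w1, w2=w2)


def embed(x: np.ndarray, m: int, l: int) -> np.ndarray:
    """Time-delay embedding: row t holds samples t, t+l, ..., t+(m-1)l.

    Returns an array of shape (len(x) - (m-1)*l, m).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError("embed expects a 1-D series")
    span = (m - 1) * l
    n = x.size - span
    if n < 1:
        raise LengthError(f"series of {x.size} samples too short for m={m}, l={l}")
    idx = np.arange(n)[:, None] + l * np.arange(m)[None, :]
    return x[idx]


def _candidate_slices(i: int, n: int, w1: int, w2: int) -> tuple[slice, slice]:
    left = slice(max(0, i - w2 + 1), max(0, i - w1))
    right = slice(min(n, i + w1 + 1), min(n, i + w2))
    return left, right


def critical_distance(vectors: np.ndarray, i: int, p_ref: float,
                      w1: int, w2: int) -> tuple[float, float]:
    """Critical distance eps for reference index ``i``.

    Returns ``(eps, achieved_fraction)`` where eps is the k-th smallest
    candidate distance, k = ceil(p_ref * n_candidates), and the achieved
    fraction is the proportion of candidates at distance <= eps (>= p_ref up
    to ties; equal to the closest realizable value above it otherwise).
    """
    vectors = np.asarray(vectors, dtype=float)
    n = vectors.shape[0]
    left, right = _candidate_slices(i, n, w1, w2)
    cand = np.concatenate([vectors[left], vectors[right]])
    if cand.size == 0:
        raise WindowError(f"no candidates for i={i} with w1={w1}, w2={w2}, n={n}")
    d = np.linalg.norm(cand - vectors[i], axis=1)
    k = max(1, math.ceil(p_ref * d.size))
    eps = float(np.partition(d, k - 1)[k - 1])
    achieved = float((d <= eps).sum() / d.size)
    return eps, achieved


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def _recurrence_matrix(x: np.ndarray, params: SLParams) -> np.ndarray:
    """Boolean matrix R with R[i, j] true when j is a recurrence of state i.

    The signal is z-scored, embedded, and thresholded per reference index at
    the adaptive critical distance.
    """
    v = embed(_zscore(x), params.m, params.l)
    n = v.shape[0]
    w1, w2, p = params.w1, params.w2, params.p_ref
    # Only candidate distances inside the Theiler band are ever needed, so
    # squared distances are computed diagonal-wise (one diagonal per offset)
    # instead of as a full n x n matrix. Thresholding on squared distances is
    # equivalent to thresholding on distances.
    offs = np.arange(w1 + 1, min(w2, n))
    if offs.size == 0:
        raise WindowError(f"no candidates possible with w1={w1}, w2={w2}, n={n}")
    n_off = offs.size
    band = np.full((n_off, n), np.inf)  # band[k, i] = d2(i, i + offs[k])
    for k, d in enumerate(offs):
        diff = v[: n - d] - v[d:]
        band[k, : n - d] = np.einsum("ij,ij->i", diff, diff)
    right = band.T  # row i: distances to j = i + d
    left = np.full((n, n_off), np.inf)  # row i: distances to j = i - d
    for k, d in enumerate(offs):
        left[d:, k] = band[k, : n - d]
    sub = np.concatenate([left, right], axis=1)
    nc = np.isfinite(sub).sum(axis=1)
    if (nc == 0).any():
        i = int(np.flatnonzero(nc == 0)[0])
        raise WindowError(f"no candidates for i={i} with w1={w1}, w2={w2}, n={n}")
    if params.global_eps:
        pooled = sub[np.isfinite(sub)]
        k = max(1, math.ceil(p * pooled.size))
        eps2 = np.full(n, np.partition(pooled, k - 1)[k - 1])
    else:
        k_arr = np.maximum(1, np.ceil(p * nc).astype(int))
        kmax = int(k_arr.max())
        head = np.partition(sub, kmax - 1, axis=1)[:, :kmax]
        head.sort(axis=1)
        eps2 = head[np.arange(n), k_arr - 1]
    mask = sub <= eps2[:, None]
    R = np.zeros((n, n), dtype=bool)
    rows = np.broadcast_to(np.arange(n)[:, None], (n, n_off))
    sel = mask[:, :n_off]
    R[rows[sel], (rows - offs[None, :])[sel]] = True
    sel = mask[:, n_off:]
    R[rows[sel], (rows + offs[None, :])[sel]] = True
    return R


def _sl_from_recurrences(Rx: np.ndarray, Ry: np.ndarray,
                         nx: np.ndarray | None = None,
                         ny: np.ndarray | None = None) -> float:
    hits = (Rx & Ry).sum(axis=1).astype(float)
    nx = Rx.sum(axis=1).astype(float) if nx is None else nx
    ny = Ry.sum(axis=1).astype(float) if ny is None else ny
    # references without recurrences (possible only with a global epsilon)
    # carry no information and drop out of the average
    mx, my = nx > 0, ny > 0
    sl_xy = float(np.mean(hits[mx] / nx[mx]))
    sl_yx = float(np.mean(hits[my] / ny[my]))
    return 0.5 * (sl_xy + sl_yx)


def sl_pair(x: np.ndarray, y: np.ndarray, params: SLParams) -> float:
    """Symmetrized synchronization likelihood between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError(f"length mismatch: {x.shape} vs {y.shape}")
    return _sl_from_recurrences(
        _recurrence_matrix(x, params), _recurrence_matrix(y, params)
    )


def sl_matrix(rec: Recording, params: SLParams) -> ConnectivityMatrix:
    """All-pairs SL for one epoch; recurrence structures are computed once per
    channel and reused across the channel pairs."""
    if rec.n_channels < 2:
        raise ConfigurationError("need at least 2 channels")
    try:
        R = [_recurrence_matrix(ch, params) for ch in rec.data]
    except (LengthError, WindowError) as exc:
        raise type(exc)(f"recording {rec.meta.get('id', '')}: {exc}") from exc
    n = rec.n_channels
    sums = [r.sum(axis=1).astype(float) for r in R]
    # recurrence rows packed to bits: pair hits become popcounts of ANDed
    # words, identical to (Rx & Ry).sum(axis=1) on the boolean matrices
    packed = [np.packbits(r, axis=1) for r in R]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                hits = np.bitwise_count(packed[i] & packed[j]).sum(axis=1)
                mi, mj = sums[i] > 0, sums[j] > 0
                out[i, j] = out[j, i] = 0.5 * (
                    np.mean(hits[mi] / sums[i][mi])
                    + np.mean(hits[mj] / sums[j][mj]))
            except FloatingPointError as exc:  # pragma: no cover
                raise ConfigurationError(
                    f"SL failed for pair ({rec.labels[i]}, {rec.labels[j]}): {exc}"
                ) from exc
    return ConnectivityMatrix(values=out, labels=list(rec.labels), params=params)


def sl_recording(rec: Recording, params: SLParams,
                 epoch_samples: int | None = None) -> ConnectivityMatrix:
    """SL matrix for a recording, averaging epoch-level matrices when the
    recording is longer than one epoch."""
    if epoch_samples is None or rec.n_samples <= epoch_samples:
        return sl_matrix(rec, params)
    mats = [sl_matrix(ep, params) for ep in rec.epochs(epoch_samples)]
    values = np.mean([m.values for m in mats], axis=0)
    return ConnectivityMatrix(values=values, labels=list(rec.labels), params=params)
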