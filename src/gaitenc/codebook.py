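"""Bag-of-codewords encoding: k-means codebooks + locality-constrained
linear coding (LLC).

A per-sensor codebook is learned by Lloyd's k-means over 3w-dimensional
sub-sequences, minimizing the within-cluster sum of squared Euclidean
distances

    J = sum_m sum_k r_mk ||x_m - c_k||^2 ,

run from ``n_restarts`` independent initializations with the best (lowest
J) run kept.

Each sub-sequence x is then encoded against the codebook by LLC: pick the
``knn`` nearest codewords, and on that support solve the locality-weighted
ridge reconstruction

    min_v ||x - C v||^2 + lambda ||d (.) v||^2   s.t.  sum(v) = 1 ,

where d_i = exp(dist(x, c_i) / sigma) penalizes distant codewords and (.)
is the element-wise product.  Off-support coefficients are exactly zero,
and the equality constraint makes the code a unit-sum local barycentric
weighting.  The constrained quadratic program is solved exactly through
its KKT linear system (size knn + 1).

Sub-sequence codes are pooled (average by default) into one descriptor
per recording and sensor; per-sensor descriptors concatenate to the final
sequence representation of length n_sensors * k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .recordings import Recording
from .windowing import SubSequence, segment_subsequences, subsequence_matrix

logger = logging.getLogger(__name__)

DEFAULT_K = 32
DEFAULT_RESTARTS = 10
DEFAULT_KNN = 5
DEFAULT_LAMBDA = 0.01


def kmeans_objective(X: np.ndarray, centers: np.ndarray,
                     assign: np.ndarray) -> float:
    """Within-cluster sum of squared distances J."""
    return float(np.sum((X - centers[assign]) ** 2))


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 100, tol: float = 1e-9):
    """One Lloyd run from a random-subset initialization.

    Returns (centers, assignment, objective_history); the history is the
    J value after each assignment step and is non-increasing.  Clusters
    that empty out are re-seeded to the point farthest from its center.
    """
    m = X.shape[0]
    centers = X[rng.choice(m, size=k, replace=False)].copy()
    history: list[float] = []
    assign = np.zeros(m, dtype=int)
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        assign = np.argmin(d2, axis=1)
        history.append(float(d2[np.arange(m), assign].sum()))
        new_centers = centers.copy()
        for j in range(k):
            mask = assign == j
            if mask.any():
                new_centers[j] = X[mask].mean(axis=0)
            else:
                # re-seed an empty cluster to the globally farthest point
                far = int(np.argmax(d2[np.arange(m), assign]))
                new_centers[j] = X[far]
                logger.debug("re-seeded empty cluster %d", j)
        if np.allclose(new_centers, centers, atol=tol, rtol=0.0):
            centers = new_centers
            break
        centers = new_centers
    # final assignment/objective for the converged centers
    d2 = cdist(X, centers, "sqeuclidean")
    assign = np.argmin(d2, axis=1)
    history.append(float(d2[np.arange(m), assign].sum()))
    return centers, assign, history


@dataclass
class Codebook:
    """k codewords over 3w-dimensional sub-sequences of one sensor."""

    centers: np.ndarray                 # (k, d)
    sensor_name: str
    w: int
    l: int
    seed: int
    n_restarts: int
    training_objective: float
    restart_objectives: list[float] = field(default_factory=list)
    objective_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def d(self) -> int:
        return self.centers.shape[1]

    def save(self, path: str | Path) -> None:
        """Persist as delimited text: a '#' header with params, then k rows."""
        path = Path(path)
        header = (
            f"sensor={self.sensor_name} w={self.w} l={self.l} k={self.k} "
            f"seed={self.seed} n_restarts={self.n_restarts} "
            f"objective={self.training_objective!r}"
        )
        np.savetxt(path, self.centers, header=header, fmt="%.17g")

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().lstrip("# ").strip()
        kv = dict(item.split("=", 1) for item in header.split())
        centers = np.loadtxt(path)
        return cls(
            centers=np.atleast_2d(centers),
            sensor_name=kv["sensor"],
            w=int(kv["w"]), l=int(kv["l"]),
            seed=int(kv["seed"]), n_restarts=int(kv["n_restarts"]),
            training_objective=float(kv["objective"]),
        )


def build_codebook(
    subseqs: list[SubSequence] | np.ndarray,
    k: int = DEFAULT_K,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    *,
    sensor_name: str | None = None,
    w: int = 64,
    l: int = 8,
    max_iter: int = 100,
) -> Codebook:
    """Learn a codebook by best-of-``n_restarts`` Lloyd k-means.

    Deterministic given ``seed``; each restart draws its initialization
    from an independently spawned stream.
    """
    if isinstance(subseqs, np.ndarray):
        X = np.asarray(subseqs, dtype=float)
    else:
        if subseqs and sensor_name is None:
            sensor_name = subseqs[0].sensor_name
        X = subsequence_matrix(subseqs)
    if X.shape[0] < k:
        raise ValueError(
            f"{X.shape[0]} sub-sequences < k={k}: lower k or add data"
        )
    streams = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    restart_objs: list[float] = []
    for ss in streams:
        rng = np.random.Generator(np.random.PCG64(ss))
        centers, assign, history = _lloyd(X, k, rng, max_iter=max_iter)
        obj = history[-1]
        restart_objs.append(obj)
        if best is None or obj < best[2][-1]:
            best = (centers, assign, history)
    centers, _, history = best
    return Codebook(
        centers=centers,
        sensor_name=sensor_name or "",
        w=w, l=l, seed=seed, n_restarts=n_restarts,
        training_objective=history[-1],
        restart_objectives=restart_objs,
        objective_history=history,
    )


@dataclass
class LLCCode:
    """Sparse LLC coefficients: at most knn nonzeros, summing to one."""

    coefficients: np.ndarray            # dense length-k vector
    support: np.ndarray                 # indices of the knn codewords used


def llc_encode(
    x: np.ndarray,
    cb: Codebook | np.ndarray,
    knn: int = DEFAULT_KNN,
    lam: float = DEFAULT_LAMBDA,
    sigma: float | None = None,
) -> LLCCode:
    """Encode one vector against a codebook by locality-constrained coding.

    ``sigma`` controls how fast the locality penalty grows with distance;
    by default it self-scales to the mean distance from x to its knn
    selected codewords.  Distance ties at the knn boundary break
    deterministically by ascending codeword index.
    """
    centers = cb.centers if isinstance(cb, Codebook) else np.asarray(cb, float)
    k = centers.shape[0]
    if knn > k:
        raise ValueError(f"knn={knn} exceeds codebook size k={k}")
    x = np.asarray(x, dtype=float)
    dist = np.sqrt(np.sum((centers - x) ** 2, axis=1))
    order = np.argsort(dist, kind="stable")     # stable => index tie-break
    support = np.sort(order[:knn])
    if knn < k and dist[order[knn - 1]] == dist[order[knn]]:
        logger.debug("knn boundary tie broken by ascending center index")

    B = centers[support]                         # (knn, d)
    d_sel = dist[support]
    if sigma is None:
        sigma = float(d_sel.mean()) or 1.0
    # exponent capped so the squared adaptor stays finite at tiny sigma;
    # relative locality ordering below the cap is untouched
    d_loc = np.exp(np.minimum(d_sel / sigma, 350.0))

    # KKT system of: min ||x - B^T u||^2 + lam ||d_loc (.) u||^2, s.t. 1'u=1
    G = 2.0 * (B @ B.T + lam * np.diag(d_loc**2))
    A = np.zeros((knn + 1, knn + 1))
    A[:knn, :knn] = G
    A[:knn, knn] = 1.0
    A[knn, :knn] = 1.0
    rhs = np.concatenate([2.0 * B @ x, [1.0]])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        jitter = lam * np.trace(G) / knn
        logger.warning("singular LLC system (duplicate centers); "
                       "adding diagonal jitter %.3g", jitter)
        A[:knn, :knn] += jitter * np.eye(knn)
        sol = np.linalg.solve(A, rhs)
    u = sol[:knn]
    coeff = np.zeros(k)
    coeff[support] = u
    return LLCCode(coefficients=coeff, support=support)


def encode_subsequences(
    X: np.ndarray,
    cb: Codebook,
    knn: int = DEFAULT_KNN,
    lam: float = DEFAULT_LAMBDA,
    sigma: float | None = None,
) -> np.ndarray:
    """LLC-encode each row of X; returns an (m, k) coefficient matrix."""
    return np.stack(
        [llc_encode(X[i], cb, knn=knn, lam=lam, sigma=sigma).coefficients
         for i in range(X.shape[0])]
    )


@dataclass
class SequenceDescriptor:
    """Pooled per-recording representation: length n_sensors * k."""

    values: np.ndarray
    pooling: str
    label: str
    subject_id: str
    recording_id: str


POOLINGS = ("average", "sum", "max")


def encode_sequence(
    rec: Recording,
    codebooks: list[Codebook],
    pooling: str = "average",
    knn: int = DEFAULT_KNN,
    lam: float = DEFAULT_LAMBDA,
    sigma: float | None = None,
) -> SequenceDescriptor:
    """Encode one recording against per-sensor codebooks.

    Per codebook: segment the sensor into 3w sub-sequences (w, l taken
    from the codebook's own training parameters), LLC-encode each, and
    pool the coefficient vectors element-wise.  Per-sensor pools are
    concatenated in codebook order.
    """
    if pooling not in POOLINGS:
        raise ValueError(f"pooling must be one of {POOLINGS}")
    parts = []
    for cb in codebooks:
        if rec.n_samples < cb.w:
            raise ValueError(
                f"recording {rec.recording_id!r} has {rec.n_samples} samples; "
                f"codebook {cb.sensor_name!r} needs at least {cb.w}"
            )
        subseqs = segment_subsequences(rec, cb.sensor_name, w=cb.w, l=cb.l)
        codes = encode_subsequences(
            subsequence_matrix(subseqs), cb, knn=knn, lam=lam, sigma=sigma
        )
        if pooling == "average":
            pooled = codes.mean(axis=0)
        elif pooling == "sum":
            pooled = codes.sum(axis=0)
        else:
            pooled = codes.max(axis=0)
        parts.append(pooled)
    return SequenceDescriptor(
        values=np.concatenate(parts),
        pooling=pooling,
        label=rec.label,
        subject_id=rec.subject_id,
        recording_id=rec.recording_id,
    )
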