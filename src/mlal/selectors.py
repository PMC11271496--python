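"""Structure selectors for active learning: energy, similarity, and distance (LOF).

The selectors decide whether a candidate configuration (always the last
frame of an MLP-MD episode) is added to the training set:

* *energy* — add when the reference/MLP energy disagreement exceeds E_T;
  discard (too distorted to be informative) when it exceeds 10·E_T. The
  only selector that needs a ground-truth call per evaluation.
* *similarity* — add when the maximum kernel similarity max(**K**) to the
  training set falls below k_T.
* *distance* — add when the candidate's local outlier factor (LOF) in
  descriptor space exceeds the 80th percentile of the training set's own
  LOF values; the threshold moves as exploration proceeds.

LOF building blocks (k-distance, reachability distance, local reachability
density) follow the standard k-nearest-neighbour definitions; a value ≈ 1
means the point sits in a region as dense as its neighbours', > 1 flags an
outlier, < 1 an inlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .descriptors import DescriptorVector, similarity_vector


@dataclass
class SelectorDecision:
    """Verdict for one candidate plus the quantity and threshold that drove it."""

    verdict: str                 # add | skip | discard
    score: float                 # energy error (eV), max(K), or LOF
    threshold_used: float
    selector: str = ""

    def __post_init__(self):
        if self.verdict not in ("add", "skip", "discard"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict == "discard" and self.selector not in ("", "energy"):
            raise ValueError("only the energy selector can discard structures")

    def as_record(self) -> dict:
        return {
            "selector": self.selector,
            "verdict": self.verdict,
            "score": float(self.score),
            "threshold": float(self.threshold_used),
        }


@dataclass
class EnergySelectorConfig:
    """E_T is the add threshold (eV); errors above discard_multiplier·E_T are discarded."""

    E_T: float = 0.02
    discard_multiplier: float = 10.0

    def __post_init__(self):
        if self.E_T <= 0:
            raise ValueError("E_T must be positive")


@dataclass
class SimilaritySelectorConfig:
    """k_T in (0, 1]: add when max kernel similarity to the training set < k_T.

    k_T = 1 is degenerate (any non-identical structure is added and no new
    information is gained); very low values admit unphysical structures.
    """

    k_T: float = 0.9995
    zeta: int = 4

    def __post_init__(self):
        if not 0.0 < self.k_T <= 1.0:
            raise ValueError("k_T must lie in (0, 1]")
        if self.zeta < 1:
            raise ValueError("zeta must be a positive integer")


@dataclass
class DistanceSelectorConfig:
    """LOF neighbour count, threshold percentile, and the minimum usable set size."""

    k: int = 10
    percentile: float = 80.0
    min_initial_size: int = field(default=None)  # defaults to k + 1

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")
        if self.min_initial_size is None:
            self.min_initial_size = self.k + 1
        if self.min_initial_size < self.k + 1:
            raise ValueError("min_initial_size must be at least k + 1")


@dataclass
class LofReport:
    """The intermediate quantities behind one LOF evaluation."""

    lof: float
    lrd: float
    neighbour_indices: np.ndarray
    neighbour_k_distances: np.ndarray
    reachability_distances: np.ndarray
    neighbour_lrds: np.ndarray
    threshold: float | None = None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def energy_select(
    E_ref: float, E_mlp: float, cfg: EnergySelectorConfig
) -> SelectorDecision:
    """Three-interval rule on |E_ref − E_mlp|: skip / add / discard."""
    if E_ref is None:
        raise ValueError("energy selector requires a reference (ground-truth) energy")
    if E_mlp is None:
        raise ValueError("energy selector requires an MLP energy")
    err = abs(E_ref - E_mlp)
    if err > cfg.discard_multiplier * cfg.E_T:
        verdict = "discard"
    elif err > cfg.E_T:
        verdict = "add"
    else:
        verdict = "skip"
    return SelectorDecision(verdict=verdict, score=err, threshold_used=cfg.E_T,
                            selector="energy")


def similarity_select(
    p_new: DescriptorVector,
    training: Sequence[DescriptorVector],
    cfg: SimilaritySelectorConfig,
) -> SelectorDecision:
    """Add iff max(K) < k_T, with K the kernel similarity vector."""
    K = similarity_vector(p_new, training, cfg.zeta)
    score = float(K.max())
    verdict = "add" if score < cfg.k_T else "skip"
    return SelectorDecision(verdict=verdict, score=score, threshold_used=cfg.k_T,
                            selector="similarity")


def _as_matrix(dataset: Sequence) -> np.ndarray:
    rows = [d.values if isinstance(d, DescriptorVector) else np.asarray(d, float).ravel()
            for d in dataset]
    return np.stack(rows)


def _dedupe(X: np.ndarray) -> np.ndarray:
    """Collapse exact duplicates (they would give zero reachability densities)."""
    _, keep = np.unique(X, axis=0, return_index=True)
    return X[np.sort(keep)]


def _knn(dist_row: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest points; ties broken by dataset index order."""
    order = np.argsort(dist_row, kind="stable")
    return order[:k]


def _dataset_lof_machinery(X: np.ndarray, k: int):
    """k-distances, neighbour lists and lrd for every dataset point (leave-self-out)."""
    n = len(X)
    if n < k + 1:
        raise ValueError(
            f"LOF with k={k} needs at least k + 1 = {k + 1} points, got {n} "
            "(min_initial_size)"
        )
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)  # leave-self-out
    neigh = np.argsort(d, axis=1, kind="stable")[:, :k]
    rows = np.arange(n)[:, None]
    k_dist = d[rows, neigh][:, -1]  # distance to the k-th neighbour
    # rd_k(o, a) = max(k-distance(a), d(o, a)) over o's neighbours a
    rd = np.maximum(k_dist[neigh], d[rows, neigh])
    mean_rd = rd.mean(axis=1)
    if np.any(mean_rd <= 0):
        raise ValueError(
            "zero reachability distance: the dataset contains duplicate points — "
            "deduplicate before computing LOF"
        )
    lrd = 1.0 / mean_rd
    return d, neigh, k_dist, lrd


def lof_profile(o, dataset: Sequence, k: int) -> LofReport:
    """LOF of a point against a dataset (the point itself is not inserted).

    k-distance(a) is the distance from dataset point a to its k-th nearest
    dataset neighbour; rd_k(o, a) = max(k-distance(a), d(o, a));
    lrd_k(o) is the inverse mean reachability distance over o's k nearest
    dataset points; LOF_k(o) is the mean ratio of the neighbours' lrd to
    lrd_k(o).
    """
    X = _dedupe(_as_matrix(dataset))
    o_vec = o.values if isinstance(o, DescriptorVector) else np.asarray(o, float).ravel()
    _, _, k_dist, lrd_data = _dataset_lof_machinery(X, k)

    d_o = np.linalg.norm(X - o_vec[None, :], axis=1)
    neigh_o = _knn(d_o, k)
    rd_o = np.maximum(k_dist[neigh_o], d_o[neigh_o])
    mean_rd = rd_o.mean()
    if mean_rd <= 0:
        raise ValueError(
            "zero reachability distance for the candidate — it duplicates a dense "
            "cluster of dataset points; deduplicate the dataset"
        )
    lrd_o = 1.0 / mean_rd
    lof = float(np.mean(lrd_data[neigh_o] / lrd_o))
    return LofReport(
        lof=lof,
        lrd=float(lrd_o),
        neighbour_indices=neigh_o,
        neighbour_k_distances=k_dist[neigh_o],
        reachability_distances=rd_o,
        neighbour_lrds=lrd_data[neigh_o],
    )


def dataset_lofs(dataset: Sequence, k: int) -> np.ndarray:
    """Leave-self-out LOF of every dataset member against the rest."""
    X = _dedupe(_as_matrix(dataset))
    d, neigh, k_dist, lrd = _dataset_lof_machinery(X, k)
    return (lrd[neigh] / lrd[:, None]).mean(axis=1)


def lof_threshold(training: Sequence, k: int, percentile: float = 80.0) -> float:
    """LOF value larger than ``percentile`` % of the training set's own LOFs.

    Lower nearest-rank convention: with n values sorted ascending the
    threshold is the ⌈n·p/100⌉-th smallest. Recompute whenever the training
    set changes — the threshold moves with the exploration of the surface.
    """
    lofs = np.sort(dataset_lofs(training, k))
    n = len(lofs)
    rank = int(np.ceil(n * percentile / 100.0))
    rank = min(max(rank, 1), n)
    return float(lofs[rank - 1])


def distance_select(
    p_new,
    training: Sequence,
    cfg: DistanceSelectorConfig,
) -> SelectorDecision:
    """Add iff LOF(p_new) exceeds the percentile threshold of the training set."""
    if len(training) < cfg.min_initial_size:
        raise ValueError(
            f"distance selector requires an initial training set of at least "
            f"{cfg.min_initial_size} structures (got {len(training)}): the LOF "
            "criterion relies on neighbour information"
        )
    threshold = lof_threshold(training, cfg.k, cfg.percentile)
    report = lof_profile(p_new, training, cfg.k)
    verdict = "add" if report.lof > threshold else "skip"
    return SelectorDecision(verdict=verdict, score=report.lof, threshold_used=threshold,
                            selector="distance")
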