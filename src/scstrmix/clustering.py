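"""Clustering single-cell profiles and estimating the number of contributors.

Cells are encoded as numeric attribute vectors (allele repeat numbers, one
slot per allele) with a missingness mask.  Two clustering algorithms are
provided, both missing-data aware:

* **EM** fits a k-component Gaussian mixture with diagonal covariances where
  each cell's component density is the marginal over its *observed* slots
  only; dropped slots contribute nothing to the likelihood.  The M-step
  re-estimates each slot's mean and variance from the cells observing that
  slot, weighted by responsibility, so the observed-data log-likelihood is
  non-decreasing.
* **K-Means** runs Lloyd iterations with k-means++-style seeding, where the
  squared distance between a cell and a (complete) centroid is the Euclidean
  distance over the cell's observed slots rescaled by
  (total slots / observed slots) — the convention WEKA uses for missing
  values.  Centroid slots are updated as weighted means over the cells
  observing them, which keeps the objective non-increasing.

The number of contributors (NOC) is chosen as the k in [k_min, k_max]
maximizing the average silhouette coefficient of the fitted partition
(ties toward smaller k).  Silhouette is undefined at k = 1, so clustering
never reports a single source; the IBS-threshold estimator
(:func:`estimate_noc_ibs`) covers that case by counting connected components
of the "pairwise IBS above threshold" graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .cell_sim import MixtureDataset
from .similarity import ibs_count

__all__ = [
    "FeatureMatrix",
    "ClusteringResult",
    "NOCEstimate",
    "encode_profiles",
    "pairwise_distances",
    "cluster_em",
    "cluster_kmeans",
    "silhouette_coefficient",
    "estimate_noc",
    "estimate_noc_ibs",
]

_VAR_FLOOR = 1e-4


@dataclass(frozen=True)
class FeatureMatrix:
    """Cells-by-allele-slots numeric matrix with missingness mask."""

    values: np.ndarray  # (n_cells, n_slots), NaN where missing
    mask: np.ndarray  # bool, True where observed
    slot_names: tuple[str, ...]
    cell_ids: tuple[str, ...]

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_slots(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusteringResult:
    """A fitted partition of the cells.

    ``objective`` is the final observed-data log-likelihood for EM and the
    within-cluster (rescaled) sum of squares for K-Means; ``objective_path``
    records it per iteration for monotonicity checks.
    """

    k: int
    assignment: np.ndarray
    silhouette: float | None
    objective: float
    objective_path: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        labels = np.unique(self.assignment)
        if labels.size and (labels.min() < 0 or labels.max() >= self.k):
            raise ValueError("assignment labels out of range")


@dataclass
class NOCEstimate:
    """Estimated number of contributors with the per-k silhouette trace."""

    noc: int
    per_k_scores: dict[int, float]
    best_clustering: ClusteringResult


def encode_profiles(dataset: MixtureDataset) -> FeatureMatrix:
    """Encode a dataset as the packed numeric slot matrix used for clustering.

    Slot order is panel locus order with (slot1, slot2) per locus for diploid
    cells and one slot per locus for haploid cells.  Observed calls are stored
    ascending and left-packed, so a heterozygote (11, 9) occupies slots
    (9, 11) and a single surviving allele occupies slot 1.
    """
    panel = dataset.panel
    per_locus = 2 if dataset.ploidy == "diploid" else 1
    if per_locus == 2:
        names = tuple(f"{locus}_{s}" for locus in panel.loci for s in (1, 2))
    else:
        names = tuple(panel.loci)
    n = dataset.n_cells
    d = per_locus * panel.n_loci
    values = np.full((n, d), np.nan)
    for i, cell in enumerate(dataset.cells):
        col = 0
        for locus in panel.loci:
            obs = cell.calls.get(locus, ())
            for j, allele in enumerate(obs):
                values[i, col + j] = allele
            col += per_locus
    mask = ~np.isnan(values)
    return FeatureMatrix(values=values, mask=mask, slot_names=names,
                         cell_ids=tuple(c.cell_id for c in dataset.cells))


def _normalized_values(matrix: FeatureMatrix) -> np.ndarray:
    """Per-slot min-max normalization of the observed values (WEKA convention).

    Slots with a constant observed value (or none) normalize to 0.  Missing
    entries keep NaN.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slots
        lo = np.nanmin(matrix.values, axis=0)
        hi = np.nanmax(matrix.values, axis=0)
    lo = np.where(np.isnan(lo), 0.0, lo)
    hi = np.where(np.isnan(hi), 0.0, hi)
    span = np.where(hi > lo, hi - lo, 1.0)
    return np.where(matrix.mask, (matrix.values - lo) / span, np.nan)


def pairwise_distances(matrix: FeatureMatrix, normalize: bool = True) -> np.ndarray:
    """Pairwise missing-rescaled Euclidean distances between cells.

    d(a, b)^2 = (total slots / shared observed slots) * sum over shared slots
    of (x_a - x_b)^2, computed on per-slot min-max normalized values by
    default (the WEKA distance convention; pass ``normalize=False`` for raw
    repeat numbers).  Pairs with no shared observed slot get distance 0 (they
    carry no comparative information).
    """
    values = _normalized_values(matrix) if normalize else matrix.values
    x0 = np.where(matrix.mask, values, 0.0)
    m = matrix.mask.astype(float)
    s = (x0 ** 2) @ m.T  # s[a, b] = sum over b-observed slots of x_a^2 (a-observed)
    cross = x0 @ x0.T
    shared = m @ m.T
    d2 = s + s.T - 2.0 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(shared > 0, d2 * (matrix.n_slots / shared), 0.0)
    d2 = np.maximum(d2, 0.0)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def _global_slot_means(matrix: FeatureMatrix) -> np.ndarray:
    counts = matrix.mask.sum(axis=0)
    x0 = np.where(matrix.mask, matrix.values, 0.0)
    means = np.where(counts > 0, x0.sum(axis=0) / np.maximum(counts, 1), 0.0)
    return means


def _fill_missing(matrix: FeatureMatrix, fill: np.ndarray) -> np.ndarray:
    return np.where(matrix.mask, matrix.values, fill)


def _cell_centroid_sq(matrix: FeatureMatrix, centroids: np.ndarray,
                      weights: np.ndarray) -> np.ndarray:
    """(n, k) rescaled squared distances from each cell to each centroid."""
    x0 = np.where(matrix.mask, matrix.values, 0.0)
    m = matrix.mask.astype(float)
    # sum over observed slots of (x - c)^2, weighted by d / n_obs per cell
    sq_x = (x0 ** 2 * m).sum(axis=1)[:, None]
    sq_c = m @ (centroids.T ** 2)
    cross = x0 @ centroids.T
    d2 = sq_x + sq_c - 2.0 * cross
    return np.maximum(d2, 0.0) * weights[:, None]


def _kmeans_pp_seed(matrix: FeatureMatrix, k: int, weights: np.ndarray,
                    fill: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = matrix.n_cells
    filled = _fill_missing(matrix, fill)
    centroids = np.empty((k, matrix.n_slots))
    first = int(rng.integers(n))
    centroids[0] = filled[first]
    for j in range(1, k):
        d2 = _cell_centroid_sq(matrix, centroids[:j], weights).min(axis=1)
        total = d2.sum()
        if total > 0:
            probs = d2 / total
            idx = int(np.searchsorted(np.cumsum(probs), rng.random()))
            idx = min(idx, n - 1)
        else:
            idx = int(rng.integers(n))  # all points coincide
        centroids[j] = filled[idx]
    return centroids


def cluster_kmeans(
    matrix: FeatureMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    compute_silhouette: bool = True,
    n_init: int = 1,
    normalize: bool = True,
) -> ClusteringResult:
    """Lloyd's K-Means with missing-rescaled Euclidean distances.

    Distances (and hence centroids and the objective) live in per-slot
    min-max normalized attribute space by default, matching the WEKA
    distance convention.  With ``n_init`` > 1 the algorithm is restarted
    from ``n_init`` different k-means++ seedings and the run with the lowest
    final objective is kept.
    """
    if n_init > 1:
        best = None
        for r in range(n_init):
            res = cluster_kmeans(matrix, k, seed=seed + 9973 * r, max_iter=max_iter,
                                 compute_silhouette=False, n_init=1,
                                 normalize=normalize)
            if best is None or res.objective < best.objective:
                best = res
        if compute_silhouette and k >= 2:
            best.silhouette = silhouette_coefficient(matrix, best.assignment)
        return best
    n = matrix.n_cells
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of cells ({n})")
    if normalize:
        matrix = FeatureMatrix(values=_normalized_values(matrix), mask=matrix.mask,
                               slot_names=matrix.slot_names, cell_ids=matrix.cell_ids)
    rng = np.random.default_rng(seed)
    n_obs = matrix.mask.sum(axis=1)
    weights = np.where(n_obs > 0, matrix.n_slots / np.maximum(n_obs, 1), 0.0)
    fill = _global_slot_means(matrix)
    filled = _fill_missing(matrix, fill)
    centroids = _kmeans_pp_seed(matrix, k, weights, fill, rng)

    x0 = np.where(matrix.mask, matrix.values, 0.0)
    m = matrix.mask.astype(float)
    wm = m * weights[:, None]

    assignment = np.full(n, -1)
    path: list[float] = []
    for _ in range(max_iter):
        d2 = _cell_centroid_sq(matrix, centroids, weights)
        new_assignment = d2.argmin(axis=1)
        # repair empty clusters: re-seed at the cell farthest from its centroid
        for j in range(k):
            if not np.any(new_assignment == j):
                own = d2[np.arange(n), new_assignment].copy()
                sizes = np.bincount(new_assignment, minlength=k)
                own[sizes[new_assignment] <= 1] = -1.0  # don't empty a singleton
                far = int(own.argmax())
                centroids[j] = filled[far]
                new_assignment[far] = j
                d2 = _cell_centroid_sq(matrix, centroids, weights)
        path.append(float(d2[np.arange(n), new_assignment].sum()))
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        # weighted per-slot centroid update over observing cells
        for j in range(k):
            members = assignment == j
            wsum = wm[members].sum(axis=0)
            numer = (x0[members] * wm[members]).sum(axis=0)
            update = wsum > 0
            centroids[j, update] = numer[update] / wsum[update]

    sil = None
    if compute_silhouette and k >= 2:
        sil = silhouette_coefficient(matrix, assignment)
    return ClusteringResult(k=k, assignment=assignment, silhouette=sil,
                            objective=path[-1], objective_path=tuple(path))


def _em_log_resp(matrix: FeatureMatrix, means, variances, log_weights):
    x0 = np.where(matrix.mask, matrix.values, 0.0)
    k = means.shape[0]
    n = matrix.n_cells
    log_prob = np.empty((n, k))
    for j in range(k):
        term = -0.5 * (np.log(2.0 * np.pi * variances[j]) +
                       (matrix.values - means[j]) ** 2 / variances[j])
        log_prob[:, j] = np.where(matrix.mask, term, 0.0).sum(axis=1) + log_weights[j]
    row_max = log_prob.max(axis=1, keepdims=True)
    log_norm = row_max + np.log(np.exp(log_prob - row_max).sum(axis=1, keepdims=True))
    return log_prob - log_norm, float(log_norm.sum())


def cluster_em(
    matrix: FeatureMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-3,
    compute_silhouette: bool = True,
    n_init: int = 1,
) -> ClusteringResult:
    """Diagonal-covariance Gaussian mixture EM with marginal-likelihood missing data.

    Initialized from a K-Means partition (means, variances and weights taken
    from that partition) to make the WEKA-style pipeline reproducible; per-slot
    variances are floored at 1e-4.  Converges when the log-likelihood improves
    by less than ``tol`` or after ``max_iter`` iterations; deterministic for a
    fixed seed.  With ``n_init`` > 1 the fit is restarted from ``n_init``
    differently seeded K-Means partitions and the run with the highest final
    log-likelihood is kept.
    """
    if n_init > 1:
        best = None
        for r in range(n_init):
            res = cluster_em(matrix, k, seed=seed + 9973 * r, max_iter=max_iter,
                             tol=tol, compute_silhouette=False, n_init=1)
            if best is None or res.objective > best.objective:
                best = res
        if compute_silhouette and k >= 2:
            best.silhouette = silhouette_coefficient(matrix, best.assignment)
        return best
    n = matrix.n_cells
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of cells ({n})")
    km = cluster_kmeans(matrix, k, seed=seed, compute_silhouette=False)
    x0 = np.where(matrix.mask, matrix.values, 0.0)
    m = matrix.mask.astype(float)
    global_mean = _global_slot_means(matrix)

    means = np.tile(global_mean, (k, 1))
    variances = np.full((k, matrix.n_slots), 1.0)
    weights = np.full(k, 1.0 / k)
    for j in range(k):
        members = km.assignment == j
        cnt = m[members].sum(axis=0)
        mu = np.where(cnt > 0, x0[members].sum(axis=0) / np.maximum(cnt, 1), global_mean)
        var = np.where(
            cnt > 0,
            ((x0[members] - mu * m[members]) ** 2 * m[members]).sum(axis=0) / np.maximum(cnt, 1),
            1.0,
        )
        means[j] = mu
        variances[j] = np.maximum(var, _VAR_FLOOR)
        weights[j] = max(members.sum(), 1) / n
    weights = weights / weights.sum()

    path: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_resp, ll = _em_log_resp(matrix, means, variances, np.log(weights))
        path.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
        resp = np.exp(log_resp)
        nj = resp.sum(axis=0)
        weights = np.maximum(nj, 1e-10) / np.maximum(nj, 1e-10).sum()
        denom = resp.T @ m  # (k, d): responsibility mass observing each slot
        numer = resp.T @ x0
        means = np.where(denom > 0, numer / np.maximum(denom, 1e-12), means)
        for j in range(k):
            sq = ((matrix.values - means[j]) ** 2)
            sq = np.where(matrix.mask, sq, 0.0)
            var_j = (resp[:, j][:, None] * sq).sum(axis=0)
            variances[j] = np.where(
                denom[j] > 0, var_j / np.maximum(denom[j], 1e-12), variances[j]
            )
        variances = np.maximum(variances, _VAR_FLOOR)

    log_resp, ll = _em_log_resp(matrix, means, variances, np.log(weights))
    assignment = log_resp.argmax(axis=1)
    # the result contract requires every cluster non-empty: repair by moving
    # the least-committed cell of the largest cluster
    for j in range(k):
        if not np.any(assignment == j):
            sizes = np.bincount(assignment, minlength=k)
            candidates = np.where(sizes[assignment] > 1)[0]
            commit = log_resp[candidates, assignment[candidates]]
            mover = candidates[int(commit.argmin())]
            assignment[mover] = j
    sil = None
    if compute_silhouette and k >= 2:
        sil = silhouette_coefficient(matrix, assignment)
    return ClusteringResult(k=k, assignment=assignment, silhouette=sil,
                            objective=path[-1] if path else ll,
                            objective_path=tuple(path))


def silhouette_coefficient(
    matrix: FeatureMatrix,
    assignment,
    dist: np.ndarray | None = None,
) -> float:
    """Average silhouette of a partition under the missing-rescaled distance.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to the
    cell's own cluster and b(i) the smallest mean distance to another cluster;
    cells in singleton clusters (and cells with a(i) = b(i) = 0) score 0.
    """
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    if labels.size < 2:
        raise ValueError("silhouette requires at least 2 non-empty clusters")
    if dist is None:
        dist = pairwise_distances(matrix)
    n = matrix.n_cells
    scores = np.zeros(n)
    sums = {lab: dist[:, assignment == lab].sum(axis=1) for lab in labels}
    sizes = {lab: int((assignment == lab).sum()) for lab in labels}
    for i in range(n):
        own = assignment[i]
        if sizes[own] == 1:
            scores[i] = 0.0
            continue
        a = sums[own][i] / (sizes[own] - 1)
        b = min(sums[lab][i] / sizes[lab] for lab in labels if lab != own)
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def estimate_noc(
    matrix: FeatureMatrix,
    algorithm: str = "em",
    k_min: int = 2,
    k_max: int = 6,
    seed: int = 0,
    n_init: int = 5,
) -> NOCEstimate:
    """Estimate the number of contributors by silhouette model selection.

    Runs the chosen algorithm for every k in [k_min, min(k_max, n_cells)]
    (with ``n_init`` restarts each, keeping the best-objective fit) and
    returns the k with the highest average silhouette, breaking ties toward
    the smaller (more conservative) k.
    """
    if algorithm not in ("em", "kmeans"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if matrix.n_cells < k_min:
        raise ValueError(f"need at least {k_min} cells to estimate the NOC")
    dist = pairwise_distances(matrix)
    cluster = cluster_em if algorithm == "em" else cluster_kmeans
    per_k: dict[int, float] = {}
    results: dict[int, ClusteringResult] = {}
    for k in range(k_min, min(k_max, matrix.n_cells) + 1):
        res = cluster(matrix, k, seed=seed, compute_silhouette=False, n_init=n_init)
        res.silhouette = silhouette_coefficient(matrix, res.assignment, dist=dist)
        per_k[k] = res.silhouette
        results[k] = res
    best_k = max(per_k, key=lambda k: (per_k[k], -k))
    return NOCEstimate(noc=best_k, per_k_scores=per_k, best_clustering=results[best_k])


def estimate_noc_ibs(dataset: MixtureDataset, min_same_source_ibs: int = 24) -> NOCEstimate:
    """Estimate the NOC from pairwise IBS connected components.

    Two cells are linked when their IBS exceeds ``min_same_source_ibs``; the
    NOC is the number of connected components of the resulting graph.  Works
    for single-source samples (one component), unlike silhouette selection.
    """
    if dataset.ploidy == "haploid":
        warnings.warn(
            "IBS-threshold NOC estimation is unreliable for haploid profiles: "
            "single-cell consensus profiles are homozygous across loci and the "
            "same-source and unrelated IBS distributions overlap",
            UserWarning,
            stacklevel=2,
        )
    n = dataset.n_cells
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if ibs_count(dataset.cells[i], dataset.cells[j]) > min_same_source_ibs:
                rows.extend((i, j))
                cols.extend((j, i))
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    result = ClusteringResult(k=n_comp, assignment=labels, silhouette=None,
                              objective=float("nan"))
    return NOCEstimate(noc=n_comp, per_k_scores={n_comp: float("nan")},
                       best_clustering=result)
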