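"""Local-catchment estimation from baseline (faunal/sediment) isotope data.

The local dietary catchment of a site is estimated from archaeological
fauna (and, where fauna are unavailable, sediment leachates) measured in
Pb-Sr space (206Pb/204Pb vs 87Sr/86Sr). Because some sampled fauna were
themselves imported, the dense central cluster of the baseline — not its
full spread — defines "local":

1. z-score the two axes per site;
2. run DBSCAN with ``minpts`` = 1, in which regime clusters are exactly
   the connected components of the graph joining points within Euclidean
   distance epsilon;
3. sweep epsilon over a regular inclusive grid (default 1000 values)
   spanning the non-trivial window — from the smallest epsilon that
   merges any two points to the largest that still leaves more than one
   cluster;
4. rank candidate cluster counts k by the Poisson probability mass at k
   under lambda-hat = the mean cluster count across the sweep, and take
   the largest cluster of the best-supported partition;
5. cross-validate with K-means and the SSE scree elbow;
6. report the local range as the per-axis min/max box over that
   cluster's members, in raw (unnormalized) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .samples import IsotopeSample, descriptive_stats

DEFAULT_AXES = ("pb206_204", "sr87_86")

# epsilon_high sits an epsilon-relative hair below the largest MST edge:
# at that edge exactly, the closed-ball graph becomes connected.
_EPS_HIGH_SHRINK = 1.0 - 1e-9


class DegenerateInputError(ValueError):
    """Input too small or geometrically degenerate for the operation."""


@dataclass(frozen=True)
class NormalizedPoints:
    """Z-scored coordinates plus the affine transform for inverse mapping."""

    points: np.ndarray          # (n, d) normalized coordinates
    mean: np.ndarray            # (d,) per-axis mean in raw units
    sd: np.ndarray              # (d,) per-axis sample SD in raw units
    axes: tuple[str, ...]
    samples: tuple[IsotopeSample, ...]

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) * self.sd + self.mean


@dataclass(frozen=True)
class SweepConfig:
    minpts: int = 1
    n_intervals: int = 1000
    axes: tuple[str, str] = DEFAULT_AXES

    def __post_init__(self) -> None:
        if self.minpts != 1:
            raise ValueError("only the minpts=1 regime is supported")
        if self.n_intervals < 2:
            raise ValueError("n_intervals must be >= 2")


@dataclass(frozen=True)
class SweepResult:
    epsilon_low: float
    epsilon_high: float
    epsilons: np.ndarray        # (m,) evenly spaced, inclusive of both bounds
    partitions: np.ndarray      # (m, n) cluster label per point at each eps
    k_counts: np.ndarray        # (m,) number of clusters at each eps


@dataclass(frozen=True)
class PoissonSelection:
    lambda_hat: float
    likelihood_by_k: dict[int, float]
    ranked_k: tuple[int, ...]   # observed k, decreasing Poisson mass


@dataclass(frozen=True)
class ScreeResult:
    sse_by_k: dict[int, float]
    elbow_k: int
    restarts: int
    seed: int
    labels_by_k: dict[int, np.ndarray] = field(repr=False, default_factory=dict)


@dataclass(frozen=True)
class LocalRange:
    """Per-isotope min/max box over the defining local cluster, raw units."""

    bounds: dict[str, tuple[float, float]]
    source: str
    member_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for axis, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"{axis}: min {lo} > max {hi}")

    @property
    def axes(self) -> tuple[str, ...]:
        return tuple(self.bounds)


def normalize(
    samples: Sequence[IsotopeSample], axes: Sequence[str] = DEFAULT_AXES
) -> NormalizedPoints:
    """Center each axis to mean 0 and scale to sample SD 1 (per site).

    Samples missing either axis are excluded with a warning; fewer than 3
    complete samples, or a constant axis, is an error.
    """
    from .samples import logger

    kept = []
    for s in samples:
        if any(getattr(s, a) is None for a in axes):
            logger.warning("sample %s missing %s; excluded from baseline",
                           s.sample_id, "/".join(axes))
            continue
        kept.append(s)
    if len(kept) < 3:
        raise DegenerateInputError(
            f"need >= 3 complete baseline samples, have {len(kept)}"
        )
    raw = np.array([[getattr(s, a) for a in axes] for s in kept], dtype=float)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [a for a, s_ in zip(axes, sd) if s_ == 0]
        raise DegenerateInputError(f"constant axis {bad}: z-score undefined")
    return NormalizedPoints(
        points=(raw - mean) / sd, mean=mean, sd=sd,
        axes=tuple(axes), samples=tuple(kept),
    )


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (canonical form)."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(int(lab), len(mapping))
    return out


def dbscan_components(points: np.ndarray, epsilon: float) -> np.ndarray:
    """DBSCAN partition in the minpts=1 regime.

    Every point is core, so clusters are exactly the connected components
    of the graph joining points at Euclidean distance <= epsilon (closed
    ball); there is no noise label. Labels are canonicalized by first
    appearance, but only the induced partition is meaningful.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = squareform(pdist(points))
    adj = csr_matrix(d <= epsilon)
    _, labels = connected_components(adj, directed=False)
    return _canonical_labels(labels)


def epsilon_bounds(points: np.ndarray) -> tuple[float, float]:
    """The non-trivial epsilon window for the minpts=1 sweep.

    The lower bound is the minimum pairwise distance (the smallest
    epsilon at which any merge occurs); the upper bound is the largest
    minimum-spanning-tree edge, shrunk by a relative 1e-9 because the
    all-in-one-cluster threshold is attained exactly at that edge under
    closed balls. Both bounds are verified to yield 1 < k < n.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if n < 3:
        raise DegenerateInputError("epsilon window undefined for n < 3")
    d = pdist(points)
    if np.all(d == 0):
        raise DegenerateInputError("all points coincident")
    lo = float(d.min())
    mst = minimum_spanning_tree(csr_matrix(squareform(d)))
    hi = float(mst.data.max()) * _EPS_HIGH_SHRINK
    if not lo < hi:
        raise DegenerateInputError(
            "no non-trivial epsilon exists (every merge is simultaneous)"
        )
    for eps in (lo, hi):
        k = len(np.unique(dbscan_components(points, eps)))
        if not 1 < k < n:
            raise DegenerateInputError(
                f"bound {eps} yields trivial partition (k={k}, n={n})"
            )
    return lo, hi


def sweep_dbscan(points: np.ndarray, config: SweepConfig = SweepConfig()) -> SweepResult:
    """Evaluate the minpts=1 partition over a regular inclusive epsilon grid
    spanning the non-trivial window."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    lo, hi = epsilon_bounds(points)
    epsilons = np.linspace(lo, hi, config.n_intervals)
    d = squareform(pdist(points))
    partitions = np.empty((len(epsilons), len(points)), dtype=int)
    k_counts = np.empty(len(epsilons), dtype=int)
    for i, eps in enumerate(epsilons):
        adj = csr_matrix(d <= eps)
        _, labels = connected_components(adj, directed=False)
        labels = _canonical_labels(labels)
        partitions[i] = labels
        k_counts[i] = labels.max() + 1
    return SweepResult(
        epsilon_low=lo, epsilon_high=hi, epsilons=epsilons,
        partitions=partitions, k_counts=k_counts,
    )


def poisson_select(sweep: SweepResult) -> PoissonSelection:
    """Rank candidate cluster counts by Poisson probability mass.

    The sweep's cluster counts parameterize a Poisson model through their
    arithmetic mean lambda-hat; each observed k is scored by the pmf
    exp(-lambda) * lambda**k / k! and ranked in decreasing order (ties
    broken toward smaller k).
    """
    if len(sweep.k_counts) == 0:
        raise ValueError("empty sweep")
    lam = float(np.mean(sweep.k_counts))
    ks = sorted(int(k) for k in np.unique(sweep.k_counts))
    lik = {k: float(stats.poisson.pmf(k, lam)) for k in ks}
    ranked = tuple(sorted(ks, key=lambda k: (-lik[k], k)))
    return PoissonSelection(lambda_hat=lam, likelihood_by_k=lik, ranked_k=ranked)


def _partition_key(labels: np.ndarray) -> frozenset[frozenset[int]]:
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    return frozenset(frozenset(g) for g in groups.values())


def representative_partition(sweep: SweepResult, k_star: int) -> np.ndarray:
    """The modal partition among sweep entries with exactly ``k_star``
    clusters; ties broken toward the partition first realized at the
    smallest epsilon."""
    idx = np.flatnonzero(sweep.k_counts == k_star)
    if idx.size == 0:
        raise ValueError(f"no sweep partition has k={k_star}")
    counts: dict[frozenset, int] = {}
    first: dict[frozenset, int] = {}
    for i in idx:
        key = _partition_key(sweep.partitions[i])
        counts[key] = counts.get(key, 0) + 1
        first.setdefault(key, int(i))
    best = max(counts, key=lambda key: (counts[key], -first[key]))
    return sweep.partitions[first[best]].copy()


def kmeans_scree(
    points: np.ndarray,
    k_max: int = 10,
    restarts: int = 50,
    seed: int = 0,
) -> ScreeResult:
    """K-means SSE scree with an algorithmic elbow.

    For each k the best within-cluster sum of squared errors over
    ``restarts`` Lloyd runs is recorded. The elbow is found by the chord
    rule: rescale the scree to the unit square and pick the interior k
    lying deepest below the straight line joining its first and last
    points. The rule is scale-invariant and stable at both ends of the
    scree, unlike curvature criteria, which fire spuriously either at
    k = 2 (raw second difference, when cluster sizes are imbalanced) or
    in the near-zero tail (relative second difference).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    ks = list(range(1, min(k_max, n) + 1))
    if len(ks) < 3:
        raise DegenerateInputError("need at least k = 1..3 for an elbow")
    sse: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for k in ks:
        km = KMeans(
            n_clusters=k, n_init=restarts, algorithm="lloyd",
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(points)
        sse[k] = float(km.inertia_)
        labels[k] = _canonical_labels(km.labels_)
    interior = ks[1:-1]
    s_first, s_last = sse[ks[0]], sse[ks[-1]]
    span = ks[-1] - ks[0]

    def chord_depth(k: int) -> float:
        if s_first <= s_last:
            return 0.0
        x = (k - ks[0]) / span
        y = (sse[k] - s_last) / (s_first - s_last)
        return (1.0 - x) - y

    elbow = max(interior, key=lambda k: (chord_depth(k), -k))
    return ScreeResult(sse_by_k=sse, elbow_k=elbow, restarts=restarts,
                       seed=seed, labels_by_k=labels)


def largest_cluster(
    partition: np.ndarray, samples: Sequence[IsotopeSample]
) -> np.ndarray:
    """Indices of the largest cluster; size ties broken toward the cluster
    with the smaller 87Sr/86Sr sample SD (the tighter, more homogeneous
    candidate for a single dietary catchment)."""
    partition = np.asarray(partition)
    if partition.size == 0:
        raise ValueError("empty partition")
    labs, sizes = np.unique(partition, return_counts=True)
    best = sizes.max()
    candidates = labs[sizes == best]
    if len(candidates) > 1:
        def sr_sd(lab: int) -> float:
            vals = [samples[i].sr87_86 for i in np.flatnonzero(partition == lab)
                    if samples[i].sr87_86 is not None]
            return descriptive_stats(vals).sd if vals else np.inf
        candidates = sorted(candidates, key=sr_sd)
    return np.flatnonzero(partition == candidates[0])


def local_range(
    partition: np.ndarray,
    samples: Sequence[IsotopeSample],
    axes: Sequence[str] = DEFAULT_AXES,
    source: str = "largest cluster",
) -> LocalRange:
    """Min/max box, in raw units, over the members of the largest cluster."""
    idx = largest_cluster(partition, samples)
    members = [samples[i] for i in idx]
    bounds = {}
    for axis in axes:
        vals = [getattr(s, axis) for s in members if getattr(s, axis) is not None]
        if not vals:
            raise ValueError(f"no values on axis {axis} in the defining cluster")
        bounds[axis] = (min(vals), max(vals))
    return LocalRange(
        bounds=bounds, source=source,
        member_ids=tuple(s.sample_id for s in members),
    )


def pool_baseline(
    groups: Sequence[Sequence[IsotopeSample]],
    axes: Sequence[str] = DEFAULT_AXES,
    source: str = "pooled baseline",
) -> LocalRange:
    """Envelope box over the union of several baseline groups.

    Used where one site's fauna are unavailable and the local range is
    defined from sediment leachates pooled with a neighbouring site's
    local faunal cluster.
    """
    members = [s for g in groups for s in g]
    if not members:
        raise ValueError("empty union of baseline groups")
    bounds = {}
    for axis in axes:
        vals = [getattr(s, axis) for s in members if getattr(s, axis) is not None]
        if not vals:
            raise ValueError(f"no values on axis {axis} in pooled baseline")
        bounds[axis] = (min(vals), max(vals))
    return LocalRange(
        bounds=bounds, source=source,
        member_ids=tuple(s.sample_id for s in members),
    )


@dataclass(frozen=True)
class BaselineReport:
    """Everything the baseline stage computed for one site."""

    site: str
    axes: tuple[str, ...]
    epsilon_low: float
    epsilon_high: float
    sweep: SweepResult
    selection: PoissonSelection
    k_star: int
    partition: np.ndarray
    scree: ScreeResult
    local: LocalRange
    normalized: NormalizedPoints


def estimate_local_range(
    samples: Sequence[IsotopeSample],
    axes: Sequence[str] = DEFAULT_AXES,
    config: SweepConfig | None = None,
    k_max: int = 10,
    restarts: int = 50,
    seed: int = 0,
    site: str = "",
) -> BaselineReport:
    """End-to-end baseline stage for one site: normalize, sweep, select,
    cross-validate with K-means, and box the largest cluster."""
    config = config or SweepConfig(axes=tuple(axes))
    norm = normalize(samples, axes)
    sweep = sweep_dbscan(norm.points, config)
    sel = poisson_select(sweep)
    k_star = sel.ranked_k[0]
    part = representative_partition(sweep, k_star)
    scree = kmeans_scree(norm.points, k_max=min(k_max, len(norm.points)),
                         restarts=restarts, seed=seed)
    lr = local_range(part, norm.samples, axes,
                     source=f"{site or 'baseline'} DBSCAN k={k_star} largest cluster")
    return BaselineReport(
        site=site, axes=tuple(axes),
        epsilon_low=sweep.epsilon_low, epsilon_high=sweep.epsilon_high,
        sweep=sweep, selection=sel, k_star=k_star, partition=part,
        scree=scree, local=lr, normalized=norm,
    )
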