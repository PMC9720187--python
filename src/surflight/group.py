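"""Group-level cluster inference on accuracy maps.

Subjects' per-vertex accuracies are compared against chance with a
one-sample one-tailed t-test; the t-map is thresholded at a vertex-wise
-log10(p) cutoff, connected clusters are found on the downsampled mesh
adjacency, and family-wise error is controlled by a sign-flip max-cluster
permutation: each vertex's t value has its sign flipped with probability
1/2, the largest suprathreshold cluster size is recorded, and after n_perm
repetitions the observed clusters must exceed the rank round(alpha*n_perm)
order statistic of the sorted maxima to survive (rank 20 of 2,000 for
alpha = 0.01, the default).

Vertices where every subject has the same accuracy get t = +/-inf (or 0 at
exactly chance); the thresholding rule handles these directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


@dataclass
class TMap:
    t: np.ndarray
    df: int
    chance: float


@dataclass(frozen=True)
class ThresholdSpec:
    """Inference thresholds: vertex-wise -log10(p), FWE alpha, permutations."""

    vertexwise: float = 3.0
    fwe_alpha: float = 0.01
    n_perm: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.vertexwise <= 0:
            raise ValueError("vertexwise threshold must be positive")
        if not 0 < self.fwe_alpha < 1:
            raise ValueError("fwe_alpha must lie in (0, 1)")
        if self.fwe_alpha * self.n_perm < 1:
            raise ValueError(
                f"fwe_alpha * n_perm = {self.fwe_alpha * self.n_perm} < 1: "
                "too few permutations to realise this alpha")

    @property
    def threshold_rank(self) -> int:
        return int(round(self.fwe_alpha * self.n_perm))


@dataclass
class Cluster:
    vertices: np.ndarray
    peak_t: float
    peak_vertex: int

    @property
    def size(self) -> int:
        return len(self.vertices)


@dataclass
class NullDistribution:
    """Sorted max-cluster sizes from the sign-flip permutations."""

    max_sizes: np.ndarray  # descending
    threshold_rank: int

    @property
    def threshold_size(self) -> int:
        return int(self.max_sizes[self.threshold_rank - 1])


# ---------------------------------------------------------------------------

def group_ttest(maps, chance: float = None) -> TMap:
    """One-sample t-test of subject accuracy maps against chance, per vertex.

    t = mean(acc - chance) / (sd / sqrt(n)), df = n - 1, one-tailed for
    t > 0.  Zero-variance vertices give +/-inf (0 at exactly chance).
    """
    accs = np.vstack([getattr(m, "accuracy", m) for m in maps])
    n = accs.shape[0]
    if n < 2:
        raise ValueError(f"group t-test needs >= 2 subjects, got {n}")
    if chance is None:
        chances = {getattr(m, "chance", None) for m in maps}
        chances.discard(None)
        if len(chances) != 1:
            raise ValueError("maps disagree on chance level; pass chance=")
        chance = chances.pop()
    d = accs - chance
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero = sd == 0
    t[zero] = np.where(mean[zero] > 0, np.inf,
                       np.where(mean[zero] < 0, -np.inf, 0.0))
    return TMap(t=t, df=n - 1, chance=float(chance))


def threshold_map(tmap: TMap, vertexwise: float = 3.0) -> np.ndarray:
    """Binary map of vertices with one-tailed p < 10**(-vertexwise)."""
    t_crit = stats.t.isf(10.0 ** (-vertexwise), df=tmap.df)
    return tmap.t > t_crit


def find_clusters(binary: np.ndarray, adjacency, tmap: TMap = None) -> list:
    """Connected components of marked vertices under mesh-edge adjacency.

    Depth-first traversal with an explicit stack (the recursive grouping
    semantics without recursion-depth limits).  Clusters are returned in
    order of their lowest vertex index.
    """
    binary = np.asarray(binary, dtype=bool)
    visited = np.zeros(len(binary), dtype=bool)
    clusters = []
    for start in np.flatnonzero(binary):
        if visited[start]:
            continue
        stack = [int(start)]
        visited[start] = True
        members = []
        while stack:
            v = stack.pop()
            members.append(v)
            for u in adjacency[v]:
                if binary[u] and not visited[u]:
                    visited[u] = True
                    stack.append(int(u))
        members = np.asarray(sorted(members), dtype=np.int64)
        if tmap is not None:
            k = members[int(np.argmax(tmap.t[members]))]
            peak_t, peak_vertex = float(tmap.t[k]), int(k)
        else:
            peak_t, peak_vertex = np.nan, int(members[0])
        clusters.append(Cluster(vertices=members, peak_t=peak_t,
                                peak_vertex=peak_vertex))
    return clusters


def _max_cluster_size(binary, adjacency) -> int:
    if not binary.any():
        return 0
    return max(c.size for c in find_clusters(binary, adjacency))


def signflip_null(tmap: TMap, adjacency, spec: ThresholdSpec,
                  flip_prob: float = 0.5) -> NullDistribution:
    """Max-cluster null by random sign flipping of the per-vertex t values.

    Each permutation independently flips every vertex's t sign with
    probability ``flip_prob`` (1/2; 0 is a test hook reproducing the
    observed map), thresholds the flipped map with the same one-tailed
    rule, and records the largest cluster size (0 if none).
    """
    rng = np.random.default_rng(spec.seed)
    t_crit = stats.t.isf(10.0 ** (-spec.vertexwise), df=tmap.df)
    pos = tmap.t > t_crit           # active while unflipped
    neg = -tmap.t > t_crit          # active when flipped
    maxima = np.empty(spec.n_perm, dtype=np.int64)
    for it in range(spec.n_perm):
        flip = rng.random(len(tmap.t)) < flip_prob
        active = np.where(flip, neg, pos)
        maxima[it] = _max_cluster_size(active, adjacency)
    return NullDistribution(max_sizes=np.sort(maxima)[::-1],
                            threshold_rank=spec.threshold_rank)


def signflip_null_subject(maps, adjacency, spec: ThresholdSpec,
                          chance: float = None) -> NullDistribution:
    """Alternative null: flip subject-level effects and recompute t.

    Flips the sign of each subject's (accuracy - chance) map as a whole and
    re-runs the group t-test per permutation — the conventional
    subject-exchangeability variant of the sign-flip test.
    """
    accs = np.vstack([getattr(m, "accuracy", m) for m in maps])
    if chance is None:
        chance = getattr(maps[0], "chance")
    d = accs - chance
    n = d.shape[0]
    rng = np.random.default_rng(spec.seed)
    t_crit = stats.t.isf(10.0 ** (-spec.vertexwise), df=n - 1)
    maxima = np.empty(spec.n_perm, dtype=np.int64)
    for it in range(spec.n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)[:, None]
        ds = d * signs
        mean = ds.mean(axis=0)
        sd = ds.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        zero = sd == 0
        t[zero] = np.where(mean[zero] > 0, np.inf,
                           np.where(mean[zero] < 0, -np.inf, 0.0))
        maxima[it] = _max_cluster_size(t > t_crit, adjacency)
    return NullDistribution(max_sizes=np.sort(maxima)[::-1],
                            threshold_rank=spec.threshold_rank)


def fwe_filter(clusters, null: NullDistribution) -> list:
    """Keep clusters strictly larger than the null's threshold-rank size."""
    return [c for c in clusters if c.size > null.threshold_size]


def cluster_report(clusters, tmap: TMap, coords: np.ndarray = None,
                   area_per_vertex: np.ndarray = None) -> pd.DataFrame:
    """Tabulate clusters: peak t, size (vertices, optionally mm^2), peak coords.

    Sorted by size descending.  ``coords`` are (alpha, beta) per vertex of
    the downsampled template; ``area_per_vertex`` optional surface areas.
    """
    rows = []
    for c in clusters:
        row = {
            "peak_t": float(tmap.t[c.peak_vertex]),
            "size_vertices": c.size,
            "peak_vertex": c.peak_vertex,
        }
        if area_per_vertex is not None:
            row["size_mm2"] = float(np.sum(area_per_vertex[c.vertices]))
        if coords is not None:
            row["peak_alpha"] = float(coords[c.peak_vertex, 0])
            row["peak_beta"] = float(coords[c.peak_vertex, 1])
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("size_vertices", ascending=False,
                            kind="stable").reset_index(drop=True)
    return df


class ClusterPermutation(BaseEstimator):
    """Group inference estimator: t-test, clustering, sign-flip FWE filter.

    Parameters
    ----------
    adjacency : per-vertex neighbour lists of the downsampled template.
    vertexwise : float
        Vertex-wise -log10(p) threshold (3 -> p < 0.001, one-tailed).
    fwe_alpha : float
        Family-wise error rate; with n_perm permutations the surviving-size
        cutoff is the rank round(fwe_alpha * n_perm) sorted maximum.
    n_perm : int
        Sign-flip permutations (2,000 by default).
    mode : {"tmap", "subject"}
        Flip per-vertex t signs (default) or subject-level effect signs.
    random_state : int
        Permutation seed.

    Attributes
    ----------
    tmap_ : TMap; binary_ : thresholded map; clusters_ : all clusters;
    null_ : NullDistribution; surviving_ : FWE-surviving clusters;
    report_ : cluster table (pandas DataFrame).
    """

    def __init__(self, adjacency, vertexwise: float = 3.0,
                 fwe_alpha: float = 0.01, n_perm: int = 2000,
                 mode: str = "tmap", random_state: int = 0):
        self.adjacency = adjacency
        self.vertexwise = vertexwise
        self.fwe_alpha = fwe_alpha
        self.n_perm = n_perm
        self.mode = mode
        self.random_state = random_state

    def fit(self, maps, chance: float = None, coords: np.ndarray = None,
            area_per_vertex: np.ndarray = None):
        """Run the full inference chain on per-subject accuracy maps."""
        if self.mode not in ("tmap", "subject"):
            raise ValueError(f"unknown mode {self.mode!r}")
        spec = ThresholdSpec(vertexwise=self.vertexwise,
                             fwe_alpha=self.fwe_alpha, n_perm=self.n_perm,
                             seed=self.random_state)
        self.tmap_ = group_ttest(maps, chance=chance)
        self.binary_ = threshold_map(self.tmap_, self.vertexwise)
        self.clusters_ = find_clusters(self.binary_, self.adjacency, self.tmap_)
        if self.mode == "tmap":
            self.null_ = signflip_null(self.tmap_, self.adjacency, spec)
        else:
            self.null_ = signflip_null_subject(maps, self.adjacency, spec,
                                               chance=chance)
        self.surviving_ = fwe_filter(self.clusters_, self.null_)
        self.report_ = cluster_report(self.surviving_, self.tmap_,
                                      coords=coords,
                                      area_per_vertex=area_per_vertex)
        return self
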