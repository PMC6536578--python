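"""Ward clustering of cell lines and chi-square cluster-response testing.

Cell lines are clustered on the signature genes with Ward's minimum-variance
criterion (each merge is the pair of clusters whose fusion minimally
increases the total within-cluster sum of squares; heights follow the
standard Lance-Williams update on Euclidean distances, so merging two
singletons happens at their Euclidean distance). Features are z-scored per
gene by default, matching clustered-image-map practice.

The resulting dendrogram is cut into k clusters, the panel's log10(IC50)
vector is dichotomised at its median M (sensitive below M, resistant at or
above), and a k x 2 chi-square test of independence asks whether cluster
membership predicts the sensitive/resistant status. The statistic is
``sum (O - E)^2 / E`` without continuity correction, with k - 1 degrees of
freedom; whenever any expected count is below 5 (routine at k = 4 on a
47-line panel) a fixed-margin Monte-Carlo p-value is added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import chi2

from .defaults import K_CLUSTERS, MC_MIN_EXPECTED, MC_REPS, MEDIAN_TIE_RULE
from .exceptions import DataError, ValidationError

__all__ = [
    "Dendrogram",
    "ClusterPartition",
    "ResponseDichotomy",
    "PredictabilityResult",
    "ward_cluster",
    "cut_dendrogram",
    "dichotomize_response",
    "test_predictability",
]

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Ward merge tree over cell lines (linkage rows: a, b, height, size)."""

    linkage: np.ndarray
    leaf_labels: list

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.leaf_labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValidationError(
                f"linkage: expected {(n - 1, 4)} merges, got {self.linkage.shape}")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9 * max(1.0, heights.max())):
            raise ValidationError("linkage: merge heights must be non-decreasing")
        if int(self.linkage[-1, 3]) != n:
            raise ValidationError("linkage: final merge must contain all leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def merges(self) -> list:
        """Merges as (node_a, node_b, height, new_size) tuples."""
        return [(int(a), int(b), float(h), int(s)) for a, b, h, s in self.linkage]

    def leaf_order(self) -> list:
        """Leaf labels in dendrogram display order."""
        return [self.leaf_labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        tree = hierarchy.to_tree(self.linkage)

        def fmt(x: float) -> str:
            return f"{x:.10g}"

        def render(node, parent_height: float) -> str:
            length = fmt(max(parent_height - node.dist, 0.0))
            if node.is_leaf():
                label = str(self.leaf_labels[node.id]).replace(" ", "_")
                return f"{label}:{length}"
            inner = f"({render(node.left, node.dist)},{render(node.right, node.dist)})"
            return f"{inner}:{length}"

        left = render(tree.left, tree.dist)
        right = render(tree.right, tree.dist)
        return f"({left},{right});"


@dataclass
class ClusterPartition:
    """A k-cluster cut; cluster ids are 1..k in dendrogram leaf order."""

    k: int
    assignment: pd.Series  # cell line -> cluster id
    sizes: list            # per-cluster counts, cluster 1 first

    def __post_init__(self) -> None:
        if sum(self.sizes) != len(self.assignment):
            raise ValidationError("sizes: must sum to the number of cell lines")
        if any(s <= 0 for s in self.sizes):
            raise ValidationError("sizes: every cluster must be non-empty")


@dataclass
class ResponseDichotomy:
    """Sensitive/resistant labels from the median log10(IC50) cutoff M."""

    median_cutoff: float
    labels: pd.Series  # cell line -> "sensitive" | "resistant"
    tie_rule: str = MEDIAN_TIE_RULE

    @property
    def counts(self) -> dict:
        vc = self.labels.value_counts()
        return {"sensitive": int(vc.get("sensitive", 0)),
                "resistant": int(vc.get("resistant", 0))}


@dataclass
class PredictabilityResult:
    """k x 2 contingency test of cluster membership vs response class."""

    table: pd.DataFrame      # observed counts, clusters x (sensitive, resistant)
    expected: pd.DataFrame
    statistic: float
    df: int
    p_value: float
    min_expected: float
    mc_p_value: float | None = None
    mc_reps: int = 0


def ward_cluster(panel: pd.DataFrame, standardize: bool = True) -> Dendrogram:
    """Ward-cluster cell lines (columns of ``panel``) on its genes (rows).

    Genes with zero variance across the cell lines carry no distance
    information and would standardise to NaN; they are dropped with a
    warning. Deterministic for a given column order.
    """
    if panel.shape[1] < 2:
        raise DataError("need at least 2 cell lines to cluster")
    if panel.shape[0] < 1:
        raise DataError("need at least 1 signature gene to cluster on")
    X = panel.to_numpy(dtype=float).T  # cell lines x genes
    if not np.all(np.isfinite(X)):
        raise DataError("panel contains non-finite expression values")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not np.all(keep):
            dropped = list(panel.index[~keep])
            logger.warning("ward_cluster: dropped %d zero-variance gene(s): %s",
                           len(dropped), ", ".join(map(str, dropped[:10])))
        if not np.any(keep):
            raise DataError("all genes have zero variance; nothing to cluster on")
        X = (X[:, keep] - mu[keep]) / sd[keep]
    linkage = hierarchy.linkage(X, method="ward")
    return Dendrogram(linkage=linkage, leaf_labels=list(panel.columns))


def cut_dendrogram(dend: Dendrogram, k: int = K_CLUSTERS) -> ClusterPartition:
    """Partition induced by removing the k - 1 highest merges."""
    n = dend.n_leaves
    if not (1 <= k <= n):
        raise ValidationError(f"k: must be in [1, {n}], got {k}")
    # union-find over the first n - k merges (linkage rows are height-ordered)
    parent = np.arange(2 * n - 1)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for m, (a, b, _, _) in enumerate(dend.merges[: n - k]):
        new = n + m
        parent[find(a)] = new
        parent[find(b)] = new

    roots = [find(i) for i in range(n)]
    # number clusters 1..k by first appearance along the dendrogram leaf order
    order = hierarchy.leaves_list(dend.linkage)
    cluster_id: dict = {}
    for leaf in order:
        cluster_id.setdefault(roots[leaf], len(cluster_id) + 1)
    assignment = pd.Series([cluster_id[roots[i]] for i in range(n)],
                           index=dend.leaf_labels, name="cluster")
    sizes = [int((assignment == c).sum()) for c in range(1, k + 1)]
    return ClusterPartition(k=k, assignment=assignment, sizes=sizes)


def dichotomize_response(response: pd.Series,
                         tie_rule: str = MEDIAN_TIE_RULE) -> ResponseDichotomy:
    """Split cell lines at the median log10(IC50) M.

    ``tie_rule="resistant"`` (default) labels lines at exactly M resistant
    (sensitive iff value < M); ``"sensitive"`` labels them sensitive
    (sensitive iff value <= M).
    """
    if tie_rule not in ("resistant", "sensitive"):
        raise ValidationError(f"tie_rule: unknown rule {tie_rule!r}")
    values = response.astype(float)
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        raise DataError("need at least 4 finite response values to dichotomize")
    if finite.nunique() == 1:
        raise DataError("all response values identical; dichotomy undefined")
    m = float(finite.median())
    if tie_rule == "resistant":
        sensitive = finite < m
    else:
        sensitive = finite <= m
    labels = pd.Series(np.where(sensitive, "sensitive", "resistant"),
                       index=finite.index, name="response_class")
    return ResponseDichotomy(median_cutoff=m, labels=labels, tie_rule=tie_rule)


def _chi_square(obs: np.ndarray):
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, expected


def test_predictability(partition: ClusterPartition,
                        dichotomy: ResponseDichotomy,
                        mc_reps: int | None = None,
                        seed: int | None = None) -> PredictabilityResult:
    """Chi-square test: does cluster membership predict sensitive/resistant?

    ``mc_reps`` forces a Monte-Carlo p-value from that many fixed-margin
    permutations of the response labels; when it is None one is added
    automatically (with :data:`~chemosig.defaults.MC_REPS` permutations) if
    any expected count falls below 5.
    """
    cells = list(partition.assignment.index)
    if set(cells) != set(dichotomy.labels.index):
        raise DataError("partition and dichotomy cover different cell lines")
    labels = dichotomy.labels.loc[cells]
    counts = dichotomy.counts
    if min(counts.values()) == 0:
        raise DataError("a response class is empty; the test is undefined")

    k = partition.k
    clusters = partition.assignment.to_numpy()
    is_sensitive = (labels == "sensitive").to_numpy()
    obs = np.zeros((k, 2))
    for c in range(1, k + 1):
        in_c = clusters == c
        obs[c - 1, 0] = np.count_nonzero(in_c & is_sensitive)
        obs[c - 1, 1] = np.count_nonzero(in_c & ~is_sensitive)

    stat, expected = _chi_square(obs)
    df = k - 1
    p = float(chi2.sf(stat, df))
    min_expected = float(expected.min())

    if mc_reps is None and min_expected < MC_MIN_EXPECTED:
        mc_reps = MC_REPS
    mc_p = None
    if mc_reps:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(
            np.tile(is_sensitive.astype(np.int64), (mc_reps, 1)), axis=1)
        onehot = (clusters[:, None] == np.arange(1, k + 1)[None, :]).astype(np.int64)
        s_counts = perms @ onehot                     # reps x k
        r_counts = onehot.sum(axis=0)[None, :] - s_counts
        e_s, e_r = expected[:, 0][None, :], expected[:, 1][None, :]
        stats = (((s_counts - e_s) ** 2 / e_s)
                 + ((r_counts - e_r) ** 2 / e_r)).sum(axis=1)
        exceed = int(np.count_nonzero(stats >= stat - 1e-9))
        mc_p = (1 + exceed) / (1 + mc_reps)

    idx = pd.Index(range(1, k + 1), name="cluster")
    cols = ["sensitive", "resistant"]
    return PredictabilityResult(
        table=pd.DataFrame(obs.astype(int), index=idx, columns=cols),
        expected=pd.DataFrame(expected, index=idx, columns=cols),
        statistic=stat, df=df, p_value=p, min_expected=min_expected,
        mc_p_value=mc_p, mc_reps=int(mc_reps or 0),
    )
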