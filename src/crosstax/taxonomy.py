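"""Cross-species consensus taxonomy construction.

Workflow: cells carrying species/donor/class/over-cluster labels are
aggregated into metacells (per-over-cluster mean log2(CPM+1) profiles),
a Ward merge tree is built over the metacells, every node is assessed
for size, species mixing and subsample stability, and the tree is pruned
recursively into consensus clusters.  A separate correlation-distance
dendrogram over cluster median profiles is bootstrapped over gene
subsets to attach per-clade confidence values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster import hierarchy as sch
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

REQUIRED_OBS = ("species", "donor", "class_label", "over_cluster")


def log2_cpm(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """log2(CPM + pseudocount) with CPM = count * 1e6 / cell total."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("cells with zero total counts")
    return np.log2(counts * 1e6 / totals + pseudocount)


@dataclass
class CellExpression:
    """Cell-by-gene counts plus the per-cell labels the pipeline needs.

    ``obs`` must carry ``species``, ``donor`` and ``class_label``;
    ``over_cluster`` may be attached later (e.g. by
    :func:`kmeans_overcluster`) but is required by
    :func:`aggregate_metacells`.
    """

    counts: np.ndarray
    obs: pd.DataFrame
    gene_ids: np.ndarray
    truth: dict | None = None  # planted ground truth, attached by generators

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.obs = pd.DataFrame(self.obs).reset_index(drop=True)
        self.gene_ids = np.asarray(self.gene_ids)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if len(self.obs) != self.counts.shape[0]:
            raise ValueError("obs rows must match counts rows")
        if len(self.gene_ids) != self.counts.shape[1]:
            raise ValueError("gene_ids must match counts columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        for col in ("species", "donor", "class_label"):
            if col not in self.obs.columns:
                raise ValueError(f"obs lacks required column '{col}'")
            if self.obs[col].isna().any():
                raise ValueError(f"obs column '{col}' has missing labels")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def require_over_cluster(self) -> pd.Series:
        if "over_cluster" not in self.obs.columns or self.obs["over_cluster"].isna().any():
            raise ValueError("over_cluster labels missing; run an over-clusterer first")
        return self.obs["over_cluster"]


def kmeans_overcluster(
    expr: CellExpression,
    k: int,
    seed: int = 0,
    n_pcs: int = 50,
    min_cluster_size: int = 5,
) -> pd.Series:
    """Fallback k-means over-clusterer on PCA-reduced log2(CPM+1) profiles.

    Clusters smaller than `min_cluster_size` are dissolved and their
    cells reassigned to the nearest surviving centroid (tiny
    over-clusters would otherwise vanish under subsampling and make
    exact leaf-set stability meaningless).  Returns per-cell labels
    ``oc000``..; intended for self-contained runs where no
    integrated-space over-clustering is available.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if k < 2 or k > expr.n_cells:
        raise ValueError("k must be in [2, n_cells]")
    x = log2_cpm(expr.counts)
    if n_pcs and n_pcs < min(x.shape):
        x = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    km = KMeans(n_clusters=k, n_init=3, random_state=seed)
    lab = km.fit_predict(x)
    sizes = np.bincount(lab, minlength=k)
    big = np.flatnonzero(sizes >= min_cluster_size)
    if len(big) == 0:
        raise ValueError("min_cluster_size leaves no clusters")
    if len(big) < k:
        dist = ((x[:, None, :] - km.cluster_centers_[None, big, :]) ** 2).sum(axis=2)
        lab = big[dist.argmin(axis=1)]
        # cells already in a surviving cluster keep their assignment
        keep = np.isin(km.labels_, big)
        lab[keep] = km.labels_[keep]
    relabel = {c: i for i, c in enumerate(np.unique(lab))}
    width = len(str(max(len(relabel) - 1, 1)))
    return pd.Series(
        [f"oc{relabel[v]:0{width}d}" for v in lab], index=expr.obs.index, name="over_cluster"
    )


@dataclass
class MetacellMatrix:
    """Per-over-cluster mean log-normalized profiles and composition."""

    profiles: pd.DataFrame  # over_cluster x genes
    sizes: pd.Series
    species_composition: pd.DataFrame  # over_cluster x species

    def __post_init__(self):
        if not self.profiles.index.equals(self.sizes.index):
            raise ValueError("profiles and sizes must share the over_cluster index")


def aggregate_metacells(expr: CellExpression) -> MetacellMatrix:
    """Aggregate cells into metacells: per-cluster mean of log2(CPM+1)."""
    oc = expr.require_over_cluster()
    x = log2_cpm(expr.counts)
    cats = pd.Categorical(oc)
    labels = list(cats.categories)
    codes = cats.codes
    if (np.bincount(codes, minlength=len(labels)) == 0).any():
        empty = [labels[i] for i in np.flatnonzero(np.bincount(codes, minlength=len(labels)) == 0)]
        raise ValueError(f"empty over_cluster(s): {empty}")
    profiles = _group_means(x, codes, len(labels))
    sizes = pd.Series(np.bincount(codes, minlength=len(labels)), index=labels, name="n_cells")
    comp = pd.crosstab(oc, expr.obs["species"]).reindex(labels).fillna(0).astype(int)
    return MetacellMatrix(
        profiles=pd.DataFrame(profiles, index=labels, columns=expr.gene_ids),
        sizes=sizes,
        species_composition=comp,
    )


def _group_means(x: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    n = x.shape[0]
    ind = sparse.csr_matrix((np.ones(n), (codes, np.arange(n))), shape=(k, n))
    sums = ind @ x
    counts = np.bincount(codes, minlength=k).astype(float)
    return sums / counts[:, None]


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class NodeStats:
    size: int
    species_mixing: float
    stability: float

    def __post_init__(self):
        if not (0 <= self.species_mixing <= 1 and 0 <= self.stability <= 1):
            raise ValueError("species_mixing and stability must lie in [0, 1]")


@dataclass
class TreeNode:
    height: float
    leaves: frozenset
    children: tuple | None = None  # (TreeNode, TreeNode) or None for leaves
    stats: NodeStats | None = None
    confidence: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def walk(self):
        yield self
        if self.children:
            for c in self.children:
                yield from c.walk()


@dataclass
class TaxonomyTree:
    """Rooted binary merge tree over over-clusters."""

    root: TreeNode
    leaf_labels: list = field(default_factory=list)

    def nodes(self):
        return list(self.root.walk())

    def internal_nodes(self):
        return [n for n in self.nodes() if not n.is_leaf]

    def clades(self) -> set:
        return {n.leaves for n in self.internal_nodes()}

    def validate(self) -> None:
        for node in self.internal_nodes():
            a, b = node.children
            if a.leaves | b.leaves != node.leaves or (a.leaves & b.leaves):
                raise AssertionError("children leaf sets must partition the parent's")
            if node.height < max(a.height, b.height) - 1e-9:
                raise AssertionError("merge heights must be non-decreasing root-ward")
        if self.root.leaves != frozenset(self.leaf_labels):
            raise AssertionError("root leaves must cover all over-clusters")

    def to_newick(self, use_confidence: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return str(next(iter(node.leaves)))
            a, b = node.children
            label = ""
            if use_confidence and node.confidence is not None:
                label = f"{node.confidence:g}"
            return f"({fmt(a)},{fmt(b)}){label}:{node.height:g}"

        return fmt(self.root) + ";"


def _tree_from_linkage(Z: np.ndarray, labels: list) -> TaxonomyTree:
    n = len(labels)
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, leaves=frozenset([labels[i]])) for i in range(n)
    }
    for k, (i, j, h, _) in enumerate(Z):
        a, b = nodes[int(i)], nodes[int(j)]
        nodes[n + k] = TreeNode(height=float(h), leaves=a.leaves | b.leaves, children=(a, b))
    tree = TaxonomyTree(root=nodes[n + len(Z) - 1], leaf_labels=list(labels))
    tree.validate()
    return tree


def _linkage_clades(Z: np.ndarray, labels: list) -> set:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    clades = set()
    for k, (i, j, _, _) in enumerate(Z):
        merged = members[int(i)] | members[int(j)]
        members[n + k] = merged
        clades.add(merged)
    return clades


def build_tree(metacells: MetacellMatrix) -> TaxonomyTree:
    """Ward's minimum-variance merge tree on metacell profiles."""
    profiles = metacells.profiles
    if len(profiles) < 2:
        raise ValueError("need at least 2 metacells")
    if profiles.isna().any().any():
        raise ValueError("NaN in metacell profiles")
    Z = sch.linkage(profiles.to_numpy(), method="ward")
    return _tree_from_linkage(Z, list(profiles.index))


def _entropy_mixing(species_counts: np.ndarray, n_species_total: int) -> float:
    """Shannon entropy of species proportions, normalized by log(n_species)."""
    if n_species_total < 2:
        return 0.0
    p = species_counts[species_counts > 0].astype(float)
    p /= p.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(n_species_total))


def assess_tree(
    expr: CellExpression,
    tree: TaxonomyTree,
    n_subsamples: int = 100,
    subsample_fraction: float = 0.95,
    seed: int = 0,
) -> TaxonomyTree:
    """Attach size, species-mixing and subsample-stability stats to every node.

    Stability of a node is the fraction of subsample replicates (cells
    drawn without replacement, metacells and tree rebuilt on the
    original gene set) in which some rebuilt node has exactly the same
    leaf set.  Species mixing is the Shannon entropy of species
    proportions of the cells under the node, normalized by
    log(n_species) over the whole dataset.
    """
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must lie in (0, 1]")
    if n_subsamples < 1:
        raise ValueError("n_subsamples must be >= 1")
    oc = expr.require_over_cluster()
    if set(oc.unique()) != set(tree.leaf_labels):
        raise ValueError("tree leaves do not match expr over_clusters")
    x = log2_cpm(expr.counts)
    cats = pd.Categorical(oc, categories=tree.leaf_labels)
    codes = cats.codes.astype(np.int64)
    k = len(tree.leaf_labels)
    species = pd.Categorical(expr.obs["species"])
    n_species = len(species.categories)
    sp_by_cluster = np.zeros((k, n_species), dtype=np.int64)
    np.add.at(sp_by_cluster, (codes, species.codes), 1)
    sizes = np.bincount(codes, minlength=k)

    rng = np.random.default_rng(seed)
    n = expr.n_cells
    m = max(2, int(round(subsample_fraction * n)))
    presence: dict[frozenset, int] = {node.leaves: 0 for node in tree.nodes()}
    leaf_alive = np.zeros(k, dtype=np.int64)
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        sub_codes = codes[idx]
        counts = np.bincount(sub_codes, minlength=k)
        alive = np.flatnonzero(counts > 0)
        leaf_alive[alive] += 1
        remap = -np.ones(k, dtype=np.int64)
        remap[alive] = np.arange(len(alive))
        prof = _group_means(x[idx], remap[sub_codes], len(alive))
        if len(alive) < 2:
            continue
        Z = sch.linkage(prof, method="ward")
        clades = _linkage_clades(Z, [tree.leaf_labels[i] for i in alive])
        clades |= {frozenset([tree.leaf_labels[i]]) for i in alive}
        for leaves in presence:
            if leaves in clades:
                presence[leaves] += 1

    label_to_idx = {lab: i for i, lab in enumerate(tree.leaf_labels)}
    for node in tree.nodes():
        member_idx = [label_to_idx[lab] for lab in node.leaves]
        sp = sp_by_cluster[member_idx].sum(axis=0)
        if node.is_leaf:
            stability = leaf_alive[member_idx[0]] / n_subsamples
        else:
            stability = presence[node.leaves] / n_subsamples
        node.stats = NodeStats(
            size=int(sizes[member_idx].sum()),
            species_mixing=_entropy_mixing(sp, n_species),
            stability=float(stability),
        )
    return tree


@dataclass
class PruneCriteria:
    min_size: int = 20
    min_mixing: float = 0.1
    min_stability: float = 0.6

    def __post_init__(self):
        if self.min_size < 0 or self.min_mixing < 0 or self.min_stability < 0:
            raise ValueError("pruning thresholds must be nonnegative")

    def passes(self, stats: NodeStats) -> bool:
        return (
            stats.size >= self.min_size
            and stats.species_mixing >= self.min_mixing
            and stats.stability >= self.min_stability
        )


@dataclass
class ConsensusClusterSet:
    """Assignment of over-clusters to consensus clusters."""

    assignment: pd.Series  # over_cluster -> consensus cluster id
    summary: pd.DataFrame  # per consensus cluster: n_cells + species counts

    def cell_labels(self, over_cluster_labels: pd.Series) -> pd.Series:
        return over_cluster_labels.map(self.assignment)


def prune_to_consensus(tree: TaxonomyTree, criteria: PruneCriteria | None = None) -> ConsensusClusterSet:
    """Recursively prune an assessed tree into consensus clusters.

    Depth-first from the root: a split is retained only when *both*
    children satisfy the criteria; otherwise the whole subtree below the
    current node collapses into one consensus cluster.  Every retained
    split therefore satisfies the criteria on both children, and
    re-pruning the pruned result is a no-op.
    """
    criteria = criteria or PruneCriteria()
    groups: list[frozenset] = []

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            groups.append(node.leaves)
            return
        a, b = node.children
        for child in (a, b):
            if child.stats is None:
                raise ValueError("prune_to_consensus requires NodeStats on every node")
        if criteria.passes(a.stats) and criteria.passes(b.stats):
            walk(a)
            walk(b)
        else:
            groups.append(node.leaves)

    walk(tree.root)
    width = len(str(max(len(groups) - 1, 1)))
    mapping = {}
    for i, grp in enumerate(sorted(groups, key=lambda g: sorted(g)[0])):
        for lab in sorted(grp):
            mapping[lab] = f"cc{i:0{width}d}"
    assignment = pd.Series(mapping, name="consensus_cluster")
    summary = pd.DataFrame(index=sorted(set(mapping.values())))
    return ConsensusClusterSet(assignment=assignment, summary=summary)


# ---------------------------------------------------------------------------
# bootstrap dendrogram
# ---------------------------------------------------------------------------


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    centred = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((centred**2).sum(axis=1))
    safe = np.where(sd > 0, sd, 1.0)
    z = centred / safe[:, None]
    z[sd == 0] = 0.0  # constant profiles: correlation 0 with everything
    corr = np.clip(z @ z.T, -1.0, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d[np.triu_indices(len(x), k=1)]


def bootstrap_dendrogram(
    profiles: pd.DataFrame,
    n_iter: int = 10_000,
    gene_fraction: float = 0.8,
    seed: int = 0,
) -> TaxonomyTree:
    """Correlation-distance dendrogram with gene-subset bootstrap confidence.

    The reference tree is average-linkage on 1 - Pearson correlation
    between cluster profiles over all genes.  Each iteration rebuilds
    the tree on a uniform random subset of ``gene_fraction`` of the
    genes (without replacement); a node's confidence is the fraction of
    iterations in which its exact leaf set reappears as a clade.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 clusters")
    if profiles.shape[1] < 5:
        raise ValueError("need at least 5 genes")
    if not (0 < gene_fraction <= 1):
        raise ValueError("gene_fraction must lie in (0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    x = profiles.to_numpy(dtype=float)
    labels = list(profiles.index)
    Z = sch.linkage(_correlation_distance(x), method="average")
    tree = _tree_from_linkage(Z, labels)
    counts: dict[frozenset, int] = {n.leaves: 0 for n in tree.internal_nodes()}
    rng = np.random.default_rng(seed)
    g = x.shape[1]
    m = max(1, int(round(gene_fraction * g)))
    for _ in range(n_iter):
        cols = rng.choice(g, size=m, replace=False)
        Zb = sch.linkage(_correlation_distance(x[:, cols]), method="average")
        clades = _linkage_clades(Zb, labels)
        for leaves in counts:
            if leaves in clades:
                counts[leaves] += 1
    for node in tree.nodes():
        node.confidence = 1.0 if node.is_leaf else counts[node.leaves] / n_iter
    return tree


# ---------------------------------------------------------------------------
# markers and matching
# ---------------------------------------------------------------------------


def select_markers_roc(
    expr: CellExpression,
    labels,
    power_threshold: float = 0.7,
    max_markers: int = 50,
) -> pd.DataFrame:
    """Cluster-vs-rest ROC marker selection.

    Per cluster and gene, AUC of the log2(CPM+1) expression for cells in
    the cluster versus all others; classification power is
    ``2 * |AUC - 0.5|``.  Genes with power > `power_threshold` are kept,
    at most `max_markers` per cluster, ranked by power.
    """
    labels = np.asarray(labels)
    if len(labels) != expr.n_cells:
        raise ValueError("labels must match the number of cells")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 cluster labels")
    x = log2_cpm(expr.counts)
    ranks = np.apply_along_axis(rankdata, 0, x)
    n = expr.n_cells
    rows = []
    for cl in uniq:
        mask = labels == cl
        n1 = int(mask.sum())
        if n1 < 2:
            logger.warning("cluster %r has < 2 cells; skipped", cl)
            continue
        n2 = n - n1
        auc = (ranks[mask].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n2)
        power = 2.0 * np.abs(auc - 0.5)
        keep = np.flatnonzero(power > power_threshold)
        keep = keep[np.argsort(-power[keep], kind="mergesort")][:max_markers]
        for r, gi in enumerate(keep, start=1):
            rows.append(
                {
                    "gene_id": expr.gene_ids[gi],
                    "cluster": cl,
                    "auc": float(auc[gi]),
                    "power": float(power[gi]),
                    "rank": r,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "cluster", "auc", "power", "rank"])


@dataclass
class ConfusionSummary:
    matrix: pd.DataFrame  # reference clusters x query clusters
    best_match: pd.Series  # query cluster -> reference cluster
    exact_match_fraction: float
    subclass_match_fraction: float | None = None


def match_taxonomies(query_labels, reference_labels, subclass_of: dict | None = None) -> ConfusionSummary:
    """Compare two labelings of the same cells by maximum-frequency match.

    ``best_match(q)`` is the reference cluster with the largest cell
    overlap with query cluster q (ties: lowest reference cluster in sort
    order, logged).  The exact match fraction is the fraction of cells
    whose reference label equals the best match of their query label;
    the subclass fraction matches at the level of ``subclass_of``.
    """
    q = pd.Series(query_labels).reset_index(drop=True)
    r = pd.Series(reference_labels).reset_index(drop=True)
    if len(q) != len(r) or len(q) == 0:
        raise ValueError("labelings must cover the same nonempty cell set")
    matrix = pd.crosstab(r, q)
    best = {}
    for qc in matrix.columns:
        col = matrix[qc]
        top = col.max()
        winners = sorted(col.index[col == top])
        if len(winners) > 1:
            logger.info("tie for best match of %r among %s; picking %r", qc, winners, winners[0])
        best[qc] = winners[0]
    best_match = pd.Series(best, name="best_match")
    pred = q.map(best_match)
    exact = float((pred == r).mean())
    sub_frac = None
    if subclass_of is not None:
        sub_frac = float((pred.map(subclass_of) == r.map(subclass_of)).mean())
    return ConfusionSummary(
        matrix=matrix,
        best_match=best_match,
        exact_match_fraction=exact,
        subclass_match_fraction=sub_frac,
    )
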