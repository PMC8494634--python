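"""Cross-species cluster statistics: profile correlations, pseudobulk
construction and negative-binomial Wald differential expression.

The DE test is a minimal, documented pseudobulk Wald test: per-gene
method-of-moments dispersion pooled across both species' donor
replicates, then a log-link negative-binomial mean model with a species
indicator fitted by IRLS (vectorized across genes).  No dispersion
moderation or fold-change shrinkage is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from crosstax.enrichment import bh_adjust

LOG2 = np.log(2.0)


def profile_spearman(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    cluster_pairs: list[tuple] | None = None,
) -> pd.Series:
    """Spearman rho between cluster median profiles of two species.

    Rows are clusters, columns genes (aligned one-to-one orthologues).
    When `cluster_pairs` is None, matching row labels are paired.
    """
    shared = profiles_a.columns.intersection(profiles_b.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    if cluster_pairs is None:
        common = profiles_a.index.intersection(profiles_b.index)
        cluster_pairs = [(c, c) for c in common]
    out = {}
    for ca, cb in cluster_pairs:
        rho, _ = sps.spearmanr(profiles_a.loc[ca, shared], profiles_b.loc[cb, shared])
        out[(ca, cb)] = float(rho)
    return pd.Series(out, name="spearman_rho")


@dataclass
class PseudobulkMatrix:
    """Summed counts per (species, donor, cluster) sample."""

    counts: pd.DataFrame  # samples x genes
    meta: pd.DataFrame  # columns: species, donor, cluster, n_cells, flagged

    def subset(self, cluster, species_pair) -> "PseudobulkMatrix":
        mask = (self.meta["cluster"] == cluster) & self.meta["species"].isin(species_pair)
        return PseudobulkMatrix(self.counts.loc[mask.to_numpy()], self.meta.loc[mask.to_numpy()])


def make_pseudobulk(counts, meta: pd.DataFrame, cluster_labels=None, min_cells: int = 10) -> PseudobulkMatrix:
    """Sum cell counts into (species, donor, cluster) pseudobulk samples.

    Parameters
    ----------
    counts
        cells x genes matrix (ndarray or DataFrame).
    meta
        Per-cell metadata with ``species`` and ``donor`` columns.
    cluster_labels
        Per-cell cluster assignment; defaults to ``meta['cluster']``.
    min_cells
        Samples built from fewer cells are flagged (not dropped).
    """
    if isinstance(counts, pd.DataFrame):
        genes = counts.columns
        mat = counts.to_numpy()
    else:
        mat = np.asarray(counts)
        genes = pd.RangeIndex(mat.shape[1])
    meta = pd.DataFrame(meta).reset_index(drop=True)
    if cluster_labels is None:
        cluster_labels = meta["cluster"]
    cl = np.asarray(cluster_labels)
    if len(meta) != mat.shape[0] or len(cl) != mat.shape[0]:
        raise ValueError("metadata/labels must match the number of cells")
    for col in ("species", "donor"):
        if col not in meta.columns:
            raise ValueError(f"meta lacks column '{col}'")
    key = pd.DataFrame({"species": meta["species"], "donor": meta["donor"], "cluster": cl})
    groups = key.groupby(["species", "donor", "cluster"], sort=True).indices
    rows, recs = [], []
    for (sp, dn, c), idx in groups.items():
        rows.append(mat[idx].sum(axis=0))
        recs.append({"species": sp, "donor": dn, "cluster": c, "n_cells": len(idx)})
    meta_out = pd.DataFrame(recs)
    meta_out["flagged"] = meta_out["n_cells"] < min_cells
    sample_ids = [f"{r.species}|{r.donor}|{r.cluster}" for r in meta_out.itertuples()]
    counts_out = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=genes)
    meta_out.index = sample_ids
    return PseudobulkMatrix(counts=counts_out, meta=meta_out)


def _size_factors(totals: np.ndarray) -> np.ndarray:
    # library-size factors normalized to geometric mean 1
    log_t = np.log(totals)
    return np.exp(log_t - log_t.mean())


def _mom_dispersion(z: np.ndarray, group: np.ndarray, inv_sf_mean: float) -> np.ndarray:
    """Pooled within-group method-of-moments dispersion per gene.

    Var(y/s) ~ mu/s + alpha*mu^2 under NB; solve for alpha from the
    pooled within-species variance of normalized counts.
    """
    n = z.shape[0]
    var_w = np.zeros(z.shape[1])
    dof = 0
    for g in np.unique(group):
        zg = z[group == g]
        if len(zg) > 1:
            var_w += zg.var(axis=0, ddof=1) * (len(zg) - 1)
            dof += len(zg) - 1
    var_w /= max(dof, 1)
    mu = z.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (var_w - mu * inv_sf_mean) / mu**2
    return np.clip(np.nan_to_num(alpha, nan=0.0), 1e-8, 100.0)


@dataclass
class DEResult:
    """Per-gene Wald test results for one cluster and species pair."""

    table: pd.DataFrame  # log2_fold_change, wald_stat, p_value, adjusted_p, passes
    cluster: object
    species_pair: tuple
    alpha: float
    lfc_threshold: float

    @property
    def n_pass_up(self) -> int:
        t = self.table
        return int((t["passes"] & (t["log2_fold_change"] > 0)).sum())

    @property
    def n_pass_down(self) -> int:
        t = self.table
        return int((t["passes"] & (t["log2_fold_change"] < 0)).sum())


def pairwise_de(
    pseudobulk: PseudobulkMatrix,
    cluster,
    species_pair: tuple,
    alpha: float = 0.05,
    lfc_threshold: float = 2.0,
    max_iter: int = 50,
) -> DEResult:
    """Negative-binomial Wald test between two species for one cluster.

    Per gene: log-link NB mean model with a species indicator; the
    reported log2_fold_change is species A over species B for the
    ordered pair (A, B).  Wald statistic = coefficient / SE, two-sided p,
    BH-adjusted across tested genes.  ``passes`` iff adjusted p < alpha
    and |log2FC| > lfc_threshold.  Genes with zero counts across all
    samples of the cluster are dropped before testing.
    """
    sp_a, sp_b = species_pair
    sub = pseudobulk.subset(cluster, [sp_a, sp_b])
    meta = sub.meta
    for sp in (sp_a, sp_b):
        n_rep = (meta["species"] == sp).sum()
        if n_rep < 2:
            raise ValueError(
                f"species {sp!r} has {n_rep} replicate(s) for cluster {cluster!r}; "
                "need >= 2 for a dispersion estimate"
            )
    y_all = sub.counts.to_numpy(dtype=float)
    genes_all = sub.counts.columns
    keep = y_all.sum(axis=0) > 0
    y = y_all[:, keep]
    genes = genes_all[keep]
    totals = y_all.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("pseudobulk sample with zero total counts")
    sf = _size_factors(totals)
    x = (meta["species"] == sp_a).to_numpy(dtype=float)  # 1 for species A
    z = y / sf[:, None]
    alpha_g = _mom_dispersion(z, x, float((1.0 / sf).mean()))

    # IRLS for beta = (intercept, species effect), vectorized over genes
    eps = 1e-8
    mean_b = np.maximum(z[x == 0].mean(axis=0), eps)
    mean_a = np.maximum(z[x == 1].mean(axis=0), eps)
    b0 = np.log(mean_b)
    b1 = np.log(mean_a) - b0
    offset = np.log(sf)
    for _ in range(max_iter):
        eta = b0[None, :] + np.outer(x, b1) + offset[:, None]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha_g[None, :] * mu)
        resid = (y - mu) / mu
        zwork = eta - offset[:, None] + resid
        s11 = w.sum(axis=0)
        s1x = (w * x[:, None]).sum(axis=0)
        sxx = (w * (x**2)[:, None]).sum(axis=0)
        sy1 = (w * zwork).sum(axis=0)
        syx = (w * zwork * x[:, None]).sum(axis=0)
        det = s11 * sxx - s1x**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        new_b0 = (sxx * sy1 - s1x * syx) / det
        new_b1 = (s11 * syx - s1x * sy1) / det
        delta = max(np.abs(new_b0 - b0).max(), np.abs(new_b1 - b1).max())
        b0, b1 = new_b0, np.clip(new_b1, -30, 30)
        if delta < 1e-10:
            break
    eta = b0[None, :] + np.outer(x, b1) + offset[:, None]
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha_g[None, :] * mu)
    s11 = w.sum(axis=0)
    s1x = (w * x[:, None]).sum(axis=0)
    sxx = (w * (x**2)[:, None]).sum(axis=0)
    det = np.maximum(s11 * sxx - s1x**2, 1e-300)
    se = np.sqrt(s11 / det)
    wald = b1 / se
    # t reference with n - 2 df: the normal reference is anticonservative
    # at typical donor-replicate counts
    p = 2.0 * sps.t.sf(np.abs(wald), df=max(len(x) - 2, 1))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adj = bh_adjust(p)
    lfc = b1 / LOG2
    table = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "wald_stat": wald,
            "p_value": p,
            "adjusted_p": adj,
            "passes": (adj < alpha) & (np.abs(lfc) > lfc_threshold),
        },
        index=genes,
    )
    return DEResult(table=table, cluster=cluster, species_pair=(sp_a, sp_b), alpha=alpha, lfc_threshold=lfc_threshold)


@dataclass
class MarkerPartition:
    """Conserved / species-enriched / shared-subset partition of markers."""

    conserved: set
    species_enriched: dict  # species -> set
    shared: dict  # frozenset of species (2 <= |s| < all) -> set

    def all_genes(self) -> set:
        out = set(self.conserved)
        for s in self.species_enriched.values():
            out |= s
        for s in self.shared.values():
            out |= s
        return out


def partition_markers(per_species_marker_sets: dict) -> MarkerPartition:
    """Partition per-species marker sets by their exact species support.

    conserved: present in every species; species_enriched[s]: present
    only in s; shared[frozenset]: present in exactly that proper subset
    of >= 2 species.  The three families are disjoint and cover the
    union of the input sets.
    """
    if len(per_species_marker_sets) < 2:
        raise ValueError("need marker sets for >= 2 species")
    species = list(per_species_marker_sets)
    sets = {s: set(v) for s, v in per_species_marker_sets.items()}
    union = set().union(*sets.values())
    conserved: set = set()
    enriched: dict = {s: set() for s in species}
    shared: dict = {}
    for g in union:
        support = frozenset(s for s in species if g in sets[s])
        if len(support) == len(species):
            conserved.add(g)
        elif len(support) == 1:
            enriched[next(iter(support))].add(g)
        else:
            shared.setdefault(support, set()).add(g)
    return MarkerPartition(conserved=conserved, species_enriched=enriched, shared=shared)
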