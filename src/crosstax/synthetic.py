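"""Seeded generators with planted ground truth.

Every generator draws all randomness from one ``numpy.random.default_rng``
seeded per call, so identical specs give byte-identical outputs.  The
planted structures (type hierarchy, regulatory modules, cCRE-gene links,
summit overlap chains, projection enrichment) are returned alongside the
data so downstream stages can be validated against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crosstax.enrichment import ProjectionCounts
from crosstax.linkage import GenomeAnnotation
from crosstax.taxonomy import CellExpression

DEFAULT_CHROM_LENGTHS = {"chr1": 10_000_000, "chr2": 10_000_000}


def _check_positive(spec, fields):
    for name in fields:
        if getattr(spec, name) <= 0:
            raise ValueError(f"{name} must be positive (got {getattr(spec, name)})")


# ---------------------------------------------------------------------------
# taxonomy counts
# ---------------------------------------------------------------------------


@dataclass
class TaxonomySimSpec:
    """Parameters for the hierarchical-taxonomy count generator.

    Counts are negative binomial (variance = mu + mu^2 / dispersion)
    with type-specific marker means; a ``species_divergence`` fraction
    of each type's markers is replaced, per species, by different genes,
    and subclass-level markers make the planted 2-level hierarchy real.
    Donor structure is a log-normal multiplicative factor per
    donor-by-gene block.
    """

    n_species: int = 2
    n_subclasses: int = 5
    types_per_subclass: int = 3
    cells_per_type_per_species: int = 60
    donors_per_species: int = 4
    n_genes: int = 500
    marker_genes_per_type: int = 15
    species_divergence: float = 0.2
    nb_mean: float = 4.0
    nb_dispersion: float = 10.0
    marker_fold: float = 8.0
    seed: int = 0
    marker_genes_per_subclass: int = 15
    donor_sd: float = 0.1

    def validate(self) -> None:
        _check_positive(
            self,
            [
                "n_species",
                "n_subclasses",
                "types_per_subclass",
                "cells_per_type_per_species",
                "donors_per_species",
                "n_genes",
                "marker_genes_per_type",
                "nb_mean",
                "nb_dispersion",
            ],
        )
        if not (0.0 <= self.species_divergence <= 1.0):
            raise ValueError(f"species_divergence must lie in [0, 1] (got {self.species_divergence})")
        if self.marker_fold < 1.0:
            raise ValueError(f"marker_fold must be >= 1 (got {self.marker_fold})")
        if self.donor_sd < 0:
            raise ValueError(f"donor_sd must be >= 0 (got {self.donor_sd})")
        n_types = self.n_subclasses * self.types_per_subclass
        n_div = int(round(self.species_divergence * self.marker_genes_per_type))
        budget = (
            self.n_subclasses * self.marker_genes_per_subclass
            + n_types * self.marker_genes_per_type
            + n_types * self.n_species * n_div
        )
        if budget > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the planted structure (needs {budget})"
            )


def simulate_taxonomy_counts(spec: TaxonomySimSpec) -> CellExpression:
    """Generate cells with a planted 2-level type hierarchy across species.

    The returned ``obs`` carries species, donor, class_label and the
    ground-truth ``subclass`` / ``cell_type`` columns; ``over_cluster``
    is left unset (attach one with
    :func:`crosstax.taxonomy.kmeans_overcluster`).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_types = spec.n_subclasses * spec.types_per_subclass
    n_div = int(round(spec.species_divergence * spec.marker_genes_per_type))

    # sequential gene allocation keeps planted sets disjoint by construction
    cursor = 0

    def take(n):
        nonlocal cursor
        out = np.arange(cursor, cursor + n)
        cursor += n
        return out

    subclass_markers = {s: take(spec.marker_genes_per_subclass) for s in range(spec.n_subclasses)}
    type_markers = {t: take(spec.marker_genes_per_type) for t in range(n_types)}
    divergent_pool = {
        (t, s): take(n_div) for t in range(n_types) for s in range(spec.n_species)
    }

    effective: dict[tuple[int, int], np.ndarray] = {}

    def effective_markers(t, s):
        if (t, s) in effective:
            return effective[(t, s)]
        base = type_markers[t]
        if n_div == 0:
            markers = base
        else:
            drop = rng.choice(len(base), size=n_div, replace=False)
            markers = np.concatenate([np.delete(base, drop), divergent_pool[(t, s)]])
        effective[(t, s)] = markers
        return markers

    theta = spec.nb_dispersion
    donor_names = {
        s: [f"sp{s}_d{d}" for d in range(spec.donors_per_species)] for s in range(spec.n_species)
    }
    donor_factor = {
        name: np.exp(rng.normal(0.0, spec.donor_sd, size=spec.n_genes))
        for s in range(spec.n_species)
        for name in donor_names[s]
    }

    blocks = []
    obs_rows = []
    for s in range(spec.n_species):
        for sc in range(spec.n_subclasses):
            for ti in range(spec.types_per_subclass):
                t = sc * spec.types_per_subclass + ti
                mu = np.full(spec.n_genes, spec.nb_mean)
                mu[subclass_markers[sc]] *= spec.marker_fold
                mu[effective_markers(t, s)] *= spec.marker_fold
                for i in range(spec.cells_per_type_per_species):
                    donor = donor_names[s][i % spec.donors_per_species]
                    cell_mu = mu * donor_factor[donor]
                    blocks.append(
                        rng.negative_binomial(theta, theta / (theta + cell_mu))
                    )
                    obs_rows.append(
                        {
                            "species": f"sp{s}",
                            "donor": donor,
                            "class_label": f"class{sc % 3}",
                            "subclass": f"sc{sc}",
                            "cell_type": f"sc{sc}_t{ti}",
                        }
                    )
    counts = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows)
    gene_ids = np.array([f"gene{i:05d}" for i in range(spec.n_genes)])
    type_names = [
        f"sc{sc}_t{ti}"
        for sc in range(spec.n_subclasses)
        for ti in range(spec.types_per_subclass)
    ]
    truth = {
        "subclass_markers": {
            f"sc{sc}": list(gene_ids[idx]) for sc, idx in subclass_markers.items()
        },
        "type_markers": {type_names[t]: list(gene_ids[idx]) for t, idx in type_markers.items()},
        "effective_markers": {
            (type_names[t], f"sp{s}"): list(gene_ids[idx]) for (t, s), idx in effective.items()
        },
    }
    return CellExpression(counts=counts, obs=obs, gene_ids=gene_ids, truth=truth)


# ---------------------------------------------------------------------------
# regulatory landscape
# ---------------------------------------------------------------------------


@dataclass
class RegSimSpec:
    """Parameters for the planted regulatory landscape on a toy genome."""

    n_clusters: int = 20
    n_ccres: int = 200
    n_genes: int = 100
    n_modules: int = 4
    n_true_links: int = 40
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    link_effect: float = 0.9
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        _check_positive(self, ["n_clusters", "n_ccres", "n_genes", "n_modules"])
        if self.n_true_links < 0:
            raise ValueError("n_true_links must be >= 0")
        if self.n_true_links > min(self.n_ccres, self.n_genes):
            raise ValueError("n_true_links exceeds available cCREs or genes")
        if not (0.0 < self.link_effect <= 1.0):
            raise ValueError(f"link_effect must lie in (0, 1] (got {self.link_effect})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_modules > self.n_clusters:
            raise ValueError("n_modules must not exceed n_clusters")
        margin = 600_000
        for chrom, length in self.chrom_lengths.items():
            if length <= 2 * margin:
                raise ValueError(f"chromosome {chrom} too short (needs > {2 * margin} bp)")


@dataclass
class LinkTruth:
    """Planted ground truth of the regulatory landscape."""

    pairs: list  # (ccre_id, gene_id)
    module_assignments: dict  # ccre_id -> module index
    cluster_activity: dict  # module index -> set of cluster ids


@dataclass
class RegLandscape:
    accessibility: pd.DataFrame  # cCRE x cluster
    expression: pd.DataFrame  # gene x cluster
    ccres: pd.DataFrame  # ccre_id, chrom, start, end
    annotation: GenomeAnnotation
    truth: LinkTruth


def simulate_regulatory_landscape(spec: RegSimSpec) -> RegLandscape:
    """Plant cis-regulatory modules and cCRE-gene links on a toy genome.

    Accessibility is a nonnegative module-basis x cluster-coefficient
    product plus (clipped) Gaussian noise.  For each planted link the
    gene's cluster expression profile equals the linked cCRE's
    accessibility profile scaled by ``link_effect`` plus noise; unlinked
    genes get independent profiles.  Every planted link pairs a cCRE
    and a TSS on the same chromosome, > 1 kb and < 500 kb apart.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    p_chrom = lengths / lengths.sum()
    margin = 600_000

    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    gene_chrom = rng.choice(len(chroms), size=spec.n_genes, p=p_chrom)
    tss = np.array(
        [rng.integers(margin, spec.chrom_lengths[chroms[c]] - margin) for c in gene_chrom]
    )
    strand = rng.choice(["+", "-"], size=spec.n_genes)

    ccre_ids = [f"ccre{i:05d}" for i in range(spec.n_ccres)]
    ccre_chrom = np.empty(spec.n_ccres, dtype=int)
    centre = np.empty(spec.n_ccres, dtype=np.int64)
    pairs = []
    for i in range(spec.n_true_links):
        # linked cCRE i targets gene i: same chromosome, 1 kb < |offset| <= 499 kb
        ccre_chrom[i] = gene_chrom[i]
        offset = int(rng.integers(1_500, 499_000)) * int(rng.choice([-1, 1]))
        centre[i] = tss[i] + offset
        pairs.append((ccre_ids[i], gene_ids[i]))
    for i in range(spec.n_true_links, spec.n_ccres):
        c = rng.choice(len(chroms), p=p_chrom)
        ccre_chrom[i] = c
        centre[i] = rng.integers(1_000, spec.chrom_lengths[chroms[c]] - 1_000)
    ccres = pd.DataFrame(
        {
            "ccre_id": ccre_ids,
            "chrom": [chroms[c] for c in ccre_chrom],
            "start": centre - 250,
            "end": centre + 251,
        }
    )

    clusters = [f"cl{c:03d}" for c in range(spec.n_clusters)]
    perm = rng.permutation(spec.n_clusters)
    chunks = np.array_split(perm, spec.n_modules)
    cluster_activity = {m: {clusters[c] for c in chunk} for m, chunk in enumerate(chunks)}
    module_of = {ccre_ids[i]: i % spec.n_modules for i in range(spec.n_ccres)}
    W0 = np.zeros((spec.n_ccres, spec.n_modules))
    for i, cid in enumerate(ccre_ids):
        W0[i, module_of[cid]] = rng.uniform(1.0, 2.0)
    H0 = np.zeros((spec.n_modules, spec.n_clusters))
    for m, chunk in enumerate(chunks):
        H0[m, chunk] = rng.uniform(0.8, 1.2, size=len(chunk))
    access = W0 @ H0
    # linked cCREs get a dominant unique profile so only their paired gene
    # correlates strongly with them (module peers would otherwise act as
    # confounder links and swamp the false-link rate)
    for i in range(spec.n_true_links):
        access[i] = 0.3 * access[i] + rng.gamma(shape=2.0, scale=0.5, size=spec.n_clusters)
    if spec.noise_sd > 0:
        access = np.clip(access + rng.normal(0.0, spec.noise_sd, access.shape), 0.0, None)

    expr = np.empty((spec.n_genes, spec.n_clusters))
    linked = set(range(spec.n_true_links))
    for g in range(spec.n_genes):
        if g in linked:
            expr[g] = spec.link_effect * access[g]
        else:
            expr[g] = rng.gamma(shape=2.0, scale=0.5, size=spec.n_clusters)
        if spec.noise_sd > 0:
            expr[g] = expr[g] + rng.normal(0.0, spec.noise_sd, spec.n_clusters)

    annotation = GenomeAnnotation(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chrom": [chroms[c] for c in gene_chrom],
                "tss": tss,
                "strand": strand,
            }
        ),
        chrom_sizes=dict(spec.chrom_lengths),
    )
    return RegLandscape(
        accessibility=pd.DataFrame(access, index=ccre_ids, columns=clusters),
        expression=pd.DataFrame(expr, index=gene_ids, columns=clusters),
        ccres=ccres,
        annotation=annotation,
        truth=LinkTruth(pairs=pairs, module_assignments=module_of, cluster_activity=cluster_activity),
    )


# ---------------------------------------------------------------------------
# summits
# ---------------------------------------------------------------------------


def simulate_summits(
    n_per_cluster: int,
    n_clusters: int,
    chrom_lengths: dict | None = None,
    overlap_chain_fraction: float = 0.0,
    seed: int = 0,
    flank: int = 250,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster summit lists with engineered A-B-C overlap chains.

    A fraction of summits is laid out as chains (A at anchor, B at
    anchor+400, C at anchor+800) where, after extension by `flank`, A
    overlaps B and B overlaps C but A does not overlap C, and B carries
    the lowest score of the three — the anti-daisy-chain stress case
    whose correct merge keeps {A, C}.  All chain members share one
    cluster so score-per-million normalization preserves their ranking.
    Anchors are spaced so that peaks from different chains/singletons
    never overlap.

    Returns
    -------
    (summits, chains)
        ``summits``: chrom, summit, score, cluster.  ``chains``: one row
        per planted chain with the three positions.
    """
    if not (0.0 <= overlap_chain_fraction <= 1.0):
        raise ValueError("overlap_chain_fraction must lie in [0, 1]")
    if n_per_cluster <= 0 or n_clusters <= 0:
        raise ValueError("n_per_cluster and n_clusters must be positive")
    chrom_lengths = chrom_lengths or dict(DEFAULT_CHROM_LENGTHS)
    rng = np.random.default_rng(seed)
    total = n_per_cluster * n_clusters
    n_chains = int(round(overlap_chain_fraction * total / 3.0))
    n_singles = total - 3 * n_chains

    spacing = 2_500
    pad = flank + 1_000
    slots = []
    for chrom, length in chrom_lengths.items():
        if length < 2 * pad + spacing:
            raise ValueError(f"chromosome {chrom} too short for summit layout")
        slots.extend((chrom, int(p)) for p in range(pad, length - pad, spacing))
    need = n_singles + n_chains
    if need > len(slots):
        raise ValueError(f"genome too small: need {need} anchor slots, have {len(slots)}")
    anchors = [slots[i] for i in rng.permutation(len(slots))[:need]]

    clusters = [f"cl{c:03d}" for c in range(n_clusters)]
    quota = {c: n_per_cluster for c in clusters}
    rows, chain_rows = [], []
    ai = 0
    for _ in range(n_chains):
        eligible = [c for c in clusters if quota[c] >= 3]
        if not eligible:
            raise ValueError("n_per_cluster too small to host the requested chains")
        cl = eligible[int(rng.integers(len(eligible)))]
        quota[cl] -= 3
        chrom, a = anchors[ai]
        ai += 1
        s = np.sort(rng.uniform(2.0, 50.0, size=3))[::-1]
        # middle summit gets the lowest score: merge must keep the outer two
        for pos, score in ((a, s[0]), (a + 400, s[2]), (a + 800, s[1])):
            rows.append({"chrom": chrom, "summit": pos, "score": float(score), "cluster": cl})
        chain_rows.append(
            {"chrom": chrom, "cluster": cl, "pos_a": a, "pos_b": a + 400, "pos_c": a + 800}
        )
    singles = [c for c in clusters for _ in range(quota[c])]
    for cl in singles:
        chrom, a = anchors[ai]
        ai += 1
        rows.append(
            {"chrom": chrom, "summit": a, "score": float(rng.uniform(2.0, 50.0)), "cluster": cl}
        )
    summits = pd.DataFrame(rows, columns=["chrom", "summit", "score", "cluster"])
    chains = pd.DataFrame(chain_rows, columns=["chrom", "cluster", "pos_a", "pos_b", "pos_c"])
    return summits, chains


# ---------------------------------------------------------------------------
# projection experiments
# ---------------------------------------------------------------------------


def simulate_projection_experiment(
    n_runs: int,
    baseline_on: int,
    baseline_off: int,
    true_fold: float,
    cells_per_run: int,
    seed: int = 0,
    target: str = "target",
) -> ProjectionCounts:
    """Per-run on/off-target counts with a planted enrichment factor.

    Each run draws on-target cells binomially with success probability
    ``r_p / (1 + r_p)`` where ``r_p = true_fold * baseline_on /
    baseline_off``, so the expected count ratio equals the planted fold
    times the baseline ratio.
    """
    if n_runs <= 0:
        raise ValueError("n_runs must be positive")
    if baseline_on <= 0 or baseline_off <= 0:
        raise ValueError("baseline counts must be positive")
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    if cells_per_run <= 0:
        raise ValueError("cells_per_run must be positive")
    rng = np.random.default_rng(seed)
    r_u = baseline_on / baseline_off
    r_p = true_fold * r_u
    q = r_p / (1.0 + r_p)
    on = rng.binomial(cells_per_run, q, size=n_runs)
    runs = pd.DataFrame(
        {
            "run": [f"run{i:03d}" for i in range(n_runs)],
            "target": target,
            "on_target": on,
            "off_target": cells_per_run - on,
        }
    )
    return ProjectionCounts(runs=runs, on_baseline=baseline_on, off_baseline=baseline_off)
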