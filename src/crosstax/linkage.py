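"""Enhancer-gene linking and cis-regulatory module discovery.

Linking pipeline: enumerate candidate cCRE-gene pairs inside a 1-Mb
window centred on each TSS, correlate cluster-level accessibility with
cluster-level expression (Pearson), build a shuffled cross-chromosome
background, fit a normal null to the background scores and threshold the
observed family at an empirical FDR.  The same normal-fit machinery
applies to any score family (e.g. externally computed co-accessibility).

Module discovery: multiplicative-update NMF ``V ~ W @ H`` on the
cCRE-by-cluster matrix with Hoyer-sparseness-guided rank selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genome annotation and empirical null
# ---------------------------------------------------------------------------


@dataclass
class GenomeAnnotation:
    """Gene TSS table plus chromosome sizes.

    ``genes`` columns: gene_id, chrom, tss (0-based bp), strand.
    """

    genes: pd.DataFrame
    chrom_sizes: dict

    def __post_init__(self):
        self.genes = pd.DataFrame(self.genes).reset_index(drop=True)
        required = {"gene_id", "chrom", "tss", "strand"}
        if not required.issubset(self.genes.columns):
            raise ValueError(f"genes must have columns {sorted(required)}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene_id values must be unique")
        sizes = self.genes["chrom"].map(self.chrom_sizes)
        if sizes.isna().any():
            raise ValueError("gene chromosome missing from chrom_sizes")
        if ((self.genes["tss"] < 0) | (self.genes["tss"] >= sizes)).any():
            raise ValueError("TSS outside chromosome bounds")


@dataclass
class NullModel:
    """Normal fit to a background score sample plus the FDR threshold.

    ``score_threshold`` is the smallest observed score t such that the
    expected false count under the fitted null at >= t, divided by the
    observed count at >= t, is <= the requested FDR; +inf when no
    observed score qualifies.
    """

    mu: float
    sigma: float
    fdr: float
    score_threshold: float
    background: np.ndarray = field(repr=False)

    def expected_false(self, t: float, family_size: int) -> float:
        return float(sps.norm.sf(t, loc=self.mu, scale=self.sigma) * family_size)


def fit_null_threshold(background_scores, observed_scores, fdr: float = 0.01) -> NullModel:
    """Fit a normal null to background scores and pick the FDR threshold.

    The null is the maximum-likelihood normal fit to
    `background_scores`.  Scanning the observed scores in ascending
    order, the threshold is the smallest observed value t with

        ``sf(t; mu, sigma) * n_observed / #(observed >= t) <= fdr``.

    Parameters
    ----------
    background_scores
        Scores from the shuffled background (>= 30 required).
    observed_scores
        The score family being thresholded (defines both the scan grid
        and the family size).
    fdr
        Target false-discovery rate (upper tail).
    """
    bg = np.asarray(background_scores, dtype=float)
    bg = bg[~np.isnan(bg)]
    if bg.size < 30:
        raise ValueError("need at least 30 background scores")
    if not (0 < fdr <= 1):
        raise ValueError("fdr must be in (0, 1]")
    mu = float(bg.mean())
    sigma = float(bg.std(ddof=0))
    if sigma <= 0:
        raise ValueError("degenerate background: zero variance")
    obs = np.asarray(observed_scores, dtype=float)
    obs = np.sort(obs[~np.isnan(obs)])
    n = obs.size
    if n == 0:
        raise ValueError("no observed scores")
    expected = sps.norm.sf(obs, loc=mu, scale=sigma) * n
    count_ge = n - np.arange(n)
    ok = expected / count_ge <= fdr
    threshold = float(obs[ok.argmax()]) if ok.any() else float("inf")
    return NullModel(mu=mu, sigma=sigma, fdr=fdr, score_threshold=threshold, background=bg)


# ---------------------------------------------------------------------------
# candidate pairs and correlation
# ---------------------------------------------------------------------------


def _peak_frame(peaks) -> pd.DataFrame:
    df = pd.DataFrame(peaks).reset_index(drop=True)
    required = {"ccre_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"peaks must have columns {sorted(required)}")
    return df


def _centres(df: pd.DataFrame) -> np.ndarray:
    return ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)


def classify_proximity(
    peaks, annotation: GenomeAnnotation, proximal_window: int = 1000
) -> pd.Series:
    """Label each peak proximal/distal by distance to the nearest TSS.

    Proximal iff the peak centre lies within ``proximal_window`` bp of
    some TSS; peaks on chromosomes without genes are distal.
    """
    df = _peak_frame(peaks)
    if annotation.genes.empty:
        raise ValueError("empty annotation")
    centres = _centres(df)
    out = np.full(len(df), "distal", dtype=object)
    for chrom, grp in df.groupby("chrom"):
        tss = np.sort(annotation.genes.loc[annotation.genes["chrom"] == chrom, "tss"].to_numpy())
        if tss.size == 0:
            continue
        c = centres[grp.index.to_numpy()]
        pos = np.searchsorted(tss, c)
        left = np.abs(c - tss[np.clip(pos - 1, 0, tss.size - 1)])
        right = np.abs(tss[np.clip(pos, 0, tss.size - 1)] - c)
        nearest = np.minimum(left, right)
        out[grp.index.to_numpy()] = np.where(nearest <= proximal_window, "proximal", "distal")
    return pd.Series(out, index=df["ccre_id"].to_numpy(), name="proximity")


def candidate_pairs(peaks, annotation: GenomeAnnotation, window: int = 1_000_000) -> pd.DataFrame:
    """All same-chromosome (cCRE, gene) pairs within ``window`` centred on the TSS.

    The distance is signed: peak centre minus TSS, sign-flipped on
    minus-strand genes so positive means downstream of the gene.  The
    window test uses the absolute distance (|d| <= window / 2).
    """
    df = _peak_frame(peaks)
    half = window // 2
    centres = _centres(df)
    rows = []
    for chrom, grp in df.groupby("chrom"):
        genes = annotation.genes[annotation.genes["chrom"] == chrom]
        if genes.empty:
            continue
        gsort = genes.sort_values("tss")
        tss = gsort["tss"].to_numpy()
        gid = gsort["gene_id"].to_numpy()
        strand = gsort["strand"].to_numpy()
        idx = grp.index.to_numpy()
        c = centres[idx]
        lo = np.searchsorted(tss, c - half, side="left")
        hi = np.searchsorted(tss, c + half, side="right")
        for k, i in enumerate(idx):
            for g in range(lo[k], hi[k]):
                d = int(c[k]) - int(tss[g])
                if strand[g] == "-":
                    d = -d
                rows.append((df.at[i, "ccre_id"], gid[g], d))
    return pd.DataFrame(rows, columns=["ccre_id", "gene_id", "distance_bp"])


def correlate_pairs(
    pairs: pd.DataFrame, accessibility: pd.DataFrame, expression: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation across joint clusters for each candidate pair.

    `accessibility` is cCRE-by-cluster (e.g. log2 CPM), `expression` is
    gene-by-cluster (e.g. log2 TPM); columns are aligned on their shared
    cluster set.  Pairs whose accessibility or expression vector has
    zero variance get ``pcc = NaN`` and are excluded from downstream
    threshold families.
    """
    clusters = accessibility.columns.intersection(expression.columns)
    if len(clusters) < 3:
        raise ValueError("need at least 3 joint clusters")
    a = accessibility[clusters].to_numpy(dtype=float)
    e = expression[clusters].to_numpy(dtype=float)

    def standardized(m):
        centred = m - m.mean(axis=1, keepdims=True)
        sd = centred.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, centred / sd, np.nan)

    az = standardized(a)
    ez = standardized(e)
    ai = accessibility.index.get_indexer(pairs["ccre_id"])
    ei = expression.index.get_indexer(pairs["gene_id"])
    if (ai < 0).any() or (ei < 0).any():
        raise KeyError("pair references an id missing from the matrices")
    pcc = (az[ai] * ez[ei]).mean(axis=1)
    out = pairs.copy()
    out["pcc"] = pcc
    n_bad = int(np.isnan(pcc).sum())
    if n_bad:
        logger.warning("%d pair(s) with zero-variance profiles flagged (pcc=NaN)", n_bad)
    return out


def shuffled_background(
    peaks,
    annotation: GenomeAnnotation,
    accessibility: pd.DataFrame,
    expression: pd.DataFrame,
    n_background: int,
    seed: int,
) -> np.ndarray:
    """Background PCC sample from cross-chromosome pairs with shuffled labels.

    Each background pair draws a cCRE and a gene on *different*
    chromosomes and permutes the cluster labels of the accessibility
    vector independently per pair before correlating.
    """
    if n_background <= 0:
        raise ValueError("n_background must be positive")
    df = _peak_frame(peaks)
    if df["chrom"].nunique() < 2 or annotation.genes["chrom"].nunique() < 2:
        raise ValueError("background construction requires >= 2 chromosomes")
    rng = np.random.default_rng(seed)
    clusters = accessibility.columns.intersection(expression.columns)
    a = accessibility[clusters].to_numpy(dtype=float)
    e = expression[clusters].to_numpy(dtype=float)
    peak_chrom = df.set_index("ccre_id")["chrom"]
    gene_chrom = annotation.genes.set_index("gene_id")["chrom"]
    a_ids = accessibility.index.to_numpy()
    e_ids = expression.index.to_numpy()
    a_ch = peak_chrom.reindex(a_ids).to_numpy()
    e_ch = gene_chrom.reindex(e_ids).to_numpy()
    ncl = len(clusters)
    out = np.empty(n_background)
    for b in range(n_background):
        while True:
            i = rng.integers(len(a_ids))
            j = rng.integers(len(e_ids))
            if a_ch[i] != e_ch[j]:
                break
        va = a[i][rng.permutation(ncl)]
        ve = e[j]
        sa, se = va.std(), ve.std()
        if sa == 0 or se == 0:
            out[b] = np.nan
            continue
        out[b] = ((va - va.mean()) * (ve - ve.mean())).mean() / (sa * se)
    return out


def select_links(
    pairs_with_pcc: pd.DataFrame,
    null: NullModel,
    proximity: pd.Series | None = None,
    positive_only: bool = True,
) -> pd.DataFrame:
    """Apply the null threshold to correlated pairs, producing a LinkTable.

    ``passes`` iff pcc >= null.score_threshold (and pcc > 0 under
    `positive_only`); NaN pcc never passes.  When a per-cCRE proximity
    series is supplied the table carries a ``proximity`` column so the
    headline distal-only view can be selected downstream.
    """
    out = pairs_with_pcc.copy()
    pcc = out["pcc"].to_numpy(dtype=float)
    passes = pcc >= null.score_threshold
    if positive_only:
        passes &= pcc > 0
    passes &= ~np.isnan(pcc)
    out["passes"] = passes
    if proximity is not None:
        out["proximity"] = proximity.reindex(out["ccre_id"]).to_numpy()
    return out


# ---------------------------------------------------------------------------
# NMF modules
# ---------------------------------------------------------------------------


def sparseness(x) -> float:
    """Hoyer sparseness of a nonnegative vector: (sqrt(n) - L1/L2) / (sqrt(n) - 1).

    1 for a one-hot vector, 0 for a constant positive vector.
    """
    v = np.asarray(x, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("sparseness needs a vector of length >= 2")
    if (v < 0).any():
        raise ValueError("vector must be nonnegative")
    l2 = np.sqrt((v**2).sum())
    if l2 == 0:
        raise ValueError("sparseness undefined for the zero vector")
    n = v.size
    return float((np.sqrt(n) - v.sum() / l2) / (np.sqrt(n) - 1))


@dataclass
class ModuleDecomposition:
    """Best-of-n-runs NMF factor pair with per-run diagnostics.

    ``V ~ W @ H`` with W (n_ccres x rank) and H (rank x n_clusters),
    both entrywise nonnegative.
    """

    W: np.ndarray
    H: np.ndarray
    rank: int
    error: float  # Frobenius norm of V - WH for the retained run
    run_sparseness: np.ndarray  # one H-sparseness value per run
    run_errors: np.ndarray
    objective_trace: np.ndarray  # per-iteration objective of the retained run
    ccre_ids: list | None = None
    cluster_ids: list | None = None


def _h_sparseness(H: np.ndarray) -> float:
    # mean Hoyer sparseness over module rows; zero rows count as 0
    vals = []
    for row in H:
        vals.append(0.0 if row.sum() == 0 else sparseness(row))
    return float(np.mean(vals))


def _mu_nmf(V, rank, rng, max_iter, tol):
    n, m = V.shape
    scale = np.sqrt(max(V.mean(), np.finfo(float).tiny) / rank)
    W = rng.uniform(0.0, 1.0, size=(n, rank)) * scale
    H = rng.uniform(0.0, 1.0, size=(rank, m)) * scale
    eps = 1e-12
    trace = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        err = np.linalg.norm(V - W @ H)
        obj = 0.5 * err**2
        trace.append(obj)
        if prev is not None and prev - obj <= tol * max(prev, 1.0):
            break
        prev = obj
    return W, H, float(np.linalg.norm(V - W @ H)), np.asarray(trace)


def nmf_decompose(
    V,
    rank: int,
    n_runs: int = 100,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
) -> ModuleDecomposition:
    """Multiplicative-update NMF minimizing squared Frobenius error.

    Runs `n_runs` seeded random nonnegative initializations (run r uses
    ``seed + r``), keeps the lowest-error run, and records the Hoyer
    sparseness of H for every run (median over runs drives rank
    selection).  The objective trace of the retained run is monotone
    non-increasing, a property of the multiplicative updates.
    """
    ccre_ids = cluster_ids = None
    if isinstance(V, pd.DataFrame):
        ccre_ids = list(V.index)
        cluster_ids = list(V.columns)
        V = V.to_numpy(dtype=float)
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("V must be entrywise nonnegative")
    if not (1 <= rank <= min(V.shape)):
        raise ValueError("rank must satisfy 1 <= rank <= min(V.shape)")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    best = None
    run_sp = np.empty(n_runs)
    run_err = np.empty(n_runs)
    for r in range(n_runs):
        rng = np.random.default_rng(seed + r)
        W, H, err, trace = _mu_nmf(V, rank, rng, max_iter, tol)
        run_sp[r] = _h_sparseness(H)
        run_err[r] = err
        if best is None or err < best[2]:
            best = (W, H, err, trace)
    W, H, err, trace = best
    return ModuleDecomposition(
        W=W,
        H=H,
        rank=rank,
        error=err,
        run_sparseness=run_sp,
        run_errors=run_err,
        objective_trace=trace,
        ccre_ids=ccre_ids,
        cluster_ids=cluster_ids,
    )


def select_rank(
    V,
    rank_grid,
    n_runs: int = 100,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the NMF rank from median H-sparseness over seeded runs.

    For each rank in `rank_grid` the median Hoyer sparseness of H over
    `n_runs` runs and the best reconstruction error are recorded.  The
    chosen rank maximizes median sparseness among ranks whose best error
    exceeds the next-larger rank's by < 5% relative (i.e. adding a
    module no longer buys much reconstruction); the largest grid rank is
    always eligible.  The full per-rank curve is returned so callers can
    override the rule.
    """
    grid = sorted(set(int(r) for r in rank_grid))
    if not grid:
        raise ValueError("rank_grid must be nonempty")
    records = []
    for r in grid:
        d = nmf_decompose(V, r, n_runs=n_runs, max_iter=max_iter, seed=seed)
        records.append(
            {
                "rank": r,
                "median_sparseness": float(np.median(d.run_sparseness)),
                "best_error": float(min(d.run_errors)),
            }
        )
    table = pd.DataFrame(records)
    err = table["best_error"].to_numpy()
    eligible = np.ones(len(grid), dtype=bool)
    for i in range(len(grid) - 1):
        nxt = max(err[i + 1], np.finfo(float).tiny)
        eligible[i] = (err[i] - err[i + 1]) / nxt < 0.05
    cand = table[eligible]
    chosen = int(cand.loc[cand["median_sparseness"].idxmax(), "rank"])
    table["eligible"] = eligible
    table["chosen"] = table["rank"] == chosen
    return chosen, table


def associate_modules(
    decomp: ModuleDecomposition, coef_threshold: float = 0.1
) -> tuple[dict, dict]:
    """Associate clusters and cCREs with modules from the factor pair.

    H is min-max scaled per column (cluster) to [0, 1]; cluster c joins
    module m iff scaled ``H[m, c] > coef_threshold``.  Each cCRE is
    assigned to the module with its largest basis coefficient, and
    ``module_elements`` lists a module's cCREs in decreasing basis
    score.  Constant H columns scale to 0 (logged).
    """
    H = decomp.H
    rng_ = H.max(axis=0) - H.min(axis=0)
    constant = rng_ == 0
    if constant.any():
        logger.warning("%d constant H column(s) scaled to 0", int(constant.sum()))
    scaled = np.zeros_like(H)
    ok = ~constant
    scaled[:, ok] = (H[:, ok] - H[:, ok].min(axis=0)) / rng_[ok]
    clusters = decomp.cluster_ids or list(range(H.shape[1]))
    ccres = decomp.ccre_ids or list(range(decomp.W.shape[0]))
    module_clusters = {
        m: {clusters[c] for c in np.flatnonzero(scaled[m] > coef_threshold)}
        for m in range(decomp.rank)
    }
    owner = decomp.W.argmax(axis=1)
    module_elements = {}
    for m in range(decomp.rank):
        members = np.flatnonzero(owner == m)
        order = members[np.argsort(-decomp.W[members, m])]
        module_elements[m] = [ccres[i] for i in order]
    return module_clusters, module_elements
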