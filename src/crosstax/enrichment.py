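"""Rank tests, FDR correction and projection-enrichment statistics.

The Mann-Whitney U test is exact (full null enumeration via the
partition-counting recurrence) for small tie-free samples and falls back
to a tie-corrected normal approximation otherwise.  The statistic
reported as ``W`` throughout is the U of the first sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_LIMIT = 30  # exact enumeration domain: n1 + n2 <= this, no ties

_ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a Mann-Whitney rank test.

    ``u_statistic`` is the U of the first sample (0 <= U <= n1*n2).
    ``method`` records whether the p-value came from exact enumeration
    or from the tie-corrected normal approximation.
    """

    u_statistic: float
    n1: int
    n2: int
    p_value: float
    method: str
    alternative: str

    def __post_init__(self):
        if not (0 <= self.u_statistic <= self.n1 * self.n2):
            raise ValueError("U outside [0, n1*n2]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value outside (0, 1]")


@lru_cache(maxsize=256)
def _u_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U for sample sizes (n1, n2), no ties.

    Counts arrangements by the classic recurrence
    ``N(u; n1, n2) = N(u - n2; n1 - 1, n2) + N(u; n1, n2 - 1)``,
    equivalent to expanding the Gaussian binomial coefficient.
    """
    # Gaussian binomial coefficient [n1+n2 choose n1]_q built factor by
    # factor: multiply by (1 - q^(n2+i)), divide by (1 - q^i).
    size = n1 * n2 + n1 + n2 + 2
    c = np.zeros(size, dtype=np.int64)
    c[0] = 1
    for i in range(1, n1 + 1):
        shift = n2 + i
        c[shift:] = c[shift:] - c[: size - shift]
        for u in range(i, size):
            c[u] += c[u - i]
    pmf = c[: n1 * n2 + 1].astype(float)
    return pmf / pmf.sum()


def u_from_values(x, y) -> tuple[float, bool]:
    """Mann-Whitney U of `x` (midrank-based) and whether ties occurred."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    has_ties = len(np.unique(pooled)) < len(pooled)
    n1 = len(x)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u), has_ties


def exact_wilcoxon_from_u(
    u: float, n1: int, n2: int, alternative: str = "two_sided"
) -> RankTestResult:
    """Exact Mann-Whitney p-value from a precomputed U statistic.

    Valid only on the tie-free exact domain (any n1, n2; enumeration is
    by recurrence, not brute force).  Two-sided p is twice the smaller
    tail, capped at 1.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    if u != int(u):
        raise ValueError("exact p-values require an integer U (no ties)")
    pmf = _u_null_pmf(int(n1), int(n2))
    ui = int(u)
    p_less = pmf[: ui + 1].sum()
    p_greater = pmf[ui:].sum()
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return RankTestResult(float(u), n1, n2, float(p), "exact", alternative)


def _normal_approx(u, n1, n2, tie_term, alternative) -> RankTestResult:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankTestResult(u, n1, n2, 1.0, "normal_approx", alternative)
    sd = np.sqrt(var)
    # continuity correction toward the null mean
    if alternative == "greater":
        p = sps.norm.sf((u - mu - 0.5) / sd)
    elif alternative == "less":
        p = sps.norm.cdf((u - mu + 0.5) / sd)
    else:
        z = (abs(u - mu) - 0.5) / sd
        p = min(1.0, 2.0 * sps.norm.sf(z))
    p = float(min(1.0, max(p, np.finfo(float).tiny)))
    return RankTestResult(u, n1, n2, p, "normal_approx", alternative)


def exact_wilcoxon(x, y, alternative: str = "two_sided") -> RankTestResult:
    """Mann-Whitney rank test of `x` versus `y`.

    Exact by enumeration of the U null distribution when
    ``n1 + n2 <= EXACT_LIMIT`` and the pooled values are tie-free;
    otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u, has_ties = u_from_values(x, y)
    n1, n2 = len(x), len(y)
    if not has_ties and n1 + n2 <= EXACT_LIMIT:
        return exact_wilcoxon_from_u(u, n1, n2, alternative)
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    return _normal_approx(u, n1, n2, tie_term, alternative)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    ``adj_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class ProjectionCounts:
    """Per-FANS-run on/off-target cell counts plus the unbiased baseline."""

    runs: pd.DataFrame  # columns: run, target, on_target, off_target
    on_baseline: int
    off_baseline: int

    def __post_init__(self):
        self.runs = pd.DataFrame(self.runs).reset_index(drop=True)
        required = {"run", "target", "on_target", "off_target"}
        if not required.issubset(self.runs.columns):
            raise ValueError(f"runs must have columns {sorted(required)}")
        if self.on_baseline <= 0 or self.off_baseline <= 0:
            raise ValueError("baseline counts must be positive")
        if (self.runs[["on_target", "off_target"]] < 0).any().any():
            raise ValueError("counts must be nonnegative")


def projection_enrichment(counts: ProjectionCounts) -> tuple[pd.DataFrame, pd.Series]:
    """Per-run enrichment ratio and fold over the unbiased baseline.

    For each run, ``r_p = on_target / off_target``; the baseline ratio
    is ``r_u = on_baseline / off_baseline``; ``fold = r_p / r_u``.
    Folds are averaged (arithmetic mean) per target group.  Runs with
    zero off-target cells have no defined ratio and are excluded (and
    logged).
    """
    r_u = counts.on_baseline / counts.off_baseline
    df = counts.runs.copy()
    bad = df["off_target"] == 0
    if bad.any():
        logger.warning("excluding %d run(s) with zero off-target cells", int(bad.sum()))
    df = df.loc[~bad].copy()
    df["r_p"] = df["on_target"] / df["off_target"]
    df["r_u"] = r_u
    df["fold"] = df["r_p"] / r_u
    per_target = df.groupby("target")["fold"].mean()
    return df, per_target


def projection_fraction_table(cells: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dot-plot fractions over single-projecting cells.

    Input rows are (cluster, projection_target, n_targets_labelled); only
    cells with exactly one labelled target enter either denominator.

    Returns
    -------
    (by_cluster, by_target)
        ``by_cluster``: per cluster, fraction of its single-projecting
        cells going to each target (rows sum to 1).  ``by_target``: per
        target, fraction contributed by each cluster (columns sum to 1).
    """
    df = pd.DataFrame(cells)
    required = {"cluster", "projection_target", "n_targets_labelled"}
    if not required.issubset(df.columns):
        raise ValueError(f"cells must have columns {sorted(required)}")
    single = df[df["n_targets_labelled"] == 1]
    if single.empty:
        raise ValueError("no single-projecting cells")
    table = pd.crosstab(single["cluster"], single["projection_target"])
    dropped = set(df["cluster"].unique()) - set(table.index)
    if dropped:
        logger.warning("clusters with no single-projecting cells omitted: %s", sorted(dropped))
    by_cluster = table.div(table.sum(axis=1), axis=0)
    by_target = table.div(table.sum(axis=0), axis=1)
    return by_cluster, by_target


@dataclass
class TFSelection:
    """Per (tf, subclass) expression/motif pass flags and the final call."""

    table: pd.DataFrame  # columns: tf, subclass, log_fold, adjusted_p, expression_pass, motif_pass
    selected: list


def select_tfs(
    expression: pd.DataFrame,
    subclass_labels,
    motif_table: pd.DataFrame,
    alpha: float = 0.05,
    fold_threshold: float = 2.0,
    motif_alpha: float = 1e-3,
    motif_or_threshold: float = 1.3,
    require_same_subclass: bool = True,
) -> TFSelection:
    """Select subclass-selective transcription factors.

    Expression criterion per (tf, subclass): one-tailed (greater)
    Mann-Whitney of the subclass's cells versus the rest, BH-corrected
    across TFs within the subclass, adjusted p < `alpha`, and fold
    change > `fold_threshold` (ratio of linear-scale group means, the
    input being log2-normalized expression).  Motif criterion comes from
    `motif_table` (columns tf, subclass, adjusted_p, odds_ratio).  A TF
    is selected when both criteria hold in at least one subclass —
    the same subclass by default.
    """
    expr = pd.DataFrame(expression)
    labels = np.asarray(subclass_labels)
    if len(labels) != len(expr):
        raise ValueError("subclass_labels length must match expression rows")
    motif = pd.DataFrame(motif_table)
    motif_pass_map = {
        (r.tf, r.subclass): (r.adjusted_p < motif_alpha and r.odds_ratio > motif_or_threshold)
        for r in motif.itertuples()
    }
    linear = np.expm1(expr.to_numpy() * np.log(2.0))  # invert log2(x + 1)
    rows = []
    eps = 1e-9
    for subclass in np.unique(labels):
        mask = labels == subclass
        pvals = []
        folds = []
        for j, tf in enumerate(expr.columns):
            res = exact_wilcoxon(expr.iloc[mask.nonzero()[0], j], expr.iloc[(~mask).nonzero()[0], j], "greater")
            pvals.append(res.p_value)
            folds.append((linear[mask, j].mean() + eps) / (linear[~mask, j].mean() + eps))
        adj = bh_adjust(pvals)
        for tf, a, f in zip(expr.columns, adj, folds):
            mp = motif_pass_map.get((tf, subclass))
            if mp is None:
                logger.warning("tf %s absent from motif table for subclass %s", tf, subclass)
                mp = False
            rows.append(
                {
                    "tf": tf,
                    "subclass": subclass,
                    "fold": f,
                    "adjusted_p": a,
                    "expression_pass": bool(a < alpha and f > fold_threshold),
                    "motif_pass": bool(mp),
                }
            )
    table = pd.DataFrame(rows)
    if require_same_subclass:
        hit = table[table["expression_pass"] & table["motif_pass"]]
        selected = sorted(hit["tf"].unique())
    else:
        e = set(table.loc[table["expression_pass"], "tf"])
        m = set(table.loc[table["motif_pass"], "tf"])
        selected = sorted(e & m)
    return TFSelection(table=table, selected=selected)
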