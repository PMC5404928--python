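"""Differential expression, nine-class time-series dynamics, thresholded
co-expression networks, and category enrichment ratios.

The differential test is a documented substitute for a negative-binomial
GLM: a Wilcoxon rank-sum test on size-factor-normalized counts (optionally a
normal-approximation test on log-transformed counts), with Benjamini-
Hochberg adjustment.  The contribution here is the decision rules layered on
top — the FDR cutoffs and the nine-class transition scheme — not the test
engine, and gene lists from any particular study are not expected to
reproduce.

Nine classes: each of the two adjacent-stage transitions (oocyte -> 1-cell,
1-cell -> 2-cell) is called U (up), D (down) or E (equal); a transition is
U/D iff its BH-adjusted p-value is below alpha (default 0.1), with direction
from the later-stage vs earlier-stage mean.  The combined label concatenates
the two calls: EE, ED, EU, DE, DD, DU, UE, UD, UU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import size_factors
from .model import CountMatrix

NINE_CLASSES = ("EE", "ED", "EU", "DE", "DD", "DU", "UE", "UD", "UU")


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def differential_test(m: CountMatrix, group_a, group_b,
                      method: str = "ranksum",
                      min_mean: float = 5.0) -> pd.DataFrame:
    """Two-group test per feature on size-factor-normalized counts.

    `group_a` / `group_b` are sample-id lists; the log2 fold change is A
    over B (pass the later stage, or the condition of interest, as A).
    Features whose mean normalized count across both groups is below
    `min_mean` are excluded before BH adjustment (padj = NaN).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    sub = m.counts[group_a + group_b]
    sf = size_factors(sub)
    norm = sub / sf
    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    pvals = np.ones(len(norm))
    for i in range(len(norm)):
        xa, xb = a[i], b[i]
        if np.all(xa == xa[0]) and np.all(xb == xa[0]):
            pvals[i] = 1.0
            continue
        if method == "ranksum":
            pvals[i] = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                          method="auto").pvalue
        elif method == "wald_log":
            res = stats.ttest_ind(np.log2(xa + 1), np.log2(xb + 1),
                                  equal_var=False)
            pvals[i] = 1.0 if np.isnan(res.pvalue) else res.pvalue
        else:
            raise ValueError(f"unknown method: {method!r}")
    tested = (mean_a + mean_b) / 2 >= min_mean
    padj = np.full(len(norm), np.nan)
    if tested.any():
        padj[tested] = _bh(pvals[tested])
    return pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "log2_fold_change": lfc,
        "pvalue": pvals, "padj": padj, "tested": tested,
    }, index=norm.index)


def de_features(result: pd.DataFrame, fdr: float = 0.05) -> set[str]:
    """Features with BH-adjusted p below the FDR cutoff."""
    mask = result["padj"] < fdr
    return set(result.index[mask.fillna(False)])


def _transition_call(row, alpha: float) -> str:
    if not np.isnan(row["padj"]) and row["padj"] < alpha:
        return "U" if row["log2_fold_change"] > 0 else "D"
    return "E"


def classify_dynamics(de_t1: pd.DataFrame, de_t2: pd.DataFrame,
                      alpha: float = 0.1) -> pd.DataFrame:
    """Nine-class labels from the two adjacent-stage tests.

    Both inputs must come from `differential_test` with the LATER stage as
    group A, so a positive fold change means upregulation at the later
    time point.
    """
    missing = set(de_t1.index) ^ set(de_t2.index)
    if missing:
        raise ValueError(f"gene(s) missing from one result: {sorted(missing)[:5]}")
    genes = list(de_t1.index)
    t1 = [_transition_call(de_t1.loc[g], alpha) for g in genes]
    t2 = [_transition_call(de_t2.loc[g], alpha) for g in genes]
    return pd.DataFrame({"transition1": t1, "transition2": t2,
                         "class": [a + b for a, b in zip(t1, t2)]},
                        index=pd.Index(genes, name="gene"))


# ---------------------------------------------------------------------------
# thresholded co-expression network
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    threshold: float
    correlation: pd.DataFrame     # pairwise Pearson rho on log2(CPM+1)
    adjacency: pd.DataFrame       # C[i,j] = rho if |rho| >= x else 0
    zero_variance: list[str]
    anchor: str | None = None
    positive_partners: list[str] = field(default_factory=list)
    negative_partners: list[str] = field(default_factory=list)


def threshold_adjacency(corr: pd.DataFrame, x: float) -> pd.DataFrame:
    """C[i,j] = rho[i,j] where |rho| >= x, else 0 (idempotent)."""
    vals = corr.to_numpy(copy=True)
    vals[np.abs(vals) < x] = 0.0
    return pd.DataFrame(vals, index=corr.index, columns=corr.columns)


def coexpression_network(logcpm: pd.DataFrame, anchor: str | None = None,
                         x: float = 0.9) -> CoexpressionNetwork:
    """Pairwise Pearson correlation over samples with the hard-threshold
    adjacency rule; zero-variance features get no edges (flagged, not NaN)."""
    if logcpm.shape[1] < 3:
        raise ValueError("need >= 3 samples to correlate")
    if anchor is not None and anchor not in logcpm.index:
        raise ValueError(f"anchor {anchor!r} absent from matrix")
    X = logcpm.to_numpy(dtype=float)
    sd = X.std(axis=1)
    zero_var = [f for f, s in zip(logcpm.index, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(X)
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    corr = pd.DataFrame(rho, index=logcpm.index, columns=logcpm.index)
    adj = threshold_adjacency(corr, x)
    net = CoexpressionNetwork(x, corr, adj, zero_var, anchor)
    if anchor is not None:
        row = corr.loc[anchor].drop(anchor)
        ok = ~row.index.isin(zero_var)
        net.positive_partners = sorted(row.index[(row >= x) & ok])
        net.negative_partners = sorted(row.index[(row <= -x) & ok])
    return net


# ---------------------------------------------------------------------------
# category enrichment ratios
# ---------------------------------------------------------------------------

def category_enrichment(up: set, down: set, categories: dict[str, set],
                        background: set) -> pd.DataFrame:
    """Per category: log2 ratio of upregulated to downregulated members and
    Fisher's exact p on the 2x2 [in-category vs not] x [up vs down] table.

    A pseudocount of 1 is applied to both cells of the ratio only when
    either cell is zero; raw counts are reported alongside.
    """
    if not up <= background or not down <= background:
        raise ValueError("up/down sets must be subsets of the background")
    rows = []
    for name, members in categories.items():
        members = members & background
        if not members:
            warnings.warn(f"category {name!r} is empty within background; skipped")
            continue
        a = len(up & members)
        b = len(down & members)
        c = 0 if (a > 0 and b > 0) else 1
        ratio = float(np.log2((a + c) / (b + c)))
        table = [[a, b], [len(up) - a, len(down) - b]]
        _, p = stats.fisher_exact(table)
        rows.append({"category": name, "n_up": a, "n_down": b,
                     "pseudocount": c, "log2_ratio": ratio, "fisher_p": p})
    return pd.DataFrame(rows).set_index("category") if rows else pd.DataFrame(
        columns=["n_up", "n_down", "pseudocount", "log2_ratio", "fisher_p"])
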