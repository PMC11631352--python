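"""Rarefaction, alpha/beta diversity, and base-vs-extended test comparisons.

Conventions follow the common amplicon diversity stack: Shannon in bits
(log base 2), Simpson's evenness E = (1/Σp²)/S_obs, Faith's PD including
the path to the tree root, rarefaction without replacement, PERMANOVA with
the (1 + more-extreme) / (1 + permutations) p-value. Distance metrics and
PERMANOVA are delegated to scikit-bio; Kruskal–Wallis to scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.stats.distance import permanova as _skbio_permanova

logger = logging.getLogger(__name__)

ALPHA_METRICS = ("observed_features", "shannon", "simpson_e", "faith_pd")
BETA_METRICS = ("jaccard", "bray_curtis", "aitchison",
                "unweighted_unifrac", "weighted_unifrac")


@dataclass
class TestResult:
    """A group-significance result: effect size (the test statistic) + p."""

    __test__ = False  # not a pytest collection target

    statistic: float
    p_value: float
    n_permutations: int
    method: str
    grouping: str

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


# ---------------------------------------------------------------------------
# rarefaction

def rarefy(table: pd.DataFrame, depth: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (logged).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    dropped = []
    for s in table.columns:
        col = table[s].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append(s)
            continue
        expanded = np.repeat(np.arange(len(col)), col)
        chosen = rng.choice(expanded, size=depth, replace=False)
        out[s] = np.bincount(chosen, minlength=len(col))
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    if not out:
        raise ValueError(f"all samples have fewer than {depth} reads")
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# alpha diversity

def _check_tree_tips(table: pd.DataFrame, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    observed = set(table.index[(table.sum(axis=1) > 0)])
    missing = sorted(observed - tips)
    if missing:
        raise ValueError(f"tree is missing observed features as tips: {missing}")


def alpha_diversity(table: pd.DataFrame, metric: str,
                    tree: TreeNode | None = None) -> pd.Series:
    """Per-sample alpha diversity (columns of ``table`` are samples)."""
    counts = table.to_numpy().T.astype(float)
    if metric == "observed_features":
        vals = (counts > 0).sum(axis=1)
    elif metric == "shannon":
        vals = []
        for row in counts:
            p = row[row > 0] / row.sum()
            vals.append(float(-(p * np.log2(p)).sum()))
    elif metric == "simpson_e":
        vals = []
        for row in counts:
            p = row[row > 0] / row.sum()
            s_obs = (row > 0).sum()
            vals.append(float((1.0 / (p ** 2).sum()) / s_obs))
    elif metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a tree")
        _check_tree_tips(table, tree)
        vals = [float(_skbio_faith_pd(row, taxa=list(table.index), tree=tree))
                for row in table.to_numpy().T]
    else:
        raise ValueError(f"unknown alpha metric {metric!r}")
    return pd.Series(vals, index=table.columns, dtype=float, name=metric)


# ---------------------------------------------------------------------------
# beta diversity

def clr_transform(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of counts + pseudocount (per sample)."""
    x = table.to_numpy().astype(float) + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=table.index, columns=table.columns)


def beta_diversity(table: pd.DataFrame, metric: str,
                   tree: TreeNode | None = None,
                   pseudocount: float = 1.0) -> DistanceMatrix:
    """Pairwise sample distances for one of the five supported metrics.

    Aitchison operates on (unrarefied) counts + pseudocount; UniFrac
    metrics require a tree covering every observed feature.
    """
    ids = list(table.columns)
    counts = table.to_numpy().T.astype(float)
    if metric == "jaccard":
        condensed = pdist(counts > 0, metric="jaccard")
        return DistanceMatrix(squareform(condensed, checks=False), ids)
    if metric == "bray_curtis":
        condensed = pdist(counts, metric="braycurtis")
        return DistanceMatrix(squareform(condensed, checks=False), ids)
    if metric == "aitchison":
        clr = clr_transform(table, pseudocount).to_numpy().T
        condensed = pdist(clr, metric="euclidean")
        return DistanceMatrix(squareform(condensed, checks=False), ids)
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a tree")
        _check_tree_tips(table, tree)
        return _skbio_beta(metric, counts.astype(int), ids=ids,
                           taxa=list(table.index), tree=tree)
    raise ValueError(f"unknown beta metric {metric!r}")


# ---------------------------------------------------------------------------
# group significance

def kruskal_wallis(values: pd.Series, groups: pd.Series,
                   grouping_name: str = "group") -> TestResult:
    """Kruskal–Wallis H (tie-corrected) with chi-square p on g−1 df."""
    groups = groups.reindex(values.index)
    labels = sorted(groups.dropna().unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [values[groups == g].to_numpy() for g in labels]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    h, p = kruskal(*arrays)
    return TestResult(statistic=float(h), p_value=float(p), n_permutations=0,
                      method="kruskal_wallis", grouping=grouping_name)


def permanova(dm: DistanceMatrix, groups: pd.Series, n_permutations: int = 999,
              seed: int = 0, grouping_name: str = "group") -> TestResult:
    """One-way PERMANOVA; p = (1 + #{F_perm >= F_obs}) / (1 + permutations)."""
    grouping = groups.reindex(dm.ids)
    if grouping.isna().any():
        missing = [i for i in dm.ids if pd.isna(grouping[i])]
        raise ValueError(f"grouping does not cover samples {missing}")
    if grouping.nunique() < 2:
        raise ValueError("need at least 2 groups")
    res = _skbio_permanova(dm, grouping.to_numpy(), permutations=n_permutations,
                           seed=seed)
    return TestResult(statistic=float(res["test statistic"]),
                      p_value=float(res["p-value"]),
                      n_permutations=n_permutations,
                      method="permanova", grouping=grouping_name)


# ---------------------------------------------------------------------------
# base-vs-extended comparison (effect-size folds, p-value shifts)

def compare_conditions(results_base: list[TestResult],
                       results_ext: list[TestResult],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Pair base/extended results by (method, grouping) and tabulate
    effect-size fold-changes (ext/base), p-value shifts (ext − base), and
    significance crossings at ``alpha``. A Benjamini–Hochberg-adjusted
    p column is included alongside for convenience."""
    def keyed(results):
        d = {}
        for r in results:
            key = (r.method, r.grouping)
            if key in d:
                raise ValueError(f"duplicate result for {key}")
            d[key] = r
        return d

    base_d, ext_d = keyed(results_base), keyed(results_ext)
    unpaired = set(base_d) ^ set(ext_d)
    if unpaired:
        raise ValueError(f"unpaired results: {sorted(unpaired)}")
    rows = []
    for key in sorted(base_d):
        b, e = base_d[key], ext_d[key]
        fold = np.inf if b.statistic == 0 and e.statistic != 0 else (
            1.0 if b.statistic == e.statistic else e.statistic / b.statistic)
        rows.append({
            "method": key[0], "grouping": key[1],
            "statistic_base": b.statistic, "statistic_ext": e.statistic,
            "effect_fold_change": fold,
            "p_base": b.p_value, "p_ext": e.p_value,
            "p_shift": e.p_value - b.p_value,
            "crossed_alpha": (b.p_value <= alpha) != (e.p_value <= alpha),
        })
    out = pd.DataFrame(rows)
    if len(out):
        from statsmodels.stats.multitest import multipletests
        out["p_base_bh"] = multipletests(out["p_base"], method="fdr_bh")[1]
        out["p_ext_bh"] = multipletests(out["p_ext"], method="fdr_bh")[1]
    return out
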