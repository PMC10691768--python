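"""Per-cluster pairwise differential expression.

For each eligible cell cluster and each of the four pairwise condition
comparisons (a: Bl Ctrl vs Bl Stress, b: Bl Ctrl vs ELA Ctrl, c: Bl Stress
vs ELA Stress, d: ELA Ctrl vs ELA Stress) every gene is fit with a linear
model of its log-normalized expression,

    Y_ij ~ 1 + C_j + B_j

where C is the two-level condition covariate and B the group/batch proxy.
The Wald statistic (condition coefficient over its standard error) is
referred to the standard normal; p values are Benjamini-Hochberg adjusted
within each (cluster, comparison) stratum.  With a single batch level the
Wald statistic reduces exactly to the pooled two-sample t statistic.

A pairwise (rather than joint four-level) fit is used throughout: the study
design confounds batch with group so a joint model shares no information
across comparisons, and pairwise fits give the same contrasts.

Fold changes are differences of per-condition means of the log-normalized
values re-expressed in log2 units, consistent with modeling log expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from stresspattern.containers import COMPARISONS, InputError, NormalizedMatrix

LN2 = float(np.log(2.0))


class ComparisonSkipped(InputError):
    """A comparison cannot be fit in this cluster (missing level, nesting)."""


@dataclass
class DEGSet:
    """Differentially expressed genes of one (cluster, comparison) stratum."""

    cluster: str
    comparison: str
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    @property
    def all(self) -> list[str]:
        return sorted(set(self.up) | set(self.down))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design_matrix(condition: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Intercept + condition indicator + batch dummies (first level ref)."""
    cols = [np.ones(condition.size), condition.astype(float)]
    levels = sorted(pd.unique(batch).tolist())
    for lv in levels[1:]:
        cols.append((batch == lv).astype(float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ComparisonSkipped(
            "design matrix is rank deficient (condition nested within batch); "
            "the condition contrast is unidentifiable"
        )
    return X


def fit_de(expr: NormalizedMatrix, cluster: str, comparison: str) -> pd.DataFrame:
    """Fit the per-gene linear model for one cluster and one comparison.

    Returns one row per gene with ``log2fc``, Wald ``p``, BH ``q``,
    per-condition means ``mean_1`` / ``mean_2`` and a ``degenerate`` flag
    (gene constant within both condition groups: p = 1, log2fc = 0).
    """
    if comparison not in COMPARISONS:
        raise InputError(f"unknown comparison {comparison!r}")
    ref, test = COMPARISONS[comparison]
    cells = expr.cells
    in_cluster = (cells["cluster"] == cluster).to_numpy()
    cond = cells["condition"].to_numpy()
    mask = in_cluster & np.isin(cond, [ref, test])
    sub_cond = cond[mask]
    n_ref = int((sub_cond == ref).sum())
    n_test = int((sub_cond == test).sum())
    if n_ref < 2 or n_test < 2:
        raise ComparisonSkipped(
            f"cluster {cluster!r} comparison {comparison!r}: need >= 2 cells per "
            f"condition level, got {n_ref} ({ref}) and {n_test} ({test})"
        )
    batch = cells["group"].to_numpy()[mask]
    x = (sub_cond == test).astype(float)
    X = _design_matrix(x, batch)

    Y = np.asarray(expr.values[:, mask].todense()).T  # cells x genes
    n, p_params = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p_params
    if dof <= 0:
        raise ComparisonSkipped(
            f"cluster {cluster!r} comparison {comparison!r}: no residual degrees "
            "of freedom"
        )
    sigma2 = (resid ** 2).sum(axis=0) / dof
    var_c = sigma2 * XtX_inv[1, 1]

    mean_1 = Y[x == 0].mean(axis=0)
    mean_2 = Y[x == 1].mean(axis=0)
    var_in_ref = Y[x == 0].var(axis=0)
    var_in_test = Y[x == 1].var(axis=0)
    degenerate = (var_in_ref == 0) & (var_in_test == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(var_c > 0, beta[1] / np.sqrt(var_c), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    log2fc = (mean_2 - mean_1) / LN2
    p = np.where(degenerate, 1.0, p)
    log2fc = np.where(degenerate, 0.0, log2fc)

    out = pd.DataFrame({
        "gene": expr.genes.index,
        "cluster": cluster,
        "comparison": comparison,
        "log2fc": log2fc,
        "wald": np.where(degenerate, 0.0, wald),
        "p": p,
        "q": bh_adjust(p),
        "mean_1": mean_1,
        "mean_2": mean_2,
        "degenerate": degenerate,
    })
    return out


def filter_degs(results: pd.DataFrame,
                q_max: float = 0.05,
                min_mean: float = 0.5,
                min_abs_l2fc: float = 0.5) -> DEGSet:
    """Apply the three DEG filters to one (cluster, comparison) stratum.

    A gene is kept when q < ``q_max``, its mean expression reaches
    ``min_mean`` in at least one of the two conditions, and |log2FC| >=
    ``min_abs_l2fc`` (a fold change exactly at the threshold passes).  The
    sign of the fold change assigns up/down regulation.
    """
    if results.empty:
        return DEGSet(cluster="", comparison="")
    clusters = results["cluster"].unique()
    comparisons = results["comparison"].unique()
    if len(clusters) != 1 or len(comparisons) != 1:
        raise InputError("filter_degs expects a single (cluster, comparison) stratum")
    keep = (
        (results["q"] < q_max)
        & ((results["mean_1"] >= min_mean) | (results["mean_2"] >= min_mean))
        & (results["log2fc"].abs() >= min_abs_l2fc)
    )
    hits = results.loc[keep]
    return DEGSet(
        cluster=str(clusters[0]),
        comparison=str(comparisons[0]),
        up=sorted(hits.loc[hits["log2fc"] > 0, "gene"].tolist()),
        down=sorted(hits.loc[hits["log2fc"] < 0, "gene"].tolist()),
    )


def run_all_comparisons(expr: NormalizedMatrix,
                        clusters: list[str],
                        q_max: float = 0.05,
                        min_mean: float = 0.5,
                        min_abs_l2fc: float = 0.5,
                        ) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Fit all four comparisons in every eligible cluster.

    Returns the full per-gene results table, a ``{(cluster, comparison):
    DEGSet}`` map, and a count table (one row per stratum with ``n_up``,
    ``n_down``, ``n_degs``).  A comparison that cannot be fit is skipped
    with a warning; the run never aborts.
    """
    frames = []
    degsets: dict[tuple[str, str], DEGSet] = {}
    count_rows = []
    for cluster in clusters:
        for comp in COMPARISONS:
            try:
                res = fit_de(expr, cluster, comp)
            except ComparisonSkipped as exc:
                warnings.warn(str(exc), stacklevel=2)
                continue
            frames.append(res)
            ds = filter_degs(res, q_max=q_max, min_mean=min_mean,
                             min_abs_l2fc=min_abs_l2fc)
            degsets[(cluster, comp)] = ds
            count_rows.append({
                "cluster": cluster,
                "comparison": comp,
                "n_up": len(ds.up),
                "n_down": len(ds.down),
                "n_degs": len(ds.up) + len(ds.down),
            })
    results = (pd.concat(frames, ignore_index=True)
               if frames else pd.DataFrame(
                   columns=["gene", "cluster", "comparison", "log2fc", "wald",
                            "p", "q", "mean_1", "mean_2", "degenerate"]))
    counts = pd.DataFrame(count_rows,
                          columns=["cluster", "comparison", "n_up", "n_down",
                                   "n_degs"])
    return results, degsets, counts


def deg_overlap(degsets: dict, clusters: list[str]) -> dict:
    """Cross-cluster DEG overlap (union of the four comparisons per cluster).

    Returns the per-cluster unions, the pairwise intersection-count matrix,
    and for each k the number of genes differential in more than k clusters.
    """
    if len(clusters) < 2:
        raise InputError("need at least 2 clusters for an overlap analysis")
    unions: dict[str, set] = {c: set() for c in clusters}
    for (cluster, _comp), ds in degsets.items():
        if cluster in unions:
            unions[cluster] |= set(ds.all)
    pairwise = pd.DataFrame(0, index=clusters, columns=clusters, dtype=int)
    for c1 in clusters:
        for c2 in clusters:
            pairwise.loc[c1, c2] = len(unions[c1] & unions[c2])
    membership = pd.Series(
        {g: sum(g in unions[c] for c in clusters)
         for g in set().union(*unions.values())},
        dtype=int,
    )
    more_than = {k: int((membership > k).sum()) for k in range(1, len(clusters))}
    return {"unions": {c: sorted(s) for c, s in unions.items()},
            "pairwise": pairwise,
            "genes_in_more_than_k_clusters": more_than}
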