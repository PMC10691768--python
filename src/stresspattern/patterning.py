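"""Transcriptional patterning: interaction scoring and pattern typing.

A gene whose acute-stress response depends on early-life adversity (ELA)
shows an interaction between the two factors of the 2x2 design.  Two
complementary statistics quantify this:

* the **gene patterning score** over the four pairwise log2 fold changes,

      PatternScore = |FC_a - FC_d| + (|FC_b| + |FC_c|)

  where a = Bl Ctrl vs Bl Stress, b = Bl Ctrl vs ELA Ctrl, c = Bl Stress
  vs ELA Stress, d = ELA Ctrl vs ELA Stress.  A stress response identical
  in both backgrounds with no ELA offset scores 0; any divergence raises
  the score.

* eight **pattern-type scores** evaluated on the four condition means
  scaled so the highest equals one.  With dBl = BlStress - BlCtrl,
  dELA = ELAStress - ELACtrl and m(x, y) the mean of two condition levels:

      ChronicUp    =  dBl - |dELA| - |BlStress - m(ELAStress, ELACtrl)|
      ChronicDown  = -dBl - |dELA| - |BlStress - m(ELAStress, ELACtrl)|
      InvertedUp   = -dBl + dELA  - |BlCtrl - ELACtrl|
      InvertedDown =  dBl - dELA  - |BlCtrl - ELACtrl|
      PrimedUp     =  dELA - |dBl| - |ELACtrl - m(BlCtrl, BlStress)|
      PrimedDown   = -dELA - |dBl| - |ELACtrl - m(BlCtrl, BlStress)|
      BluntedUp    =  dBl - |dELA| - |BlCtrl - m(ELAStress, ELACtrl)|
      BluntedDown  = -dBl - |dELA| - |BlCtrl - m(ELAStress, ELACtrl)|

  Each score is clamped at zero, so a gene matching a canonical template
  perfectly scores 1 for that type and 0 elsewhere.  The combiner m(x, y)
  is the arithmetic mean by default ("max" is available but non-default):
  it folds the two remaining condition levels into one reference level and
  is the symmetric choice under which every canonical template reaches
  score exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stresspattern.containers import InputError
from stresspattern.de import DEGSet

#: Fixed label order; also the tie-break priority in classification.
PATTERN_LABELS: tuple[str, ...] = (
    "ChronicUp", "ChronicDown",
    "InvertedUp", "InvertedDown",
    "PrimedUp", "PrimedDown",
    "BluntedUp", "BluntedDown",
)


@dataclass
class ConditionMeans:
    """Four per-condition mean expressions, raw and max-scaled."""

    raw: tuple[float, float, float, float]  # (BlCtrl, BlStress, ELACtrl, ELAStress)
    scaled: tuple[float, float, float, float] = field(init=False)
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        raw = tuple(float(x) for x in self.raw)
        if any(x < 0 for x in raw):
            raise InputError("condition means must be non-negative")
        self.raw = raw
        m = max(raw)
        if m > 0:
            self.scaled = tuple(x / m for x in raw)
            self.degenerate = False
        else:
            self.scaled = (0.0, 0.0, 0.0, 0.0)
            self.degenerate = True

    @property
    def delta_bl(self) -> float:
        return self.scaled[1] - self.scaled[0]

    @property
    def delta_ela(self) -> float:
        return self.scaled[3] - self.scaled[2]


def scale_condition_means(raw) -> ConditionMeans:
    """Scale four non-negative condition means so the maximum equals one.

    An all-zero input is returned unchanged with the degenerate flag set.
    """
    raw = tuple(raw)
    if len(raw) != 4:
        raise InputError("expected four condition means")
    return ConditionMeans(raw)


def pattern_score(fc_a: float, fc_b: float, fc_c: float, fc_d: float) -> float:
    """|FC_a - FC_d| + |FC_b| + |FC_c| -- the interaction score.

    High values flag a likely ELA-by-stress interaction; a gene responding
    identically to stress in both backgrounds with no constitutive offset
    scores 0.  All four fold changes must be finite (a gene missing one
    comparison cannot be scored; the caller excludes it).
    """
    vals = (fc_a, fc_b, fc_c, fc_d)
    if not all(np.isfinite(v) for v in vals):
        raise InputError("pattern_score requires four finite fold changes")
    return abs(fc_a - fc_d) + abs(fc_b) + abs(fc_c)


def _combine(x: float, y: float, mode: str) -> float:
    if mode == "mean":
        return 0.5 * (x + y)
    if mode == "max":
        return max(x, y)
    raise InputError(f"unknown combiner mode {mode!r}")


def pattern_type_scores(cm: ConditionMeans, combine: str = "mean",
                        clamp: bool = True) -> dict[str, float]:
    """Evaluate the eight pattern-type formulas on scaled condition means.

    Scores are clamped at zero by default (the lowest possible score);
    ``clamp=False`` returns the raw values for diagnostics.  A degenerate
    (all-zero) gene scores 0 for every type.
    """
    if cm.degenerate:
        return {k: 0.0 for k in PATTERN_LABELS}
    bl_ctrl, bl_stress, ela_ctrl, ela_stress = cm.scaled
    d_bl = cm.delta_bl
    d_ela = cm.delta_ela
    m_ela = _combine(ela_stress, ela_ctrl, combine)
    m_bl = _combine(bl_ctrl, bl_stress, combine)
    raw = {
        "ChronicUp": d_bl - abs(d_ela) - abs(bl_stress - m_ela),
        "ChronicDown": -d_bl - abs(d_ela) - abs(bl_stress - m_ela),
        "InvertedUp": -d_bl + d_ela - abs(bl_ctrl - ela_ctrl),
        "InvertedDown": d_bl - d_ela - abs(bl_ctrl - ela_ctrl),
        "PrimedUp": d_ela - abs(d_bl) - abs(ela_ctrl - m_bl),
        "PrimedDown": -d_ela - abs(d_bl) - abs(ela_ctrl - m_bl),
        "BluntedUp": d_bl - abs(d_ela) - abs(bl_ctrl - m_ela),
        "BluntedDown": -d_bl - abs(d_ela) - abs(bl_ctrl - m_ela),
    }
    if clamp:
        return {k: max(0.0, v) for k, v in raw.items()}
    return raw


def classify_pattern(scores: dict[str, float]) -> tuple[str, bool]:
    """Label of the maximal clamped type score.

    Returns ``("none", False)`` when every score is zero.  Ties are broken
    by the fixed label order (Chronic < Inverted < Primed < Blunted, Up <
    Down within a family) and flagged.
    """
    best = max(scores.values())
    if best <= 0:
        return "none", False
    winners = [k for k in PATTERN_LABELS if scores[k] == best]
    return winners[0], len(winners) > 1


def union_degs(degsets: list[DEGSet]) -> list[str]:
    """Unique DEGs of one cluster across its four comparisons, sorted."""
    clusters = {d.cluster for d in degsets if d.up or d.down or d.cluster}
    clusters.discard("")
    if len(clusters) > 1:
        raise InputError(f"union_degs received mixed clusters: {sorted(clusters)}")
    out: set[str] = set()
    for d in degsets:
        out |= set(d.up) | set(d.down)
    return sorted(out)


def _condition_means_table(expr, cluster: str) -> pd.DataFrame:
    """Per-gene mean log-normalized expression in each of the 4 conditions."""
    from stresspattern.containers import CONDITIONS

    mask_cluster = (expr.cells["cluster"] == cluster).to_numpy()
    cond = expr.cells["condition"].to_numpy()
    cols = {}
    for c in CONDITIONS:
        m = mask_cluster & (cond == c)
        if m.sum() == 0:
            cols[c] = np.full(expr.n_genes, np.nan)
        else:
            cols[c] = np.asarray(expr.values[:, m].mean(axis=1)).ravel()
    return pd.DataFrame(cols, index=expr.genes.index)


def build_pattern_profiles(results: pd.DataFrame,
                           degsets: dict,
                           expr=None,
                           combine: str = "mean",
                           genes: str = "union") -> pd.DataFrame:
    """Assemble per-(gene, cluster) pattern profiles for the cluster DEG unions.

    For every cluster present in ``degsets`` the four comparisons' DEGs are
    unified; each gene with all four fold changes available gets its
    PatternScore, eight raw and clamped type scores, assigned type, and a
    score tier (top25 / mid50 / low25 within its cluster).  Genes missing a
    comparison are excluded rather than imputed (imputing FC = 0 would
    deflate the score asymmetrically).

    Condition means feeding the type scores are the same per-condition
    means of log-normalized expression used by the DEG filters, read off
    the results table (comparisons a and d jointly cover all four
    conditions).

    ``genes="all"`` profiles every tested gene instead of the DEG unions --
    useful for comparing scores of hit genes against the background.
    """
    rows = []
    clusters = sorted({c for (c, _comp) in degsets})
    for cluster in clusters:
        sub = results[results["cluster"] == cluster]
        if genes == "union":
            sets = [degsets[(cluster, comp)] for comp in "abcd"
                    if (cluster, comp) in degsets]
            gene_list = union_degs(sets)
        elif genes == "all":
            gene_list = sorted(sub["gene"].unique())
        else:
            raise InputError("genes must be 'union' or 'all'")
        if not gene_list:
            continue
        fc = sub.pivot(index="gene", columns="comparison", values="log2fc")
        m1 = sub.pivot(index="gene", columns="comparison", values="mean_1")
        m2 = sub.pivot(index="gene", columns="comparison", values="mean_2")
        for gene in gene_list:
            if gene not in fc.index:
                continue
            fcs = [fc.at[gene, c] if c in fc.columns else np.nan for c in "abcd"]
            if not all(np.isfinite(v) for v in fcs):
                continue
            # comparison a = (Bl Ctrl, Bl Stress), d = (ELA Ctrl, ELA Stress)
            raw_means = (m1.at[gene, "a"], m2.at[gene, "a"],
                         m1.at[gene, "d"], m2.at[gene, "d"])
            cm = scale_condition_means(raw_means)
            raw_scores = pattern_type_scores(cm, combine=combine, clamp=False)
            clamped = {k: max(0.0, v) for k, v in raw_scores.items()}
            label, tie = classify_pattern(clamped)
            row = {
                "gene": gene,
                "cluster": cluster,
                "fc_a": fcs[0], "fc_b": fcs[1], "fc_c": fcs[2], "fc_d": fcs[3],
                "mean_bl_ctrl": raw_means[0], "mean_bl_stress": raw_means[1],
                "mean_ela_ctrl": raw_means[2], "mean_ela_stress": raw_means[3],
                "pattern_score": pattern_score(*fcs),
                "assigned_type": label,
                "tie": tie,
            }
            for k in PATTERN_LABELS:
                row[f"score_{k}"] = clamped[k]
                row[f"raw_{k}"] = raw_scores[k]
            rows.append(row)
    profiles = pd.DataFrame(rows)
    if profiles.empty:
        return profiles
    profiles["tier"] = ""
    for cluster, grp in profiles.groupby("cluster"):
        if len(grp) >= 4:
            top, mid, low = split_by_score(grp)
            profiles.loc[profiles["cluster"].eq(cluster)
                         & profiles["gene"].isin(top), "tier"] = "top25"
            profiles.loc[profiles["cluster"].eq(cluster)
                         & profiles["gene"].isin(mid), "tier"] = "mid50"
            profiles.loc[profiles["cluster"].eq(cluster)
                         & profiles["gene"].isin(low), "tier"] = "low25"
    return profiles.sort_values(["cluster", "gene"]).reset_index(drop=True)


def _sorted_by_score(profiles: pd.DataFrame, ascending: bool) -> pd.DataFrame:
    # ties broken lexicographically by gene id, deterministically
    return profiles.sort_values(
        ["pattern_score", "gene"], ascending=[ascending, True],
        kind="mergesort").reset_index(drop=True)


def rank_genes(profiles: pd.DataFrame, n: int = 30,
               direction: str = "top") -> list[str]:
    """The ``n`` highest (or lowest) PatternScore genes of one cluster."""
    if direction not in ("top", "bottom"):
        raise InputError("direction must be 'top' or 'bottom'")
    if profiles["cluster"].nunique() > 1:
        raise InputError("rank_genes expects profiles from a single cluster")
    if n > len(profiles):
        warnings.warn(
            f"requested {n} genes but only {len(profiles)} available",
            stacklevel=2)
        n = len(profiles)
    s = _sorted_by_score(profiles, ascending=(direction == "bottom"))
    return s["gene"].head(n).tolist()


def split_by_score(profiles: pd.DataFrame) -> tuple[list[str], list[str], list[str]]:
    """Partition genes by PatternScore into top 25% / middle 50% / bottom 25%.

    Tail sizes are ``floor(n / 4)`` each; the remainder forms the middle.
    Boundary ties follow the global sort order (score desc, then gene id),
    so partition sizes are deterministic.
    """
    n = len(profiles)
    if n < 4:
        raise InputError("need at least 4 genes to form score tiers")
    k = n // 4
    s = _sorted_by_score(profiles, ascending=False)
    genes = s["gene"].tolist()
    return genes[:k], genes[k:n - k], genes[n - k:]


def cluster_patterning_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster PatternScore distribution and per-type score totals.

    One row per cluster plus a pooled ``all`` reference row; columns give
    the gene count, mean / median / quartiles of the PatternScore, and the
    summed clamped score of each pattern type.
    """
    if profiles.empty:
        raise InputError("no profiles to summarize")

    def _row(name: str, grp: pd.DataFrame) -> dict:
        q1, med, q3 = np.percentile(grp["pattern_score"], [25, 50, 75])
        row = {
            "cluster": name,
            "n_genes": len(grp),
            "mean_score": float(grp["pattern_score"].mean()),
            "q25": float(q1), "median_score": float(med), "q75": float(q3),
        }
        for k in PATTERN_LABELS:
            row[f"total_{k}"] = float(grp[f"score_{k}"].sum())
        return row

    rows = [_row(c, g) for c, g in profiles.groupby("cluster")]
    rows.append(_row("all", profiles))
    return pd.DataFrame(rows)
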