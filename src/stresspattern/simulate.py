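"""Synthetic data with known ground truth.

Three generators emulate the study design the analysis assumes:

* :func:`generate_counts` -- a negative-binomial gene x cell count matrix
  for the 2x2 factorial (baseline/ELA x control/stress) with 4 conditions
  x ``n_groups`` replicate samples, several cell clusters of unequal size,
  a group-confounded batch effect, mitochondrial genes, and genes whose
  four condition means follow one of the eight canonical patterning
  templates (chronic / inverted / primed / blunted, up and down).
* :func:`generate_dominance` -- daily dyadic chase matrices for a group of
  animals whose win probabilities follow a logistic function of true rank
  difference.
* :func:`generate_tube_test` -- per-animal tube-test behavioural records
  (wins, pushes, percent time moving forward / retreating) for
  dominant/subordinate pairs.

All outputs are bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from stresspattern.containers import CONDITIONS, CountMatrix, InputError

LN2 = float(np.log(2.0))

#: Canonical condition-mean templates over (Bl Ctrl, Bl Stress, ELA Ctrl,
#: ELA Stress).  0 = low, 1 = high; "inverted" puts both controls at the
#: intermediate level with opposite-direction stress responses.
PATTERN_TEMPLATES: dict[str, tuple[float, float, float, float]] = {
    "ChronicUp": (0.0, 1.0, 1.0, 1.0),
    "ChronicDown": (1.0, 0.0, 0.0, 0.0),
    "InvertedUp": (0.5, 0.0, 0.5, 1.0),
    "InvertedDown": (0.5, 1.0, 0.5, 0.0),
    "PrimedUp": (0.0, 0.0, 0.0, 1.0),
    "PrimedDown": (1.0, 1.0, 1.0, 0.0),
    "BluntedUp": (0.0, 1.0, 0.0, 0.0),
    "BluntedDown": (1.0, 0.0, 1.0, 1.0),
    "Null": (0.0, 0.0, 0.0, 0.0),
}


@dataclass
class SimDesign:
    """Parameters of the factorial count simulation.

    ``cells_per_cluster_per_sample`` may be a single integer or one value
    per cluster; the default gives cluster totals of 1440 / 720 / 240 cells
    across the 12 samples, so the 300-cell cluster-eligibility rule is
    exercised in both directions.  ``nb_dispersion`` is the negative
    binomial size parameter theta (variance = mu + mu^2/theta).
    ``batch_sd`` is the standard deviation of the per-group additive offset
    on the log-mean scale; each group contributes one sample per condition,
    so batch is confounded with nothing but group, as in the study design
    this emulates.
    """

    n_clusters: int = 3
    cells_per_cluster_per_sample: int | Sequence[int] = (120, 60, 20)
    n_genes: int = 2000
    n_groups: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    baseline_log_mean_range: tuple[float, float] = (-2.0, 1.5)
    nb_dispersion: float = 2.0
    batch_sd: float = 0.15
    mito_fraction_mean: float = 0.08
    mito_gene_fraction: float = 0.05
    cluster_effect_sd: float = 0.3
    size_factor_sd: float = 0.35
    injected_base_log_mean: float = 0.5
    seed: int = 0

    def cells_per_cluster(self) -> list[int]:
        c = self.cells_per_cluster_per_sample
        if isinstance(c, (int, np.integer)):
            per = [int(c)] * self.n_clusters
        else:
            per = [int(x) for x in c]
            if len(per) != self.n_clusters:
                raise InputError(
                    "cells_per_cluster_per_sample must be scalar or have one "
                    f"entry per cluster ({self.n_clusters}), got {len(per)}"
                )
        if any(x <= 0 for x in per):
            raise InputError("cells per cluster per sample must be positive")
        return per

    def validate(self) -> None:
        if self.n_clusters < 1 or self.n_genes < 1 or self.n_groups < 1:
            raise InputError("n_clusters, n_genes and n_groups must be positive")
        if self.nb_dispersion <= 0:
            raise InputError("nb_dispersion must be positive")
        if self.batch_sd < 0 or self.size_factor_sd < 0:
            raise InputError("standard deviations must be non-negative")
        if not 0 <= self.mito_fraction_mean < 1:
            raise InputError("mito_fraction_mean must be in [0, 1)")
        self.cells_per_cluster()


@dataclass
class InjectedPattern:
    """A ground-truth expression pattern planted in one gene of one cluster.

    ``effect_size`` is the log2-scale separation between the template's
    "high" and "low" condition means.
    """

    gene_index: int
    cluster_index: int
    pattern_type: str
    effect_size: float = 1.5

    def __post_init__(self) -> None:
        if self.pattern_type not in PATTERN_TEMPLATES:
            raise InputError(
                f"unknown pattern_type {self.pattern_type!r}; "
                f"known types: {sorted(PATTERN_TEMPLATES)}"
            )
        if self.effect_size < 0:
            raise InputError("effect_size must be non-negative")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated count matrix."""

    genes: pd.DataFrame  #: injected (gene, cluster, pattern, effect, 4 true means)
    cells: pd.DataFrame  #: per-cell sample / condition / group / cluster
    batch_effects: pd.DataFrame  #: per-group log-scale offset actually drawn


def default_patterns(design: SimDesign, n_per_type: int = 4,
                     effect_size: float = 1.5) -> list[InjectedPattern]:
    """A standard injection set: ``n_per_type`` genes of each of the eight
    pattern types in every cluster, at non-overlapping gene indices."""
    patterns: list[InjectedPattern] = []
    idx = 0
    types = [t for t in PATTERN_TEMPLATES if t != "Null"]
    for k in range(design.n_clusters):
        for t in types:
            for _ in range(n_per_type):
                patterns.append(InjectedPattern(idx, k, t, effect_size))
                idx += 1
    if idx > design.n_genes:
        raise InputError("not enough genes for the requested injection set")
    return patterns


def generate_counts(design: SimDesign,
                    patterns: Sequence[InjectedPattern] = (),
                    ) -> tuple[CountMatrix, SimTruth]:
    """Draw a gene x cell count matrix from the factorial NB model.

    For cell ``c`` in cluster ``k``, sample ``s`` (condition ``t``, group
    ``g``) the count of gene ``j`` is NB with mean
    ``exp(base_jk + template_j[t] * effect * ln 2 + batch_g) * size_factor_c``
    and dispersion ``design.nb_dispersion``.  Mitochondrial genes are
    rescaled per cell so the expected mitochondrial share follows a Beta
    distribution centred on ``design.mito_fraction_mean``, giving the QC
    stage both passing and failing cells.
    """
    design.validate()
    for p in patterns:
        if not 0 <= p.gene_index < design.n_genes:
            raise InputError(f"pattern gene_index {p.gene_index} out of range")
        if not 0 <= p.cluster_index < design.n_clusters:
            raise InputError(f"pattern cluster_index {p.cluster_index} out of range")

    rng = np.random.default_rng(design.seed)
    n_genes = design.n_genes
    per_cluster = design.cells_per_cluster()
    conditions = list(design.conditions)
    n_samples = len(conditions) * design.n_groups

    # Sample table: one sample per (group, condition).
    samples = pd.DataFrame(
        [
            {
                "sample": f"g{g + 1}_{cond.replace(' ', '')}",
                "condition": cond,
                "group": f"g{g + 1}",
            }
            for g in range(design.n_groups)
            for cond in conditions
        ]
    )
    assert len(samples) == n_samples

    lo, hi = design.baseline_log_mean_range
    base = rng.uniform(lo, hi, size=n_genes)
    cluster_shift = rng.normal(0.0, design.cluster_effect_sd,
                               size=(design.n_clusters, n_genes))
    batch = rng.normal(0.0, design.batch_sd, size=design.n_groups)

    mito_n = int(round(design.mito_gene_fraction * n_genes))
    mito_idx = rng.choice(n_genes, size=mito_n, replace=False) if mito_n else np.array([], int)
    mito_mask = np.zeros(n_genes, dtype=bool)
    mito_mask[mito_idx] = True

    # Per-(gene, cluster) pattern templates; injected genes get a fixed,
    # comfortably expressed baseline so the planted effect is observable.
    offsets = np.zeros((design.n_clusters, n_genes, len(conditions)))
    injected_base = np.full((design.n_clusters, n_genes), np.nan)
    truth_rows = []
    seen: set[tuple[int, int]] = set()
    for p in patterns:
        key = (p.cluster_index, p.gene_index)
        if key in seen:
            raise InputError(f"duplicate injection at cluster {key[0]}, gene {key[1]}")
        seen.add(key)
        template = np.array(PATTERN_TEMPLATES[p.pattern_type])
        offsets[p.cluster_index, p.gene_index, :] = template * p.effect_size * LN2
        injected_base[p.cluster_index, p.gene_index] = design.injected_base_log_mean
        true_means = np.exp(design.injected_base_log_mean
                            + template * p.effect_size * LN2)
        truth_rows.append({
            "gene": f"gene{p.gene_index:05d}",
            "cluster": f"cluster{p.cluster_index + 1}",
            "pattern_type": p.pattern_type,
            "effect_size": p.effect_size,
            **{f"mean_{c.replace(' ', '_')}": m for c, m in zip(conditions, true_means)},
        })

    blocks = []
    cell_rows = []
    cell_counter = 0
    theta = design.nb_dispersion
    for k in range(design.n_clusters):
        base_k = base + cluster_shift[k]
        inj = injected_base[k]
        base_k = np.where(np.isnan(inj), base_k, inj)
        n_cells_k = per_cluster[k] * n_samples
        # log-mean per gene per cell within this cluster
        log_mu = np.empty((n_genes, n_cells_k))
        col = 0
        for s_idx, srow in samples.iterrows():
            t_idx = conditions.index(srow["condition"])
            g_idx = int(srow["group"][1:]) - 1
            mu_s = base_k + offsets[k, :, t_idx] + batch[g_idx]
            nc = per_cluster[k]
            log_mu[:, col:col + nc] = mu_s[:, None]
            for _ in range(nc):
                cell_rows.append({
                    "barcode": f"cell{cell_counter:06d}",
                    "sample": srow["sample"],
                    "condition": srow["condition"],
                    "group": srow["group"],
                    "cluster": f"cluster{k + 1}",
                })
                cell_counter += 1
            col += nc
        mu = np.exp(log_mu)

        # Rescale mitochondrial rows per cell to a Beta-distributed target
        # share of expected depth.
        if mito_n:
            a = design.mito_fraction_mean * 30.0
            b = (1.0 - design.mito_fraction_mean) * 30.0
            f = rng.beta(a, b, size=n_cells_k)
            non_mito_sum = mu[~mito_mask, :].sum(axis=0)
            mito_sum = mu[mito_mask, :].sum(axis=0)
            scale = (f / (1.0 - f)) * non_mito_sum / np.maximum(mito_sum, 1e-12)
            mu[mito_mask, :] *= scale[None, :]

        size_f = rng.lognormal(0.0, design.size_factor_sd, size=n_cells_k)
        mu *= size_f[None, :]

        lam = rng.gamma(shape=theta, scale=mu / theta)
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))

    counts = sp.hstack(blocks, format="csr").astype(np.int64)
    cells = pd.DataFrame(cell_rows).set_index("barcode")
    genes = pd.DataFrame(
        {
            "symbol": [("mt-" if mito_mask[i] else "") + f"gene{i:05d}"
                       for i in range(n_genes)],
            "mito": mito_mask,
        },
        index=pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene"),
    )
    truth = SimTruth(
        genes=pd.DataFrame(truth_rows),
        cells=cells.copy(),
        batch_effects=pd.DataFrame(
            {"group": [f"g{g + 1}" for g in range(design.n_groups)],
             "log_offset": batch}
        ),
    )
    return CountMatrix(counts, cells, genes), truth


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def generate_dominance(n_animals: int,
                       true_ranks: Sequence[int] | None = None,
                       steepness: float = 2.0,
                       n_days: int = 4,
                       interactions_per_day: int = 10,
                       seed: int = 0,
                       ) -> tuple[list[pd.DataFrame], np.ndarray]:
    """Simulate daily chase matrices for one group of animals.

    ``true_ranks[i]`` is the rank of animal ``i`` (1 = most dominant).  In
    each dyad each interaction is won by animal ``i`` with probability
    ``logistic(steepness * (rank_j - rank_i))``; ``steepness = 0`` gives
    fair coin flips, large steepness a deterministic transitive hierarchy.

    Returns one wins matrix per day (entry ``(i, j)`` = chases of ``i``
    over ``j``) and the rank vector used.
    """
    if n_animals < 2:
        raise InputError("need at least 2 animals")
    if steepness < 0:
        raise InputError("steepness must be non-negative")
    if n_days < 1 or interactions_per_day < 1:
        raise InputError("n_days and interactions_per_day must be positive")
    if true_ranks is None:
        ranks = np.arange(1, n_animals + 1)
    else:
        ranks = np.asarray(true_ranks, dtype=int)
        if sorted(ranks.tolist()) != list(range(1, n_animals + 1)):
            raise InputError("true_ranks must be a permutation of 1..n_animals")
    rng = np.random.default_rng(seed)
    animals = [f"animal{i + 1}" for i in range(n_animals)]
    days = []
    for _ in range(n_days):
        wins = np.zeros((n_animals, n_animals), dtype=int)
        for i in range(n_animals):
            for j in range(i + 1, n_animals):
                p_i = _logistic(steepness * (ranks[j] - ranks[i]))
                w_i = rng.binomial(interactions_per_day, p_i)
                wins[i, j] = w_i
                wins[j, i] = interactions_per_day - w_i
        days.append(pd.DataFrame(wins, index=animals, columns=animals))
    return days, ranks


def generate_tube_test(n_pairs: int,
                       rank_gap: float = 2.0,
                       n_days: int = 3,
                       bouts_per_day: int = 3,
                       seed: int = 0) -> pd.DataFrame:
    """Simulate tube-test records for ``n_pairs`` dominant/subordinate pairs.

    Within a pair the putatively dominant animal wins each bout with
    probability ``logistic(rank_gap)``; ``rank_gap = 0`` gives a fair coin,
    ``rank_gap = inf`` a deterministic winner.  Pushes scale with wins, and
    the expected percent time moving forward (retreating) increases
    (decreases) with the animal's win share, so a bout's winner has forward
    tendency at least its retreat tendency under the generative means.

    Returns one row per animal with total ``wins``, ``pushes``, mean
    ``forward`` / ``retreat`` percentages and ``n_tests``.
    """
    if n_days < 1:
        raise InputError("n_days must be >= 1")
    if n_pairs < 1 or bouts_per_day < 1:
        raise InputError("n_pairs and bouts_per_day must be positive")
    rng = np.random.default_rng(seed)
    n_bouts = n_days * bouts_per_day
    p_dom = float(_logistic(rank_gap))
    rows = []
    for p in range(n_pairs):
        wins_dom = int(rng.binomial(n_bouts, p_dom))
        for which, wins in (("dom", wins_dom), ("sub", n_bouts - wins_dom)):
            share = wins / n_bouts
            pushes = int(rng.poisson(1.0 + 3.0 * share))
            forward = float(np.clip(40.0 + 40.0 * share + rng.normal(0, 3), 0, 100))
            retreat = float(np.clip(45.0 - 35.0 * share + rng.normal(0, 3), 0, 100))
            rows.append({
                "pair": f"pair{p + 1}",
                "animal": f"pair{p + 1}_{which}",
                "wins": wins,
                "pushes": pushes,
                "forward": forward,
                "retreat": retreat,
                "n_tests": n_bouts,
            })
    return pd.DataFrame(rows)
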