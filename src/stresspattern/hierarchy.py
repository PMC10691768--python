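"""Social-dominance statistics: David's score and tube-test z-scores.

David's score summarizes a group's dominance structure from dyadic win
proportions ``P_ij``:

    w_i  = sum_j P_ij          (dyadic wins)
    w2_i = sum_j P_ij * w_j    (wins weighted by opponents' wins)
    l_i  = sum_j P_ji          (losses)
    l2_i = sum_j P_ji * l_j
    DS_i = w_i + w2_i - l_i - l2_i

Scores sum to zero over the group; higher means more dominant.  Daily
scores are summed into a cumulative score, and animals are ranked alpha,
beta, gamma, sigma (rank 1..n in general).

The tube-test composite hierarchy score standardizes each behaviour (wins,
pushes, percent time moving forward, percent time retreating) across the
cohort as z = (x - mu) / sigma with the population (divisor n) standard
deviation, then averages the four z-scores.  Higher indicates higher rank.
Retreating enters with a configurable sign (default +1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stresspattern.containers import InputError

RANK_LABELS = ("alpha", "beta", "gamma", "sigma")


def _as_win_matrix(m) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, pd.DataFrame):
        wins = m.to_numpy(dtype=float)
        animals = [str(a) for a in m.index]
        if list(m.columns.astype(str)) != animals:
            raise InputError("win matrix rows and columns must list the same animals")
    else:
        wins = np.asarray(m, dtype=float)
        animals = [f"animal{i + 1}" for i in range(wins.shape[0])]
    if wins.ndim != 2 or wins.shape[0] != wins.shape[1]:
        raise InputError("win matrix must be square")
    if np.any(wins < 0):
        raise InputError("win counts must be non-negative")
    if np.any(np.diag(wins) != 0):
        raise InputError("win matrix must have a zero diagonal")
    return wins, animals


def dyadic_proportions(m) -> pd.DataFrame:
    """P_ij = wins_ij / (wins_ij + wins_ji); untouched dyads get 0 both ways."""
    wins, animals = _as_win_matrix(m)
    total = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(total > 0, wins / np.maximum(total, 1e-300), 0.0)
    np.fill_diagonal(P, 0.0)
    return pd.DataFrame(P, index=animals, columns=animals)


def david_score(P: pd.DataFrame) -> pd.DataFrame:
    """David's score components from a dyadic proportion matrix."""
    Pm = P.to_numpy(dtype=float)
    w = Pm.sum(axis=1)
    l = Pm.sum(axis=0)
    w2 = Pm @ w
    l2 = Pm.T @ l
    ds = w + w2 - l - l2
    return pd.DataFrame(
        {"w": w, "w2": w2, "l": l, "l2": l2, "DS": ds},
        index=P.index,
    )


def cumulative_ranks(daily: list) -> pd.DataFrame:
    """Cumulative David's score over days, with rank labels.

    Animals are ranked by descending cumulative DS; ties are broken by
    total wins, then by id order, and flagged.  For four animals ranks are
    labelled alpha / beta / gamma / sigma; otherwise ``rank1..rankN``.
    """
    if not daily:
        raise InputError("need at least one daily matrix")
    first_wins, animals = _as_win_matrix(daily[0])
    cum_ds = np.zeros(len(animals))
    total_wins = np.zeros(len(animals))
    for day in daily:
        wins, ids = _as_win_matrix(day)
        if ids != animals:
            raise InputError("inconsistent animal ids across days")
        P = dyadic_proportions(day)
        cum_ds += david_score(P)["DS"].to_numpy()
        total_wins += wins.sum(axis=1)

    order = sorted(range(len(animals)),
                   key=lambda i: (-cum_ds[i], -total_wins[i], animals[i]))
    rank = np.empty(len(animals), dtype=int)
    for pos, i in enumerate(order):
        rank[i] = pos + 1
    ds_rounded = np.round(cum_ds, 12)
    tied = pd.Series(ds_rounded).duplicated(keep=False).to_numpy()
    if len(animals) == 4:
        labels = [RANK_LABELS[r - 1] for r in rank]
    else:
        labels = [f"rank{r}" for r in rank]
    return pd.DataFrame(
        {"cumulative_DS": cum_ds, "total_wins": total_wins,
         "rank": rank, "label": labels, "tie": tied},
        index=pd.Index(animals, name="animal"),
    )


def zscore(x, population: bool = True) -> tuple[np.ndarray, bool]:
    """Standardize a cohort vector: (x - mean) / sd.

    Uses the population (divisor n) standard deviation by default.  A
    constant vector returns all zeros with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InputError("zscore needs at least 2 values")
    mu = x.mean()
    sd = x.std(ddof=0 if population else 1)
    if sd == 0:
        return np.zeros_like(x), True
    return (x - mu) / sd, False


def hierarchy_score(records: pd.DataFrame,
                    retreat_sign: float = 1.0,
                    population_sd: bool = True) -> pd.DataFrame:
    """Composite tube-test hierarchy score per animal.

    Each behaviour (wins, pushes, forward, retreat) is z-scored across the
    cohort; the composite is their mean, with the retreat component
    multiplied by ``retreat_sign`` (default +1, i.e. summed like the
    others; set -1 to count retreating against an animal's rank).  Higher
    scores indicate higher social rank.  All animals must have the same
    number of tests.
    """
    required = {"animal", "wins", "pushes", "forward", "retreat", "n_tests"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"records missing columns: {sorted(missing)}")
    if len(records) < 2:
        raise InputError("need at least 2 animals")
    if records["n_tests"].nunique() != 1:
        raise InputError("n_tests must be equal across animals")
    out = pd.DataFrame({"animal": records["animal"]})
    components = []
    for col, sign in (("wins", 1.0), ("pushes", 1.0),
                      ("forward", 1.0), ("retreat", retreat_sign)):
        z, _deg = zscore(records[col].to_numpy(), population=population_sd)
        out[f"z_{col}"] = z
        components.append(sign * z)
    out["hierarchy_score"] = np.mean(components, axis=0)
    return out
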