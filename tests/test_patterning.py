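"""Pattern score, the eight type-score formulas, classification and tiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stresspattern import (
    InputError,
    PATTERN_LABELS,
    build_pattern_profiles,
    classify_pattern,
    cluster_patterning_summary,
    pattern_score,
    pattern_type_scores,
    rank_genes,
    scale_condition_means,
    split_by_score,
    union_degs,
)
from stresspattern.de import DEGSet


def type_scores_reference(bl_ctrl, bl_stress, ela_ctrl, ela_stress):
    """Independent re-typing of the eight formulas (second path, no clamp)."""
    d_bl = bl_stress - bl_ctrl
    d_ela = ela_stress - ela_ctrl
    mean_ela = (ela_stress + ela_ctrl) / 2.0
    mean_bl = (bl_ctrl + bl_stress) / 2.0
    return {
        "ChronicUp": d_bl - abs(d_ela) - abs(bl_stress - mean_ela),
        "ChronicDown": -d_bl - abs(d_ela) - abs(bl_stress - mean_ela),
        "InvertedUp": -d_bl + d_ela - abs(bl_ctrl - ela_ctrl),
        "InvertedDown": d_bl - d_ela - abs(bl_ctrl - ela_ctrl),
        "PrimedUp": d_ela - abs(d_bl) - abs(ela_ctrl - mean_bl),
        "PrimedDown": -d_ela - abs(d_bl) - abs(ela_ctrl - mean_bl),
        "BluntedUp": d_bl - abs(d_ela) - abs(bl_ctrl - mean_ela),
        "BluntedDown": -d_bl - abs(d_ela) - abs(bl_ctrl - mean_ela),
    }


unit = st.floats(0, 1, allow_nan=False)


class TestPatternScore:
    @pytest.mark.parametrize("fc,expected", [
        ((0, 0, 0, 0), 0.0),
        ((1, 0, 0, 1), 0.0),   # same stress response both backgrounds
        ((1, 0.5, -0.5, -1), 3.0),
    ])
    def test_hand_values(self, fc, expected):
        assert pattern_score(*fc) == pytest.approx(expected)

    def test_missing_component_rejected(self):
        with pytest.raises(InputError):
            pattern_score(1.0, np.nan, 0.0, 0.0)

    @settings(derandomize=True, max_examples=300)
    @given(st.tuples(*[st.floats(-5, 5) for _ in range(4)]))
    def test_swap_invariance(self, fc):
        a, b, c, d = fc
        assert pattern_score(a, b, c, d) == pytest.approx(
            pattern_score(d, c, b, a))


class TestScaling:
    def test_direct_division(self):
        cm = scale_condition_means((2, 4, 8, 8))
        assert cm.scaled == (0.25, 0.5, 1.0, 1.0)
        assert not cm.degenerate

    def test_zero_case_flagged(self):
        cm = scale_condition_means((0, 0, 0, 0))
        assert cm.scaled == (0, 0, 0, 0) and cm.degenerate

    def test_identity_and_negatives(self):
        assert scale_condition_means((1, 1, 1, 1)).scaled == (1, 1, 1, 1)
        with pytest.raises(InputError):
            scale_condition_means((1, -1, 1, 1))


class TestTypeScores:
    def test_flat_gene_scores_zero(self):
        cm = scale_condition_means((1, 1, 1, 1))
        assert all(v == 0 for v in pattern_type_scores(cm).values())

    @pytest.mark.parametrize("means,label", [
        ((0, 1, 1, 1), "ChronicUp"),
        ((0, 0, 0, 1), "PrimedUp"),
        ((0.5, 0, 0.5, 1), "InvertedUp"),
        ((0, 1, 0, 0), "BluntedUp"),
    ])
    def test_canonical_templates_score_one(self, means, label):
        scores = pattern_type_scores(scale_condition_means(means))
        assert scores[label] == pytest.approx(1.0)

    def test_hand_evaluations(self):
        # (0,1,1,1): ChronicUp = 1; PrimedUp raw = -1.5, clamped to 0
        cm = scale_condition_means((0, 1, 1, 1))
        raw = pattern_type_scores(cm, clamp=False)
        assert raw["ChronicUp"] == pytest.approx(1.0)
        assert raw["PrimedUp"] == pytest.approx(-1.5)
        assert pattern_type_scores(cm)["PrimedUp"] == 0.0
        # (0,0,0,1): PrimedUp = 1, ChronicUp clamps
        cm = scale_condition_means((0, 0, 0, 1))
        scores = pattern_type_scores(cm)
        assert scores["PrimedUp"] == pytest.approx(1.0)
        assert scores["ChronicUp"] == 0.0
        # (0.5,0,0.5,1): InvertedUp = 1
        cm = scale_condition_means((0.5, 0, 0.5, 1))
        assert pattern_type_scores(cm)["InvertedUp"] == pytest.approx(1.0)

    def test_degenerate_means_score_zero(self):
        cm = scale_condition_means((0, 0, 0, 0))
        assert set(pattern_type_scores(cm).values()) == {0.0}

    @settings(derandomize=True, max_examples=500)
    @given(st.tuples(unit, unit, unit, unit))
    def test_agrees_with_reference_evaluator(self, means):
        cm = scale_condition_means(means)
        if cm.degenerate:
            return
        raw = pattern_type_scores(cm, clamp=False)
        ref = type_scores_reference(*cm.scaled)
        for k in PATTERN_LABELS:
            assert raw[k] == pytest.approx(ref[k], abs=1e-12)

    @settings(derandomize=True, max_examples=300)
    @given(st.tuples(unit, unit, unit, unit))
    def test_label_swap_duality(self, means):
        """Exchanging the baseline and ELA condition pairs maps
        Primed <-> Blunted and InvertedUp <-> InvertedDown (pre-clamp)."""
        cm = scale_condition_means(means)
        if cm.degenerate:
            return
        b_c, b_s, e_c, e_s = cm.scaled
        swapped = scale_condition_means((e_c, e_s, b_c, b_s))
        orig = pattern_type_scores(cm, clamp=False)
        swap = pattern_type_scores(swapped, clamp=False)
        for a, b in (("PrimedUp", "BluntedUp"), ("PrimedDown", "BluntedDown"),
                     ("BluntedUp", "PrimedUp"), ("BluntedDown", "PrimedDown"),
                     ("InvertedUp", "InvertedDown"),
                     ("InvertedDown", "InvertedUp")):
            assert swap[a] == pytest.approx(orig[b], abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(unit, unit, unit, unit),
           st.floats(0.01, 100, allow_nan=False))
    def test_scale_invariance(self, means, factor):
        a = pattern_type_scores(scale_condition_means(means))
        b = pattern_type_scores(
            scale_condition_means(tuple(m * factor for m in means)))
        for k in PATTERN_LABELS:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_primed_template_ties_with_inverted(self):
        """Structural degeneracy of the formulas: a pure primed-up gene
        scores identically for PrimedUp and InvertedUp, for any low level."""
        for low in (0.0, 0.3, 0.6):
            scores = pattern_type_scores(
                scale_condition_means((low, low, low, 1.0)))
            assert scores["PrimedUp"] == pytest.approx(scores["InvertedUp"])


class TestClassify:
    def test_all_zero_is_none(self):
        assert classify_pattern({k: 0.0 for k in PATTERN_LABELS}) == ("none", False)

    def test_unique_max(self):
        scores = {k: 0.0 for k in PATTERN_LABELS}
        scores["PrimedUp"] = 1.0
        assert classify_pattern(scores) == ("PrimedUp", False)

    def test_tie_break_order(self):
        scores = {k: 0.0 for k in PATTERN_LABELS}
        scores["ChronicUp"] = scores["InvertedDown"] = 0.4
        assert classify_pattern(scores) == ("ChronicUp", True)


class TestUnion:
    def test_hand_union(self):
        sets = [DEGSet("c1", "a", up=["A", "B"]), DEGSet("c1", "b", up=["B"]),
                DEGSet("c1", "c"), DEGSet("c1", "d", down=["C"])]
        assert union_degs(sets) == ["A", "B", "C"]

    def test_degenerate_and_idempotent(self):
        assert union_degs([DEGSet("c1", "a")] * 4) == []
        same = [DEGSet("c1", c, up=["X"]) for c in "abcd"]
        assert union_degs(same) == ["X"]

    def test_mixed_clusters_rejected(self):
        with pytest.raises(InputError):
            union_degs([DEGSet("c1", "a", up=["A"]),
                        DEGSet("c2", "b", up=["B"])])


def _profiles(scores, cluster="c1"):
    df = pd.DataFrame({
        "gene": [f"g{i:03d}" for i in range(len(scores))],
        "cluster": cluster,
        "pattern_score": scores,
    })
    for k in PATTERN_LABELS:
        df[f"score_{k}"] = 0.0
    return df


class TestRankAndTiers:
    def test_top_ordering(self):
        p = _profiles([3.0, 2.0, 1.0])
        assert rank_genes(p, n=2) == ["g000", "g001"]
        assert rank_genes(p, n=2, direction="bottom") == ["g002", "g001"]

    def test_ties_lexicographic_and_overflow(self):
        p = _profiles([1.0, 1.0, 1.0])
        assert rank_genes(p, n=3) == ["g000", "g001", "g002"]
        with pytest.warns(UserWarning):
            out = rank_genes(p, n=10)
        assert len(out) == 3
        assert rank_genes(p, n=0) == []

    def test_split_sizes(self):
        top, mid, low = split_by_score(_profiles([8, 7, 6, 5, 4, 3, 2, 1]))
        assert (len(top), len(mid), len(low)) == (2, 4, 2)
        assert top == ["g000", "g001"] and low == ["g006", "g007"]
        top, mid, low = split_by_score(_profiles(list(range(100))))
        assert (len(top), len(mid), len(low)) == (25, 50, 25)

    def test_split_tied_boundary_sizes_stable(self):
        top, mid, low = split_by_score(_profiles([5, 4, 4, 4, 4, 4, 4, 1]))
        assert (len(top), len(mid), len(low)) == (2, 4, 2)
        assert top == ["g000", "g001"]  # tie resolved by gene id

    def test_split_needs_four(self):
        with pytest.raises(InputError):
            split_by_score(_profiles([1, 2, 3]))


class TestSummary:
    def test_arithmetic(self):
        s = cluster_patterning_summary(_profiles([1.0, 2.0, 3.0]))
        row = s[s["cluster"] == "c1"].iloc[0]
        assert row["mean_score"] == 2.0 and row["median_score"] == 2.0

    def test_identical_clusters_identical_rows(self):
        p = pd.concat([_profiles([1.0, 2.0], "cA"), _profiles([1.0, 2.0], "cB")],
                      ignore_index=True)
        s = cluster_patterning_summary(p).set_index("cluster")
        a = s.loc["cA"].drop("cluster", errors="ignore")
        b = s.loc["cB"].drop("cluster", errors="ignore")
        assert (a == b).all()


class TestProfilesEndToEnd:
    def test_injected_chronic_dominates_type_totals(self, default_run):
        """Clamped ChronicUp totals exceed every other family's total among
        genes planted as ChronicUp (recovery of the planted signal)."""
        prof = build_pattern_profiles(default_run["results"],
                                      default_run["degsets"])
        truth = default_run["truth"].genes
        merged = prof.merge(truth[["gene", "cluster", "pattern_type"]],
                            on=["gene", "cluster"], how="inner")
        chron = merged[merged["pattern_type"] == "ChronicUp"]
        assert len(chron) >= 4
        totals = {k: chron[f"score_{k}"].sum() for k in PATTERN_LABELS}
        assert max(totals, key=totals.get) == "ChronicUp"

    def test_chronic_and_inverted_assignments_recover(self, default_run):
        prof = build_pattern_profiles(default_run["results"],
                                      default_run["degsets"])
        truth = default_run["truth"].genes
        merged = prof.merge(truth[["gene", "cluster", "pattern_type"]],
                            on=["gene", "cluster"], how="inner")
        sub = merged[merged["pattern_type"].isin(
            ["ChronicUp", "ChronicDown", "InvertedUp", "InvertedDown"])]
        assert len(sub) >= 16
        assert (sub["assigned_type"] == sub["pattern_type"]).mean() >= 0.9

    def test_tiers_partition_each_cluster(self, default_run):
        prof = build_pattern_profiles(default_run["results"],
                                      default_run["degsets"])
        for _cl, grp in prof.groupby("cluster"):
            if len(grp) < 4:
                continue
            assert set(grp["tier"]) <= {"top25", "mid50", "low25"}
            n = len(grp)
            assert (grp["tier"] == "top25").sum() == n // 4
            assert (grp["tier"] == "low25").sum() == n // 4
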