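"""Comparative-Ct quantitation: replicate aggregation, hand-computed fold
changes, and the ANOVA/Tukey group comparison against sums-of-squares
oracles."""

import numpy as np
import pandas as pd
import pytest

from rgstable import (
    CtTable,
    aggregate_replicates,
    ddct_fold_change,
    group_compare,
)
from tests.conftest import make_ct


def ct_rows(entries):
    return CtTable(
        pd.DataFrame(
            entries, columns=["sample", "group", "gene", "replicate", "ct"]
        )
    )


# ----------------------------------------------------------------- aggregation

def test_aggregate_mean_sd_unflagged():
    ct = ct_rows(
        [("s1", "AK", "g", r, v) for r, v in enumerate([25.0, 25.2, 24.8], 1)]
    )
    agg = aggregate_replicates(ct)
    row = agg.iloc[0]
    assert row["ct_mean"] == pytest.approx(25.0)
    assert row["ct_sd"] == pytest.approx(0.2)
    assert not row["flagged"]


def test_aggregate_single_replicate_passthrough():
    agg = aggregate_replicates(ct_rows([("s1", "AK", "g", 1, 24.5)]))
    assert agg.iloc[0]["ct_mean"] == pytest.approx(24.5)
    assert np.isnan(agg.iloc[0]["ct_sd"])


def test_aggregate_flags_noisy_triplicate():
    agg = aggregate_replicates(
        ct_rows([("s1", "AK", "g", r, v) for r, v in enumerate([20.0, 26.0, 26.0], 1)])
    )
    assert agg.iloc[0]["ct_sd"] == pytest.approx(np.std([20, 26, 26], ddof=1))
    assert bool(agg.iloc[0]["flagged"])  # sd ~ 3.46 > 0.5


# ------------------------------------------------------------------------ ddCt

def lesion_vs_norm(target_lesion=24.0, target_norm=26.0, ref=20.0):
    mat = pd.DataFrame(
        {
            "L1": [target_lesion, ref],
            "L2": [target_lesion, ref],
            "N1": [target_norm, ref],
            "N2": [target_norm, ref],
        },
        index=["KRT17", "REF"],
    )
    groups = {"L1": "AK", "L2": "AK", "N1": "NORM", "N2": "NORM"}
    return make_ct(mat, groups)


def test_ddct_hand_computed_fold_4():
    # target 24 in lesion vs 26 in calibrator, ref 20 everywhere:
    # dCt = 4 vs 6, ddCt = -2, fold = 4
    res = ddct_fold_change(lesion_vs_norm(), "KRT17", ["REF"], "NORM")
    lesion = res.per_sample[res.per_sample["group"] == "AK"]
    assert np.allclose(lesion["ddct"], -2.0)
    assert np.allclose(lesion["fold"], 4.0)


def test_ddct_two_refs_equal_single_mean_ref():
    mat = pd.DataFrame(
        {
            "L1": [24.0, 20.0, 22.0, 21.0],
            "N1": [26.0, 20.0, 22.0, 21.0],
            "N2": [26.0, 20.0, 22.0, 21.0],
        },
        index=["T", "R1", "R2", "Rm"],
    )
    groups = {"L1": "AK", "N1": "NORM", "N2": "NORM"}
    ct = make_ct(mat, groups)
    two = ddct_fold_change(ct, "T", ["R1", "R2"], "NORM")
    one = ddct_fold_change(ct, "T", ["Rm"], "NORM")
    assert np.allclose(two.per_sample["fold"], one.per_sample["fold"])


def test_ddct_identical_cts_give_fold_one():
    mat = pd.DataFrame(
        {"s1": [25.0, 20.0], "s2": [25.0, 20.0], "s3": [25.0, 20.0], "s4": [25.0, 20.0]},
        index=["T", "R"],
    )
    groups = {"s1": "A", "s2": "A", "s3": "NORM", "s4": "NORM"}
    res = ddct_fold_change(make_ct(mat, groups), "T", ["R"], "NORM")
    assert np.allclose(res.per_sample["fold"], 1.0)


def test_calibrator_group_fold_geometric_mean_one(rng):
    mat = pd.DataFrame(
        rng.uniform(20, 30, size=(2, 6)),
        index=["T", "R"],
        columns=[f"s{j}" for j in range(6)],
    )
    groups = {f"s{j}": ("NORM" if j < 3 else "AK") for j in range(6)}
    res = ddct_fold_change(make_ct(mat, groups), "T", ["R"], "NORM")
    cal = res.per_sample[res.per_sample["group"] == "NORM"]["fold"]
    assert np.exp(np.mean(np.log(cal))) == pytest.approx(1.0)


def test_ddct_invariant_to_per_sample_ct_shift(rng):
    mat = pd.DataFrame(
        rng.uniform(20, 30, size=(3, 6)),
        index=["T", "R1", "R2"],
        columns=[f"s{j}" for j in range(6)],
    )
    groups = {f"s{j}": ("NORM" if j < 3 else "AK") for j in range(6)}
    base = ddct_fold_change(make_ct(mat, groups), "T", ["R1", "R2"], "NORM")
    shifted_mat = mat.copy()
    shifted_mat["s4"] += 3.7  # e.g. less cDNA loaded in one well series
    shifted = ddct_fold_change(make_ct(shifted_mat, groups), "T", ["R1", "R2"], "NORM")
    assert np.allclose(base.per_sample["fold"], shifted.per_sample["fold"])


def test_ddct_missing_gene_error():
    with pytest.raises(ValueError, match="absent"):
        ddct_fold_change(lesion_vs_norm(), "NOPE", ["REF"], "NORM")


def test_unstable_reference_biases_folds_opposite_its_drift():
    # the reference rises by 2 cycles in lesions (its expression drops
    # 4-fold); a flat target then shows a spurious 4-fold *decrease*...
    mat = pd.DataFrame(
        {
            "L1": [25.0, 22.0],
            "L2": [25.0, 22.0],
            "N1": [25.0, 20.0],
            "N2": [25.0, 20.0],
        },
        index=["T", "DRIFTER"],
    )
    groups = {"L1": "AK", "L2": "AK", "N1": "NORM", "N2": "NORM"}
    res = ddct_fold_change(make_ct(mat, groups), "T", ["DRIFTER"], "NORM")
    lesion_folds = res.per_sample[res.per_sample["group"] == "AK"]["fold"]
    assert np.allclose(lesion_folds, 4.0)  # bias opposite the reference drift


# ---------------------------------------------------------------- group compare

def test_identical_groups_p_one():
    mat = pd.DataFrame(
        {f"s{j}": [25.0, 20.0] for j in range(6)}, index=["T", "R"]
    )
    groups = {f"s{j}": ["A", "A", "B", "B", "NORM", "NORM"][j] for j in range(6)}
    res = ddct_fold_change(make_ct(mat, groups), "T", ["R"], "NORM")
    res = group_compare(res)
    assert res.anova_p == pytest.approx(1.0)
    assert np.allclose(res.tukey["p_adj"], 1.0)


def test_anova_f_matches_sums_of_squares_oracle():
    # classic 3-group toy data, computed through ddCt with a flat reference
    data = {"A": [4.0, 5.0, 6.0], "B": [7.0, 8.0, 9.0], "NORM": [1.0, 2.0, 3.0]}
    cols, groups = {}, {}
    j = 0
    for grp, dcts in data.items():
        for d in dcts:
            cols[f"s{j}"] = [20.0 + d, 20.0]
            groups[f"s{j}"] = grp
            j += 1
    mat = pd.DataFrame(cols, index=["T", "R"])
    res = group_compare(
        ddct_fold_change(make_ct(mat, groups), "T", ["R"], "NORM"), on="ddct"
    )
    # brute-force one-way ANOVA on the ddCt values
    arrays = [np.array(v) - 2.0 for v in data.values()]  # ddct = dct - mean(NORM dct)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    f_oracle = (ss_between / 2) / (ss_within / 6)
    from scipy.stats import f as fdist

    p_oracle = float(fdist.sf(f_oracle, 2, 6))
    assert res.anova_p == pytest.approx(p_oracle, rel=1e-10)


def test_two_group_tukey_matches_studentized_range():
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
    cols, groups = {}, {}
    for j, d in enumerate(np.concatenate([a, b])):
        cols[f"s{j}"] = [20.0 + d, 20.0]
        groups[f"s{j}"] = "A" if j < 5 else "NORM"
    mat = pd.DataFrame(cols, index=["T", "R"])
    res = group_compare(
        ddct_fold_change(make_ct(mat, groups), "T", ["R"], "NORM"), on="ddct"
    )
    from scipy.stats import studentized_range

    arrays = res.per_sample.groupby("group", sort=False)["ddct"].apply(np.array)
    x, y = arrays.iloc[0], arrays.iloc[1]
    s2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / 8
    qstat = abs(x.mean() - y.mean()) / np.sqrt(s2 / 5)
    p_oracle = float(studentized_range.sf(qstat, 2, 8))
    assert res.tukey["p_adj"].iloc[0] == pytest.approx(p_oracle, rel=1e-6)


def test_group_compare_degenerate_errors():
    mat = pd.DataFrame({"s1": [25.0, 20.0], "s2": [25.0, 20.0]}, index=["T", "R"])
    res = ddct_fold_change(
        make_ct(mat, {"s1": "A", "s2": "A"}), "T", ["R"], "A"
    )
    with pytest.raises(ValueError, match="2 groups"):
        group_compare(res)
    mat3 = pd.DataFrame(
        {"s1": [25.0, 20.0], "s2": [25.0, 20.0], "s3": [24.0, 20.0]}, index=["T", "R"]
    )
    res3 = ddct_fold_change(
        make_ct(mat3, {"s1": "A", "s2": "A", "s3": "B"}), "T", ["R"], "A"
    )
    with pytest.raises(ValueError, match="fewer than 2"):
        group_compare(res3)
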