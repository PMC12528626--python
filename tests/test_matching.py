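"""Coarsened-exact-matching engine: bins, rounds, repeats, feasibility."""

import numpy as np
import pandas as pd
import pytest

from pmcdr import CohortTable, IQCategory, compute_bins, match_all_categories, repeated_matching
from pmcdr.matching import BinSpec, _Pool, _match_keys, default_bins, match_round

from conftest import exam_frame, make_exam


def _frame(rows):
    return pd.DataFrame(rows, columns=["exam_id", "age", "psa", "facility", "biopsy_status"])


def test_quantile_bins_split_1_to_9_into_thirds():
    spec = compute_bins(list(range(1, 10)), 3, "x")
    assigned = {}
    for v in range(1, 10):
        assigned.setdefault(spec.assign(v), []).append(v)
    assert assigned == {0: [1, 2, 3], 1: [4, 5, 6], 2: [7, 8, 9]}


def test_constant_values_degenerate_to_single_bin_with_warning():
    with pytest.warns(UserWarning, match="distinct quantiles"):
        spec = compute_bins([5.0] * 10, 3, "x")
    assert spec.assign(5.0) == 0


def test_missing_values_get_the_dedicated_bin():
    spec = compute_bins([1.0, 2.0, 3.0, None], 3, "psa", missing_bin=True)
    assert spec.assign(None) == -1
    assert spec.assign(2.0) >= 0


def test_k_below_one_rejected():
    with pytest.raises(ValueError):
        compute_bins([1, 2, 3], 0)


def _setup(targets, pool):
    union = pd.concat([targets, pool], ignore_index=True)
    bins = default_bins(union)
    t_n, t_w = _match_keys(targets, bins)
    p_n, p_w = _match_keys(pool, bins)
    return list(zip(t_n, t_w)), _Pool(pool["exam_id"].tolist(), p_n, p_w)


def test_round_matches_each_target_to_its_exact_narrow_candidate():
    targets = _frame([("T1", 50.0, 4.0, "I", "naive"), ("T2", 80.0, 20.0, "II", "unknown")])
    pool = _frame([("C1", 50.0, 4.0, "I", "naive"), ("C2", 80.0, 20.0, "II", "unknown")])
    keys, p = _setup(targets, pool)
    res = match_round(targets, p, keys, np.random.default_rng(0))
    assert res is not None
    pairs = {t: (c, tier) for t, c, tier in res.pairs}
    assert pairs == {"T1": ("C1", "narrow"), "T2": ("C2", "narrow")}


def test_round_fails_whole_when_a_facility_is_absent_and_pool_is_unchanged():
    targets = _frame([("T1", 50.0, 4.0, "III", "naive")])
    pool = _frame([("C1", 50.0, 4.0, "I", "naive")])
    keys, p = _setup(targets, pool)
    assert match_round(targets, p, keys, np.random.default_rng(0)) is None
    assert all(p.available.values())  # failure consumes nothing


def test_wide_tier_used_when_narrow_has_no_candidate():
    # union ages {50,60,70,80}: narrow (k=6) isolates the 50-year-old target,
    # wide (k=3) puts C1 (60) into its bin; PSA all missing (shared bin)
    targets = _frame([("T1", 50.0, None, "I", "naive")])
    pool = _frame(
        [
            ("C1", 60.0, None, "I", "naive"),
            ("C2", 70.0, None, "I", "naive"),
            ("C3", 80.0, None, "I", "naive"),
        ]
    )
    keys, p = _setup(targets, pool)
    res = match_round(targets, p, keys, np.random.default_rng(0))
    assert res is not None
    (t, c, tier) = res.pairs[0]
    assert c == "C1" and tier == "wide"


def test_repeated_matching_unlimited_copies_reaches_max_rounds():
    targets = _frame([("T1", 50.0, 4.0, "I", "naive"), ("T2", 60.0, 8.0, "II", "unknown")])
    pool = _frame(
        [(f"C{i}_{j}", age, psa, fac, bs) for i, (age, psa, fac, bs) in
         enumerate([(50.0, 4.0, "I", "naive"), (60.0, 8.0, "II", "unknown")])
         for j in range(10)]
    )
    mc = repeated_matching(targets, pool, max_rounds=4, seed=0)
    assert mc.rounds_completed == 4
    assert mc.ratio == 4
    assert len(mc.control_ids) == 8


def test_no_control_reuse_and_exact_count_identity():
    rng = np.random.default_rng(42)
    targets = _frame(
        [(f"T{i}", float(rng.integers(50, 80)), float(rng.integers(2, 20)), "I", "naive") for i in range(10)]
    )
    pool = _frame(
        [(f"C{i}", float(rng.integers(50, 80)), float(rng.integers(2, 20)), "I", "naive") for i in range(200)]
    )
    mc = repeated_matching(targets, pool, max_rounds=8, seed=1)
    assert len(set(mc.control_ids)) == len(mc.control_ids)
    assert len(mc.control_ids) == mc.ratio * len(targets)
    # each completed round holds exactly one control per target
    per_round = mc.provenance.groupby("round")["target_id"].nunique()
    assert (per_round == len(targets)).all()


def test_matched_pairs_agree_exactly_on_facility_biopsy_and_recorded_tier_bins():
    rng = np.random.default_rng(3)
    rows_t, rows_p = [], []
    for i in range(12):
        rows_t.append(
            (f"T{i}", float(rng.integers(50, 80)), float(rng.integers(2, 20)),
             ["I", "II"][i % 2], ["naive", "unknown"][i % 2])
        )
    for i in range(150):
        rows_p.append(
            (f"C{i}", float(rng.integers(50, 80)),
             None if i % 7 == 0 else float(rng.integers(2, 20)),
             ["I", "II"][i % 2], ["naive", "unknown"][i % 2])
        )
    targets, pool = _frame(rows_t), _frame(rows_p)
    mc = repeated_matching(targets, pool, max_rounds=5, seed=9)
    assert mc.rounds_completed >= 1
    union = pd.concat([targets, pool], ignore_index=True)
    bins = default_bins(union)
    t_n, t_w = _match_keys(targets, bins)
    p_n, p_w = _match_keys(pool, bins)
    tkey = {tid: (n, w) for tid, n, w in zip(targets["exam_id"], t_n, t_w)}
    ckey = {cid: (n, w) for cid, n, w in zip(pool["exam_id"], p_n, p_w)}
    for _, row in mc.provenance.iterrows():
        tn, tw = tkey[row["target_id"]]
        cn, cw = ckey[row["control_id"]]
        assert tn[:2] == cn[:2]  # facility, biopsy_status always exact
        if row["tier"] == "narrow":
            assert tn == cn
        else:
            assert tw == cw


def test_empty_pool_gives_zero_rounds():
    targets = _frame([("T1", 50.0, 4.0, "I", "naive")])
    mc = repeated_matching(targets, _frame([]), max_rounds=5, seed=0)
    assert mc.rounds_completed == 0 and mc.control_ids == []


def test_overlapping_target_and_pool_ids_rejected():
    t = _frame([("X", 50.0, 4.0, "I", "naive")])
    with pytest.raises(ValueError, match="disjoint"):
        repeated_matching(t, t, seed=0)


def test_feasibility_agrees_with_bipartite_matching_oracle():
    """On <=6 targets x <=12 pool single-tier instances, a round can succeed
    for some seed iff a perfect bipartite matching exists (Hall condition,
    checked with networkx maximum matching)."""
    import networkx as nx

    rng = np.random.default_rng(2024)
    for trial in range(30):
        nt = int(rng.integers(1, 7))
        npool = int(rng.integers(1, 13))
        # age/psa constant -> only facility & biopsy define eligibility
        t_rows = [(f"T{i}", 60.0, 5.0, ["I", "II", "III"][rng.integers(3)],
                   ["naive", "unknown"][rng.integers(2)]) for i in range(nt)]
        p_rows = [(f"C{i}", 60.0, 5.0, ["I", "II", "III"][rng.integers(3)],
                   ["naive", "unknown"][rng.integers(2)]) for i in range(npool)]
        targets, pool = _frame(t_rows), _frame(p_rows)

        g = nx.Graph()
        g.add_nodes_from([f"T{i}" for i in range(nt)], bipartite=0)
        for i, (tid, _, _, tf, tb) in enumerate(t_rows):
            for cid, _, _, cf, cb in p_rows:
                if (tf, tb) == (cf, cb):
                    g.add_edge(tid, cid)
        matching = nx.bipartite.maximum_matching(g, top_nodes=[f"T{i}" for i in range(nt)])
        feasible = len(matching) // 2 == nt

        succeeded = False
        for seed in range(20):
            keys, p = _setup(targets, pool)
            if match_round(targets, p, keys, np.random.default_rng(seed)) is not None:
                succeeded = True
                break
        assert succeeded == feasible, f"trial {trial}: oracle {feasible}, engine {succeeded}"


def _graded_cohort():
    exams = []
    i = 0
    rng = np.random.default_rng(0)
    for cat, src, n in [
        (IQCategory.OPTIMAL, "model", 60),
        (IQCategory.OPTIMAL, "radiologist", 10),
        (IQCategory.MILD, "radiologist", 5),
        (IQCategory.MILD, "model", 5),
        (IQCategory.MODERATE, "radiologist", 4),
    ]:
        for _ in range(n):
            exams.append(
                make_exam(
                    i,
                    age=float(rng.integers(50, 80)),
                    facility="I",
                    biopsy_status="naive",
                    exam_iq=cat,
                    iq_source=src,
                )
            )
            i += 1
    return CohortTable(exams)


def test_match_all_categories_targets_are_radiologist_graded_and_pool_is_any_optimal():
    with pytest.warns(UserWarning, match="severe"):
        matched = match_all_categories(_graded_cohort(), seed=0, max_rounds=3)
    assert len(matched[IQCategory.SEVERE].target_ids) == 0
    mild = matched[IQCategory.MILD]
    assert len(mild.target_ids) == 5  # model-graded mild exams are not targets
    mod = matched[IQCategory.MODERATE]
    assert len(mod.target_ids) == 4
    # a control may appear in more than one category, never twice within one
    assert len(set(mild.control_ids)) == len(mild.control_ids)
    if set(mild.control_ids) & set(mod.control_ids):
        pass  # overlap across categories is allowed by design


def test_match_all_categories_is_deterministic_under_seed():
    with pytest.warns(UserWarning):
        a = match_all_categories(_graded_cohort(), seed=5, max_rounds=3)
    with pytest.warns(UserWarning):
        b = match_all_categories(_graded_cohort(), seed=5, max_rounds=3)
    for cat in a:
        assert a[cat].control_ids == b[cat].control_ids
        assert a[cat].provenance.equals(b[cat].provenance)
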