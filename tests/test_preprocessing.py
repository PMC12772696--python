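"""Merging, variance screening, covariate encoding, and split contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methconvt.data import BetaMatrix, SampleTable
from methconvt.preprocessing import (
    _largest_remainder,
    encode_covariates,
    intersect_and_merge,
    select_variable_cpgs,
    stratified_split,
)


def make_table(ids, diagnosis=None, tissue=None, age=None, cohort="c0"):
    n = len(ids)
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "diagnosis": diagnosis if diagnosis is not None else [0] * n,
                "age": age if age is not None else np.linspace(60, 80, n),
                "sex": [i % 2 for i in range(n)],
                "tissue": tissue if tissue is not None else [0] * n,
                "cohort": cohort,
            }
        )
    )


def make_beta(values, cpgs, ids):
    return BetaMatrix(np.asarray(values, float), cpgs, ids)


class TestIntersectAndMerge:
    def test_set_intersection_and_sample_stacking(self):
        rng = np.random.default_rng(0)
        b1 = make_beta(rng.random((3, 3)), ["cgA", "cgB", "cgC"], ["s1", "s2", "s3"])
        b2 = make_beta(rng.random((2, 3)), ["cgB", "cgC", "cgD"], ["s4", "s5"])
        merged, table = intersect_and_merge(
            [b1, b2], [make_table(b1.sample_ids), make_table(b2.sample_ids, cohort="c1")]
        )
        assert merged.cpg_ids == ["cgB", "cgC"]
        assert merged.n_samples == 5
        assert table.df["cohort"].tolist() == ["c0"] * 3 + ["c1"] * 2
        # values preserved through column alignment
        np.testing.assert_allclose(merged.values[3], b2.values[0, :2])

    def test_single_input_identity_up_to_reordering(self):
        rng = np.random.default_rng(1)
        b = make_beta(rng.random((2, 3)), ["cgC", "cgA", "cgB"], ["s1", "s2"])
        merged, _ = intersect_and_merge([b], [make_table(b.sample_ids)])
        assert merged.cpg_ids == ["cgA", "cgB", "cgC"]
        np.testing.assert_allclose(merged.values, b.values[:, [1, 2, 0]])

    def test_random_dropout_matches_set_oracle(self):
        rng = np.random.default_rng(2)
        universe = [f"cg{i:04d}" for i in range(200)]
        mats, tabs, kept_sets = [], [], []
        for c in range(3):
            keep = sorted(
                np.array(universe)[rng.random(200) > 0.3].tolist()
            )
            kept_sets.append(set(keep))
            ids = [f"c{c}_s{i}" for i in range(4)]
            mats.append(make_beta(rng.random((4, len(keep))), keep, ids))
            tabs.append(make_table(ids, cohort=f"c{c}"))
        merged, _ = intersect_and_merge(mats, tabs)
        assert set(merged.cpg_ids) == set.intersection(*kept_sets)

    def test_empty_intersection_names_worst_pair(self):
        b1 = make_beta([[0.1]], ["cgA"], ["s1"])
        b2 = make_beta([[0.2]], ["cgB"], ["s2"])
        with pytest.raises(ValueError, match="batch 0 and batch 1"):
            intersect_and_merge([b1, b2], [make_table(["s1"]), make_table(["s2"])])

    def test_duplicate_sample_id_rejected(self):
        b1 = make_beta([[0.1]], ["cgA"], ["s1"])
        b2 = make_beta([[0.2]], ["cgA"], ["s1"])
        with pytest.raises(ValueError, match="duplicate sample_id"):
            intersect_and_merge([b1, b2], [make_table(["s1"]), make_table(["s1"])])

    def test_associative_over_batches(self):
        rng = np.random.default_rng(3)
        mats = []
        tabs = []
        for c, cpgs in enumerate([["cgA", "cgB", "cgC"], ["cgB", "cgC", "cgD"],
                                  ["cgA", "cgB", "cgC", "cgD"]]):
            ids = [f"c{c}_s{i}" for i in range(2)]
            mats.append(make_beta(rng.random((2, len(cpgs))), cpgs, ids))
            tabs.append(make_table(ids, cohort=f"c{c}"))
        all_at_once, _ = intersect_and_merge(mats, tabs)
        step1, t1 = intersect_and_merge(mats[:2], tabs[:2])
        step2, _ = intersect_and_merge([step1, mats[2]], [t1, tabs[2]])
        assert step2.cpg_ids == all_at_once.cpg_ids


class TestSelectVariableCpgs:
    def test_matches_brute_force_per_tissue_sort(self):
        rng = np.random.default_rng(4)
        cpgs = [f"cg{i:03d}" for i in range(50)]
        ids = [f"s{i}" for i in range(20)]
        beta = make_beta(rng.random((20, 50)), cpgs, ids)
        tissue = [0] * 10 + [1] * 10
        sel = select_variable_cpgs(beta, make_table(ids, tissue=tissue), k=5)
        for t in (0, 1):
            rows = beta.values[np.array(tissue) == t]
            var = rows.var(axis=0, ddof=1)
            expect = [c for _, c in sorted(zip(-var, cpgs))][:5]
            assert sel.per_tissue_topk[t] == expect
        assert sel.selected_ids == sorted(set(sel.per_tissue_topk[0]) | set(sel.per_tissue_topk[1]))

    def test_constant_cpg_excluded_and_saturation(self):
        rng = np.random.default_rng(5)
        vals = rng.random((8, 10))
        vals[:, 3] = 0.5  # constant in every tissue
        cpgs = [f"cg{i:03d}" for i in range(10)]
        ids = [f"s{i}" for i in range(8)]
        beta = make_beta(vals, cpgs, ids)
        table = make_table(ids, tissue=[0] * 4 + [1] * 4)
        sel = select_variable_cpgs(beta, table, k=9)
        assert all("cg003" not in lst for lst in sel.per_tissue_topk.values())
        sel_all = select_variable_cpgs(beta, table, k=10)
        assert sel_all.selected_ids == sorted(cpgs)

    def test_invariant_to_sample_and_column_order(self):
        rng = np.random.default_rng(6)
        cpgs = [f"cg{i:03d}" for i in range(30)]
        ids = [f"s{i}" for i in range(12)]
        vals = rng.random((12, 30))
        table = make_table(ids, tissue=[0] * 6 + [1] * 6)
        sel = select_variable_cpgs(make_beta(vals, cpgs, ids), table, k=4)
        perm_r = rng.permutation(12)
        perm_c = rng.permutation(30)
        beta2 = make_beta(vals[perm_r][:, perm_c],
                          [cpgs[j] for j in perm_c], [ids[i] for i in perm_r])
        sel2 = select_variable_cpgs(beta2, table, k=4)
        assert sel.selected_ids == sel2.selected_ids
        assert sel.per_tissue_topk == sel2.per_tissue_topk

    def test_nan_entries_mean_imputed_not_fatal(self):
        rng = np.random.default_rng(7)
        vals = rng.random((6, 5))
        vals[0, 0] = np.nan
        ids = [f"s{i}" for i in range(6)]
        sel = select_variable_cpgs(
            make_beta(vals, [f"cg{i}" for i in range(5)], ids), make_table(ids), k=3
        )
        assert len(sel.selected_ids) == 3

    def test_errors(self):
        ids = ["s0", "s1"]
        beta = make_beta(np.random.default_rng(1).random((2, 3)), ["a", "b", "c"], ids)
        with pytest.raises(ValueError, match="k must be positive"):
            select_variable_cpgs(beta, make_table(ids), k=0)
        with pytest.raises(ValueError, match="tissue 0"):
            select_variable_cpgs(beta, make_table(ids, tissue=[0, 1]), k=1)


class TestEncodeCovariates:
    def test_self_standardization_zero_mean_unit_sd(self):
        table = make_table([f"s{i}" for i in range(20)],
                           age=np.random.default_rng(8).uniform(55, 95, 20))
        cov, tissue, (m, s) = encode_covariates(table)
        assert abs(cov[:, 0].mean()) < 1e-12
        assert abs(cov[:, 0].std(ddof=1) - 1) < 1e-12
        np.testing.assert_array_equal(cov[:, 1], table.sex)
        np.testing.assert_array_equal(tissue, table.tissue)

    def test_external_stats_hand_computed(self):
        ages = [60.0, 65.0, 70.0, 75.0, 80.0, 85.0]
        table = make_table([f"s{i}" for i in range(6)], age=ages)
        cov, _, stats = encode_covariates(table, age_stats=(70.0, 10.0))
        np.testing.assert_allclose(cov[:, 0], (np.array(ages) - 70.0) / 10.0)
        assert stats == (70.0, 10.0)
        # single sample at the training mean standardizes to zero
        one = make_table(["x"], age=[70.0])
        cov1, _, _ = encode_covariates(one, age_stats=(70.0, 10.0))
        assert cov1[0, 0] == 0.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            encode_covariates(make_table(["a", "b"], age=[70, 71]), age_stats=(70, 0.0))


class TestStratifiedSplit:
    def test_exact_divisibility_counts(self):
        ids = [f"s{i}" for i in range(100)]
        table = make_table(ids, diagnosis=[1] * 60 + [0] * 40)
        split = stratified_split(table, (0.8, 0.1, 0.1), seed=0)
        y = dict(zip(table.sample_ids, table.diagnosis))
        counts = {g: [0, 0] for g in ("train", "val", "test")}
        for s, g in split.assignment.items():
            counts[g][y[s]] += 1
        assert counts["train"] == [32, 48]
        assert counts["val"] == [4, 6]
        assert counts["test"] == [4, 6]

    def test_largest_remainder_oracle_97_samples(self):
        table = make_table([f"s{i}" for i in range(97)], diagnosis=[1] * 53 + [0] * 44)
        split = stratified_split(table, (0.8, 0.1, 0.1), seed=1)

        def oracle(n, fracs):
            raw = [f * n for f in fracs]
            base = [int(np.floor(r)) for r in raw]
            order = sorted(range(3), key=lambda i: (-(raw[i] - base[i]), i))
            for i in order[: n - sum(base)]:
                base[i] += 1
            return base

        assert _largest_remainder(53, (0.8, 0.1, 0.1)) == oracle(53, (0.8, 0.1, 0.1))
        y = dict(zip(table.sample_ids, table.diagnosis))
        for cls, n_cls in ((1, 53), (0, 44)):
            got = [
                sum(1 for s, g in split.assignment.items() if g == name and y[s] == cls)
                for name in ("train", "val", "test")
            ]
            assert got == oracle(n_cls, (0.8, 0.1, 0.1))

    def test_determinism_and_seed_sensitivity(self):
        table = make_table([f"s{i}" for i in range(50)], diagnosis=[1] * 25 + [0] * 25)
        s1 = stratified_split(table, seed=5)
        s2 = stratified_split(table, seed=5)
        s3 = stratified_split(table, seed=6)
        assert s1.assignment == s2.assignment
        assert s1.assignment != s3.assignment
        for name in ("train", "val", "test"):
            assert len(s1.ids(name)) == len(s3.ids(name))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n1=st.integers(5, 60),
        n0=st.integers(5, 60),
        seed=st.integers(0, 10_000),
    )
    def test_class_fraction_within_one_sample_property(self, n1, n0, seed):
        ids = [f"s{i}" for i in range(n1 + n0)]
        table = make_table(ids, diagnosis=[1] * n1 + [0] * n0)
        split = stratified_split(table, (0.8, 0.1, 0.1), seed=seed)
        y = dict(zip(ids, [1] * n1 + [0] * n0))
        global_frac = n1 / (n1 + n0)
        for name in ("train", "val", "test"):
            members = split.ids(name)
            if not members:
                continue
            frac = sum(y[s] for s in members) / len(members)
            assert abs(frac - global_frac) <= 1.0 / len(members) + 1e-12

    def test_small_class_rejected(self):
        table = make_table(["a", "b", "c", "d"], diagnosis=[1, 0, 0, 0])
        with pytest.raises(ValueError, match="class 1"):
            stratified_split(table)
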