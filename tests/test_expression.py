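"""Meta-cohort assembly, candidate screening, quartiles and the joint
underexpression combination analysis."""

import numpy as np
import pandas as pd
import pytest

from crcmet import expression as xp
from crcmet.fixtures import load_roster, load_candidate_table


class TestAssemble:
    def _dataset(self, rng, n_genes=30, n_samples=12, name="A", shift=0.0):
        genes = [f"G{i}" for i in range(n_genes)]
        df = pd.DataFrame(
            rng.normal(shift, 1, (n_genes, n_samples)),
            index=genes,
            columns=[f"{name}{j}" for j in range(n_samples)],
        )
        return df, pd.Series(name, index=df.columns)

    def test_standardized_per_batch_mean_zero_var_one(self, rng):
        d1 = self._dataset(rng, name="A", shift=2.0)
        d2 = self._dataset(rng, name="B", shift=-1.0)
        expr, batches = xp.assemble_meta_cohort([d1, d2])
        for b in ("A", "B"):
            cols = batches.index[batches == b]
            block = expr[cols]
            assert np.abs(block.mean(axis=1)).max() < 1e-8
            assert np.abs(block.var(axis=1, ddof=1) - 1).max() < 1e-6

    def test_gene_intersection_restriction(self, rng):
        d1 = self._dataset(rng, n_genes=30, name="A")
        df2, b2 = self._dataset(rng, n_genes=30, name="B")
        df2.index = [f"G{i}" for i in range(10, 40)]
        expr, _ = xp.assemble_meta_cohort([d1, (df2, b2)])
        assert sorted(expr.index) == sorted(f"G{i}" for i in range(10, 30))

    def test_empty_intersection_errors(self, rng):
        d1 = self._dataset(rng, name="A")
        df2, b2 = self._dataset(rng, name="B")
        df2.index = [f"H{i}" for i in range(len(df2))]
        with pytest.raises(ValueError, match="no genes"):
            xp.assemble_meta_cohort([d1, (df2, b2)])

    def test_roster_sums_reproduce_meta_cohort_sizes(self):
        roster = load_roster()
        assert len(roster) == 20
        assert roster["n_tumor"].sum() == 1820
        assert roster["n_normal"].sum() == 167
        assert (roster["n_normal"] > 0).sum() == 7


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = xp.mannwhitney_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_small_sample_enumeration(self):
        # all of a below all of b: U=0 and the two-sided exact p is
        # 2/C(6,3) = 0.1 (only the two extreme orderings are as extreme)
        u, p = xp.mannwhitney_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_null_rejection_rate_nominal(self):
        mc = np.random.default_rng(17)
        rejections = 0
        n_reps = 2000
        for _ in range(n_reps):
            _, p = xp.mannwhitney_test(mc.normal(0, 1, 30), mc.normal(0, 1, 30))
            rejections += p < 0.05
        assert rejections / n_reps == pytest.approx(0.05, abs=0.01)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            xp.mannwhitney_test([], [1.0])


class TestQuartiles:
    def test_hand_case_one_to_eight(self):
        q = xp.quartile_stratify(pd.Series([1, 2, 3, 4, 5, 6, 7, 8], dtype=float))
        assert q.tolist() == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_constant_gene_errors(self):
        with pytest.raises(ValueError, match="constant"):
            xp.quartile_stratify(pd.Series([2.0] * 10))

    def test_balanced_at_n_1000(self, rng):
        q = xp.quartile_stratify(pd.Series(rng.normal(0, 1, 1000)))
        counts = q.value_counts()
        assert set(counts.index) == {"Q1", "Q2", "Q3", "Q4"}
        assert all(abs(c - 250) <= 1 for c in counts)

    def test_boundary_ties_go_to_lower_quartile(self):
        v = pd.Series([1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        q = xp.quartile_stratify(v)
        # 25th percentile is 1.0; every tied 1.0 lands in Q1
        assert (q[v == 1.0] == "Q1").all()


def _screen_meta(rng, n=120):
    bad = rng.random(n) < 0.35
    t = rng.exponential(np.where(bad, 2.0, 8.0))
    return (
        pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "dataset": "DS1",
                "tissue": "tumor",
                "dfs_time": t,
                "dfs_event": 1,
                "os_time": t * 1.2,
                "os_event": 1,
                "msi": "MSS",
                "stage": "II",
                "grade": "Moderate",
            }
        ),
        bad,
    )


class TestScreen:
    def test_sign_rule_blocks_direction_inconsistent_gene(self, rng):
        meta, bad = _screen_meta(rng)
        # strongly prognostic but with expression HIGH in short-survivors:
        # positive coefficient, so it cannot pass as a loss-direction gene
        expr = pd.DataFrame(
            {"G1": 2.0 * bad + rng.normal(0, 0.3, len(bad))}, index=meta["sample_id"]
        ).T
        rec = xp.screen_gene("G1", expr, meta, direction="loss")
        assert rec["cox_dfs_coef"] > 0
        assert not rec["primary_pass"]
        rec_gain = xp.screen_gene("G1", expr, meta, direction="gain")
        assert rec_gain["primary_pass"]

    def test_dosage_coupled_loss_gene_passes_with_negative_coef(self, rng):
        meta, bad = _screen_meta(rng)
        expr = pd.DataFrame(
            {"G1": -1.5 * bad + rng.normal(0, 0.5, len(bad))}, index=meta["sample_id"]
        ).T
        rec = xp.screen_gene("G1", expr, meta, direction="loss")
        assert rec["primary_pass"]
        assert rec["cox_dfs_coef"] < 0
        assert rec["cox_dfs_p"] < 0.05


class TestCandidateTableFixture:
    def test_record_count_and_direction_partition(self):
        t2 = load_candidate_table()
        assert len(t2) == 42
        assert (t2["cna_event"] == "Loss").sum() == 29
        assert (t2["cna_event"] == "Gain").sum() == 13

    def test_known_rows_transcribed(self):
        t2 = load_candidate_table().set_index("gene")
        adra1a = t2.loc["ADRA1A"]
        assert adra1a["cna_event"] == "Loss"
        assert adra1a["pct_normal_overlap"] == 0.42
        assert adra1a["cox_os_coef"] == pytest.approx(-0.40185)
        assert adra1a["cox_os_p"] == pytest.approx(0.152322)
        assert adra1a["cox_dfs_coef"] == pytest.approx(-1.67582)
        assert adra1a["cox_dfs_p"] == pytest.approx(0.001948)
        mpdz = t2.loc["MPDZ"]
        assert mpdz["cna_event"] == "Gain"
        assert mpdz["cox_dfs_coef"] == pytest.approx(0.657405)
        assert mpdz["cox_dfs_p"] == pytest.approx(3.98e-5)

    def test_fixture_replay_of_screen_rule(self):
        # applying the primary-screen decision rule to the published
        # coefficients: RAB11FIP1 (loss, OS p 5.6e-5, negative coef) passes;
        # ADRA1D (loss) does not pass on DFS (p=0.88)
        t2 = load_candidate_table().set_index("gene")

        def passes(row, endpoint):
            coef, p = row[f"cox_{endpoint}_coef"], row[f"cox_{endpoint}_p"]
            want = -1 if row["cna_event"] == "Loss" else 1
            return p < 0.05 and np.sign(coef) == want

        assert passes(t2.loc["RAB11FIP1"], "os")
        assert not passes(t2.loc["ADRA1D"], "dfs")

    def test_stringent_filter_leaves_19_genes(self):
        t2 = load_candidate_table().rename(
            columns={"cox_os_p": "cox_os_p", "cox_dfs_p": "cox_dfs_p"}
        )
        assert len(xp.stringent_filter(t2, alpha=0.005)) == 19
        assert len(xp.stringent_filter(t2, alpha=1.0)) == 42
        assert len(xp.stringent_filter(t2, alpha=0.0)) == 0


class TestCombo:
    def _cohort(self, rng, joint_effect=True, n=160):
        # two deleted genes with additive log-hazard effects: jointly
        # underexpressed samples carry the highest hazard
        g1, g2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        hazard = 0.1 * np.exp(-0.8 * g1 - 0.8 * g2) if joint_effect else np.full(n, 0.1)
        t = rng.exponential(1.0 / hazard)
        expr = pd.DataFrame({"G1": g1, "G2": g2}, index=[f"S{i}" for i in range(n)]).T
        meta = pd.DataFrame(
            {
                "sample_id": expr.columns,
                "dataset": "DS1",
                "tissue": "tumor",
                "dfs_time": t,
                "dfs_event": 1,
                "os_time": t,
                "os_event": 1,
                "msi": "MSS",
                "stage": "II",
                "grade": "Moderate",
            }
        )
        return expr, meta

    def test_single_gene_duplicated_reduces_to_q1_vs_rest(self, rng):
        expr, meta = self._cohort(rng)
        combo = xp.combo_survival(["G1", "G1"], expr, meta)
        single = xp.combo_survival(["G1"], expr, meta)
        assert combo["logrank_p"] == pytest.approx(single["logrank_p"])
        assert combo["n_joint_q1"] == single["n_joint_q1"]

    def test_joint_underexpression_strengthens_prognosis(self):
        # two deleted genes jointly tagging high-hazard samples: the combo
        # log-rank should usually beat the better single-gene log-rank
        mc = np.random.default_rng(23)
        wins = trials = 0
        for _ in range(100):
            expr, meta = self._cohort(mc)
            try:
                combo = xp.combo_survival(["G1", "G2"], expr, meta)
            except ValueError:
                continue
            singles = [xp.combo_survival([g], expr, meta)["logrank_p"] for g in ("G1", "G2")]
            trials += 1
            wins += combo["logrank_p"] < min(singles)
        assert trials >= 90
        assert wins / trials >= 0.8

    def test_non_informative_genes_nominal_rejection(self):
        mc = np.random.default_rng(29)
        rejections = trials = 0
        for _ in range(200):
            expr, meta = self._cohort(mc, joint_effect=False)
            try:
                p = xp.combo_survival(["G1", "G2"], expr, meta)["logrank_p"]
            except ValueError:
                continue
            trials += 1
            rejections += p < 0.05
        assert rejections / trials == pytest.approx(0.05, abs=0.04)

    def test_empty_joint_group_errors(self, rng):
        expr, meta = self._cohort(rng)
        # force disjoint Q1s by anti-correlating the two genes
        expr.loc["G2"] = -expr.loc["G1"].to_numpy()
        with pytest.raises(ValueError, match="fewer genes or a larger cohort"):
            xp.combo_survival(["G1", "G2"], expr, meta)
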