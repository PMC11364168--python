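import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from splicelab.counts import CountTable
from splicelab.diffuse import (Comparison, Thresholds, bh_fdr, diff_gene_test,
                               diff_usage_test, ingest_results, normalized_logfc)
from splicelab.synthetic import SimConfig, simulate_count_pair

CMP = Comparison("c", ("t1", "t2"), ("c1", "c2"))


def table(counts, libs=None, gene_map=None, samples=("t1", "t2", "c1", "c2")):
    counts = np.asarray(counts)
    libs = np.full(counts.shape[1], 1000.0) if libs is None else np.asarray(libs)
    fids = [f"f{i}" for i in range(counts.shape[0])]
    return CountTable(fids, list(samples), counts, libs, gene_map=gene_map or {})


class TestNormalizedLogfc:
    def test_symmetry_zero(self):
        t = table([[5, 5, 5, 5]])
        assert normalized_logfc(t, CMP) == pytest.approx([0.0])

    def test_twofold(self):
        t = table([[400, 400, 200, 200]])
        lfc = normalized_logfc(t, CMP, prior=1e-9)
        assert lfc == pytest.approx([1.0], abs=1e-6)

    def test_hand_arithmetic_with_prior(self):
        # independent arithmetic: log2((8 + 0.125) / (2 + 0.125))
        t = table([[8, 8, 2, 2]])
        expected = np.log2(8.125 / 2.125)
        assert normalized_logfc(t, CMP, prior=0.125) == pytest.approx([expected])

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            table([[1, 1, 1, 1]], libs=[0, 1, 1, 1])


class TestBhFdr:
    def brute_force(self, p):
        """Step-up definition applied literally."""
        p = np.asarray(p, float)
        m = len(p)
        q = np.empty(m)
        for i, pi in enumerate(p):
            rank_candidates = []
            for j, pj in enumerate(p):
                # q_i = min over all p_j >= p_i of p_j * m / rank(p_j)
                rank = (p <= pj).sum()
                if pj >= pi:
                    rank_candidates.append(min(1.0, pj * m / rank))
            q[i] = min(rank_candidates)
        return q

    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert bh_fdr([]).size == 0

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_bruteforce(self, pvals):
        assert bh_fdr(pvals) == pytest.approx(self.brute_force(pvals), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.random(200)
        assert bh_fdr(p) == pytest.approx(multipletests(p, method="fdr_bh")[1])

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestDiffUsage:
    def gene_map(self, n, per_gene=2):
        return {f"f{i}": f"g{i // per_gene}" for i in range(n)}

    def test_null_case_identical_proportions(self):
        t = table([[50, 50, 50, 50], [50, 50, 50, 50]])
        res = diff_usage_test(t, self.gene_map(2), CMP)
        assert res["p"].to_numpy() == pytest.approx([1.0, 1.0])
        assert res["logFC"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_reduces_to_chi_square_at_zero_dispersion(self):
        # identical replicates within condition -> moment ICC is zero, so
        # the score statistic must equal the pooled 2x2 chi-square
        t = table([[80, 80, 40, 40], [20, 20, 60, 60]])
        res = diff_usage_test(t, self.gene_map(2), CMP)
        chi2 = stats.chi2_contingency(
            np.array([[160, 40], [80, 120]]), correction=False)
        assert res["p"].iloc[0] == pytest.approx(chi2.pvalue, abs=1e-6)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(42)
        n = np.array([200] * 6)
        k_f0 = np.concatenate([rng.binomial(200, 0.9, 3),
                               rng.binomial(200, 0.5, 3)])
        counts = np.vstack([k_f0, n - k_f0])
        t = table(counts, samples=("t1", "t2", "t3", "c1", "c2", "c3"))
        c = Comparison("c", ("t1", "t2", "t3"), ("c1", "c2", "c3"))
        res = diff_usage_test(t, self.gene_map(2), c)
        assert res["p"].iloc[0] < 0.05
        assert res["logFC"].iloc[0] > 0

    def test_label_symmetry(self):
        t = table([[80, 70, 40, 45], [25, 20, 65, 60]])
        res_fwd = diff_usage_test(t, self.gene_map(2), CMP)
        res_rev = diff_usage_test(t, self.gene_map(2),
                                  Comparison("r", CMP.control, CMP.test))
        assert res_rev["logFC"].to_numpy() == pytest.approx(
            -res_fwd["logFC"].to_numpy())
        assert res_rev["p"].to_numpy() == pytest.approx(res_fwd["p"].to_numpy())

    def test_single_feature_genes_excluded(self):
        t = table([[5, 5, 5, 5], [9, 9, 9, 9]])
        res = diff_usage_test(t, {"f0": "gA", "f1": "gB"}, CMP)
        assert res.empty

    def test_untestable_gene_flagged(self):
        t = table([[0, 0, 5, 5], [0, 0, 5, 5]])
        res = diff_usage_test(t, self.gene_map(2), CMP)
        assert (res["p"] == 1.0).all()
        assert (~res["testable"]).all()

    def test_monotone_power_in_effect_size(self):
        """Detection rate does not decrease with planted effect size."""
        rates = []
        for shift in (0.05, 0.2, 0.4):
            cfg = SimConfig(seed=77, n_genes=150, n_planted=30,
                            usage_shift=shift, depth=60)
            tab, gm, truth = simulate_count_pair(cfg)
            c = Comparison("c", ("test1", "test2", "test3"),
                           ("control1", "control2", "control3"))
            res = diff_usage_test(tab, gm, c).merge(truth, on="feature_id")
            planted = res[res["role"] == "planted"]
            rates.append((planted["fdr"] < 0.05).mean())
        assert rates == sorted(rates)


class TestDiffGene:
    def test_equal_rates_null(self):
        t = table([[100, 100, 100, 100]])
        res = diff_gene_test(t, CMP)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_poisson_wald_closed_form(self):
        # 1v1, dispersion estimate is 0 -> Wald z with variance 1/K per side
        k_t, k_c, lib = 120.0, 60.0, 1000.0
        prior = 0.125
        t = table([[int(k_t), int(k_c)]], libs=[lib, lib], samples=("t1", "c1"))
        res = diff_gene_test(t, Comparison("c", ("t1",), ("c1",)))
        z = (np.log((k_t + prior) / lib) - np.log((k_c + prior) / lib)) / np.sqrt(
            1.0 / (k_t + prior) + 1.0 / (k_c + prior))
        expected = 2 * stats.norm.sf(abs(z))
        assert res["p"].iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_all_zero_gene(self):
        t = table([[0, 0, 0, 0]])
        res = diff_gene_test(t, CMP)
        assert res["p"].iloc[0] == 1.0 and res["logFC"].iloc[0] == 0.0

    def test_power_for_fourfold_change(self):
        """Planted 4-fold changes at depth 100, 3v3, NB dispersion 0.1."""
        rng = np.random.default_rng(7)
        n_changed, n_null, phi, depth = 100, 400, 0.1, 100.0

        def nb(mean, size):
            lam = rng.gamma(1 / phi, phi * mean, size=size)
            return rng.poisson(lam)

        rows = [np.concatenate([nb(4 * depth, 3), nb(depth, 3)])
                for _ in range(n_changed)]
        rows += [np.concatenate([nb(depth, 3), nb(depth, 3)])
                 for _ in range(n_null)]
        counts = np.vstack(rows)
        t = table(counts, libs=np.full(6, 1e5),
                  samples=("t1", "t2", "t3", "c1", "c2", "c3"))
        res = diff_gene_test(t, Comparison("c", ("t1", "t2", "t3"),
                                           ("c1", "c2", "c3")))
        power = (res["fdr"].iloc[:n_changed] < 0.05).mean()
        assert power >= 0.9


class TestIngestResults:
    def write(self, tmp_path, rows, header="feature_id\tgene_id\tlogFC\tp\tfdr"):
        path = tmp_path / "res.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_well_formed(self, tmp_path):
        path = self.write(tmp_path, ["j1\tg1\t0.5\t0.01\t0.02",
                                     "j2\tg1\t-0.2\t0.5\t0.6",
                                     "j3\tg2\t1.1\t0.001\t0.004"])
        df = ingest_results(path)
        assert len(df) == 3 and df["logFC"].iloc[2] == pytest.approx(1.1)

    def test_na_row_dropped(self, tmp_path):
        path = self.write(tmp_path, ["j1\tg1\t0.5\t0.01\tNA",
                                     "j2\tg1\t-0.2\t0.5\t0.6"])
        df = ingest_results(path)
        assert list(df["feature_id"]) == ["j2"]

    def test_out_of_range_p_fatal(self, tmp_path):
        path = self.write(tmp_path, ["j1\tg1\t0.5\t1.5\t0.9"])
        with pytest.raises(ValueError, match="outside"):
            ingest_results(path)

    def test_missing_column_fatal(self, tmp_path):
        path = self.write(tmp_path, ["j1\t0.5\t0.01"],
                          header="feature_id\tlogFC\tp")
        with pytest.raises(ValueError, match="fdr"):
            ingest_results(path)


class TestThresholds:
    def test_defaults_consistent(self):
        t = Thresholds()
        assert t.fdr_sig < t.fdr_control
        assert t.site_rep_lfc < 0 < t.site_enh_lfc

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(fdr_sig=0.6)
        with pytest.raises(ValueError):
            Thresholds(site_rep_lfc=0.1)
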