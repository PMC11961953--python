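"""TMM factors, common dispersion, the NB conditional exact test, BH, calls."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, rankdata

from lavapipe.destats import (
    bh_fdr,
    call_de,
    estimate_common_dispersion,
    exact_nb_de,
    nb_exact_test,
    tmm_factors,
)


def nb_counts(rng, mu, phi, size):
    if phi == 0:
        return rng.poisson(mu, size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size)


class TestTmm:
    def test_identical_samples_get_unit_factors(self):
        df = pd.DataFrame({"A": [10, 50, 100], "B": [10, 50, 100]})
        assert np.allclose(tmm_factors(df).to_numpy(), 1.0)

    def test_pure_depth_difference_absorbed_by_library_scaling(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(100, 2000)
        df = pd.DataFrame({"A": a, "B": 2 * a})
        assert np.allclose(tmm_factors(df).to_numpy(), 1.0, atol=1e-9)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(nb_counts(rng, 80.0, 0.2, (800, 5)),
                          columns=list("ABCDE"))
        f = tmm_factors(df)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(df)

    def test_asymmetric_de_matches_direct_trimmed_mean_oracle(self):
        # 5% of genes 8-fold up in B; trimming should shrug them off
        rng = np.random.default_rng(7)
        n = 2000
        base = rng.lognormal(4, 1, n)
        a = rng.poisson(base)
        b = rng.poisson(base * np.where(np.arange(n) < n // 20, 8.0, 1.0))
        df = pd.DataFrame({"A": a, "B": b})
        got = tmm_factors(df, reference="A")
        # independent scalar re-implementation of the doubly trimmed weighted mean
        na, nb_ = a.sum(), b.sum()
        keep = (a > 0) & (b > 0)
        oa, ob = a[keep] / na, b[keep] / nb_
        m = np.log2(ob / oa)
        av = 0.5 * np.log2(ob * oa)
        w = (nb_ - b[keep]) / (nb_ * b[keep]) + (na - a[keep]) / (na * a[keep])
        nk = keep.sum()
        lo_m, lo_a = np.floor(nk * 0.3) + 1, np.floor(nk * 0.05) + 1
        sel = ((rankdata(m) >= lo_m) & (rankdata(m) <= nk + 1 - lo_m)
               & (rankdata(av) >= lo_a) & (rankdata(av) <= nk + 1 - lo_a))
        f_b = 2 ** (np.sum(m[sel] / w[sel]) / np.sum(1 / w[sel]))
        expected_ratio = f_b  # factor(B)/factor(A) before geometric rescaling
        assert got["B"] / got["A"] == pytest.approx(expected_ratio, rel=0.03)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_edger_reference_implementation(self, tmp_path):
        rng = np.random.default_rng(3)
        y = nb_counts(rng, rng.lognormal(4, 1, 500)[:, None] * np.ones((1, 4)), 0.1,
                      (500, 4))
        y[:25, 3] *= 8
        df = pd.DataFrame(y, index=[f"g{i}" for i in range(500)],
                          columns=list("ABCD"))
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"y <- as.matrix(read.delim('{path}', row.names=1))\n"
            "cat(paste(calcNormFactors(y, method='TMM'), collapse='\\t'))\n"
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        if res.returncode != 0:
            pytest.skip(f"edgeR unavailable: {res.stderr.strip()[:200]}")
        ref = np.array([float(x) for x in res.stdout.split()])
        assert np.allclose(tmm_factors(df).to_numpy(), ref, rtol=1e-6)


class TestCommonDispersion:
    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(21)
        y = rng.poisson(rng.lognormal(4, 1, 2000)[:, None] * np.ones((1, 8)))
        df = pd.DataFrame(y)
        phi = estimate_common_dispersion(df, ["A"] * 4 + ["B"] * 4)
        assert phi < 0.02

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(22)
        mu = rng.lognormal(4, 1, 2000)[:, None] * np.ones((1, 8))
        y = nb_counts(rng, mu, 0.2, mu.shape)
        phi = estimate_common_dispersion(pd.DataFrame(y), ["A"] * 4 + ["B"] * 4)
        assert 0.15 <= phi <= 0.25

    def test_duplicated_columns_hit_lower_bound(self):
        col = np.arange(1, 101) * 3
        df = pd.DataFrame({"A": col, "B": col, "C": col})
        phi = estimate_common_dispersion(df, ["g"] * 3)
        assert phi <= 1e-4

    def test_single_sample_groups_unidentifiable(self):
        df = pd.DataFrame({"A": [1, 2], "B": [3, 4]})
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_common_dispersion(df, ["x", "y"])


class TestExactTest:
    def test_balanced_split_has_pvalue_one(self):
        assert nb_exact_test((7, 7), (4, 4), 0.1) == pytest.approx(1.0, abs=1e-9)
        assert nb_exact_test((0, 0), (4, 4), 0.1) == 1.0

    def test_matches_binomial_enumeration_at_zero_dispersion(self):
        for t in (1, 5, 10, 17, 33, 50):
            pm = binom.pmf(np.arange(t + 1), t, 0.5)
            for a in range(t + 1):
                ref = pm[pm <= pm[a] + 1e-12].sum()
                assert nb_exact_test((a, t - a), (3, 3), 0.0) == pytest.approx(
                    ref, abs=1e-9)

    def test_unbalanced_sizes_shift_the_null(self):
        pm = binom.pmf(np.arange(13), 12, 2 / 5)
        ref = pm[pm <= pm[10] + 1e-12].sum()
        assert nb_exact_test((10, 2), (2, 3), 0.0) == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_pvalue_non_increasing_in_imbalance(self, phi):
        t = 20
        ps = [nb_exact_test((a, t - a), (4, 4), phi) for a in range(t // 2, t + 1)]
        assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(len(ps) - 1))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nb_exact_test((-1, 5), (2, 2), 0.1)


class TestBhFdr:
    def test_step_up_collapses_linear_pvalues(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_and_degenerate_inputs(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_order_restored_to_input(self):
        p = [0.9, 0.001, 0.5, 0.04]
        fdr = bh_fdr(p)
        assert fdr[1] == min(fdr)
        # direct step-up computation
        m = len(p)
        order = np.argsort(p)
        ranked = np.array(p)[order] * m / (np.arange(m) + 1)
        expected = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(expected, 1)
        assert np.allclose(fdr, out)


class TestCallDe:
    @pytest.mark.parametrize(
        "fdr,lfc,call",
        [
            (0.04, 1.5, "up"),
            (0.04, -1.5, "down"),
            (0.04, 1.0, "ns"),    # strict |log2FC| > 1
            (0.05, 3.0, "ns"),    # strict FDR < 0.05
            (0.06, 3.0, "ns"),
        ],
    )
    def test_threshold_boundaries(self, fdr, lfc, call):
        table = pd.DataFrame({"feature": ["g"], "log2fc": [lfc], "fdr": [fdr]})
        assert call_de(table)["call"].iloc[0] == call


class TestPipelinePowerAndError:
    def test_planted_fold_changes_recovered(self):
        # |log2FC| = 2 on 100 of 1500 genes, phi=0.1, 4 vs 4, means >= 50
        rng = np.random.default_rng(31)
        n, n_de = 1500, 100
        base = np.maximum(rng.lognormal(4.5, 0.8, n), 50)
        lfc = np.zeros(n)
        lfc[:n_de] = np.where(np.arange(n_de) % 2 == 0, 2.0, -2.0)
        mu_a = base * 2.0 ** lfc
        y = np.column_stack(
            [nb_counts(rng, mu_a, 0.1, n) for _ in range(4)]
            + [nb_counts(rng, base, 0.1, n) for _ in range(4)]
        )
        df = pd.DataFrame(y, index=[f"g{i}" for i in range(n)])
        table = exact_nb_de(df, ["A"] * 4 + ["B"] * 4, "A", "B")
        called = table.index[table["call"] != "ns"].to_numpy()
        tp = (called < n_de).sum()
        sensitivity = tp / n_de
        fdp = (len(called) - tp) / max(len(called), 1)
        assert sensitivity >= 0.8
        assert fdp <= 0.1
        # directions agree with the planted signs
        calls = table["call"].to_numpy()[:n_de]
        planted = np.where(lfc[:n_de] > 0, "up", "down")
        assert (calls[calls != "ns"] == planted[calls != "ns"]).all()

    def test_groups_need_two_samples_each(self):
        df = pd.DataFrame(np.arange(20).reshape(5, 4))
        with pytest.raises(ValueError, match=">= 2 samples"):
            exact_nb_de(df, ["A", "B", "B", "B"], "A", "B")
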