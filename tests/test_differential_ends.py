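"""TMM normalization, the exact count test, BH FDR and window clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import srps
from srps.differential_ends import (Thresholds, cluster_positions, count_test,
                                    tmm_factors)


# ---------------------------------------------------------------------------
# Independent brute-force TMM (the oracle): a direct, unoptimized transcription
# of the trimmed-mean-of-M-values definition.
# ---------------------------------------------------------------------------

def brute_force_tmm(y, m_trim=0.30, a_trim=0.05):
    y = np.asarray(y, dtype=float)
    n = y.sum(axis=0)
    q75 = [np.quantile(y[:, j] / n[j], 0.75) for j in range(y.shape[1])]
    ref = int(np.argmin([abs(q - np.mean(q75)) for q in q75]))
    logf = []
    for j in range(y.shape[1]):
        if j == ref:
            logf.append(0.0)
            continue
        rows = [i for i in range(y.shape[0]) if y[i, j] > 0 and y[i, ref] > 0]
        m = [np.log2((y[i, j] / n[j]) / (y[i, ref] / n[ref])) for i in rows]
        a = [0.5 * np.log2((y[i, j] / n[j]) * (y[i, ref] / n[ref])) for i in rows]
        w = [(n[j] - y[i, j]) / (n[j] * y[i, j])
             + (n[ref] - y[i, ref]) / (n[ref] * y[i, ref]) for i in rows]
        k = len(rows)
        lo_m, lo_a = int(np.floor(k * m_trim)) + 1, int(np.floor(k * a_trim)) + 1
        hi_m, hi_a = k + 1 - lo_m, k + 1 - lo_a
        rm, ra = sps.rankdata(m), sps.rankdata(a)
        keep = [i for i in range(k)
                if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a]
        num = sum(m[i] / w[i] for i in keep)
        den = sum(1.0 / w[i] for i in keep)
        logf.append(num / den if den else 0.0)
    f = 2.0 ** np.asarray(logf)
    return f / np.exp(np.mean(np.log(f)))


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        y = np.array([[10, 10], [5, 5], [100, 100]])
        assert np.allclose(tmm_factors(y), [1.0, 1.0])

    def test_pure_depth_difference_gives_unit_factors(self):
        y = np.array([[10, 20], [5, 10], [100, 200], [7, 14]])
        assert np.allclose(tmm_factors(y), [1.0, 1.0])

    def test_outlier_row_matches_brute_force_within_one_percent(self):
        rng = np.random.default_rng(5)
        y = rng.integers(20, 200, size=(10, 2)).astype(float)
        y[3, 1] *= 50          # one strongly library-specific row
        got = tmm_factors(y)
        want = brute_force_tmm(y)
        assert np.all(np.abs(got / want - 1) < 0.01)

    def test_all_zero_library_is_an_error(self):
        with pytest.raises(ValueError, match="zero total"):
            tmm_factors(np.array([[1, 0], [2, 0]]))


class TestCountTest:
    def _matrix(self, rows, cols=("a", "b")):
        return pd.DataFrame(rows, columns=list(cols))

    def test_identical_groups_are_null(self):
        counts = self._matrix([[50, 50], [10, 10], [200, 200]])
        res = count_test(counts, ["g1", "g2"], [1000, 1000], dispersion=0.0)
        assert np.allclose(res.log2fc, 0.0)
        assert np.allclose(res.pvalue, 1.0)

    def test_extreme_split_matches_binomial_closed_form(self):
        counts = self._matrix([[100, 0], [50, 50]])
        res = count_test(counts, ["g1", "g2"], [1000, 1000], dispersion=0.0)
        # all 100 scaled counts in one of two equal libraries: p = 2 * 0.5^100
        assert res.pvalue.iloc[0] == pytest.approx(2 * 0.5 ** 100, rel=1e-6)
        assert res.pvalue.iloc[0] < 1e-6

    def test_binomial_oracle_on_random_two_library_rows(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 100, size=60)
        b = rng.integers(0, 100, size=60)
        counts = self._matrix(np.column_stack([a, b]))
        res = count_test(counts, ["g1", "g2"], [500, 500], dispersion=0.0,
                         factors=[1.0, 1.0])
        for i in range(60):
            t = a[i] + b[i]
            want = sps.binomtest(int(a[i]), int(t), 0.5).pvalue if t else 1.0
            assert res.pvalue.iloc[i] == pytest.approx(want, rel=1e-9, abs=1e-300)

    def test_swapping_group_membership_negates_log2fc_keeps_pvalues(self):
        rng = np.random.default_rng(4)
        counts = self._matrix(rng.integers(0, 300, size=(20, 4)),
                              cols=list("abcd"))
        labels = ["x", "x", "y", "y"]
        r1 = count_test(counts, labels, [1e4] * 4, dispersion=0.1)
        # same libraries with the two groups' roles exchanged
        r2 = count_test(counts[["c", "d", "a", "b"]], labels, [1e4] * 4,
                        dispersion=0.1)
        assert np.allclose(r1.log2fc, -r2.log2fc)
        assert np.allclose(r1.pvalue, r2.pvalue)

    def test_single_replicate_groups_need_fixed_dispersion(self):
        counts = self._matrix([[5, 9]])
        with pytest.raises(ValueError, match="fixed value"):
            count_test(counts, ["g1", "g2"], [100, 100], dispersion="estimate")

    def test_negative_dispersion_is_an_error(self):
        counts = self._matrix([[5, 9]])
        with pytest.raises(ValueError, match=">= 0"):
            count_test(counts, ["g1", "g2"], [100, 100], dispersion=-0.1)

    def test_dispersion_widens_the_null(self):
        counts = self._matrix([[80, 20]])
        p0 = count_test(counts, ["g1", "g2"], [1000, 1000],
                        dispersion=0.0).pvalue.iloc[0]
        p1 = count_test(counts, ["g1", "g2"], [1000, 1000],
                        dispersion=0.5).pvalue.iloc[0]
        assert p1 > p0


class TestBhFdr:
    def test_closed_form_triple(self):
        # BH: p_(i) * m / i, cumulative-min from the largest
        got = srps.bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(got, [0.03, 0.03, 0.03])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        fdr = srps.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestClusterPositions:
    def _rows(self, entries, strand="+"):
        return pd.DataFrame([{"contig": "chr", "strand": strand, "pos": p,
                              "end_type": "3p", "prop_ref": v}
                             for p, v in entries])

    def test_keeps_highest_proportion_within_window(self):
        kept = cluster_positions(self._rows([(100, 0.03), (103, 0.07)]))
        assert list(kept.pos) == [103]

    def test_outside_window_keeps_both(self):
        kept = cluster_positions(self._rows([(100, 0.03), (106, 0.07)]))
        assert sorted(kept.pos) == [100, 106]

    def test_greedy_sweep_keeps_single_maximum(self):
        kept = cluster_positions(self._rows(
            [(100, 0.02), (102, 0.09), (104, 0.05)]))
        assert list(kept.pos) == [102]


class TestThresholds:
    def test_yaml_round_trip(self, tmp_path):
        (tmp_path / "t.yaml").write_text(
            "thresholds:\n  cpm_min: 5\n  fdr_max: 0.01\n")
        thr = Thresholds.from_yaml(tmp_path / "t.yaml")
        assert thr.cpm_min == 5 and thr.fdr_max == 0.01
        assert thr.lfc_min == 1.0      # untouched default

    def test_unknown_enzyme_is_an_error(self, small_sim):
        _, _, _, _, profiles = small_sim
        wt = {n: p for n, p in profiles.items()
              if p.spec.strain == "WT" and p.spec.fraction == "total"}
        mut = {n: p for n, p in profiles.items() if p.spec.strain == "pnp_del"}
        with pytest.raises(ValueError, match="unknown enzyme"):
            srps.call_exo_sites(wt, mut, "rnq")
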