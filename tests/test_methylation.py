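"""Methylation-array region analysis tests."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from cellmech import (
    BetaMatrix,
    ClinicalTable,
    RegionSpec,
    cluster_samples,
    filter_probes,
    fisher_association,
    quantile_normalize,
    region_methylation_call,
)
from cellmech.methylation import probes_in_region
from cellmech.simulate import CohortSpec, simulate_beta_cohort


def _bm(beta: dict, detection=None, positions=None) -> BetaMatrix:
    bdf = pd.DataFrame(beta)
    ddf = pd.DataFrame(detection) if detection is not None else None
    if ddf is not None:
        ddf.index = bdf.index
    info = None
    if positions is not None:
        info = pd.DataFrame(
            {"chrom": "chr1", "pos": positions, "build": "hg19"}, index=bdf.index
        )
    return BetaMatrix(beta=bdf, detection_p=ddf, probe_info=info)


class TestFilterProbes:
    def test_failure_fraction_enumeration(self):
        # probe p1 fails in 2/4 samples (50%) -> dropped;
        # probe p2 fails in 1/4 (25%) -> kept with one missing entry
        beta = {s: [0.5, 0.5] for s in "abcd"}
        det = {
            "a": [0.5, 0.5], "b": [0.5, 0.001],
            "c": [0.001, 0.001], "d": [0.001, 0.001],
        }
        m = BetaMatrix(
            beta=pd.DataFrame(beta, index=["p1", "p2"]),
            detection_p=pd.DataFrame(det, index=["p1", "p2"]),
        )
        out, report = filter_probes(m)
        assert out.probes == ["p2"]
        assert report.loc["p1", "dropped"] and not report.loc["p2", "dropped"]
        assert out.beta.loc["p2"].isna().sum() == 1

    def test_vacuous_p_threshold(self):
        m = _bm({"a": [0.1, 0.9], "b": [0.2, 0.8]},
                detection={"a": [0.9, 0.9], "b": [0.9, 0.9]})
        out, _ = filter_probes(m, p_max=1.0)
        pd.testing.assert_frame_equal(out.beta, m.beta)

    def test_identity_when_all_pass(self):
        m = _bm({"a": [0.1, 0.9], "b": [0.2, 0.8]},
                detection={"a": [0.001, 0.001], "b": [0.001, 0.001]})
        out, _ = filter_probes(m)
        pd.testing.assert_frame_equal(out.beta, m.beta)

    def test_all_dropped_raises(self):
        m = _bm({"a": [0.1], "b": [0.2]}, detection={"a": [0.9], "b": [0.9]})
        with pytest.raises(ValueError, match="all probes dropped"):
            filter_probes(m)


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = _bm({"a": [0.1, 0.5, 0.9], "b": [0.1, 0.5, 0.9]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.beta.to_numpy(), m.beta.to_numpy())

    def test_hand_enumeration_of_rank_means(self):
        # columns (1,3) and (2,4) in tenths -> both become (0.15, 0.35)
        m = _bm({"a": [0.1, 0.3], "b": [0.2, 0.4]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.beta["a"].to_numpy(), [0.15, 0.35])
        np.testing.assert_allclose(out.beta["b"].to_numpy(), [0.15, 0.35])

    def test_columns_share_sorted_values(self, rng):
        m = _bm({f"s{i}": rng.uniform(0, 1, 40) for i in range(5)})
        out = quantile_normalize(m)
        ref = np.sort(out.beta.iloc[:, 0].to_numpy())
        for c in out.beta.columns:
            np.testing.assert_allclose(np.sort(out.beta[c].to_numpy()), ref)

    def test_rank_order_preserved(self, rng):
        m = _bm({f"s{i}": rng.uniform(0, 1, 30) for i in range(4)})
        out = quantile_normalize(m)
        for c in m.beta.columns:
            before = m.beta[c].rank()
            after = out.beta[c].rank()
            pd.testing.assert_series_equal(before, after)

    def test_missing_entries_stay_missing(self, rng):
        vals = rng.uniform(0, 1, (20, 3))
        vals[3, 1] = np.nan
        m = _bm({f"s{i}": vals[:, i] for i in range(3)})
        out = quantile_normalize(m)
        assert np.isnan(out.beta.iloc[3, 1])
        assert out.beta.isna().sum().sum() == 1

    def test_all_missing_sample_errors(self):
        m = _bm({"a": [0.1, 0.2], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="'b'"):
            quantile_normalize(m)

    def test_permutation_equivariance(self, rng):
        """filter + normalize commutes with sample relabeling."""
        vals = rng.uniform(0, 1, (15, 4))
        det = rng.uniform(0, 0.02, (15, 4))
        cols = ["s1", "s2", "s3", "s4"]
        m = BetaMatrix(beta=pd.DataFrame(vals, columns=cols),
                       detection_p=pd.DataFrame(det, columns=cols))
        perm = ["s3", "s1", "s4", "s2"]
        direct = quantile_normalize(filter_probes(m)[0]).beta[perm]
        m_perm = BetaMatrix(beta=m.beta[perm], detection_p=m.detection_p[perm])
        permuted = quantile_normalize(filter_probes(m_perm)[0]).beta
        pd.testing.assert_frame_equal(direct, permuted)


REGION = RegionSpec(name="r", chromosome="chr1", start=100, end=200)


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        m = _bm({"a": [0.1, 0.2], "b": [0.1, 0.2], "c": [0.9, 0.9]},
                positions=[100, 150])
        res = cluster_samples(m, REGION)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_nearest_pair_merges_first(self):
        m = _bm({"a": [0.1, 0.1], "b": [0.1, 0.1], "c": [0.9, 0.9]},
                positions=[100, 150])
        res = cluster_samples(m, REGION)
        first = {int(res.linkage[0, 0]), int(res.linkage[0, 1])}
        assert first == {res.samples.index("a"), res.samples.index("b")}

    def test_merge_heights_match_bruteforce_complete_linkage(self, rng):
        vals = rng.uniform(0, 1, (3, 4))
        m = _bm({f"s{i}": vals[:, i] for i in range(4)}, positions=[100, 120, 140])
        res = cluster_samples(m, REGION)

        # naive complete-linkage agglomeration oracle
        points = {i: [i] for i in range(4)}
        X = vals.T
        heights = []
        while len(points) > 1:
            best = None
            for i, j in itertools.combinations(sorted(points), 2):
                dmax = max(
                    np.linalg.norm(X[a] - X[b])
                    for a in points[i] for b in points[j]
                )
                if best is None or dmax < best[0]:
                    best = (dmax, i, j)
            d, i, j = best
            heights.append(d)
            points[min(i, j)] = points.pop(i) + points.pop(j)
        np.testing.assert_allclose(np.sort(res.linkage[:, 2]), np.sort(heights))

    def test_empty_region_errors(self):
        m = _bm({"a": [0.1], "b": [0.2]}, positions=[5000])
        with pytest.raises(ValueError, match="no probes"):
            cluster_samples(m, REGION)

    def test_gene_body_clusters_recover_generating_labels(self):
        """The bimodal gene-body CpG pair splits the synthetic cohort into
        the two generated groups (adjusted Rand index >= 0.9)."""
        from sklearn.metrics import adjusted_rand_score

        from cellmech.presets import LMNA_GENE_BODY

        res = simulate_beta_cohort(CohortSpec(seed=5))
        clust = cluster_samples(res.beta, LMNA_GENE_BODY).cut(2)
        truth = [s in set(res.gene_body_high) for s in clust.index]
        assert adjusted_rand_score(truth, clust.to_numpy()) >= 0.9


class TestRegionCall:
    def test_all_zero_beta_no_calls(self):
        m = _bm({"a": [0.0, 0.0], "b": [0.0, 0.0]}, positions=[100, 150])
        calls = region_methylation_call(m, REGION)
        assert not calls.any()

    def test_single_high_probe_triggers_call(self):
        m = _bm({"a": [0.95, 0.0], "b": [0.05, 0.0]}, positions=[100, 150])
        calls = region_methylation_call(m, REGION)
        assert calls["a"] and not calls["b"]

    def test_synthetic_cohort_recovers_promoter_truth(self):
        res = simulate_beta_cohort(CohortSpec(seed=3))
        promoter = RegionSpec(name="prom", chromosome="chr1",
                              start=156_084_462, end=156_084_832)
        calls = region_methylation_call(res.beta, promoter)
        assert sorted(calls.index[calls]) == res.promoter_methylated
        assert int(calls.sum()) == 3


def _fisher_oracle(a, b, c, d):
    """Exhaustive two-tailed Fisher p: sum of hypergeometric probabilities
    of all tables with the observed margins that are no more probable."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def _fisher_from_table(a, b, c, d):
    calls = pd.Series([True] * (a + b) + [False] * (c + d),
                      index=[f"s{i}" for i in range(a + b + c + d)])
    risk = (["high"] * a + ["low"] * b + ["high"] * c + ["low"] * d)
    clin = ClinicalTable(pd.DataFrame(
        {"risk": risk, "inss_stage": "4"}, index=calls.index))
    return fisher_association(calls, clin)


class TestFisher:
    def test_balanced_table_p_one(self):
        res = _fisher_from_table(5, 5, 5, 5)
        assert res.pvalue == pytest.approx(1.0)
        assert res.table == ((5, 5), (5, 5))

    def test_diagonal_table_enumeration(self):
        # [[3,0],[0,3]]: 2 of the C(6,3)=20 equally-margined tables are as
        # extreme -> p = 0.1
        res = _fisher_from_table(3, 0, 0, 3)
        assert res.pvalue == pytest.approx(0.1)

    def test_matches_enumeration_oracle_all_small_tables(self):
        """Exhaustive agreement with the hypergeometric oracle for every
        2x2 table with positive margins and total <= 14, plus random
        larger tables up to n = 30."""
        for n in range(4, 15):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        res = _fisher_from_table(a, b, c, d)
                        assert res.pvalue == pytest.approx(
                            _fisher_oracle(a, b, c, d), rel=1e-9
                        ), (a, b, c, d)

        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(15, 31))
            a, b, c, d = (int(x) for x in rng.multinomial(n, [0.25] * 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            res = _fisher_from_table(a, b, c, d)
            assert res.pvalue == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-9)

    def test_association_power_at_generating_odds(self):
        """With the default risk-association odds (6) linking gene-body
        methylation to elevated risk, the Fisher test detects the
        association (p < 0.05) in >= 80% of seeded cohorts."""
        from cellmech.presets import LMNA_GENE_BODY

        significant = 0
        reps = 200
        for seed in range(reps):
            res = simulate_beta_cohort(CohortSpec(seed=seed))
            calls = region_methylation_call(res.beta, LMNA_GENE_BODY)
            significant += fisher_association(calls, res.clinical).pvalue < 0.05
        assert significant / reps >= 0.80

    def test_unknown_risk_label_rejected(self):
        with pytest.raises(ValueError, match="unknown risk"):
            ClinicalTable(pd.DataFrame(
                {"risk": ["low", "extreme"], "inss_stage": ["1", "4"]},
                index=["s1", "s2"]))


class TestRegionSpec:
    def test_promoter_window_plus_strand(self):
        r = RegionSpec.promoter_window("p", "chr1", tss=1000, strand="+",
                                       upstream=-37, downstream=333)
        assert (r.start, r.end) == (963, 1333)

    def test_promoter_window_minus_strand_mirrored(self):
        r = RegionSpec.promoter_window("p", "chr1", tss=1000, strand="-",
                                       upstream=-37, downstream=333)
        assert (r.start, r.end) == (667, 1037)

    def test_build_mismatch_detected(self):
        m = _bm({"a": [0.5], "b": [0.5]}, positions=[150])
        hg38 = RegionSpec(name="r", chromosome="chr1", start=100, end=200,
                          build="hg38")
        with pytest.raises(ValueError, match="build"):
            probes_in_region(m, hg38)
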