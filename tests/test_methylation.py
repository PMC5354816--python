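"""Probe mapping, beta bands, moderated t, BH, calls, CIMP, recurrence."""

import os
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bivatlas.domains import ConsensusRegion
from bivatlas.intervals import GenomicInterval
from bivatlas.methylation import (
    BETA_BANDS,
    band_counts_by_category,
    beta_categories,
    bh_fdr,
    call_dmps,
    category_distribution,
    map_probes,
    moderated_t_test,
    recurrence,
    stratify_cimp,
    trigamma_inverse,
)

from oracles import bh_bruteforce

GI = GenomicInterval


def region(s, e, category="bivalent", rid="r1", cluster=None, chrom="chr1"):
    return ConsensusRegion(
        GI(chrom, s, e), category, frozenset(["H1"]), region_id=rid, cluster=cluster
    )


def manifest_frame(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:03d}" for i in range(len(positions))],
            "chrom": chrom,
            "position": positions,
        }
    )


class TestMapProbes:
    def test_probe_inside_region(self):
        out = map_probes(manifest_frame([1500]), [region(1000, 2000, cluster=2)])
        assert out.iloc[0]["category"] == "bivalent"
        assert out.iloc[0]["cluster"] == 2
        assert out.iloc[0]["region_id"] == "r1"

    def test_half_open_end_is_outside(self):
        out = map_probes(manifest_frame([2000]), [region(1000, 2000)])
        assert out.iloc[0]["category"] == "none"

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            map_probes(
                manifest_frame([0]),
                [region(1000, 2000, rid="a"), region(1500, 2500, rid="b")],
            )

    def test_matches_linear_scan_oracle(self, rng):
        regions = []
        pos = 0
        for i in range(50):
            pos += int(rng.integers(3000, 10_000))
            width = int(rng.integers(1000, 3000))
            cat = ["bivalent", "K4only", "K27only"][i % 3]
            regions.append(region(pos, pos + width, cat, rid=f"r{i}"))
            pos += width
        probes = rng.integers(0, pos + 5000, size=500)
        out = map_probes(manifest_frame(list(probes)), regions)
        for p, got in zip(probes, out["category"]):
            want = "none"
            for r in regions:  # brute-force linear scan
                if r.interval.start <= p < r.interval.end:
                    want = r.category
                    break
            assert got == want

    def test_partition_every_probe_one_category(self, small_study):
        from bivatlas.synth import simulate_methylomes

        truth = small_study["truth"]
        meth = simulate_methylomes(truth, n_pairs=4, n_types=2, n_probes=3000)
        lists = small_study["lists"]
        regions = lists["bivalent"] + lists["K4only"] + lists["K27only"]
        out = map_probes(meth.manifest, regions)
        assert len(out) == len(meth.manifest)
        counts = out["category"].value_counts()
        assert counts.sum() == len(out)
        assert set(counts.index) <= {"none", "bivalent", "K4only", "K27only"}


class TestBetaCategories:
    def test_one_probe_per_band(self):
        bands = beta_categories(pd.Series([0.05, 0.5, 0.8]))
        assert bands.tolist() == [BETA_BANDS[0], BETA_BANDS[2], BETA_BANDS[3]]

    def test_boundary_0_3_is_mid_band(self):
        assert beta_categories(pd.Series([0.3])).iloc[0] == BETA_BANDS[2]

    def test_boundary_0_7_is_mid_band(self):
        assert beta_categories(pd.Series([0.7])).iloc[0] == BETA_BANDS[2]

    def test_bands_partition_non_missing(self, rng):
        v = pd.Series(rng.random(500))
        v.iloc[:20] = np.nan
        bands = beta_categories(v)
        assert bands.notna().sum() == 480

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_categories(pd.Series([1.2]))

    def test_counts_by_category_sum(self, rng):
        beta = pd.Series(rng.random(300), index=[f"cg{i}" for i in range(300)])
        cats = pd.Series(
            rng.choice(["none", "bivalent", "K4only"], 300), index=beta.index
        )
        table = band_counts_by_category(beta, cats)
        assert table.to_numpy().sum() == 300


def beta_frame(x):
    return pd.DataFrame(
        x,
        index=[f"cg{i:04d}" for i in range(x.shape[0])],
        columns=[f"s{i}" for i in range(x.shape[1])],
    )


class TestModeratedT:
    def test_equal_variances_reduce_to_ordinary_t(self, rng):
        """When every probe has the same sample variance the prior has no
        excess spread (d0 = inf) and t_mod must equal the ordinary t."""
        n1 = n2 = 5
        base = rng.normal(0, 1, n1 + n2)
        shifts = rng.normal(0, 2, 50)
        x = np.stack([base + s for s in shifts])  # identical within-probe variance
        labels = ["tumor"] * n1 + ["normal"] * n2
        res = moderated_t_test(beta_frame(x), labels)
        assert np.isinf(res.attrs["d0"])
        t_ord = stats.ttest_ind(x[:, :n1], x[:, n1:], axis=1).statistic
        assert np.allclose(res["t_mod"].to_numpy(), t_ord, rtol=1e-10)

    def test_d0_zero_limit_is_ordinary_t(self, rng):
        x = rng.normal(0.5, 0.05, size=(200, 12))
        labels = ["tumor"] * 6 + ["normal"] * 6
        res = moderated_t_test(beta_frame(x), labels, d0=0.0, s0_sq=1.0)
        t_ord = stats.ttest_ind(x[:, :6], x[:, 6:], axis=1)
        assert np.allclose(res["t_mod"].to_numpy(), t_ord.statistic, rtol=1e-10)
        assert np.allclose(res["p"].to_numpy(), t_ord.pvalue, rtol=1e-9)

    def test_null_p_values_roughly_uniform(self, rng):
        x = rng.normal(0.5, 0.05, size=(4000, 20))
        res = moderated_t_test(beta_frame(x), ["tumor"] * 10 + ["normal"] * 10)
        frac = (res["p"] < 0.05).mean()
        assert 0.035 < frac < 0.065

    def test_missing_values_skip_underpowered_probes(self, rng):
        x = rng.normal(0.5, 0.05, size=(10, 8))
        x[0, :3] = np.nan  # only 1 tumor value left
        res = moderated_t_test(beta_frame(x), ["tumor"] * 4 + ["normal"] * 4)
        assert not res["tested"].iloc[0]
        assert np.isnan(res["t_mod"].iloc[0])
        assert res["tested"].iloc[1:].all()

    def test_too_few_samples_rejected(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            moderated_t_test(beta_frame(x), ["tumor", "normal", "normal"])

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (1e-5, 0.01, 0.5, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-6)

    def test_agrees_with_limma(self, rng):
        """Independent oracle: Bioconductor limma on the same matrix."""
        n1 = n2 = 5
        x = rng.normal(0.3, 0.05, size=(300, n1 + n2))
        x[:20, :n1] += 0.3
        df = beta_frame(x)
        with tempfile.TemporaryDirectory() as td:
            mat, out = os.path.join(td, "m.tsv"), os.path.join(td, "res.tsv")
            df.to_csv(mat, sep="\t")
            rcode = f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{mat}", row.names=1))
            design <- cbind(Intercept=1, Tumor=c(rep(1,{n1}), rep(0,{n2})))
            fit <- eBayes(lmFit(x, design))
            write.table(data.frame(t=fit$t[,"Tumor"], d0=fit$df.prior,
                        s0=fit$s2.prior), "{out}", sep="\\t", quote=FALSE)
            """
            subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
            limma = pd.read_csv(out, sep="\t")
        res = moderated_t_test(df, ["tumor"] * n1 + ["normal"] * n2)
        assert res.attrs["d0"] == pytest.approx(limma["d0"].iloc[0], rel=1e-6)
        assert res.attrs["s0_sq"] == pytest.approx(limma["s0"].iloc[0], rel=1e-6)
        assert np.allclose(res["t_mod"].to_numpy(), limma["t"].to_numpy(), atol=1e-8)


class TestBhFdr:
    def test_hand_computed_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_order_preserving(self, rng):
        p = rng.random(200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_bruteforce_definition(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 200)))
            assert np.allclose(bh_fdr(p), bh_bruteforce(p), atol=1e-12)

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])


class TestCallDmps:
    def _results(self, delta, p):
        return pd.DataFrame(
            {
                "delta_beta": delta,
                "t_mod": np.zeros(len(delta)),
                "p": p,
                "df_total": 10.0,
                "s2": 1.0,
                "tested": True,
            },
            index=[f"cg{i}" for i in range(len(delta))],
        )

    def test_hyper_rule(self):
        out = call_dmps(self._results([0.30], [1e-4]))
        assert out["call"].iloc[0] == "hyper"

    def test_insignificant_q_blocks_call(self):
        out = call_dmps(self._results([0.30], [0.20]))
        assert out["call"].iloc[0] == "none"

    def test_hypo_rule_negative_delta(self):
        out = call_dmps(self._results([-0.30], [1e-4]))
        assert out["call"].iloc[0] == "hypo"

    def test_small_effect_blocked_despite_significance(self):
        out = call_dmps(self._results([0.10], [1e-6]))
        assert out["call"].iloc[0] == "none"


class TestStratifyCimp:
    def _samples(self, cimps):
        rows = []
        for i, cimp in enumerate(cimps):
            rows.append(
                {"sample_id": f"T{i}", "status": "tumor", "pair_id": f"P{i}", "cimp": cimp}
            )
            rows.append(
                {"sample_id": f"N{i}", "status": "normal", "pair_id": f"P{i}", "cimp": "NA"}
            )
        return pd.DataFrame(rows)

    def test_all_positive_means_no_negative_arm(self):
        arms = stratify_cimp(self._samples(["positive"] * 4))
        assert set(arms) == {"positive"}

    def test_split_arms_are_disjoint_tumor_subsets(self):
        arms = stratify_cimp(self._samples(["positive"] * 3 + ["negative"] * 3))
        pos = set(arms["positive"].loc[arms["positive"]["status"] == "tumor", "sample_id"])
        neg = set(arms["negative"].loc[arms["negative"]["status"] == "tumor", "sample_id"])
        assert pos.isdisjoint(neg)
        # matched normals follow their tumors
        assert set(arms["positive"]["pair_id"]) == {"P0", "P1", "P2"}

    def test_na_tumors_excluded(self):
        arms = stratify_cimp(self._samples(["positive", "NA", "negative"]))
        all_ids = set(
            pd.concat(list(arms.values()))["sample_id"]
        )
        assert "T1" not in all_ids and "N1" not in all_ids


class TestCategoryDistribution:
    def _cats(self, categories, clusters=None):
        n = len(categories)
        return pd.DataFrame(
            {
                "category": categories,
                "region_id": [f"r{i}" for i in range(n)],
                "cluster": clusters if clusters is not None else [np.nan] * n,
            },
            index=[f"cg{i}" for i in range(n)],
        )

    def _calls(self, calls):
        return pd.DataFrame(
            {"call": calls, "delta_beta": 0.0, "p": 0.5, "q": 0.5, "tested": True},
            index=[f"cg{i}" for i in range(len(calls))],
        )

    def test_all_hyper_in_bivalent(self):
        cats = self._cats(["bivalent"] * 4, clusters=[2, 2, 2, 2])
        dist = category_distribution(self._calls(["hyper"] * 4), cats)
        assert dist["hyper"]["fractions"]["bivalent"] == 1.0
        assert dist["hyper"]["cluster_fractions"][2.0] == 1.0

    def test_no_calls_flagged_absent(self):
        cats = self._cats(["bivalent", "none"])
        dist = category_distribution(self._calls(["none", "none"]), cats)
        assert dist["hyper"] is None and dist["hypo"] is None
        assert dist["reference"].sum() == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, rng):
        n = 200
        cats = self._cats(list(rng.choice(["none", "bivalent", "K4only", "K27only"], n)))
        calls = list(rng.choice(["hyper", "hypo", "none"], n, p=[0.2, 0.1, 0.7]))
        dist = category_distribution(self._calls(calls), cats)
        for d in ("hyper", "hypo"):
            assert dist[d]["fractions"].sum() == pytest.approx(1.0)


class TestRecurrence:
    def _sets(self, memberships):
        # memberships: probe -> number of types it is hyper in (of 8)
        types = [f"T{i}" for i in range(8)]
        sets = {t: set() for t in types}
        for probe, k in memberships.items():
            for t in types[:k]:
                sets[t].add(probe)
        return sets

    def test_five_of_eight_boundary(self):
        rec = recurrence(self._sets({"a": 5, "b": 4}), min_types=5)
        assert rec["probes"] == {"a"}

    def test_monotone_in_min_types(self):
        sets = self._sets({"a": 8, "b": 6, "c": 5, "d": 3})
        sizes = [recurrence(sets, min_types=k)["n_probes"] for k in (1, 3, 5, 7, 8)]
        assert sizes == sorted(sizes, reverse=True)

    def test_too_few_analyses_rejected(self):
        with pytest.raises(ValueError):
            recurrence({"T0": {"a"}}, min_types=5)

    def test_promoter_regions_reported(self):
        sets = self._sets({"a": 6, "b": 6})
        regions = pd.Series({"a": "BIV00001", "b": "BIV00001"})
        rec = recurrence(sets, min_types=5, probe_regions=regions)
        assert rec["regions"] == {"BIV00001"}
        assert rec["n_regions"] == 1
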