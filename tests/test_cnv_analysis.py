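"""CNV annotation against a per-base oracle, cohort battery, region reports."""

import numpy as np
import pandas as pd
import pytest

import neuroscore as ns
from neuroscore.cnv_analysis import (
    LEVEL_ORDER,
    _max_level_counts,
    drop_unscored_cnvs,
    filter_aneuploidies,
)


def _scores(values: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"symbol": list(values), "score": pd.array(list(values.values()), dtype="Int64")}
    )


@pytest.fixture()
def toy_index():
    exons = pd.DataFrame(
        {
            "chrom": ["chr1"] * 5,
            "start": [100, 400, 1000, 1200, 2000],
            "end": [200, 500, 1100, 1300, 2100],
            "gene": ["A", "A", "B", "B", "C"],
        }
    )
    return ns.GeneModelIndex(exons)


class TestAnnotate:
    def test_two_gene_summary(self, toy_index):
        cnv = ns.CNVRecord("chr1", 150, 1250)
        out = ns.annotate_cnv(cnv, toy_index, _scores({"A": 4, "B": 2, "C": 0}))
        assert out.genes == ["A", "B"]
        assert out.max_level == 4
        assert out.median_percent == 60.0 and out.mean_percent == 60.0
        assert out.high_count == 1 and out.scored_genes == 2

    def test_intronic_overlap_excluded(self, toy_index):
        # interval between gene A's exons
        out = ns.annotate_cnv(ns.CNVRecord("chr1", 250, 350), toy_index,
                              _scores({"A": 4}))
        assert out.genes == [] and out.max_level is None

    def test_na_only_genes_dropped_downstream(self, toy_index):
        cnvs = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [180]})
        ann = ns.annotate_cnvs(cnvs, toy_index, _scores({"A": None}))
        assert ann.loc[0, "scored_genes"] == 0 and pd.isna(ann.loc[0, "max_level"])
        cnvs2 = drop_unscored_cnvs(ann.assign(n_genes=[0]))
        assert cnvs2.empty

    def test_unknown_chromosome_errors(self, toy_index):
        with pytest.raises(KeyError):
            ns.annotate_cnv(ns.CNVRecord("chrZ", 1, 10), toy_index, _scores({"A": 1}))

    def test_record_order_invariance(self):
        exons = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "start": [100, 400, 900, 50],
                "end": [200, 500, 950, 80],
                "gene": ["A", "B", "B", "C"],
            }
        )
        scores = _scores({"A": 2, "B": 5, "C": 1})
        a = ns.annotate_cnv(ns.CNVRecord("chr1", 0, 1000), ns.GeneModelIndex(exons), scores)
        shuffled = exons.sample(frac=1, random_state=1)
        b = ns.annotate_cnv(ns.CNVRecord("chr1", 0, 1000), ns.GeneModelIndex(shuffled), scores)
        assert a == b

    def test_matches_per_base_membership_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n_ex = rng.integers(5, 25)
            starts = rng.integers(0, 900, n_ex)
            exons = pd.DataFrame(
                {
                    "chrom": "c1",
                    "start": starts,
                    "end": starts + rng.integers(1, 80, n_ex),
                    "gene": [f"g{i}" for i in rng.integers(0, 8, n_ex)],
                }
            )
            index = ns.GeneModelIndex(exons)
            s, e = sorted(rng.integers(0, 1000, 2).tolist())
            if s == e:
                e += 1
            got = index.query("c1", s, e)
            cnv_bases = set(range(s, e))
            oracle = {
                g
                for g, sub in exons.groupby("gene")
                if any(cnv_bases & set(range(a, b)) for a, b in zip(sub["start"], sub["end"]))
            }
            assert got == oracle

    def test_gene_body_mode(self, toy_index):
        exons = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [100, 400], "end": [200, 500], "gene": ["A", "A"]}
        )
        body = ns.GeneModelIndex(exons, mode="gene_body")
        assert body.query("chr1", 250, 350) == {"A"}  # intron covered by gene body

    def test_aneuploidy_guard(self):
        summaries = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 10], "end": [95, 30]}
        )
        with pytest.warns(UserWarning):
            kept = filter_aneuploidies(summaries, {"chr1": 100})
        assert len(kept) == 1


def _mk_summaries(n, rng, cnv_type="loss", mean_pct=10.0, size=100_000, high_rate=0.1):
    return pd.DataFrame(
        {
            "cnv_type": cnv_type,
            "size_bp": rng.normal(size, size / 5, n).clip(1000),
            "n_genes": rng.poisson(3, n) + 1,
            "scored_genes": rng.poisson(2, n) + 1,
            "mean_percent": rng.normal(mean_pct, 8, n).clip(0, 100),
            "median_percent": rng.normal(mean_pct, 8, n).clip(0, 100),
            "high_count": (rng.random(n) < high_rate).astype(int),
        }
    )


class TestCompareCohorts:
    def test_identical_cohorts_nothing_significant(self):
        rng = np.random.default_rng(0)
        df = pd.concat(
            [_mk_summaries(400, rng, "loss"), _mk_summaries(400, rng, "gain")]
        )
        out = ns.compare_cohorts(df, df.copy())
        assert not out["significant"].any()
        assert (out["p"] > 0.9).all()

    def test_shifted_scores_detected(self):
        rng = np.random.default_rng(1)
        cases = pd.concat(
            [_mk_summaries(800, rng, t, mean_pct=16) for t in ("loss", "gain")]
        )
        controls = pd.concat(
            [_mk_summaries(800, rng, t, mean_pct=9) for t in ("loss", "gain")]
        )
        out = ns.compare_cohorts(cases, controls).set_index(["test", "stratum"])
        assert out.loc[("mean_percent", "loss"), "significant"]
        assert out.loc[("mean_percent", "gain"), "significant"]

    def test_equal_scores_triple_size_only_size_tests_fire(self):
        rng = np.random.default_rng(2)
        cases = pd.concat(
            [_mk_summaries(700, rng, t, size=300_000) for t in ("loss", "gain")]
        )
        controls = pd.concat(
            [_mk_summaries(700, rng, t, size=100_000) for t in ("loss", "gain")]
        )
        out = ns.compare_cohorts(cases, controls)
        fired = set(out.loc[out["significant"], "test"])
        assert fired == {"size_bp"}

    def test_bonferroni_schedule(self):
        rng = np.random.default_rng(3)
        df = pd.concat([_mk_summaries(50, rng, t) for t in ("loss", "gain")])
        out = ns.compare_cohorts(df, df.copy())
        assert (out["bonferroni_alpha"] == 0.05 / 10).all()

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            ns.compare_cohorts(pd.DataFrame(), pd.DataFrame({"cnv_type": []}))


class TestMaxScoreDistribution:
    @pytest.fixture(scope="class")
    def table3(self):
        return ns.load_fixture("table3_counts")

    def test_loss_score5_fisher_significant(self, table3):
        out = ns.level_tests_from_counts(
            table3["loss"]["case"], table3["loss"]["control"]
        ).set_index("level")
        row = out.loc[5]
        assert row["test"] == "fisher"
        assert row["p"] == pytest.approx(9e-4, rel=0.05)
        assert row["significant"]

    def test_large_cells_use_chi2(self, table3):
        out = ns.level_tests_from_counts(
            table3["loss"]["case"], table3["loss"]["control"]
        ).set_index("level")
        assert out.loc[0, "test"] == "chi2"

    def test_partition_conservation(self, labeled, scored, gene_map, model_index):
        cnvs = ns.simulate_cnv_cohorts(
            ns.CNVSimConfig(n_case_loss=80, n_case_gain=80, n_control_loss=80,
                            n_control_gain=80),
            gene_map[0], scored, seed=9, exons=gene_map[1],
        )
        ann = ns.annotate_cnvs(cnvs, model_index, scored)
        for stratum in ("loss", "gain"):
            for cohort in ("case", "control"):
                sub = ann[(ann.cnv_type == stratum) & (ann.cohort == cohort)]
                counts = _max_level_counts(sub)
                assert counts.sum() == len(sub)
                assert list(counts.index) == list(LEVEL_ORDER)

    def test_degenerate_level_skipped(self):
        case = pd.Series({5: 0, 4: 0, 3: 0, 2: 0, 1: 0, 0: 10, "NA": 0})
        control = pd.Series({5: 0, 4: 0, 3: 0, 2: 0, 1: 0, 0: 12, "NA": 0})
        out = ns.level_tests_from_counts(case, control).set_index("level")
        assert out.loc[5, "test"] == "degenerate"
        assert not out.loc[5, "significant"]


class TestHighGeneOR:
    def test_from_table3_counts(self):
        t3 = ns.load_fixture("table3_counts")
        res = ns.high_gene_or_from_counts(
            {k: v["case"] for k, v in t3.items()},
            {k: v["control"] for k, v in t3.items()},
        )
        assert round(res.or_estimate, 1) == 9.3

    def test_equal_rates_near_one(self):
        rng = np.random.default_rng(4)
        a = _mk_summaries(2000, rng, high_rate=0.1)
        b = _mk_summaries(2000, rng, high_rate=0.1)
        res = ns.high_gene_or(a, b)
        assert res.ci_low <= 1.0 <= res.ci_high


class TestSubgroups:
    def _cases(self, rng, n=200, shift=0.0):
        df = _mk_summaries(n, rng, "loss")
        df["sex"] = np.where(rng.random(n) < 0.5, "male", "female")
        df["inheritance"] = rng.choice(
            ["maternal", "paternal", "de_novo", "unknown"], n, p=[0.3, 0.3, 0.3, 0.1]
        )
        denovo = df["inheritance"] == "de_novo"
        df.loc[denovo, "mean_percent"] += shift
        df.loc[denovo, "median_percent"] += shift
        return df

    def test_null_groups_no_difference(self):
        rng = np.random.default_rng(5)
        out = ns.subgroup_compare(self._cases(rng, 400), by="sex")
        assert (out["p"] > 0.001).all()

    def test_injected_inheritance_shift_detected(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(25):
            cases = self._cases(rng, 140, shift=10.0)  # ~40 per inheritance group
            out = ns.subgroup_compare(cases, by="inheritance").set_index("test")
            hits += out.loc["mean_percent", "p"] < 0.05
        assert hits >= 0.8 * 25

    def test_unknown_category_excluded_and_counted(self):
        rng = np.random.default_rng(7)
        out = ns.subgroup_compare(self._cases(rng, 300), by="inheritance")
        assert (out["excluded"] > 0).all()

    def test_unknown_grouping_errors(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            ns.subgroup_compare(self._cases(rng, 50), by="cohort")


class TestPathogenicityRegression:
    def _cohort(self, rng, n=800, slope=0.5, size_confound=False):
        cls = rng.integers(1, 5, n)
        size = rng.normal(2e5, 5e4, n).clip(1e4)
        if size_confound:
            size = size + 1e5 * cls  # classification drives size only
            lam = 1e-6 * size
        else:
            lam = 0.2 + slope * (cls - 1)
        high = rng.poisson(lam)
        return pd.DataFrame(
            {
                "classification": cls,
                "size_bp": size,
                "high_count": high,
                "scored_genes": high + rng.poisson(2, n),
                "n_genes": high + rng.poisson(3, n) + 1,
                "median_percent": 10.0 + 6.7 * (cls - 1) + rng.normal(0, 10, n),
            }
        )

    def test_recovers_high_gene_slope(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            out = ns.pathogenicity_regression(self._cohort(rng)).set_index("outcome")
            row = out.loc["high_count"]
            hits += abs(row["beta"] - 0.5) < 2 * row["se"]
        assert hits >= 0.9 * 20

    def test_shuffled_classification_null(self):
        rng = np.random.default_rng(10)
        cohort = self._cohort(rng)
        cohort["classification"] = rng.permutation(cohort["classification"].values)
        out = ns.pathogenicity_regression(cohort).set_index("outcome")
        assert abs(out.loc["high_count", "beta"]) < 3 * out.loc["high_count", "se"]

    def test_size_covariate_absorbs_confound(self):
        rng = np.random.default_rng(11)
        cohort = self._cohort(rng, n=3000, size_confound=True)
        adjusted = ns.pathogenicity_regression(cohort).set_index("outcome")
        import statsmodels.api as sm

        unadjusted = sm.OLS(
            cohort["high_count"],
            sm.add_constant(cohort["classification"].astype(float)),
        ).fit()
        assert unadjusted.params["classification"] > 0.05
        assert abs(adjusted.loc["high_count", "beta"]) < 0.05

    def test_single_level_errors(self):
        rng = np.random.default_rng(12)
        cohort = self._cohort(rng, n=50)
        cohort["classification"] = 2
        with pytest.raises(ValueError):
            ns.pathogenicity_regression(cohort)


class TestRegionReport:
    @pytest.fixture()
    def setup(self):
        exons = pd.DataFrame(
            {
                "chrom": "chr7",
                "start": [100, 600, 1100, 1600, 2100],
                "end": [300, 800, 1300, 1800, 2300],
                "gene": list("ABCDE"),
            }
        )
        scores = _scores({"A": 4, "B": 0, "C": 3, "D": 1, "E": None})
        return ns.GeneModelIndex(exons), scores

    def test_segment_union_equals_region(self, setup):
        index, scores = setup
        profiles, table = ns.region_report(
            ("chr7", 0, 2500), {"left": (0, 1000), "right": (1000, 2500)}, index, scores
        )
        whole = profiles["region"]
        left, right = profiles["left"], profiles["right"]
        assert left.total_genes + right.total_genes == whole.total_genes
        assert len(left.high_scoring_genes) + len(right.high_scoring_genes) == len(
            whole.high_scoring_genes
        )
        assert table["gene"].tolist() == list("ABCDE")
        assert table.set_index("gene").loc["A", "high_scoring"]

    def test_segment_outside_region_errors(self, setup):
        index, scores = setup
        with pytest.raises(ValueError):
            ns.region_report(("chr7", 0, 1000), {"bad": (500, 2000)}, index, scores)

    def test_empty_segment_warns(self, setup):
        index, scores = setup
        with pytest.warns(UserWarning):
            profiles, _ = ns.region_report(
                ("chr7", 0, 2500), {"gap": (310, 590)}, index, scores
            )
        assert profiles["gap"].total_genes == 0


class TestRegionFixtures:
    def test_wbs_counts(self):
        fx = ns.load_fixture("wbs_region")
        prof = ns.profile_gene_set(fx["genes"]["symbol"].tolist(), fx["genes"])
        assert prof.total_genes == 25
        assert prof.scored_genes == 15
        assert len(prof.high_scoring_genes) == 6
        assert set(prof.high_scoring_genes) == {
            "GTF2I", "STX1A", "LIMK1", "BAZ1B", "EIF4H", "CLIP2"
        }

    def test_22q11_counts_and_segments(self):
        fx = ns.load_fixture("region_22q11")
        genes = fx["genes"]
        prof = ns.profile_gene_set(genes["symbol"].tolist(), genes)
        assert prof.total_genes == 64
        assert prof.scored_genes == 38
        assert len(prof.high_scoring_genes) == 8
        assert int(genes.set_index("symbol").loc["MAPK1", "score"]) == 4
        for segment, sub in genes.groupby("segment"):
            seg_prof = ns.profile_gene_set(sub["symbol"].tolist(), genes)
            assert len(seg_prof.high_scoring_genes) >= 1


class TestCNVRecord:
    def test_validation(self):
        with pytest.raises(ValueError):
            ns.CNVRecord("chr1", 100, 100)
        with pytest.raises(ValueError):
            ns.CNVRecord("chr1", 0, 10, cnv_type="inversion")
        with pytest.raises(ValueError):
            ns.CNVRecord("chr1", 0, 10, classification=7)
        assert ns.CNVRecord("chr1", 0, 10).size_bp == 10
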