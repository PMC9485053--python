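"""Cytosine contexts, coverage filtering, and methylation aggregation."""

import numpy as np
import pandas as pd
import pytest

from carpet.errors import InvalidInputError, UndefinedMeanError
from carpet.intervals import IntervalSet
from carpet.methylome import (
    assign_context,
    context_mask,
    coverage_fraction,
    filter_by_coverage,
    gene_mcac_covariates,
    local_inside_outside,
    mean_methylation,
    read_cytosine_report,
    repeat_chunk_methylation,
    window_mcac_track,
    write_cytosine_report,
)


def make_sites(rows):
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context3", "meth", "total"]
    )
    df["ratio"] = np.where(df["total"] > 0, df["meth"] / df["total"].replace(0, 1), np.nan)
    return df


class TestAssignContext:
    def test_plus_strand(self):
        genome = {"c": "ACACGT"}
        assert assign_context(genome, "c", 1, "+") == "CAC"
        assert assign_context(genome, "c", 3, "+") == "CGT"

    def test_minus_strand_gtg_reads_cac(self):
        # plus strand GTG; the minus-strand C opposite the last G has context CAC
        genome = {"c": "AGTGA"}
        assert assign_context(genome, "c", 3, "-") == "CAC"

    def test_truncated_context_padded(self):
        genome = {"c": "GGC"}
        assert assign_context(genome, "c", 2, "+") == "CNN"
        assert assign_context(genome, "c", 0, "-") == "CNN"

    def test_non_c_base_rejected(self):
        with pytest.raises(InvalidInputError):
            assign_context({"c": "AAAA"}, "c", 0, "+")


class TestReport:
    def test_read_basics(self, tmp_path):
        p = tmp_path / "cx.tsv"
        p.write_text("chr1\t11\t+\t3\t2\tCHH\tCAC\nchr1\t20\t-\t0\t0\tCpG\tCGA\n")
        sites = read_cytosine_report(p)
        assert sites.loc[0, "pos"] == 10  # 1-based -> 0-based
        assert sites.loc[0, "ratio"] == pytest.approx(0.6)
        assert sites.loc[1, "total"] == 0 and np.isnan(sites.loc[1, "ratio"])

    def test_round_trip(self, tmp_path, mini_study):
        sub = mini_study.sites.head(500)[
            ["chrom", "pos", "strand", "context3", "meth", "total", "ratio"]
        ]
        p = tmp_path / "roundtrip.tsv"
        write_cytosine_report(sub, p)
        back = read_cytosine_report(p)
        for col in ("chrom", "pos", "strand", "context3", "meth", "total"):
            assert back[col].tolist() == sub[col].tolist()


class TestContextMask:
    def test_hierarchy_on_simulated_sites(self, mini_study):
        sites = mini_study.sites
        n_ca = int(context_mask(sites, "CA").sum())
        n_cac = int(context_mask(sites, "CAC").sum())
        n_cah = int(context_mask(sites, "CAH").sum())
        assert n_ca == n_cac + n_cah
        assert not (context_mask(sites, "CG") & context_mask(sites, "CA")).any()


class TestAggregation:
    def test_filter_by_coverage(self):
        sites = make_sites([("c", 5, "+", "CAC", 2, 4), ("c", 9, "+", "CAC", 5, 10)])
        assert filter_by_coverage(sites, 5)["pos"].tolist() == [9]
        assert filter_by_coverage(sites, 10)["pos"].tolist() == [9]
        assert len(filter_by_coverage(sites.iloc[0:0], 5)) == 0

    def test_mean_methylation(self):
        sites = make_sites(
            [("c", 5, "+", "CAC", 8, 10), ("c", 9, "-", "CAC", 2, 10),
             ("c", 20, "+", "CGA", 10, 10)]
        )
        assert mean_methylation(sites, "CAC") == pytest.approx(0.5)
        assert mean_methylation(sites, None) == pytest.approx((0.8 + 0.2 + 1.0) / 3)
        with pytest.raises(UndefinedMeanError):
            mean_methylation(sites, "CAC", IntervalSet({"c": np.array([[100, 200]])}))

    def test_scope_and_outside(self):
        sites = make_sites(
            [("c", 5, "+", "CAC", 10, 10), ("c", 50, "+", "CAC", 0, 10)]
        )
        scope = IntervalSet({"c": np.array([[0, 10]])})
        assert mean_methylation(sites, "CAC", scope) == pytest.approx(1.0)
        assert mean_methylation(sites, "CAC", scope, outside=True) == pytest.approx(0.0)

    def test_coverage_fraction(self):
        sites = make_sites(
            [("c", i, "+", "CAC", 0, t) for i, t in enumerate([6, 8, 2, 5])]
        )
        assert coverage_fraction(sites, "CAC", 5) == pytest.approx(0.75)
        assert coverage_fraction(sites, "CAC", 1) == 1.0
        with pytest.raises(UndefinedMeanError):
            coverage_fraction(sites, "CG", 5)

    def test_planted_rate_recovered(self, mini_study):
        cfg = mini_study.config
        sites = filter_by_coverage(mini_study.sites, 5)
        est = mean_methylation(sites, "CG")
        n = int(context_mask(sites, "CG").sum())
        se = np.sqrt(cfg.rate_mcg * (1 - cfg.rate_mcg) / 5) / np.sqrt(n)
        assert abs(est - cfg.rate_mcg) < 5 * se + 0.01


class TestWindowTrack:
    def test_sum_definition_and_uncovered_flag(self):
        sites = make_sites(
            [("c", 10, "+", "CAC", 10, 10), ("c", 20, "-", "CAC", 10, 10),
             ("c", 30, "+", "CAC", 5, 10)]
        )
        track = window_mcac_track(sites, {"c": 2000}, width=1000)
        assert track.loc[0, "value"] == pytest.approx(2.5)
        assert bool(track.loc[1, "covered"]) is False
        assert track.loc[1, "value"] == 0.0

    def test_partial_window_scaled(self):
        sites = make_sites([("c", 1100, "+", "CAC", 10, 10)])
        track = window_mcac_track(sites, {"c": 1500}, width=1000)
        assert track.loc[1, "value"] == pytest.approx(1.0 * 1000 / 500)

    def test_conservation_over_windows(self, mini_study):
        from carpet.methylome import filter_by_coverage

        sites = filter_by_coverage(mini_study.sites, 5)
        track = window_mcac_track(sites, mini_study.contig_sizes, width=1000)
        mask = context_mask(sites, "CAC") & (sites["total"] > 0).to_numpy()
        assert track["sum_ratio"].sum() == pytest.approx(sites.loc[mask, "ratio"].sum())


class TestRepeatChunks:
    def _loci(self, coords):
        return pd.DataFrame(
            [
                {"chrom": "c", "start": s, "end": e, "strand": ".", "unit": "CA",
                 "unit_count": (e - s) // 2, "repeat_class": "CA_repeat"}
                for s, e in coords
            ]
        )

    def test_greedy_grouping_and_scaling(self):
        loci = self._loci([(0, 600), (1000, 1500)])  # 600 + 500 -> one 1100 bp chunk
        sites = make_sites([("c", 10, "+", "CAC", 10, 10), ("c", 1200, "+", "CAC", 10, 10)])
        chunks, tagged = repeat_chunk_methylation(sites, loci, target_len=1000)
        assert len(chunks) == 1
        assert chunks.loc[0, "repeat_bases"] == 1100
        assert chunks.loc[0, "per_kb"] == pytest.approx(2.0 * 1000 / 1100)
        assert tagged["chunk_id"].tolist() == [0, 0]

    def test_single_kilobase_locus(self):
        loci = self._loci([(0, 1000)])
        sites = make_sites([("c", 10, "+", "CAC", 5, 10)])
        chunks, _ = repeat_chunk_methylation(sites, loci, target_len=1000)
        assert chunks.loc[0, "per_kb"] == pytest.approx(0.5)

    def test_trailing_chunk_kept_and_conservation(self):
        loci = self._loci([(0, 600), (1000, 1600), (2000, 2300)])  # chunks: 1200, 300
        sites = make_sites(
            [("c", p, "+", "CAC", 10, 10) for p in (5, 1005, 2005)]
        )
        chunks, _ = repeat_chunk_methylation(sites, loci, target_len=1000)
        assert chunks["repeat_bases"].tolist() == [1200, 300]
        assert chunks["sum_ratio"].sum() == pytest.approx(3.0)


class TestGeneCovariates:
    def test_incl_excl_decomposition(self):
        genes = pd.DataFrame([{"chrom": "c", "start": 0, "end": 1000, "gene_id": "g1"}])
        ca_set = IntervalSet({"c": np.array([[100, 120]])})
        rows = [("c", p, "+", "CAC", 10, 10) for p in (10, 50, 105, 110, 500, 900)]
        rows += [("c", 107, "-", "CAA", 10, 10)]  # CA-context inside array
        sites = make_sites(rows)
        cov = gene_mcac_covariates(sites, genes, ca_set)
        assert cov.loc[0, "mcac_incl"] == pytest.approx(6.0)
        assert cov.loc[0, "mcac_excl"] == pytest.approx(4.0)
        assert cov.loc[0, "mca_in_arrays"] == pytest.approx(3.0)  # 2 CAC + 1 CAA
        assert cov.loc[0, "mcac_per_kb"] == pytest.approx(6.0)

    def test_gene_without_arrays(self):
        genes = pd.DataFrame([{"chrom": "c", "start": 0, "end": 1000, "gene_id": "g1"}])
        sites = make_sites([("c", 10, "+", "CAC", 10, 10)])
        cov = gene_mcac_covariates(sites, genes, IntervalSet())
        assert cov.loc[0, "mcac_incl"] == cov.loc[0, "mcac_excl"]
        assert cov.loc[0, "mca_in_arrays"] == 0.0

    def test_uncovered_gene_flagged(self):
        genes = pd.DataFrame([{"chrom": "c", "start": 0, "end": 500, "gene_id": "g1"}])
        sites = make_sites([("c", 10, "+", "CAC", 0, 0)])
        cov = gene_mcac_covariates(sites, genes, IntervalSet())
        assert bool(cov.loc[0, "uncovered"]) is True
        assert cov.loc[0, "mcac_incl"] == 0.0

    def test_brute_force_recount_on_simulation(self, mini_study):
        from carpet.methylome import filter_by_coverage

        sites = filter_by_coverage(mini_study.sites, 5)
        genes = mini_study.genes.head(12)
        cov = gene_mcac_covariates(sites, genes, mini_study.ca_set)
        for i, g in genes.iterrows():
            sub = sites[
                (sites["chrom"] == g["chrom"])
                & (sites["pos"] >= g["start"])
                & (sites["pos"] < g["end"])
                & (sites["context3"] == "CAC")
            ]
            expect = sub["ratio"].sum()
            row = cov[cov["gene_id"] == g["gene_id"]].iloc[0]
            assert row["mcac_incl"] == pytest.approx(expect)
            in_arr = mini_study.ca_set.contains_points(
                g["chrom"], sub["pos"].to_numpy()
            )
            assert row["mcac_excl"] == pytest.approx(sub["ratio"].to_numpy()[~in_arr].sum())


class TestStrandSymmetry:
    def test_aggregates_invariant_under_reverse_complement(self):
        from carpet.simulate import SimConfig, simulate_methylome
        from carpet.seq import revcomp

        genome = {"c": "TTCACACACACACATTGCGCGTACGTTGGTGTGTGTGTGTT" * 20}
        cfg = SimConfig(seed=5, coverage_mean=20.0)
        fld = {"c": np.ones(1)}
        fwd = simulate_methylome(genome, IntervalSet(), cfg, fld)
        rc_genome = {"c": revcomp(genome["c"])}
        rev = simulate_methylome(rc_genome, IntervalSet(), cfg, fld)
        # same context composition either way
        for ctx in ("CAC", "CA", "CG"):
            assert int(context_mask(fwd, ctx).sum()) == int(context_mask(rev, ctx).sum())
        # and identical true-probability multisets
        np.testing.assert_allclose(
            np.sort(fwd["true_p"].to_numpy()), np.sort(rev["true_p"].to_numpy())
        )


class TestLocalInsideOutside:
    def test_paired_comparison_detects_planted_enrichment(self):
        rng = np.random.default_rng(0)
        arrays = pd.DataFrame(
            [{"chrom": "c", "start": s, "end": s + 50} for s in range(1000, 20000, 2000)]
        )
        ca_set = IntervalSet.from_frame(arrays)
        rows = []
        for pos in range(0, 21000, 7):
            inside = ca_set.contains_points("c", np.array([pos]))[0]
            p = 0.3 if inside else 0.1
            total = 10
            rows.append(("c", pos, "+", "CAC", rng.binomial(total, p), total))
        sites = make_sites(rows)
        res = local_inside_outside(sites, arrays, ca_set, flank=1000)
        assert res["mean_diff"] > 3 * res["se_diff"]
        assert res["ratio"] == pytest.approx(3.0, rel=0.25)
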