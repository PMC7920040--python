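import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poolscan as ps
from poolscan.fst import _ScaffoldIndex, heterozygosity_components


def oracle_snp_fst(p1, p2):
    """Independent scalar reimplementation of the Nei-style estimator."""
    h1 = 1.0 - p1 * p1 - (1.0 - p1) * (1.0 - p1)
    h2 = 1.0 - p2 * p2 - (1.0 - p2) * (1.0 - p2)
    hw = (h1 + h2) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 1.0 - pbar * pbar - (1.0 - pbar) * (1.0 - pbar)
    return (ht - hw) / ht


def oracle_region_fst(pairs):
    """Ratio-of-sums aggregation recomputed from scratch."""
    hts, hws = [], []
    for p1, p2 in pairs:
        h1 = 2 * p1 * (1 - p1)
        h2 = 2 * p2 * (1 - p2)
        hws.append((h1 + h2) / 2)
        pbar = (p1 + p2) / 2
        hts.append(2 * pbar * (1 - pbar))
    return (sum(hts) - sum(hws)) / sum(hts)


def make_snp(p1_counts, p2_counts, pos=1):
    return ps.call_snp(ps.SyncSite("s", pos, "A", p1_counts, p2_counts))


class TestCallSnp:
    def test_fixed_difference(self):
        snp = make_snp((10, 0, 0, 0, 0, 0), (0, 10, 0, 0, 0, 0))
        assert snp.major_allele == "A" and snp.minor_allele == "T"
        assert snp.p1 == 0.0 and snp.p2 == 1.0

    def test_monomorphic_rejected(self):
        assert make_snp((10, 0, 0, 0, 0, 0), (10, 0, 0, 0, 0, 0)) is None

    def test_intermediate_frequencies(self):
        # T totals 12 reads vs A's 8, so A is minor by summed counts;
        # p(T) = 0.4 / 0.8 equals 1 - p(minor) and gives the same FST.
        snp = make_snp((6, 4, 0, 0, 0, 0), (2, 8, 0, 0, 0, 0))
        assert (snp.major_allele, snp.minor_allele) == ("T", "A")
        assert snp.p1 == pytest.approx(0.6) and snp.p2 == pytest.approx(0.2)
        assert 1 - snp.p1 == pytest.approx(0.4) and 1 - snp.p2 == pytest.approx(0.8)

    def test_coverage_bounds(self):
        filt = ps.SnpFilter(min_coverage=10, max_coverage=20)
        low = ps.SyncSite("s", 1, "A", (5, 4, 0, 0, 0, 0), (6, 6, 0, 0, 0, 0))
        high = ps.SyncSite("s", 1, "A", (15, 10, 0, 0, 0, 0), (6, 6, 0, 0, 0, 0))
        assert ps.call_snp(low, filt) is None
        assert ps.call_snp(high, filt) is None

    def test_min_minor_count(self):
        site = ps.SyncSite("s", 1, "A", (11, 1, 0, 0, 0, 0), (12, 0, 0, 0, 0, 0))
        assert ps.call_snp(site, ps.SnpFilter(min_minor_count=2)) is None
        assert ps.call_snp(site, ps.SnpFilter(min_minor_count=1)) is not None

    def test_third_allele_dropped_from_coverage(self):
        # C reads are neither major nor minor: they vanish, not redistribute
        site = ps.SyncSite("s", 1, "A", (10, 6, 3, 0, 0, 0), (10, 6, 0, 0, 0, 0))
        snp = ps.call_snp(site)
        assert snp.n1_major + snp.n1_minor == 16

    def test_n_and_deletion_never_alleles(self):
        site = ps.SyncSite("s", 1, "A", (10, 5, 0, 0, 90, 0), (10, 5, 0, 0, 0, 90))
        snp = ps.call_snp(site)
        assert {snp.major_allele, snp.minor_allele} == {"A", "T"}

    def test_tie_broken_alphabetically(self):
        # A and T tie at 10 reads each: A major, T minor
        snp = make_snp((10, 0, 0, 0, 0, 0), (0, 10, 0, 0, 0, 0))
        assert (snp.major_allele, snp.minor_allele) == ("A", "T")

    def test_rejection_counts(self, tiny_sites):
        df, rej = ps.call_snps(tiny_sites, ps.SnpFilter())
        assert len(df) == 2
        assert rej["monomorphic"] == 1 and rej["coverage_low"] == 1


class TestSnpFst:
    def test_complete_fixation(self):
        snp = make_snp((10, 0, 0, 0, 0, 0), (0, 10, 0, 0, 0, 0))
        assert ps.snp_fst(snp) == pytest.approx(1.0)

    def test_identical_frequencies(self):
        snp = make_snp((7, 3, 0, 0, 0, 0), (7, 3, 0, 0, 0, 0))
        assert ps.snp_fst(snp) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_example(self):
        # p1=0.4, p2=0.8: Hw=0.40, Ht=0.48, FST=1/6
        snp = make_snp((6, 4, 0, 0, 0, 0), (2, 8, 0, 0, 0, 0))
        assert ps.snp_fst(snp) == pytest.approx(1.0 / 6.0, abs=1e-12)

    @settings(max_examples=300, deadline=None)
    @given(
        a1=st.integers(1, 200), b1=st.integers(1, 200),
        a2=st.integers(1, 200), b2=st.integers(1, 200),
    )
    def test_matches_oracle_on_random_counts(self, a1, b1, a2, b2):
        snp = make_snp((a1, b1, 0, 0, 0, 0), (a2, b2, 0, 0, 0, 0))
        if snp is None:
            return
        assert ps.snp_fst(snp) == pytest.approx(oracle_snp_fst(snp.p1, snp.p2), abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        a1=st.integers(1, 100), b1=st.integers(1, 100),
        a2=st.integers(1, 100), b2=st.integers(1, 100),
    )
    def test_symmetric_under_pool_exchange(self, a1, b1, a2, b2):
        s1 = make_snp((a1, b1, 0, 0, 0, 0), (a2, b2, 0, 0, 0, 0))
        s2 = make_snp((a2, b2, 0, 0, 0, 0), (a1, b1, 0, 0, 0, 0))
        if s1 is None or s2 is None:
            return
        assert ps.snp_fst(s1) == pytest.approx(ps.snp_fst(s2), abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        a1=st.integers(1, 100), b1=st.integers(1, 100),
        a2=st.integers(1, 100), b2=st.integers(1, 100),
    )
    def test_invariant_to_allele_relabelling(self, a1, b1, a2, b2):
        s = make_snp((a1, b1, 0, 0, 0, 0), (a2, b2, 0, 0, 0, 0))
        if s is None:
            return
        # swap counts of the two alleles: FST computed from 1-p must agree
        assert oracle_snp_fst(1 - s.p1, 1 - s.p2) == pytest.approx(ps.snp_fst(s), abs=1e-12)

    def test_monotone_in_divergence(self):
        # p1 fixed at 0.5; FST grows as p2 moves away from 0.5
        fsts = [oracle_snp_fst(0.5, p2) for p2 in (0.5, 0.6, 0.75, 0.9, 1.0)]
        assert all(b > a for a, b in zip(fsts, fsts[1:]))
        fsts_down = [oracle_snp_fst(0.5, p2) for p2 in (0.5, 0.4, 0.25, 0.1, 0.0)]
        assert all(b > a for a, b in zip(fsts_down, fsts_down[1:]))

    def test_corrected_form_can_go_negative_but_not_above_one(self):
        snp = make_snp((7, 3, 0, 0, 0, 0), (7, 3, 0, 0, 0, 0))
        corrected = ps.snp_fst(snp, pool_sizes=(50, 50))
        assert corrected < 0.0
        fixed = make_snp((10, 0, 0, 0, 0, 0), (0, 10, 0, 0, 0, 0))
        assert ps.snp_fst(fixed, pool_sizes=(50, 50)) <= 1.0

    def test_correction_factor_formula(self):
        # n_i = min(coverage, 2*pool_size); check against direct algebra
        snp = make_snp((6, 4, 0, 0, 0, 0), (2, 8, 0, 0, 0, 0))
        n1 = n2 = 10  # coverage 10 < 2*50
        h1 = 2 * 0.4 * 0.6 * n1 / (n1 - 1)
        h2 = 2 * 0.8 * 0.2 * n2 / (n2 - 1)
        ht = 2 * 0.6 * 0.4
        expected = (ht - (h1 + h2) / 2) / ht
        assert ps.snp_fst(snp, pool_sizes=(50, 50)) == pytest.approx(expected, abs=1e-12)

    def test_uncorrected_in_unit_interval_on_simulated_data(self, desk_dataset):
        fst = desk_dataset["snp_df"]["fst"].to_numpy()
        assert np.all(fst >= 0.0) and np.all(fst <= 1.0)


class TestRegionFst:
    def test_single_snp_equals_snp_fst(self):
        snp = make_snp((6, 4, 0, 0, 0, 0), (2, 8, 0, 0, 0, 0))
        assert ps.region_fst_of_snps([snp]) == pytest.approx(ps.snp_fst(snp), abs=1e-15)

    def test_two_snp_hand_computed(self):
        # (Ht,Hw) pairs (0.48,0.40) and (0.50,0.50) -> 0.08/0.98
        assert ps.region_fst([0.48, 0.50], [0.40, 0.50]) == pytest.approx(
            0.08 / 0.98, abs=1e-12
        )

    def test_all_fixed_region_is_one(self):
        snps = [make_snp((10, 0, 0, 0, 0, 0), (0, 10, 0, 0, 0, 0), pos=i) for i in (1, 2, 3)]
        assert ps.region_fst_of_snps(snps) == pytest.approx(1.0)

    def test_empty_region_is_nan_not_zero(self):
        assert np.isnan(ps.region_fst([], []))
        assert np.isnan(ps.region_fst_of_snps([]))

    def test_identical_snps_keep_single_value(self):
        snp = make_snp((6, 4, 0, 0, 0, 0), (2, 8, 0, 0, 0, 0))
        assert ps.region_fst_of_snps([snp] * 5) == pytest.approx(ps.snp_fst(snp), abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0.01, 0.99), st.floats(0.01, 0.99)),
            min_size=1, max_size=12,
        )
    )
    def test_ratio_of_sums_matches_oracle(self, pairs):
        ht, hw = heterozygosity_components(
            np.array([p for p, _ in pairs]), np.array([q for _, q in pairs])
        )
        assert ps.region_fst(ht, hw) == pytest.approx(oracle_region_fst(pairs), abs=1e-12)

    def test_mean_method_differs_from_ratio(self):
        pairs = [(0.4, 0.8), (0.5, 0.5)]
        ht, hw = heterozygosity_components(
            np.array([p for p, _ in pairs]), np.array([q for _, q in pairs])
        )
        mean = ps.region_fst(ht, hw, method="mean")
        assert mean == pytest.approx(np.mean([(a - b) / a for a, b in zip(ht, hw)]), abs=1e-12)


class TestGeneFst:
    def _snp_frame(self, positions, p1, p2, scaffold="s"):
        df = pd.DataFrame(
            {
                "scaffold": scaffold,
                "position": positions,
                "major_allele": "A",
                "minor_allele": "T",
                "n1_major": [round(20 * (1 - x)) for x in p1],
                "n1_minor": [round(20 * x) for x in p1],
                "n2_major": [round(20 * (1 - x)) for x in p2],
                "n2_minor": [round(20 * x) for x in p2],
                "p1": p1,
                "p2": p2,
            }
        )
        return ps.add_fst_columns(df)

    def test_flank_clipped_at_scaffold_start(self):
        gene = ps.GeneModel("g", "s", "+", ((1000, 2000),))
        df = self._snp_frame([10, 1500], [0.1, 0.4], [0.5, 0.8])
        gf = ps.gene_fst(gene, df, flank=5000, scaffold_length=10_000)
        # the upstream SNP at 1-based 10 is inside the clipped flank [0,1000)
        assert gf.n_snps == 1 and gf.n_snps_flanking == 2

    def test_no_flanking_snps_equals_gene_fst(self):
        gene = ps.GeneModel("g", "s", "+", ((1000, 2000),))
        df = self._snp_frame([1200, 1700], [0.1, 0.4], [0.5, 0.8])
        gf = ps.gene_fst(gene, df, flank=5000, scaffold_length=10_000)
        assert gf.fst_flanking_combined == pytest.approx(gf.fst_gene, abs=1e-15)

    def test_intronic_snps_excluded_from_exonic_fst(self):
        gene = ps.GeneModel("g", "s", "+", ((100, 200), (400, 500)))
        df = self._snp_frame([150, 300, 450], [0.1, 0.4, 0.2], [0.6, 0.9, 0.7])
        gf = ps.gene_fst(gene, df, flank=0, scaffold_length=10_000)
        assert gf.n_snps == 2

    def test_zero_exonic_snps_gives_nan(self):
        gene = ps.GeneModel("g", "s", "+", ((100, 200),))
        df = self._snp_frame([5000], [0.1], [0.6])
        gf = ps.gene_fst(gene, df, flank=100, scaffold_length=10_000)
        assert gf.n_snps == 0 and np.isnan(gf.fst_gene)

    def test_table_matches_single_gene_function(self, desk_dataset):
        ann = desk_dataset["annotation"]
        snp_df = desk_dataset["snp_df"]
        table = desk_dataset["gene_df"].set_index("gene_id")
        lengths = desk_dataset["config"].scaffold_lengths
        for g in list(ann.genes)[::17]:  # spot check a spread of genes
            sub = snp_df[snp_df["scaffold"] == g.scaffold]
            gf = ps.gene_fst(g, sub, flank=5000, scaffold_length=lengths[g.scaffold])
            row = table.loc[g.gene_id]
            assert row["n_snps"] == gf.n_snps
            if gf.n_snps:
                assert row["fst_gene"] == pytest.approx(gf.fst_gene, abs=1e-9)
            assert row["n_snps_flanking"] == gf.n_snps_flanking

    def test_scaffold_index_aggregate_matches_region_fst(self):
        df = self._snp_frame([10, 20, 30, 40], [0.1, 0.2, 0.3, 0.4], [0.6, 0.7, 0.8, 0.9])
        idx = _ScaffoldIndex(df)
        n, val = idx.aggregate([(0, 100)], "ratio")
        assert n == 4
        assert val == pytest.approx(ps.region_fst(df["h_total"], df["h_within"]), abs=1e-12)


class TestSummary:
    def test_empty_inputs(self):
        summary = ps.genomewide_summary(pd.DataFrame(), pd.DataFrame())
        assert (summary["n"] == 0).all()
        assert summary["mean"].isna().all()

    def test_mean_matches_external_recomputation(self, desk_dataset):
        summary = ps.genomewide_summary(desk_dataset["gene_df"], desk_dataset["snp_df"])
        snp_row = summary[summary["level"] == "snp"].iloc[0]
        assert snp_row["mean"] == pytest.approx(
            float(np.mean(desk_dataset["snp_df"]["fst"])), abs=1e-12
        )
        gene_row = summary[summary["level"] == "gene"].iloc[0]
        vals = desk_dataset["gene_df"]["fst_gene"].dropna()
        assert gene_row["n"] == len(vals)
        assert gene_row["mean"] == pytest.approx(float(vals.mean()), abs=1e-12)

    def test_assign_exonic_genes_labels(self, desk_dataset):
        snp_df = ps.assign_exonic_genes(
            desk_dataset["snp_df"], list(desk_dataset["annotation"].genes)
        )
        labelled = snp_df["gene_id"].notna()
        # labelled SNP count equals the sum of per-gene exonic SNP counts
        assert labelled.sum() == desk_dataset["gene_df"]["n_snps"].sum()
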