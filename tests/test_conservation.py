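import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosphosat import (
    AlignedPair,
    MappingStatus,
    OrthologTable,
    PhosphoSite,
    align_pair,
    category_enrichment,
    category_enrichment_from_counts,
    cross_species_overlap,
    generate_ortholog_pair,
    generate_phosphoproteome,
    generate_proteome,
    map_site,
)


class TestAlignPair:
    def test_identical_sequences_align_gaplessly(self):
        pair = align_pair("q", "MKSYDE", "t", "MKSYDE")
        assert pair.query_row == pair.target_row == "MKSYDE"

    def test_single_insertion_in_target(self):
        # hand-checked 3x4 dynamic-programming table: one gap in the query row
        pair = align_pair("q", "MKY", "t", "MKAY")
        assert pair.query_row.replace("-", "") == "MKY"
        assert pair.target_row == "MKAY"
        assert pair.query_row.count("-") == 1

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            align_pair("q", "", "t", "MK")

    def test_non_amino_acid_raises(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            align_pair("q", "MXZ1", "t", "MK")

    def test_deterministic(self):
        a1 = align_pair("q", "MKSTYDEKR", "t", "MKTYDDKR")
        a2 = align_pair("q", "MKSTYDEKR", "t", "MKTYDDKR")
        assert a1.query_row == a2.query_row and a1.target_row == a2.target_row


class TestMapSite:
    def test_self_alignment_maps_to_own_position(self):
        pair = AlignedPair("q", "q2", "MKSY", "MKSY")
        target = {PhosphoSite("q2", 3, "S")}
        m = map_site(PhosphoSite("q", 3, "S"), pair, target)
        assert m.status is MappingStatus.CONSERVED and m.target_position == 3

    def test_column_arithmetic_across_gap(self):
        # query row MK-SY: site S is query position 3 -> column 4 (1-based)
        pair = AlignedPair("q", "t", "MK-SY", "MKASY")
        m = map_site(PhosphoSite("q", 3, "S"), pair, {PhosphoSite("t", 4, "S")})
        assert m.target_position == 4
        assert m.status is MappingStatus.CONSERVED
        m2 = map_site(PhosphoSite("q", 3, "S"), pair, set())
        assert m2.status is MappingStatus.ALIGNED_NOT_PHOSPHORYLATED

    def test_gap_in_target_not_conserved(self):
        pair = AlignedPair("q", "t", "MKSY", "MK-Y")
        m = map_site(PhosphoSite("q", 3, "S"), pair, {PhosphoSite("t", 3, "Y")})
        assert m.status is MappingStatus.GAP_IN_TARGET
        assert m.target_position is None

    def test_any_phospho_residue_counts_unless_strict(self):
        pair = AlignedPair("q", "t", "MKSY", "MKTY")
        site = PhosphoSite("q", 3, "S")
        relaxed = map_site(site, pair, {PhosphoSite("t", 3, "T")})
        strict = map_site(site, pair, {PhosphoSite("t", 3, "T")}, strict_residue=True)
        assert relaxed.status is MappingStatus.CONSERVED
        assert strict.status is MappingStatus.ALIGNED_NOT_PHOSPHORYLATED

    def test_round_trip_through_swapped_alignment(self):
        rng = np.random.default_rng(3)
        prot = generate_proteome(5, 120, seed=rng)
        truth = generate_phosphoproteome(prot, 0.5, 0.0, seed=rng)
        pair_data = generate_ortholog_pair(truth, 0.2, 0.05, 1.0, seed=rng)
        for aln in pair_data.alignments:
            for s in truth.true_sites:
                if s.protein_id != aln.query_id:
                    continue
                fwd = map_site(s, aln, pair_data.target_sites)
                if fwd.target_position is None:
                    continue
                back = map_site(
                    PhosphoSite(aln.target_id, fwd.target_position, s.residue),
                    aln.swapped(),
                    {s},
                )
                assert back.target_position == s.position

    @settings(derandomize=True, max_examples=60)
    @given(
        seq_a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=25),
        seq_b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=25),
        data=st.data(),
    )
    def test_position_bookkeeping_through_arbitrary_alignments(self, seq_a, seq_b, data):
        """Any gapped alignment of two sequences maps non-gap columns both ways."""
        rows_a, rows_b = list(seq_a), list(seq_b)
        # interleave arbitrary gaps while keeping rows equal length
        n_cols = len(seq_a) + len(seq_b)
        qrow, trow = [], []
        ia = ib = 0
        for col in range(n_cols):
            remaining = n_cols - col
            need_a, need_b = len(seq_a) - ia, len(seq_b) - ib
            opts = []
            if need_a and need_b and remaining > max(need_a, need_b) - 1:
                opts.append("match")
            if need_a and remaining > need_a - 1:
                opts.append("gap_b")
            if need_b and remaining > need_b - 1:
                opts.append("gap_a")
            if not opts:
                break
            choice = data.draw(st.sampled_from(opts))
            if choice == "match":
                qrow.append(rows_a[ia]); trow.append(rows_b[ib]); ia += 1; ib += 1
            elif choice == "gap_b":
                qrow.append(rows_a[ia]); trow.append("-"); ia += 1
            else:
                qrow.append("-"); trow.append(rows_b[ib]); ib += 1
        qrow += rows_a[ia:] + ["-"] * (len(seq_b) - ib)
        trow += ["-"] * (len(seq_a) - ia) + rows_b[ib:]
        pair = AlignedPair("q", "t", "".join(qrow), "".join(trow))
        assert pair.query_seq == seq_a and pair.target_seq == seq_b
        for pos in range(1, len(seq_a) + 1):
            if seq_a[pos - 1] not in "STY":
                continue
            fwd = map_site(PhosphoSite("q", pos, seq_a[pos - 1]), pair, set())
            if fwd.target_position is None:
                continue
            res_b = seq_b[fwd.target_position - 1]
            if res_b not in "STY":
                continue
            back = map_site(
                PhosphoSite("t", fwd.target_position, res_b), pair.swapped(), set()
            )
            assert back.target_position == pos

    def test_position_beyond_row_raises(self):
        pair = AlignedPair("q", "t", "MKSY", "MKSY")
        with pytest.raises(IndexError):
            map_site(PhosphoSite("q", 9, "S"), pair, set())


class TestCrossSpeciesOverlap:
    def test_no_orthologs_gives_zero_fraction(self):
        sites = {PhosphoSite("q", 3, "S")}
        res = cross_species_overlap(sites, set(), OrthologTable([]), [])
        assert res.fraction_conserved == 0.0
        assert res.mappings[0].status is MappingStatus.NO_ORTHOLOG

    def test_missing_alignment_counts_in_denominator(self):
        sites = {PhosphoSite("q", 3, "S")}
        res = cross_species_overlap(sites, set(), OrthologTable([("q", "t")]), [])
        assert res.mappings[0].status is MappingStatus.NO_ALIGNMENT
        assert res.n_query_sites == 1

    def test_conservation_probability_recovered(self):
        """Generator round-trip: conservation_prob 0.3 within 3 binomial SE."""
        rng = np.random.default_rng(11)
        prot = generate_proteome(40, 400, seed=rng)
        truth = generate_phosphoproteome(prot, 0.25, 0.0, seed=rng)
        n_sites = len(truth.true_sites)
        assert n_sites >= 500
        pair_data = generate_ortholog_pair(truth, 0.2, 0.02, 0.3, seed=rng)
        res = cross_species_overlap(
            truth.site_set, pair_data.target_sites, pair_data.orthologs,
            pair_data.alignments,
        )
        se = math.sqrt(0.3 * 0.7 / n_sites)
        assert abs(res.fraction_conserved - 0.3) <= 3 * se
        # and the analyzer agrees exactly with the generator's bookkeeping
        assert res.n_conserved >= len(pair_data.conserved_query_sites)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        prot = generate_proteome(10, 150, seed=rng)
        truth = generate_phosphoproteome(prot, 0.3, 0.0, seed=rng)
        pd = generate_ortholog_pair(truth, 0.1, 0.02, 0.5, seed=rng)
        r1 = cross_species_overlap(truth.site_set, pd.target_sites, pd.orthologs, pd.alignments)
        r2 = cross_species_overlap(
            truth.site_set, pd.target_sites, pd.orthologs, list(reversed(pd.alignments))
        )
        assert r1.fraction_conserved == r2.fraction_conserved


def fisher_greater_oracle(table):
    """One-sided Fisher p by enumerating all tables with the observed margins."""
    (a, b), (c, d) = table
    row1, col1, N = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(N - col1, row1 - x)
            / math.comb(N, row1)
        )

    return sum(prob(x) for x in range(a, min(row1, col1) + 1))


class TestCategoryEnrichment:
    def test_printed_kinase_table_is_highly_significant(self):
        # 9 conserved sites of which 7 on kinases; 268 sites total, 25 on kinases
        enr = category_enrichment_from_counts(268, 9, 25, 7)
        assert enr.p_value < 1e-6

    def test_category_covering_everything_is_null(self):
        enr = category_enrichment_from_counts(50, 10, 50, 10)
        assert enr.p_value == 1.0

    @pytest.mark.parametrize(
        "counts", [(20, 6, 8, 4), (30, 10, 12, 9), (12, 3, 5, 1), (25, 5, 5, 5)]
    )
    def test_matches_exhaustive_hypergeometric_oracle(self, counts):
        n_sites, n_cons, n_cat, n_cat_cons = counts
        enr = category_enrichment_from_counts(n_sites, n_cons, n_cat, n_cat_cons)
        assert enr.p_value == pytest.approx(fisher_greater_oracle(enr.table), abs=1e-12)

    def test_from_conservation_result(self):
        rng = np.random.default_rng(4)
        prot = generate_proteome(20, 200, seed=rng)
        truth = generate_phosphoproteome(prot, 0.3, 0.0, seed=rng)
        pd = generate_ortholog_pair(truth, 0.1, 0.01, 0.4, seed=rng)
        res = cross_species_overlap(truth.site_set, pd.target_sites, pd.orthologs, pd.alignments)
        category = set(list(prot.protein_ids)[:5])
        enr = category_enrichment(res, category)
        assert sum(enr.table[0]) == res.n_conserved
        assert sum(enr.table[0]) + sum(enr.table[1]) == res.n_query_sites
        assert 0.0 <= enr.p_value <= 1.0

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            category_enrichment_from_counts(10, 12, 3, 1)
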