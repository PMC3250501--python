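import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nagnag.evolution import (
    ExonPairAlignment,
    aa_gain_loss_spectrum,
    align_exon_pair,
    assign_gap_positions,
    classify_boundary_change,
    extract_insertion_event,
    fisher_exact_bruteforce,
    gap_profile,
    inserted_residues,
    nagnag_boundary_association,
    permutation_test_enrichment,
    qc_alignment,
    residual_motif,
    shannon_entropy,
    shift_gaps_to_boundaries,
)


def gotoh_score(a, b, match=1.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0):
    """Exhaustive affine-gap global alignment score (Gotoh DP oracle).

    A gap of length k costs gap_open + k * gap_extend, matching the
    production aligner's convention.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open + gap_extend,
                          X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_extend,
                          Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


DNA = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestAligner:
    def test_identical_sequences_no_gaps(self):
        aln = align_exon_pair("ACGTACGT", "ACGTACGT")
        assert aln.identity == 100.0
        assert aln.total_inserted == 0

    def test_internal_three_nt_deletion_single_gap(self, rng):
        a = "".join(rng.choice(list("ACGT"), 60))
        b = a[:30] + a[33:]
        aln = align_exon_pair(a, b)
        gaps = [r for r in aln.rows[1].split(aln.rows[1].strip("-")) if r]
        assert aln.rows[1].count("-") == 3
        assert "---" in aln.rows[1]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=DNA, b=DNA)
    def test_score_equals_exhaustive_dp(self, a, b):
        aln = align_exon_pair(a, b)
        assert aln.score == pytest.approx(gotoh_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_exon_pair("", "ACGT")


class TestQc:
    def _aln(self, rows, exon_len):
        return ExonPairAlignment(("a", "b"), rows, {}, exon_len)

    def test_low_identity_fails(self, rng):
        a = "".join(rng.choice(list("ACGT"), 100))
        b = "".join(rng.choice(list("ACGT"), 100))
        aln = align_exon_pair(a, b, exon_len={"a": 100, "b": 100})
        # random sequences align near 25-60% identity: must fail at the
        # 70% threshold
        assert aln.identity <= 70.0
        assert not qc_alignment(aln)

    def test_identity_exactly_70_fails(self):
        row_a = "A" * 70 + "C" * 30
        row_b = "A" * 70 + "G" * 30
        aln = self._aln((row_a, row_b), {"a": 100, "b": 100})
        assert aln.identity == pytest.approx(70.0)
        assert not qc_alignment(aln)

    def test_excess_insertion_fails(self):
        # 30-nt exon with 7 inserted bases: 7 > 0.2 * 30
        row_a = "A" * 30 + "-" * 7
        row_b = "A" * 30 + "C" * 7
        aln = self._aln((row_a, row_b), {"a": 30, "b": 37})
        assert aln.identity == 100.0
        assert not qc_alignment(aln)

    def test_clean_alignment_passes(self):
        row = "ACGT" * 20
        aln = self._aln((row, row), {"a": 80, "b": 80})
        assert qc_alignment(aln)


def mk_aln(row_a, row_b, start_a, start_b, names=("a", "b")):
    return ExonPairAlignment(
        names, (row_a, row_b),
        {names[0]: start_a, names[1]: start_b},
        {names[0]: len(row_a.replace("-", "")) - start_a,
         names[1]: len(row_b.replace("-", "")) - start_b},
    )


class TestGapShifting:
    def test_slide_to_boundary_in_repeat_context(self):
        # junction after 4 bases; gap of 3 sits 2 columns inside the exon
        # but the repeat context lets it slide to abut the junction
        row_a = "TTTT" + "AAAAACGT"
        row_b = "TTTT" + "AA---CGT"
        aln = mk_aln(row_a, row_b, 4, 4)
        shifted = shift_gaps_to_boundaries(aln)
        assert shifted.rows[1] == "TTTT" + "---AACGT"
        assert shifted.n_matches == aln.n_matches

    def test_no_slide_when_matches_lost(self):
        row_a = "TTTT" + "CAGTACGT"
        row_b = "TTTT" + "CA---CGT"
        aln = mk_aln(row_a, row_b, 4, 4)
        shifted = shift_gaps_to_boundaries(aln)
        assert shifted.rows == aln.rows

    def test_match_count_always_preserved(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 50))
            cut = int(rng.integers(5, 40))
            b = a[:cut] + a[cut + 3:]
            aln = align_exon_pair(a, b, exon_start={"a": 20, "b": 20},
                                  exon_len={"a": 30, "b": 27})
            shifted = shift_gaps_to_boundaries(aln)
            assert shifted.n_matches == aln.n_matches


class TestGapPositions:
    def test_gap_at_exon_start_is_acceptor_zero(self):
        # b lacks the first three exonic bases a carries
        row_a = "TTTTCCCC" + "CAGAAAGGG"
        row_b = "TTTTCCCC" + "---AAAGGG"
        aln = mk_aln(row_a, row_b, 8, 8)
        recs = [r for r in assign_gap_positions(aln) if not r.ambiguous]
        assert len(recs) == 1
        assert (recs[0].splice_site, recs[0].position, recs[0].length) == \
            ("3ss", 0, 3)

    def test_gap_five_columns_into_exon(self):
        row_a = "TTTTCCCC" + "AAAAACAGGG"
        row_b = "TTTTCCCC" + "AAAAA---GG"
        aln = mk_aln(row_a, row_b, 8, 8)
        recs = [r for r in assign_gap_positions(aln) if not r.ambiguous]
        assert (recs[0].splice_site, recs[0].position) == ("3ss", 5)

    def test_upstream_gap_is_donor_side_negative(self):
        row_a = "TTTTAACCGG" + "AAAGGG"
        row_b = "TTTT---CGG" + "AAAGGG"
        aln = mk_aln(row_a, row_b, 10, 7)
        recs = [r for r in assign_gap_positions(aln) if not r.ambiguous]
        assert (recs[0].splice_site, recs[0].position) == ("5ss", -3)

    def test_terminal_gaps_ambiguous(self):
        row_a = "AAAACGTAA"
        row_b = "---ACGTAA"
        aln = mk_aln(row_a, row_b, 4, 1)
        recs = assign_gap_positions(aln)
        assert recs[0].ambiguous

    def test_counts_conserved(self, rng):
        """Sum of per-position counts equals the number of unambiguous
        profiled gap records."""
        records = {}
        total = 0
        for k in range(50):
            a = "".join(rng.choice(list("ACGT"), 80))
            cut = int(rng.integers(10, 65))
            b = a[:cut] + a[cut + 3:]
            aln = align_exon_pair(a, b, names=("a", "b"),
                                  exon_start={"a": 30, "b": 30},
                                  exon_len={"a": 50, "b": 47})
            recs = assign_gap_positions(aln)
            records[f"p{k}"] = recs
            total += sum(
                1 for r in recs
                if not r.ambiguous and r.splice_site is not None
                and ((r.splice_site == "3ss" and 0 <= r.position <= 30)
                     or (r.splice_site == "5ss" and -30 <= r.position <= 0))
            )
        prof = gap_profile(records, span=30)
        assert int(prof.table["n_pairs_with_gap"].sum()) <= total
        # pairs carry one gap each here, so the dedup never bites
        assert int(prof.table["n_pairs_with_gap"].sum()) == total


class TestGapProfile:
    def _uniform_records(self, rng, n_pairs=400, p_gap=0.3):
        from nagnag.evolution import GapRecord, profiled_positions

        cells = profiled_positions(30)
        records = {}
        for k in range(n_pairs):
            recs = []
            if rng.random() < p_gap:
                ss, pos = cells[rng.integers(0, len(cells))]
                recs.append(GapRecord(3, 1, "b", ss, pos))
            records[f"p{k}"] = recs
        return records

    def test_uniform_null_enrichment_near_one(self, rng):
        prof = gap_profile(self._uniform_records(rng, 2000))
        assert prof.enrichment == pytest.approx(1.0, abs=0.9)

    def test_no_gaps_enrichment_undefined(self):
        prof = gap_profile({"p0": [], "p1": []})
        assert prof.enrichment is None
        assert (prof.table["fraction"] == 0).all()

    def test_tenfold_generator_truth_recovered(self, rng):
        from nagnag.evolution import GapRecord, profiled_positions

        cells = [c for c in profiled_positions(30) if c != ("3ss", 0)]
        records = {}
        p0 = 0.004
        for k in range(3000):
            recs = []
            if rng.random() < 10 * p0:
                recs.append(GapRecord(3, 1, "b", "3ss", 0))
            for ss, pos in cells:
                if rng.random() < p0:
                    recs.append(GapRecord(3, 1, "b", ss, pos))
            records[f"p{k}"] = recs
        prof = gap_profile(records)
        assert prof.enrichment == pytest.approx(10.0, rel=0.25)


class TestPermutationTest:
    def test_uniform_truth_p_near_half(self, rng):
        from nagnag.evolution import GapRecord, profiled_positions

        cells = profiled_positions(30)
        records = {}
        for k in range(1500):
            recs = []
            for _ in range(rng.poisson(0.3)):
                ss, pos = cells[rng.integers(0, len(cells))]
                recs.append(GapRecord(3, 1, "b", ss, pos))
            records[f"p{k}"] = recs
        p = permutation_test_enrichment(records, 400, seed=3)
        assert 0.1 < p < 0.95

    def test_extreme_enrichment_attains_minimum(self):
        from nagnag.evolution import GapRecord

        records = {f"p{k}": [GapRecord(3, 1, "b", "3ss", 0)]
                   for k in range(60)}
        n = 1000
        p = permutation_test_enrichment(records, n, seed=0)
        assert p == pytest.approx(1 / (n + 1))

    def test_null_p_values_uniform(self, rng):
        """Calibration: p under the uniform null is itself uniform."""
        from nagnag.evolution import GapRecord, profiled_positions

        cells = profiled_positions(10)
        ps = []
        for trial in range(40):
            records = {}
            for k in range(150):
                recs = []
                for _ in range(rng.poisson(0.5)):
                    ss, pos = cells[rng.integers(0, len(cells))]
                    recs.append(GapRecord(3, 1, "b", ss, pos))
                records[f"p{k}"] = recs
            ps.append(permutation_test_enrichment(records, 199,
                                                  seed=int(rng.integers(1e6)),
                                                  span=10))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBoundaryClassification:
    def _records(self, rng, shift=None):
        """Build mouse/rat records from one ancestor; optionally shift one
        lineage's acceptor by +3 (expansion) using the intronic NAG."""
        tail = "".join(rng.choice(list("ACGT"), 30))
        exon = "".join(rng.choice(list("ACGT"), 60))
        nag = "TAG"
        recs = {"mouse": tail + exon, "rat": tail + exon}
        starts = {"mouse": 30, "rat": 30}
        if shift:
            recs[shift] = tail + nag + exon
            starts[shift] = 30
        out = ("human", tail + exon, 30)
        return recs, starts, out

    def test_unchanged_when_boundaries_match(self, rng):
        recs, starts, out = self._records(rng)
        aln = align_exon_pair(recs["mouse"], recs["rat"],
                              names=("mouse", "rat"), exon_start=starts)
        change = classify_boundary_change(aln, [out])
        assert change.cls == "unchanged"

    def test_expansion_detected_against_outgroup(self, rng):
        recs, starts, out = self._records(rng, shift="mouse")
        aln = align_exon_pair(recs["mouse"], recs["rat"],
                              names=("mouse", "rat"), exon_start=starts)
        change = classify_boundary_change(aln, [out])
        assert change.cls == "expanded"
        assert change.lineage == "mouse"
        assert change.outgroup == "human"

    def test_second_outgroup_used_when_first_uninformative(self, rng):
        recs, starts, out = self._records(rng, shift="rat")
        # human outgroup matches NEITHER boundary: its exon start is six
        # bases off both ingroups, so its acceptor offset is never zero
        tail, exon = out[1][:30], out[1][30:]
        bad_out = ("human", tail + "GGGGGG" + exon, 30)
        cow = ("cow", out[1], 30)
        aln = align_exon_pair(recs["mouse"], recs["rat"],
                              names=("mouse", "rat"), exon_start=starts)
        change = classify_boundary_change(aln, [bad_out, cow])
        assert change.cls == "expanded"
        assert change.lineage == "rat"
        assert change.outgroup == "cow"


class TestResidualMotif:
    def test_expanded_class_shows_nag_at_plus_one_to_three(self, rng):
        seqs = []
        for _ in range(40):
            intron = "".join(rng.choice(list("ACGT"), 10))
            exon = rng.choice(list("ACGT")) + "AG" + "".join(
                rng.choice(list("ACGT"), 3))
            seqs.append(intron + exon)
        mats = residual_motif({"expanded": seqs})
        ic = mats["expanded"].set_index("position")["ic"]
        assert ic.loc[2] > 1.0 and ic.loc[3] > 1.0  # the A and G
        assert ic.loc[-8] < 0.5

    def test_random_sequences_near_zero(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 16)) for _ in range(200)]
        mats = residual_motif({"bg": seqs})
        assert mats["bg"]["ic"].max() < 0.25


class TestAssociation:
    def test_frequency_ratio_example(self):
        ratio, p = nagnag_boundary_association(30, 100, 4, 100)
        assert ratio == pytest.approx(7.5)
        assert p < 1e-5

    def test_balanced_table(self):
        ratio, p = nagnag_boundary_association(10, 100, 10, 100)
        assert ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_denominator(self):
        ratio, p = nagnag_boundary_association(5, 50, 0, 50)
        assert ratio is None
        assert 0 <= p <= 1

    @pytest.mark.parametrize("table", [[[2, 3], [4, 1]], [[0, 5], [5, 0]],
                                       [[3, 3], [3, 3]]])
    def test_fisher_matches_bruteforce(self, table):
        p_scipy = stats.fisher_exact(table, alternative="two-sided")[1]
        assert fisher_exact_bruteforce(table) == pytest.approx(p_scipy,
                                                               rel=1e-6)

    def test_bruteforce_all_small_margins(self):
        """scipy's Fisher exact equals the hypergeometric enumeration for
        every 2x2 table with all margins <= 12."""
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a + b > 12 or c + d > 12 or a + c > 12 or b + d > 12:
                continue
            if (a + b) == 0 or (c + d) == 0:
                continue
            p1 = stats.fisher_exact([[a, b], [c, d]])[1]
            p2 = fisher_exact_bruteforce([[a, b], [c, d]])
            assert p2 == pytest.approx(p1, rel=1e-6), (a, b, c, d)


class TestAaSpectrum:
    def test_phase0_cag_counts_glutamine(self):
        assert inserted_residues("CAGTTT", "TTT", 0) == "Q"

    def test_single_residue_insertion_sr_vs_r(self):
        # human SR vs mouse R: only S inserted (phase 2 example)
        # longer: AGC CGC (S R); shorter: CGC (R)
        assert inserted_residues("AGCCGC", "CGC", 2) == "S"

    def test_double_change_sr_vs_k(self):
        # longer: AGT AGG (S R); shorter: AAG (K): count both S and R
        assert inserted_residues("AGTAGG", "AAG", 2) == "SR"

    def test_stop_codon_excluded(self):
        spec = aa_gain_loss_spectrum([("TAGTTT", "TTT", 0)])
        assert spec.n_excluded_stop == 1
        assert spec.counts["overall"].empty

    def test_uniform_codons_recover_genetic_code_distribution(self, rng):
        """Phase-0 insertions with uniform NNN codons reproduce the
        genetic-code-induced residue distribution."""
        from Bio.Data.CodonTable import standard_dna_table

        codons = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
        events = [(c + "AAA", "AAA", 0) for c in codons]
        spec = aa_gain_loss_spectrum(events)
        expected = {}
        for codon, aa in standard_dna_table.forward_table.items():
            if set(codon) <= set("ACGT"):
                expected[aa] = expected.get(aa, 0) + 1
        assert spec.counts["overall"].to_dict() == expected
        assert spec.n_excluded_stop == 3

    def test_extraction_from_alignment(self, rng):
        tail = "".join(rng.choice(list("ACGT"), 12))
        exon = "".join(rng.choice(list("ACGT"), 30))
        long_rec = tail + "CAG" + exon
        short_rec = tail + exon
        aln = align_exon_pair(long_rec, short_rec, names=("m", "r"),
                              exon_start={"m": 12, "r": 12})
        aln = shift_gaps_to_boundaries(aln)
        event = extract_insertion_event(aln, phase=0)
        assert event is not None
        longer, shorter, phase = event
        assert longer[:3] == "CAG"


class TestEntropy:
    @pytest.mark.parametrize(
        "freqs,expected",
        [([1.0], 0.0), ([0.5, 0.5], 1.0), ([1 / 20] * 20, 4.3219)],
    )
    def test_closed_forms(self, freqs, expected):
        assert shannon_entropy(freqs) == pytest.approx(expected, abs=1e-3)

    def test_counts_renormalised(self):
        assert shannon_entropy([5, 5]) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([-0.1, 1.1])
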