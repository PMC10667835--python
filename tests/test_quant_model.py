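"""Folding, processing/end ratios, trinucleotide scores, base frequencies."""

import numpy as np
import pytest

import srps
from srps.quant_model import (DEFAULT_SCORE_TABLE, UnscoredTrinucleotideError,
                              base_frequency_matrix, end_ratio,
                              endratio_mfe_correlation, first_three_nucleotides,
                              fold_mfe, mfe_offset_profile, processing_ratio,
                              revcomp, score_vs_ratio, tss_score, upstream_mfe)

HAIRPIN = "GGGGCGCGCC" + "GAAA" + "GGCGCGCCCC"   # strong GC stem
AU_HAIRPIN = "AAAUAUAUAA" + "GAAA" + "UUAUAUAUUU"


class TestFoldMfe:
    def test_poly_a_is_unstructured(self):
        structure, dg = fold_mfe("A" * 20)
        assert dg == 0.0
        assert structure == "." * 20

    def test_gc_stem_is_more_stable_than_au_stem(self):
        assert fold_mfe(HAIRPIN)[1] < fold_mfe(AU_HAIRPIN)[1]

    def test_reverse_complement_folds_comparably(self):
        hairpin = "GCGGCCGGG" + "CTCA" + revcomp("GCGGCCGGG")
        dg = fold_mfe(hairpin)[1]
        dg_rc = fold_mfe(revcomp(hairpin))[1]
        assert dg < -15
        assert abs(dg - dg_rc) < 0.5

    def test_dna_alphabet_is_accepted(self):
        assert fold_mfe("GGGGCGCGCCGAAAGGCGCGCCCC".replace("U", "T"))[1] < -5

    def test_invalid_character_is_an_error(self):
        with pytest.raises(ValueError, match="invalid characters"):
            fold_mfe("ACGUN")


class TestMfeProfiles:
    def test_polya_context_gives_flat_zero_profile(self):
        genome = {"chr": "A" * 400}
        prof = mfe_offset_profile([("chr", "+", 200)], genome)
        assert np.allclose(prof.mean_dg, 0.0)
        assert prof.offsets[0] == -50 and prof.offsets[-1] == 50

    def test_hairpin_ending_at_site_dips_near_offset_zero(self):
        stem = "GGGGCGCGCC" + "GAAA" + "GGCGCGCCCC"
        genome = {"chr": "A" * 200 + stem.replace("U", "T") + "A" * 200}
        site = 200 + len(stem) - 1          # 3' edge of the hairpin
        prof = mfe_offset_profile([("chr", "+", site)], genome)
        at = dict(zip(prof.offsets.tolist(), prof.mean_dg))
        # windows whose 3' edge reaches the site hold the full hairpin ...
        assert at[0] < -10
        # ... windows ending 30+ nt upstream hold almost none of it
        assert at[-40] > -5
        assert prof.mean_dg.min() < -10

    def test_duplicate_sites_average_to_single_site_profile(self):
        genome = {"chr": "A" * 150 + "GCGCTTTTGCGC" * 10 + "A" * 150}
        one = mfe_offset_profile([("chr", "+", 210)], genome)
        two = mfe_offset_profile([("chr", "+", 210), ("chr", "+", 210)], genome)
        assert np.allclose(one.mean_dg, two.mean_dg)

    def test_all_sites_near_edges_is_an_error(self):
        with pytest.raises(ValueError, match="skipped"):
            mfe_offset_profile([("chr", "+", 10)], {"chr": "A" * 300})


class TestUpstreamMfe:
    def test_unstructured_upstream_is_zero(self):
        assert upstream_mfe(("chr", "+", 200), {"chr": "A" * 300}) == 0.0

    def test_stemloop_just_upstream_is_detected(self):
        stem = "GGGGCGCGCGCC" + "GAAA" + "GGCGCGCGCCCC"
        genome = {"chr": "A" * 200 + stem + "A" * 100}
        site = 200 + len(stem)              # stop right after the hairpin
        assert upstream_mfe(("chr", "+", site), genome) < -5

    def test_sliding_mode_dilutes_the_adjacent_stem(self):
        stem = "GGGGCGCGCGCC" + "GAAA" + "GGCGCGCGCCCC"
        genome = {"chr": "A" * 200 + stem + "A" * 100}
        site = 200 + len(stem)
        single = upstream_mfe(("chr", "+", site), genome, mode="window")
        sliding = upstream_mfe(("chr", "+", site), genome, mode="sliding")
        assert single < sliding < 0

    def test_insufficient_flank_is_an_error(self):
        with pytest.raises(ValueError, match="upstream"):
            upstream_mfe(("chr", "+", 50), {"chr": "A" * 300})


def _profiles_with_n5(values, contig_len=100):
    prof = srps.EndProfile({"chr": contig_len},
                           spec=srps.LibrarySpec("WT", "total", 1))
    for pos, v in values:
        prof.n5("chr", "+")[pos] = v
    return {"lib": prof}


class TestProcessingRatio:
    def test_direct_quotient(self):
        proc = _profiles_with_n5([(50, 10), (52, 20)])
        tot = _profiles_with_n5([(50, 40), (52, 60)])
        rec = processing_ratio(("chr", "+", 50), proc, tot)
        assert rec.ratio == pytest.approx(30 / 100)

    def test_identical_profiles_give_unity(self):
        tot = _profiles_with_n5([(50, 33)])
        rec = processing_ratio(("chr", "+", 50), tot, tot)
        assert rec.ratio == 1.0

    def test_zero_processed_gives_zero(self):
        rec = processing_ratio(("chr", "+", 50),
                               _profiles_with_n5([]),
                               _profiles_with_n5([(50, 10)]))
        assert rec.ratio == 0.0

    def test_zero_total_window_is_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="srps"):
            rec = processing_ratio(("chr", "+", 50),
                                   _profiles_with_n5([(50, 5)]),
                                   _profiles_with_n5([]))
        assert rec is None

    def test_window_is_nine_nt(self):
        proc = _profiles_with_n5([(45, 100), (55, 100)])   # outside +/-4
        tot = _profiles_with_n5([(50, 10)])
        rec = processing_ratio(("chr", "+", 50), proc, tot)
        assert rec.ratio == 0.0


class TestTssScore:
    @pytest.mark.parametrize("tri,score", sorted(DEFAULT_SCORE_TABLE.items()))
    def test_default_table(self, tri, score):
        assert tss_score(tri) == score

    def test_rna_alphabet_key(self):
        assert tss_score("AAU") == 14

    def test_unknown_trinucleotide_raises(self):
        with pytest.raises(UnscoredTrinucleotideError):
            tss_score("GGG")

    def test_user_extended_table(self):
        assert tss_score("GGG", {**DEFAULT_SCORE_TABLE, "GGG": 5}) == 5

    def test_score_table_file(self, tmp_path):
        (tmp_path / "t.tsv").write_text("AAT\t14\nGGG\t4\n")
        table = srps.load_score_table(tmp_path / "t.tsv")
        assert table == {"AAT": 14, "GGG": 4}


class TestScoreVsRatio:
    def _genome_with_tss(self, tris):
        seq = "".join(tri + "A" * 7 for tri in tris)
        return {"chr": seq}, [("chr", "+", i * 10) for i in range(len(tris))]

    def test_perfectly_linear_groups_give_r_one(self):
        tris = ["CCT", "CAT", "GAT", "ACT", "ATT", "AAT"]
        genome, sites = self._genome_with_tss(tris)
        records = [(site, 0.02 + 0.05 * DEFAULT_SCORE_TABLE[tri])
                   for site, tri in zip(sites, tris)]
        table, r = score_vs_ratio(records, genome)
        assert r == pytest.approx(1.0)
        assert len(table) == 6

    def test_constant_ratios_are_an_error(self):
        genome, sites = self._genome_with_tss(["CCT", "CAT", "GAT"])
        with pytest.raises(ValueError, match="zero variance"):
            score_vs_ratio([(s, 0.5) for s in sites], genome)

    def test_fewer_than_three_groups_is_an_error(self):
        genome, sites = self._genome_with_tss(["CCT", "CAT"])
        with pytest.raises(ValueError, match="need >= 3"):
            score_vs_ratio([(s, 0.1) for s in sites], genome)

    def test_minus_strand_trinucleotide_readout(self):
        genome = {"chr": "A" * 10 + revcomp("CAT") + "A" * 10}
        assert first_three_nucleotides(genome, "chr", "-", 12) == "CAT"


def _wt_n3(values, contig_len=600):
    prof = srps.EndProfile({"chr": contig_len},
                           spec=srps.LibrarySpec("WT", "total", 1))
    for pos, v in values:
        prof.n3("chr", "+")[pos] = v
    return {"wt": prof}


class TestEndRatio:
    def test_all_ends_at_stop_give_unity(self):
        wt = _wt_n3([(300, 50)])
        rec = end_ratio(("chr", "+", 300), 400, wt)
        assert rec.end_ratio == 1.0

    def test_direct_quotient(self):
        wt = _wt_n3([(300, 40), (380, 60)])
        rec = end_ratio(("chr", "+", 300), 400, wt)
        assert rec.end_ratio == pytest.approx(0.4)

    def test_start_inside_numerator_window_warns_and_gives_unity(self, caplog):
        wt = _wt_n3([(300, 10), (303, 5)])
        with caplog.at_level("WARNING", logger="srps"):
            rec = end_ratio(("chr", "+", 300), 303, wt)
        assert rec.end_ratio == 1.0
        assert "degenerate" in caplog.text

    def test_zero_denominator_is_skipped(self, caplog):
        with caplog.at_level("WARNING", logger="srps"):
            assert end_ratio(("chr", "+", 300), 400, _wt_n3([])) is None

    def test_minus_strand_windows(self):
        prof = srps.EndProfile({"chr": 600},
                               spec=srps.LibrarySpec("WT", "total", 1))
        prof.n3("chr", "-")[300] = 30      # the stop
        prof.n3("chr", "-")[220] = 70      # between stop and downstream start
        rec = end_ratio(("chr", "-", 300), 200, {"wt": prof})
        assert rec.end_ratio == pytest.approx(0.3)


class TestEndRatioCorrelation:
    def test_monotone_records_give_minus_one(self):
        recs = [srps.EndRatioRecord("chr", "+", i, i + 50, r, dg)
                for i, (dg, r) in enumerate([(-20, 0.9), (-10, 0.7), (-5, 0.6)])]
        assert endratio_mfe_correlation(recs) == pytest.approx(-1.0)

    def test_shuffled_pairing_decorrelates(self):
        rng = np.random.default_rng(0)
        dgs = np.linspace(-25, -2, 40)
        ratios = np.linspace(0.95, 0.2, 40)
        paired = [srps.EndRatioRecord("chr", "+", i, 0, r, d)
                  for i, (d, r) in enumerate(zip(dgs, ratios))]
        shuffled_ratios = rng.permutation(ratios)
        shuffled = [srps.EndRatioRecord("chr", "+", i, 0, r, d)
                    for i, (d, r) in enumerate(zip(dgs, shuffled_ratios))]
        assert endratio_mfe_correlation(paired) == pytest.approx(-1.0)
        assert abs(endratio_mfe_correlation(shuffled)) < 0.4

    def test_too_few_records_is_an_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            endratio_mfe_correlation([])


class TestBaseFrequencies:
    def test_identical_contexts_give_unit_columns(self):
        genome = {"chr": "ACGTACGTACGTACGTACGTACGTACGT"}
        mat = base_frequency_matrix([("chr", "+", 14)], genome, flank=5)
        assert np.allclose(mat.freqs.max(axis=1), 1.0)

    def test_uniform_background_approaches_quarter(self):
        rng = np.random.default_rng(0)
        genome = {"chr": "".join(rng.choice(list("ACGT"), size=30000))}
        sites = [("chr", "+", int(p)) for p in rng.integers(20, 29980, 1000)]
        mat = base_frequency_matrix(sites, genome)
        assert np.abs(mat.freqs.values - 0.25).max() < 0.05

    def test_implanted_motif_shows_u_at_plus_two(self, small_sim):
        _, genome, _, truth, _ = small_sim
        sites = truth.positions("rne5")
        mat = base_frequency_matrix(sites, genome)
        assert mat.frequency("U", 2) > 0.9
        assert mat.frequency("U", 1) > 0.9
        # R = A/G at -2
        assert mat.frequency("A", -2) + mat.frequency("G", -2) > 0.9

    def test_rows_sum_to_one(self, small_sim):
        _, genome, _, truth, _ = small_sim
        mat = base_frequency_matrix(truth.positions("rpph"), genome)
        assert np.allclose(mat.freqs.sum(axis=1), 1.0, atol=1e-9)
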