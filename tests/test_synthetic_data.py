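"""Simulator: determinism, implanted features, links, recovery scoring."""

import numpy as np
import pandas as pd
import pytest

import srps
from srps.quant_model import fold_mfe
from srps.synthetic_data import (CONTIG, SimConfig, design_stemloop,
                                 evaluate_recovery, generate_genome,
                                 simulate_libraries, _species_for,
                                 _plans_from_truth)


class TestDesignStemloop:
    @pytest.mark.parametrize("band", [(-3.0, 0.0), (-16.0, -12.0),
                                      (-30.0, -20.0)])
    def test_dg_lands_in_band(self, band):
        rng = np.random.default_rng(0)
        seq, dg = design_stemloop(band, rng)
        assert band[0] <= dg <= band[1]
        assert fold_mfe(seq)[1] == pytest.approx(dg)

    def test_unreachable_band_errors(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="no stem-loop"):
            design_stemloop((-100.0, -90.0), rng, max_stem=15)

    def test_deterministic_for_fixed_generator(self):
        a = design_stemloop((-12.0, -8.0), np.random.default_rng(42))
        b = design_stemloop((-12.0, -8.0), np.random.default_rng(42))
        assert a == b


class TestGenerateGenome:
    def test_byte_identical_reruns(self):
        cfg = SimConfig(seed=5, n_operons=10)
        g1, _, t1 = generate_genome(cfg)
        g2, _, t2 = generate_genome(cfg)
        assert g1[CONTIG] == g2[CONTIG]
        pd.testing.assert_frame_equal(t1.sites, t2.sites)
        pd.testing.assert_frame_equal(t1.operons, t2.operons)

    def test_rnase_e_sites_carry_the_motif(self, small_sim):
        _, genome, _, truth, _ = small_sim
        seq = genome[CONTIG]
        comp = str.maketrans("ACGT", "TGCA")
        for contig, strand, pos in truth.positions("rne5"):
            if strand == "+":
                window = seq[pos - 2:pos + 3]
            else:
                window = seq[pos - 2:pos + 3].translate(comp)[::-1]
            r, _n, w, u1, u2 = window
            assert r in "GA" and w in "AT" and u1 == "T" and u2 == "T"

    def test_tss_trinucleotides_written_into_genome(self, small_sim):
        _, genome, _, truth, _ = small_sim
        from srps.quant_model import first_three_nucleotides

        for row in truth.tss.itertuples():
            got = first_three_nucleotides(genome, row.contig, row.strand,
                                          int(row.pos))
            assert got == row.tri

    def test_stemloop_truth_dg_matches_folding_engine(self, small_sim):
        _, _, _, truth, _ = small_sim
        for row in truth.stemloops.itertuples():
            assert fold_mfe(row.seq)[1] == pytest.approx(row.dg_hairpin)

    def test_processed_fraction_follows_the_linear_link(self, small_sim):
        cfg, _, _, truth, _ = small_sim
        for row in truth.tss.itertuples():
            want = np.clip(cfg.link_intercept + cfg.link_slope * row.score,
                           0, 1)
            assert row.p_processed == pytest.approx(want)


class TestSimulateLibraries:
    def test_end_count_conservation_per_library(self, small_sim):
        _, _, _, _, profiles = small_sim
        for name, prof in profiles.items():
            n5 = sum(prof.n5(CONTIG, s).sum() for s in "+-")
            n3 = sum(prof.n3(CONTIG, s).sum() for s in "+-")
            assert n5 == n3, name

    def test_deterministic_profiles(self):
        cfg = SimConfig(seed=9, n_operons=8)
        genome, _, truth = generate_genome(cfg)
        p1 = simulate_libraries(genome, truth, cfg)
        p2 = simulate_libraries(genome, truth, cfg)
        for name in p1:
            for s in "+-":
                assert np.array_equal(p1[name].n5(CONTIG, s),
                                      p2[name].n5(CONTIG, s)), name

    def test_expected_species_conserve_ends_per_strain(self, small_sim):
        cfg, _, _, truth, _ = small_sim
        for plan in _plans_from_truth(truth):
            for strain in ("WT", "rne_ts", "pnp_del", "rnb_del", "rnr_del"):
                species = _species_for(plan, strain, cfg)
                assert all(i > 0 for *_ab, i, _p in species)
                # every cohort contributes exactly one 5' and one 3' end
                assert all(a <= b for a, b, *_ in species)

    def test_rne_mutant_depletes_cleavage_derived_ends(self, small_sim):
        cfg, _, _, truth, profiles = small_sim
        wt = [p for p in profiles.values()
              if p.spec.strain == "WT" and p.spec.fraction == "total"]
        mut = [p for p in profiles.values() if p.spec.strain == "rne_ts"]
        wt_n5 = sum(sum(p.n5(CONTIG, s)[pos] for p in wt) / len(wt)
                    for _, s, pos in truth.positions("rne5"))
        mut_n5 = sum(sum(p.n5(CONTIG, s)[pos] for p in mut) / len(mut)
                     for _, s, pos in truth.positions("rne5"))
        assert mut_n5 < 0.15 * wt_n5

    def test_processed_library_is_a_subset_of_total(self, small_sim):
        _, _, _, _, profiles = small_sim
        for rep in (1, 2, 3):
            tot = profiles[f"WT_total_{rep}"]
            proc = profiles[f"WT_processed_{rep}"]
            for s in "+-":
                assert (proc.n5(CONTIG, s) <= tot.n5(CONTIG, s)).all()

    def test_stop_probability_closed_form(self):
        cfg = SimConfig()
        assert cfg.stop_probability(cfg.logistic_dg0) == pytest.approx(0.5)
        want = 1.0 / (1.0 + np.exp(cfg.logistic_k * (0.0 - cfg.logistic_dg0)))
        assert cfg.stop_probability(0.0) == pytest.approx(want)
        assert cfg.stop_probability(-30) > 0.99


class TestMonotonicity:
    def test_steeper_score_link_raises_mean_processed_fraction(self):
        lo = generate_genome(SimConfig(seed=3, n_operons=40,
                                       link_slope=0.02))[2]
        hi = generate_genome(SimConfig(seed=3, n_operons=40,
                                       link_slope=0.06))[2]
        assert hi.tss.p_processed.mean() > lo.tss.p_processed.mean()

    def test_more_stable_stems_stop_more(self):
        cfg = SimConfig()
        dgs = np.linspace(-30, 0, 20)
        probs = [cfg.stop_probability(d) for d in dgs]
        assert (np.diff(probs) < 0).all()


class TestEvaluateRecovery:
    def _truth(self):
        sites = pd.DataFrame([
            {"site_class": "rne5", "enzyme": "", "contig": "chr",
             "strand": "+", "pos": p} for p in (100, 300, 500)])
        return srps.TruthTable(tss=pd.DataFrame(), sites=sites,
                               stemloops=pd.DataFrame(),
                               operons=pd.DataFrame())

    def test_perfect_calls_score_one(self):
        truth = self._truth()
        rec = evaluate_recovery(
            {"rne5": [("chr", "+", p) for p in (100, 300, 500)]}, truth)
        row = rec.iloc[0]
        assert row.precision == 1.0 and row.recall == 1.0

    def test_empty_call_set(self):
        rec = evaluate_recovery({"rne5": []}, self._truth())
        row = rec.iloc[0]
        assert row.recall == 0.0 and np.isnan(row.precision)

    def test_shifted_calls_beyond_tolerance_miss(self):
        rec = evaluate_recovery(
            {"rne5": [("chr", "+", p + 5) for p in (100, 300, 500)]},
            self._truth(), tolerance=2)
        assert rec.iloc[0].recall == 0.0

    def test_within_tolerance_hits(self):
        rec = evaluate_recovery(
            {"rne5": [("chr", "+", p + 2) for p in (100, 300, 500)]},
            self._truth(), tolerance=2)
        assert rec.iloc[0].recall == 1.0

    def test_absent_class_reports_na(self):
        rec = evaluate_recovery({"start5": [("chr", "+", 1)]}, self._truth())
        assert np.isnan(rec.iloc[0].precision)


class TestFileEmission:
    def test_written_files_reload_consistently(self, tmp_path):
        cfg = SimConfig(seed=21, n_operons=6)
        genome, ann, truth, profiles = srps.simulate(cfg, out_dir=tmp_path)
        assert (tmp_path / "genome.fa").exists()
        loaded = srps.load_genome(tmp_path / "genome.fa")
        assert loaded[CONTIG] == genome[CONTIG]
        ann2 = srps.parse_annotation(tmp_path / "genes.gff3",
                                     tmp_path / "operons.tsv")
        assert set(ann2.genes) == set(ann.genes)
        assert len(ann2.operons) == len(ann.operons)
        name = "WT_total_1"
        back = srps.EndProfile.from_bedgraph(
            {CONTIG: len(genome[CONTIG])}, tmp_path / name,
            spec=srps.LibrarySpec("WT", "total", 1))
        for s in "+-":
            assert np.array_equal(back.n5(CONTIG, s),
                                  profiles[name].n5(CONTIG, s))
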