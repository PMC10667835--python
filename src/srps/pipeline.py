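"""End-to-end orchestration: profiles in, called targetomes and statistics out.

Thin glue over the module-level operations, in the order the method runs:
processed-fraction calling (RppH / other monophosphate ends), differential
end calling (RNase E, then each exonuclease), site matching, quantitative
statistics, and operon-level classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import differential_ends as de
from . import operon_analysis as oa
from . import quant_model as qm
from . import rpph_caller as rc
from . import site_matching as sm
from .io_profiles import EndProfile, GenomeAnnotation, fpkm_table

logger = logging.getLogger("srps")


@dataclass
class SiteCalls:
    """All called site classes, as (contig, strand, pos) triples."""

    rpph: list[rc.ProcessedSite] = field(default_factory=list)
    other_processed: list[rc.ProcessedSite] = field(default_factory=list)
    rne5: list[de.RneEnd] = field(default_factory=list)
    rne3: list[de.RneEnd] = field(default_factory=list)
    exo: dict[str, list[de.ExoSite]] = field(default_factory=dict)

    def positions(self, which: str, enzyme: str | None = None
                  ) -> list[tuple[str, str, int]]:
        if which in ("rpph", "other_processed"):
            return [(s.contig, s.strand, s.pos) for s in getattr(self, which)]
        if which in ("rne5", "rne3"):
            return [(s.contig, s.strand, s.pos) for s in getattr(self, which)]
        out = []
        for enz, sites in self.exo.items():
            if enzyme is not None and enz != enzyme:
                continue
            out.extend((s.contig, s.strand, s.pos)
                       for s in sites if s.site_class == which)
        return sorted(set(out))

    def matching_sites(self, which: str, enzyme: str | None = None
                       ) -> list[sm.Site]:
        return [sm.Site(c, s, p) for c, s, p in self.positions(which, enzyme)]


def group_profiles(profiles: Mapping[str, EndProfile]
                   ) -> dict[tuple[str, str], dict[str, EndProfile]]:
    """Index libraries by (strain, fraction)."""
    out: dict[tuple[str, str], dict[str, EndProfile]] = {}
    for name, prof in profiles.items():
        if prof.spec is None:
            raise ValueError(f"library {name} lacks a LibrarySpec")
        out.setdefault((prof.spec.strain, prof.spec.fraction), {})[name] = prof
    return out


def call_all_sites(profiles: Mapping[str, EndProfile],
                   annotation: GenomeAnnotation,
                   thresholds: de.Thresholds | None = None,
                   candidate_min_reads: int = rc.DEFAULT_CANDIDATE_MIN_READS,
                   bin_min_reads: int = rc.DEFAULT_BIN_MIN_READS,
                   min_samples: int = rc.DEFAULT_MIN_SAMPLES) -> SiteCalls:
    """Run every caller the library set supports."""
    thr = thresholds or de.Thresholds()
    groups = group_profiles(profiles)
    wt_total = groups.get(("WT", "total"), {})
    calls = SiteCalls()

    processed = groups.get(("WT", "processed"), {})
    if processed:
        sites = rc.call_from_profiles(processed, annotation.tss_set,
                                      candidate_min_reads=candidate_min_reads,
                                      bin_min_reads=bin_min_reads,
                                      min_samples=min_samples)
        calls.rpph = [s for s in sites if s.site_class == "rpph"]
        calls.other_processed = [s for s in sites
                                 if s.site_class == "other_processed"]

    rne = groups.get(("rne_ts", "total"), {})
    if rne and wt_total:
        ends = de.call_rne_ends(wt_total, rne, calls.other_processed, thr)
        calls.rne5 = [e for e in ends if e.end_type == "five_prime"]
        calls.rne3 = [e for e in ends if e.end_type == "three_prime"]

    for enzyme, strain in de.ENZYME_STRAINS.items():
        mut = groups.get((strain, "total"), {})
        if mut and wt_total:
            calls.exo[enzyme] = de.call_exo_sites(wt_total, mut, enzyme, thr)
    return calls


@dataclass
class QuantResults:
    ratio_records: list[qm.ProcessingRatioRecord]
    score_table: pd.DataFrame | None
    score_ratio_r: float | None
    end_ratio_records: list[qm.EndRatioRecord]
    endratio_mfe_r: float | None
    rne3_fractions: dict[str, float]
    rnb_offsets: dict[int, int]
    rnb_offset_fraction: float


def quantify(calls: SiteCalls,
             profiles: Mapping[str, EndProfile],
             genome: Mapping[str, str],
             score_table=None,
             end_ratio_enzyme: str = "pnp") -> QuantResults:
    """The quantitative layer: ratios, correlations and matching summaries."""
    groups = group_profiles(profiles)
    wt_total = groups.get(("WT", "total"), {})
    processed = groups.get(("WT", "processed"), {})

    # processing ratios of RppH sites and their score correlation
    ratio_records = []
    for s in calls.rpph:
        rec = qm.processing_ratio((s.contig, s.strand, s.pos),
                                  processed, wt_total)
        if rec is not None:
            ratio_records.append(rec)
    score_df = score_r = None
    try:
        score_df, score_r = qm.score_vs_ratio(
            (((r.contig, r.strand, r.pos), r.ratio) for r in ratio_records),
            genome, table=score_table)
    except ValueError as exc:
        logger.warning("score_vs_ratio unavailable: %s", exc)

    # rne3 vs exo stop/start partition
    stops = calls.matching_sites("stop3")
    starts = calls.matching_sites("start3")
    _, fractions = sm.link_rne3(calls.matching_sites("rne3"), stops, starts)

    # stop/start pairs, end ratios and the dG correlation (PNPase by default)
    pairs = sm.pair_stop_start(calls.matching_sites("stop3", end_ratio_enzyme),
                               calls.matching_sites("start3", end_ratio_enzyme),
                               end_ratio_enzyme)
    er_records = []
    for p in pairs:
        rec = qm.end_ratio((p.stop.contig, p.stop.strand, p.stop.pos),
                           p.start.pos, wt_total, genome=genome)
        if rec is not None:
            er_records.append(rec)
    er_r = None
    try:
        er_r = qm.endratio_mfe_correlation(er_records)
    except ValueError as exc:
        logger.warning("end-ratio correlation unavailable: %s", exc)

    rnb_pairs = sm.pair_stop_start(calls.matching_sites("stop3", "rnb"),
                                   calls.matching_sites("start3", "rnb"), "rnb")
    hist, _, frac35 = sm.rnb_offset_histogram(rnb_pairs)

    return QuantResults(ratio_records, score_df, score_r, er_records, er_r,
                        fractions, hist, frac35)


def recovery_benchmark(config=None, seed: int | None = None) -> dict:
    """Simulate, call, quantify and score one full pipeline run.

    Returns a flat dict of the run's headline numbers: per-class
    precision/recall against the implanted truth (+/-2 nt), the processing-
    ratio mean absolute error, the two Pearson correlations, and the
    matching-stage summary fractions.
    """
    from . import synthetic_data as sd

    if config is None:
        config = sd.SimConfig(seed=1 if seed is None else seed)
    genome, annotation, truth, profiles = sd.simulate(config)
    calls = call_all_sites(profiles, annotation)
    quant = quantify(calls, profiles, genome)

    called = {
        "rpph": calls.positions("rpph"),
        "rne5": calls.positions("rne5"),
        "rne3": calls.positions("rne3"),
        "pnp_stop3": calls.positions("stop3", "pnp"),
        "rnb_stop3": calls.positions("stop3", "rnb"),
        "start3": calls.positions("start3"),
        "start5": calls.positions("start5"),
    }
    class_map = {"pnp_stop3": ("stop3", "pnp"), "rnb_stop3": ("stop3", "rnb")}
    rec = sd.evaluate_recovery(called, truth, tolerance=2, class_map=class_map)

    tss_p = {(r.contig, r.strand, int(r.pos)): r.p_processed
             for r in truth.tss.itertuples()}
    errors = []
    for r in quant.ratio_records:
        for w in range(-2, 3):
            key = (r.contig, r.strand, r.pos + w)
            if key in tss_p:
                errors.append(abs(r.ratio - tss_p[key]))
                break
    out = {
        "recovery": rec,
        "n_operons": config.n_operons,
        "processing_ratio_mae": float(np.mean(errors)) if errors else np.nan,
        "n_ratio_records": len(errors),
        "score_ratio_r": quant.score_ratio_r,
        "endratio_mfe_r": quant.endratio_mfe_r,
        "n_end_ratio_records": len(quant.end_ratio_records),
        "rne3_fractions": quant.rne3_fractions,
        "rnb_offset_fraction_3_5": quant.rnb_offset_fraction,
        "calls": calls,
        "truth": truth,
        "genome": genome,
        "annotation": annotation,
        "profiles": profiles,
        "quant": quant,
    }
    for row in rec.itertuples():
        out[f"{row.site_class}_recall"] = float(row.recall)
        out[f"{row.site_class}_precision"] = float(row.precision)
    return out


def operon_summary(calls: SiteCalls,
                   gene_counts: pd.DataFrame,
                   annotation: GenomeAnnotation,
                   profiles: Mapping[str, EndProfile]) -> dict:
    """FPKM, complex-operon classification and the site distribution table."""
    totals = gene_counts.sum(axis=0).values
    lengths = {g.gene_id: g.length for g in annotation.genes.values()}
    fpkm = fpkm_table(gene_counts, totals, lengths)
    classes = oa.classify_complex_operons(fpkm["fpkm"], annotation)
    sites_by_class = {
        "rpph": calls.positions("rpph"),
        "rne5": calls.positions("rne5"),
        "rne3": calls.positions("rne3"),
    }
    for enzyme in calls.exo:
        for cls in ("stop3", "start3", "start5"):
            sites_by_class[f"{enzyme}_{cls}"] = calls.positions(cls, enzyme)
    table = oa.site_distribution_table(sites_by_class, classes, annotation)
    wt_total = group_profiles(profiles).get(("WT", "total"), {})
    utr_cases = oa.find_multi_cleavage_utr(calls.positions("rne5"),
                                           annotation, wt_total)
    return {"fpkm": fpkm, "operon_classes": classes,
            "distribution": table, "utr_cases": utr_cases}
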