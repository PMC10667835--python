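"""Operon-level analysis: complex operons, site distribution, 5'-UTR cleavage.

A polycistronic operon whose adjacent genes have strongly skewed transcript
abundances (a "complex operon") is the hallmark of selective processing and
stabilization: the primary transcript is cut and its segments decay at
different rates.  This module classifies operons from gene-level FPKM,
tabulates where each called site class falls (all sites / inside
polycistronic operons / inside complex operons), and enumerates operons in
which RNase E cuts the 5'-UTR or one intergenic region repeatedly, creating
transcript isoforms with different 5'-UTR lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_profiles import EndProfile, GenomeAnnotation


@dataclass(frozen=True)
class OperonClass:
    operon_id: str
    n_genes: int
    polycistronic: bool
    complex_operon: bool
    evidence: tuple[str, ...] = ()   # adjacent gene pairs that triggered the call


@dataclass(frozen=True)
class DistributionRow:
    site_class: str
    total: int
    in_polycistronic: int
    in_complex: int

    @property
    def pct_polycistronic(self) -> float | None:
        return 100.0 * self.in_polycistronic / self.total if self.total else None

    @property
    def pct_complex(self) -> float | None:
        return (100.0 * self.in_complex / self.in_polycistronic
                if self.in_polycistronic else None)


@dataclass(frozen=True)
class UtrCleavageCase:
    operon_id: str
    downstream_gene: str
    region: str                     # "5utr" | "igr"
    rne5_positions: tuple[int, ...]
    utr_lengths: tuple[int, ...]    # 5'-UTR length of each implied isoform


def _pair_is_skewed(f1: float, f2: float,
                    fpkm_floor: float = 2.0,
                    ratio_min: float = 3.0,
                    diff_min: float = 10.0) -> bool:
    """The adjacent-pair skew rule: both FPKM >= 2 with a >= 3-fold ratio in
    either direction, or one FPKM < 2 with an absolute difference >= 10."""
    if f1 >= fpkm_floor and f2 >= fpkm_floor:
        ratio = f1 / f2
        return ratio >= ratio_min or ratio <= 1.0 / ratio_min
    if min(f1, f2) < fpkm_floor:
        return abs(f1 - f2) >= diff_min
    return False


def classify_complex_operons(fpkm: Mapping[str, float] | pd.Series,
                             annotation: GenomeAnnotation,
                             fpkm_floor: float = 2.0,
                             ratio_min: float = 3.0,
                             diff_min: float = 10.0) -> list[OperonClass]:
    """Classify each operon as polycistronic and/or complex from gene FPKM."""
    out = []
    for op in annotation.operons.values():
        poly = op.n_genes >= 2
        evidence = []
        if poly:
            for g1, g2 in zip(op.gene_ids[:-1], op.gene_ids[1:]):
                for g in (g1, g2):
                    if g not in fpkm:
                        raise ValueError(f"gene {g} missing from FPKM table")
                if _pair_is_skewed(float(fpkm[g1]), float(fpkm[g2]),
                                   fpkm_floor, ratio_min, diff_min):
                    evidence.append(f"{g1}|{g2}")
        out.append(OperonClass(op.operon_id, op.n_genes, poly,
                               bool(evidence), tuple(evidence)))
    return out


def site_distribution_table(sites_by_class: Mapping[str, Sequence[tuple[str, str, int]]],
                            operon_classes: Sequence[OperonClass],
                            annotation: GenomeAnnotation) -> pd.DataFrame:
    """Per-class site counts: total, inside polycistronic operon extents,
    inside complex operons (a half-open extent from TSS to the 3' end of the
    last gene, same strand only)."""
    class_by_id = {c.operon_id: c for c in operon_classes}
    extents = []
    for oid, op in annotation.operons.items():
        cls = class_by_id.get(oid)
        if cls is None or not cls.polycistronic:
            continue
        lo, hi = annotation.operon_extent(oid)
        extents.append((op.contig, op.strand, lo, hi, cls.complex_operon))

    rows = []
    for site_class, sites in sites_by_class.items():
        total = len(sites)
        in_poly = in_complex = 0
        for contig, strand, pos in sites:
            hit_poly = hit_complex = False
            for (c, s, lo, hi, is_complex) in extents:
                if c == contig and s == strand and lo <= pos < hi:
                    hit_poly = True
                    hit_complex = hit_complex or is_complex
            in_poly += hit_poly
            in_complex += hit_complex
        row = DistributionRow(site_class, total, in_poly, in_complex)
        rows.append({
            "site_class": site_class,
            "total": total,
            "in_polycistronic": in_poly,
            "pct_polycistronic": row.pct_polycistronic,
            "in_complex": in_complex,
            "pct_complex": row.pct_complex,
        })
    return pd.DataFrame(rows)


def find_multi_cleavage_utr(rne5_sites: Sequence[tuple[str, str, int]],
                            annotation: GenomeAnnotation,
                            wt_total_profiles: Mapping[str, EndProfile],
                            max_tss_dist: int = 200,
                            max_adjacent_dist: int = 200,
                            min_evidence: int = 1) -> list[UtrCleavageCase]:
    """Operons where RNase E generates alternative 5'-UTR isoforms.

    Case (a): >= 1 5' rne end inside the 5'-UTR (TSS to first gene start),
    < ``max_tss_dist`` nt downstream of the TSS.  Case (b): >= 2 5' rne ends
    in one intergenic region with adjacent spacing < ``max_adjacent_dist``.
    Every implied isoform 5' end (the TSS, or the cleavage positions) must
    show n5 evidence pooled across the WT total libraries.
    """
    pooled: dict[tuple[str, str], np.ndarray] = {}

    def n5_at(contig: str, strand: str, pos: int) -> int:
        key = (contig, strand)
        if key not in pooled:
            pooled[key] = sum(p.n5(contig, strand).astype(np.int64)
                              for p in wt_total_profiles.values())
        arr = pooled[key]
        return int(arr[pos]) if 0 <= pos < arr.size else 0

    by_track: dict[tuple[str, str], list[int]] = {}
    for contig, strand, pos in rne5_sites:
        by_track.setdefault((contig, strand), []).append(pos)

    def tx_dist(strand: str, upstream: int, downstream: int) -> int:
        return downstream - upstream if strand == "+" else upstream - downstream

    cases: list[UtrCleavageCase] = []
    for oid, op in annotation.operons.items():
        if not op.tss_positions:
            continue
        tss = op.tss_positions[0] if op.strand == "+" else max(op.tss_positions)
        genes = [annotation.genes[g] for g in op.gene_ids]
        positions = by_track.get((op.contig, op.strand), [])

        # -- regions in transcript order: 5'-UTR then the IGRs -------------
        regions: list[tuple[str, str, int, int]] = []   # (kind, downstream gene, lo, hi)
        first = genes[0]
        if op.strand == "+":
            if tss < first.start:
                regions.append(("5utr", first.gene_id, tss, first.start))
            for g_up, g_dn in zip(genes[:-1], genes[1:]):
                if g_up.end < g_dn.start:
                    regions.append(("igr", g_dn.gene_id, g_up.end, g_dn.start))
        else:
            if tss >= first.end:
                regions.append(("5utr", first.gene_id, first.end, tss + 1))
            for g_up, g_dn in zip(genes[:-1], genes[1:]):
                if g_dn.end < g_up.start:
                    regions.append(("igr", g_dn.gene_id, g_dn.end, g_up.start))

        for kind, gene_id, lo, hi in regions:
            inside = sorted(p for p in positions if lo <= p < hi)
            if not inside:
                continue
            if op.strand == "-":
                inside = inside[::-1]       # transcript order
            if kind == "5utr":
                hits = [p for p in inside if 0 < tx_dist(op.strand, tss, p) < max_tss_dist]
                qualifies = len(hits) >= 1
            else:
                hits = inside
                spacings = [abs(b - a) for a, b in zip(hits[:-1], hits[1:])]
                qualifies = len(hits) >= 2 and all(s < max_adjacent_dist for s in spacings)
            if not qualifies:
                continue
            isoform_starts = ([tss] + hits) if kind == "5utr" else hits
            if any(n5_at(op.contig, op.strand, p) < min_evidence
                   for p in isoform_starts):
                continue
            gene = annotation.genes[gene_id]
            gene_start = gene.start if op.strand == "+" else gene.end - 1
            utr_lengths = tuple(abs(gene_start - p) for p in isoform_starts)
            cases.append(UtrCleavageCase(oid, gene_id, kind,
                                         tuple(hits), utr_lengths))
    return cases
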