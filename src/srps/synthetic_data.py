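"""Generative simulator of SEnd-seq-style end-count libraries.

The simulator is the inverse of the calling pipeline: it implants the same
biology the callers look for, records the ground truth, and emits per-base
5'/3' end-count and coverage tracks for every strain/fraction the study
design uses (WT total x3, WT processed x3, rne-ts total x2, and one total
library each for the pnp, rnb and rnr knockouts).

Per operon the generative model is:

* a TSS whose first three transcribed nucleotides carry a score ``s``; the
  RppH-processed (5'-monophosphate) fraction of its transcripts is the
  clamped linear link ``p = a + b*s``;
* with probability ``p_rne_event``, one RNase E cleavage site bearing the
  RN|WUU motif, cleaved in a fraction ``q = cleavage_coef * p`` of molecules
  (cleavage requires the monophosphate 5' end, so its intensity follows p);
  the upstream fragment's exposed 3' end is trimmed 3'->5' by the operon's
  exonuclease (PNPase / RNase II / RNase R), halting at a designed stem-loop
  with a logistic probability in the stem-loop's folding dG (RNase II, a
  distributive nibbler, always halts 3-10 nt in); halted molecules leave a
  3' end at the trimming stop, un-trimmed molecules at the exposure point,
  the rest are fully degraded;
* otherwise one endonuclease-generated internal fragment that the operon's
  exonuclease degrades completely in WT, so both its ends surface only in
  that exonuclease's knockout.

Mutants are activity ablations: the residual activity ``eps`` scales the
affected intensities (matching a temperature-sensitive allele rather than a
clean null).  Counts are negative-binomially distributed around expected
intensities; coverage derives from the simulated fragment spans, so per-
library end-count conservation (sum n5 = sum n3) holds exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_profiles import (EndProfile, Gene, GenomeAnnotation, LibrarySpec,
                          Operon)
from .quant_model import DEFAULT_SCORE_TABLE, fold_mfe, revcomp

logger = logging.getLogger("srps")

CONTIG = "simchr"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one simulation run."""

    seed: int = 1
    n_operons: int = 200
    depth: float = 200.0            # mean end-reads per implanted event

    # score -> processed-fraction link: p = clamp(a + b * score, 0, 1)
    link_intercept: float = 0.05
    link_slope: float = 0.06

    # stem-loop dG -> trimming-stop link: P(stop) = 1 / (1 + exp(k*(dG - dG0)))
    logistic_dg0: float = -10.0
    logistic_k: float = 0.4

    eps: float = 0.02               # residual activity of ablated enzymes
    nb_dispersion: float = 0.05     # NB dispersion of end counts

    cleavage_coef: float = 0.8      # q = cleavage_coef * p, capped below 1
    untrimmed_fraction: float = 0.08  # WT molecules caught before trimming (pnp/rnr)
    fragment_intensity: float = 0.3  # internal-fragment fraction of molecules
    p_rne_event: float = 0.7
    enzyme_weights: tuple[tuple[str, float], ...] = (
        ("pnp", 0.5), ("rnb", 0.35), ("rnr", 0.15))

    frac_scored_tss: float = 0.9    # remainder get random trinucleotides
    background_gc: float = 0.30     # AT-rich background: implanted stem-loops,
                                    # not incidental structure, carry the dG signal
    dg_band_pnp: tuple[float, float] = (-14.0, -6.0)
    dg_band_rnb: tuple[float, float] = (-20.0, -8.0)
    band_halfwidth: float = 1.0     # stem-loop design tolerance around target

    genes_per_operon: tuple[int, int] = (1, 4)
    gene_length: tuple[int, int] = (200, 500)
    igr_length: tuple[int, int] = (30, 120)
    utr_length: tuple[int, int] = (60, 250)
    term_utr: int = 40
    operon_spacing: tuple[int, int] = (150, 300)
    edge_margin: int = 200

    wobble_weights: tuple[float, ...] = (0.08, 0.14, 0.56, 0.14, 0.08)
    background_per_kb: float = 0.05  # stray fragment species per kb per library
    size_factor_sigma: float = 0.15  # lognormal library-size variation

    wt_total_reps: int = 3
    wt_processed_reps: int = 3
    rne_reps: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.eps < 1):
            raise ValueError("eps must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")

    def processed_fraction(self, score: float) -> float:
        return float(np.clip(self.link_intercept + self.link_slope * score, 0.0, 1.0))

    def stop_probability(self, dg: float) -> float:
        return float(1.0 / (1.0 + np.exp(self.logistic_k * (dg - self.logistic_dg0))))

    def library_specs(self) -> list[LibrarySpec]:
        specs = []
        for r in range(1, self.wt_total_reps + 1):
            specs.append(LibrarySpec("WT", "total", r))
        for r in range(1, self.wt_processed_reps + 1):
            specs.append(LibrarySpec("WT", "processed", r))
        for r in range(1, self.rne_reps + 1):
            specs.append(LibrarySpec("rne_ts", "total", r))
        for strain in ("pnp_del", "rnb_del", "rnr_del"):
            specs.append(LibrarySpec(strain, "total", 1))
        return specs


@dataclass
class TruthTable:
    """Ground truth of one simulated genome."""

    tss: pd.DataFrame        # contig strand pos tri score p_processed
    sites: pd.DataFrame      # site_class enzyme contig strand pos (+dg, p_stop)
    stemloops: pd.DataFrame  # contig strand stop_pos enzyme seq dg p_stop
    operons: pd.DataFrame    # per-operon generative parameters

    def positions(self, site_class: str,
                  enzyme: str | None = None) -> list[tuple[str, str, int]]:
        df = self.sites[self.sites.site_class == site_class]
        if enzyme is not None:
            df = df[df.enzyme == enzyme]
        return [(r.contig, r.strand, int(r.pos)) for r in df.itertuples()]

    def to_files(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.tss.to_csv(out_dir / "truth_tss.tsv", sep="\t", index=False)
        self.sites.to_csv(out_dir / "truth_sites.tsv", sep="\t", index=False)
        self.stemloops.to_csv(out_dir / "truth_stemloops.tsv", sep="\t", index=False)
        self.operons.to_csv(out_dir / "truth_operons.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Stem-loop design
# ---------------------------------------------------------------------------

def design_stemloop(band: tuple[float, float],
                    rng: np.random.Generator,
                    max_stem: int = 15,
                    max_iter: int = 200) -> tuple[str, float]:
    """Construct a DNA inverted repeat whose transcript folds within a dG band.

    Stem length and GC content are adjusted by rejection sampling around a
    crude nearest-neighbor estimate until the folding engine reports a dG in
    ``[lo, hi]``; deterministic for a fixed generator state.
    """
    lo, hi = band
    if lo > hi:
        raise ValueError("band must be (lo, hi) with lo <= hi")
    target = abs((lo + hi) / 2.0)
    for _ in range(max_iter):
        # empirical hairpin energetics: dG ~ -(stem_len - 6) - 2 * n_gc
        stem_len = int(np.clip(round((target + 6) / 3) + rng.integers(0, 5),
                               4, max_stem))
        n_gc = int(np.clip(round((target - (stem_len - 6)) / 2.0)
                           + rng.integers(-1, 2), 0, stem_len))
        gc_slots = rng.choice(stem_len, size=n_gc, replace=False)
        stem = []
        for i in range(stem_len):
            if i in gc_slots:
                stem.append(rng.choice(["G", "C"]))
            else:
                stem.append(rng.choice(["A", "T"]))
        stem_seq = "".join(stem)
        loop_len = int(rng.integers(4, 7))
        loop = "".join(rng.choice(["A", "C"], size=loop_len))
        seq = stem_seq + loop + revcomp(stem_seq)
        dg = fold_mfe(seq)[1]
        if lo <= dg <= hi:
            return seq, dg
    raise ValueError(f"no stem-loop with dG in [{lo}, {hi}] found within "
                     f"{max_iter} iterations (max stem {max_stem})")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

_R = ("G", "A")
_W = ("A", "T")


@dataclass
class _OperonPlan:
    operon_id: str
    strand: str
    tss: int                 # genomic position of transcript offset 0
    length: int              # transcript length
    genes: list[tuple[str, int, int]]   # (gene_id, tx start offset, tx end offset)
    tri: str
    score: int
    p: float
    q: float
    event: str               # "rne" | "fragment" | "none"
    enzyme: str | None
    c_off: int | None = None
    start_off: int | None = None       # trimming start (exposure) offset
    stop_off: int | None = None        # trimming stop offset
    dg: float | None = None
    p_stop: float | None = None
    f5_off: int | None = None
    f3_off: int | None = None

    def g(self, offset: int) -> int:
        """Genomic position of a transcript offset."""
        return self.tss + offset if self.strand == "+" else self.tss - offset


def _write_tx(seq: np.ndarray, plan: _OperonPlan, offset: int, s: str) -> None:
    """Write transcript-sense bases into the genome array at a tx offset."""
    for i, ch in enumerate(s):
        gpos = plan.g(offset + i)
        seq[gpos] = ch if plan.strand == "+" else ch.translate(
            str.maketrans("ACGT", "TGCA"))


def _tx_slice(seq: np.ndarray, plan: _OperonPlan, lo: int, hi: int) -> str:
    """Transcript-sense sequence for tx offsets [lo, hi)."""
    comp = str.maketrans("ACGT", "TGCA")
    chars = [str(seq[plan.g(o)]) for o in range(lo, hi)]
    if plan.strand == "-":
        chars = [c.translate(comp) for c in chars]
    return "".join(chars)


def generate_genome(config: SimConfig
                    ) -> tuple[dict[str, str], GenomeAnnotation, TruthTable]:
    """Build the synthetic genome, annotation and ground truth."""
    rng = np.random.default_rng(config.seed)
    scored_tris = sorted(DEFAULT_SCORE_TABLE)
    enzymes, weights = zip(*config.enzyme_weights)
    weights = np.asarray(weights) / np.sum(weights)

    plans: list[_OperonPlan] = []
    cursor = config.edge_margin
    layout: list[dict] = []
    for k in range(config.n_operons):
        n_genes = int(rng.integers(config.genes_per_operon[0],
                                   config.genes_per_operon[1] + 1))
        utr = int(rng.integers(*config.utr_length))
        gene_lens = [int(rng.integers(*config.gene_length)) for _ in range(n_genes)]
        igr_lens = [int(rng.integers(*config.igr_length)) for _ in range(n_genes - 1)]
        genes = []
        off = utr
        for gi in range(n_genes):
            genes.append((f"g{k:04d}_{gi}", off, off + gene_lens[gi]))
            off += gene_lens[gi]
            if gi < n_genes - 1:
                off += igr_lens[gi]
        length = off + config.term_utr
        layout.append({"n_genes": n_genes, "utr": utr, "genes": genes,
                       "igr_lens": igr_lens, "length": length,
                       "strand": "+" if rng.random() < 0.5 else "-",
                       "spacing": int(rng.integers(*config.operon_spacing))})

    genome_len = config.edge_margin * 2 + sum(
        d["length"] + d["spacing"] for d in layout)
    gc = config.background_gc
    seq = rng.choice(np.array(list("ACGT")), size=genome_len,
                     p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    truth_sites: list[dict] = []
    truth_tss: list[dict] = []
    truth_loops: list[dict] = []
    op_rows: list[dict] = []
    ann_genes: dict[str, Gene] = {}
    ann_operons: dict[str, Operon] = {}

    for k, d in enumerate(layout):
        oid = f"op{k:04d}"
        strand = d["strand"]
        if strand == "+":
            tss = cursor
            cursor += d["length"] + d["spacing"]
        else:
            tss = cursor + d["length"] - 1
            cursor += d["length"] + d["spacing"]

        if rng.random() < config.frac_scored_tss:
            tri = scored_tris[int(rng.integers(len(scored_tris)))]
            score = DEFAULT_SCORE_TABLE[tri]
        else:
            tri = "".join(rng.choice(list("ACGT"), size=3))
            score = (DEFAULT_SCORE_TABLE[tri] if tri in DEFAULT_SCORE_TABLE
                     else int(rng.integers(3, 15)))
        p = config.processed_fraction(score)
        q = min(config.cleavage_coef * p, 0.95)

        event = "rne" if rng.random() < config.p_rne_event else "fragment"
        enzyme = str(rng.choice(enzymes, p=weights))
        plan = _OperonPlan(oid, strand, tss, d["length"], d["genes"],
                           tri, score, p, q, event, enzyme)
        _write_tx(seq, plan, 0, tri)

        if event == "rne":
            _plan_rne_event(plan, d, config, rng, seq, truth_loops)
        else:
            _plan_fragment_event(plan, d, config, rng)
        plans.append(plan)

        # --- annotation ------------------------------------------------
        gids = []
        for gid, a, b in d["genes"]:
            ga, gb = plan.g(a), plan.g(b - 1)
            ann_genes[gid] = Gene(gid, CONTIG, strand, min(ga, gb),
                                  max(ga, gb) + 1, operon_id=oid)
            gids.append(gid)
        ann_operons[oid] = Operon(oid, tuple(gids), CONTIG, strand, (tss,))

        # --- truth ------------------------------------------------------
        truth_tss.append({"contig": CONTIG, "strand": strand, "pos": tss,
                          "tri": tri, "score": score, "p_processed": p})
        truth_sites.append({"site_class": "rpph", "enzyme": "",
                            "contig": CONTIG, "strand": strand, "pos": tss})
        if plan.event == "rne" and plan.c_off is not None:
            c_g = plan.g(plan.c_off)
            truth_sites.append({"site_class": "rne5", "enzyme": "",
                                "contig": CONTIG, "strand": strand, "pos": c_g})
            truth_sites.append({"site_class": "other_processed", "enzyme": "",
                                "contig": CONTIG, "strand": strand, "pos": c_g})
            start_g = plan.g(plan.start_off)
            stop_g = plan.g(plan.stop_off)
            truth_sites.append({"site_class": "stop3", "enzyme": plan.enzyme,
                                "contig": CONTIG, "strand": strand,
                                "pos": stop_g, "dg": plan.dg,
                                "p_stop": plan.p_stop})
            truth_sites.append({"site_class": "start3", "enzyme": plan.enzyme,
                                "contig": CONTIG, "strand": strand,
                                "pos": start_g})
            truth_sites.append({"site_class": "rne3", "enzyme": plan.enzyme,
                                "contig": CONTIG, "strand": strand,
                                "pos": stop_g})
            if plan.enzyme in ("pnp", "rnr"):
                # the untrimmed-residue 3' signal is RNase-E-dependent too
                truth_sites.append({"site_class": "rne3", "enzyme": plan.enzyme,
                                    "contig": CONTIG, "strand": strand,
                                    "pos": start_g})
        elif plan.event == "fragment":
            truth_sites.append({"site_class": "start5", "enzyme": plan.enzyme,
                                "contig": CONTIG, "strand": strand,
                                "pos": plan.g(plan.f5_off)})
            truth_sites.append({"site_class": "start3", "enzyme": plan.enzyme,
                                "contig": CONTIG, "strand": strand,
                                "pos": plan.g(plan.f3_off)})

        row = {"operon_id": oid, "strand": strand, "tss": tss,
               "length": d["length"], "tri": tri, "score": score,
               "p": p, "q": q, "event": plan.event, "enzyme": plan.enzyme,
               "c_off": plan.c_off, "start_off": plan.start_off,
               "stop_off": plan.stop_off, "dg": plan.dg,
               "p_stop": plan.p_stop, "f5_off": plan.f5_off,
               "f3_off": plan.f3_off}
        op_rows.append(row)

    genome = {CONTIG: "".join(seq.tolist())}
    annotation = GenomeAnnotation(genes=ann_genes, operons=ann_operons)
    truth = TruthTable(tss=pd.DataFrame(truth_tss),
                       sites=pd.DataFrame(truth_sites),
                       stemloops=pd.DataFrame(truth_loops),
                       operons=pd.DataFrame(op_rows))
    return genome, annotation, truth


def _plan_rne_event(plan: _OperonPlan, d: dict, config: SimConfig,
                    rng: np.random.Generator, seq: np.ndarray,
                    truth_loops: list[dict]) -> None:
    """Choose cleavage/trimming geometry and implant motif + stem-loop."""
    utr = d["utr"]
    # cleavage position: 5'-UTR when it is long enough (alternative-UTR
    # cases), else the first IGR, else the first gene body
    placed = None
    if plan.enzyme == "rnb":
        min_c = 70
        if utr >= min_c + 20 and rng.random() < 0.35:
            placed = int(rng.integers(min_c, min(utr - 5, 190)))
    if placed is None:
        min_c = 115 if plan.enzyme in ("pnp", "rnr") else 70
        if d["n_genes"] >= 2:
            g1_end = d["genes"][0][2]
            igr_mid = g1_end + d["igr_lens"][0] // 2
            placed = max(igr_mid, min_c + 1)
        else:
            body_mid = (utr + d["genes"][0][2]) // 2
            placed = max(body_mid, min_c + 1)
    c = int(min(placed, plan.length - config.term_utr - 10))
    plan.c_off = c
    plan.start_off = c - 1

    if plan.enzyme == "rnb":
        dist = int(rng.choice([3, 4, 5, 6, 7, 8, 9, 10],
                              p=[0.25, 0.25, 0.22, 0.08, 0.07, 0.06, 0.04, 0.03]))
        band = config.dg_band_rnb
        tail = 0            # the distributive nibbler trims flush to the stem
        plan.p_stop = 1.0   # and always halts there
    else:
        d_max = min(280, c - 1 - 56)
        dist = int(rng.integers(50, max(d_max, 51) + 1))
        band = config.dg_band_pnp
        tail = 3            # processive enzymes stall a footprint short of the stem
    plan.stop_off = c - 1 - dist

    target = float(rng.uniform(*band))
    loop_seq, dg = design_stemloop(
        (target - config.band_halfwidth, target + config.band_halfwidth), rng)
    plan.dg = dg

    # implant: stem-loop ends `tail` nt upstream of the stop; motif RN|WUU
    # around the cleavage position
    _write_tx(seq, plan, plan.stop_off - tail - len(loop_seq) + 1, loop_seq)
    motif = (str(rng.choice(_R)) + str(rng.choice(list("ACGT")))
             + str(rng.choice(_W)) + "TT")
    _write_tx(seq, plan, c - 2, motif)

    # the enzyme responds to the folded 3' end in context: the stop
    # probability follows the dG of the 50-nt window just upstream of the stop
    ctx = _tx_slice(seq, plan, plan.stop_off - 50, plan.stop_off)
    dg_ctx = fold_mfe(ctx)[1]
    plan.dg = dg_ctx
    if plan.enzyme != "rnb":
        plan.p_stop = config.stop_probability(dg_ctx)
    truth_loops.append({"contig": CONTIG, "strand": plan.strand,
                        "stop_pos": plan.g(plan.stop_off),
                        "enzyme": plan.enzyme, "seq": loop_seq,
                        "dg_hairpin": dg, "dg": dg_ctx,
                        "p_stop": plan.p_stop})


def _plan_fragment_event(plan: _OperonPlan, d: dict, config: SimConfig,
                         rng: np.random.Generator) -> None:
    lo = d["utr"] + 20
    hi = plan.length - config.term_utr - 10
    dist = int(rng.integers(80, 251))
    if hi - lo <= dist + 1:
        dist = max(60, hi - lo - 2)
    f5 = int(rng.integers(lo, hi - dist))
    plan.f5_off = f5
    plan.f3_off = f5 + dist


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def _species_for(plan: _OperonPlan, strain: str, config: SimConfig
                 ) -> list[tuple[int, int, float, float]]:
    """Expected fragment cohorts for one operon in one strain.

    Returns (five_offset, three_offset, intensity, processed_intensity)
    tuples; intensities are expected fragment counts at depth
    ``config.depth``.
    """
    N = config.depth
    p, q = plan.p, plan.q
    eps = config.eps
    last = plan.length - 1
    out: list[tuple[int, int, float, float]] = []
    if plan.event == "rne":
        q_eff = q * eps if strain == "rne_ts" else q
        out.append((0, last, (1.0 - q_eff) * N, p * (1.0 - q_eff) * N))
        if q_eff > 0:
            out.append((plan.c_off, last, q_eff * N, q_eff * N))
            enzyme_strain = {"pnp": "pnp_del", "rnb": "rnb_del",
                             "rnr": "rnr_del"}[plan.enzyme]
            upstream = q_eff * N
            if strain == enzyme_strain:
                # trimming ablated: the exposed 3' end persists (residual eps
                # of the activity still reaches the stop)
                out.append((0, plan.start_off, (1 - eps) * upstream,
                            p * (1 - eps) * upstream))
                out.append((0, plan.stop_off, eps * upstream,
                            p * eps * upstream))
            elif plan.enzyme == "rnb":
                out.append((0, plan.stop_off, upstream, p * upstream))
            else:
                u = config.untrimmed_fraction
                stopped = (1 - u) * plan.p_stop * upstream
                out.append((0, plan.start_off, u * upstream, p * u * upstream))
                if stopped > 0:
                    out.append((0, plan.stop_off, stopped, p * stopped))
    else:
        out.append((0, last, N, p * N))
        enzyme_strain = {"pnp": "pnp_del", "rnb": "rnb_del",
                         "rnr": "rnr_del"}[plan.enzyme]
        qf = config.fragment_intensity
        if strain == "rne_ts":
            inten = qf * N * eps          # the fragment is RNase E-generated
        elif strain == enzyme_strain:
            inten = qf * N                # not degraded without the enzyme
        else:
            inten = qf * N * eps          # fully degraded in WT
        if inten > 0:
            out.append((plan.f5_off, plan.f3_off, inten, inten))
    return [s for s in out if s[2] > 0]


def _nb_sample(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    return int(rng.poisson(lam))


def _plans_from_truth(truth: TruthTable) -> list[_OperonPlan]:
    plans = []
    for r in truth.operons.itertuples():
        plans.append(_OperonPlan(
            r.operon_id, r.strand, int(r.tss), int(r.length), [],
            r.tri, int(r.score), float(r.p), float(r.q), r.event, r.enzyme,
            c_off=None if pd.isna(r.c_off) else int(r.c_off),
            start_off=None if pd.isna(r.start_off) else int(r.start_off),
            stop_off=None if pd.isna(r.stop_off) else int(r.stop_off),
            dg=None if pd.isna(r.dg) else float(r.dg),
            p_stop=None if pd.isna(r.p_stop) else float(r.p_stop),
            f5_off=None if pd.isna(r.f5_off) else int(r.f5_off),
            f3_off=None if pd.isna(r.f3_off) else int(r.f3_off)))
    return plans


def simulate_libraries(genome: Mapping[str, str], truth: TruthTable,
                       config: SimConfig) -> dict[str, EndProfile]:
    """Draw end-count/coverage profiles for every library in the study design.

    The WT processed libraries mirror the experimental protocol: the
    processed fraction is extracted from the total library, so each processed
    replicate is a binomial thinning of its matching total replicate (shared
    sequencing-depth factor, processed probability = monophosphate fraction
    of each fragment cohort).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    length = len(genome[CONTIG])
    plans = _plans_from_truth(truth)
    wobble = np.asarray(config.wobble_weights)
    wobble = wobble / wobble.sum()
    half = len(wobble) // 2

    profiles: dict[str, EndProfile] = {}

    def sample_library(spec: LibrarySpec, size_factor: float,
                       paired_processed: EndProfile | None) -> EndProfile:
        prof = EndProfile({CONTIG: length}, spec=spec)
        for plan in plans:
            for f_off, t_off, inten, proc_inten in _species_for(
                    plan, spec.strain, config):
                p_frac = min(proc_inten / inten, 1.0) if inten > 0 else 0.0
                offsets = (zip(range(-half, half + 1), wobble)
                           if f_off == 0 else ((0, 1.0),))
                for w, wgt in offsets:
                    k = _nb_sample(rng, inten * wgt * size_factor,
                                   config.nb_dispersion)
                    if not k:
                        continue
                    _add_tx_span(prof, plan, f_off + w, t_off, k)
                    if paired_processed is not None and p_frac > 0:
                        kp = int(rng.binomial(k, p_frac))
                        if kp:
                            _add_tx_span(paired_processed, plan,
                                         f_off + w, t_off, kp)
        # stray background fragments
        n_bg = rng.poisson(config.background_per_kb * length / 1000.0)
        for _ in range(n_bg):
            s = int(rng.integers(0, length - 400))
            flen = int(rng.integers(100, 300))
            strand = "+" if rng.random() < 0.5 else "-"
            prof.add_span(CONTIG, strand, s, s + flen, 1)
        prof.spec = LibrarySpec(spec.strain, spec.fraction, spec.replicate,
                                prof.total_fragments())
        return prof

    for spec in config.library_specs():
        if spec.fraction == "processed":
            continue            # emitted together with the matched WT total
        size_factor = float(np.exp(rng.normal(0.0, config.size_factor_sigma)))
        paired = None
        if spec.strain == "WT" and spec.replicate <= config.wt_processed_reps:
            pspec = LibrarySpec("WT", "processed", spec.replicate)
            paired = EndProfile({CONTIG: length}, spec=pspec)
        prof = sample_library(spec, size_factor, paired)
        profiles[spec.name] = prof
        if paired is not None:
            paired.spec = LibrarySpec("WT", "processed", spec.replicate,
                                      paired.total_fragments())
            profiles[paired.spec.name] = paired
    return profiles


def _add_tx_span(prof: EndProfile, plan: _OperonPlan, f_off: int, t_off: int,
                 count: int) -> None:
    a, b = plan.g(f_off), plan.g(t_off)
    lo, hi = (a, b + 1) if plan.strand == "+" else (b, a + 1)
    prof.add_span(CONTIG, plan.strand, lo, hi, count)


def simulate_gene_counts(truth: TruthTable, annotation: GenomeAnnotation,
                         config: SimConfig, n_reps: int = 3,
                         nominal_fragment: int = 300) -> pd.DataFrame:
    """RNA-seq-like per-gene fragment counts for the WT FPKM table.

    Expected counts follow the simulated coverage (species intensity times
    gene overlap, scaled by a nominal fragment length), NB-sampled per
    replicate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    plans = {p.operon_id: p for p in _plans_from_truth(truth)}
    rows = {}
    for gid, gene in annotation.genes.items():
        plan = plans[gene.operon_id]
        if plan.strand == "+":
            a, b = gene.start - plan.tss, gene.end - 1 - plan.tss
        else:
            a, b = plan.tss - (gene.end - 1), plan.tss - gene.start
        expected = 0.0
        for f_off, t_off, inten, _ in _species_for(plan, "WT", config):
            ov = min(t_off, b) - max(f_off, a) + 1
            if ov > 0:
                expected += inten * ov / nominal_fragment
        rows[gid] = [
            _nb_sample(rng, expected, config.nb_dispersion) for _ in range(n_reps)]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"rep{i+1}" for i in range(n_reps)])


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(called: Mapping[str, Sequence[tuple[str, str, int]]],
                      truth: TruthTable,
                      tolerance: int = 2,
                      class_map: Mapping[str, tuple[str, str | None]] | None = None
                      ) -> pd.DataFrame:
    """Precision/recall of called sites against implanted truth per class.

    A call is correct when a truth site of the same class lies within
    ``tolerance`` nt on the same strand; a truth site is recalled when a call
    does.  ``called`` keys are truth ``site_class`` names unless ``class_map``
    maps a key to ``(site_class, enzyme-or-None)`` (e.g. ``"pnp_stop3" ->
    ("stop3", "pnp")``).  Classes absent from truth get NA precision/recall.
    """
    rows = []
    for cls, calls in called.items():
        site_class, enzyme = (class_map or {}).get(cls, (cls, None))
        truth_pos = truth.positions(site_class, enzyme)
        by_track: dict[tuple[str, str], np.ndarray] = {}
        for c, s, p in truth_pos:
            by_track.setdefault((c, s), []).append(p)
        by_track = {k: np.asarray(sorted(set(v))) for k, v in by_track.items()}

        def near(track, pos):
            arr = by_track.get(track)
            if arr is None or arr.size == 0:
                return False
            i = np.searchsorted(arr, pos)
            return any(0 <= j < arr.size and abs(int(arr[j]) - pos) <= tolerance
                       for j in (i - 1, i))

        n_true = sum(len(v) for v in by_track.values())
        if n_true == 0:
            rows.append({"site_class": cls, "n_truth": 0, "n_called": len(calls),
                         "tp": 0, "precision": np.nan, "recall": np.nan})
            continue
        tp_calls = sum(near((c, s), p) for c, s, p in calls)
        call_tracks: dict[tuple[str, str], np.ndarray] = {}
        for c, s, p in calls:
            call_tracks.setdefault((c, s), []).append(p)
        call_tracks = {k: np.asarray(sorted(v)) for k, v in call_tracks.items()}
        recalled = 0
        for (c, s), arr in by_track.items():
            cal = call_tracks.get((c, s))
            for pos in arr:
                if cal is not None and cal.size:
                    i = np.searchsorted(cal, pos)
                    if any(0 <= j < cal.size and abs(int(cal[j]) - pos) <= tolerance
                           for j in (i - 1, i)):
                        recalled += 1
        precision = tp_calls / len(calls) if len(calls) else np.nan
        rows.append({"site_class": cls, "n_truth": n_true,
                     "n_called": len(calls), "tp": tp_calls,
                     "precision": precision, "recall": recalled / n_true})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_simulation(out_dir: str | Path, genome: Mapping[str, str],
                     annotation: GenomeAnnotation, truth: TruthTable,
                     profiles: Mapping[str, EndProfile]) -> None:
    """Emit FASTA, GFF3, operon TSV, per-library bedGraphs and truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "genome.fa", "w") as fh:
        for contig, s in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")
    with open(out_dir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes.values(), key=lambda g: g.start):
            fh.write(f"{g.contig}\tsrps_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
    with open(out_dir / "operons.tsv", "w") as fh:
        fh.write("operon_id\tgene_id\ttss_pos\tstrand\n")
        for op in annotation.operons.values():
            for gid in op.gene_ids:
                fh.write(f"{op.operon_id}\t{gid}\t{op.tss_positions[0] + 1}\t"
                         f"{op.strand}\n")
    truth.to_files(out_dir)
    for name, prof in profiles.items():
        prof.to_bedgraph(out_dir / name)


def simulate(config: SimConfig, out_dir: str | Path | None = None
             ) -> tuple[dict[str, str], GenomeAnnotation, TruthTable,
                        dict[str, EndProfile]]:
    """One-call simulation: genome + annotation + truth + libraries."""
    genome, annotation, truth = generate_genome(config)
    profiles = simulate_libraries(genome, truth, config)
    if out_dir is not None:
        write_simulation(out_dir, genome, annotation, truth, profiles)
    return genome, annotation, truth, profiles
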