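"""Calling RppH processing positions from processed-fraction 5' end profiles.

RppH converts 5'-triphosphate (primary) transcript ends to 5'-monophosphate,
so its targets appear as sharp 5'-end pile-ups in the adapter-selected
processed libraries, at or within a few nt of a transcription start site
(transcription-initiation wobble spreads the signal over ~5 nt).  Processed
5' ends far from any TSS are monophosphate ends created by other enzymes
(chiefly RNase E) and are reported as ``other_processed``; the differential
caller later uses them to validate 5' RNase E ends.

Calling proceeds in three stages per library, then across libraries:

1. candidate positions: > ``candidate_min_reads`` read starts and a coverage
   step of >= 30% relative to the base immediately 5' of the position;
2. wobble resolution: +/-2 nt bins around candidates must hold enough read
   starts in aggregate and show the 30% step from the bin to the next base
   3' of it; each surviving bin is represented by its max-start position, and
   representatives closer than the cluster window are merged;
3. reproducibility: representatives seen (within 5 nt, same strand) in at
   least ``min_samples`` libraries are kept and classified by TSS distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_profiles import EndProfile, STRANDS

logger = logging.getLogger("srps")

DEFAULT_CANDIDATE_MIN_READS = 3     # "> 3 reads starting at this position"
DEFAULT_BIN_MIN_READS = 10          # read starts summed over the 5-nt bin
DEFAULT_COV_STEP = 1.3              # ">= 30% increase in read coverage"
DEFAULT_WOBBLE = 2                  # bin = position +/- 2 nt
DEFAULT_CLUSTER_WINDOW = 5
DEFAULT_MIN_SAMPLES = 2
DEFAULT_TSS_TOLERANCE = 5


@dataclass(frozen=True)
class CandidatePosition:
    contig: str
    strand: str
    pos: int
    reads_start: int
    cov_up: int
    cov_down: int


@dataclass(frozen=True)
class ProcessedSite:
    contig: str
    strand: str
    pos: int
    n_supporting_samples: int
    site_class: str                  # "rpph" | "other_processed"
    reads_start: int = 0
    nearest_tss: int | None = None
    tss_distance: int | None = None


def _upstep(strand: str) -> int:
    """Genomic offset of the base immediately 5' of a position."""
    return -1 if strand == "+" else 1


def find_candidate_positions(profile: EndProfile,
                             min_reads: int = DEFAULT_CANDIDATE_MIN_READS,
                             cov_step: float = DEFAULT_COV_STEP,
                             ) -> list[CandidatePosition]:
    """Positions with ``n5 > min_reads`` and a >=30% coverage step at the site."""
    out: list[CandidatePosition] = []
    for contig in profile.tracks:
        for strand in STRANDS:
            n5 = profile.n5(contig, strand)
            cov = profile.cov(contig, strand)
            up = np.empty_like(cov)
            if strand == "+":
                up[1:] = cov[:-1]
                up[0] = 0
            else:
                up[:-1] = cov[1:]
                up[-1] = 0
            mask = (n5 > min_reads) & (cov.astype(float) >= cov_step * up)
            for p in np.flatnonzero(mask):
                out.append(CandidatePosition(contig, strand, int(p),
                                             int(n5[p]), int(up[p]), int(cov[p])))
    return out


def resolve_wobble_bins(candidates: list[CandidatePosition],
                        profile: EndProfile,
                        wobble: int = DEFAULT_WOBBLE,
                        bin_min_reads: int = DEFAULT_BIN_MIN_READS,
                        cov_step: float = DEFAULT_COV_STEP,
                        cluster_window: int = DEFAULT_CLUSTER_WINDOW,
                        bin_cov_mode: str = "min",
                        ) -> list[CandidatePosition]:
    """Collapse transcription-initiation wobble to one representative per site.

    The 5-nt bin around each candidate must hold ``bin_min_reads`` read starts
    in total and the coverage at the single base immediately 3' of the bin
    must exceed ``cov_step`` times the bin's coverage (`bin_cov_mode` selects
    the bin summary: ``min`` -- coverage at the bin's upstream shoulder, which
    reflects pre-processing coverage even when the step falls inside the bin
    -- or ``mean``).  The representative is the position with the most read
    starts (ties break 5'-most); representatives within ``cluster_window`` nt
    are merged, keeping the larger read-start count.
    """
    if bin_cov_mode not in ("min", "mean"):
        raise ValueError(f"bin_cov_mode must be 'min' or 'mean', got {bin_cov_mode!r}")
    reps: list[CandidatePosition] = []
    for cand in candidates:
        n5 = profile.n5(cand.contig, cand.strand)
        cov = profile.cov(cand.contig, cand.strand)
        length = n5.size
        lo = max(0, cand.pos - wobble)
        hi = min(length, cand.pos + wobble + 1)
        bin_n5 = n5[lo:hi]
        if int(bin_n5.sum()) < bin_min_reads:
            continue
        down = cand.pos + wobble + 1 if cand.strand == "+" else cand.pos - wobble - 1
        if not (0 <= down < length):
            continue
        bin_cov = cov[lo:hi].astype(float)
        ref = bin_cov.min() if bin_cov_mode == "min" else bin_cov.mean()
        if float(cov[down]) < cov_step * ref:
            continue
        rel = np.flatnonzero(bin_n5 == bin_n5.max())
        if cand.strand == "+":
            rep = lo + int(rel[0])
        else:
            rep = lo + int(rel[-1])
        up = rep + _upstep(cand.strand)
        reps.append(CandidatePosition(cand.contig, cand.strand, rep,
                                      int(n5[rep]),
                                      int(cov[up]) if 0 <= up < length else 0,
                                      int(cov[rep])))
    return _merge_representatives(reps, cluster_window)


def _merge_representatives(reps: list[CandidatePosition],
                           window: int) -> list[CandidatePosition]:
    """Greedy merge of representatives within `window` nt (keep max reads,
    ties toward the 5'-most position)."""
    out: list[CandidatePosition] = []
    for (contig, strand) in sorted({(r.contig, r.strand) for r in reps}):
        group = sorted((r for r in reps if r.contig == contig and r.strand == strand),
                       key=lambda r: r.pos)
        kept: list[CandidatePosition] = []
        for r in group:
            if kept and r.pos - kept[-1].pos <= window:
                prev = kept[-1]
                if r.reads_start > prev.reads_start or (
                        r.reads_start == prev.reads_start and strand == "-"):
                    kept[-1] = r
            else:
                kept.append(r)
        out.extend(kept)
    return out


def call_rpph_sites(per_sample_representatives: dict[str, list[CandidatePosition]],
                    tss_set: list[tuple[str, str, int]],
                    min_samples: int = DEFAULT_MIN_SAMPLES,
                    tss_tolerance: int = DEFAULT_TSS_TOLERANCE,
                    merge_window: int = DEFAULT_CLUSTER_WINDOW,
                    ) -> list[ProcessedSite]:
    """Cross-sample reproducibility filter and TSS classification.

    Representatives within ``merge_window`` nt (same strand) across samples
    are grouped; groups supported by >= ``min_samples`` distinct samples are
    reported at the max-read-start position.  Sites within ``tss_tolerance``
    nt of a TSS on the same strand are class ``rpph``; all others,
    ``other_processed``.
    """
    if not tss_set:
        logger.warning("call_rpph_sites: empty TSS set; all sites will be "
                       "classed other_processed")
    tss_by_key: dict[tuple[str, str], np.ndarray] = {}
    for contig, strand, pos in tss_set:
        tss_by_key.setdefault((contig, strand), [])
    for contig, strand, pos in tss_set:
        tss_by_key[(contig, strand)].append(pos)  # type: ignore[union-attr]
    tss_by_key = {k: np.asarray(sorted(v)) for k, v in tss_by_key.items()}

    pooled: list[tuple[str, str, int, int, str]] = []
    for sample, reps in per_sample_representatives.items():
        for r in reps:
            pooled.append((r.contig, r.strand, r.pos, r.reads_start, sample))

    sites: list[ProcessedSite] = []
    for (contig, strand) in sorted({(c, s) for c, s, *_ in pooled}):
        entries = sorted((p for p in pooled if p[0] == contig and p[1] == strand),
                         key=lambda e: e[2])
        group: list[tuple[str, str, int, int, str]] = []
        for e in entries + [None]:  # type: ignore[list-item]
            if group and (e is None or e[2] - group[-1][2] > merge_window):
                samples = {g[4] for g in group}
                if len(samples) >= min_samples:
                    best = max(group, key=lambda g: (g[3], -g[2] if strand == "+" else g[2]))
                    pos = best[2]
                    nearest, dist = _nearest(tss_by_key.get((contig, strand)), pos)
                    cls = "rpph" if dist is not None and dist <= tss_tolerance \
                        else "other_processed"
                    sites.append(ProcessedSite(contig, strand, pos, len(samples),
                                               cls, reads_start=best[3],
                                               nearest_tss=nearest,
                                               tss_distance=dist))
                group = []
            if e is not None:
                group.append(e)
    return sites


def _nearest(sorted_positions: np.ndarray | None,
             pos: int) -> tuple[int | None, int | None]:
    if sorted_positions is None or sorted_positions.size == 0:
        return None, None
    i = int(np.searchsorted(sorted_positions, pos))
    best = None
    for j in (i - 1, i):
        if 0 <= j < sorted_positions.size:
            cand = int(sorted_positions[j])
            if best is None or abs(cand - pos) < abs(best - pos):
                best = cand
    assert best is not None
    return best, abs(best - pos)


def call_from_profiles(processed_profiles: dict[str, EndProfile],
                       tss_set: list[tuple[str, str, int]],
                       candidate_min_reads: int = DEFAULT_CANDIDATE_MIN_READS,
                       bin_min_reads: int = DEFAULT_BIN_MIN_READS,
                       min_samples: int = DEFAULT_MIN_SAMPLES,
                       tss_tolerance: int = DEFAULT_TSS_TOLERANCE,
                       ) -> list[ProcessedSite]:
    """Convenience wrapper running all three stages on processed libraries."""
    reps = {
        name: resolve_wobble_bins(
            find_candidate_positions(prof, min_reads=candidate_min_reads),
            prof, bin_min_reads=bin_min_reads)
        for name, prof in processed_profiles.items()
    }
    return call_rpph_sites(reps, tss_set, min_samples=min_samples,
                           tss_tolerance=tss_tolerance)
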