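"""Quantitative statistics of the SRPS model.

Four numbers summarize how sequence and structure steer processing:

* the processing ratio of an RppH site -- the fraction of transcript 5' ends
  in a +/-4 nt window that are 5'-monophosphate (processed / total library
  end counts), averaged over replicates;
* the trinucleotide score of a TSS -- an integer assigned to the first three
  transcribed nucleotides; the processing ratio is (nearly) linear in it;
* the end ratio of an exonuclease trimming stop -- the fraction of 3' ends
  in the stop-to-start interval that are concentrated in the 11 nt around
  the stop, a read-out of how reliably the upstream stem-loop halts the
  enzyme, hence negatively correlated with the stem-loop's folding dG;
* minimum-free-energy (MFE) profiles -- mean dG of 50-nt windows slid around
  a site class, which reveal stem-loops as a dip upstream of trimming stops.

Folding is delegated to the ViennaRNA nearest-neighbor engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_profiles import EndProfile

logger = logging.getLogger("srps")

#: Scores of the first three transcribed nucleotides (DNA alphabet).  The
#: eight validated entries; extend with a user table for other trinucleotides.
DEFAULT_SCORE_TABLE: Mapping[str, int] = MappingProxyType({
    "CCT": 3, "CAT": 7, "GAT": 8, "ACT": 10,
    "TAT": 10, "ATT": 13, "AAT": 14, "AGT": 14,
})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class UnscoredTrinucleotideError(KeyError):
    """Raised for a trinucleotide absent from the score table."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def transcript_sequence(genome: Mapping[str, str], contig: str, strand: str,
                        start: int, end: int) -> str:
    """Genomic [start, end) as transcribed RNA-sense DNA (reverse-complemented
    on the minus strand)."""
    seq = genome[contig][start:end]
    return revcomp(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# Folding
# ---------------------------------------------------------------------------

def fold_mfe(sequence: str) -> tuple[str, float]:
    """Minimum-free-energy structure and dG (kcal/mol) of an RNA sequence.

    Accepts RNA or DNA alphabet (T is read as U); anything else is an error.
    """
    import RNA

    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    structure, dg = RNA.fold(seq)
    return structure, float(dg)


@dataclass
class MfeProfile:
    """Mean 50-nt-window dG per offset around a site class."""

    offsets: np.ndarray          # -50..+50
    mean_dg: np.ndarray
    n_sites: int


def mfe_offset_profile(sites: Sequence[tuple[str, str, int]],
                       genome: Mapping[str, str],
                       window: int = 50,
                       flank: int = 50) -> MfeProfile:
    """Sliding-window MFE profile around a set of sites.

    For each offset o in -flank..+flank the 50-nt window whose 3' edge lies
    at ``site + o`` (transcript orientation) is folded; dG values are
    averaged across sites per offset.  Sites too close to a contig edge are
    skipped with a warning.
    """
    offsets = np.arange(-flank, flank + 1)
    sums = np.zeros(offsets.size)
    n_used = 0
    for contig, strand, pos in sites:
        length = len(genome[contig])
        # need window-1 bases 5' of the most upstream 3' edge and `flank` 3'
        if strand == "+":
            lo = pos - flank - (window - 1)
            hi = pos + flank + 1
        else:
            lo = pos - flank
            hi = pos + flank + window
        if lo < 0 or hi > length:
            logger.warning("mfe_offset_profile: site %s%s:%d too close to "
                           "contig edge; skipped", contig, strand, pos)
            continue
        for i, o in enumerate(offsets):
            if strand == "+":
                w_lo, w_hi = pos + o - (window - 1), pos + o + 1
            else:
                w_lo, w_hi = pos - o, pos - o + window
            seq = transcript_sequence(genome, contig, strand, w_lo, w_hi)
            sums[i] += fold_mfe(seq)[1]
        n_used += 1
    if n_used == 0:
        raise ValueError("all sites skipped (too close to contig edges)")
    return MfeProfile(offsets=offsets, mean_dg=sums / n_used, n_sites=n_used)


def upstream_mfe(site: tuple[str, str, int],
                 genome: Mapping[str, str],
                 flank: int = 100,
                 window: int = 50,
                 mode: str = "window") -> float:
    """Folding dG upstream of a trimming stop.

    ``mode="window"`` (default) folds the single 50-nt window immediately
    upstream of the site -- the window that holds the stem-loop blocking the
    exonuclease.  ``mode="sliding"`` averages all 50-nt windows inside the
    100-nt upstream flank (51 windows), which dilutes a site-adjacent
    stem-loop roughly 50-fold and is provided for profile-style summaries.
    """
    contig, strand, pos = site
    length = len(genome[contig])
    if strand == "+":
        lo, hi = pos - flank, pos
    else:
        lo, hi = pos + 1, pos + 1 + flank
    if lo < 0 or hi > length:
        raise ValueError(f"site {contig}{strand}:{pos}: fewer than {flank} nt upstream")
    seq = transcript_sequence(genome, contig, strand, lo, hi)   # 5'->3', len 100
    if mode == "window":
        return fold_mfe(seq[-window:])[1]
    if mode == "sliding":
        dgs = [fold_mfe(seq[s:s + window])[1] for s in range(flank - window + 1)]
        return float(np.mean(dgs))
    raise ValueError(f"mode must be 'window' or 'sliding', got {mode!r}")


# ---------------------------------------------------------------------------
# Processing ratio (RppH)
# ---------------------------------------------------------------------------

@dataclass
class ProcessingRatioRecord:
    contig: str
    strand: str
    pos: int
    per_replicate: tuple[float, ...]
    ratio: float                     # replicate mean, capped at 1


def processing_ratio(site: tuple[str, str, int],
                     processed_profiles: Mapping[str, EndProfile],
                     total_profiles: Mapping[str, EndProfile],
                     halfwidth: int = 4) -> ProcessingRatioRecord | None:
    """Processed / total 5'-end ratio over the +/-4 nt window around a site.

    Computed per replicate (processed and total libraries are matched by
    sorted order) and averaged; replicates with a zero total-window sum are
    skipped; ``None`` (with a warning) if no replicate is usable.
    """
    contig, strand, pos = site
    ratios = []
    for pname, tname in zip(sorted(processed_profiles), sorted(total_profiles)):
        proc, tot = processed_profiles[pname], total_profiles[tname]
        lo = max(0, pos - halfwidth)
        hi = pos + halfwidth + 1
        p_sum = float(proc.n5(contig, strand)[lo:hi].sum())
        t_sum = float(tot.n5(contig, strand)[lo:hi].sum())
        if t_sum == 0:
            continue
        ratios.append(min(p_sum / t_sum, 1.0))
    if not ratios:
        logger.warning("processing_ratio: zero total 5' ends around "
                       "%s%s:%d in every replicate; skipped", contig, strand, pos)
        return None
    return ProcessingRatioRecord(contig, strand, pos, tuple(ratios),
                                 float(np.mean(ratios)))


# ---------------------------------------------------------------------------
# TSS trinucleotide score
# ---------------------------------------------------------------------------

def tss_score(trinucleotide: str,
              table: Mapping[str, int] | None = None) -> int:
    """Score of the first three transcribed nucleotides (DNA alphabet)."""
    table = DEFAULT_SCORE_TABLE if table is None else table
    key = trinucleotide.upper().replace("U", "T")
    if key not in table:
        raise UnscoredTrinucleotideError(
            f"trinucleotide {trinucleotide!r} has no score; supply an extended table")
    return int(table[key])


def load_score_table(path) -> dict[str, int]:
    """Read a 2-column TSV (trinucleotide, score) as a score table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tri", "score"],
                     comment="#")
    table = {str(r.tri).upper(): int(r.score) for r in df.itertuples()}
    for k in table:
        if len(k) != 3 or set(k) - set("ACGT"):
            raise ValueError(f"bad trinucleotide key {k!r}")
    return table


def first_three_nucleotides(genome: Mapping[str, str], contig: str,
                            strand: str, tss: int) -> str:
    """First three transcribed bases at a TSS (strand-aware, DNA alphabet)."""
    if strand == "+":
        return genome[contig][tss:tss + 3]
    return revcomp(genome[contig][tss - 2:tss + 1])


def score_vs_ratio(records: Iterable[tuple[tuple[str, str, int], float]],
                   genome: Mapping[str, str],
                   table: Mapping[str, int] | None = None,
                   ) -> tuple[pd.DataFrame, float]:
    """Group RppH sites by their TSS trinucleotide and correlate score with
    mean processing ratio.

    ``records`` yields ((contig, strand, pos), processing_ratio).  Sites whose
    trinucleotide is absent from the score table are excluded.  Returns the
    grouped table (trinucleotide, score, n, mean_ratio) and the Pearson r of
    score vs group mean ratio.  Requires >= 3 scored groups with score and
    ratio variance.
    """
    table = DEFAULT_SCORE_TABLE if table is None else table
    rows = []
    for (contig, strand, pos), ratio in records:
        tri = first_three_nucleotides(genome, contig, strand, pos)
        if tri in table:
            rows.append((tri, int(table[tri]), ratio))
    if not rows:
        raise ValueError("no sites with a scored trinucleotide")
    df = pd.DataFrame(rows, columns=["tri", "score", "ratio"])
    grouped = (df.groupby(["tri", "score"], as_index=False)
                 .agg(n=("ratio", "size"), mean_ratio=("ratio", "mean"))
                 .sort_values("score", ignore_index=True))
    if len(grouped) < 3:
        raise ValueError(f"only {len(grouped)} scored trinucleotide groups; "
                         "need >= 3 for a meaningful correlation")
    if grouped.mean_ratio.nunique() == 1 or grouped.score.nunique() == 1:
        raise ValueError("zero variance in scores or group mean ratios; "
                         "correlation undefined")
    r = float(sps.pearsonr(grouped.score, grouped.mean_ratio).statistic)
    return grouped, r


# ---------------------------------------------------------------------------
# End ratio (exonuclease stops)
# ---------------------------------------------------------------------------

@dataclass
class EndRatioRecord:
    contig: str
    strand: str
    stop_pos: int
    start_pos: int
    end_ratio: float
    upstream_dg: float | None = None


def end_ratio(stop: tuple[str, str, int], start_pos: int,
              wt_profiles: Mapping[str, EndProfile],
              genome: Mapping[str, str] | None = None,
              halfwidth: int = 5) -> EndRatioRecord | None:
    """Fraction of stop-to-start 3' ends concentrated at the trimming stop.

    numerator: 3' ends over the 11 nt centered on the stop; denominator: 3'
    ends from 5 nt upstream of the stop to 5 nt downstream of the paired
    start (transcript orientation), pooled over the WT total libraries.
    Attaches the mean upstream dG when a genome is given.
    """
    contig, strand, pos = stop
    n3 = sum(p.n3(contig, strand).astype(np.int64) for p in wt_profiles.values())
    if strand == "+":
        num_lo, num_hi = pos - halfwidth, pos + halfwidth + 1
        den_lo, den_hi = pos - halfwidth, start_pos + halfwidth + 1
    else:
        num_lo, num_hi = pos - halfwidth, pos + halfwidth + 1
        den_lo, den_hi = start_pos - halfwidth, pos + halfwidth + 1
    num = float(n3[max(0, num_lo):num_hi].sum())
    den = float(n3[max(0, den_lo):den_hi].sum())
    if den == 0:
        logger.warning("end_ratio: zero denominator at %s%s:%d; skipped",
                       contig, strand, pos)
        return None
    d = abs(start_pos - pos)
    if d <= halfwidth:
        logger.warning("end_ratio: start inside the numerator window at "
                       "%s%s:%d (distance %d); degenerate geometry",
                       contig, strand, pos, d)
    ratio = min(num / den, 1.0)
    dg = upstream_mfe(stop, genome) if genome is not None else None
    return EndRatioRecord(contig, strand, pos, start_pos, ratio, dg)


def endratio_mfe_correlation(records: Sequence[EndRatioRecord]) -> float:
    """Pearson r between end ratio and upstream dG (signed; a stabilizing
    stem-loop -- more negative dG -- should give higher end ratios, r < 0)."""
    recs = [r for r in records if r.upstream_dg is not None]
    if len(recs) < 3:
        raise ValueError(f"need >= 3 records with upstream dG, got {len(recs)}")
    ratios = [r.end_ratio for r in recs]
    dgs = [r.upstream_dg for r in recs]
    return float(sps.pearsonr(dgs, ratios).statistic)


# ---------------------------------------------------------------------------
# Positional base frequencies
# ---------------------------------------------------------------------------

@dataclass
class BaseFrequencyMatrix:
    offsets: np.ndarray                 # -flank..+flank
    freqs: pd.DataFrame                 # index offsets, columns A/C/G/U
    n_sites: int

    def frequency(self, base: str, offset: int) -> float:
        return float(self.freqs.loc[offset, base.upper().replace("T", "U")])


def base_frequency_matrix(sites: Sequence[tuple[str, str, int]],
                          genome: Mapping[str, str],
                          flank: int = 10) -> BaseFrequencyMatrix:
    """Per-offset nucleotide frequencies around sites (RNA alphabet,
    transcript orientation; offset 0 is the site itself)."""
    offsets = np.arange(-flank, flank + 1)
    counts = pd.DataFrame(0.0, index=offsets, columns=list("ACGU"))
    n = 0
    for contig, strand, pos in sites:
        length = len(genome[contig])
        if pos - flank < 0 or pos + flank + 1 > length:
            logger.warning("base_frequency_matrix: site %s%s:%d lacks full "
                           "flanks; skipped", contig, strand, pos)
            continue
        seq = transcript_sequence(genome, contig, strand,
                                  pos - flank, pos + flank + 1)
        seq = seq.replace("T", "U")
        for o, base in zip(offsets, seq):
            if base in "ACGU":
                counts.loc[o, base] += 1
        n += 1
    if n == 0:
        raise ValueError("no sites with full flanks")
    freqs = counts.div(counts.sum(axis=1), axis=0)
    return BaseFrequencyMatrix(offsets=offsets, freqs=freqs, n_sites=n)
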