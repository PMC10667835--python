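"""Input/output layer: annotations, libraries, per-base end-count profiles.

SEnd-seq reports, for every sequenced cDNA fragment, the paired 5' and 3'
termini of one RNA molecule.  Everything downstream of alignment is driven by
three per-base, per-strand tracks for each library:

* ``n5[p]`` -- number of fragments whose 5' terminus is at position ``p``;
* ``n3[p]`` -- number of fragments whose 3' terminus is at position ``p``;
* ``cov[p]`` -- number of fragments whose span covers ``p``.

Coordinates are 0-based half-open internally; bedGraph output is 0-based,
GFF3 input and human-readable TSV reports are 1-based, following each
format's convention.  The 3' terminus of a plus-strand fragment ``[s, e)`` is
``e - 1`` (the last transcribed base); on the minus strand the roles of the
two ends are mirrored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("srps")

STRANDS = ("+", "-")

#: 5' adapter ligated to 5'-monophosphate (processed) RNA only.  Reads in the
#: total library carrying this prefix (plus 4 random bases) originate from
#: processed molecules.
PROCESSED_ADAPTER = "AAACTCTCCACGT"
ADAPTER_N_RANDOM = 4

#: SEnd-seq fragments longer than this are treated as artifacts.
MAX_FRAGMENT_LENGTH = 10_000


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    contig: str
    strand: str
    start: int          # 0-based inclusive
    end: int            # 0-based exclusive
    operon_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Operon:
    operon_id: str
    gene_ids: tuple[str, ...]
    contig: str
    strand: str
    tss_positions: tuple[int, ...]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class GenomeAnnotation:
    """Genes, operons (ordered gene lists) and TSSs with strand/coordinates."""

    genes: dict[str, Gene]
    operons: dict[str, Operon]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for op in self.operons.values():
            for gid in op.gene_ids:
                if gid not in self.genes:
                    raise ValueError(
                        f"operon {op.operon_id} references unknown gene {gid}")
                g = self.genes[gid]
                if g.strand != op.strand or g.contig != op.contig:
                    raise ValueError(
                        f"gene {gid} ({g.contig}{g.strand}) inconsistent with "
                        f"operon {op.operon_id} ({op.contig}{op.strand})")

    @property
    def tss_set(self) -> list[tuple[str, str, int]]:
        """All TSSs as (contig, strand, position)."""
        out = []
        for op in self.operons.values():
            for t in op.tss_positions:
                out.append((op.contig, op.strand, t))
        return out

    def operon_extent(self, operon_id: str) -> tuple[int, int]:
        """Genomic extent [TSS, 3' end of last gene), half-open, strand-aware."""
        op = self.operons[operon_id]
        genes = [self.genes[g] for g in op.gene_ids]
        if op.strand == "+":
            lo = min(op.tss_positions) if op.tss_positions else min(g.start for g in genes)
            hi = max(g.end for g in genes)
        else:
            lo = min(g.start for g in genes)
            hi = (max(op.tss_positions) + 1) if op.tss_positions else max(g.end for g in genes)
        return lo, hi


@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library: strain, fraction, replicate, library size."""

    strain: str                    # WT, rne_ts, pnp_del, rnb_del, rnr_del
    fraction: str                  # total | processed
    replicate: int = 1
    library_size: int = 0          # total uniquely mapped fragments

    VALID_STRAINS = ("WT", "rne_ts", "pnp_del", "rnb_del", "rnr_del")

    def __post_init__(self) -> None:
        if self.strain not in self.VALID_STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")
        if self.fraction not in ("total", "processed"):
            raise ValueError(f"unknown fraction {self.fraction!r}")
        if self.fraction == "processed" and self.strain != "WT":
            raise ValueError("processed fraction exists only for strain WT")

    @property
    def name(self) -> str:
        return f"{self.strain}_{self.fraction}_{self.replicate}"


@dataclass(frozen=True)
class Fragment:
    """A strand-resolved merged read pair: one RNA molecule's two termini."""

    contig: str
    strand: str
    start: int   # 0-based inclusive (genomic left)
    end: int     # exclusive (genomic right)

    def __post_init__(self) -> None:
        length = self.end - self.start
        if not (0 < length < MAX_FRAGMENT_LENGTH):
            raise ValueError(f"fragment length {length} outside (0, {MAX_FRAGMENT_LENGTH})")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


class EndProfile:
    """Per-strand n5/n3/coverage tracks for one library over one or more contigs."""

    def __init__(self, contig_lengths: Mapping[str, int],
                 spec: LibrarySpec | None = None,
                 dtype=np.int64) -> None:
        self.contig_lengths = dict(contig_lengths)
        self.spec = spec
        self.tracks: dict[str, dict[str, dict[str, np.ndarray]]] = {}
        for contig, length in self.contig_lengths.items():
            self.tracks[contig] = {
                s: {k: np.zeros(length, dtype=dtype) for k in ("n5", "n3", "cov")}
                for s in STRANDS
            }

    # -- accessors ---------------------------------------------------------
    def n5(self, contig: str, strand: str) -> np.ndarray:
        return self.tracks[contig][strand]["n5"]

    def n3(self, contig: str, strand: str) -> np.ndarray:
        return self.tracks[contig][strand]["n3"]

    def cov(self, contig: str, strand: str) -> np.ndarray:
        return self.tracks[contig][strand]["cov"]

    def total_fragments(self) -> int:
        return int(sum(self.n5(c, s).sum()
                       for c in self.tracks for s in STRANDS))

    # -- mutation ----------------------------------------------------------
    def add_fragment(self, frag: Fragment, count: int = 1) -> None:
        self.add_span(frag.contig, frag.strand, frag.start, frag.end, count)

    def add_span(self, contig: str, strand: str, start: int, end: int,
                 count: int = 1) -> None:
        """Register `count` identical fragments spanning [start, end)."""
        length = self.contig_lengths.get(contig)
        if length is None:
            raise ValueError(f"unknown contig {contig!r}")
        if start < 0 or end > length or end <= start:
            raise ValueError(
                f"fragment {contig}:{start}-{end} outside contig bounds (len {length})")
        t = self.tracks[contig][strand]
        if strand == "+":
            t["n5"][start] += count
            t["n3"][end - 1] += count
        else:
            t["n5"][end - 1] += count
            t["n3"][start] += count
        t["cov"][start:end] += count

    # -- I/O ---------------------------------------------------------------
    def to_bedgraph(self, out_prefix: str | Path) -> list[Path]:
        """Write one bedGraph per (track, strand): ``<prefix>.<track>.<fwd|rev>.bedgraph``."""
        out_prefix = Path(out_prefix)
        paths = []
        for track in ("n5", "n3", "cov"):
            for strand, tag in (("+", "fwd"), ("-", "rev")):
                path = out_prefix.parent / f"{out_prefix.name}.{track}.{tag}.bedgraph"
                with open(path, "w") as fh:
                    for contig in self.tracks:
                        arr = self.tracks[contig][strand][track]
                        for s, e, v in _runs(arr):
                            fh.write(f"{contig}\t{s}\t{e}\t{v}\n")
                paths.append(path)
        return paths

    @classmethod
    def from_bedgraph(cls, contig_lengths: Mapping[str, int],
                      prefix: str | Path,
                      spec: LibrarySpec | None = None) -> "EndProfile":
        prof = cls(contig_lengths, spec=spec)
        prefix = Path(prefix)
        for track in ("n5", "n3", "cov"):
            for strand, tag in (("+", "fwd"), ("-", "rev")):
                path = prefix.parent / f"{prefix.name}.{track}.{tag}.bedgraph"
                if not path.exists():
                    raise FileNotFoundError(path)
                df = pd.read_csv(path, sep="\t", header=None,
                                 names=["contig", "start", "end", "value"])
                for row in df.itertuples(index=False):
                    prof.tracks[row.contig][strand][track][row.start:row.end] = row.value
        if spec is not None and spec.library_size == 0:
            prof.spec = LibrarySpec(spec.strain, spec.fraction, spec.replicate,
                                    prof.total_fragments())
        return prof


def _runs(arr: np.ndarray) -> Iterator[tuple[int, int, int]]:
    """Yield (start, end, value) runs of non-zero values."""
    if arr.size == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    bounds = np.concatenate(([0], change, [arr.size]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        v = arr[s]
        if v != 0:
            yield int(s), int(e), int(v)


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def parse_annotation(gff3_path: str | Path,
                     operon_table_path: str | Path | None = None) -> GenomeAnnotation:
    """Read gene models (GFF3) and an operon/TSS table (TSV).

    The operon table has columns ``operon_id, gene_id, tss_pos, strand`` with
    one row per gene (TSS repeated per operon; 1-based positions).  Genes
    absent from the table become singleton operons whose TSS is the gene's
    own 5' end.
    """
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: dict[str, Gene] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes[gid] = Gene(gene_id=gid, contig=feat.seqid, strand=feat.strand,
                          start=feat.start - 1, end=feat.end)

    operons: dict[str, Operon] = {}
    assigned: set[str] = set()
    if operon_table_path is not None and Path(operon_table_path).exists():
        tbl = pd.read_csv(operon_table_path, sep="\t",
                          dtype={"operon_id": str, "gene_id": str})
        if len(tbl):
            required = {"operon_id", "gene_id", "tss_pos", "strand"}
            missing = required - set(tbl.columns)
            if missing:
                raise ValueError(f"operon table missing columns: {sorted(missing)}")
            for oid, grp in tbl.groupby("operon_id", sort=False):
                gids = tuple(grp["gene_id"])
                for gid in gids:
                    if gid not in genes:
                        raise ValueError(f"operon {oid} references unknown gene {gid}")
                contig = genes[gids[0]].contig
                strand = str(grp["strand"].iloc[0])
                tss = tuple(sorted({int(t) - 1 for t in grp["tss_pos"].dropna()}))
                order = sorted(gids, key=lambda g: genes[g].start,
                               reverse=(strand == "-"))
                operons[oid] = Operon(oid, tuple(order), contig, strand, tss)
                assigned.update(gids)

    for gid, g in genes.items():
        if gid not in assigned:
            tss = g.start if g.strand == "+" else g.end - 1
            operons[f"op_{gid}"] = Operon(f"op_{gid}", (gid,), g.contig,
                                          g.strand, (tss,))
    genes = {gid: Gene(g.gene_id, g.contig, g.strand, g.start, g.end,
                       operon_id=next(o.operon_id for o in operons.values()
                                      if gid in o.gene_ids))
             for gid, g in genes.items()}
    return GenomeAnnotation(genes=genes, operons=operons)


def load_genome(fasta_path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into a {contig: sequence} dict (upper-case DNA)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}


# ---------------------------------------------------------------------------
# Read partitioning (processed vs total)
# ---------------------------------------------------------------------------

def partition_processed_reads(
    reads: Iterable[tuple[str, str]],
    adapter: str = PROCESSED_ADAPTER,
    n_random: int = ADAPTER_N_RANDOM,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], int]:
    """Split raw reads into the processed fraction and the remainder.

    ``reads`` yields ``(read_id, sequence)``.  A read whose sequence starts
    with the exact adapter followed by at least ``n_random`` bases goes to the
    processed stream with adapter and random bases removed; everything else
    passes through unchanged.  Adapter-bearing reads too short to retain any
    insert are dropped (their count is returned and logged).
    """
    prefix_len = len(adapter) + n_random
    processed: list[tuple[str, str]] = []
    remainder: list[tuple[str, str]] = []
    dropped = 0
    for rid, seq in reads:
        if seq.startswith(adapter):
            if len(seq) <= prefix_len:
                dropped += 1
                continue
            processed.append((rid, seq[prefix_len:]))
        else:
            remainder.append((rid, seq))
    if dropped:
        logger.warning("partition_processed_reads: dropped %d adapter reads "
                       "shorter than %d nt", dropped, prefix_len + 1)
    return processed, remainder, dropped


def partition_fastq(fastq_path: str | Path,
                    processed_out: str | Path,
                    remainder_out: str | Path,
                    adapter: str = PROCESSED_ADAPTER,
                    n_random: int = ADAPTER_N_RANDOM) -> tuple[int, int, int]:
    """File-level wrapper around :func:`partition_processed_reads`."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    prefix_len = len(adapter) + n_random
    n_proc = n_rem = n_drop = 0
    with open(processed_out, "w") as fproc, open(remainder_out, "w") as frem:
        for rec in SeqIO.parse(str(fastq_path), "fastq"):
            seq = str(rec.seq)
            if seq.startswith(adapter):
                if len(seq) <= prefix_len:
                    n_drop += 1
                    continue
                sub = rec[prefix_len:]
                SeqIO.write(sub, fproc, "fastq")
                n_proc += 1
            else:
                SeqIO.write(rec, frem, "fastq")
                n_rem += 1
    if n_drop:
        logger.warning("partition_fastq: dropped %d short adapter reads", n_drop)
    return n_proc, n_rem, n_drop


# ---------------------------------------------------------------------------
# Alignment filtering
# ---------------------------------------------------------------------------

def filter_fragment_pairs(alignment_path: str | Path,
                          min_mapq: int = 30,
                          max_length: int = MAX_FRAGMENT_LENGTH) -> tuple[list[Fragment], dict]:
    """Extract strand-resolved fragments from paired alignments (SAM/BAM).

    Kept pairs must have both mates mapped and uniquely mapped (primary
    alignment, MAPQ >= ``min_mapq``, no secondary/supplementary flags), mates
    on the same strand (the SEnd-seq circularization chemistry places both
    reads of a pair on the transcribed strand) and a fragment length below
    ``max_length``.  Returns the fragments plus a counter dict of discards.
    """
    import pysam

    stats = {"kept": 0, "unpaired": 0, "not_unique": 0, "wrong_strand": 0,
             "too_long": 0}
    frags: list[Fragment] = []
    pending: dict[str, "pysam.AlignedSegment"] = {}
    with pysam.AlignmentFile(str(alignment_path)) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if not aln.is_paired:
                stats["unpaired"] += 1
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            pair = (mate, aln)
            if any(a.mapping_quality < min_mapq for a in pair):
                stats["not_unique"] += 1
                continue
            if pair[0].is_reverse != pair[1].is_reverse:
                stats["wrong_strand"] += 1
                continue
            if pair[0].reference_id != pair[1].reference_id:
                stats["wrong_strand"] += 1
                continue
            start = min(a.reference_start for a in pair)
            end = max(a.reference_end for a in pair)
            if not (0 < end - start < max_length):
                stats["too_long"] += 1
                continue
            strand = "-" if pair[0].is_reverse else "+"
            frags.append(Fragment(pair[0].reference_name, strand, start, end))
            stats["kept"] += 1
    stats["unpaired"] += len(pending)
    if pending:
        logger.warning("filter_fragment_pairs: %d reads had no mate", len(pending))
    return frags, stats


def build_end_profile(fragments: Iterable[Fragment],
                      contig_lengths: Mapping[str, int],
                      spec: LibrarySpec | None = None) -> EndProfile:
    """Accumulate fragments into per-base end-count and coverage tracks."""
    prof = EndProfile(contig_lengths, spec=spec)
    n = 0
    for frag in fragments:
        prof.add_fragment(frag)
        n += 1
    if spec is not None:
        prof.spec = LibrarySpec(spec.strain, spec.fraction, spec.replicate, n)
    return prof


# ---------------------------------------------------------------------------
# Gene-level FPKM
# ---------------------------------------------------------------------------

def fpkm_table(counts: pd.DataFrame | Mapping[str, Sequence[float]],
               totals: Sequence[float],
               gene_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Per-gene FPKM, averaged across replicate libraries.

    FPKM_g = counts_g * 1e9 / (total * length_g), one column per library;
    the ``fpkm`` column is the replicate mean.
    """
    counts = pd.DataFrame(counts)
    totals = np.asarray(totals, dtype=float)
    if counts.shape[1] != totals.size:
        raise ValueError("one total per count column required")
    if (totals <= 0).any():
        raise ValueError("library totals must be > 0")
    lengths = pd.Series({g: gene_lengths[g] for g in counts.index}, dtype=float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"gene {bad} has non-positive length")
    if (counts.values < 0).any():
        raise ValueError("counts must be >= 0")
    per_rep = counts * 1e9 / (totals[np.newaxis, :] * lengths.values[:, np.newaxis])
    out = pd.DataFrame({
        "length": lengths.astype(int),
    }, index=counts.index)
    for i, col in enumerate(counts.columns):
        out[f"counts_{col}"] = counts[col]
        out[f"fpkm_{col}"] = per_rep.iloc[:, i]
    out["fpkm"] = per_rep.mean(axis=1)
    out.index.name = "gene_id"
    return out


def count_fragments_per_gene(fragments: Iterable[Fragment],
                             annotation: GenomeAnnotation) -> pd.Series:
    """Count fragments overlapping each gene (same strand, any overlap)."""
    counts = {gid: 0 for gid in annotation.genes}
    by_key: dict[tuple[str, str], list[Gene]] = {}
    for g in annotation.genes.values():
        by_key.setdefault((g.contig, g.strand), []).append(g)
    for frag in fragments:
        for g in by_key.get((frag.contig, frag.strand), ()):
            if frag.start < g.end and frag.end > g.start:
                counts[g.gene_id] += 1
    return pd.Series(counts, name="counts")
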