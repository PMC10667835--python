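import numpy as np
import pytest

import srps


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset shared by unit tests."""
    cfg = srps.SimConfig(seed=11, n_operons=30)
    genome, annotation, truth, profiles = srps.simulate(cfg)
    return cfg, genome, annotation, truth, profiles


@pytest.fixture
def simple_profile():
    """An EndProfile on a 200-nt contig, built from explicit spans."""
    def build(spans, contig_len=200, strand="+"):
        prof = srps.EndProfile({"chr": contig_len})
        for start, end, count in spans:
            prof.add_span("chr", strand, start, end, count)
        return prof
    return build


def write_gff3(path, genes):
    """genes: (gene_id, contig, strand, start0, end0)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, contig, strand, start, end in genes:
            fh.write(f"{contig}\tsrc\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                     f"ID={gid}\n")


def write_operon_table(path, rows):
    """rows: (operon_id, gene_id, tss_pos1, strand) with 1-based TSS."""
    with open(path, "w") as fh:
        fh.write("operon_id\tgene_id\ttss_pos\tstrand\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
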