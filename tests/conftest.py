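import numpy as np
import pandas as pd
import pytest

from nagnag.catalog import AcceptorSite, GenomeSequence

# the PTBP2-style acceptor: intron ends ...TTGTTTCAG, exon starts AAGATTGCACCACC...
PTBP2_INTRON = "CAGTGTCTAATTTTATAATTTTGTTTCAG"
PTBP2_EXON = "AAGATTGCACCACCCGAAACACCTGACTCCAAAGTTCGTATGGTTC"
UPSTREAM_EXON = "GATTACAGATTACAGATTACAGATTACA"  # 28 nt


def make_locus(intron: str, exon: str, upstream: str = UPSTREAM_EXON):
    """A single-acceptor locus on one contig, plus its AcceptorSite."""
    seq = upstream + intron + exon
    genome = GenomeSequence({"chr1": seq})
    site = AcceptorSite(
        gene_id="g1", contig="chr1", strand="+",
        intron_start=len(upstream), intron_end=len(upstream) + len(intron),
        exon_start=len(upstream) + len(intron),
        exon_end=len(upstream) + len(intron) + len(exon),
        upstream_exon_len=len(upstream),
    )
    return genome, site


@pytest.fixture
def ptbp2_locus():
    return make_locus(PTBP2_INTRON, PTBP2_EXON)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def counts_frame(rows):
    """rows: (site_id, sample_id, n_prox, n_dist)."""
    return pd.DataFrame(rows, columns=["site_id", "sample_id",
                                       "n_prox", "n_dist"])
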