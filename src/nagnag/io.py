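"""Readers and writers for the standard formats the pipeline consumes.

Genomes arrive as FASTA, annotations as GFF3/GTF, junction read counts as
TSV, conservation as bedGraph.  Everything is parsed with established
libraries (Bio.SeqIO, gffutils, pandas); this module only adapts their
output to the pipeline's in-memory types.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("nagnag")

COUNTS_COLUMNS = ["site_id", "sample_id", "n_prox", "n_dist"]


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case contig sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_paired_fasta(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a paired FASTA of orthologous records.

    Record ids follow ``<pair_id>::<species>``; returns
    ``{pair_id: {species: sequence}}``.
    """
    pairs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pair_id, _, species = rec.id.partition("::")
        pairs.setdefault(pair_id, {})[species] = str(rec.seq).upper()
    return pairs


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a junction read-count table (site_id, sample_id, n_prox, n_dist)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph track into (contig, start, end, score) rows."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["contig", "start", "end", "score"],
        dtype={"contig": str, "start": int, "end": int, "score": float},
    )
    return df


def acceptors_from_gff(path: str | Path, genome: dict[str, str] | None = None):
    """Extract 3' splice-site acceptors from a GFF3/GTF annotation.

    Consecutive exons of each transcript define introns; each intron's
    downstream exon start is an acceptor.  GFF coordinates are 1-based
    closed and are converted to 0-based half-open here.  CDS phase, when
    annotated on the exon-matching CDS feature, is converted to intron
    phase (bases of the interrupted codon carried by the upstream exon).

    Returns a list of :class:`nagnag.catalog.AcceptorSite`.
    """
    from .catalog import AcceptorSite

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True,
    )
    cds_phase: dict[tuple[str, int, str], int] = {}
    for cds in db.features_of_type("CDS"):
        if cds.frame in ("0", "1", "2"):
            cds_phase[(cds.seqid, cds.start - 1, cds.strand)] = int(cds.frame)

    acceptors: list[AcceptorSite] = []
    parent_types = ("mRNA", "transcript")
    transcripts = [t for pt in parent_types for t in db.features_of_type(pt)]
    for tx in transcripts:
        exons = sorted(db.children(tx, featuretype="exon"), key=lambda e: e.start)
        gene = tx.attributes.get("gene_id", tx.attributes.get("Parent", [tx.id]))[0]
        for up, down in zip(exons, exons[1:]):
            # intron between consecutive exons, 0-based half-open
            intron = (up.end, down.start - 1)
            if tx.strand == "+":
                exon_iv = (down.start - 1, down.end)
                gff_phase = cds_phase.get((tx.seqid, down.start - 1, "+"))
            else:
                exon_iv = (up.start - 1, up.end)
                gff_phase = cds_phase.get((tx.seqid, up.start - 1, "-"))
            phase = None if gff_phase is None else (3 - gff_phase) % 3
            acceptors.append(
                AcceptorSite(
                    gene_id=gene, contig=tx.seqid, strand=tx.strand,
                    intron_start=intron[0], intron_end=intron[1],
                    exon_start=exon_iv[0], exon_end=exon_iv[1],
                    phase=phase,
                )
            )
    if not acceptors:
        logger.warning("annotation %s yielded no acceptor sites", path)
    return acceptors
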