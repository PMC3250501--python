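"""Enumeration of NAGNAG tandem 3' splice sites.

A NAGNAG acceptor carries two AG dinucleotides 3 nt apart; splicing at the
intron-proximal AG retains one extra codon (the second NAG) in the mRNA.
This module scans annotated acceptors for the NAGNAG motif, builds the two
junction sequences each site can produce, and removes sites whose junctions
are not uniquely mappable.

Coordinates are 0-based half-open throughout.  Splice-site-relative
numbering follows the convention: last intron base = -1, first exon base =
+1, the junction itself = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq

logger = logging.getLogger("nagnag")

_ALPHABET = set("ACGTN")
_MOTIF_BASES = set("ACGT")


class CoordinateError(ValueError):
    """Interval outside contig bounds."""


class InvalidAcceptorError(ValueError):
    """Annotated intron does not end in AG on the transcribed strand."""


class TruncatedFlankError(ValueError):
    """Flanking sequence shorter than the requested junction arm."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class GenomeSequence:
    """Contig sequences with strand-aware interval extraction.

    Lookups use 0-based half-open genomic intervals; a '-' strand fetch
    returns the reverse complement (i.e., the transcribed sequence).
    """

    def __init__(self, contigs: dict[str, str]):
        self.contigs = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            if set(seq) - _ALPHABET:
                bad = sorted(set(seq) - _ALPHABET)
                raise ValueError(f"contig {name}: alphabet outside ACGTN: {bad}")
            self.contigs[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        if contig not in self.contigs:
            raise CoordinateError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise CoordinateError(
                f"{contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub


@dataclass(frozen=True)
class AcceptorSite:
    """One annotated 3' splice site: the intron it terminates and its exon."""

    gene_id: str
    contig: str
    strand: str
    intron_start: int
    intron_end: int
    exon_start: int
    exon_end: int
    constitutive: bool = True
    phase: int | None = None
    upstream_exon_len: int | None = None

    def junction(self) -> int:
        """Genomic coordinate of the junction (first exonic base boundary).

        On '+' this is the exon start; on '-' the exon end (exclusive), so
        that transcribed position +1 is the base just inside the exon.
        """
        return self.exon_start if self.strand == "+" else self.exon_end

    def transcribed(self, genome: GenomeSequence, rel_start: int, rel_end: int) -> str:
        """Sequence between splice-site-relative offsets [rel_start, rel_end).

        Offsets count transcribed bases from the junction (0 = junction,
        negative = intronic, positive = exonic); ``rel_start=-3, rel_end=0``
        returns the last three intron bases.
        """
        j = self.junction()
        if self.strand == "+":
            return genome.fetch(self.contig, j + rel_start, j + rel_end, "+")
        return genome.fetch(self.contig, j - rel_end, j - rel_start, "-")


@dataclass(frozen=True)
class NagnagSite:
    """A tandem acceptor: two competing AGs exactly 3 nt apart."""

    site_id: str
    acceptor: AcceptorSite
    proximal_junction: int   # genomic junction coordinate of the proximal AG
    distal_junction: int     # genomic junction coordinate of the distal AG
    motif: str               # 6-mer NAGNAG on the transcribed strand
    annotated_role: str      # 'proximal' or 'distal': role of the annotated AG
    phase: int | None = None
    constitutive: bool = True

    def __post_init__(self):
        if not _is_nagnag(self.motif):
            raise ValueError(f"motif {self.motif!r} is not NAGNAG")

    @property
    def contig(self) -> str:
        return self.acceptor.contig

    @property
    def strand(self) -> str:
        return self.acceptor.strand

    @property
    def minus3_pair(self) -> tuple[str, str]:
        """Bases at -3 of the proximal and distal splice sites (the two Ns)."""
        return self.motif[0], self.motif[3]

    def upstream_intron(self, genome: GenomeSequence, length: int) -> str:
        """Transcribed intronic sequence ending at the proximal junction."""
        j = self.proximal_junction
        if self.strand == "+":
            return genome.fetch(self.contig, j - length, j, "+")
        return genome.fetch(self.contig, j, j + length, "-")


@dataclass(frozen=True)
class JunctionPair:
    """The two junction sequences a NAGNAG site can produce.

    Both are length 2L with the junction at position L; they share their
    first L characters (the upstream exon) and differ by the 3-nt NAG the
    proximal isoform retains.
    """

    site_id: str
    proximal: str
    distal: str
    flank: int
    unique: bool = True

    def __post_init__(self):
        L = self.flank
        if len(self.proximal) != 2 * L or len(self.distal) != 2 * L:
            raise ValueError("junction sequences must have length 2L")
        if self.proximal[:L] != self.distal[:L]:
            raise ValueError("junction sequences must share the upstream arm")


def _is_nagnag(motif: str) -> bool:
    return (
        len(motif) == 6
        and set(motif) <= _MOTIF_BASES
        and motif[1:3] == "AG"
        and motif[4:6] == "AG"
    )


def scan_acceptor_for_nagnag(
    genome: GenomeSequence, site: AcceptorSite, index: int = 0
) -> NagnagSite | None:
    """Search one annotated acceptor for a NAGNAG tandem motif.

    Two placements are tried: (a) a second NAG 3 nt upstream of the
    annotated AG, both intronic (the annotated site is then the distal AG);
    (b) the first three exonic bases form a NAG (the annotated site is the
    proximal AG).  Ns anywhere in the candidate 6-mer reject the placement.
    Returns None when neither placement matches.
    """
    terminal = site.transcribed(genome, -2, 0)
    if terminal != "AG":
        raise InvalidAcceptorError(
            f"intron of {site.gene_id} ends in {terminal!r}, not AG"
        )
    j = site.junction()
    sign = 1 if site.strand == "+" else -1

    # (a) annotated AG is distal: NAGNAG entirely within the intron
    motif_a = site.transcribed(genome, -6, 0)
    if _is_nagnag(motif_a):
        return NagnagSite(
            site_id=f"site{index}",
            acceptor=site,
            proximal_junction=j - 3 * sign,
            distal_junction=j,
            motif=motif_a,
            annotated_role="distal",
            phase=site.phase,
            constitutive=site.constitutive,
        )
    # (b) annotated AG is proximal: distal NAG = first three exonic bases
    motif_b = site.transcribed(genome, -3, 3)
    if _is_nagnag(motif_b):
        return NagnagSite(
            site_id=f"site{index}",
            acceptor=site,
            proximal_junction=j,
            distal_junction=j + 3 * sign,
            motif=motif_b,
            annotated_role="proximal",
            phase=site.phase,
            constitutive=site.constitutive,
        )
    return None


def enumerate_nagnags(
    genome: GenomeSequence, acceptors: Sequence[AcceptorSite]
) -> list[NagnagSite]:
    """Enumerate all distinct NAGNAG sites reachable from annotated acceptors.

    Sites reachable from several transcripts collapse to one record (keyed
    by contig, strand and the two junction coordinates); output order is
    deterministic (contig, proximal coordinate).
    """
    if not acceptors:
        logger.warning("empty annotation: no acceptors to scan")
        return []
    found: dict[tuple, NagnagSite] = {}
    for site in acceptors:
        hit = scan_acceptor_for_nagnag(genome, site)
        if hit is None:
            continue
        key = (hit.contig, hit.strand, hit.proximal_junction, hit.distal_junction)
        # a site seen as constitutive from one transcript and alternative
        # from another is kept with the non-constitutive label
        if key in found and not hit.constitutive:
            found[key] = replace(found[key], constitutive=False)
        found.setdefault(key, hit)
    ordered = sorted(found.values(), key=lambda s: (s.contig, s.proximal_junction))
    return [replace(s, site_id=f"site{i}") for i, s in enumerate(ordered)]


def build_junction_sequences(
    site: NagnagSite, genome: GenomeSequence, L: int
) -> JunctionPair:
    """Build the proximal and distal junction sequences with L-nt arms.

    The upstream arm is the last L nt of the upstream exon; the downstream
    arm is the first L nt of the mRNA produced by each splice choice.  The
    proximal mRNA begins with the downstream NAG; the distal mRNA begins
    right after the distal AG.
    """
    acc = site.acceptor
    if acc.upstream_exon_len is not None and acc.upstream_exon_len < L:
        raise TruncatedFlankError(
            f"{site.site_id}: upstream exon ({acc.upstream_exon_len} nt) < L={L}"
        )
    jp, jd = site.proximal_junction, site.distal_junction
    # transcribed distance from the proximal junction back to the upstream
    # exon boundary (the intron start); 3 nt shorter than the annotated
    # intron when the annotated AG is the distal one
    if site.strand == "+":
        prox_intron_len = jp - acc.intron_start
    else:
        prox_intron_len = acc.intron_end - jp

    def fetch_rel(junction: int, rel_start: int, rel_end: int) -> str:
        if site.strand == "+":
            return genome.fetch(site.contig, junction + rel_start, junction + rel_end)
        return genome.fetch(site.contig, junction - rel_end, junction - rel_start, "-")

    try:
        # the upstream exon ends where the intron starts; walk back across
        # the intron from the proximal junction
        upstream = fetch_rel(jp, -prox_intron_len - L, -prox_intron_len)
        prox_down = fetch_rel(jp, 0, L)
        dist_down = fetch_rel(jd, 0, L)
    except CoordinateError as err:
        raise TruncatedFlankError(f"{site.site_id}: {err}") from err
    return JunctionPair(
        site_id=site.site_id,
        proximal=upstream + prox_down,
        distal=upstream + dist_down,
        flank=L,
    )


def _genome_kmers(genome: GenomeSequence, k: int) -> set[str]:
    kmers: set[str] = set()
    for seq in genome.contigs.values():
        for s in (seq, revcomp(seq)):
            kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
    return kmers


def uniqueness_filter(
    pairs: Iterable[JunctionPair],
    genome: GenomeSequence,
    k: int = 36,
    min_overhang: int = 6,
) -> list[JunctionPair]:
    """Drop sites whose junction k-mers are not uniquely mappable.

    A site is retained only if (a) none of its junction-spanning k-mers
    (windows crossing the junction with at least ``min_overhang`` bases on
    each side — the windows a counted junction read can produce) occurs in
    the genome on either strand, and (b) none of its junction k-mers, at
    any offset, is shared with another site's junctions.  Exact k-mer set
    membership; result is independent of input order.
    """
    pairs = list(pairs)
    for p in pairs:
        if k > 2 * p.flank:
            raise ValueError(f"k={k} exceeds junction length 2L={2 * p.flank}")

    def windows(seq: str) -> list[str]:
        return [seq[i : i + k] for i in range(len(seq) - k + 1)]

    def spanning(seq: str, L: int) -> list[str]:
        lo = max(0, L - k + min_overhang)
        hi = min(len(seq) - k, L - min_overhang)
        return [seq[i : i + k] for i in range(lo, hi + 1)]

    genome_set = _genome_kmers(genome, k)
    owners: dict[str, set[str]] = {}
    for p in pairs:
        for seq in (p.proximal, p.distal):
            for w in windows(seq):
                owners.setdefault(w, set()).add(p.site_id)

    kept = []
    for p in pairs:
        span = {w for seq in (p.proximal, p.distal) for w in spanning(seq, p.flank)}
        alls = {w for seq in (p.proximal, p.distal) for w in windows(seq)}
        if span & genome_set:
            continue
        if any(owners[w] - {p.site_id} for w in alls):
            continue
        kept.append(replace(p, unique=True))
    return kept


def catalog_to_frame(sites: Sequence[NagnagSite], unique_ids: set[str] | None = None):
    """Tabulate a catalog as the TSV-ready DataFrame the CLI writes."""
    import pandas as pd

    rows = []
    for s in sites:
        n3p, n3d = s.minus3_pair
        rows.append(
            dict(
                site_id=s.site_id, contig=s.contig, strand=s.strand,
                proximal_junction=s.proximal_junction,
                distal_junction=s.distal_junction,
                motif=s.motif, minus3_prox=n3p, minus3_dist=n3d,
                phase="" if s.phase is None else s.phase,
                annotated_role=s.annotated_role,
                constitutive=s.constitutive,
                unique=True if unique_ids is None else s.site_id in unique_ids,
            )
        )
    return pd.DataFrame(rows)
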