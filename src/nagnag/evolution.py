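"""Orthologous exon alignment and gap-position analysis at splice sites.

The aligned unit is an annotation-bounded mRNA fragment per species: the
tail of the upstream exon followed by the exon under study, so the 3'
splice site (acceptor) is internal to the alignment.  A three-base shift of
the acceptor in one lineage therefore appears as an internal 3-nt gap at
the junction.  Gap positions are numbered relative to the nearest splice
site: the junction = 0; exonic positions downstream of the 3'ss are +1,
+2, ...; positions in the upstream exon (the 5'ss side) are negative.
Which splice site a junction-abutting gap belongs to is decided by the
annotation of the row that carries the inserted bases: inserted bases that
are exonic in their own species sit at the 3'ss, inserted bases belonging
to the upstream exon sit at the 5'ss.

Downstream analyses: positional gap enrichment with a permutation test,
boundary-change classification against outgroups, residual splice-site
motifs, the NAGNAG association test, and the amino-acid gain/loss spectrum
by intron phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from scipy import stats

from .features import positional_info_content

logger = logging.getLogger("nagnag")

GAP = "-"
DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP_OPEN = -4.0
DEFAULT_GAP_EXTEND = -1.0
DEFAULT_SPAN = 30


@dataclass
class ExonPairAlignment:
    """Global alignment of two orthologous records.

    ``exon_start`` maps each row name to the ungapped offset of the exon's
    first base in that species' record (the junction); ``exon_len`` to its
    exon length.
    """

    names: tuple[str, str]
    rows: tuple[str, str]
    exon_start: dict[str, int]
    exon_len: dict[str, int]
    score: float = 0.0

    def __post_init__(self):
        a, b = self.rows
        if len(a) != len(b):
            raise ValueError("aligned rows differ in length")

    def ungapped(self, idx: int) -> str:
        return self.rows[idx].replace(GAP, "")

    @property
    def n_matches(self) -> int:
        return sum(x == y and x != GAP for x, y in zip(*self.rows))

    @property
    def identity(self) -> float:
        """Percent identity over aligned residue pairs (gap columns
        excluded)."""
        pairs = sum(x != GAP and y != GAP for x, y in zip(*self.rows))
        if pairs == 0:
            return 0.0
        return 100.0 * self.n_matches / pairs

    @property
    def total_inserted(self) -> int:
        return sum(r.count(GAP) for r in self.rows)

    def column_of(self, row_idx: int, offset: int) -> int:
        """Alignment column holding ungapped ``offset`` of row ``row_idx``
        (for offset == sequence length: one past the last residue)."""
        seen = 0
        for col, ch in enumerate(self.rows[row_idx]):
            if ch != GAP:
                if seen == offset:
                    return col
                seen += 1
        if seen == offset:
            return len(self.rows[row_idx])
        raise IndexError(f"offset {offset} beyond row {row_idx}")

    def junction_col(self, row_idx: int) -> int:
        return self.column_of(row_idx, self.exon_start[self.names[row_idx]])


def _aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_exon_pair(
    seq_a: str,
    seq_b: str,
    names: tuple[str, str] = ("a", "b"),
    exon_start: dict[str, int] | None = None,
    exon_len: dict[str, int] | None = None,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ExonPairAlignment:
    """Global affine-gap alignment of two orthologous records.

    Defaults: match +1, mismatch -1, gap of length k costs -(4 + k).
    The first optimal alignment in the aligner's deterministic enumeration
    order is returned.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return ExonPairAlignment(
        names=names,
        rows=(str(aln[0]), str(aln[1])),
        exon_start=dict(exon_start or {}),
        exon_len=dict(exon_len or {}),
        score=float(aln.score),
    )


def qc_alignment(
    aln: ExonPairAlignment,
    min_identity: float = 70.0,
    max_insert_fraction: float = 0.20,
) -> bool:
    """Alignment quality filter.

    Fails when identity <= ``min_identity`` percent or when the total
    inserted (gapped) length exceeds ``max_insert_fraction`` of the
    shortest exon.
    """
    if aln.identity <= min_identity:
        return False
    exon_lens = list(aln.exon_len.values()) or [
        len(aln.ungapped(0)), len(aln.ungapped(1))
    ]
    return aln.total_inserted <= max_insert_fraction * min(exon_lens)


@dataclass(frozen=True)
class GapRecord:
    length: int
    row: int                      # which row bears the gap characters
    species: str
    splice_site: str | None       # '3ss' | '5ss' | None when ambiguous
    position: int | None          # 0 at the splice site
    ambiguous: bool = False


def _gap_runs(row: str) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, ch in enumerate(row):
        if ch == GAP and start is None:
            start = i
        elif ch != GAP and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def shift_gaps_to_boundaries(aln: ExonPairAlignment) -> ExonPairAlignment:
    """Slide gaps to abut exon boundaries when match count is preserved.

    For each internal gap, candidate placements abutting the junction
    column of the opposite (inserted-material) row are tried; a slide is
    applied only if the number of exact matches is unchanged.  Ties between
    equivalent placements go to the nearest boundary, then toward the 3'
    splice site.  The output match count always equals the input's.
    """
    rows = [list(r) for r in aln.rows]
    before = aln.n_matches

    def matches(r0, r1):
        return sum(x == y and x != GAP for x, y in zip(r0, r1))

    for row_idx in (0, 1):
        other = 1 - row_idx
        runs = _gap_runs("".join(rows[row_idx]))
        for (i, j) in runs:
            if i == 0 or j == len(rows[row_idx]):
                continue  # terminal gaps stay put
            try:
                boundary = aln_junction_col(aln, rows, other)
            except KeyError:
                continue
            glen = j - i
            candidates = []
            for new_i in (boundary, boundary - glen):
                if new_i == i or new_i < 0 or new_i + glen > len(rows[row_idx]):
                    continue
                lo, hi = min(i, new_i), max(j, new_i + glen)
                window = rows[row_idx][lo:hi]
                if GAP in rows[other][lo:hi]:
                    continue  # never slide across another gap
                resid = [c for c in window if c != GAP]
                if GAP in resid:
                    continue
                new_row = (rows[row_idx][:lo]
                           + _place_gap(resid, new_i - lo, glen)
                           + rows[row_idx][hi:])
                if matches(new_row, rows[other]) == before:
                    dist = abs(new_i - i)
                    prefer_3ss = 0 if new_i == boundary else 1
                    candidates.append((dist, prefer_3ss, new_i, new_row))
            if candidates:
                candidates.sort()
                rows[row_idx] = candidates[0][3]
    shifted = replace(aln, rows=("".join(rows[0]), "".join(rows[1])))
    assert shifted.n_matches == before, "gap shifting changed match count"
    return shifted


def _place_gap(resid: list[str], gap_at: int, glen: int) -> list[str]:
    return resid[:gap_at] + [GAP] * glen + resid[gap_at:]


def aln_junction_col(aln: ExonPairAlignment, rows, row_idx: int) -> int:
    """Junction column of ``row_idx`` computed on (possibly modified) rows."""
    name = aln.names[row_idx]
    if name not in aln.exon_start:
        raise KeyError(name)
    offset = aln.exon_start[name]
    seen = 0
    for col, ch in enumerate(rows[row_idx]):
        if ch != GAP:
            if seen == offset:
                return col
            seen += 1
    return len(rows[row_idx])


def assign_gap_positions(aln: ExonPairAlignment) -> list[GapRecord]:
    """Assign each internal gap a splice-site-relative position.

    For a gap in one row, the opposite row carries the inserted material;
    its junction column s sets the position scale: gaps starting at or
    after s are acceptor-side (3'ss, position = columns past s, 0 when
    abutting), gaps ending at or before s are donor-side (5'ss, position =
    0 when abutting, negative further upstream).

    Gaps touching the junction region itself are disambiguated by the
    species' exon annotations — the information the annotation-bounded
    record extraction carries: if the intact species' exon is longer than
    the gapped species', the change is at the acceptor (3'ss position 0);
    if the upstream-exon tails differ instead, it is donor-side (5'ss
    position 0).  Terminal gaps, and junction-straddling gaps the
    annotations cannot resolve, are flagged ambiguous and excluded.
    """
    records = []
    rows = [list(r) for r in aln.rows]
    try:
        jcols = [aln_junction_col(aln, rows, 0), aln_junction_col(aln, rows, 1)]
    except KeyError:
        jcols = None
    for row_idx in (0, 1):
        other = 1 - row_idx
        name, other_name = aln.names[row_idx], aln.names[other]
        for (i, j) in _gap_runs(aln.rows[row_idx]):
            length = j - i
            if i == 0 or j == len(aln.rows[row_idx]):
                records.append(GapRecord(length, row_idx, name,
                                         None, None, ambiguous=True))
                continue
            if jcols is None:
                records.append(GapRecord(length, row_idx, name,
                                         None, None, ambiguous=True))
                continue
            s = jcols[other]
            touches_junction = i <= max(jcols) and j >= min(jcols)
            if touches_junction:
                exon_gap = aln.exon_len.get(name)
                exon_other = aln.exon_len.get(other_name)
                tail_gap = aln.exon_start.get(name)
                tail_other = aln.exon_start.get(other_name)
                if (exon_gap is not None and exon_other is not None
                        and exon_other > exon_gap):
                    records.append(GapRecord(length, row_idx, name, "3ss", 0))
                    continue
                if (tail_gap is not None and tail_other is not None
                        and tail_other > tail_gap):
                    records.append(GapRecord(length, row_idx, name, "5ss", 0))
                    continue
            if i >= s:
                records.append(GapRecord(length, row_idx, name, "3ss", i - s))
            elif j <= s:
                records.append(GapRecord(length, row_idx, name, "5ss", j - s))
            else:
                records.append(GapRecord(length, row_idx, name,
                                         None, None, ambiguous=True))
    return records


def profiled_positions(span: int = DEFAULT_SPAN) -> list[tuple[str, int]]:
    """The profiled (splice_site, position) cells: 3'ss 0..+span and
    5'ss -span..0."""
    return ([("3ss", p) for p in range(0, span + 1)]
            + [("5ss", p) for p in range(-span, 1)])


@dataclass
class GapProfile:
    table: pd.DataFrame        # splice_site, position, n_pairs_with_gap, fraction
    n_pairs: int
    background: float
    enrichment: float | None


def gap_profile(
    records_by_pair: dict[str, list[GapRecord]],
    n_pairs: int | None = None,
    length_filter: int | None = None,
    span: int = DEFAULT_SPAN,
) -> GapProfile:
    """Fraction of exon pairs with a gap at each profiled position.

    ``records_by_pair`` maps pair id -> gap records; an exon pair counts at
    most once per position.  ``length_filter`` restricts to gaps of exactly
    that length (e.g. 3 for the single-codon analysis).  The background is
    the mean fraction over all profiled positions except the 3'ss position
    0; enrichment = fraction(3'ss, 0) / background (undefined when the
    background is zero).
    """
    n_pairs = n_pairs if n_pairs is not None else len(records_by_pair)
    if n_pairs < 1:
        raise ValueError("at least one exon pair required")
    cells = profiled_positions(span)
    counts = {c: 0 for c in cells}
    for recs in records_by_pair.values():
        seen = set()
        for r in recs:
            if r.ambiguous:
                continue
            if length_filter is not None and r.length != length_filter:
                continue
            key = (r.splice_site, r.position)
            if key in counts and key not in seen:
                counts[key] += 1
                seen.add(key)
    table = pd.DataFrame(
        [dict(splice_site=ss, position=p, n_pairs_with_gap=counts[(ss, p)],
              fraction=counts[(ss, p)] / n_pairs) for ss, p in cells]
    )
    bg_cells = [c for c in cells if c != ("3ss", 0)]
    background = float(np.mean([counts[c] / n_pairs for c in bg_cells]))
    target = counts[("3ss", 0)] / n_pairs
    enrichment = None if background == 0 else target / background
    return GapProfile(table, n_pairs, background, enrichment)


def permutation_test_enrichment(
    records_by_pair: dict[str, list[GapRecord]],
    n_permutations: int = 10_000,
    seed: int = 0,
    n_pairs: int | None = None,
    length_filter: int | None = None,
    span: int = DEFAULT_SPAN,
) -> float:
    """Permutation p-value for the 3'ss position-0 enrichment.

    Null: each profiled gap is reassigned, within its own alignment, to a
    uniformly random profiled position (per-alignment gap counts
    preserved); p = (1 + #{null enrichment >= observed}) / (1 + n).
    """
    obs = gap_profile(records_by_pair, n_pairs, length_filter, span)
    target_frac = obs.table.query(
        "splice_site == '3ss' and position == 0")["fraction"].iloc[0]
    if obs.enrichment is not None:
        obs_enrichment = obs.enrichment
    elif target_frac > 0:
        obs_enrichment = np.inf  # every gap at the target, none elsewhere
    else:
        raise ValueError("no profiled gaps: enrichment undefined")
    n_pairs = obs.n_pairs
    cells = profiled_positions(span)
    P = len(cells)
    pair_gap_counts = []
    for recs in records_by_pair.values():
        k = sum(
            1 for r in recs
            if not r.ambiguous
            and (length_filter is None or r.length == length_filter)
            and (r.splice_site, r.position) in set(cells)
        )
        if k:
            pair_gap_counts.append(k)
    gaps = np.repeat(np.arange(len(pair_gap_counts)),
                     pair_gap_counts)  # alignment index per gap
    G = gaps.size
    if G == 0:
        raise ValueError("no profiled gaps")
    rng = np.random.default_rng(seed)
    target_idx = cells.index(("3ss", 0))
    hits = 0
    chunk = max(1, min(n_permutations, 2_000_000 // max(G, 1)))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        pos = rng.integers(0, P, size=(m, G))
        # fraction of pairs with >=1 gap per cell, deduplicated per pair
        keys = pos * len(pair_gap_counts) + gaps[None, :]
        null_enr = np.empty(m)
        for t in range(m):
            uniq = np.unique(keys[t])
            cell_counts = np.bincount(uniq // len(pair_gap_counts), minlength=P)
            frac = cell_counts / n_pairs
            bg = (frac.sum() - frac[target_idx]) / (P - 1)
            null_enr[t] = np.inf if bg == 0 else frac[target_idx] / bg
        hits += int((null_enr >= obs_enrichment).sum())
        done += m
    return (1 + hits) / (1 + n_permutations)


@dataclass(frozen=True)
class BoundaryChange:
    cls: str                      # unchanged | expanded | contracted | unclassified
    lineage: str | None = None    # which ingroup changed
    size: int = 3
    outgroup: str | None = None


def acceptor_offset(aln: ExonPairAlignment) -> int:
    """Signed acceptor-boundary offset between the two rows.

    +3 when row 0's exon has three extra bases at its start relative to
    row 1 (a 3-nt 3'ss-position-0 gap in row 1), -3 for the converse, and
    0 when the boundaries coincide.
    """
    for rec in assign_gap_positions(aln):
        if rec.splice_site == "3ss" and rec.position == 0:
            return rec.length if rec.row == 1 else -rec.length
    return 0


def classify_boundary_change(
    ingroup_aln: ExonPairAlignment,
    outgroups: list[tuple[str, str, int]],
    align_kwargs: dict | None = None,
) -> BoundaryChange:
    """Classify an acceptor-boundary difference against outgroups.

    ``outgroups`` are (name, record sequence, exon_start offset) in
    priority order.  Offset 0 between the ingroups means unchanged; offset
    3 means one lineage's exon gained or lost a codon at its start, and the
    first outgroup whose boundary matches exactly one ingroup identifies
    the ancestral state: the lineage with the longer exon is 'expanded' if
    the shorter matches the outgroup, else the shorter is 'contracted'.
    """
    align_kwargs = align_kwargs or {}
    off = acceptor_offset(ingroup_aln)
    if off == 0:
        return BoundaryChange("unchanged")
    if abs(off) != 3:
        raise ValueError(f"acceptor offset {off} not in {{0, +/-3}}")
    name_a, name_b = ingroup_aln.names
    longer = name_a if off > 0 else name_b
    shorter = name_b if off > 0 else name_a
    seqs = {name_a: ingroup_aln.ungapped(0), name_b: ingroup_aln.ungapped(1)}
    for out_name, out_seq, out_start in outgroups:
        offsets = {}
        for name in (name_a, name_b):
            aln = align_exon_pair(
                seqs[name], out_seq, names=(name, out_name),
                exon_start={name: ingroup_aln.exon_start[name],
                            out_name: out_start},
                **align_kwargs,
            )
            offsets[name] = acceptor_offset(aln)
        matches = [n for n in (name_a, name_b) if offsets[n] == 0]
        if len(matches) != 1:
            continue  # uninformative outgroup
        ancestral = matches[0]
        if ancestral == shorter:
            return BoundaryChange("expanded", lineage=longer, outgroup=out_name)
        return BoundaryChange("contracted", lineage=shorter, outgroup=out_name)
    return BoundaryChange("unclassified")


def residual_motif(
    class_sequences: dict[str, list[str]], window: tuple[int, int] = (-10, 6)
) -> dict[str, pd.DataFrame]:
    """Positional information content per boundary-change class.

    Input sequences are acceptor windows of the changed lineage anchored at
    its current 3' splice site, covering splice-site-relative positions
    ``window`` (intronic -10..-1 then exonic +1..+6 by default).  Expanded
    exons are expected to retain the ancestral NAG at exonic +1..+3,
    contracted exons at intronic -6..-4.
    """
    positions = [p for p in range(window[0], window[1] + 1) if p != 0]
    out = {}
    for cls, seqs in class_sequences.items():
        if len(seqs) < 2:
            logger.warning("class %s has %d sequences; matrix unstable",
                           cls, len(seqs))
            continue
        ic, freqs = positional_info_content(seqs)
        df = freqs.copy()
        df.insert(0, "position", positions[: len(df)])
        df["ic"] = ic
        df.attrs["n"] = len(seqs)
        out[cls] = df
    return out


def nagnag_boundary_association(
    n_changed_nagnag: int,
    n_changed: int,
    n_unchanged_nagnag: int,
    n_unchanged: int,
) -> tuple[float | None, float]:
    """NAGNAG frequency ratio between changed and unchanged exon classes.

    ratio = P(NAGNAG | changed) / P(NAGNAG | unchanged); the p-value is the
    two-sided Fisher exact test of the 2x2 table.
    """
    table = [
        [n_changed_nagnag, n_changed - n_changed_nagnag],
        [n_unchanged_nagnag, n_unchanged - n_unchanged_nagnag],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if n_changed == 0 or n_unchanged == 0 or n_unchanged_nagnag == 0:
        return None, float(p)
    ratio = (n_changed_nagnag / n_changed) / (n_unchanged_nagnag / n_unchanged)
    return float(ratio), float(p)


def fisher_exact_bruteforce(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Independent oracle for small 2x2 tables: sums the probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (with a small relative tolerance for float ties).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    rv = stats.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return float(min(1.0, total))


GENETIC_CODE_STOP = "*"


def _translate(codons: str) -> str:
    return str(Seq(codons).translate())


@dataclass
class AaSpectrum:
    counts: dict[str, pd.Series]     # 'phase0'|'phase1'|'phase2'|'overall'|'background'
    entropies: dict[str, float]
    n_excluded_stop: int = 0


def shannon_entropy(freqs) -> float:
    """H = -sum p log2 p in bits (counts are renormalised; 0 log 0 = 0)."""
    p = np.asarray(list(freqs), float)
    if np.any(p < 0):
        raise ValueError("negative frequencies")
    s = p.sum()
    if s == 0:
        raise ValueError("empty distribution")
    p = p[p > 0] / s
    return float(-(p * np.log2(p)).sum())


def inserted_residues(
    longer_cds: str, shorter_cds: str, phase: int
) -> str | None:
    """Residue(s) inserted by a 3-nt gain at a 3' splice site.

    ``longer_cds``/``shorter_cds`` are the local coding windows beginning
    at the first codon that overlaps the insertion (the codon starting
    ``phase`` bases into the upstream exon).  For phase 0 the inserted
    codon is counted directly; for phases 1 and 2 the insertion spans two
    codons in the longer species against one in the shorter: if one of the
    two equals the shorter's residue the other was inserted, otherwise both
    are counted.  Returns None when a stop codon falls in the window.
    """
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
    if phase == 0:
        pep_l = _translate(longer_cds[:3])
        if GENETIC_CODE_STOP in pep_l:
            return None
        return pep_l
    pep_l = _translate(longer_cds[:6])
    pep_s = _translate(shorter_cds[:3])
    if GENETIC_CODE_STOP in pep_l or GENETIC_CODE_STOP in pep_s:
        return None
    r1, r2 = pep_l[0], pep_l[1]
    s1 = pep_s[0]
    if s1 == r1:
        return r2
    if s1 == r2:
        return r1
    return r1 + r2


def aa_gain_loss_spectrum(
    events: list[tuple[str, str, int]],
    background_codons: list[str] | None = None,
) -> AaSpectrum:
    """Amino-acid gain/loss spectrum for 3-nt acceptor-boundary gaps.

    ``events`` are (longer local CDS, shorter local CDS, phase) tuples as
    described for :func:`inserted_residues`; ``background_codons`` are the
    codons four codons downstream of the 3' splice site.  Shannon entropy
    is reported per distribution.
    """
    per_phase: dict[str, list[str]] = {"phase0": [], "phase1": [], "phase2": []}
    n_stop = 0
    for longer, shorter, phase in events:
        res = inserted_residues(longer, shorter, phase)
        if res is None:
            n_stop += 1
            logger.info("event excluded: stop codon in insertion window")
            continue
        per_phase[f"phase{phase}"].extend(res)
    per_phase["overall"] = sum(
        (per_phase[k] for k in ("phase0", "phase1", "phase2")), []
    )
    if background_codons is not None:
        bg = []
        for codon in background_codons:
            aa = _translate(codon)
            if aa != GENETIC_CODE_STOP:
                bg.append(aa)
        per_phase["background"] = bg
    counts, entropies = {}, {}
    for key, residues in per_phase.items():
        ser = pd.Series(residues, dtype=str).value_counts().sort_index()
        counts[key] = ser
        entropies[key] = shannon_entropy(ser.to_numpy()) if len(ser) else np.nan
    return AaSpectrum(counts, entropies, n_stop)


def extract_insertion_event(
    aln: ExonPairAlignment, phase: int
) -> tuple[str, str, int] | None:
    """Local CDS windows around a 3-nt acceptor gap, ready for the
    amino-acid spectrum.

    Returns (longer local CDS, shorter local CDS, phase) or None when the
    alignment has no 3-nt 3'ss-position-0 gap.
    """
    for rec in assign_gap_positions(aln):
        if rec.splice_site == "3ss" and rec.position == 0 and rec.length == 3:
            longer_idx = 1 - rec.row
            break
    else:
        return None
    shorter_idx = 1 - longer_idx
    s_long = aln.exon_start[aln.names[longer_idx]]
    s_short = aln.exon_start[aln.names[shorter_idx]]
    long_seq = aln.ungapped(longer_idx)
    short_seq = aln.ungapped(shorter_idx)
    lo_l, lo_s = s_long - phase, s_short - phase
    if lo_l < 0 or lo_s < 0:
        return None
    return long_seq[lo_l : lo_l + 6], short_seq[lo_s : lo_s + 3], phase


def background_codon(aln: ExonPairAlignment, row_idx: int, phase: int,
                     codons_downstream: int = 4) -> str | None:
    """The codon ``codons_downstream`` full codons past the 3' splice site."""
    name = aln.names[row_idx]
    start = aln.exon_start[name] + (3 - phase) % 3 + 3 * (codons_downstream - 1)
    seq = aln.ungapped(row_idx)
    codon = seq[start : start + 3]
    return codon if len(codon) == 3 else None
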