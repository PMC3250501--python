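"""Sequence and conservation features of tandem acceptors.

Positions are splice-site relative: last intron base = -1, first exon base
= +1 (no position 0 base).  The polypyrimidine tract is operationalised as
the first run of >= 5 consecutive pyrimidines upstream of the -3 position;
the AG exclusion zone is proxied by the first AG upstream of -15.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("nagnag")

PYRIMIDINES = set("CT")


@dataclass(frozen=True)
class PptMetrics:
    found: bool
    length: int | None = None
    end_offset: int | None = None  # junction-proximal base of the tract (<= -4)
    sequence: str | None = None


@dataclass(frozen=True)
class YagyagClass:
    label: str  # proximal_major | distal_major | strongly_regulated | other


def classify_yagyag(
    minus3_pair: tuple[str, str],
    psis,
    strong: float = 0.25,
    major: float = 0.75,
) -> YagyagClass:
    """Classify a YAGYAG site by its psi pattern across covered tissues.

    proximal_major: psi >= 0.75 everywhere; distal_major: psi <= 0.25
    everywhere; strongly_regulated: switch score >= 0.25 (takes precedence
    over 'other').  Non-YAGYAG sites (a -3 base outside C/T) are rejected.
    """
    if not (set(minus3_pair) <= PYRIMIDINES):
        raise ValueError(f"-3 bases {minus3_pair} are not both pyrimidines")
    psis = np.asarray(list(psis), float)
    if psis.size == 0:
        raise ValueError("at least one covered tissue required")
    if np.all(psis >= major):
        return YagyagClass("proximal_major")
    if np.all(psis <= 1 - major):
        return YagyagClass("distal_major")
    if psis.max() - psis.min() >= strong:
        return YagyagClass("strongly_regulated")
    return YagyagClass("other")


def _offset_base(seq: str, offset: int) -> str:
    """Base at negative splice-site-relative offset in an upstream intron
    string that ends at the junction (offset -1 = last character)."""
    return seq[len(seq) + offset]


def ppt_metrics(upstream_intron: str, min_run: int = 5) -> PptMetrics:
    """Locate the polypyrimidine tract in an upstream intron sequence.

    Scans upstream from position -4 for the first (most junction-proximal)
    run of >= ``min_run`` consecutive C/T; reports the full run extent and
    the offset of its junction-proximal end.
    """
    seq = upstream_intron.upper()
    if len(seq) < 20:
        logger.warning(
            "upstream intron only %d nt; PPT scan over available bases", len(seq)
        )
    offset = -4
    while offset >= -len(seq):
        if _offset_base(seq, offset) in PYRIMIDINES:
            run_end = offset  # junction-proximal end of this run
            length = 0
            while offset >= -len(seq) and _offset_base(seq, offset) in PYRIMIDINES:
                length += 1
                offset -= 1
            if length >= min_run:
                tract = seq[len(seq) + offset + 1 : len(seq) + run_end + 1]
                return PptMetrics(True, length, run_end, tract)
        else:
            offset -= 1
    return PptMetrics(False)


_CT_PATTERN = re.compile(r"T?(?:CT)+C?")


def ct_content(tract: str) -> float:
    """Fraction of the tract covered by CT-dinucleotide runs.

    Maximal substrings matching optional-T + (CT)+ + optional-C are tiled
    over the tract; the fraction is covered bases / tract length (0 when no
    CT dinucleotide is present).
    """
    tract = tract.upper()
    if not tract:
        raise ValueError("empty tract")
    covered = sum(m.end() - m.start() for m in _CT_PATTERN.finditer(tract))
    return covered / len(tract)


def ag_exclusion_boundary(upstream_intron: str, from_offset: int = -16) -> int | None:
    """Offset of the A of the first AG dinucleotide upstream of -15.

    Scans upstream starting at ``from_offset``; AGs inside the exclusion
    window (closer to the junction) are ignored.  None when no AG occurs in
    the provided sequence.
    """
    seq = upstream_intron.upper()
    if len(seq) < -from_offset:
        raise ValueError(
            f"window of {len(seq)} nt does not extend beyond {from_offset}"
        )
    for a in range(from_offset, -len(seq) - 1, -1):
        if _offset_base(seq, a) == "A" and _offset_base(seq, a + 1) == "G":
            return a
    return None


def positional_info_content(sequences, background: float = 0.25):
    """Per-position information content of aligned sequences, in bits.

    IC(pos) = sum_b f_b * log2(f_b / 0.25) = 2 - H(pos) for an ACGT
    alphabet against a uniform background.  Gap characters are excluded
    from the frequencies with renormalisation.  Returns (ic, freqs) where
    ``freqs`` is a (positions x ACGT) DataFrame for logo rendering.
    """
    seqs = [s.upper() for s in sequences]
    if len(seqs) < 2:
        raise ValueError("at least two sequences required")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must have equal length")
    order = "ACGT"
    W = len(seqs[0])
    counts = np.zeros((W, 4))
    for s in seqs:
        for j, b in enumerate(s):
            if b in order:
                counts[j, order.index(b)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1
    freqs = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs / background), 0.0)
    ic = terms.sum(axis=1)
    return ic, pd.DataFrame(freqs, columns=list(order))


class ConservationTrack:
    """Per-base conservation scores in [0, 1] keyed by genomic position."""

    def __init__(self, scores: dict[str, dict[int, float]]):
        for contig, d in scores.items():
            bad = [v for v in d.values() if not (0.0 <= v <= 1.0)]
            if bad:
                raise ValueError(f"{contig}: scores outside [0, 1]")
        self.scores = scores

    @classmethod
    def from_bedgraph(cls, df: pd.DataFrame) -> "ConservationTrack":
        scores: dict[str, dict[int, float]] = {}
        for r in df.itertuples(index=False):
            d = scores.setdefault(r.contig, {})
            for pos in range(r.start, r.end):
                d[pos] = float(r.score)
        return cls(scores)

    def get(self, contig: str, pos: int) -> float | None:
        return self.scores.get(contig, {}).get(pos)


def _relative_to_genomic(junction: int, strand: str, rel: int) -> int:
    """Map a splice-site-relative offset (no 0) to a genomic position."""
    step = rel - 1 if rel > 0 else rel
    return junction + step if strand == "+" else junction - step - 1


def site_scores_by_position(
    site: pd.Series | dict,
    track: ConservationTrack,
    span: tuple[int, int] = (-150, 90),
) -> dict[int, float]:
    """Conservation scores of one site over splice-site-relative positions."""
    out = {}
    for rel in range(span[0], span[1] + 1):
        if rel == 0:
            continue
        pos = _relative_to_genomic(
            int(site["proximal_junction"]), site["strand"], rel
        )
        v = track.get(site["contig"], pos)
        if v is not None:
            out[rel] = v
    return out


DEFAULT_SWITCH_BINS = ((0.0, 0.05), (0.05, 0.25), (0.25, 0.5), (0.5, 1.0))


def switch_group(switch: float, bins=DEFAULT_SWITCH_BINS) -> str:
    for lo, hi in bins:
        if lo <= switch < hi or (hi == bins[-1][1] and switch == hi):
            return f"[{lo},{hi})" if hi != bins[-1][1] else f"[{lo},{hi}]"
    raise ValueError(f"switch score {switch} outside [0, 1]")


def conservation_profile(
    sites: pd.DataFrame,
    track: ConservationTrack,
    group_col: str = "group",
    span: tuple[int, int] = (-150, 90),
    window: int = 2,
) -> pd.DataFrame:
    """Positional mean +/- SEM of window-averaged conservation per group.

    Sites are aligned at their proximal 3' splice-site junction; scores are
    averaged over a ``window``-nt sliding window (window=1 reproduces raw
    per-base means).  Positions with no data in any site of a group are
    emitted as missing (NaN).
    """
    per_site = []
    for _, site in sites.iterrows():
        per_site.append((site[group_col],
                         site_scores_by_position(site, track, span)))
    positions = [r for r in range(span[0], span[1] + 1) if r != 0]
    rows = []
    for group in sorted({g for g, _ in per_site}):
        members = [s for g, s in per_site if g == group]
        for rel in positions:
            vals = []
            for scores in members:
                win = [scores[r] for r in range(rel, rel + window)
                       if r != 0 and r in scores]
                if win:
                    vals.append(np.mean(win))
            if vals:
                mean = float(np.mean(vals))
                sem = float(stats.sem(vals)) if len(vals) > 1 else 0.0
            else:
                mean = sem = np.nan
            rows.append(dict(group=group, position=rel, mean=mean, sem=sem,
                             n=len(vals)))
    return pd.DataFrame(rows)


def minus4_relative_conservation(
    sites: pd.DataFrame,
    track: ConservationTrack,
    class_col: str = "class",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median of per-site score(-4)/score(-3) ratios per class, with a
    bootstrap standard error (sites with score(-3) = 0 are excluded)."""
    rng = np.random.default_rng(seed)
    rows = []
    for cls, grp in sites.groupby(class_col, sort=True):
        ratios = []
        for _, site in grp.iterrows():
            p3 = track.get(site["contig"],
                           _relative_to_genomic(int(site["proximal_junction"]),
                                                site["strand"], -3))
            p4 = track.get(site["contig"],
                           _relative_to_genomic(int(site["proximal_junction"]),
                                                site["strand"], -4))
            if p3 is None or p4 is None or p3 == 0:
                continue
            ratios.append(p4 / p3)
        if not ratios:
            continue
        ratios = np.asarray(ratios)
        boot = np.median(
            rng.choice(ratios, size=(n_boot, len(ratios)), replace=True), axis=1
        )
        rows.append(dict(**{class_col: cls}, median=float(np.median(ratios)),
                         se=float(boot.std(ddof=1)), n=len(ratios)))
    return pd.DataFrame(rows)


def compare_ortholog_psi(
    pairs: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Spearman correlation of ortholog psi by splice-site-score conservation.

    ``pairs`` columns: psi_a, psi_b (per-species mean psi) and ds_a, ds_b
    (per-species proximal-minus-distal score differences).  Pairs with
    |ds_a - ds_b| <= threshold form the 'conserved' class, the rest
    'diverged'.  The difference in Spearman rho is tested with the Fisher
    z transformation (two-sided); p is undefined when a class has n <= 3.
    """
    conserved = (pairs["ds_a"] - pairs["ds_b"]).abs() <= threshold
    out = []
    stats_by_class = {}
    for label, mask in (("conserved", conserved), ("diverged", ~conserved)):
        sub = pairs[mask]
        if len(sub) < 4:
            rho = (stats.spearmanr(sub["psi_a"], sub["psi_b"]).statistic
                   if len(sub) >= 2 else np.nan)
            stats_by_class[label] = (rho, len(sub))
            continue
        rho = float(stats.spearmanr(sub["psi_a"], sub["psi_b"]).statistic)
        stats_by_class[label] = (rho, len(sub))
    p = z = np.nan
    (r1, n1), (r2, n2) = stats_by_class["conserved"], stats_by_class["diverged"]
    if n1 > 3 and n2 > 3 and abs(r1) < 1 and abs(r2) < 1:
        z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
            1 / (n1 - 3) + 1 / (n2 - 3)
        )
        p = float(2 * stats.norm.sf(abs(z)))
    for label in ("conserved", "diverged"):
        rho, n = stats_by_class[label]
        out.append(dict(cls=label, rho=rho, n=n, fisher_z=float(z),
                        p_difference=p))
    return pd.DataFrame(out)


def replicate_concordance(psi_1, psi_2) -> tuple[float, float]:
    """Pearson r between replicate psi vectors and the 75th percentile of
    |psi_1 - psi_2| (linear interpolation between order statistics)."""
    a = np.asarray(psi_1, float)
    b = np.asarray(psi_2, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired psi values")
    r = float(stats.pearsonr(a, b).statistic)
    dev = float(np.percentile(np.abs(a - b), 75, method="linear"))
    return r, dev
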