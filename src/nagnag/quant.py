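"""Junction-read quantification of NAGNAG isoform usage.

Reads spanning a splice junction are assigned to the proximal or distal
junction sequence; per-sample isoform usage is summarised as psi = the
fraction of junction reads supporting the proximal splice site.  Downstream
statistics: per-site switch scores (max - min psi across covered samples),
a chi-square homogeneity test for tissue regulation, replicate-based false
discovery rates, and the tissue-number extrapolation of the strongly
regulated fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .catalog import JunctionPair, revcomp

logger = logging.getLogger("nagnag")

DEFAULT_MIN_READS = 10
DEFAULT_MIN_MINOR = 0.05
DEFAULT_ALPHA = 0.01
DEFAULT_STRONG = 0.25


@dataclass(frozen=True)
class JunctionCounts:
    site_id: str
    sample_id: str
    n_prox: int
    n_dist: int

    @property
    def total(self) -> int:
        return self.n_prox + self.n_dist


@dataclass(frozen=True)
class PsiEstimate:
    """psi with a 95% Wilson score interval; covered = total >= threshold."""

    psi: float | None
    ci_low: float | None
    ci_high: float | None
    total: int
    covered: bool


def _spans_junction(seq: str, read: str, L: int, min_overhang: int) -> bool:
    """Exact substring match covering the junction with >= min_overhang
    bases on each side."""
    start = 0
    while True:
        o = seq.find(read, start)
        if o == -1:
            return False
        if o <= L - min_overhang and o + len(read) >= L + min_overhang:
            return True
        start = o + 1


def assign_reads(
    reads, pair: JunctionPair, min_overhang: int = 6
) -> JunctionCounts:
    """Count reads matching the proximal or distal junction sequence.

    A read (or its reverse complement) counts toward a junction if it is an
    exact substring spanning the junction with at least ``min_overhang``
    bases on each side.  Reads matching both junctions or neither are not
    counted; reads shorter than 2*min_overhang are skipped.
    """
    L = pair.flank
    n_prox = n_dist = n_short = 0
    for read in reads:
        seq = str(getattr(read, "seq", read)).upper()
        if len(seq) < 2 * min_overhang:
            n_short += 1
            continue
        hit_p = hit_d = False
        for r in (seq, revcomp(seq)):
            hit_p = hit_p or _spans_junction(pair.proximal, r, L, min_overhang)
            hit_d = hit_d or _spans_junction(pair.distal, r, L, min_overhang)
        if hit_p and not hit_d:
            n_prox += 1
        elif hit_d and not hit_p:
            n_dist += 1
    if n_short:
        logger.info("%s: skipped %d reads shorter than %d nt",
                    pair.site_id, n_short, 2 * min_overhang)
    return JunctionCounts(pair.site_id, "", n_prox, n_dist)


def estimate_psi(
    n_prox: int, n_dist: int, min_reads: int = DEFAULT_MIN_READS
) -> PsiEstimate:
    """psi = n_prox / (n_prox + n_dist) with a 95% Wilson score interval."""
    total = n_prox + n_dist
    if total == 0:
        return PsiEstimate(None, None, None, 0, False)
    lo, hi = proportion_confint(n_prox, total, alpha=0.05, method="wilson")
    return PsiEstimate(n_prox / total, float(lo), float(hi), total,
                       total >= min_reads)


def _covered(group: pd.DataFrame, min_reads: int) -> pd.DataFrame:
    totals = group["n_prox"] + group["n_dist"]
    return group[totals >= min_reads]


def is_alternative(
    site_counts: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    min_minor: float = DEFAULT_MIN_MINOR,
) -> bool:
    """True iff some covered sample expresses the minor isoform at >= 5%.

    Samples with fewer than ``min_reads`` junction reads are ignored, so a
    site whose only >=5%-minor sample is under-covered is not alternative.
    """
    cov = _covered(site_counts, min_reads)
    if cov.empty:
        return False
    psi = cov["n_prox"] / (cov["n_prox"] + cov["n_dist"])
    return bool((np.minimum(psi, 1 - psi) >= min_minor).any())


def switch_score(site_counts: pd.DataFrame,
                 min_reads: int = DEFAULT_MIN_READS) -> float | None:
    """max psi - min psi over covered samples (absolute difference)."""
    cov = _covered(site_counts, min_reads)
    if cov.empty:
        return None
    psi = cov["n_prox"] / (cov["n_prox"] + cov["n_dist"])
    return float(psi.max() - psi.min())


def test_regulation(site_counts: pd.DataFrame,
                    min_reads: int = DEFAULT_MIN_READS) -> float | None:
    """Chi-square homogeneity test of proportions across covered samples.

    Equivalent to R's prop.test without continuity correction, generalised
    to T samples.  Returns None with fewer than two covered samples.
    """
    cov = _covered(site_counts, min_reads)
    if len(cov) < 2:
        return None
    table = cov[["n_prox", "n_dist"]].to_numpy()
    # degenerate margins: all reads on one junction => identical proportions
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def psi_table(
    counts: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    min_minor: float = DEFAULT_MIN_MINOR,
    alpha: float = DEFAULT_ALPHA,
    strong: float = DEFAULT_STRONG,
) -> pd.DataFrame:
    """Per-site summary of psi estimates and regulation calls.

    ``counts`` holds one row per (site_id, sample_id) with n_prox/n_dist.
    Returns one row per site: switch score, homogeneity p-value, and the
    alternative / regulated / strongly-regulated flags.
    """
    rows = []
    for site_id, grp in counts.groupby("site_id", sort=True):
        sw = switch_score(grp, min_reads)
        p = test_regulation(grp, min_reads)
        alt = is_alternative(grp, min_reads, min_minor)
        regulated = bool(p is not None and p <= alpha and alt)
        rows.append(
            dict(
                site_id=site_id,
                n_covered=int(len(_covered(grp, min_reads))),
                switch_score=np.nan if sw is None else sw,
                p_value=np.nan if p is None else p,
                alternative=alt,
                regulated=regulated,
                # tiny tolerance: 0.35 - 0.10 is below 0.25 in binary floats
                strongly_regulated=bool(
                    regulated and sw is not None and sw >= strong - 1e-12
                ),
            )
        )
    return pd.DataFrame(rows)


def psi_estimates(counts: pd.DataFrame,
                  min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Per (site, sample) psi estimate table with Wilson 95% CIs."""
    rows = []
    for (_, r) in counts.iterrows():
        est = estimate_psi(int(r["n_prox"]), int(r["n_dist"]), min_reads)
        rows.append(
            dict(site_id=r["site_id"], sample_id=r["sample_id"],
                 psi=est.psi, ci_low=est.ci_low, ci_high=est.ci_high,
                 total=est.total, covered=est.covered)
        )
    return pd.DataFrame(rows)


@dataclass
class FdrReport:
    per_tissue: pd.DataFrame  # tissue, n_alternative, n_flagged, fdr
    weighted_mean: float


def estimate_fdr(
    counts_rep1: pd.DataFrame,
    counts_rep2: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    min_minor: float = DEFAULT_MIN_MINOR,
    alpha: float = DEFAULT_ALPHA,
) -> FdrReport:
    """Replicate-based false discovery rate, per tissue and weighted mean.

    For each tissue (sample_id shared between replicates), the analysis
    restricts to sites alternatively spliced in at least one replicate and
    reports the fraction whose between-replicate 2x2 homogeneity test gives
    p <= alpha.  The mean FDR weights each tissue by its alternative count.
    """
    tissues = sorted(
        set(counts_rep1["sample_id"]) & set(counts_rep2["sample_id"])
    )
    rows = []
    for tissue in tissues:
        a = counts_rep1[counts_rep1["sample_id"] == tissue].set_index("site_id")
        b = counts_rep2[counts_rep2["sample_id"] == tissue].set_index("site_id")
        shared = a.index.intersection(b.index)
        n_alt = n_flag = 0
        for sid in shared:
            one = a.loc[[sid]].reset_index()
            two = b.loc[[sid]].reset_index()
            if not (is_alternative(one, min_reads, min_minor)
                    or is_alternative(two, min_reads, min_minor)):
                continue
            both = pd.concat([one, two], ignore_index=True)
            p = test_regulation(both, min_reads)
            if p is None:
                continue
            n_alt += 1
            n_flag += int(p <= alpha)
        if n_alt == 0:
            continue
        rows.append(dict(tissue=tissue, n_alternative=n_alt,
                         n_flagged=n_flag, fdr=n_flag / n_alt))
    per_tissue = pd.DataFrame(rows)
    if per_tissue.empty:
        return FdrReport(per_tissue, float("nan"))
    w = per_tissue["n_alternative"]
    mean = float((per_tissue["fdr"] * w).sum() / w.sum())
    return FdrReport(per_tissue, mean)


def regulated_fraction_vs_tissues(
    counts: pd.DataFrame,
    ks: list[int] | None = None,
    n_subsets: int = 200,
    seed: int = 0,
    min_reads: int = DEFAULT_MIN_READS,
    min_minor: float = DEFAULT_MIN_MINOR,
    alpha: float = DEFAULT_ALPHA,
    strong: float = DEFAULT_STRONG,
) -> pd.DataFrame:
    """Mean strongly-regulated fraction over random tissue subsets of size k.

    For each k, the strongly-regulated fraction (among sites alternative
    within the subset) is averaged over ``n_subsets`` random subsets; when
    k equals the number of tissues the single full subset is used.
    """
    tissues = sorted(counts["sample_id"].unique())
    T = len(tissues)
    if T < 2:
        raise ValueError("at least two tissues required")
    if ks is None:
        ks = list(range(2, T + 1))
    rng = np.random.default_rng(seed)
    out = []
    for k in ks:
        if k > T:
            logger.warning("subset size %d exceeds %d tissues; skipped", k, T)
            continue
        from math import comb

        n_draw = 1 if k == T else min(n_subsets, comb(T, k))
        fracs = []
        for _ in range(n_draw):
            subset = list(rng.choice(tissues, size=k, replace=False))
            sub = counts[counts["sample_id"].isin(subset)]
            tab = psi_table(sub, min_reads, min_minor, alpha, strong)
            alt = tab[tab["alternative"]]
            if alt.empty:
                continue
            fracs.append(alt["strongly_regulated"].mean())
        out.append(dict(k=k, fraction=float(np.mean(fracs)) if fracs else np.nan,
                        n_subsets=n_draw))
    return pd.DataFrame(out)


def extrapolate_strong_fraction(
    curve: pd.DataFrame, mean_fdr: float, target_tissues: int = 16
) -> float:
    """Linear extrapolation of the strong fraction to ``target_tissues``,
    minus the replicate-based mean FDR, floored at zero."""
    pts = curve.dropna(subset=["fraction"])
    if len(pts) < 3:
        raise ValueError("need at least three (k, fraction) points")
    if pts["k"].nunique() < 2:
        raise ValueError("degenerate curve: all points at the same k")
    slope, intercept = np.polyfit(pts["k"], pts["fraction"], 1)
    return max(0.0, float(slope * target_tissues + intercept - mean_fdr))
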