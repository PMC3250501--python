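"""Two-parameter Boltzmann model of tandem acceptor competition.

The proximal and distal splice sites compete with statistical weights
exp(B*S_prox + Q) and exp(B*S_dist), where S are 3' splice-site scores in
bits, B is a scaling factor (1/bits) and Q an inherent proximal preference.
The probability of proximal use is the logistic

    psi = 1 / (1 + exp(-(B*dS + Q))),    dS = S_prox - S_dist.

Fitting follows the binned procedure: sites are binned by dS with
overlapping windows (width 3.25 bits, step 0.5 bits), the median of the
per-site mean psi is taken per bin, a straight line is fit through the six
bins flanking the psi = 0.5 crossing, and (Q, B) are recovered from the
first-order Taylor expansion of the logistic at its midpoint:
slope = B/4 and Q = -B * dS0, with dS0 the fitted 50% crossing.

A position-weight-matrix acceptor scorer is provided as plumbing for
producing splice-site scores; externally computed scores (e.g. from a
maximum-entropy model) are accepted interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 3.25
DEFAULT_BIN_STEP = 0.5


class FitError(RuntimeError):
    """Binned medians never cross psi = 0.5, or the fitted slope is not
    positive."""


@dataclass(frozen=True)
class SpliceSiteScores:
    s_prox: float
    s_dist: float
    source: str = "external"

    @property
    def delta(self) -> float:
        return self.s_prox - self.s_dist


@dataclass
class BoltzmannFit:
    Q: float
    B: float
    slope: float
    intercept: float
    crossing: float            # dS0 where the fitted line reaches psi = 0.5
    bins: pd.DataFrame         # center, median_psi, n

    @property
    def midpoint(self) -> float:
        """Score difference at which the model predicts psi = 0.5 (-Q/B)."""
        return -self.Q / self.B


def predict_psi(delta_s, Q: float, B: float):
    """Model psi for a score difference (vectorised), saturating smoothly."""
    x = np.asarray(B * np.asarray(delta_s, dtype=float) + Q)
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def bin_medians(
    delta_s: np.ndarray,
    mean_psi: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    bin_step: float = DEFAULT_BIN_STEP,
) -> pd.DataFrame:
    """Median mean-psi in overlapping dS bins (half-open [c-w/2, c+w/2))."""
    delta_s = np.asarray(delta_s, float)
    mean_psi = np.asarray(mean_psi, float)
    lo, hi = delta_s.min(), delta_s.max()
    centers = np.arange(lo + bin_width / 2, hi - bin_width / 2 + 1e-9, bin_step)
    rows = []
    for c in centers:
        mask = (delta_s >= c - bin_width / 2) & (delta_s < c + bin_width / 2)
        if mask.sum() == 0:
            continue
        rows.append(dict(center=float(c),
                         median_psi=float(np.median(mean_psi[mask])),
                         n=int(mask.sum())))
    return pd.DataFrame(rows)


def _crossing_index(bins: pd.DataFrame) -> int:
    """Index i such that bins i, i+1 bracket psi = 0.5.

    Scanning by increasing dS; when several adjacent pairs bracket 0.5 the
    pair containing more sites wins, earliest pair on a tie.
    """
    med = bins["median_psi"].to_numpy()
    n = bins["n"].to_numpy()
    cands = [
        i for i in range(len(med) - 1)
        if (med[i] - 0.5) * (med[i + 1] - 0.5) <= 0
        and not (med[i] == 0.5 and med[i + 1] == 0.5)
    ]
    if not cands:
        raise FitError("binned medians never cross psi = 0.5")
    best = max(cands, key=lambda i: (n[i] + n[i + 1], -i))
    return best


def fit_boltzmann(
    delta_s,
    mean_psi,
    bin_width: float = DEFAULT_BIN_WIDTH,
    bin_step: float = DEFAULT_BIN_STEP,
) -> BoltzmannFit:
    """Fit (Q, B) by the binned straight-line procedure.

    ``mean_psi`` is each site's psi averaged over its covered tissues.  A
    least-squares line through the six bins flanking the 0.5 crossing gives
    slope m and intercept a; inverting the logistic's first-order Taylor
    expansion at its midpoint yields B = 4m, dS0 = (0.5 - a)/m, Q = -B*dS0.
    """
    bins = bin_medians(delta_s, mean_psi, bin_width, bin_step)
    if len(bins) < 6:
        raise FitError(f"only {len(bins)} populated bins; need >= 6")
    i = _crossing_index(bins)
    lo = max(0, min(i - 2, len(bins) - 6))
    six = bins.iloc[lo : lo + 6]
    m, a = np.polyfit(six["center"], six["median_psi"], 1)
    if m <= 0:
        raise FitError(f"non-positive slope {m:.4g} at the crossing")
    crossing = (0.5 - a) / m
    B = 4.0 * m
    Q = -B * crossing
    return BoltzmannFit(Q=float(Q), B=float(B), slope=float(m),
                        intercept=float(a), crossing=float(crossing), bins=bins)


def expected_measurement_sd(psi: float, totals) -> float:
    """Binomial sampling sd of estimated psi, averaged over read totals:
    E[sqrt(psi*(1-psi)/n)] for n drawn from the observed totals."""
    totals = np.asarray(totals, float)
    if np.any(totals < 1):
        raise ValueError("read totals must be >= 1")
    return float(np.mean(np.sqrt(psi * (1.0 - psi) / totals)))


@dataclass
class AcceptorPwm:
    """Log-odds acceptor scorer over splice-site-relative positions.

    ``positions`` lists the window columns (default -20..-1, +1..+3; there
    is no position 0); ``log_odds`` is a (len(positions), 4) array of
    log2(f/background) over A,C,G,T.  Scores are in bits.
    """

    positions: list[int]
    log_odds: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    _ORDER = "ACGT"

    @classmethod
    def default_window(cls) -> list[int]:
        return [p for p in range(-20, 4) if p != 0]

    @classmethod
    def train(
        cls,
        sequences,
        positions: list[int] | None = None,
        background=None,
        pseudocount: float = 1.0,
    ) -> "AcceptorPwm":
        """Train from acceptor windows (one string per site, one char per
        window position), with a +1 pseudocount per base."""
        positions = positions or cls.default_window()
        background = (np.full(4, 0.25) if background is None
                      else np.asarray(background, float))
        W = len(positions)
        counts = np.full((W, 4), pseudocount)
        for seq in sequences:
            seq = seq.upper()
            if len(seq) != W:
                raise ValueError(
                    f"sequence length {len(seq)} != window size {W}"
                )
            for j, base in enumerate(seq):
                counts[j, cls._ORDER.index(base)] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            log_odds = np.log2(freqs / background)  # -inf for unseen bases
        return cls(positions=list(positions), log_odds=log_odds,
                   background=background)

    def score(self, seq: str) -> float:
        """Sum of per-position log-odds, in bits; the window must be fully
        covered and N-free."""
        seq = seq.upper()
        if len(seq) != len(self.positions):
            raise ValueError(
                f"sequence length {len(seq)} != window size {len(self.positions)}"
            )
        if "N" in seq:
            raise ValueError("acceptor window contains N")
        return float(sum(self.log_odds[j, self._ORDER.index(b)]
                         for j, b in enumerate(seq)))

    def consensus(self) -> str:
        return "".join(self._ORDER[i] for i in self.log_odds.argmax(axis=1))


def score_acceptor(seq: str, pwm: AcceptorPwm) -> float:
    """Score one acceptor window with a trained PWM (bits)."""
    return pwm.score(seq)
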