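"""Proximity enrichment of call sets around annotations, and the
calibration statistics of the screen.

Enrichment compares the proportion of foreground sites (e.g. significant
ASHM calls) within a window of a target set against the same proportion
in the high-coverage background, via a 2x2 chi-square (Yates-corrected
by default) or Fisher exact test.  Also here: posterior-odds calibration
of a significance threshold, the Bonferroni threshold arithmetic, and
the Clopper-Pearson exact binomial proportion interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta, chi2_contingency, fisher_exact

logger = logging.getLogger(__name__)


def _distances_to_targets(sites: pd.DataFrame, targets) -> np.ndarray:
    """Distance from each site to its nearest target, per chromosome.

    ``targets`` is either an annotation frame (``chrom, start, end``;
    0-based half-open; distance 0 inside, else bp to the nearest edge) or
    a site-like frame (``chrom, pos``; absolute position difference).
    """
    out = np.full(len(sites), np.inf)
    pos0 = sites["pos"].to_numpy() - 1          # 0-based
    by_chrom = sites.groupby("chrom").indices
    interval = "start" in targets.columns
    for chrom, idx in by_chrom.items():
        tg = targets[targets["chrom"] == chrom]
        if tg.empty:
            continue
        p = pos0[idx]
        if interval:
            starts = tg["start"].to_numpy()[None, :]
            ends = tg["end"].to_numpy()[None, :]
            d = np.maximum.reduce([starts - p[:, None],
                                   p[:, None] - (ends - 1),
                                   np.zeros((len(p), tg.shape[0]))])
        else:
            tpos = tg["pos"].to_numpy()[None, :] - 1
            d = np.abs(p[:, None] - tpos)
        out[idx] = d.min(axis=1)
    return out


def proximity_fraction(sites: pd.DataFrame, targets, window: int
                       ) -> tuple[int, int, float]:
    """(count within window, total, proportion) of sites near targets.

    A site inside a region is at distance 0; the window is inclusive
    (a site exactly ``window`` bp from a region edge counts).
    """
    if len(targets) == 0:
        logger.warning("empty target set: proximity fraction is 0")
        return 0, len(sites), 0.0
    dist = _distances_to_targets(sites, targets)
    count = int((dist <= window).sum())
    total = len(sites)
    return count, total, count / total if total else 0.0


@dataclass(frozen=True)
class EnrichmentResult:
    window: int
    fg_in: int
    fg_total: int
    bg_in: int
    bg_total: int
    p_value: float
    test: str

    @property
    def fg_prop(self) -> float:
        return self.fg_in / self.fg_total if self.fg_total else float("nan")

    @property
    def bg_prop(self) -> float:
        return self.bg_in / self.bg_total if self.bg_total else float("nan")

    @property
    def fold(self) -> float:
        if not self.bg_prop:
            return float("nan")
        return self.fg_prop / self.bg_prop


def enrichment_test(fg: tuple[int, int], bg: tuple[int, int],
                    method: str = "chi2", window: int = 0
                    ) -> EnrichmentResult:
    """2x2 test of foreground vs background proximity membership.

    ``method``: ``chi2`` (Yates continuity correction), ``chi2_plain``
    (no correction) or ``fisher`` (exact; for tiny expected counts).
    """
    fg_in, fg_total = fg
    bg_in, bg_total = bg
    if fg_total < 1 or bg_total < 1:
        raise ValueError("totals must be >= 1")
    table = np.array([[fg_in, fg_total - fg_in],
                      [bg_in, bg_total - bg_in]])
    if method == "fisher":
        p = float(fisher_exact(table)[1])
    elif method in ("chi2", "chi2_plain"):
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p = 1.0
        else:
            p = float(chi2_contingency(
                table, correction=(method == "chi2"))[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return EnrichmentResult(window=window, fg_in=fg_in, fg_total=fg_total,
                            bg_in=bg_in, bg_total=bg_total,
                            p_value=p, test=method)


def proximity_enrichment(fg_sites: pd.DataFrame, bg_sites: pd.DataFrame,
                         targets, window: int, method: str = "chi2"
                         ) -> EnrichmentResult:
    """Convenience: proximity fractions for both sets, then the test."""
    fg = proximity_fraction(fg_sites, targets, window)[:2]
    bg = proximity_fraction(bg_sites, targets, window)[:2]
    return enrichment_test(fg, bg, method=method, window=window)


def posterior_odds(prior_fraction: float, power: float, alpha: float
                   ) -> float:
    """Posterior odds that a threshold-passing site is a true positive.

    ``prior_odds x power / alpha``: with a prior fraction of 0.001% of
    sites truly affected, power 0.1 and alpha 1e-7, the odds are 10:1.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < prior_fraction < 1 or not 0 < power < 1:
        raise ValueError("prior_fraction and power must be in (0, 1)")
    prior_odds = prior_fraction / (1.0 - prior_fraction)
    return prior_odds * power / alpha


def bonferroni_threshold(alpha_fw: float, n_tests: int) -> float:
    """Per-test threshold controlling the family-wise rate at alpha_fw."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha_fw / n_tests


def proportion_ci(k: int, n: int, confidence: float = 0.95
                  ) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a proportion."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    tail = (1.0 - confidence) / 2.0
    low = 0.0 if k == 0 else float(beta.ppf(tail, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1.0 - tail, k + 1, n - k))
    return low, high


def composite_proximity_filter(sites: pd.DataFrame,
                               ase_sites: pd.DataFrame,
                               deletion_regions: pd.DataFrame,
                               ase_window: int = 10_000,
                               deletion_window: int = 250_000
                               ) -> np.ndarray:
    """Mask of sites near both a significant ASE site and a deletion
    region — the disease-candidate filter of the screen."""
    near_ase = (_distances_to_targets(sites, ase_sites) <= ase_window
                if len(ase_sites) else np.zeros(len(sites), dtype=bool))
    near_del = (_distances_to_targets(sites, deletion_regions)
                <= deletion_window
                if len(deletion_regions) else np.zeros(len(sites),
                                                       dtype=bool))
    return np.asarray(near_ase) & np.asarray(near_del)
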