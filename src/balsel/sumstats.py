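"""Windowed summary statistics: pi, Watterson's theta, Tajima's D,
haplotype diversity, and mean |D'| over sliding windows.

All statistics operate on 0/1 haplotype matrices (rows = chromosomes,
columns = biallelic sites).  pi and theta_W are reported per site
(window-length normalised); undefined statistics propagate as NaN, never
as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .wf_engine import HaplotypeSample

__all__ = [
    "WindowSummary",
    "nucleotide_diversity",
    "pairwise_differences_total",
    "wattersons_theta",
    "tajimas_d",
    "haplotype_diversity",
    "mean_d_prime",
    "sliding_window_table",
    "windows_to_frame",
]


def pairwise_differences_total(matrix: np.ndarray) -> float:
    """Mean number of pairwise differences over all C(n,2) chromosome
    pairs (unnormalised by length)."""
    m = np.asarray(matrix)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    k = m.sum(axis=0, dtype=np.int64)
    # per-site heterozygosity summed: k * (n - k) ordered pairs / C(n,2)
    return float((k * (n - k)).sum()) / (n * (n - 1) / 2.0)


def nucleotide_diversity(matrix: np.ndarray, window_length: int) -> float:
    """pi per site: mean pairwise Hamming distance / window length."""
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    return pairwise_differences_total(matrix) / window_length


def wattersons_theta(n: int, n_segregating: int, window_length: int) -> float:
    """Watterson's estimator per site: S / a1 / L."""
    if n < 2:
        raise ValueError("need n >= 2")
    a1 = np.sum(1.0 / np.arange(1, n))
    return n_segregating / a1 / window_length


def tajimas_d(n: int, n_segregating: int, pi_total: float) -> float:
    """Tajima's D from sample size, segregating sites, and total pi.

    Uses the standard constants of Tajima's (1989) test.  Undefined
    (NaN) when S = 0.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    s = n_segregating
    if s == 0:
        return float("nan")
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return float("nan")
    return (pi_total - s / a1) / np.sqrt(var)


def haplotype_diversity(matrix: np.ndarray) -> float:
    """H = (n/(n-1)) * (1 - sum p_h^2) over distinct haplotype strings."""
    m = np.ascontiguousarray(np.asarray(matrix, dtype=np.uint8))
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if m.shape[1] == 0:
        return 0.0
    _, counts = np.unique(m, axis=0, return_counts=True)
    p = counts / n
    return (n / (n - 1.0)) * (1.0 - float((p * p).sum()))


def _d_prime_pair(col_a: np.ndarray, col_b: np.ndarray) -> float:
    n = col_a.size
    p_a = col_a.mean()
    p_b = col_b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return float("nan")
    p_ab = float(np.logical_and(col_a, col_b).sum()) / n
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        return 0.0
    return abs(d) / d_max


def mean_d_prime(matrix: np.ndarray) -> float:
    """Mean |D'| over all pairs of polymorphic sites (no MAF filter);
    NaN with fewer than two polymorphic sites."""
    m = np.asarray(matrix, dtype=np.uint8)
    n, n_sites = m.shape
    k = m.sum(axis=0, dtype=np.int64)
    poly = np.flatnonzero((k > 0) & (k < n))
    if poly.size < 2:
        return float("nan")
    sub = m[:, poly].astype(np.float64)
    p = sub.mean(axis=0)
    # pairwise D via the co-occurrence matrix
    p_ab = (sub.T @ sub) / n
    d = p_ab - np.outer(p, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_max_pos = np.minimum(np.outer(p, (1 - p)), np.outer((1 - p), p))
        d_max_neg = np.minimum(np.outer(p, p), np.outer((1 - p), (1 - p)))
        d_max = np.where(d > 0, d_max_pos, d_max_neg)
        dprime = np.where(d == 0, 0.0, np.abs(d) / d_max)
    iu = np.triu_indices(poly.size, k=1)
    return float(np.nanmean(dprime[iu]))


@dataclass(frozen=True)
class WindowSummary:
    start: int
    end: int
    n: int
    n_segregating: int
    pi: float
    theta_w: float
    tajimas_d: float
    hap_diversity: float
    mean_d_prime: float


def sliding_window_table(
    sample: HaplotypeSample, window: int = 2000, step: int = 1000
) -> list[WindowSummary]:
    """All five statistics over sliding windows starting at 1, 1+step, ...;
    windows extending past the region end are excluded."""
    if not window >= step >= 1:
        raise ValueError("need window >= step >= 1")
    total = sample.total_length
    if window > total:
        raise ValueError("window exceeds region length")
    m = sample.matrix
    pos = sample.positions
    n = sample.n
    out = []
    start = 1
    while start + window - 1 <= total:
        end = start + window - 1
        in_win = np.flatnonzero((pos >= start) & (pos <= end))
        sub = m[:, in_win]
        s = in_win.size
        if s:
            pi_total = pairwise_differences_total(sub)
        else:
            pi_total = 0.0
        out.append(
            WindowSummary(
                start=start,
                end=end,
                n=n,
                n_segregating=s,
                pi=pi_total / window,
                theta_w=wattersons_theta(n, s, window),
                tajimas_d=tajimas_d(n, s, pi_total) if s else float("nan"),
                hap_diversity=haplotype_diversity(sub),
                mean_d_prime=mean_d_prime(sub) if s >= 2 else float("nan"),
            )
        )
        start += step
    return out


def windows_to_frame(
    windows: Iterable[WindowSummary],
    replicate: Optional[int] = None,
    tau_label: Optional[str] = None,
) -> pd.DataFrame:
    """Plot-ready long-format table, one row per window."""
    df = pd.DataFrame([w.__dict__ for w in windows])
    if replicate is not None:
        df.insert(0, "replicate", replicate)
    if tau_label is not None:
        df.insert(0, "tau", tau_label)
    return df
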