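"""SFS-based composite-likelihood-ratio scan for balancing selection.

At every SNP the scan contrasts a mixture model against the genome-wide
background site frequency spectrum g(k).  Informative sites are all
sample-polymorphic SNPs (derived counts k = 1..n-1) plus substitutions
(the k = n class).  A site at distance d from the putatively balanced
test position contributes with mixing weight

    alpha(d) = exp(-d / A)

a balanced-spectrum component h_beta(k) -- a binomial centred on the
candidate equilibrium frequency beta, renormalised over k = 1..n -- and
with weight 1 - alpha the background g(k).  The statistic is

    CLR = 2 * max_{beta, A}  sum_l ln[ (a_l h_beta(k_l) + (1-a_l) g(k_l)) / g(k_l) ]

maximised over a grid that includes a degenerate no-signal point, so
CLR >= 0 with the null nested.  This is a reconstruction in the style of
the B2 statistic (unfolded SFS plus substitutions); absolute CLR values
are not comparable with the original implementation -- rank and ROC
behaviour are what the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

from .ihs_scan import ScanResult
from .wf_engine import HaplotypeSample

__all__ = [
    "SpectrumModel",
    "B2Config",
    "background_sfs",
    "balanced_component",
    "b2_clr",
    "b2_scan",
    "b2_scan_set",
    "informative_sites",
]


@dataclass(frozen=True)
class SpectrumModel:
    """Background probabilities over derived counts k = 1..n (k = n is
    the substitution class), floored by a pseudocount."""

    n: int
    g: np.ndarray  # shape (n,), g[k-1] = P(k)

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        if g.shape != (self.n,):
            raise ValueError("g must have length n")
        if (g < 0).any() or not np.isclose(g.sum(), 1.0):
            raise ValueError("g must be a probability vector over k = 1..n")
        object.__setattr__(self, "g", g)


@dataclass(frozen=True)
class B2Config:
    """Grids for the CLR maximisation.

    ``beta_grid``: candidate equilibrium frequencies; ``footprint_grid``:
    exponential decay scales A in bp.  The degenerate no-signal point
    (alpha = 0 everywhere) is always included.
    """

    beta_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
    footprint_grid: tuple[float, ...] = tuple(np.logspace(2, 6, 9))

    def __post_init__(self) -> None:
        if any(not 0 < b < 1 for b in self.beta_grid):
            raise ValueError("beta values must lie in (0, 1)")
        if any(a <= 0 for a in self.footprint_grid):
            raise ValueError("footprint scales must be positive")


def background_sfs(
    samples: Sequence[HaplotypeSample], pseudocount: float = 1.0
) -> SpectrumModel:
    """Pool derived-count occurrences (plus substitutions as class k = n)
    over replicates into a normalised background spectrum."""
    if not samples:
        raise ValueError("need at least one sample")
    n = samples[0].n
    if any(s.n != n for s in samples):
        raise ValueError("samples have mixed sizes")
    counts = np.zeros(n, dtype=float)
    for s in samples:
        k = s.derived_counts()
        counts[:-1] += np.bincount(k, minlength=n)[1:n]
        counts[-1] += s.substitution_positions.size
    counts += pseudocount
    return SpectrumModel(n=n, g=counts / counts.sum())


def balanced_component(beta: float, n: int) -> np.ndarray:
    """h_beta(k) for k = 1..n: Binomial(k; n, beta) renormalised after
    dropping the unobservable k = 0 class."""
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    k = np.arange(1, n + 1)
    h = binom.pmf(k, n, beta)
    return h / h.sum()


def informative_sites(sample: HaplotypeSample) -> tuple[np.ndarray, np.ndarray]:
    """(positions, derived counts) of all informative sites: polymorphic
    SNPs plus substitutions coded as k = n."""
    k = sample.derived_counts()
    pos = np.concatenate([sample.positions, sample.substitution_positions])
    kk = np.concatenate(
        [k, np.full(sample.substitution_positions.size, sample.n, dtype=np.int64)]
    )
    order = np.argsort(pos, kind="stable")
    return pos[order], kk[order]


def _clr_matrix(
    test_positions: np.ndarray,
    site_positions: np.ndarray,
    site_k: np.ndarray,
    model: SpectrumModel,
    config: B2Config,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CLR (and maximising beta-hat, A-hat) for each test position."""
    g_site = model.g[site_k - 1]
    if (g_site <= 0).any():
        raise ValueError("background probability is zero at an observed count")
    ln_g_site = np.log(g_site)
    d = np.abs(test_positions[:, None] - site_positions[None, :]).astype(float)
    best = np.zeros(test_positions.size)  # the no-signal point: CLR = 0
    best_beta = np.full(test_positions.size, np.nan)
    best_a = np.full(test_positions.size, np.nan)
    h_by_beta = {b: balanced_component(b, model.n)[site_k - 1] for b in config.beta_grid}
    for a_scale in config.footprint_grid:
        alpha = np.exp(-d / a_scale)
        one_minus = (1.0 - alpha) * g_site[None, :]
        for b in config.beta_grid:
            mix = alpha * h_by_beta[b][None, :] + one_minus
            ll = np.log(mix).sum(axis=1) - ln_g_site.sum()
            better = ll > best
            best = np.where(better, ll, best)
            best_beta = np.where(better, b, best_beta)
            best_a = np.where(better, a_scale, best_a)
    return 2.0 * best, best_beta, best_a


def b2_clr(
    test_position: int,
    sites: Sequence[tuple[int, int]],
    model: SpectrumModel,
    config: Optional[B2Config] = None,
) -> tuple[float, float, float]:
    """CLR at one test position given (position, derived count) sites.

    Returns (CLR, beta_hat, A_hat); beta_hat/A_hat are NaN when the
    no-signal point maximises the likelihood (CLR = 0).
    """
    config = config or B2Config()
    pos = np.asarray([p for p, _ in sites], dtype=np.int64)
    kk = np.asarray([k for _, k in sites], dtype=np.int64)
    if pos.size == 0:
        raise ValueError("need at least one informative site")
    if ((kk < 1) | (kk > model.n)).any():
        raise ValueError("derived counts must lie in 1..n")
    clr, beta, a = _clr_matrix(
        np.asarray([test_position], dtype=np.int64), pos, kk, model, config
    )
    return float(clr[0]), float(beta[0]), float(a[0])


def b2_scan(
    sample: HaplotypeSample,
    model: SpectrumModel,
    config: Optional[B2Config] = None,
) -> ScanResult:
    """Evaluate the CLR with the test position at every SNP, using all
    polymorphic sites and substitutions as informative sites."""
    config = config or B2Config()
    pos, kk = informative_sites(sample)
    test_positions = sample.positions
    if test_positions.size == 0:
        return ScanResult(
            method="b2",
            positions=np.empty(0, dtype=np.int64),
            scores=np.empty(0),
            extras={},
        )
    clr, beta, a = _clr_matrix(test_positions, pos, kk, model, config)
    return ScanResult(
        method="b2",
        positions=test_positions.copy(),
        scores=clr,
        extras={"beta_hat": beta, "footprint_hat": a},
    )


def b2_scan_set(
    samples: Sequence[HaplotypeSample],
    model: Optional[SpectrumModel] = None,
    config: Optional[B2Config] = None,
) -> list[ScanResult]:
    """Scan a replicate set against a shared background spectrum (pooled
    from the set itself when not supplied)."""
    if model is None:
        model = background_sfs(samples)
    return [b2_scan(s, model, config) for s in samples]
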