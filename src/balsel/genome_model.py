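"""Chromosome architecture, mutation/recombination rate maps, and discrete DFEs.

Two chromosome presets are supported: a single neutral region (default
50 kb) and a human-like functional layout of three gene-dense regions
separated by intergenic blocks, in which exonic mutations draw selection
coefficients from a four-class discrete distribution of fitness effects
(DFE) while intronic/intergenic mutations are neutral.  Coordinates are
1-based and inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChromosomeLayout",
    "DiscreteDFE",
    "RateMap",
    "build_functional_layout",
    "build_neutral_layout",
    "draw_rate_map",
    "sample_selection_coefficient",
    "sample_selection_coefficients",
    "cm_per_mb_to_per_bp",
    "DFE_PRESETS",
]

# Element kind labels used in layouts.
EXON = "exon"
INTRON = "intron"
INTERGENIC = "intergenic"
NEUTRAL = "neutral"


def cm_per_mb_to_per_bp(rate_cm_per_mb: float) -> float:
    """Convert a recombination rate in cM/Mb to per-bp per-generation.

    1 cM/Mb = 0.01 crossovers per 1e6 bp = 1e-8 per bp.
    """
    return rate_cm_per_mb * 1e-8


@dataclass(frozen=True)
class ChromosomeLayout:
    """Tiled element map of the simulated chromosome.

    ``elements`` is an ordered list of ``(kind, start, end)`` with 1-based
    inclusive coordinates that tile ``[1, total_length]`` without gaps or
    overlaps.  ``balanced_site_position`` marks where the focal (balanced
    or swept) mutation is introduced.  When ``synonymous_rule`` is set,
    every exonic site whose offset within its exon is congruent to 0
    (mod 3) is treated as neutral (a synonymous-site stand-in).
    """

    total_length: int
    elements: tuple[tuple[str, int, int], ...]
    balanced_site_position: int
    synonymous_rule: bool = True

    def __post_init__(self) -> None:
        expected = 1
        for kind, start, end in self.elements:
            if kind not in (EXON, INTRON, INTERGENIC, NEUTRAL):
                raise ValueError(f"unknown element kind {kind!r}")
            if start != expected:
                raise ValueError(
                    f"elements must tile without gaps/overlaps; expected "
                    f"start {expected}, got {start}"
                )
            if end < start:
                raise ValueError(f"element ({kind}, {start}, {end}) has end < start")
            expected = end + 1
        if expected != self.total_length + 1:
            raise ValueError("elements do not tile [1, total_length]")
        if not 1 <= self.balanced_site_position <= self.total_length:
            raise ValueError("balanced_site_position outside chromosome")

    def selected_site_mask(self) -> np.ndarray:
        """Boolean mask over positions 1..L (index 0 unused) of sites whose
        mutations draw from the DFE (non-synonymous exonic sites)."""
        mask = np.zeros(self.total_length + 1, dtype=bool)
        for kind, start, end in self.elements:
            if kind != EXON:
                continue
            mask[start : end + 1] = True
            if self.synonymous_rule:
                # offsets 0, 3, 6, ... within the exon are neutral
                mask[start : end + 1 : 3] = False
        return mask

    def to_records(self) -> list[dict]:
        return [
            {"kind": k, "start": s, "end": e} for k, s, e in self.elements
        ]


def build_functional_layout(
    n_regions: int = 3,
    exons_per_region: int = 9,
    exon_len: int = 1317,
    introns_per_region: int = 8,
    intron_len: int = 1520,
    intergenic_len: int = 4322,
    synonymous_rule: bool = True,
) -> ChromosomeLayout:
    """Build the functional chromosome preset.

    The chromosome tiles functional-region-first: F-I-F-I-F-I, where each
    functional region alternates exons and introns, starting and ending
    with an exon.  With the defaults this yields a 85,005-bp chromosome of
    three 24,013-bp functional regions separated by 4,322-bp intergenic
    blocks, and places the balanced site at the center of the middle
    functional region (position 40,342).
    """
    for name, v in [
        ("n_regions", n_regions),
        ("exons_per_region", exons_per_region),
        ("exon_len", exon_len),
        ("introns_per_region", introns_per_region),
        ("intron_len", intron_len),
        ("intergenic_len", intergenic_len),
    ]:
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if introns_per_region != exons_per_region - 1:
        # alternating exon/intron starting and ending with an exon
        raise ValueError(
            "introns_per_region must equal exons_per_region - 1 for an "
            "exon-bounded alternating region"
        )

    elements: list[tuple[str, int, int]] = []
    region_bounds: list[tuple[int, int]] = []
    pos = 1
    for i in range(n_regions):
        region_start = pos
        for j in range(exons_per_region):
            elements.append((EXON, pos, pos + exon_len - 1))
            pos += exon_len
            if j < introns_per_region:
                elements.append((INTRON, pos, pos + intron_len - 1))
                pos += intron_len
        region_bounds.append((region_start, pos - 1))
        # functional-region-first tiling: an intergenic block follows every
        # functional region (F-I-F-I-F-I)
        elements.append((INTERGENIC, pos, pos + intergenic_len - 1))
        pos += intergenic_len
    total = pos - 1

    mid_start, mid_end = region_bounds[n_regions // 2]
    balanced = (mid_start + mid_end) // 2
    return ChromosomeLayout(
        total_length=total,
        elements=tuple(elements),
        balanced_site_position=balanced,
        synonymous_rule=synonymous_rule,
    )


def build_neutral_layout(length: int = 50_000) -> ChromosomeLayout:
    """Single strictly neutral region with the focal site at its midpoint."""
    if length < 2:
        raise ValueError(f"length must be >= 2, got {length}")
    return ChromosomeLayout(
        total_length=length,
        elements=((NEUTRAL, 1, length),),
        balanced_site_position=length // 2,
        synonymous_rule=False,
    )


@dataclass(frozen=True)
class DiscreteDFE:
    """Four-class discrete DFE on the population-scaled 2*N_ancestral*s axis.

    Class ``i`` has probability ``class_probs[i]`` and its 2Ns values are
    uniform on ``[class_bounds_2ns[i], class_bounds_2ns[i+1])``.  The
    default bin edges (0, 1, 10, 100, 2N) correspond to effectively
    neutral, weakly, moderately, and strongly deleterious mutations; ``s``
    is the fitness reduction of the mutant homozygote, so the top bin is
    capped at s = 1 (lethal homozygote).  All mutations share dominance
    ``h`` (0.5 = semidominant).
    """

    class_probs: tuple[float, float, float, float]
    n_ancestral: int
    h: float = 0.5
    class_bounds_2ns: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.class_probs, dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("class_probs must be non-negative and sum to 1")
        if self.n_ancestral < 1:
            raise ValueError("n_ancestral must be >= 1")
        bounds = self.class_bounds_2ns
        if bounds is None:
            bounds = (0.0, 1.0, 10.0, 100.0, 2.0 * self.n_ancestral)
            object.__setattr__(self, "class_bounds_2ns", bounds)
        if len(bounds) != len(self.class_probs) + 1:
            raise ValueError("need one more bin edge than class")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("bin edges must be strictly increasing")

    def with_n_ancestral(self, n: int) -> "DiscreteDFE":
        """Same class structure referenced to a different diploid size.

        Bin edges expressed as 2Ns are kept, except a top edge equal to
        2N (the s = 1 cap) tracks the new size.
        """
        bounds = list(self.class_bounds_2ns)
        if bounds[-1] == 2.0 * self.n_ancestral:
            bounds[-1] = 2.0 * n
        return DiscreteDFE(
            class_probs=self.class_probs,
            n_ancestral=n,
            h=self.h,
            class_bounds_2ns=tuple(bounds),
        )


def sample_selection_coefficients(
    dfe: DiscreteDFE, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` deleterious selection coefficients s >= 0 from the DFE.

    Classes are chosen with the class probabilities and 2Ns is uniform
    within each class's bin; returned s = 2Ns / (2 * n_ancestral).
    """
    bounds = np.asarray(dfe.class_bounds_2ns)
    ks = rng.choice(len(dfe.class_probs), size=size, p=dfe.class_probs)
    two_ns = rng.uniform(bounds[ks], bounds[ks + 1])
    return two_ns / (2.0 * dfe.n_ancestral)


def sample_selection_coefficient(
    dfe: DiscreteDFE, rng: np.random.Generator
) -> float:
    """Draw one selection coefficient from the DFE (scalar convenience)."""
    return float(sample_selection_coefficients(dfe, 1, rng)[0])


# Labeled archetypes for the six DFE shapes explored in the experiments:
# an excess of weak, moderate, or strong deleterious mutations, a uniform
# spread, and two bimodal shapes.  The exact proportions are package
# defaults and user-overridable.
DFE_PRESETS: dict[str, tuple[float, float, float, float]] = {
    "dfe1_excess_weak": (0.15, 0.55, 0.15, 0.15),
    "dfe2_excess_moderate": (0.15, 0.15, 0.55, 0.15),
    "dfe3_excess_strong": (0.15, 0.15, 0.15, 0.55),
    "dfe4_uniform": (0.25, 0.25, 0.25, 0.25),
    "dfe5_bimodal_wide": (0.40, 0.10, 0.10, 0.40),
    "dfe6_bimodal_mild": (0.30, 0.20, 0.20, 0.30),
}


@dataclass(frozen=True)
class RateMap:
    """Per-block mutation or recombination rates over the chromosome.

    Blocks are 1-based, inclusive, and tile ``[1, total_length]``;
    ``block_edges`` holds block start positions plus a final sentinel
    ``total_length + 1``.  ``block_rates[i]`` is the per-bp
    per-generation rate over ``[block_edges[i], block_edges[i+1] - 1]``.
    """

    kind: str  # "mutation" or "recombination"
    block_edges: tuple[int, ...]
    block_rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("mutation", "recombination"):
            raise ValueError(f"kind must be mutation|recombination, got {self.kind!r}")
        if len(self.block_edges) != len(self.block_rates) + 1:
            raise ValueError("need one more edge than rate")
        if any(e2 <= e1 for e1, e2 in zip(self.block_edges, self.block_edges[1:])):
            raise ValueError("block edges must be strictly increasing")
        if self.block_edges[0] != 1:
            raise ValueError("blocks must start at position 1")
        if any(r < 0 for r in self.block_rates):
            raise ValueError("rates must be non-negative")

    @property
    def total_length(self) -> int:
        return self.block_edges[-1] - 1

    @property
    def total_rate(self) -> float:
        """Sum of per-bp rates over the whole chromosome (expected events
        per gamete per generation)."""
        cached = self.__dict__.get("_total_rate")
        if cached is None:
            cached = float(self.cumulative_mass()[-1])
            object.__setattr__(self, "_total_rate", cached)
        return cached

    def mean_rate(self) -> float:
        return self.total_rate / self.total_length

    def scaled(self, q: float) -> "RateMap":
        return RateMap(
            kind=self.kind,
            block_edges=self.block_edges,
            block_rates=tuple(r * q for r in self.block_rates),
        )

    def cumulative_mass(self) -> np.ndarray:
        """Cumulative rate mass at block starts; used to draw event
        positions proportionally to local rate."""
        cached = self.__dict__.get("_cum_mass")
        if cached is None:
            edges = np.asarray(self.block_edges)
            widths = np.diff(edges)
            cached = np.concatenate(
                [[0.0], np.cumsum(widths * np.asarray(self.block_rates))]
            )
            object.__setattr__(self, "_cum_mass", cached)
        return cached

    def draw_positions(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``k`` integer positions in [1, L] with probability
        proportional to the local per-bp rate."""
        if k == 0:
            return np.empty(0, dtype=np.int64)
        if len(self.block_rates) == 1:
            # uniform-rate fast path
            return rng.integers(1, self.total_length + 1, size=k, dtype=np.int64)
        cum = self.cumulative_mass()
        u = rng.uniform(0.0, cum[-1], size=k)
        blk = np.searchsorted(cum, u, side="right") - 1
        edges = np.asarray(self.block_edges)
        rates = np.asarray(self.block_rates)
        # uniform within the block (all sites in a block share a rate)
        frac = (u - cum[blk]) / np.maximum(rates[blk], np.finfo(float).tiny)
        pos = edges[blk] + np.floor(frac).astype(np.int64)
        return np.minimum(pos, edges[blk + 1] - 1)


def draw_rate_map(
    kind: str,
    layout: ChromosomeLayout,
    mode: str = "fixed",
    fixed_rate: float | None = None,
    lo: float | None = None,
    hi: float | None = None,
    seed: int | np.random.Generator | None = None,
    block_size: int = 1000,
) -> RateMap:
    """Build a fixed- or variable-rate map over 1-kb blocks.

    In ``variable`` mode each full block's rate is an independent draw
    from Uniform(lo, hi); a final partial block inherits the last full
    block's rate.  Draws are reproducible given ``seed``.
    """
    length = layout.total_length
    if mode == "fixed":
        if fixed_rate is None or fixed_rate < 0:
            raise ValueError("fixed mode requires fixed_rate >= 0")
        return RateMap(kind=kind, block_edges=(1, length + 1), block_rates=(fixed_rate,))
    if mode != "variable":
        raise ValueError(f"mode must be fixed|variable, got {mode!r}")
    if lo is None or hi is None:
        raise ValueError("variable mode requires lo and hi")
    if lo < 0 or hi < lo:
        raise ValueError("need 0 <= lo <= hi")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_full = length // block_size
    edges = [1 + i * block_size for i in range(n_full + 1)]
    rates = list(rng.uniform(lo, hi, size=n_full))
    if edges[-1] != length + 1:
        # partial final block inherits the last drawn rate
        rates.append(rates[-1] if rates else rng.uniform(lo, hi))
        edges.append(length + 1)
    if n_full == 0:
        edges = [1, length + 1]
    return RateMap(kind=kind, block_edges=tuple(edges), block_rates=tuple(rates))
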