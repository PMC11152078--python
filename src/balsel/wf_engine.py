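"""Forward-in-time diploid Wright-Fisher engine.

This is the pipeline's synthetic-data generator.  Discrete,
non-overlapping generations; both parents of each offspring are drawn
independently with probability proportional to fitness (selfing
permitted); fitness is multiplicative across loci.  A focal "balanced"
mutation experiences negative frequency-dependent selection with
coefficient

    S_bp = f_eq - F_bp

recomputed once per generation from the parental-generation frequency
(positive S favours the balanced allele; heterozygote fitness
1 + h*S_bp, homozygote 1 + S_bp).  Deleterious mutations drawn from a
discrete DFE contribute 1 - h*s (het) and 1 - s (hom).  Mutation follows
an infinite-sites approximation on discrete positions (a draw landing on
an occupied position is redrawn), recombination places Poisson-many
crossovers at rate-weighted positions, and fixed mutations are moved to
a substitution record (their fitness effect thereafter part of the
baseline).

Populations may consist of several demes with backward migration: each
offspring in deme i first draws a source deme j with probability m_ij,
then draws both parents from deme j.  Piecewise demography (size
changes, splits, migration changes) is described by a
:class:`DemographyPlan` whose event times are generations relative to
the introduction of the focal mutation (negative = during burn-in).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .genome_model import (
    ChromosomeLayout,
    DiscreteDFE,
    RateMap,
    sample_selection_coefficients,
)

__all__ = [
    "DemographyPlan",
    "DemographyEvent",
    "ScenarioConfig",
    "PopulationState",
    "HaplotypeSample",
    "Substitution",
    "SampleAtFrequency",
    "ScenarioError",
    "ExtinctionError",
    "EstablishmentError",
    "balanced_selection_coefficient",
    "individual_fitness",
    "step_generation",
    "run_burn_in",
    "introduce_variant",
    "run_replicate",
    "rescale_scenario",
]

# mutation kind codes
KIND_NEUTRAL = 0
KIND_DELETERIOUS = 1
KIND_BALANCED = 2
KIND_BENEFICIAL = 3


class ScenarioError(RuntimeError):
    """Fatal scenario-level error."""


class ExtinctionError(ScenarioError):
    """A deme reached size zero."""


class EstablishmentError(ScenarioError):
    """The focal mutation failed to establish within the retry budget."""


def balanced_selection_coefficient(f_eq: float, f_bp: float) -> float:
    """Frequency-dependent selection coefficient S_bp = f_eq - f_bp.

    Positive values favour the balanced allele (below equilibrium).
    """
    if not (0.0 <= f_eq <= 1.0 and 0.0 <= f_bp <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    return f_eq - f_bp


def individual_fitness(
    genotype: tuple[set, set],
    registry: dict[int, tuple[float, float, int]],
    s_bp: float = 0.0,
) -> float:
    """Multiplicative fitness of one diploid genotype.

    ``genotype`` is a pair of haplotypes, each a set of mutation ids;
    ``registry`` maps id -> (s, h, kind).  Deleterious mutations
    contribute 1 - h*s / 1 - s (het / hom); balanced and beneficial ones
    contribute 1 + h*S / 1 + S, where S is ``s_bp`` for the balanced
    mutation and the registered s for a beneficial one.  Fitness is
    floored at zero.  This scalar path is the reference the vectorised
    engine is tested against.
    """
    hap_a, hap_b = genotype
    w = 1.0
    for mid in hap_a | hap_b:
        s, h, kind = registry[mid]
        n_copies = (mid in hap_a) + (mid in hap_b)
        if kind == KIND_DELETERIOUS:
            factor = 1.0 - h * s if n_copies == 1 else 1.0 - s
        elif kind in (KIND_BALANCED, KIND_BENEFICIAL):
            eff = s_bp if kind == KIND_BALANCED else s
            factor = 1.0 + h * eff if n_copies == 1 else 1.0 + eff
        else:
            continue
        w *= max(factor, 0.0)
    return max(w, 0.0)


@dataclass(frozen=True)
class DemographyEvent:
    """One demographic event at ``time`` generations relative to the
    introduction of the focal mutation (negative = during burn-in).

    kinds:
      - ``size_change``: params {"deme": int, "size": int}
      - ``split``: params {"deme": int, "sizes": (int, int)} -- the deme
        is replaced by two daughter demes founded by sampling parental
        individuals with replacement.
      - ``set_migration``: params {"matrix": row-stochastic off-diagonal
        per-generation backward migration probabilities} or
        {"m": float} for a symmetric two-deme rate.
    """

    time: int
    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in ("size_change", "split", "set_migration"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class DemographyPlan:
    """Deme sizes, ordered events, and the initial migration matrix."""

    deme_sizes: tuple[int, ...] = (10_000,)
    events: tuple[DemographyEvent, ...] = ()
    migration: Optional[tuple[tuple[float, ...], ...]] = None

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.deme_sizes):
            raise ValueError("deme sizes must be >= 1")
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        if self.migration is not None:
            m = np.asarray(self.migration, dtype=float)
            _check_migration(m)

    @property
    def n_ancestral(self) -> int:
        return self.deme_sizes[0]


def _check_migration(m: np.ndarray) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("migration matrix must be square")
    if (m < 0).any():
        raise ValueError("migration probabilities must be >= 0")
    if not np.allclose(m.sum(axis=1), 1.0):
        raise ValueError("migration rows must sum to 1 (m_ii is the non-migrant mass)")


def symmetric_two_deme_migration(m: float) -> tuple[tuple[float, ...], ...]:
    """Row-stochastic backward matrix for two demes exchanging migrants at
    per-generation rate ``m`` each way."""
    if not 0.0 <= m <= 0.5:
        raise ValueError("per-generation migration rate must be in [0, 0.5]")
    return ((1.0 - m, m), (m, 1.0 - m))


@dataclass(frozen=True)
class SampleAtFrequency:
    """Sampling trigger: draw the sample the first generation the focal
    allele's frequency reaches ``freq`` (scale-robust stand-in for
    'immediately after the sweep phase')."""

    freq: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.freq < 1.0:
            raise ValueError("trigger frequency must be in (0, 1)")


SamplingTime = Union[float, SampleAtFrequency]


@dataclass
class ScenarioConfig:
    """Complete description of one simulation scenario."""

    layout: ChromosomeLayout
    mutation_map: RateMap
    recombination_map: RateMap
    demography: DemographyPlan
    dfe: Optional[DiscreteDFE] = None
    f_eq: Optional[float] = None
    balanced_h: float = 0.5
    sweep_s: Optional[float] = None
    intro_copies: int = 1
    establishment_threshold: float = 0.1
    sampling_times: tuple[SamplingTime, ...] = ()
    sample_size: int = 100
    sample_demes: Optional[tuple[tuple[int, int], ...]] = None  # (deme, n) pairs
    n_replicates: int = 200
    seed: int = 0
    rescale_q: int = 1
    burn_in_n_multiplier: float = 10.0
    retry_budget: int = 1000
    sample_pre_introduction: bool = False

    def __post_init__(self) -> None:
        if self.f_eq is not None and not 0.0 < self.f_eq < 1.0:
            raise ValueError("f_eq must be in (0, 1)")
        if not 0.0 < self.establishment_threshold < 1.0:
            raise ValueError("establishment_threshold must be in (0, 1)")
        if self.rescale_q < 1:
            raise ValueError("rescale_q must be >= 1")
        for t in self.sampling_times:
            if isinstance(t, (int, float)) and t < 0:
                raise ValueError("sampling times (units of N) must be >= 0")
        if self.f_eq is not None and self.sweep_s is not None:
            raise ValueError("set either f_eq (balanced) or sweep_s (sweep), not both")

    @property
    def n_ancestral(self) -> int:
        return self.demography.n_ancestral

    @property
    def burn_in_generations(self) -> int:
        return int(round(self.burn_in_n_multiplier * self.n_ancestral))

    @property
    def has_focal_mutation(self) -> bool:
        return self.f_eq is not None or self.sweep_s is not None

    def selected_site_mask(self) -> Optional[np.ndarray]:
        if self.dfe is None:
            return None
        return self.layout.selected_site_mask()


def rescale_scenario(config: ScenarioConfig, q: int) -> ScenarioConfig:
    """Population-rescale a scenario by integer factor Q.

    N -> N/Q, mu -> Q*mu, r -> Q*r, fixed selection coefficients -> Q*s,
    event times in generations -> /Q; population-scaled quantities
    (4*N*mu, 4*N*r, 2*N*s, times in units of N) are invariant.  The
    frequency-dependent S_bp = f_eq - F_bp is already O(1) and is not
    multiplied by Q.
    """
    if q < 1 or int(q) != q:
        raise ValueError("Q must be a positive integer")
    q = int(q)
    if q == 1:
        return config
    new_sizes = tuple(int(round(n / q)) for n in config.demography.deme_sizes)
    if any(n < 50 for n in new_sizes):
        raise ValueError("rescaling would reduce a deme below 50 diploids")
    new_events = tuple(
        DemographyEvent(
            time=int(round(e.time / q)),
            kind=e.kind,
            params=_rescale_event_params(e, q),
        )
        for e in config.demography.events
    )
    migration = config.demography.migration
    if migration is not None:
        migration = tuple(
            tuple(float(x) for x in row)
            for row in _scale_migration(np.asarray(migration, float), q)
        )
    demog = DemographyPlan(
        deme_sizes=new_sizes, events=new_events, migration=migration
    )
    new = _copy.copy(config)
    new.demography = demog
    new.mutation_map = config.mutation_map.scaled(q)
    new.recombination_map = config.recombination_map.scaled(q)
    if config.dfe is not None:
        new.dfe = config.dfe.with_n_ancestral(new_sizes[0])
    if config.sweep_s is not None:
        new.sweep_s = config.sweep_s * q
    new.rescale_q = config.rescale_q * q
    return new


def _scale_migration(m: np.ndarray, q: int) -> np.ndarray:
    """Multiply off-diagonal backward migration probabilities by Q
    (preserves Nm when N shrinks by Q); the diagonal re-absorbs the
    remaining mass."""
    out = m * q
    np.fill_diagonal(out, 0.0)
    row = out.sum(axis=1)
    if (row > 1.0).any():
        raise ValueError("rescaled migration rates exceed 1; reduce Q")
    np.fill_diagonal(out, 1.0 - row)
    return out


def _rescale_event_params(event: DemographyEvent, q: int) -> dict:
    params = dict(event.params)
    if event.kind == "size_change" and "size" in params:
        params["size"] = int(round(params["size"] / q))
    if event.kind == "split":
        params["sizes"] = tuple(int(round(n / q)) for n in params["sizes"])
    if event.kind == "set_migration":
        if "m" in params:
            params["m"] = params["m"] * q
        if "matrix" in params:
            params["matrix"] = _scale_migration(
                np.asarray(params["matrix"], dtype=float), q
            )
    return params


@dataclass
class Substitution:
    position: int
    s: float
    kind: int
    origin_gen: int
    fixation_gen: int


class PopulationState:
    """Mutable population state: haplotype matrix plus mutation metadata.

    ``G`` is a (2 * sum(deme_sizes), M) uint8 matrix of active
    (population-polymorphic) mutations; rows are chromosomes grouped by
    deme, with individual k of a deme occupying two adjacent rows.
    """

    def __init__(
        self,
        deme_sizes: Sequence[int],
        total_length: int,
        generation: int = 0,
        migration: Optional[np.ndarray] = None,
    ) -> None:
        self.deme_sizes = list(int(n) for n in deme_sizes)
        self.total_length = int(total_length)
        self.generation = int(generation)
        n_chrom = 2 * sum(self.deme_sizes)
        self.G = np.zeros((n_chrom, 0), dtype=np.uint8)
        self.positions = np.empty(0, dtype=np.int64)
        self.sel_s = np.empty(0, dtype=np.float64)
        self.kinds = np.empty(0, dtype=np.int8)
        self.origin_gen = np.empty(0, dtype=np.int64)
        self.substitutions: list[Substitution] = []
        # occupancy over positions 1..L (index 0 unused): active mutations
        # and past substitutions both block re-mutation
        self.occupied = np.zeros(self.total_length + 1, dtype=bool)
        self.migration = None if migration is None else np.asarray(migration, float)
        self.intro_generation: Optional[int] = None

    # -- bookkeeping -----------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return self.G.shape[0]

    @property
    def n_active(self) -> int:
        return self.G.shape[1]

    def deme_row_slices(self) -> list[slice]:
        out, offset = [], 0
        for n in self.deme_sizes:
            out.append(slice(offset, offset + 2 * n))
            offset += 2 * n
        return out

    def focal_column(self) -> int:
        """Index of the balanced/beneficial focal column, or -1."""
        idx = np.flatnonzero(
            (self.kinds == KIND_BALANCED) | (self.kinds == KIND_BENEFICIAL)
        )
        return int(idx[0]) if idx.size else -1

    def focal_frequency(self) -> float:
        """Metapopulation frequency of the focal allele (0 if absent)."""
        col = self.focal_column()
        if col < 0:
            return 0.0
        return float(self.G[:, col].sum(dtype=np.int64)) / self.n_chromosomes

    def allele_counts(self) -> np.ndarray:
        return self.G.sum(axis=0, dtype=np.int64)

    def copy(self) -> "PopulationState":
        new = PopulationState(self.deme_sizes, self.total_length, self.generation)
        new.G = self.G.copy()
        new.positions = self.positions.copy()
        new.sel_s = self.sel_s.copy()
        new.kinds = self.kinds.copy()
        new.origin_gen = self.origin_gen.copy()
        new.substitutions = list(self.substitutions)
        new.occupied = self.occupied.copy()
        new.migration = None if self.migration is None else self.migration.copy()
        new.intro_generation = self.intro_generation
        return new

    # -- demographic events ---------------------------------------------
    def apply_event(
        self, event: DemographyEvent, rng: np.random.Generator
    ) -> None:
        if event.kind == "size_change":
            deme = event.params.get("deme", 0)
            if "size" in event.params:
                size = int(event.params["size"])
            else:
                size = int(round(self.deme_sizes[deme] * event.params["factor"]))
            if size < 1:
                raise ExtinctionError(f"size change drives deme {deme} to {size}")
            self.deme_sizes[deme] = size
        elif event.kind == "split":
            self._apply_split(event.params, rng)
        elif event.kind == "set_migration":
            if "matrix" in event.params:
                m = np.asarray(event.params["matrix"], dtype=float)
            else:
                m = np.asarray(symmetric_two_deme_migration(event.params["m"]))
            _check_migration(m)
            self.migration = m

    def _apply_split(self, params: dict, rng: np.random.Generator) -> None:
        deme = params.get("deme", 0)
        sizes = params["sizes"]
        if len(self.deme_sizes) != 1 or deme != 0:
            raise ScenarioError("split currently supported for a single ancestral deme")
        n_parent = self.deme_sizes[0]
        blocks = []
        for n_d in sizes:
            # found each daughter by drawing parental individuals with
            # replacement (one WF-like founding event)
            picks = rng.integers(0, n_parent, size=int(n_d))
            rows = np.empty(2 * int(n_d), dtype=np.int64)
            rows[0::2] = 2 * picks
            rows[1::2] = 2 * picks + 1
            blocks.append(self.G[rows])
        self.G = np.ascontiguousarray(np.vstack(blocks))
        self.deme_sizes = [int(n) for n in sizes]
        self._prune_fixed_lost(record_fixed=True)
        if self.migration is None:
            self.migration = np.eye(len(sizes))

    def clear_position(self, position: int) -> None:
        """Remove any active mutation segregating at ``position`` (used to
        free the focal site before introduction when the burn-in left a
        standing mutation there)."""
        hit = np.flatnonzero(self.positions == position)
        if hit.size:
            keep = np.ones(self.n_active, dtype=bool)
            keep[hit] = False
            self.G = np.ascontiguousarray(self.G[:, keep])
            self.positions = self.positions[keep]
            self.sel_s = self.sel_s[keep]
            self.kinds = self.kinds[keep]
            self.origin_gen = self.origin_gen[keep]
        self.occupied[position] = False

    def _prune_fixed_lost(self, record_fixed: bool = True) -> None:
        counts = self.allele_counts()
        total = self.n_chromosomes
        lost = counts == 0
        fixed = counts == total
        if record_fixed and fixed.any():
            for j in np.flatnonzero(fixed):
                self.substitutions.append(
                    Substitution(
                        position=int(self.positions[j]),
                        s=float(self.sel_s[j]),
                        kind=int(self.kinds[j]),
                        origin_gen=int(self.origin_gen[j]),
                        fixation_gen=self.generation,
                    )
                )
        keep = ~(lost | fixed)
        if not keep.all():
            self.occupied[self.positions[lost]] = False
            self.G = np.ascontiguousarray(self.G[:, keep])
            self.positions = self.positions[keep]
            self.sel_s = self.sel_s[keep]
            self.kinds = self.kinds[keep]
            self.origin_gen = self.origin_gen[keep]


# ---------------------------------------------------------------------------
# core generation step
# ---------------------------------------------------------------------------


def _fitness_by_deme(
    state: PopulationState, config: "ScenarioConfig", s_bp: float
) -> Optional[list[np.ndarray]]:
    """Per-individual fitness arrays per deme, or None if all equal."""
    sel = np.flatnonzero(state.kinds != KIND_NEUTRAL)
    if sel.size == 0:
        return None
    s = state.sel_s[sel]
    kinds = state.kinds[sel]
    h_del = config.dfe.h if config.dfe is not None else 0.5
    h_focal = config.balanced_h
    # per-mutation genotype multipliers: het (1 copy) and hom (2 copies)
    eff = np.where(kinds == KIND_BALANCED, s_bp, s)
    is_del = kinds == KIND_DELETERIOUS
    het = np.where(is_del, 1.0 - h_del * s, 1.0 + h_focal * eff)
    hom = np.where(is_del, 1.0 - s, 1.0 + eff)
    np.maximum(het, 0.0, out=het)
    np.maximum(hom, 0.0, out=hom)

    out = []
    if sel.size == 1:
        # fast path: single selected locus (e.g. the focal mutation on a
        # neutral background)
        col = state.G[:, sel[0]]
        for sl in state.deme_row_slices():
            c = col[sl][0::2].astype(np.int16) + col[sl][1::2]
            w = np.ones(c.size)
            w[c == 1] = het[0]
            w[c == 2] = hom[0]
            out.append(w)
        return out

    with np.errstate(divide="ignore"):
        log_het = np.log(het)
        log_hom = np.log(hom)
    single = len(state.deme_sizes) == 1
    Gsel = state.G[:, sel] if single else None
    for sl in state.deme_row_slices():
        Gs = Gsel if single else state.G[sl][:, sel]
        c = Gs[0::2].astype(np.int16) + Gs[1::2]
        logw = (c == 1) @ log_het + (c == 2) @ log_hom
        m = logw.max() if logw.size else 0.0
        if not np.isfinite(m):
            m = 0.0
        w = np.exp(logw - m)
        out.append(w)
    return out


def step_generation(
    state: PopulationState,
    config: ScenarioConfig,
    rng: np.random.Generator,
    offspring_sizes: Optional[Sequence[int]] = None,
) -> PopulationState:
    """Advance the population by one Wright-Fisher generation in place.

    Any demographic events due this generation must already have been
    applied (size changes via ``offspring_sizes`` or
    ``state.apply_event``).  Returns ``state``.
    """
    parent_sizes = list(state.deme_sizes)
    sizes = list(offspring_sizes) if offspring_sizes is not None else parent_sizes
    if any(n < 1 for n in sizes):
        raise ExtinctionError(f"offspring deme sizes {sizes} include an empty deme")
    n_demes = len(parent_sizes)
    if len(sizes) != n_demes:
        raise ScenarioError("offspring_sizes must match the current deme count")

    # frequency-dependent coefficient from the parental generation
    s_bp = 0.0
    if config.f_eq is not None:
        col = state.focal_column()
        if col >= 0:
            f_bp = float(state.G[:, col].sum(dtype=np.int64)) / state.n_chromosomes
            s_bp = balanced_selection_coefficient(config.f_eq, f_bp)

    fitness = _fitness_by_deme(state, config, s_bp)
    deme_slices = state.deme_row_slices()
    n_off_total = sum(sizes)

    # choose parents (global individual indices) for every offspring
    parent_a = np.empty(n_off_total, dtype=np.int64)
    parent_b = np.empty(n_off_total, dtype=np.int64)
    ind_offsets = np.concatenate([[0], np.cumsum(parent_sizes)])
    off_start = 0
    for d, n_d in enumerate(sizes):
        if n_d == 0:
            continue
        if state.migration is None or n_demes == 1:
            src = np.full(n_d, d, dtype=np.int64)
        else:
            src = rng.choice(n_demes, size=n_d, p=state.migration[d])
        for j in range(n_demes):
            sel_off = np.flatnonzero(src == j)
            if sel_off.size == 0:
                continue
            if fitness is None:
                picks = rng.integers(0, parent_sizes[j], size=(sel_off.size, 2))
            else:
                w = fitness[j]
                tot = w.sum()
                if tot <= 0:
                    raise ExtinctionError(f"all individuals in deme {j} have fitness 0")
                picks = rng.choice(
                    parent_sizes[j], size=(sel_off.size, 2), p=w / tot
                )
            parent_a[off_start + sel_off] = ind_offsets[j] + picks[:, 0]
            parent_b[off_start + sel_off] = ind_offsets[j] + picks[:, 1]
        off_start += n_d

    # build gametes: order rows so offspring k occupies rows 2k, 2k+1
    parents = np.empty(2 * n_off_total, dtype=np.int64)
    parents[0::2] = parent_a
    parents[1::2] = parent_b
    start_chrom = 2 * parents + rng.integers(0, 2, size=2 * n_off_total)

    r_total = config.recombination_map.total_rate
    child = state.G[start_chrom]
    if r_total > 0 and state.n_active > 0:
        n_co = rng.poisson(r_total, size=2 * n_off_total)
        singles = np.flatnonzero(n_co == 1)
        if singles.size:
            # batch the dominant single-crossover case
            bps = config.recombination_map.draw_positions(singles.size, rng)
            after = state.positions[None, :] > bps[:, None]
            c0 = start_chrom[singles]
            child[singles] = np.where(after, state.G[c0 ^ 1], state.G[c0])
        for g in np.flatnonzero(n_co >= 2):
            bps = np.sort(
                config.recombination_map.draw_positions(int(n_co[g]), rng).astype(float)
            )
            parity = np.searchsorted(bps, state.positions, side="right") % 2
            c0 = start_chrom[g]
            child[g] = np.where(parity == 0, state.G[c0], state.G[c0 ^ 1])

    state.generation += 1

    # fixation / loss bookkeeping for inherited columns
    counts = child.sum(axis=0, dtype=np.int64)
    total = child.shape[0]
    fixed_j = np.flatnonzero(counts == total)
    for j in fixed_j:
        state.substitutions.append(
            Substitution(
                position=int(state.positions[j]),
                s=float(state.sel_s[j]),
                kind=int(state.kinds[j]),
                origin_gen=int(state.origin_gen[j]),
                fixation_gen=state.generation,
            )
        )
    lost_j = np.flatnonzero(counts == 0)
    state.occupied[state.positions[lost_j]] = False
    keep_j = np.flatnonzero((counts > 0) & (counts < total))

    # new mutations (infinite sites on discrete positions: occupied draws
    # are redrawn)
    mu_total = config.mutation_map.total_rate
    n_new = int(rng.poisson(2 * n_off_total * mu_total)) if mu_total > 0 else 0
    if n_new > 0:
        draws = _draw_unoccupied_positions(
            n_new, config.mutation_map, state.occupied, rng
        )
        state.occupied[draws] = True
        rows = rng.integers(0, 2 * n_off_total, size=draws.size)
        sel_mask = config.selected_site_mask()
        s_new = np.zeros(draws.size)
        if sel_mask is not None:
            is_sel = sel_mask[draws]
            n_sel = int(is_sel.sum())
            if n_sel:
                s_new[is_sel] = sample_selection_coefficients(config.dfe, n_sel, rng)
        kinds_new = np.where(s_new > 0, KIND_DELETERIOUS, KIND_NEUTRAL).astype(np.int8)
    else:
        draws = np.empty(0, dtype=np.int64)
        rows = s_new = kinds_new = None

    # assemble the next generation's matrix in one pass
    m_keep = keep_j.size
    final = np.empty((total, m_keep + draws.size), dtype=np.uint8)
    np.take(child, keep_j, axis=1, out=final[:, :m_keep])
    if draws.size:
        final[:, m_keep:] = 0
        final[rows, m_keep + np.arange(draws.size)] = 1
    state.G = final
    state.deme_sizes = sizes
    state.positions = np.concatenate([state.positions[keep_j], draws])
    state.sel_s = np.concatenate(
        [state.sel_s[keep_j], s_new if s_new is not None else np.empty(0)]
    )
    state.kinds = np.concatenate(
        [state.kinds[keep_j], kinds_new if kinds_new is not None else np.empty(0, np.int8)]
    ).astype(np.int8)
    state.origin_gen = np.concatenate(
        [
            state.origin_gen[keep_j],
            np.full(draws.size, state.generation, dtype=np.int64),
        ]
    )
    return state


def _draw_unoccupied_positions(
    n: int,
    rate_map: RateMap,
    occupied: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw up to ``n`` distinct, unoccupied rate-weighted positions;
    collided draws are redrawn (a handful of retries each; a saturated
    neighbourhood drops the mutation)."""
    draws = rate_map.draw_positions(n, rng)
    uniq, first = np.unique(draws, return_index=True)
    draws = draws[np.sort(first)]
    good = draws[~occupied[draws]]
    n_retry = n - good.size
    if n_retry == 0:
        return good
    taken = occupied.copy()
    taken[good] = True
    extra = []
    for _ in range(n_retry):
        for _try in range(1000):
            p = int(rate_map.draw_positions(1, rng)[0])
            if not taken[p]:
                taken[p] = True
                extra.append(p)
                break
    if extra:
        return np.concatenate([good, np.asarray(extra, dtype=np.int64)])
    return good


# ---------------------------------------------------------------------------
# burn-in, introduction, replicates
# ---------------------------------------------------------------------------


def _events_between(
    config: ScenarioConfig, t0: int, t1: int
) -> list[DemographyEvent]:
    """Events with time in [t0, t1), times relative to introduction."""
    return [e for e in config.demography.events if t0 <= e.time < t1]


def run_burn_in(
    config: ScenarioConfig, rng: Optional[np.random.Generator] = None
) -> PopulationState:
    """Evolve a single ancestral deme for 10*N generations from an empty
    (mutation-free) state; the returned state is poised for the
    introduction of the focal mutation."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_gens = config.burn_in_generations
    state = PopulationState(
        deme_sizes=config.demography.deme_sizes[:1],
        total_length=config.layout.total_length,
        generation=0,
        migration=None,
    )
    events = sorted(_events_between(config, -n_gens, 0), key=lambda e: e.time)
    ev_i = 0
    for g in range(n_gens):
        t_rel = g - n_gens  # relative to introduction
        while ev_i < len(events) and events[ev_i].time == t_rel:
            state.apply_event(events[ev_i], rng)
            ev_i += 1
        step_generation(state, config, rng)
    while ev_i < len(events):  # events scheduled exactly at t = 0- boundary
        state.apply_event(events[ev_i], rng)
        ev_i += 1
    return state


def introduce_variant(
    state: PopulationState,
    position: int,
    copies: int,
    kind: str,
    s_or_feq: float,
    rng: np.random.Generator,
) -> PopulationState:
    """Place the focal variant on ``copies`` distinct random chromosomes."""
    if kind not in ("balanced", "beneficial"):
        raise ValueError("kind must be balanced|beneficial")
    if state.occupied[position]:
        raise ValueError(f"position {position} is already occupied")
    if not 1 <= copies <= state.n_chromosomes:
        raise ValueError("copies must be in [1, 2N]")
    col = np.zeros((state.n_chromosomes, 1), dtype=np.uint8)
    rows = rng.choice(state.n_chromosomes, size=copies, replace=False)
    col[rows, 0] = 1
    state.G = np.ascontiguousarray(np.concatenate([state.G, col], axis=1))
    state.positions = np.concatenate([state.positions, [position]]).astype(np.int64)
    kcode = KIND_BALANCED if kind == "balanced" else KIND_BENEFICIAL
    s_store = 0.0 if kind == "balanced" else float(s_or_feq)
    state.sel_s = np.concatenate([state.sel_s, [s_store]])
    state.kinds = np.concatenate([state.kinds, [kcode]]).astype(np.int8)
    state.origin_gen = np.concatenate([state.origin_gen, [state.generation]]).astype(
        np.int64
    )
    state.occupied[position] = True
    state.intro_generation = state.generation
    return state


@dataclass
class HaplotypeSample:
    """n haplotypes x S segregating sites (0 = ancestral, 1 = derived).

    ``substitution_positions`` holds fixed differences accumulated since
    the introduction of the focal mutation, folded together with sites
    that are derived in every sampled chromosome (indistinguishable from
    fixed differences in a sample).  ``balanced_col`` is the column index
    of the focal site, or None if it is absent from the sample's
    polymorphic sites.
    """

    tau_label: str
    matrix: np.ndarray
    positions: np.ndarray
    substitution_positions: np.ndarray
    balanced_col: Optional[int]
    total_length: int
    generation: int
    demes: tuple[int, ...] = (0,)
    focal_position: Optional[int] = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def derived_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0, dtype=np.int64)


def draw_sample(
    state: PopulationState,
    config: ScenarioConfig,
    rng: np.random.Generator,
    tau_label: str,
) -> HaplotypeSample:
    """Draw ``sample_size`` chromosomes without replacement and build a
    HaplotypeSample (optionally split across demes)."""
    slices = state.deme_row_slices()
    if config.sample_demes is not None:
        rows_list, demes = [], []
        for deme, count in config.sample_demes:
            sl = slices[deme]
            pool = np.arange(sl.start, sl.stop)
            rows_list.append(rng.choice(pool, size=count, replace=False))
            demes.append(deme)
        rows = np.concatenate(rows_list)
        demes = tuple(demes)
    else:
        sl = slices[0]
        pool = np.arange(sl.start, sl.stop)
        rows = rng.choice(pool, size=config.sample_size, replace=False)
        demes = (0,)
    sub = state.G[rows]
    counts = sub.sum(axis=0, dtype=np.int64)
    n = sub.shape[0]
    poly = (counts > 0) & (counts < n)
    sample_fixed = counts == n

    order = np.argsort(state.positions[poly], kind="stable")
    matrix = np.ascontiguousarray(sub[:, np.flatnonzero(poly)[order]])
    positions = state.positions[poly][order]

    intro_gen = state.intro_generation
    subs = [
        s.position
        for s in state.substitutions
        if intro_gen is None or s.fixation_gen > intro_gen
    ]
    subs.extend(int(p) for p in state.positions[sample_fixed])
    sub_positions = np.unique(np.asarray(subs, dtype=np.int64))

    focal_pos = config.layout.balanced_site_position
    bcol = None
    hit = np.flatnonzero(positions == focal_pos)
    if hit.size and state.focal_column() >= 0:
        bcol = int(hit[0])
    return HaplotypeSample(
        tau_label=tau_label,
        matrix=matrix,
        positions=positions.astype(np.int64),
        substitution_positions=sub_positions,
        balanced_col=bcol,
        total_length=config.layout.total_length,
        generation=state.generation,
        demes=demes,
        focal_position=focal_pos,
    )


@dataclass
class ReplicateResult:
    trajectory_gens: np.ndarray  # generations since introduction
    trajectory_freq: np.ndarray
    samples: list[HaplotypeSample]
    n_establishment_attempts: int
    pre_introduction_sample: Optional[HaplotypeSample] = None


def _sampling_schedule(config: ScenarioConfig) -> tuple[list[tuple[int, str]], list[SampleAtFrequency]]:
    fixed, triggers = [], []
    n = config.n_ancestral
    for t in config.sampling_times:
        if isinstance(t, SampleAtFrequency):
            triggers.append(t)
        else:
            fixed.append((int(round(float(t) * n)), f"{float(t):g}N"))
    fixed.sort()
    return fixed, triggers


def run_replicate(
    config: ScenarioConfig, replicate_seed: int
) -> ReplicateResult:
    """Run one replicate: burn-in, focal-mutation introduction conditioned
    on establishment (lost introductions restart from the saved
    post-burn-in state with a fresh RNG substream), and sampling at each
    configured time or frequency trigger."""
    root = np.random.SeedSequence([int(config.seed), int(replicate_seed)])
    burn_ss, *attempt_ss = root.spawn(2 + config.retry_budget)
    rng = np.random.default_rng(burn_ss)
    state = run_burn_in(config, rng)

    pre_sample = None
    if config.sample_pre_introduction:
        pre_sample = draw_sample(state, config, rng, tau_label="pre")

    fixed_times, freq_triggers = _sampling_schedule(config)

    if not config.has_focal_mutation:
        if freq_triggers:
            raise ScenarioError("frequency triggers require a focal mutation")
        result = _evolve_and_sample(state, config, rng, fixed_times, [])
        result.n_establishment_attempts = 0
        result.pre_introduction_sample = pre_sample
        return result

    state.clear_position(config.layout.balanced_site_position)
    base_state = state.copy() if config.retry_budget > 0 else state
    kind = "balanced" if config.f_eq is not None else "beneficial"
    s_or_feq = config.f_eq if config.f_eq is not None else config.sweep_s

    for attempt in range(max(1, config.retry_budget)):
        arng = np.random.default_rng(attempt_ss[attempt])
        st = base_state.copy()
        introduce_variant(
            st,
            config.layout.balanced_site_position,
            config.intro_copies,
            kind,
            s_or_feq,
            arng,
        )
        try:
            result = _evolve_and_sample(st, config, arng, fixed_times, freq_triggers)
        except _FocalLost:
            continue
        result.n_establishment_attempts = attempt + 1
        result.pre_introduction_sample = pre_sample
        return result
    raise EstablishmentError(
        f"focal mutation failed to establish in {config.retry_budget} attempts"
    )


class _FocalLost(Exception):
    """Internal: focal allele lost before establishment / pending trigger."""


def _evolve_and_sample(
    state: PopulationState,
    config: ScenarioConfig,
    rng: np.random.Generator,
    fixed_times: list[tuple[int, str]],
    freq_triggers: list[SampleAtFrequency],
) -> ReplicateResult:
    samples: list[HaplotypeSample] = []
    traj_g: list[int] = []
    traj_f: list[float] = []
    pending_fixed = list(fixed_times)
    pending_trig = list(freq_triggers)
    established = not config.has_focal_mutation
    events = sorted(
        (e for e in config.demography.events if e.time >= 0), key=lambda e: e.time
    )
    ev_i = 0
    t = 0  # generations since introduction
    f = state.focal_frequency()
    traj_g.append(t)
    traj_f.append(f)
    if config.has_focal_mutation and f >= config.establishment_threshold:
        established = True
    pending_trig, samples_now = _fire_triggers(pending_trig, f, state, config, rng, t)
    samples.extend(samples_now)
    while pending_fixed and pending_fixed[0][0] <= t:
        gen, label = pending_fixed.pop(0)
        samples.append(draw_sample(state, config, rng, tau_label=label))

    max_gens = 1000 * config.n_ancestral  # guard against unreachable triggers
    while pending_fixed or pending_trig:
        if t > max_gens:
            raise ScenarioError(
                "sampling schedule not completed within 1000*N generations"
            )
        while ev_i < len(events) and events[ev_i].time == t:
            state.apply_event(events[ev_i], rng)
            ev_i += 1
        step_generation(state, config, rng)
        t += 1
        f = state.focal_frequency()
        traj_g.append(t)
        traj_f.append(f)
        if config.has_focal_mutation:
            if f >= config.establishment_threshold:
                established = True
            if f == 0.0 and state.focal_column() < 0:
                if not established or pending_trig:
                    raise _FocalLost()
        pending_trig, samples_now = _fire_triggers(
            pending_trig, f, state, config, rng, t
        )
        samples.extend(samples_now)
        while pending_fixed and pending_fixed[0][0] <= t:
            gen, label = pending_fixed.pop(0)
            samples.append(draw_sample(state, config, rng, tau_label=label))
    return ReplicateResult(
        trajectory_gens=np.asarray(traj_g, dtype=np.int64),
        trajectory_freq=np.asarray(traj_f),
        samples=samples,
        n_establishment_attempts=1,
    )


def _fire_triggers(
    pending: list[SampleAtFrequency],
    f: float,
    state: PopulationState,
    config: ScenarioConfig,
    rng: np.random.Generator,
    t: int,
) -> tuple[list[SampleAtFrequency], list[HaplotypeSample]]:
    still, fired = [], []
    for trig in pending:
        if f >= trig.freq:
            label = trig.label or f"freq{trig.freq:g}"
            fired.append(draw_sample(state, config, rng, tau_label=label))
        else:
            still.append(trig)
    return still, fired
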