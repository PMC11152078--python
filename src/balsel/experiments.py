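"""Named experiment grids: temporal power sweeps, establishment
(stochastic-loss) experiments, and structure/admixture false-positive
runs, plus the scenario runner tying simulation, scans, and ROC
evaluation together.

Scenario presets mirror a standard human-like parameterisation: ancestral
diploid size N = 10,000, mu = 2.5e-8 and r = 1e-8 per bp per generation,
samples of 100 chromosomes, a balanced mutation at the chromosome centre
introduced after a 10N-generation burn-in, and sampling times expressed
in units of N generations.  Desk-scale runs use population rescaling
(Q > 1) via :func:`balsel.wf_engine.rescale_scenario`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from . import __version__
from .b2_scan import B2Config, b2_scan, b2_scan_set, background_sfs
from .genome_model import (
    DFE_PRESETS,
    ChromosomeLayout,
    DiscreteDFE,
    RateMap,
    build_functional_layout,
    build_neutral_layout,
    draw_rate_map,
)
from .ihs_scan import ScanResult, ihs_scan_set
from .io_formats import config_digest
from .power_eval import ROCResult, normalized_fpr_curve, roc, window_scores
from .wf_engine import (
    DemographyEvent,
    DemographyPlan,
    HaplotypeSample,
    SampleAtFrequency,
    ScenarioConfig,
    rescale_scenario,
    run_replicate,
    symmetric_two_deme_migration,
)

__all__ = [
    "EstablishmentResult",
    "ScenarioBundle",
    "equilibrium_scenario",
    "partial_sweep_scenario",
    "stochastic_loss_scenario",
    "structure_scenario",
    "size_change_scenario",
    "run_scenario",
    "establishment_experiment",
    "simulate_frequency_chains",
    "diffusion_establishment_probability",
    "structure_fpr_experiment",
    "structure_fpr_comparison",
    "StructureFprResult",
    "generations_to_years",
    "DEFAULT_TAU_GRID",
]

N_ANCESTRAL = 10_000
MU_FIXED = 2.5e-8
R_FIXED = 1e-8
DEFAULT_TAU_GRID = (0.01, 0.1, 1.0, 10.0, 25.0, 50.0, 75.0, 100.0)
GENERATION_TIME_YEARS = 26.9


def generations_to_years(
    tau_in_n: float,
    n_ancestral: int = N_ANCESTRAL,
    generation_time_years: float = GENERATION_TIME_YEARS,
) -> float:
    """Convert a time in units of N generations to years."""
    return tau_in_n * n_ancestral * generation_time_years


# ---------------------------------------------------------------------------
# scenario builders (full scale; rescale with rescale_scenario for desk runs)
# ---------------------------------------------------------------------------


def _base_maps(layout: ChromosomeLayout, variable_mu: bool, variable_r: bool, seed: int):
    mu_map = (
        draw_rate_map("mutation", layout, "variable", lo=1.3e-8, hi=3.4e-8, seed=seed)
        if variable_mu
        else draw_rate_map("mutation", layout, "fixed", fixed_rate=MU_FIXED)
    )
    r_map = (
        draw_rate_map(
            "recombination",
            layout,
            "variable",
            lo=0.124e-8,
            hi=4.930e-8,
            seed=seed + 1,
        )
        if variable_r
        else draw_rate_map("recombination", layout, "fixed", fixed_rate=R_FIXED)
    )
    return mu_map, r_map


def equilibrium_scenario(
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    f_eq: float = 0.5,
    dfe_preset: Optional[str] = None,
    variable_mu: bool = False,
    variable_r: bool = False,
    n_replicates: int = 200,
    seed: int = 0,
    sample_at_equilibrium: bool = False,
    sample_pre_introduction: bool = False,
) -> ScenarioConfig:
    """Balanced mutation in an equilibrium population.

    ``dfe_preset`` selects the functional chromosome with the named DFE;
    None gives the 50-kb strictly neutral background.  With
    ``sample_at_equilibrium`` an extra sample is drawn the first
    generation the balanced allele reaches f_eq (a rescaling-robust
    proxy for sampling immediately after the sweep phase).
    """
    if dfe_preset is not None:
        layout = build_functional_layout()
        dfe = DiscreteDFE(class_probs=DFE_PRESETS[dfe_preset], n_ancestral=N_ANCESTRAL)
    else:
        layout = build_neutral_layout(50_000)
        dfe = None
    mu_map, r_map = _base_maps(layout, variable_mu, variable_r, seed + 1000)
    times: list = list(tau_grid)
    if sample_at_equilibrium:
        times.append(SampleAtFrequency(freq=f_eq, label="young"))
    return ScenarioConfig(
        layout=layout,
        mutation_map=mu_map,
        recombination_map=r_map,
        demography=DemographyPlan(deme_sizes=(N_ANCESTRAL,)),
        dfe=dfe,
        f_eq=f_eq,
        sampling_times=tuple(times),
        n_replicates=n_replicates,
        seed=seed,
        sample_pre_introduction=sample_pre_introduction,
    )


def partial_sweep_scenario(
    two_ns: float = 100.0,
    sample_freq: float = 0.5,
    n_replicates: int = 200,
    seed: int = 0,
) -> ScenarioConfig:
    """Positively selected mutation on the neutral background, sampled
    when it first reaches ``sample_freq`` (no frequency dependence)."""
    layout = build_neutral_layout(50_000)
    mu_map, r_map = _base_maps(layout, False, False, seed + 1000)
    return ScenarioConfig(
        layout=layout,
        mutation_map=mu_map,
        recombination_map=r_map,
        demography=DemographyPlan(deme_sizes=(N_ANCESTRAL,)),
        sweep_s=two_ns / (2.0 * N_ANCESTRAL),
        sampling_times=(SampleAtFrequency(freq=sample_freq, label="sweep"),),
        n_replicates=n_replicates,
        seed=seed,
    )


def stochastic_loss_scenario(
    two_ns: float,
    dfe_preset: Optional[str] = None,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> ScenarioConfig:
    """Beneficial mutation whose fate (establishment at frequency 0.1 vs
    loss) is recorded; neutral or DFE background."""
    if dfe_preset is not None:
        layout = build_functional_layout()
        dfe = DiscreteDFE(class_probs=DFE_PRESETS[dfe_preset], n_ancestral=N_ANCESTRAL)
    else:
        layout = build_neutral_layout(50_000)
        dfe = None
    mu_map, r_map = _base_maps(layout, False, False, seed + 1000)
    return ScenarioConfig(
        layout=layout,
        mutation_map=mu_map,
        recombination_map=r_map,
        demography=DemographyPlan(deme_sizes=(N_ANCESTRAL,)),
        dfe=dfe,
        sweep_s=two_ns / (2.0 * N_ANCESTRAL),
        sampling_times=(),
        n_replicates=n_replicates,
        seed=seed,
        retry_budget=0,
    )


def size_change_scenario(
    factor: float,
    timing: str = "before_sampling",
    tau_grid: Sequence[float] = (75.0,),
    dfe_preset: Optional[str] = None,
    n_replicates: int = 200,
    seed: int = 0,
) -> ScenarioConfig:
    """Instantaneous size change to ``factor * N`` either at the
    introduction of the balanced allele or 1N generations before the
    (last) sampling time."""
    config = equilibrium_scenario(
        tau_grid=tau_grid, dfe_preset=dfe_preset, n_replicates=n_replicates, seed=seed
    )
    if timing == "at_introduction":
        t = 0
    elif timing == "before_sampling":
        t = int((max(tau_grid) - 1.0) * N_ANCESTRAL)
    else:
        raise ValueError("timing must be at_introduction|before_sampling")
    event = DemographyEvent(
        time=t, kind="size_change", params={"deme": 0, "size": int(factor * N_ANCESTRAL)}
    )
    config.demography = DemographyPlan(
        deme_sizes=config.demography.deme_sizes, events=(event,)
    )
    return config


def structure_scenario(
    model: str,
    nm: float = 0.0,
    n_replicates: int = 200,
    seed: int = 0,
) -> ScenarioConfig:
    """Neutral population-structure scenarios (no focal mutation).

    - ``panmictic``: single equilibrium deme, sampled after burn-in.
    - ``two_deme_geneflow``: split into two demes exchanging migrants at
      population-scaled rate ``nm``; one deme sampled 10N generations
      later.
    - ``admixture``: split, isolation for 5N generations (divergence),
      then strong migration (4Nm = 0.25) for 5N generations (merging);
      one deme sampled.
    - ``hidden_structure``: split, complete isolation for 5N
      generations, then 50 chromosomes sampled from each deme.

    Population-scaled migration values are interpreted on the 4Nm
    convention (per-generation probability m = value / 4N): the source
    study quotes the grid both as "Nm" and as "4Nm", and only the 4Nm
    reading makes its admixture rate (0.25) the strongest of the set.
    """
    layout = build_neutral_layout(50_000)
    mu_map, r_map = _base_maps(layout, False, False, seed + 1000)
    n = N_ANCESTRAL
    events: tuple[DemographyEvent, ...] = ()
    sample_demes = None
    times: tuple = ()
    if model == "panmictic":
        times = (0.0,)
    elif model == "two_deme_geneflow":
        events = (
            DemographyEvent(time=0, kind="split", params={"deme": 0, "sizes": (n, n)}),
            DemographyEvent(
                time=0, kind="set_migration", params={"m": nm / (4 * n)}
            ),
        )
        times = (10.0,)
    elif model == "admixture":
        # divergence first, merging last ("populations that diverge
        # before again merging"): isolation for 5N, then strong gene flow
        events = (
            DemographyEvent(time=0, kind="split", params={"deme": 0, "sizes": (n, n)}),
            DemographyEvent(time=0, kind="set_migration", params={"m": 0.0}),
            DemographyEvent(
                time=5 * n, kind="set_migration", params={"m": 0.25 / (4 * n)}
            ),
        )
        times = (10.0,)
    elif model == "hidden_structure":
        events = (
            DemographyEvent(time=0, kind="split", params={"deme": 0, "sizes": (n, n)}),
            DemographyEvent(time=0, kind="set_migration", params={"m": 0.0}),
        )
        times = (5.0,)
        sample_demes = ((0, 50), (1, 50))
    else:
        raise ValueError(f"unknown structure model {model!r}")
    return ScenarioConfig(
        layout=layout,
        mutation_map=mu_map,
        recombination_map=r_map,
        demography=DemographyPlan(deme_sizes=(n,), events=events),
        sampling_times=times,
        sample_demes=sample_demes,
        n_replicates=n_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------


@dataclass
class ScenarioBundle:
    """In-memory result of a scenario run."""

    config: ScenarioConfig
    samples_by_tau: dict[str, list[HaplotypeSample]]
    scans: dict[tuple[str, str], list[ScanResult]] = field(default_factory=dict)
    rocs: dict[tuple[str, str], ROCResult] = field(default_factory=dict)
    pre_samples: list[HaplotypeSample] = field(default_factory=list)
    establishment_attempts: list[int] = field(default_factory=list)
    ihs_reference: Optional[object] = None  # IhsStandardization once fit

    def roc_for(self, method: str, tau: str) -> ROCResult:
        return self.rocs[(method, tau)]


def simulate_scenario(config: ScenarioConfig, progress: bool = False) -> ScenarioBundle:
    """Run all replicates of a scenario, grouping samples by tau label."""
    by_tau: dict[str, list[HaplotypeSample]] = {}
    pre = []
    attempts = []
    for rep in range(config.n_replicates):
        result = run_replicate(config, rep)
        attempts.append(result.n_establishment_attempts)
        if result.pre_introduction_sample is not None:
            pre.append(result.pre_introduction_sample)
        for s in result.samples:
            by_tau.setdefault(s.tau_label, []).append(s)
    return ScenarioBundle(
        config=config,
        samples_by_tau=by_tau,
        pre_samples=pre,
        establishment_attempts=attempts,
    )


def scan_bundle(
    bundle: ScenarioBundle,
    methods: Iterable[str] = ("b2", "ihs"),
    b2_config: Optional[B2Config] = None,
) -> ScenarioBundle:
    """Apply the requested scans per tau cohort (background spectrum and
    iHS standardisation pooled within each cohort)."""
    for tau, samples in bundle.samples_by_tau.items():
        if "b2" in methods:
            model = background_sfs(samples)
            bundle.scans[("b2", tau)] = [b2_scan(s, model, b2_config) for s in samples]
        if "ihs" in methods:
            bundle.scans[("ihs", tau)] = ihs_scan_set(samples)
    return bundle


def evaluate_bundle(bundle: ScenarioBundle) -> ScenarioBundle:
    """Build a windowed ROC per (method, tau) cohort."""
    for (method, tau), scans in bundle.scans.items():
        ws = [window_scores(s, bundle.config.layout) for s in scans]
        bundle.rocs[(method, tau)] = roc(ws, method=method)
    return bundle


def paired_power_analysis(
    bundle: ScenarioBundle,
    b2_taus: Sequence[str] = (),
    ihs_taus: Sequence[str] = (),
    b2_config: Optional[B2Config] = None,
) -> ScenarioBundle:
    """Scan the requested tau cohorts and build null-referenced ROCs.

    The bundle's paired pre-introduction samples serve as the matched
    neutral reference: they provide the FPR windows and (for iHS) the
    frequency-bin standardisation statistics, approximating the
    genome-wide neutral expectation a single-region scan lacks.
    """
    from .ihs_scan import _unstandardized_scan, fit_standardization
    from .power_eval import paired_roc

    pre = bundle.pre_samples
    if not pre:
        raise ValueError("bundle has no pre-introduction (neutral) samples")
    layout = bundle.config.layout
    if b2_taus:
        neutral_b2 = b2_scan_set(pre, config=b2_config)
        bundle.scans[("b2", "pre")] = neutral_b2
        for tau in b2_taus:
            scans = [
                b2_scan(s, background_sfs(bundle.samples_by_tau[tau]), b2_config)
                for s in bundle.samples_by_tau[tau]
            ]
            bundle.scans[("b2", tau)] = scans
            bundle.rocs[("b2", tau)] = paired_roc(scans, neutral_b2, layout, "b2")
    if ihs_taus:
        ref_flat = [
            (sc.unstandardized, sc.derived_freq)
            for s in pre
            for sc in _unstandardized_scan(s, 0.05)
        ]
        reference = fit_standardization(ref_flat)
        bundle.ihs_reference = reference
        neutral_ihs = ihs_scan_set(pre, reference=reference)
        bundle.scans[("ihs", "pre")] = neutral_ihs
        for tau in ihs_taus:
            scans = ihs_scan_set(bundle.samples_by_tau[tau], reference=reference)
            bundle.scans[("ihs", tau)] = scans
            bundle.rocs[("ihs", tau)] = paired_roc(scans, neutral_ihs, layout, "ihs")
    return bundle


def run_scenario(
    config: ScenarioConfig,
    methods: Iterable[str] = ("b2", "ihs"),
    out_dir: Optional[Path] = None,
    b2_config: Optional[B2Config] = None,
) -> ScenarioBundle:
    """Simulate, scan, and evaluate one scenario; optionally write ROC
    tables and a manifest under ``out_dir``."""
    bundle = simulate_scenario(config)
    scan_bundle(bundle, methods, b2_config)
    evaluate_bundle(bundle)
    if out_dir is not None:
        write_bundle(bundle, Path(out_dir))
    return bundle


def write_bundle(bundle: ScenarioBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for (method, tau), r in bundle.rocs.items():
        path = out_dir / f"roc_{method}_tau{tau}.tsv"
        with path.open("w", newline="\n") as fh:
            fh.write("threshold\ttpr\tfpr\n")
            for t, tp, fp in zip(r.thresholds, r.tpr, r.fpr):
                fh.write(f"{t:.6g}\t{tp:.6g}\t{fp:.6g}\n")
    manifest = {
        "version": __version__,
        "seed": bundle.config.seed,
        "n_replicates": bundle.config.n_replicates,
        "rescale_q": bundle.config.rescale_q,
        "config_digest": config_digest(describe_config(bundle.config)),
        "taus": sorted(bundle.samples_by_tau),
        "establishment_attempts": bundle.establishment_attempts,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def describe_config(config: ScenarioConfig) -> dict:
    return {
        "layout_length": config.layout.total_length,
        "balanced_site": config.layout.balanced_site_position,
        "deme_sizes": list(config.demography.deme_sizes),
        "events": [
            {"time": e.time, "kind": e.kind, "params": e.params}
            for e in config.demography.events
        ],
        "f_eq": config.f_eq,
        "sweep_s": config.sweep_s,
        "dfe": None if config.dfe is None else list(config.dfe.class_probs),
        "mu_mean": config.mutation_map.mean_rate(),
        "r_mean": config.recombination_map.mean_rate(),
        "sampling_times": [str(t) for t in config.sampling_times],
        "sample_size": config.sample_size,
        "n_replicates": config.n_replicates,
        "seed": config.seed,
        "rescale_q": config.rescale_q,
    }


# ---------------------------------------------------------------------------
# establishment (stochastic loss) experiments
# ---------------------------------------------------------------------------


@dataclass
class EstablishmentResult:
    scenario_id: str
    two_ns: float
    intro_copies: int
    n_replicates: int
    n_established: int
    proportion: float
    ci_low: float
    ci_high: float
    ratio_to_baseline: Optional[float] = None

    @staticmethod
    def from_counts(
        scenario_id: str, two_ns: float, intro_copies: int, n_rep: int, n_est: int
    ) -> "EstablishmentResult":
        p = n_est / n_rep
        lo, hi = _binomial_ci(n_est, n_rep)
        return EstablishmentResult(
            scenario_id=scenario_id,
            two_ns=two_ns,
            intro_copies=intro_copies,
            n_replicates=n_rep,
            n_established=n_est,
            proportion=p,
            ci_low=lo,
            ci_high=hi,
        )


def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval."""
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def simulate_frequency_chains(
    n_diploid: int,
    s: float,
    h: float,
    threshold: float,
    n_replicates: int,
    rng: np.random.Generator,
    p0: Optional[float] = None,
    f_eq: Optional[float] = None,
    max_generations: Optional[int] = None,
) -> int:
    """Exact marginal Wright-Fisher allele-frequency chains (binomial
    sampling around the deterministic selection update) run until loss
    or first crossing of ``threshold``; returns the number established.

    Equivalent to the full engine for an unlinked focal allele, making
    very large replicate counts desk-scale.  ``f_eq`` switches on the
    frequency-dependent coefficient s = f_eq - p.
    """
    two_n = 2 * n_diploid
    p = np.full(n_replicates, p0 if p0 is not None else 1.0 / two_n)
    established = 0
    max_gens = max_generations or 200 * n_diploid
    for _ in range(max_gens):
        if p.size == 0:
            break
        s_eff = (f_eq - p) if f_eq is not None else np.full(p.size, s)
        q = 1.0 - p
        num = p * p * (1.0 + s_eff) + p * q * (1.0 + h * s_eff)
        wbar = 1.0 + 2.0 * p * q * h * s_eff + p * p * s_eff
        p_sel = np.clip(num / wbar, 0.0, 1.0)
        p = rng.binomial(two_n, p_sel) / two_n
        hit = p >= threshold
        established += int(hit.sum())
        p = p[~hit & (p > 0.0)]
    return established


def diffusion_establishment_probability(
    n_diploid: int, s: float, h: float, threshold: float, p0: Optional[float] = None
) -> float:
    """Kimura diffusion probability that an additive-equivalent allele
    (effective coefficient h*s) starting at p0 reaches ``threshold``
    before loss: (1 - exp(-4N h s p0)) / (1 - exp(-4N h s q))."""
    p0 = p0 if p0 is not None else 1.0 / (2 * n_diploid)
    a = 4.0 * n_diploid * h * s
    if a == 0.0:
        return p0 / threshold  # neutral martingale identity
    return float(np.expm1(-a * p0) / np.expm1(-a * threshold))


def establishment_experiment(
    config: ScenarioConfig,
    n_replicates: Optional[int] = None,
    scenario_id: str = "",
    seed: Optional[int] = None,
) -> EstablishmentResult:
    """Count replicates whose focal mutation reaches the establishment
    threshold before loss.

    On a strictly neutral background the focal-allele trajectory is a
    standalone frequency process and is simulated with the exact
    marginal chain; with a DFE the full engine is used (one burn-in per
    batch of introductions, each from an independent RNG substream).
    """
    n_rep = n_replicates or config.n_replicates
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    two_ns = (
        2 * config.n_ancestral * config.sweep_s if config.sweep_s is not None else 0.0
    )
    if config.dfe is None:
        n = config.demography.deme_sizes[0]
        if config.sweep_s is not None:
            s, f_eq = config.sweep_s, None
        else:
            s, f_eq = 0.0, config.f_eq
        n_est = simulate_frequency_chains(
            n_diploid=n,
            s=s,
            h=config.balanced_h,
            threshold=config.establishment_threshold,
            n_replicates=n_rep,
            rng=rng,
            p0=config.intro_copies / (2 * n),
            f_eq=f_eq,
        )
        return EstablishmentResult.from_counts(
            scenario_id, two_ns, config.intro_copies, n_rep, n_est
        )
    return _establishment_with_background(config, n_rep, scenario_id, seed, two_ns)


def _establishment_with_background(
    config: ScenarioConfig,
    n_rep: int,
    scenario_id: str,
    seed: int,
    two_ns: float,
    trials_per_burnin: int = 1000,
) -> EstablishmentResult:
    from .wf_engine import introduce_variant, run_burn_in, step_generation

    n_burnins = max(1, int(np.ceil(n_rep / trials_per_burnin)))
    root = np.random.SeedSequence([seed, 11])
    n_est = 0
    done = 0
    kind = "balanced" if config.f_eq is not None else "beneficial"
    s_or_feq = config.f_eq if config.f_eq is not None else config.sweep_s
    for b, ss in enumerate(root.spawn(n_burnins)):
        rng = np.random.default_rng(ss)
        base = run_burn_in(config, rng)
        base.clear_position(config.layout.balanced_site_position)
        for _ in range(min(trials_per_burnin, n_rep - done)):
            st = base.copy()
            introduce_variant(
                st,
                config.layout.balanced_site_position,
                config.intro_copies,
                kind,
                s_or_feq,
                rng,
            )
            while True:
                f = st.focal_frequency()
                if f >= config.establishment_threshold:
                    n_est += 1
                    break
                if f == 0.0 and st.focal_column() < 0:
                    break
                step_generation(st, config, rng)
            done += 1
    return EstablishmentResult.from_counts(
        scenario_id, two_ns, config.intro_copies, n_rep, n_est
    )


# ---------------------------------------------------------------------------
# structure / admixture false-positive experiment
# ---------------------------------------------------------------------------


@dataclass
class StructureFprResult:
    """FPR curves and pooled window scores per (method, model).

    ``curves[method][model] = (normalised thresholds, FPR)`` on a joint
    min-max axis; ``window_scores[method][model]`` holds the raw pooled
    window scores behind them.
    """

    curves: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    window_scores: dict[str, dict[str, np.ndarray]]
    null_model: str = "panmictic"

    def fpr_at_null_quantile(
        self, method: str, model: str, nominal_fpr: float = 0.05
    ) -> float:
        """FPR of ``model`` at the score threshold an analyst would set
        from the null model (the null's (1 - nominal_fpr) quantile) —
        the miscalibration an unaccounted-for history causes."""
        null_scores = self.window_scores[method][self.null_model]
        t = float(np.quantile(null_scores, 1.0 - nominal_fpr))
        scores = self.window_scores[method][model]
        return float((scores >= t).mean())


def structure_fpr_comparison(
    models: Sequence[tuple[str, float]] = (
        ("panmictic", 0.0),
        ("two_deme_geneflow", 0.2),
        ("admixture", 0.0),
        ("hidden_structure", 0.0),
    ),
    n_replicates: int = 200,
    rescale_q: int = 1,
    seed: int = 0,
    methods: Sequence[str] = ("b2", "ihs"),
    n_thresholds: int = 100,
) -> StructureFprResult:
    """FPR curves for a set of neutral structure models on a shared
    normalised-threshold axis.

    The comparison emulates an analyst whose baseline model is
    panmictic: the B2 background spectrum and the iHS frequency-bin
    statistics are fit on the panmictic cohort and applied to every
    model (calibrating each structured model against its own data would
    amount to accounting for the structure, absorbing exactly the
    confounding being quantified).  Each model's window scores are then
    min-max normalised to [0, 1] and the FPR evaluated at evenly spaced
    normalised thresholds; the raw pooled scores are also kept so that
    calibrated-threshold inflation can be read off.
    """
    from .ihs_scan import _unstandardized_scan, fit_standardization
    from .power_eval import window_scores as _window_scores

    samples_by_model: dict[str, list[HaplotypeSample]] = {}
    layout = None
    for i, (model, nm) in enumerate(models):
        config = structure_scenario(
            model, nm=nm, n_replicates=n_replicates, seed=seed + 101 * i
        )
        if rescale_q > 1:
            config = rescale_scenario(config, rescale_q)
        layout = config.layout
        bundle = simulate_scenario(config)
        (tau,) = bundle.samples_by_tau
        samples_by_model[model] = bundle.samples_by_tau[tau]

    ref_model = models[0][0]  # panmictic first by convention
    reference = None
    if "ihs" in methods:
        ref_flat = [
            (sc.unstandardized, sc.derived_freq)
            for s in samples_by_model[ref_model]
            for sc in _unstandardized_scan(s, 0.05)
        ]
        reference = fit_standardization(ref_flat)
    b2_background = (
        background_sfs(samples_by_model[ref_model]) if "b2" in methods else None
    )

    curves: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    raw: dict[str, dict[str, np.ndarray]] = {}
    for method in methods:
        scores_by_model = {}
        for model, samples in samples_by_model.items():
            if method == "b2":
                scans = [b2_scan(s, b2_background) for s in samples]
            else:
                scans = ihs_scan_set(samples, reference=reference)
            pooled = [
                _window_scores(s, layout, truth_radius=-1).negative_scores
                for s in scans
            ]
            scores_by_model[model] = np.concatenate(pooled + [np.empty(0)])
        thr = np.linspace(0.0, 1.0, int(n_thresholds))
        curves[method] = {}
        raw[method] = scores_by_model
        for model, v in scores_by_model.items():
            lo, hi = float(v.min()), float(v.max())
            if hi <= lo:
                raise ValueError(f"degenerate scores for model {model!r}")
            norm = (v - lo) / (hi - lo)
            fpr = (norm[None, :] >= thr[:, None]).sum(axis=1) / norm.size
            curves[method][model] = (thr, fpr.astype(float))
    return StructureFprResult(curves=curves, window_scores=raw)


def structure_fpr_experiment(
    model: str,
    n_replicates: int = 200,
    nm: float = 0.0,
    rescale_q: int = 1,
    seed: int = 0,
    methods: Iterable[str] = ("b2", "ihs"),
    n_thresholds: int = 100,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Run a neutral structure scenario and return normalised-threshold
    FPR curves per method: {method: (thresholds, fpr)}."""
    config = structure_scenario(model, nm=nm, n_replicates=n_replicates, seed=seed)
    if rescale_q > 1:
        config = rescale_scenario(config, rescale_q)
    bundle = simulate_scenario(config)
    scan_bundle(bundle, methods)
    out = {}
    for (method, tau), scans in bundle.scans.items():
        out[method] = normalized_fpr_curve(scans, config.layout, n_thresholds)
    return out
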