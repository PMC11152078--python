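"""Shared fixtures.

Desk-scale simulation bundles are session-scoped: the temporal power
grid, the young-allele/partial-sweep comparison sets, and the
structure/admixture false-positive runs are each simulated once and
shared between the module tests and the acceptance tests.  Scales and
replicate counts are the package's desk-scale defaults documented in
docs/methods.md: Q = 50 (N = 200) for the 75N-horizon grid, Q = 20
(N = 500) for sweep-phase scenarios, Q = 80 (N = 125) for neutral
structure runs.
"""

import numpy as np
import pytest

from balsel.experiments import (
    equilibrium_scenario,
    evaluate_bundle,
    paired_power_analysis,
    partial_sweep_scenario,
    scan_bundle,
    simulate_scenario,
    structure_fpr_comparison,
)
from balsel.wf_engine import rescale_scenario, run_replicate

MASTER_SEED = 20_260_921

TEMPORAL_Q = 50
TEMPORAL_REPS = 32
SWEEP_Q = 20
SWEEP_REPS = 32
STRUCTURE_Q = 80
STRUCTURE_REPS = 28

# With S_bp deliberately unscaled, the desk-scale balanced allele's initial
# phase matches a standard-rescaled sweep of full-scale 2Ns = 2N * f_eq / Q.
MATCHED_SWEEP_2NS = 2 * 10_000 * 0.5 / SWEEP_Q  # = 500


@pytest.fixture(scope="session")
def neutral_equilibrium_samples():
    """Post-burn-in neutral samples (no focal mutation): 40 replicates at
    N = 100 (Q = 100).  Returns (samples, theta_per_site)."""
    config = equilibrium_scenario(
        tau_grid=(0.0,), n_replicates=40, seed=MASTER_SEED + 1
    )
    config.f_eq = None  # strictly neutral run
    config = rescale_scenario(config, 100)
    samples = [run_replicate(config, rep).samples[0] for rep in range(40)]
    n = config.demography.deme_sizes[0]
    theta = 4 * n * config.mutation_map.mean_rate()
    return samples, theta


@pytest.fixture(scope="session")
def temporal_bundle():
    """Equilibrium neutral-background scenario at Q = 50 (N = 200),
    sampled at tau_b in {1, 25, 50, 75}N, with paired pre-introduction
    neutral samples; B2 scans and within-replicate windowed ROCs per
    tau cohort."""
    config = equilibrium_scenario(
        tau_grid=(1.0, 25.0, 50.0, 75.0),
        n_replicates=TEMPORAL_REPS,
        seed=MASTER_SEED,
        sample_pre_introduction=True,
    )
    config = rescale_scenario(config, TEMPORAL_Q)
    bundle = simulate_scenario(config)
    scan_bundle(bundle, methods=("b2",))
    evaluate_bundle(bundle)
    return bundle


@pytest.fixture(scope="session")
def young_bundle():
    """Young balanced allele at Q = 20 (N = 500): sampled at the first
    attainment of f_eq ('young', the scale-robust reading of tau =
    0.01N) and at tau = 1N; iHS scans standardised against the paired
    neutral samples, with null-referenced ROCs."""
    config = equilibrium_scenario(
        tau_grid=(1.0,),
        n_replicates=SWEEP_REPS,
        seed=MASTER_SEED + 2,
        sample_at_equilibrium=True,
        sample_pre_introduction=True,
    )
    config = rescale_scenario(config, SWEEP_Q)
    bundle = simulate_scenario(config)
    paired_power_analysis(bundle, ihs_taus=("young", "1N"))
    return bundle


@pytest.fixture(scope="session")
def sweep_samples():
    """Partial-sweep replicates sampled at frequency 0.5 on the neutral
    background, at the same desk scale as young_bundle and with sweep
    strength matched to the (unscaled) balanced allele's initial phase."""
    config = partial_sweep_scenario(
        two_ns=MATCHED_SWEEP_2NS, n_replicates=SWEEP_REPS, seed=MASTER_SEED + 3
    )
    config = rescale_scenario(config, SWEEP_Q)
    out = []
    for rep in range(config.n_replicates):
        out.extend(run_replicate(config, rep).samples)
    return config, out


@pytest.fixture(scope="session")
def structure_curves():
    """Jointly-normalised FPR curves: {method: {model: (thr, fpr)}}."""
    return structure_fpr_comparison(
        n_replicates=STRUCTURE_REPS,
        rescale_q=STRUCTURE_Q,
        seed=MASTER_SEED + 4,
    )
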