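"""Monte-Carlo evaluation: rejection rates of the four tests over replicated
simulated cohorts, with one shared stream of permutation flip vectors per
replicate (each test's marginal p-value is exact, so sharing the flips is
statistically valid and saves most of the compute).

Replicate r draws its generator from ``SeedSequence(master_seed).spawn``,
so results are bit-identical regardless of how replicates are scheduled
across workers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from joblib import Parallel, delayed

from .classical import (
    TestResult,
    draw_flips,
    perm_stats_combined_tdt,
    perm_stats_max_tdt,
    perm_stats_multivariable,
)
from .io import TrioCohort
from .relrt import LrtResult, RandomEffectsSpec, lrt_lambda_perm
from .simulate import SimulationConfig, config_to_dict, simulate_trio_cohort
from .transmission import summarize_transmission

__all__ = ["METHODS", "ExperimentResult", "run_all_tests", "run_rejection_experiment"]

METHODS = ("ts", "tmult", "ctdt", "lrt")


@dataclasses.dataclass
class ExperimentResult:
    """Per-test rejection rates with Monte-Carlo standard errors."""

    rates: dict[str, float]
    se: dict[str, float]
    n_reps: int
    n_perm: int
    alpha: float
    seed: int
    config: dict
    methods: tuple[str, ...]


def _run_all_tests_rng(
    cohort: TrioCohort,
    n_perm: int,
    rng: np.random.Generator,
    gamma: float,
    methods: tuple[str, ...],
    seed_label: int = 0,
) -> dict[str, TestResult]:
    summary = summarize_transmission(cohort)
    X = summary.X.astype(np.float64)
    H = summary.H
    S_obs = summary.X.sum(axis=0)[None, :]
    flips = draw_flips(rng, n_perm, summary.n_families)
    S = flips @ summary.X
    out: dict[str, TestResult] = {}

    def add(name: str, obs: float, perm: np.ndarray) -> None:
        p = (1 + int((perm >= obs - 1e-12).sum())) / (1 + n_perm)
        out[name] = TestResult(statistic=obs, p_value=p, n_perm=n_perm, seed=seed_label)

    if "ts" in methods:
        add("ts", float(perm_stats_max_tdt(S_obs, H)[0]), perm_stats_max_tdt(S, H))
    if "ctdt" in methods:
        add("ctdt", float(perm_stats_combined_tdt(S_obs, H)[0]), perm_stats_combined_tdt(S, H))
    if "tmult" in methods:
        V = X.T @ X
        add("tmult", float(perm_stats_multivariable(S_obs.astype(float), V)[0]),
            perm_stats_multivariable(S.astype(float), V))
    if "lrt" in methods:
        spec = RandomEffectsSpec.from_cohort(cohort, gamma=gamma)
        pi_obs, lam_obs = lrt_lambda_perm(summary, spec, np.ones((1, summary.n_families), dtype=np.int64))
        # reuse the shared flip matrix
        _, lam_perm = lrt_lambda_perm(summary, spec, flips)
        p = (1 + int((lam_perm >= lam_obs[0] - 1e-12).sum())) / (1 + n_perm)
        out["lrt"] = LrtResult(
            statistic=float(lam_obs[0]), pi_hat=float(pi_obs[0]), p_value=p,
            n_perm=n_perm, seed=seed_label, gamma=gamma,
        )
    return out


def run_all_tests(
    cohort: TrioCohort,
    n_perm: int = 10000,
    seed: int = 0,
    gamma: float = 5.0,
    methods: tuple[str, ...] = METHODS,
) -> dict[str, TestResult]:
    """Run the requested tests on one cohort with a shared permutation set."""
    bad = set(methods) - set(METHODS)
    if bad:
        raise ValueError(f"unknown methods {sorted(bad)}; choose from {METHODS}")
    rng = np.random.default_rng(seed)
    return _run_all_tests_rng(cohort, n_perm, rng, gamma, tuple(methods), seed_label=seed)


def _one_replicate(config, n_perm, gamma, methods, alpha, child_seed):
    rng = np.random.default_rng(child_seed)
    cohort = simulate_trio_cohort(config, rng=rng)
    results = _run_all_tests_rng(cohort, n_perm, rng, gamma, methods)
    return {m: results[m].p_value < alpha for m in methods}


def run_rejection_experiment(
    config: SimulationConfig,
    n_reps: int = 500,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    gamma: float = 5.0,
    methods: tuple[str, ...] = METHODS,
    n_jobs: int = 1,
) -> ExperimentResult:
    """Estimate per-test rejection rates at level ``alpha``.

    Each replicate simulates a fresh cohort (region redrawn), runs the
    requested tests with ``n_perm`` permutations, and records whether
    p < alpha; rates are means over replicates with standard errors
    sqrt(rate (1-rate) / n_reps).  Deterministic for a master seed and
    independent of ``n_jobs``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    methods = tuple(methods)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    if n_jobs == 1:
        hits = [_one_replicate(config, n_perm, gamma, methods, alpha, c) for c in children]
    else:
        hits = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(config, n_perm, gamma, methods, alpha, c) for c in children
        )
    rates = {m: float(np.mean([h[m] for h in hits])) for m in methods}
    se = {m: float(np.sqrt(rates[m] * (1 - rates[m]) / n_reps)) for m in methods}
    return ExperimentResult(
        rates=rates, se=se, n_reps=n_reps, n_perm=n_perm, alpha=alpha,
        seed=seed, config=config_to_dict(config), methods=methods,
    )
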