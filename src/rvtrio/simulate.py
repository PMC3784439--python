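"""Simulation of ascertained case-parents cohorts.

The generator reproduces the statistical structure of the evaluation
design: a gene region of rare variants (MAFs uniform on a configurable
range, default 0.1%-1%), optionally mixed with common variants at fixed
MAFs; functional variants receive relative risks by linear interpolation
over the configured RR range, with the smallest-MAF variant getting the
largest RR; disease risk is multiplicative across variants with a
configurable per-variant inheritance form (default dominant); the baseline
penetrance is calibrated so the population prevalence is exact under
independent sites; and families are rejection-sampled until the target
number of trios with an affected child is reached.

Sites are generated independently at their configured MAFs, a parametric
stand-in for a coalescent haplotype pool: at these frequencies rare
variants carry negligible linkage disequilibrium over a gene-sized region,
and every test statistic conditions on per-family genotype vectors, so
cross-variant dependence enters only through power, second-order.  A
haplotype-pool hook (``pool=`` argument) accepts an external (n_haplotypes,
L) 0/1 matrix — e.g. coalescent output — from which parental haplotypes
are drawn instead, without changing anything downstream.

A two-subpopulation mode generates stratified null cohorts (family-level
mixing, no admixed matings) with distinct MAFs and prevalences, used to
check robustness of the tests to population stratification.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Sequence

import numpy as np

from .io import TrioCohort

__all__ = [
    "CommonVariant",
    "StratSettings",
    "SimulationConfig",
    "RegionModel",
    "assign_relative_risks",
    "calibrate_baseline_penetrance",
    "draw_region",
    "simulate_trio_cohort",
    "simulate_stratified_cohort",
    "config_to_dict",
    "config_from_dict",
    "config_hash",
]

_FORMS = ("dominant", "multiplicative", "recessive")


@dataclasses.dataclass
class CommonVariant:
    """A fixed-MAF (common) variant added to the region."""

    maf: float
    functional: bool = False
    rr_min: float = 1.0
    rr_max: float = 1.0


@dataclasses.dataclass
class StratSettings:
    """Two-subpopulation null: proportion, prevalence and MAF range of pop 2."""

    prop2: float = 0.2
    prevalence2: float = 0.04
    maf_low2: float = 0.001
    maf_high2: float = 0.03


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the evaluation design.

    ``L`` counts the rare variants (MAF uniform on [maf_low, maf_high]);
    the first ``n_functional`` of them are functional with RRs linearly
    interpolated over [rr_min, rr_max] by MAF.  Common variants are listed
    separately and appended after the rare ones.  ``protective_prob`` is
    the chance each functional variant's RR is replaced by its inverse.
    """

    n_trios: int = 500
    L: int = 5
    n_functional: int = 0
    rr_min: float = 1.0
    rr_max: float = 1.0
    maf_low: float = 0.001
    maf_high: float = 0.01
    common: Sequence[CommonVariant] = ()
    prevalence: float = 0.01
    protective_prob: float = 0.0
    per_variant_form: str = "dominant"
    strat: StratSettings | None = None
    max_families_drawn: int = 100_000_000

    def __post_init__(self) -> None:
        if self.n_functional > self.L:
            raise ValueError("n_functional cannot exceed L (rare variants)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        if self.rr_min > self.rr_max:
            raise ValueError("rr_min must not exceed rr_max")
        if not self.maf_low < self.maf_high:
            raise ValueError("maf_low must be below maf_high")
        if self.per_variant_form not in _FORMS:
            raise ValueError(f"per_variant_form must be one of {_FORMS}")
        if self.L < 1 and not self.common:
            raise ValueError("region must contain at least one variant")
        self.common = tuple(
            c if isinstance(c, CommonVariant) else CommonVariant(**c) for c in self.common
        )

    @property
    def n_variants(self) -> int:
        return self.L + len(self.common)


@dataclasses.dataclass
class RegionModel:
    """A realized region: per-variant MAFs and RRs plus calibrated baseline.

    ``f0`` is the non-carrier penetrance chosen so the population
    prevalence matches the configured value exactly under independent
    sites.
    """

    mafs: np.ndarray
    rr: np.ndarray
    f0: float
    form: str = "dominant"


def assign_relative_risks(
    mafs: np.ndarray,
    functional_idx: np.ndarray,
    rr_min: float,
    rr_max: float,
    protective_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """RR vector with the smaller-MAF functional variants getting larger RRs.

    For functional variant j,
    ``rr_j = rr_max - (rr_max - rr_min) (q_j - q_min) / (q_max - q_min)``
    with q_min/q_max the extreme functional MAFs; a single functional
    variant (or all-equal MAFs) gets the midpoint.  Each functional RR is
    then independently inverted with probability ``protective_prob``.
    Nonfunctional variants keep RR 1.
    """
    if rr_min > rr_max:
        raise ValueError("rr_min must not exceed rr_max")
    rr = np.ones(len(mafs))
    idx = np.asarray(functional_idx, dtype=np.int64)
    if idx.size == 0:
        return rr
    q = mafs[idx]
    q_min, q_max = q.min(), q.max()
    if idx.size == 1 or q_min == q_max:
        rr[idx] = 0.5 * (rr_min + rr_max)
    else:
        rr[idx] = rr_max - (rr_max - rr_min) * (q - q_min) / (q_max - q_min)
    if protective_prob > 0:
        flip = rng.random(idx.size) < protective_prob
        rr[idx[flip]] = 1.0 / rr[idx[flip]]
    return rr


def _carrier_factor(q: np.ndarray, rr: np.ndarray, form: str) -> np.ndarray:
    """E[relative penetrance] per variant under HWE: 1 + (rr-1) P(at risk)."""
    if form == "dominant":
        return 1.0 + (rr - 1.0) * (1.0 - (1.0 - q) ** 2)
    if form == "multiplicative":
        return ((1.0 - q) + q * rr) ** 2
    if form == "recessive":
        return 1.0 + (rr - 1.0) * q**2
    raise ValueError(f"unknown form {form!r}")


def _penetrance_overflow_prob_bound(q, rr, form, f0) -> float:
    """Chernoff bound on P(penetrance of a random child > 1).

    Exceeding 1 requires co-carrying many high-RR variants, an event of
    astronomically small probability in realistic designs; the bound
    certifies that so the simulator may clip the tail at 1.
    """
    if f0 * np.prod(np.maximum(_max_weight(rr, form), 1.0)) <= 1.0:
        return 0.0  # penetrance can never exceed 1
    best = 1.0
    for s in (1.0, 2.0, 4.0, 8.0, 16.0, 32.0):
        # E[w^s] per variant, independent sites
        ew = _carrier_factor(q, np.maximum(rr, 1.0 / rr) ** s, form)
        with np.errstate(over="ignore"):
            bound = f0**s * float(np.prod(ew))
        best = min(best, bound)
    return best


def _max_weight(rr: np.ndarray, form: str) -> np.ndarray:
    w = np.maximum(rr, 1.0)
    if form == "multiplicative":
        return w * w
    return w


def calibrate_baseline_penetrance(
    mafs: np.ndarray, rr: np.ndarray, form: str, prevalence: float
) -> float:
    """Baseline (non-carrier) penetrance giving the target prevalence.

    ``f0 = prevalence / prod_j E[w_j]`` with w_j the per-variant relative
    penetrance; exact under independent sites.  Raises if the disease model
    would exceed penetrance 1 with non-negligible probability.
    """
    f0 = prevalence / float(np.prod(_carrier_factor(mafs, rr, form)))
    if _penetrance_overflow_prob_bound(mafs, rr, form, f0) > 1e-6:
        raise ValueError(
            "penetrance exceeds 1 with non-negligible probability; "
            "reduce relative risks, MAFs or prevalence"
        )
    return f0


def draw_region(config: SimulationConfig, rng: np.random.Generator | None = None) -> RegionModel:
    """Realize MAFs and relative risks for one region.

    Rare MAFs are uniform on [maf_low, maf_high]; common variants sit at
    their fixed MAFs.  RR interpolation runs separately over the rare
    functional set and over each group of common functional variants
    sharing an RR range (so a lone common functional variant gets its
    range's midpoint).
    """
    rng = np.random.default_rng() if rng is None else rng
    rare_mafs = rng.uniform(config.maf_low, config.maf_high, size=config.L)
    common_mafs = np.array([c.maf for c in config.common], dtype=np.float64)
    mafs = np.concatenate([rare_mafs, common_mafs]) if len(common_mafs) else rare_mafs
    rr = assign_relative_risks(
        mafs,
        np.arange(config.n_functional),
        config.rr_min,
        config.rr_max,
        config.protective_prob,
        rng,
    )
    # common functional variants, grouped by their RR range
    groups: dict[tuple[float, float], list[int]] = {}
    for k, c in enumerate(config.common):
        if c.functional:
            groups.setdefault((c.rr_min, c.rr_max), []).append(config.L + k)
    for (lo, hi), idx in groups.items():
        rr_grp = assign_relative_risks(
            mafs, np.array(idx), lo, hi, config.protective_prob, rng
        )
        rr[idx] = rr_grp[idx]
    f0 = calibrate_baseline_penetrance(mafs, rr, config.per_variant_form, config.prevalence)
    return RegionModel(mafs=mafs, rr=rr, f0=f0, form=config.per_variant_form)


def _transmit(parent_geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One allele per parent per variant: 0/2 transmit deterministically."""
    het = parent_geno == 1
    out = (parent_geno == 2).astype(np.int64)
    out[het] = rng.integers(0, 2, size=int(het.sum()))
    return out


def _relative_penetrance(child: np.ndarray, region: RegionModel) -> np.ndarray:
    log_rr = np.log(region.rr)
    if region.form == "dominant":
        expo = (child >= 1).astype(np.float64)
    elif region.form == "multiplicative":
        expo = child.astype(np.float64)
    else:  # recessive
        expo = (child == 2).astype(np.float64)
    return np.exp(expo @ log_rr)


def _sample_parents(
    n: int, mafs: np.ndarray, rng: np.random.Generator, pool: np.ndarray | None
) -> np.ndarray:
    if pool is None:
        return rng.binomial(2, mafs, size=(n, len(mafs)))
    hap = pool[rng.integers(0, pool.shape[0], size=2 * n)]
    return (hap[:n] + hap[n:]).astype(np.int64)


def simulate_trio_cohort(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    pool: np.ndarray | None = None,
    region: RegionModel | None = None,
) -> TrioCohort:
    """Rejection-sample trios with an affected child until ``n_trios``.

    Parents are drawn from HWE at the region MAFs (or from ``pool``, an
    (n_haplotypes, L) 0/1 haplotype matrix); each child receives one allele
    per parent per variant; the child is affected with probability
    ``f0 * prod_j rr_j^{indicator}`` (clipped at 1).  Deterministic given
    the generator state; errors out if the configured draw cap is exceeded.
    """
    if config.strat is not None:
        return simulate_stratified_cohort(config, rng=rng, seed=seed)
    rng = np.random.default_rng(seed) if rng is None else rng
    if region is None:
        region = draw_region(config, rng)
    n_target = config.n_trios
    keep_f, keep_m, keep_c = [], [], []
    n_kept = 0
    n_drawn = 0
    while n_kept < n_target:
        batch = int(np.ceil(1.5 * (n_target - n_kept) / config.prevalence)) + 100
        if n_drawn + batch > config.max_families_drawn:
            raise RuntimeError(
                "expected number of family draws exceeds the configured cap "
                f"({config.max_families_drawn}); increase prevalence or the cap"
            )
        father = _sample_parents(batch, region.mafs, rng, pool)
        mother = _sample_parents(batch, region.mafs, rng, pool)
        child = _transmit(father, rng) + _transmit(mother, rng)
        pen = np.minimum(region.f0 * _relative_penetrance(child, region), 1.0)
        affected = rng.random(batch) < pen
        n_drawn += batch
        if affected.any():
            keep_f.append(father[affected])
            keep_m.append(mother[affected])
            keep_c.append(child[affected])
            n_kept += int(affected.sum())
    father = np.concatenate(keep_f)[:n_target]
    mother = np.concatenate(keep_m)[:n_target]
    child = np.concatenate(keep_c)[:n_target]
    ids = [f"v{j + 1}" for j in range(config.L)] + [
        f"cv{k + 1}" for k in range(len(config.common))
    ]
    return TrioCohort(father, mother, child, ids)


def simulate_stratified_cohort(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> TrioCohort:
    """Two-subpopulation null cohort with family-level mixing.

    Each family belongs to population 2 with probability ``strat.prop2``
    (mating within its own population only); the populations have distinct
    per-variant MAFs (population 2's drawn from its own range) and
    prevalences.  Requires a null region: under no association the disease
    is independent of genotype, so ascertainment reduces to per-population
    Bernoulli acceptance.
    """
    if config.strat is None:
        raise ValueError("config.strat must be set")
    if config.n_functional != 0 or any(c.functional for c in config.common):
        raise ValueError("stratified simulation requires a null region (no functional variants)")
    rng = np.random.default_rng(seed) if rng is None else rng
    st = config.strat
    mafs1 = rng.uniform(config.maf_low, config.maf_high, size=config.L)
    mafs2 = rng.uniform(st.maf_low2, st.maf_high2, size=config.L)
    if config.common:
        cm = np.array([c.maf for c in config.common])
        mafs1 = np.concatenate([mafs1, cm])
        mafs2 = np.concatenate([mafs2, cm])
    n_target = config.n_trios
    prev = np.array([config.prevalence, st.prevalence2])
    keep_f, keep_m, keep_c = [], [], []
    n_kept = 0
    n_drawn = 0
    mean_prev = (1 - st.prop2) * config.prevalence + st.prop2 * st.prevalence2
    while n_kept < n_target:
        batch = int(np.ceil(1.5 * (n_target - n_kept) / mean_prev)) + 100
        if n_drawn + batch > config.max_families_drawn:
            raise RuntimeError("expected number of family draws exceeds the configured cap")
        pop = (rng.random(batch) < st.prop2).astype(np.int64)
        m = np.where(pop[:, None] == 0, mafs1[None, :], mafs2[None, :])
        father = rng.binomial(2, m)
        mother = rng.binomial(2, m)
        child = _transmit(father, rng) + _transmit(mother, rng)
        affected = rng.random(batch) < prev[pop]
        n_drawn += batch
        if affected.any():
            keep_f.append(father[affected])
            keep_m.append(mother[affected])
            keep_c.append(child[affected])
            n_kept += int(affected.sum())
    father = np.concatenate(keep_f)[:n_target]
    mother = np.concatenate(keep_m)[:n_target]
    child = np.concatenate(keep_c)[:n_target]
    ids = [f"v{j + 1}" for j in range(config.L)] + [
        f"cv{k + 1}" for k in range(len(config.common))
    ]
    return TrioCohort(father, mother, child, ids)


# ---------------------------------------------------------------------------
# Config (de)serialization for the CLI and experiment logs
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["common"] = [dataclasses.asdict(c) for c in config.common]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if d.get("strat") is not None and not isinstance(d["strat"], StratSettings):
        d["strat"] = StratSettings(**d["strat"])
    return SimulationConfig(**d)


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config_to_dict(config), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
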