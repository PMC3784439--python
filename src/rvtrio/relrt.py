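"""Random-effects mixture likelihood-ratio test for grouped variants.

Model
-----
Conditional on ``H_j`` heterozygous parents at variant j, the transmitted
count ``T_j`` is Binomial(H_j, p_j).  A nonfunctional variant has p_j = 1/2
exactly; a deleterious functional variant has 1/2 < p_j < 1, and with a
known relative-risk ceiling ``gamma`` (default 5) under a dominant model,
p_j <= delta_j where delta_j is the transmission probability at relative
risk gamma and the variant's estimated minor allele frequency.  Treating
p_j as a random effect — point mass at 1/2 with probability 1-pi, Uniform
(1/2, delta_j) with probability pi — gives the marginal

    P(T_j = t) = (1-pi) C(H,t) (1/2)^H
               + pi [F_delta(t+1, H-t+1) - F_1/2(t+1, H-t+1)]
                    / ((H+1)(delta - 1/2)),

with F_x the regularized incomplete beta (Beta cdf); the second line uses
C(H,t) B(t+1, H-t+1) = 1/(H+1).  The proportion of functional variants pi
is the single parameter; association testing is the boundary test of
pi = 0 via Lambda = 2 log L(pi_hat) - 2 log L(0), where L is the
pseudo-likelihood (product of per-variant marginals, treated as a
likelihood despite possible inter-variant dependence).  Validity is
restored by the within-family permutation null, which conditions on
parental genotypes: allele-frequency estimates and delta bounds are
computed once and reused across permutations, since flips change only the
children's transmissions.

Because each per-variant term is the log of a function linear in pi, the
pseudo log-likelihood is concave in pi; the permutation engine solves the
first-order condition by vectorized bisection, while :func:`fit_pi` uses a
grid-plus-refinement search for the public path (the two agree).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, special, stats

from .classical import TestResult, draw_flips
from .io import TrioCohort
from .transmission import TransmissionSummary, summarize_transmission

__all__ = [
    "PenetranceModel",
    "RandomEffectsSpec",
    "LrtResult",
    "transmission_probability",
    "estimate_maf",
    "delta_bound",
    "mixture_log_pmf",
    "pseudo_loglik",
    "fit_pi",
    "lrt_test",
]

_FORMS = ("dominant", "multiplicative", "recessive")


def _penetrance_weights(rr: float, form: str) -> np.ndarray:
    """Relative penetrance by child mutant-allele count (baseline cancels)."""
    if form == "dominant":
        return np.array([1.0, rr, rr])
    if form == "multiplicative":
        return np.array([1.0, rr, rr * rr])
    if form == "recessive":
        return np.array([1.0, 1.0, rr])
    raise ValueError(f"unknown model form {form!r}; expected one of {_FORMS}")


def transmission_probability(q: float, rr: float, form: str = "dominant") -> float:
    """P(heterozygous parent transmits the mutant | child affected).

    Computed by exact enumeration: the focal parent is heterozygous (HWE
    probability 2q(1-q), cancels), transmits its mutant or normal allele
    with probability 1/2 each; the other parent is drawn from HWE and
    transmits one allele; the child is affected with penetrance weight by
    its resulting count.  The ratio of the transmitting to the total mass
    is the transmission probability; it equals 1/2 at rr = 1 for every q
    and tends to rr/(1+rr) as q -> 0 under the dominant model.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"allele frequency must be in (0,1), got {q}")
    if rr < 0:
        raise ValueError(f"relative risk must be >= 0, got {rr}")
    w = _penetrance_weights(rr, form)
    # other parent's transmitted-allele distribution under HWE:
    # P(transmit mutant) = q^2 * 1 + 2q(1-q) * 1/2 = q
    p_other = np.array([1.0 - q, q])  # transmits normal / mutant
    b1 = 0.0  # focal het parent transmits mutant AND child affected
    b2 = 0.0  # focal het parent does not transmit AND child affected
    for a_other, pa in enumerate(p_other):
        b1 += 0.5 * pa * w[1 + a_other]
        b2 += 0.5 * pa * w[0 + a_other]
    return b1 / (b1 + b2)


@dataclasses.dataclass
class PenetranceModel:
    """Disease model at one variant: MAF, relative risk, inheritance form.

    ``b1``/``b2`` are the joint probabilities (up to the baseline-penetrance
    and heterozygosity factors, which cancel) of a heterozygous parent
    transmitting / not transmitting the mutant allele with an affected
    child; ``p = b1/(b1+b2)`` is the transmission probability.
    """

    q: float
    rr: float
    form: str = "dominant"

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0,1)")
        w = _penetrance_weights(self.rr, self.form)
        self.b1 = 0.5 * ((1 - self.q) * w[1] + self.q * w[2])
        self.b2 = 0.5 * ((1 - self.q) * w[0] + self.q * w[1])
        self.p = self.b1 / (self.b1 + self.b2)


def estimate_maf(cohort: TrioCohort) -> np.ndarray:
    """Per-variant mutant-allele frequency from the 4n parental alleles.

    Clamped to ``[1/(4n+2), 1 - 1/(4n+2)]`` so the delta bound stays
    defined for variants monomorphic among parents (such variants have
    H_j = 0 and contribute nothing to the likelihood anyway).
    """
    n = cohort.n_families
    q = (cohort.father.sum(axis=0) + cohort.mother.sum(axis=0)) / (4.0 * n)
    eps = 1.0 / (4 * n + 2)
    return np.clip(q, eps, 1.0 - eps)


def delta_bound(q_hat: float, gamma: float) -> float:
    """Largest transmission probability consistent with relative risk <= gamma.

    Uses the dominant-model transmission probability at the estimated MAF;
    decreasing in q_hat, so rarer variants are allowed larger effects.
    """
    if gamma <= 1:
        raise ValueError(f"gamma must exceed 1, got {gamma}")
    return transmission_probability(q_hat, gamma, "dominant")


@dataclasses.dataclass
class RandomEffectsSpec:
    """Fixed quantities of the mixture model for one cohort.

    gamma   relative-risk ceiling (default 5)
    q_hat   per-variant MAF estimates from parental alleles
    delta   per-variant transmission-probability bounds at gamma
    pi      mixture weight (functional-variant proportion), if fitted
    """

    gamma: float
    q_hat: np.ndarray
    delta: np.ndarray
    pi: float | None = None

    @classmethod
    def from_cohort(cls, cohort: TrioCohort, gamma: float = 5.0) -> "RandomEffectsSpec":
        q_hat = estimate_maf(cohort)
        delta = np.array([delta_bound(q, gamma) for q in q_hat])
        return cls(gamma=gamma, q_hat=q_hat, delta=delta)


@dataclasses.dataclass
class LrtResult:
    statistic: float  # Lambda = 2 log L(pi_hat) - 2 log L(0), >= 0
    pi_hat: float
    p_value: float
    n_perm: int
    seed: int
    gamma: float = 5.0


def _log_mixture_component(t: np.ndarray, H: int, delta: float) -> np.ndarray:
    """log of the Uniform(1/2, delta) marginal component at counts t."""
    a = t + 1.0
    b = H - t + 1.0
    diff = special.betainc(a, b, delta) - special.betainc(a, b, 0.5)
    diff = np.clip(diff, 1e-300, None)
    return np.log(diff) - np.log((H + 1.0) * (delta - 0.5))


def mixture_log_pmf(t, H, delta: float, pi: float):
    """Log marginal pmf of the transmitted count under the mixture model.

    ``pi = 0`` reduces exactly to log Binomial(t; H, 1/2); ``pi = 1`` to the
    Uniform(1/2, delta) random-effect marginal.  Stable in log space for H
    at least up to 10^4.  Accepts scalars or arrays of t.
    """
    if not 0.5 < delta < 1.0:
        raise ValueError(f"delta must be in (0.5, 1), got {delta}")
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must be in [0,1], got {pi}")
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any((t_arr < 0) | (t_arr > H)):
        raise ValueError("t must lie in [0, H]")
    log_binom = stats.binom.logpmf(t_arr, H, 0.5)
    if pi == 0.0:
        out = log_binom
    else:
        log_mix = _log_mixture_component(t_arr, H, delta)
        if pi == 1.0:
            out = log_mix
        else:
            out = np.logaddexp(np.log1p(-pi) + log_binom, np.log(pi) + log_mix)
    return out if np.ndim(t) else float(out)


def pseudo_loglik(pi: float, summary: TransmissionSummary, spec: RandomEffectsSpec) -> float:
    """Sum of per-variant log marginals; variants with H_j = 0 contribute 0."""
    if len(spec.delta) != summary.L:
        raise ValueError("spec.delta length does not match the number of variants")
    H = summary.H
    T = summary.T
    total = 0.0
    for j in range(summary.L):
        if H[j] > 0:
            total += float(mixture_log_pmf(int(T[j]), int(H[j]), float(spec.delta[j]), pi))
    return total


def fit_pi(summary: TransmissionSummary, spec: RandomEffectsSpec) -> float:
    """MLE of the functional proportion pi over [0, 1].

    Coarse grid (step 0.01) followed by bounded scalar refinement to 1e-6;
    boundary values 0 and 1 are admissible without warnings.
    """
    if not (summary.H > 0).any():
        raise ValueError("all variants are uninformative (no heterozygous parents)")
    grid = np.linspace(0.0, 1.0, 101)
    vals = np.array([pseudo_loglik(p, summary, spec) for p in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[k])
    res = optimize.minimize_scalar(
        lambda p: -pseudo_loglik(p, summary, spec),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    best = float(res.x) if -res.fun >= vals[k] else float(grid[k])
    # snap to the boundary when the refinement hugs it
    if best < 1e-6:
        best = 0.0
    elif best > 1 - 1e-6:
        best = 1.0
    return best


# ---------------------------------------------------------------------------
# Vectorized likelihood machinery shared by the test and the permutation null
# ---------------------------------------------------------------------------

def _ratio_tables(H: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """(L, max(H)+1) table of r_j(t) = mixture component / binomial pmf.

    The pseudo log-likelihood is sum_j log((1-pi) + pi r_j(T_j)) up to a
    pi-free constant, so the ratios are sufficient for the fit.  Variants
    with H_j = 0 get r = 1 (no contribution); entries beyond H_j are
    padding (never indexed).
    """
    L = len(H)
    width = int(H.max()) + 1
    R = np.ones((L, width))
    for j in range(L):
        Hj = int(H[j])
        if Hj == 0:
            continue
        t = np.arange(Hj + 1, dtype=np.float64)
        lr = _log_mixture_component(t, Hj, float(delta[j])) - stats.binom.logpmf(t, Hj, 0.5)
        R[j, : Hj + 1] = np.exp(np.clip(lr, -700.0, 700.0))
    return R


def _fit_pi_rows(r: np.ndarray, n_iter: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Maximize sum_j log(1 + pi (r_j - 1)) over pi in [0,1], row-wise.

    The objective is concave, so the first-order condition
    g(pi) = sum_j (r_j - 1) / (1 + pi (r_j - 1)) = 0 is solved by bisection,
    with boundary solutions detected from the sign of g at 0 and 1.
    Returns (pi_hat, Lambda) with Lambda = 2 * objective at pi_hat.
    """
    d = r - 1.0  # each > -1 up to underflow of the mixture component
    m = d.shape[0]
    pi = np.zeros(m)
    g0 = d.sum(axis=1)
    interior = g0 > 0.0
    if interior.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            g1 = np.where(interior, (d / np.maximum(1.0 + d, 1e-300)).sum(axis=1), -1.0)
        at_one = interior & (g1 >= 0.0)
        pi[at_one] = 1.0
        mid = interior & ~at_one
        if mid.any():
            dm = d[mid]
            lo = np.zeros(dm.shape[0])
            hi = np.ones(dm.shape[0])
            for _ in range(n_iter):
                p = 0.5 * (lo + hi)
                g = (dm / (1.0 + p[:, None] * dm)).sum(axis=1)
                up = g > 0.0
                lo = np.where(up, p, lo)
                hi = np.where(up, hi, p)
            pi[mid] = 0.5 * (lo + hi)
    with np.errstate(divide="ignore"):
        lam = 2.0 * np.log1p(np.clip(pi[:, None] * d, -1.0, None)).sum(axis=1)
    return pi, np.maximum(lam, 0.0)


def lrt_lambda_perm(
    summary: TransmissionSummary, spec: RandomEffectsSpec, flips: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(pi_hat, Lambda) for each flip vector (rows of ``flips``).

    delta and the MAF estimates are parental quantities, identical across
    permutation replicates; only T_j changes with the flips.
    """
    H = summary.H
    R = _ratio_tables(H, spec.delta)
    S = flips @ summary.X  # (m, L) signed sums
    T = (H[None, :] + S) // 2
    r = R[np.arange(summary.L)[None, :], T]
    return _fit_pi_rows(r)


def lrt_test(cohort: TrioCohort, gamma: float = 5.0, n_perm: int = 10000, seed: int = 0) -> LrtResult:
    """Run the mixture LRT with a within-family permutation p-value.

    MAF estimates and delta bounds are computed once from the parents;
    Lambda is recomputed on each complement-swapped summary with the same
    bounds, and the add-one permutation p-value is returned.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    spec = RandomEffectsSpec.from_cohort(cohort, gamma=gamma)
    summary = summarize_transmission(cohort)
    if not (summary.H > 0).any():
        raise ValueError("all variants are uninformative (no heterozygous parents)")
    rng = np.random.default_rng(seed)
    identity = np.ones((1, summary.n_families), dtype=np.int64)
    pi_obs, lam_obs = lrt_lambda_perm(summary, spec, identity)
    flips = draw_flips(rng, n_perm, summary.n_families)
    _, lam_perm = lrt_lambda_perm(summary, spec, flips)
    p = (1 + int((lam_perm >= lam_obs[0] - 1e-12).sum())) / (1 + n_perm)
    return LrtResult(
        statistic=float(lam_obs[0]),
        pi_hat=float(pi_obs[0]),
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        gamma=gamma,
    )
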