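"""The three comparison tests on transmission summaries.

* ``max_tdt`` — the largest per-variant transmission disequilibrium
  statistic (b-c)^2/(b+c), procedure T_s;
* ``multivariable_statistic`` — the multi-marker score test
  U' V^- U with U the column sums of X and V = sum_i X_i X_i' the null
  covariance estimate (Moore–Penrose generalized inverse);
* ``combined_tdt`` — the collapsing test pooling transmitted and
  non-transmitted mutant alleles across all variants, (B-C)^2/(B+C).

None of these has a convenient exact null distribution with correlated
variants, so p-values come from the within-family permutation null
(:func:`permutation_pvalue`), which is valid under population
stratification because it conditions on parental genotypes.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .transmission import TransmissionSummary, complement_swap

__all__ = [
    "TestResult",
    "MultivariableScore",
    "tdt_statistic",
    "max_tdt",
    "combined_tdt",
    "multivariable_score",
    "multivariable_statistic",
    "multivariable_chi2_pvalue",
    "permutation_pvalue",
]


@dataclasses.dataclass
class TestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int


@dataclasses.dataclass
class MultivariableScore:
    """Score vector U, null covariance V and its numerical rank."""

    U: np.ndarray
    V: np.ndarray
    rank: int


def tdt_statistic(b: float, c: float) -> float:
    """Classical TDT statistic (b-c)^2/(b+c); 0 for an uninformative variant."""
    if b < 0 or c < 0:
        raise ValueError("transmission counts must be non-negative")
    tot = b + c
    if tot == 0:
        return 0.0
    return (b - c) ** 2 / tot


def max_tdt(summary: TransmissionSummary) -> float:
    """Largest single-variant TDT statistic over the region (T_s)."""
    return float(np.max(_tdt_columns(summary.X.sum(axis=0), summary.H)))


def combined_tdt(summary: TransmissionSummary) -> float:
    """Collapsing TDT on pooled counts B = sum_j b_j, C = sum_j c_j."""
    S = int(summary.X.sum())        # B - C
    H = int(summary.H.sum())        # B + C
    return 0.0 if H == 0 else float(S) ** 2 / H


def multivariable_score(summary: TransmissionSummary) -> MultivariableScore:
    X = summary.X.astype(np.float64)
    U = X.sum(axis=0)
    V = X.T @ X
    rank = int(np.linalg.matrix_rank(V)) if V.any() else 0
    return MultivariableScore(U=U, V=V, rank=rank)


def _pinv_quadform(U: np.ndarray, V: np.ndarray) -> float:
    if not V.any():
        return 0.0
    return float(U @ np.linalg.pinv(V, hermitian=True) @ U)


def multivariable_statistic(summary: TransmissionSummary) -> float:
    """Quadratic-form score statistic U' V^- U (T_mult).

    Rank-deficient V — expected with rare variants — is handled by the
    Moore–Penrose pseudo-inverse; the statistic is invariant to variant
    reordering and to duplicated columns.
    """
    score = multivariable_score(summary)
    return _pinv_quadform(score.U, score.V)


def multivariable_chi2_pvalue(summary: TransmissionSummary) -> float:
    """Asymptotic chi-square p-value with df = rank(V).

    Diagnostic only: it is conservative unless the number of markers is
    small, which is why the permutation p-value is the primary path.
    """
    from scipy import stats

    score = multivariable_score(summary)
    if score.rank == 0:
        return 1.0
    stat = _pinv_quadform(score.U, score.V)
    return float(stats.chi2.sf(stat, df=score.rank))


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def draw_flips(rng: np.random.Generator, n_perm: int, n_families: int) -> np.ndarray:
    """(n_perm, n_families) matrix of independent +/-1 fair-coin flips."""
    return rng.integers(0, 2, size=(n_perm, n_families)) * 2 - 1


def _tdt_columns(S: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Per-variant (b-c)^2/(b+c) from signed sums S and totals H."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(H > 0, S.astype(np.float64) ** 2 / H, 0.0)
    return out


def perm_stats_max_tdt(S: np.ndarray, H: np.ndarray) -> np.ndarray:
    return _tdt_columns(S, H).max(axis=-1)


def perm_stats_combined_tdt(S: np.ndarray, H: np.ndarray) -> np.ndarray:
    tot = H.sum()
    s = S.sum(axis=-1).astype(np.float64)
    return np.zeros_like(s) if tot == 0 else s**2 / tot


def perm_stats_multivariable(S: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Quadratic forms S_p' V^- S_p for each permutation row.

    V = sum_i X_i X_i' is invariant under per-family sign flips, so one
    pseudo-inverse serves every permutation.
    """
    if not V.any():
        return np.zeros(S.shape[0])
    Vp = np.linalg.pinv(V, hermitian=True)
    return np.einsum("pj,jk,pk->p", S, Vp, S)


def permutation_pvalue(
    stat_fn: Callable[[TransmissionSummary], float],
    summary: TransmissionSummary,
    n_perm: int,
    seed: int,
) -> TestResult:
    """Within-family permutation p-value for any statistic on a summary.

    Draws ``n_perm`` independent +/-1 flip vectors, recomputes the statistic
    on each complement-swapped summary, and returns the add-one estimator
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)``, which is a valid
    p-value (never zero) and deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(stat_fn(summary))
    flips = draw_flips(rng, n_perm, summary.n_families)
    exceed = 0
    for i in range(n_perm):
        if float(stat_fn(complement_swap(summary, flips[i]))) >= observed - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return TestResult(statistic=observed, p_value=p, n_perm=n_perm, seed=seed)
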