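"""Transmission counts from trios: the sufficient data for all four tests.

For family ``i`` and variant ``j`` the signed transmission difference is

    X_ij = 2*g_child - g_father - g_mother,

the number of mutant alleles transmitted minus non-transmitted.  Only
heterozygous parents are informative: |X_ij| <= het_parents_ij, and with
``H_j`` the total heterozygous parents at variant j, the transmitted count
``b_j`` and non-transmitted count ``c_j`` from heterozygous parents satisfy
``b_j + c_j = H_j`` and ``b_j - c_j = sum_i X_ij``.  Under no linkage and no
association, ``b_j | H_j ~ Binomial(H_j, 1/2)`` regardless of population
structure — the basis of every test here and of the permutation null.

The permutation null swaps, within a family, the child's transmitted
genotype vector with its complement ``g_f + g_m - g_c`` (one +/-1 flip per
family applied to the whole cross-variant row of X).  This conditions on the
heterozygous-parent counts, preserves cross-variant dependence, and needs
genotypes only — no phase.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import TrioCohort

__all__ = ["TransmissionSummary", "summarize_transmission", "complement_swap"]


@dataclasses.dataclass
class TransmissionSummary:
    """Per-family signed transmissions and per-variant tallies."""

    X: np.ndarray            # (n_families, L) signed transmitted-minus-non-transmitted
    het_parents: np.ndarray  # (n_families, L) heterozygous-parent counts in {0,1,2}

    @property
    def n_families(self) -> int:
        return self.X.shape[0]

    @property
    def L(self) -> int:
        return self.X.shape[1]

    @property
    def H(self) -> np.ndarray:
        """Per-variant total heterozygous parents."""
        return self.het_parents.sum(axis=0)

    @property
    def b(self) -> np.ndarray:
        """Per-variant mutant alleles transmitted from heterozygous parents."""
        return (self.H + self.X.sum(axis=0)) // 2

    @property
    def c(self) -> np.ndarray:
        """Per-variant mutant alleles not transmitted from heterozygous parents."""
        return self.H - self.b

    @property
    def T(self) -> np.ndarray:
        """Alias for ``b``: the transmitted-count statistic per variant."""
        return self.b


def summarize_transmission(cohort: TrioCohort) -> TransmissionSummary:
    """Reduce a Mendelian-consistent cohort to its transmission summary.

    Homozygous parents contribute nothing to either X or H.
    """
    X = 2 * cohort.child - cohort.father - cohort.mother
    het = (cohort.father == 1).astype(np.int64) + (cohort.mother == 1)
    # |X| <= het holds for Mendelian data; assert cheaply as an internal check
    if (np.abs(X) > het).any():
        raise ValueError("transmission difference exceeds heterozygous-parent count; "
                         "cohort is not Mendelian-consistent")
    return TransmissionSummary(X=X, het_parents=het)


def complement_swap(summary: TransmissionSummary, flips: np.ndarray) -> TransmissionSummary:
    """Apply per-family +/-1 flips to the rows of X.

    ``flips[i] == -1`` exchanges family i's transmitted and non-transmitted
    genotype vectors; heterozygous-parent counts are unchanged, so b and c
    are exchanged wherever the net family contribution flips sign.
    Applying the same flips twice is the identity.
    """
    flips = np.asarray(flips)
    if flips.shape != (summary.n_families,):
        raise ValueError(f"flips must have shape ({summary.n_families},), got {flips.shape}")
    if not np.isin(flips, (-1, 1)).all():
        raise ValueError("flips must contain only +1 and -1")
    return TransmissionSummary(X=summary.X * flips[:, None], het_parents=summary.het_parents)
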