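"""Reading and writing case-parents trio genotype data and test results.

A :class:`TrioCohort` holds, for ``n_families`` father/mother/affected-child
trios and ``L`` biallelic variants, the per-individual mutant-allele counts
(0, 1 or 2).  The "mutant" allele is the allele whose transmissions are
counted by the association tests; by convention it is the minor allele, but
the VCF reader can also count the ALT allele directly.

Cohorts can be loaded from a VCF + PED pair or from a flat TSV table, and
are validated for Mendelian consistency on construction: a child's count at
every variant must be attainable from one transmitted allele per parent.
Families with any missing genotype are dropped (the count is kept on the
cohort) because the tests and the within-family permutation null require
complete per-family genotype vectors.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .classical import TestResult

__all__ = [
    "TrioCohort",
    "MendelianError",
    "read_trio_vcf",
    "read_trio_tsv",
    "write_trio_tsv",
    "write_trio_vcf",
    "write_results",
    "read_results",
]


class MendelianError(ValueError):
    """A child genotype is impossible given its parents' genotypes."""


@dataclasses.dataclass
class TrioCohort:
    """Mutant-allele counts for complete case-parents trios.

    Attributes
    ----------
    father, mother, child
        ``(n_families, L)`` integer matrices with entries in {0, 1, 2}.
    variant_ids
        Per-variant identifiers (length ``L``).
    variant_positions
        Optional 1-based coordinates, length ``L``.
    mutant_allele
        Per-variant label of the allele being counted.
    n_excluded
        Families dropped at load time because of missing genotypes.
    """

    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray
    variant_ids: list[str]
    variant_positions: np.ndarray | None = None
    mutant_allele: list[str] | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.father = np.asarray(self.father, dtype=np.int64)
        self.mother = np.asarray(self.mother, dtype=np.int64)
        self.child = np.asarray(self.child, dtype=np.int64)
        if self.father.ndim != 2:
            raise ValueError("genotype matrices must be 2-D (families x variants)")
        if not (self.father.shape == self.mother.shape == self.child.shape):
            raise ValueError("father/mother/child matrices must share a shape")
        n, L = self.father.shape
        if n < 1 or L < 1:
            raise ValueError("cohort needs at least one family and one variant")
        if len(self.variant_ids) != L:
            raise ValueError("variant_ids length does not match variant count")
        for name, g in (("father", self.father), ("mother", self.mother), ("child", self.child)):
            bad = (g < 0) | (g > 2)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"{name} genotype out of range at family {i}, variant {self.variant_ids[j]}: {g[i, j]}"
                )
        self.validate_mendelian()

    @property
    def n_families(self) -> int:
        return self.father.shape[0]

    @property
    def n_variants(self) -> int:
        return self.father.shape[1]

    def validate_mendelian(self) -> None:
        """Raise :class:`MendelianError` naming family and variant on violation.

        A parent with count 0 can only transmit 0 mutant alleles, count 2 only
        1, and a heterozygote either; hence the child count must lie in
        ``[(f==2)+(m==2), (f>=1)+(m>=1)]``.
        """
        lo = (self.father == 2).astype(np.int64) + (self.mother == 2)
        hi = (self.father >= 1).astype(np.int64) + (self.mother >= 1)
        bad = (self.child < lo) | (self.child > hi)
        if bad.any():
            rows = np.argwhere(bad)
            msgs = [
                f"family {i} variant {self.variant_ids[j]} "
                f"({self.father[i, j]}x{self.mother[i, j]} -> {self.child[i, j]})"
                for i, j in rows[:10]
            ]
            raise MendelianError("Mendelian-inconsistent trio(s): " + "; ".join(msgs))


# ---------------------------------------------------------------------------
# TSV cohort dialect: one row per family, columns father_v1..father_vL,
# mother_v1..mother_vL, child_v1..child_vL.
# ---------------------------------------------------------------------------

def read_trio_tsv(path: str | Path) -> TrioCohort:
    """Load a cohort from the flat TSV dialect."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty cohort table")
    cols = list(df.columns)
    members = ("father_", "mother_", "child_")
    by_member: dict[str, list[str]] = {m: [c for c in cols if c.startswith(m)] for m in members}
    L = len(by_member["father_"])
    if L == 0 or any(len(v) != L for v in by_member.values()):
        raise ValueError(f"{path}: expected father_*/mother_*/child_* column triples")
    variant_ids = [c[len("father_"):] for c in by_member["father_"]]
    mats = {}
    for m in members:
        sub = df[by_member[m]]
        arr = sub.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or np.isnan(arr.astype(float)).any():
            raise ValueError(f"{path}: non-numeric or missing entry in {m} columns")
        arr = arr.astype(np.int64)
        bad = (arr < 0) | (arr > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"{path}: entry {arr[i, j]} not in {{0,1,2}} at row {i}, column {by_member[m][j]}"
            )
        mats[m] = arr
    return TrioCohort(mats["father_"], mats["mother_"], mats["child_"], variant_ids)


def write_trio_tsv(cohort: TrioCohort, path: str | Path) -> None:
    """Write the TSV dialect read back by :func:`read_trio_tsv`."""
    data = {}
    for member, mat in (("father", cohort.father), ("mother", cohort.mother), ("child", cohort.child)):
        for j, vid in enumerate(cohort.variant_ids):
            data[f"{member}_{vid}"] = mat[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF + PED
# ---------------------------------------------------------------------------

def _read_ped_trios(ped_path: str | Path) -> list[tuple[str, str, str, str]]:
    """Return (family, father, mother, child) sample-id tuples from a 6-column PED."""
    trios = []
    with open(ped_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{ped_path}: PED line has fewer than 6 columns: {line!r}")
            fam, iid, fid, mid = fields[0], fields[1], fields[2], fields[3]
            if fid not in ("0", "") and mid not in ("0", ""):
                trios.append((fam, fid, mid, iid))
    if not trios:
        raise ValueError(f"{ped_path}: no complete trios (rows with both parents) found")
    return trios


def read_trio_vcf(vcf_path: str | Path, ped_path: str | Path, mutant_rule: str = "minor") -> TrioCohort:
    """Load trios from a biallelic-SNV VCF and a PED pedigree.

    ``mutant_rule='alt'`` counts the VCF ALT allele; ``'minor'`` counts the
    rarer allele among the parental chromosomes (4n alleles), so that
    ascertained children cannot flip the label.  Multiallelic or non-SNV
    records and pedigree samples absent from the VCF are errors.  Families
    with a missing genotype at any variant are dropped and counted in
    ``n_excluded``.
    """
    from cyvcf2 import VCF

    if mutant_rule not in ("minor", "alt"):
        raise ValueError(f"mutant_rule must be 'minor' or 'alt', got {mutant_rule!r}")
    trios = _read_ped_trios(ped_path)
    vcf = VCF(str(vcf_path))
    sample_index = {s: i for i, s in enumerate(vcf.samples)}
    for fam, fid, mid, cid in trios:
        for sid in (fid, mid, cid):
            if sid not in sample_index:
                raise ValueError(f"pedigree sample {sid!r} (family {fam}) absent from VCF")

    variant_ids: list[str] = []
    positions: list[int] = []
    alt_counts: list[np.ndarray] = []  # per-variant ALT dosage for all samples
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS} {rec.REF}->{','.join(rec.ALT)} is not a biallelic SNV"
            )
        gt = rec.genotype.array()  # (n_samples, ploidy+1); last col = phasedness
        alleles = gt[:, :2]
        dose = np.where((alleles < 0).any(axis=1), -1, alleles.clip(min=0).sum(axis=1))
        variant_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        positions.append(rec.POS)
        alt_counts.append(dose.astype(np.int64))
    if not alt_counts:
        raise ValueError(f"{vcf_path}: no variant records")
    dose_mat = np.stack(alt_counts, axis=1)  # (n_samples, L)

    fa_idx = [sample_index[t[1]] for t in trios]
    mo_idx = [sample_index[t[2]] for t in trios]
    ch_idx = [sample_index[t[3]] for t in trios]
    father = dose_mat[fa_idx]
    mother = dose_mat[mo_idx]
    child = dose_mat[ch_idx]
    complete = ((father >= 0) & (mother >= 0) & (child >= 0)).all(axis=1)
    n_excluded = int((~complete).sum())
    if not complete.any():
        raise ValueError("all families have missing genotypes; nothing to analyse")
    father, mother, child = father[complete], mother[complete], child[complete]

    mutant = ["ALT"] * len(variant_ids)
    if mutant_rule == "minor":
        # parental ALT allele frequency over 4n chromosomes decides the label
        alt_freq = (father.sum(axis=0) + mother.sum(axis=0)) / (4.0 * father.shape[0])
        flip = alt_freq > 0.5
        for j in np.flatnonzero(flip):
            father[:, j] = 2 - father[:, j]
            mother[:, j] = 2 - mother[:, j]
            child[:, j] = 2 - child[:, j]
            mutant[j] = "REF"
    return TrioCohort(
        father,
        mother,
        child,
        variant_ids,
        variant_positions=np.asarray(positions, dtype=np.int64),
        mutant_allele=mutant,
        n_excluded=n_excluded,
    )


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
)


def write_trio_vcf(cohort: TrioCohort, vcf_path: str | Path, ped_path: str | Path) -> None:
    """Emit a cohort as an unphased biallelic-SNV VCF plus matching PED.

    Mutant-allele counts are written as ALT dosages, so reading back with
    ``mutant_rule='alt'`` reproduces the cohort exactly.
    """
    n, L = cohort.father.shape
    samples: list[str] = []
    rows: list[tuple[str, str, str, str]] = []
    for i in range(n):
        fid, mid, cid = f"F{i}_fa", f"F{i}_mo", f"F{i}_ch"
        samples += [fid, mid, cid]
        rows.append((f"F{i}", fid, mid, cid))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    pos = (
        cohort.variant_positions
        if cohort.variant_positions is not None
        else np.arange(1, L + 1, dtype=np.int64) * 100
    )
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(L):
            calls = []
            for i in range(n):
                calls += [
                    gt_map[int(cohort.father[i, j])],
                    gt_map[int(cohort.mother[i, j])],
                    gt_map[int(cohort.child[i, j])],
                ]
            fh.write(
                f"1\t{int(pos[j])}\t{cohort.variant_ids[j]}\tA\tC\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )
    with open(ped_path, "w") as fh:
        for fam, fid, mid, cid in rows:
            fh.write(f"{fam}\t{fid}\t0\t0\t1\t1\n")
            fh.write(f"{fam}\t{mid}\t0\t0\t2\t1\n")
            fh.write(f"{fam}\t{cid}\t{fid}\t{mid}\t1\t2\n")


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

_RESULT_FIELDS = ("test", "statistic", "p_value", "n_perm", "seed")


def _result_records(results: Mapping[str, "TestResult"]) -> list[dict]:
    if not results:
        raise ValueError("results map is empty")
    recs = []
    for name, res in results.items():
        rec = {
            "test": name,
            "statistic": float(res.statistic),
            "p_value": float(res.p_value),
            "n_perm": int(res.n_perm),
            "seed": int(res.seed),
        }
        for extra in ("pi_hat", "gamma"):
            if hasattr(res, extra):
                rec[extra] = float(getattr(res, extra))
        recs.append(rec)
    return recs


def write_results(results: Mapping[str, "TestResult"], path: str | Path, format: str = "tsv") -> None:
    """Write one record per test (name, statistic, p-value, permutations, seed).

    Output is bit-stable across runs with identical inputs.
    """
    recs = _result_records(results)
    if format == "tsv":
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(recs, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")


def read_results(path: str | Path, format: str = "tsv") -> dict[str, "TestResult"]:
    """Read back a results file written by :func:`write_results`."""
    from .classical import TestResult

    if format == "tsv":
        recs: Iterable[dict] = pd.read_csv(path, sep="\t").to_dict("records")
    elif format == "json":
        with open(path) as fh:
            recs = json.load(fh)
    else:
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
    out = {}
    for rec in recs:
        out[rec["test"]] = TestResult(
            statistic=float(rec["statistic"]),
            p_value=float(rec["p_value"]),
            n_perm=int(rec["n_perm"]),
            seed=int(rec["seed"]),
        )
    return out
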