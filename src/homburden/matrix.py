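"""Core in-memory container for a case-control genotype cohort.

A :class:`CohortMatrix` holds per-variant annotations (gene symbol,
consequence class, CADD phred, maximum population allele frequency, indel
flag), per-subject group labels, and the dense call-level arrays (alt-allele
count, genotype quality, ref/alt read depths) that the QC filters and the
homozygous-burden statistics operate on.

Conventions
-----------
* ``geno`` holds the alt-allele count per call: 0, 1, 2, or ``MISSING``
  (−1) for a missing / invalidated genotype.
* ``gq`` is the phred-scaled genotype quality; ``−1`` marks "not provided".
* ``ref_reads`` / ``alt_reads`` are allelic depths; ``−1`` marks
  "not provided" (e.g. a VCF without the AD FORMAT field).
* Variant annotations live in a :class:`pandas.DataFrame` with one row per
  variant; rows align with axis 0 of the call arrays, subjects with axis 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: Annotation columns every CohortMatrix carries, in canonical order.
VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "csq_class",
    "cadd",
    "popmax_af",
    "is_indel",
]

#: Recognised consequence classes; anything else is handled as "other".
CSQ_CLASSES = ("missense", "nonsense", "splice_junction", "other")


class CohortValidationError(ValueError):
    """Raised when a cohort matrix or configuration fails validation."""


@dataclass
class CohortMatrix:
    """Variants × subjects genotype calls plus case/control labels.

    Parameters
    ----------
    variants
        One row per variant with the columns in :data:`VARIANT_COLUMNS`.
    subject_ids
        Subject identifiers, aligned with axis 1 of the call arrays.
    is_case
        Boolean group label per subject (True = case).
    geno
        ``(n_variants, n_subjects)`` int8 array of alt-allele counts with
        ``MISSING`` for missing calls.
    gq
        Same shape, phred genotype quality (int16, −1 if absent).
    ref_reads, alt_reads
        Same shape, allelic depths (int32, −1 if absent).
    """

    variants: pd.DataFrame
    subject_ids: np.ndarray
    is_case: np.ndarray
    geno: np.ndarray
    gq: np.ndarray
    ref_reads: np.ndarray
    alt_reads: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.gq = np.asarray(self.gq, dtype=np.int16)
        self.ref_reads = np.asarray(self.ref_reads, dtype=np.int32)
        self.alt_reads = np.asarray(self.alt_reads, dtype=np.int32)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check internal consistency; raise CohortValidationError if broken."""
        n_var = len(self.variants)
        n_sub = len(self.subject_ids)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise CohortValidationError(
                f"variant table lacks columns: {missing_cols}"
            )
        for name in ("geno", "gq", "ref_reads", "alt_reads"):
            arr = getattr(self, name)
            if arr.shape != (n_var, n_sub):
                raise CohortValidationError(
                    f"{name} has shape {arr.shape}, expected ({n_var}, {n_sub})"
                )
        if self.is_case.shape != (n_sub,):
            raise CohortValidationError("is_case length does not match subjects")
        if n_var and not ((self.geno >= MISSING) & (self.geno <= 2)).all():
            raise CohortValidationError("geno values must be in {-1, 0, 1, 2}")
        if len(np.unique(self.subject_ids)) != n_sub:
            raise CohortValidationError("duplicate subject IDs")

    # ------------------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    @property
    def variant_ids(self) -> pd.Series:
        v = self.variants
        return (
            v["chrom"].astype(str)
            + ":"
            + v["pos"].astype(str)
            + ":"
            + v["ref"].astype(str)
            + ">"
            + v["alt"].astype(str)
        )

    def is_missing(self) -> np.ndarray:
        return self.geno == MISSING

    # ------------------------------------------------------------------
    def copy(self) -> "CohortMatrix":
        return CohortMatrix(
            variants=self.variants.copy(),
            subject_ids=self.subject_ids.copy(),
            is_case=self.is_case.copy(),
            geno=self.geno.copy(),
            gq=self.gq.copy(),
            ref_reads=self.ref_reads.copy(),
            alt_reads=self.alt_reads.copy(),
        )

    def take_variants(self, index: np.ndarray) -> "CohortMatrix":
        """Return a new matrix restricted to the given variant positions."""
        index = np.asarray(index)
        return CohortMatrix(
            variants=self.variants.iloc[index].reset_index(drop=True),
            subject_ids=self.subject_ids,
            is_case=self.is_case,
            geno=self.geno[index],
            gq=self.gq[index],
            ref_reads=self.ref_reads[index],
            alt_reads=self.alt_reads[index],
        )

    def take_subjects(self, index: np.ndarray) -> "CohortMatrix":
        """Return a new matrix restricted to the given subject positions."""
        index = np.asarray(index)
        return CohortMatrix(
            variants=self.variants,
            subject_ids=self.subject_ids[index],
            is_case=self.is_case[index],
            geno=self.geno[:, index],
            gq=self.gq[:, index],
            ref_reads=self.ref_reads[:, index],
            alt_reads=self.alt_reads[:, index],
        )

    def equals(self, other: "CohortMatrix") -> bool:
        """Strict equality of labels, calls and annotations.

        Float annotations (CADD, popmax AF) are compared to within 1e-5
        relative tolerance so that a round-trip through a text format with
        finite precision still compares equal.
        """
        if self.geno.shape != other.geno.shape:
            return False
        if not (
            np.array_equal(self.subject_ids, other.subject_ids)
            and np.array_equal(self.is_case, other.is_case)
            and np.array_equal(self.geno, other.geno)
            and np.array_equal(self.gq, other.gq)
            and np.array_equal(self.ref_reads, other.ref_reads)
            and np.array_equal(self.alt_reads, other.alt_reads)
        ):
            return False
        a, b = self.variants, other.variants
        for col in ("chrom", "ref", "alt", "gene", "csq_class"):
            if not (a[col].astype(str) == b[col].astype(str)).all():
                return False
        for col in ("pos", "is_indel"):
            if not (a[col].to_numpy() == b[col].to_numpy()).all():
                return False
        for col in ("cadd", "popmax_af"):
            if not np.allclose(
                a[col].to_numpy(float), b[col].to_numpy(float), rtol=1e-5, atol=1e-9
            ):
                return False
        return True


def make_variant_table(
    chrom,
    pos,
    ref,
    alt,
    gene,
    csq_class,
    cadd,
    popmax_af,
    is_indel,
) -> pd.DataFrame:
    """Assemble a variant annotation table in canonical column order."""
    return pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "ref": pd.Series(ref, dtype=str),
            "alt": pd.Series(alt, dtype=str),
            "gene": pd.Series(gene, dtype=str),
            "csq_class": pd.Series(csq_class, dtype=str),
            "cadd": pd.Series(cadd, dtype=float),
            "popmax_af": pd.Series(popmax_af, dtype=float),
            "is_indel": pd.Series(is_indel, dtype=bool),
        }
    )
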