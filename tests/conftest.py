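import numpy as np
import pytest

from homburden import CohortConfig, CohortMatrix, generate_cohort, make_variant_table


@pytest.fixture(scope="session")
def small_cohort():
    """A small null cohort with injected QC artefacts (session-wide)."""
    cfg = CohortConfig(
        n_cases=120,
        n_controls=150,
        n_genes=200,
        target_set_size=20,
        variants_per_gene=6.0,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """A cohort with a planted case excess of homozygous carriers."""
    cfg = CohortConfig(
        n_cases=300,
        n_controls=300,
        n_genes=400,
        target_set_size=40,
        variants_per_gene=6.0,
        planted_case_hom_excess=6,
        seed=7,
    )
    return generate_cohort(cfg)


def build_matrix(
    geno,
    is_case,
    gq=None,
    ref_reads=None,
    alt_reads=None,
    gene=None,
    csq_class=None,
    cadd=None,
    popmax_af=None,
    is_indel=None,
):
    """Hand-build a CohortMatrix from a genotype array for targeted tests."""
    geno = np.asarray(geno, dtype=np.int8)
    n_var, n_sub = geno.shape
    if gq is None:
        gq = np.full_like(geno, 99, dtype=np.int16)
    if ref_reads is None:
        depth = 50
        alt_reads = np.where(geno == 2, depth, np.where(geno == 1, depth // 2, 0))
        ref_reads = depth - alt_reads
    variants = make_variant_table(
        chrom=["1"] * n_var,
        pos=list(range(100, 100 + n_var)),
        ref=["A"] * n_var,
        alt=["C"] * n_var,
        gene=gene if gene is not None else [f"G{i:03d}" for i in range(n_var)],
        csq_class=csq_class if csq_class is not None else ["missense"] * n_var,
        cadd=cadd if cadd is not None else [25.0] * n_var,
        popmax_af=popmax_af if popmax_af is not None else [1e-5] * n_var,
        is_indel=is_indel if is_indel is not None else [False] * n_var,
    )
    return CohortMatrix(
        variants=variants,
        subject_ids=np.array([f"S{i:04d}" for i in range(n_sub)], dtype=object),
        is_case=np.asarray(is_case, dtype=bool),
        geno=geno,
        gq=np.asarray(gq, dtype=np.int16),
        ref_reads=np.asarray(ref_reads, dtype=np.int32),
        alt_reads=np.asarray(alt_reads, dtype=np.int32),
    )
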