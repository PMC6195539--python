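"""VCF, gene-set and subject-list I/O.

The cohort travels as VCF v4.2 with ``FORMAT GT:GQ:AD`` and the INFO keys
``GENE`` (symbol), ``CSQ_CLASS`` (missense | nonsense | splice_junction |
other), ``CADD`` (phred float), ``POPMAX_AF`` (float) and ``INDEL``
(flag).  Coordinates are 1-based per the VCF standard.  Reading goes
through :mod:`cyvcf2`; writing emits the dialect directly, and a
write → read round trip is lossless for genotypes, GQ, allelic depths and
annotations.

Gene sets are plain text, one symbol per line; subject exclusion lists
one ID per line.  ``#`` comment lines and blank lines are ignored.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .matrix import MISSING, CohortMatrix, make_variant_table

__all__ = [
    "write_cohort_vcf",
    "read_vcf",
    "read_gene_list",
    "write_gene_list",
    "read_subject_list",
]

_HEADER = """\
##fileformat=VCFv4.2
##source=homburden
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class (missense|nonsense|splice_junction|other)">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">
##INFO=<ID=POPMAX_AF,Number=1,Type=Float,Description="Maximum allele frequency across population reference panels">
##INFO=<ID=INDEL,Number=0,Type=Flag,Description="Variant is an insertion/deletion">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Phred-scaled genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_cohort_vcf(matrix: CohortMatrix, path) -> None:
    """Write a cohort as VCF v4.2 (plus a sidecar ``.groups.tsv``).

    VCF has no standard slot for case/control labels, so group membership
    is written next to the VCF as ``<path>.groups.tsv`` with columns
    ``subject_id`` and ``group`` (case | control);
    :func:`read_vcf` picks it up automatically and falls back to
    an explicit label file argument otherwise.
    """
    path = Path(path)
    matrix.validate()
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for chrom in dict.fromkeys(matrix.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(matrix.subject_ids.astype(str))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
            + ("\t" + cols if len(matrix.subject_ids) else "")
            + "\n"
        )
        v = matrix.variants
        for i in range(matrix.n_variants):
            info = (
                f"GENE={v.at[i, 'gene']};CSQ_CLASS={v.at[i, 'csq_class']};"
                f"CADD={float(v.at[i, 'cadd']):.6g};"
                f"POPMAX_AF={float(v.at[i, 'popmax_af']):.6g}"
            )
            if bool(v.at[i, "is_indel"]):
                info += ";INDEL"
            fields = [
                str(v.at[i, "chrom"]),
                str(int(v.at[i, "pos"])),
                ".",
                str(v.at[i, "ref"]),
                str(v.at[i, "alt"]),
                ".",
                "PASS",
                info,
                "GT:GQ:AD",
            ]
            geno = matrix.geno[i]
            gq = matrix.gq[i]
            rr = matrix.ref_reads[i]
            ar = matrix.alt_reads[i]
            calls = [
                f"{_GT[int(geno[j])]}"
                f":{gq[j] if gq[j] >= 0 else '.'}"
                f":{f'{rr[j]},{ar[j]}' if rr[j] >= 0 and ar[j] >= 0 else '.'}"
                for j in range(len(geno))
            ]
            fh.write("\t".join(fields + calls) + "\n")
    _write_groups(matrix, Path(str(path) + ".groups.tsv"))


def _write_groups(matrix: CohortMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("subject_id\tgroup\n")
        for sid, case in zip(matrix.subject_ids, matrix.is_case):
            fh.write(f"{sid}\t{'case' if case else 'control'}\n")


def _read_groups(path: Path, subject_ids: np.ndarray) -> np.ndarray:
    groups = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            sid, group = line.rstrip("\n").split("\t")
            groups[sid] = group
    missing = [s for s in subject_ids if s not in groups]
    if missing:
        raise ValueError(f"group labels missing for {len(missing)} subjects")
    return np.array([groups[s] == "case" for s in subject_ids], dtype=bool)


def read_vcf(path, group_file=None) -> CohortMatrix:
    """Load a cohort from the VCF dialect written by :func:`write_cohort_vcf`.

    ``group_file`` overrides the default ``<path>.groups.tsv`` sidecar.
    Missing GQ or AD FORMAT fields are tolerated with a warning (the
    corresponding arrays are filled with −1, and the filters that need
    them treat those calls as unfilterable).
    """
    from cyvcf2 import VCF

    path = Path(path)
    vcf = VCF(str(path))
    subject_ids = np.array(vcf.samples, dtype=object)
    n_sub = len(subject_ids)

    chroms, poss, refs, alts, genes, csqs, cadds, pops, indels = (
        [] for _ in range(9)
    )
    geno_rows, gq_rows, rr_rows, ar_rows = [], [], [], []
    warned_gq = warned_ad = False
    for rec in vcf:
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        genes.append(rec.INFO.get("GENE", "NA"))
        csqs.append(rec.INFO.get("CSQ_CLASS", "other"))
        cadds.append(float(rec.INFO.get("CADD", np.nan)))
        pops.append(float(rec.INFO.get("POPMAX_AF", np.nan)))
        indels.append(bool(rec.INFO.get("INDEL", False)))

        gt = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        row = np.select(
            [gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING
        ).astype(np.int8)
        geno_rows.append(row)

        try:
            gq = rec.format("GQ")
        except KeyError:
            gq = None
        if gq is None:
            if not warned_gq:
                warnings.warn(f"{path.name}: no GQ FORMAT field", stacklevel=2)
                warned_gq = True
            gq_rows.append(np.full(n_sub, -1, dtype=np.int16))
        else:
            g = gq.astype(float).reshape(n_sub)
            g = np.where(np.isfinite(g) & (g >= 0), g, -1)
            gq_rows.append(g.astype(np.int16))

        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            if not warned_ad:
                warnings.warn(f"{path.name}: no AD FORMAT field", stacklevel=2)
                warned_ad = True
            rr_rows.append(np.full(n_sub, -1, dtype=np.int32))
            ar_rows.append(np.full(n_sub, -1, dtype=np.int32))
        else:
            ad = ad.astype(np.int64)
            rr = np.where(ad[:, 0] >= 0, ad[:, 0], -1)
            ar = np.where(ad[:, 1] >= 0, ad[:, 1], -1) if ad.shape[1] > 1 else np.full(
                n_sub, -1
            )
            rr_rows.append(rr.astype(np.int32))
            ar_rows.append(ar.astype(np.int32))
    vcf.close()

    n_var = len(chroms)
    shape = (n_var, n_sub)
    variants = make_variant_table(
        chrom=chroms, pos=poss, ref=refs, alt=alts, gene=genes,
        csq_class=csqs, cadd=cadds, popmax_af=pops, is_indel=indels,
    )
    gfile = Path(group_file) if group_file else Path(str(path) + ".groups.tsv")
    if gfile.exists():
        is_case = _read_groups(gfile, subject_ids)
    else:
        warnings.warn(
            f"no group-label file found at {gfile}; all subjects loaded as controls",
            stacklevel=2,
        )
        is_case = np.zeros(n_sub, dtype=bool)

    stack = lambda rows, dtype: (
        np.vstack(rows) if rows else np.empty(shape, dtype=dtype)
    )
    return CohortMatrix(
        variants=variants,
        subject_ids=subject_ids,
        is_case=is_case,
        geno=stack(geno_rows, np.int8),
        gq=stack(gq_rows, np.int16),
        ref_reads=stack(rr_rows, np.int32),
        alt_reads=stack(ar_rows, np.int32),
    )


def _read_lines(path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_gene_list(path) -> list[str]:
    """Read a gene set: one symbol per line, ``#`` comments ignored."""
    return _read_lines(path)


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_subject_list(path) -> list[str]:
    """Read a subject (exclusion) list: one ID per line."""
    return _read_lines(path)
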