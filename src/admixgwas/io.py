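"""Cohort persistence.

Genotypes are exported as a minimal VCFv4.2 file (unphased diploid GT, one
record per variant, single ALT, contigs and positions from the frequency
panel) and read back through cyvcf2. Admixture proportions, local-ancestry
copy counts and the frequency panel travel as tab-separated sidecar tables
next to the VCF, so ``read_cohort(write_cohort(c))`` reproduces genotypes,
positions and pi exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .sim import AncestralFrequencyPanel, Cohort

__all__ = ["write_cohort", "read_cohort", "write_vcf", "read_vcf"]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(cohort: Cohort, path) -> None:
    """Write cohort genotypes as a minimal VCFv4.2 file."""
    panel = cohort.panel
    samples = [f"S{i}" for i in range(cohort.n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixgwas\n")
        for c in pd.unique(panel.chrom):
            length = int(panel.pos_bp[panel.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(panel.n_variants):
            gts = "\t".join(_GT[int(g)] for g in cohort.genotypes[:, j])
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos_bp[j]}\tv{j}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path):
    """Read a VCF into (chrom, pos_bp, dosage matrix).

    Returns dosages as an (n, m) int8 array of ALT-allele counts. A record
    that cannot be parsed raises a ValueError naming its index.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path), gts012=True)
    chroms, positions, rows = [], [], []
    record_index = -1
    try:
        for record_index, rec in enumerate(vcf):
            gt = np.asarray(rec.gt_types)
            if np.any(gt == 3):  # gts012: 3 is unknown
                raise ValueError("missing genotype")
            chroms.append(rec.CHROM)
            positions.append(rec.POS)
            rows.append(gt.astype(np.int8))
    except Exception as exc:  # noqa: BLE001 - annotate with record index
        raise ValueError(
            f"malformed VCF record at index {record_index + 1}: {exc}"
        ) from exc
    finally:
        vcf.close()
    if not rows:
        raise ValueError("VCF contains no records")
    return (
        np.asarray(chroms, dtype=str),
        np.asarray(positions, dtype=np.int64),
        np.vstack(rows).T,
    )


def write_cohort(cohort: Cohort, prefix) -> Path:
    """Persist a cohort under ``prefix`` (.vcf + .panel/.pi/.ancestry TSVs)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_vcf(cohort, prefix.with_suffix(".vcf"))
    cohort.panel.to_tsv(prefix.with_suffix(".panel.tsv"))
    pd.DataFrame({"pi": cohort.pi}).to_csv(
        prefix.with_suffix(".pi.tsv"), sep="\t", index=False
    )
    pd.DataFrame(cohort.ancestry).to_csv(
        prefix.with_suffix(".ancestry.tsv"), sep="\t", index=False, header=False
    )
    return prefix


def read_cohort(prefix) -> Cohort:
    """Load a cohort written by :func:`write_cohort`."""
    prefix = Path(prefix)
    panel = AncestralFrequencyPanel.from_tsv(prefix.with_suffix(".panel.tsv"))
    chrom, pos, genotypes = read_vcf(prefix.with_suffix(".vcf"))
    if not (np.array_equal(chrom, panel.chrom) and np.array_equal(pos, panel.pos_bp)):
        raise ValueError("VCF records do not match the sidecar panel")
    pi = pd.read_csv(prefix.with_suffix(".pi.tsv"), sep="\t")["pi"].to_numpy()
    ancestry = pd.read_csv(
        prefix.with_suffix(".ancestry.tsv"), sep="\t", header=None
    ).to_numpy(dtype=np.int8)
    return Cohort(pi=pi, ancestry=ancestry, genotypes=genotypes, panel=panel)
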