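"""File formats: minimal VCF 4.2, TSV dosage matrices, phenotype CSV.

Genotypes travel either as a GT-only VCF (all markers on chromosome "1"
at 1-based positions 1..n_markers) or as a plain TSV matrix with
individuals as rows and marker ids as columns, cells 0/1/2 or NA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, validate_phenotypes

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_phenotypes",
    "read_phenotypes",
]

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT fields only."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(str(s) for s in genotypes.individuals)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, marker in enumerate(genotypes.markers):
            col = genotypes.dosages[:, j]
            gts = "\t".join("./." if np.isnan(v) else _GT_CODE[float(v)] for v in col)
            fh.write(f"1\t{j + 1}\t{marker}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT dosages from a VCF (uses cyvcf2 when available)."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - exercised only without cyvcf2
        return _read_vcf_plain(path)
    vcf = VCF(str(path))
    individuals = np.asarray(vcf.samples, dtype=object)
    markers, rows = [], []
    for variant in vcf:
        markers.append(variant.ID)
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        codes = np.asarray(variant.gt_types, dtype=float)
        dose = np.where(codes == 3, 2.0, codes)
        dose[codes == 2] = np.nan
        rows.append(dose)
    vcf.close()
    dosages = np.column_stack(rows) if rows else np.empty((len(individuals), 0))
    return GenotypeMatrix(dosages, individuals=individuals, markers=np.asarray(markers, dtype=object))


def _read_vcf_plain(path: str | Path) -> GenotypeMatrix:
    """Fallback GT-only VCF reader for environments without cyvcf2."""
    individuals: list[str] = []
    markers: list[str] = []
    rows: list[list[float]] = []
    decode = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0, "0|0": 0.0,
              "0|1": 1.0, "1|0": 1.0, "1|1": 2.0}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                individuals = fields[9:]
                continue
            markers.append(fields[2])
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            rows.append(
                [decode.get(cell.split(":")[gt_i], np.nan) for cell in fields[9:]]
            )
    dosages = np.column_stack([np.asarray(r) for r in rows]) if rows else np.empty((len(individuals), 0))
    return GenotypeMatrix(
        dosages,
        individuals=np.asarray(individuals, dtype=object),
        markers=np.asarray(markers, dtype=object),
    )


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = genotypes.to_frame()
    df.index.name = "individual"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix.from_frame(df)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(pheno).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path))


def detect_and_read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Dispatch on extension: .vcf -> VCF reader, otherwise TSV matrix."""
    p = Path(path)
    if p.suffix.lower() == ".vcf":
        return read_vcf(p)
    return read_genotype_tsv(p)
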