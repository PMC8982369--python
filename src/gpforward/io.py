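"""Text I/O for genotype panels and trait tables.

Panels travel as two TSVs: a dosage matrix (header row of SNP ids, one
row per animal: id then dosages, missing as ``NA``) and a SNP map
(``snp_id``, ``chrom``, ``cm``). Trait tables are plain CSV. A minimal
unphased VCF writer/reader is provided for interoperability; PLINK
``.raw``-style files are readable as panels too.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SchemaError
from .pheno import TraitTable
from .qc import GenotypePanel

__all__ = [
    "write_panel",
    "read_panel",
    "read_raw_panel",
    "write_traits",
    "read_traits",
    "write_vcf",
    "read_vcf",
]


def write_panel(panel: GenotypePanel, dosage_path, map_path) -> None:
    df = pd.DataFrame(panel.dosages, columns=panel.snp_ids)
    df.insert(0, "animal_id", panel.animal_ids)
    df.to_csv(dosage_path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    panel.snp_map.to_csv(map_path, sep="\t", index=False)


def read_panel(dosage_path, map_path) -> GenotypePanel:
    df = pd.read_csv(dosage_path, sep="\t", na_values=["NA"])
    if df.columns[0] != "animal_id":
        raise SchemaError("first panel column must be 'animal_id'")
    snp_map = pd.read_csv(map_path, sep="\t")
    for col in ("snp_id", "chrom", "cm"):
        if col not in snp_map.columns:
            raise SchemaError(f"SNP map lacks column {col!r}")
    return GenotypePanel(
        animal_ids=df["animal_id"].to_numpy(object),
        snp_ids=np.asarray(df.columns[1:], dtype=object),
        dosages=df.iloc[:, 1:].to_numpy(float),
        snp_map=snp_map,
    )


def read_raw_panel(raw_path, map_path=None) -> GenotypePanel:
    """Read a PLINK ``.raw``-style additive dosage file (whitespace separated).

    Expects the usual leading columns (FID IID PAT MAT SEX PHENOTYPE)
    followed by per-SNP dosages; SNP ids keep their ``_ALLELE`` suffix
    stripped. Without a map file, all SNPs land on one pseudo-chromosome
    at unit spacing.
    """
    df = pd.read_csv(raw_path, sep=r"\s+", na_values=["NA"])
    lead = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in lead:
        raise SchemaError(".raw file lacks an IID column")
    snp_cols = [c for c in df.columns if c not in lead]
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    if map_path is not None:
        snp_map = pd.read_csv(map_path, sep="\t")
    else:
        snp_map = pd.DataFrame(
            {"snp_id": snp_ids, "chrom": 1, "cm": np.arange(1.0, len(snp_ids) + 1.0)}
        )
    return GenotypePanel(
        animal_ids=df["IID"].astype(str).to_numpy(object),
        snp_ids=np.asarray(snp_ids, dtype=object),
        dosages=df[snp_cols].to_numpy(float),
        snp_map=snp_map,
    )


def write_traits(traits: TraitTable, path) -> None:
    traits.data.to_csv(path, index=False, float_format="%.10g")


def read_traits(path, trait_names=None) -> TraitTable:
    df = pd.read_csv(path)
    if trait_names is None:
        reserved = {"animal_id", "generation", "sex", "diet", "litter", "sire", "dam"}
        trait_names = [c for c in df.columns if c not in reserved]
    return TraitTable(data=df, trait_names=list(trait_names))


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Unphased biallelic VCF (REF=A, ALT=B placeholders; cM scaled to bp)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        cols = "\t".join(str(a) for a in panel.animal_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        gt = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(panel.n_snps):
            row = panel.snp_map.iloc[j]
            pos = int(round(float(row["cm"]) * 1_000_000))
            calls = []
            for d in panel.dosages[:, j]:
                calls.append("./." if np.isnan(d) else gt[int(round(d))])
            fh.write(
                f"{row['chrom']}\t{pos}\t{row['snp_id']}\tA\tB\t.\t.\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypePanel:
    """Read a biallelic VCF into a panel (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ParameterError("VCF input requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    animal_ids = np.asarray(vcf.samples, dtype=object)
    snp_ids, chroms, cms, rows = [], [], [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        cms.append(var.POS / 1_000_000)
        g = np.asarray(var.genotypes)[:, :2].astype(float)
        g[g < 0] = np.nan
        rows.append(g.sum(axis=1))
    if not rows:
        raise SchemaError("VCF contains no variants")
    return GenotypePanel(
        animal_ids=animal_ids,
        snp_ids=np.asarray(snp_ids, dtype=object),
        dosages=np.column_stack(rows),
        snp_map=pd.DataFrame({"snp_id": snp_ids, "chrom": chroms, "cm": cms}),
    )
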