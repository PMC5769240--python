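"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are plain TSV with headers. Genotypes are also
written as a minimal VCF with a DS (dosage) FORMAT field. Genomic
intervals are 1-based inclusive throughout.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from eqtl_ensemble.synthdata import Cohort, GenotypeMatrix, PANEL_COLUMNS


def write_genotype_tsv(gt: GenotypeMatrix, path) -> None:
    gt.dosages.rename_axis("subject").to_csv(path, sep="\t")


def read_genotype_tsv(path, panel: pd.DataFrame) -> GenotypeMatrix:
    dosages = pd.read_csv(path, sep="\t", index_col="subject")
    missing = [rs for rs in panel["rsid"] if rs not in dosages.columns]
    if missing:
        raise ValueError(f"genotype matrix missing panel SNPs: {missing[:3]}")
    return GenotypeMatrix(dosages=dosages[panel["rsid"].tolist()], panel=panel.reset_index(drop=True))


def write_snp_panel(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_snp_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return panel


def write_vcf(gt: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with dosages in the DS FORMAT field."""
    subjects = gt.subjects
    panel = gt.panel
    dos = gt.dosages.to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Allele dosage">\n')
        for chrom in dict.fromkeys(panel["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects) + "\n")
        for j, row in panel.iterrows():
            fields = [str(row["chrom"]), str(int(row["pos"])), row["rsid"], "A", "G", ".", "PASS", ".", "DS"]
            fields += [f"{d:g}" for d in dos[:, j]]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a DS-field VCF back into a dosage matrix.

    Uses cyvcf2 when installed; otherwise falls back to a plain-text
    parse of the simple VCFs this package writes.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        VCF = None
    if VCF is not None:
        vcf = VCF(str(path))
        subjects = list(vcf.samples)
        rows, rsids, chroms, poss = [], [], [], []
        for var in vcf:
            rsids.append(var.ID)
            chroms.append(str(var.CHROM))
            poss.append(int(var.POS))
            rows.append(np.asarray(var.format("DS"), dtype=float).reshape(-1))
        dos = np.column_stack(rows) if rows else np.empty((len(subjects), 0))
    else:  # pragma: no cover - exercised only without cyvcf2
        subjects, rsids, chroms, poss, rows = [], [], [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    subjects = parts[9:]
                    continue
                chroms.append(parts[0])
                poss.append(int(parts[1]))
                rsids.append(parts[2])
                ds_idx = parts[8].split(":").index("DS")
                rows.append([float(v.split(":")[ds_idx]) for v in parts[9:]])
        dos = np.array(rows, dtype=float).T if rows else np.empty((len(subjects), 0))
    dosages = pd.DataFrame(dos, index=subjects, columns=rsids)
    freq = dosages.to_numpy().mean(axis=0) / 2.0
    panel = pd.DataFrame(
        {"rsid": rsids, "chrom": chroms, "pos": poss, "maf": np.minimum(freq, 1 - freq)}
    )
    return GenotypeMatrix(dosages=dosages, panel=panel)


def write_matrix_tsv(mat: pd.DataFrame, path) -> None:
    mat.rename_axis("subject").to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject")


def write_probe_annotation(probes: pd.DataFrame, path) -> None:
    # BED-like but 1-based inclusive, as documented
    probes.to_csv(path, sep="\t", index=False)


def read_probe_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_phenotype(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, sep="\t", index=False)


def read_phenotype(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_provenance(prov: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=False)


def read_provenance(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write every cohort artefact; returns {name: path}."""
    from eqtl_ensemble.gwas_integration import write_gwas_summary

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "plan": os.path.join(outdir, "plan.yaml"),
        "panel": os.path.join(outdir, "snp_panel.tsv"),
        "genotypes_tsv": os.path.join(outdir, "genotypes.tsv"),
        "genotypes_vcf": os.path.join(outdir, "genotypes.vcf"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "methylation": os.path.join(outdir, "methylation.tsv"),
        "probes": os.path.join(outdir, "probe_annotation.tsv"),
        "cpgs": os.path.join(outdir, "cpg_annotation.tsv"),
        "phenotype": os.path.join(outdir, "phenotype.tsv"),
        "covariates": os.path.join(outdir, "covariates.tsv"),
        "gwas": os.path.join(outdir, "gwas.assoc"),
    }
    cohort.design.plan.to_yaml(paths["plan"])
    write_snp_panel(cohort.design.panel, paths["panel"])
    write_genotype_tsv(cohort.genotypes, paths["genotypes_tsv"])
    write_vcf(cohort.genotypes, paths["genotypes_vcf"])
    write_matrix_tsv(cohort.expression, paths["expression"])
    write_matrix_tsv(cohort.methylation, paths["methylation"])
    write_probe_annotation(cohort.design.probes, paths["probes"])
    cohort.design.cpgs.to_csv(paths["cpgs"], sep="\t", index=False)
    write_phenotype(cohort.phenotype, paths["phenotype"])
    cohort.covariates.rename_axis("subject").to_csv(paths["covariates"], sep="\t")
    write_gwas_summary(cohort.gwas, paths["gwas"])
    return paths
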