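"""Synthetic cohorts with the statistical structure the pipeline assumes.

Generates LD-blocked genotype dosages, covariates, expression with planted
cis/trans eQTLs, a case-control phenotype driven by a subset of eQTL SNPs
(logistic liability with exact quotas), an independent GWAS cohort reduced
to summary statistics, and methylation beta values with planted
case-control shifts. Defaults emulate a lung-tissue cohort of 86 cases and
31 controls with an external, larger GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from eqtl_ensemble._association import assoc_table

PANEL_COLUMNS = ["rsid", "chrom", "pos", "maf"]


@dataclass
class SimulationPlan:
    """Everything the generators need to plant signal.

    Effect sizes are in natural units: expression betas in residual-SD
    units per allele, disease effects in log-odds per allele, methylation
    effects as case-control differences on the beta-value scale.
    """

    n_cases: int = 86
    n_controls: int = 31
    n_snps: int = 2000
    n_genes: int = 200
    n_cpgs: int = 500
    ld_block_size: int = 10
    ld_rho: float = 0.8
    cis_effects: list = field(default_factory=list)  # (rsid, gene_symbol, beta)
    trans_effects: list = field(default_factory=list)  # (rsid, gene_symbol, beta)
    disease_causal: list = field(default_factory=list)  # (rsid, log_odds)
    de_effects: list = field(default_factory=list)  # (gene_symbol, case-control shift)
    dm_effects: list = field(default_factory=list)  # (cpg_id, case-control beta diff)
    noise_sd: float = 1.0
    covariate_coef_sd: float = 0.1
    meth_latent_sd: float = 0.5
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        for key in ("cis_effects", "trans_effects", "disease_causal", "de_effects", "dm_effects"):
            raw[key] = [list(item) for item in raw[key]]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationPlan":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("cis_effects", "trans_effects", "disease_causal", "de_effects", "dm_effects"):
            if key in raw and raw[key]:
                raw[key] = [tuple(item) for item in raw[key]]
        return cls(**raw)


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosage table plus the SNP annotation panel."""

    dosages: pd.DataFrame  # index: subject ids, columns: rsids
    panel: pd.DataFrame  # rsid, chrom, pos, maf

    @property
    def subjects(self) -> list:
        return list(self.dosages.index)


@dataclass
class StudyDesign:
    """A plan together with the annotations its effects refer to."""

    plan: SimulationPlan
    panel: pd.DataFrame  # rsid, chrom, pos, maf
    probes: pd.DataFrame  # probe_id, gene_symbol, chrom, start, end
    cpgs: pd.DataFrame  # cpg_id, gene_symbol, base_mean


@dataclass
class Cohort:
    """One simulated study: genotypes through GWAS summary."""

    design: StudyDesign
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    expression: pd.DataFrame
    phenotype: pd.DataFrame  # subject, status
    methylation: pd.DataFrame
    gwas: pd.DataFrame  # rsid, chrom, pos, p, monomorphic


def _validate_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    if panel.empty:
        raise ValueError("panel is empty")
    if panel["rsid"].duplicated().any():
        dup = panel.loc[panel["rsid"].duplicated(), "rsid"].iloc[0]
        raise ValueError(f"duplicate rsID in panel: {dup}")
    maf = panel["maf"].to_numpy(dtype=float)
    if np.any(maf <= 0.0) or np.any(maf > 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    for _, grp in panel.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("pos must be strictly increasing within chromosome")


def make_snp_panel(
    n_snps: int = 2000,
    seed: int = 0,
    chroms: tuple = ("1", "2"),
    spacing_bp: int = 5000,
    start_bp: int = 100_000,
    maf_range: tuple = (0.05, 0.5),
) -> pd.DataFrame:
    """Evenly spaced SNP panel with uniform minor-allele frequencies.

    Frequencies stay above 5% to match the common-variant filter applied
    before eQTL analysis.
    """
    rng = np.random.default_rng(seed)
    per_chrom = int(np.ceil(n_snps / len(chroms)))
    rows = []
    idx = 0
    for chrom in chroms:
        for j in range(per_chrom):
            if idx >= n_snps:
                break
            rows.append(
                {
                    "rsid": f"rs{idx + 1:06d}",
                    "chrom": str(chrom),
                    "pos": start_bp + j * spacing_bp,
                    "maf": float(rng.uniform(*maf_range)),
                }
            )
            idx += 1
    panel = pd.DataFrame(rows)
    _validate_panel(panel)
    return panel


def make_probe_annotation(
    panel: pd.DataFrame,
    n_genes: int = 200,
    seed: int = 0,
    gene_length_bp: int = 10_000,
    multi_probe_every: int = 20,
) -> pd.DataFrame:
    """Gene/probe intervals laid out across the panel's chromosomes.

    Genes are spread evenly over each chromosome's SNP span so every gene
    has SNPs inside its cis window. Every ``multi_probe_every``-th gene
    gets a second probe, mirroring the probe/symbol multiplicity of
    microarray annotations.
    """
    chroms = list(dict.fromkeys(panel["chrom"]))
    per_chrom = int(np.ceil(n_genes / len(chroms)))
    rows = []
    g = 0
    for chrom in chroms:
        sub = panel[panel["chrom"] == chrom]
        lo, hi = int(sub["pos"].min()), int(sub["pos"].max())
        span = max(hi - lo - gene_length_bp, 1)
        for j in range(per_chrom):
            if g >= n_genes:
                break
            start = lo + int(span * (j + 0.5) / per_chrom)
            symbol = f"GENE{g + 1:04d}"
            n_probes = 2 if (g % multi_probe_every == multi_probe_every - 1) else 1
            for k in range(n_probes):
                rows.append(
                    {
                        "probe_id": f"{symbol}_p{k + 1}",
                        "gene_symbol": symbol,
                        "chrom": str(chrom),
                        "start": start,
                        "end": start + gene_length_bp,
                    }
                )
            g += 1
    return pd.DataFrame(rows)


def make_cpg_annotation(n_cpgs: int, genes: list, seed: int = 0) -> pd.DataFrame:
    """CpG sites assigned round-robin to genes with baseline beta means."""
    rng = np.random.default_rng(seed)
    rows = [
        {
            "cpg_id": f"cg{i + 1:07d}",
            "gene_symbol": genes[i % len(genes)],
            "base_mean": float(rng.uniform(0.2, 0.8)),
        }
        for i in range(n_cpgs)
    ]
    return pd.DataFrame(rows)


def generate_genotypes(
    panel: pd.DataFrame,
    n_subjects: int,
    ld_block_size: int,
    ld_rho: float,
    seed: int,
) -> GenotypeMatrix:
    """Simulate hard-call dosages with block-local linkage disequilibrium.

    Two haplotypes per subject. Within an LD block the latent uniform of
    each SNP is copied from the previous SNP's with probability
    ``ld_rho``, otherwise drawn fresh; the allele is the indicator
    ``u < maf``. Copying on the uniform scale keeps every SNP's marginal
    frequency exactly at its maf while making equal-maf neighbours nearly
    perfectly correlated as rho -> 1.
    """
    _validate_panel(panel)
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if ld_block_size <= 0:
        raise ValueError("ld_block_size must be positive")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_subjects
    n_snps = len(panel)
    maf = panel["maf"].to_numpy(dtype=float)
    chrom = panel["chrom"].to_numpy()

    u = np.empty((n_hap, n_snps))
    # block boundaries reset the copying chain; chromosomes always do
    block_pos = 0
    for j in range(n_snps):
        fresh = rng.random(n_hap)
        new_chrom = j == 0 or chrom[j] != chrom[j - 1]
        if new_chrom:
            block_pos = 0
        if block_pos == 0 or ld_rho == 0.0:
            u[:, j] = fresh
        else:
            copy = rng.random(n_hap) < ld_rho
            u[:, j] = np.where(copy, u[:, j - 1], fresh)
        block_pos = (block_pos + 1) % ld_block_size
    alleles = (u < maf[None, :]).astype(np.int8)
    dosage = alleles[0::2] + alleles[1::2]
    subjects = [f"S{i + 1:04d}" for i in range(n_subjects)]
    dosages = pd.DataFrame(dosage.astype(float), index=subjects, columns=panel["rsid"].tolist())
    return GenotypeMatrix(dosages=dosages, panel=panel.reset_index(drop=True))


def generate_covariates(n_subjects: int, seed: int, n_ancestry_pcs: int = 2) -> pd.DataFrame:
    """Age, sex, smoking pack-years and ancestry PCs for a COPD-like cohort."""
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:04d}" for i in range(n_subjects)]
    cov = pd.DataFrame(
        {
            "age": rng.normal(65.0, 8.0, n_subjects),
            "sex": rng.integers(0, 2, n_subjects).astype(float),
            "pack_years": rng.gamma(shape=4.0, scale=12.0, size=n_subjects),
        },
        index=subjects,
    )
    for k in range(n_ancestry_pcs):
        cov[f"ancestry_pc{k + 1}"] = rng.normal(0.0, 1.0, n_subjects)
    cov.index.name = "subject"
    return cov


def generate_expression(
    gt: GenotypeMatrix,
    plan: SimulationPlan,
    covariates: pd.DataFrame,
    probes: pd.DataFrame,
    phen: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expression = planted genetic effects + covariate terms + noise.

    Planted effects apply to every probe of the target gene. Disease-state
    shifts (``plan.de_effects``) require the phenotype and emulate
    case-control differential expression on top of the genetic signal.
    """
    rng = np.random.default_rng(plan.seed + 1 if seed is None else seed)
    known_genes = set(probes["gene_symbol"])
    known_snps = set(gt.dosages.columns)
    for rsid, gene, _ in list(plan.cis_effects) + list(plan.trans_effects):
        if rsid not in known_snps:
            raise ValueError(f"effect references unknown SNP {rsid}")
        if gene not in known_genes:
            raise ValueError(f"effect references unknown gene {gene}")
    n = len(gt.dosages)
    probe_ids = probes["probe_id"].tolist()
    expr = np.zeros((n, len(probe_ids)))

    cov_mat = covariates.to_numpy(dtype=float)
    cov_std = (cov_mat - cov_mat.mean(axis=0)) / np.where(cov_mat.std(axis=0) > 0, cov_mat.std(axis=0), 1.0)
    coefs = rng.normal(0.0, plan.covariate_coef_sd, size=(cov_std.shape[1], len(probe_ids)))
    expr += cov_std @ coefs

    probe_idx: dict[str, list[int]] = {}
    for i, (pid, sym) in enumerate(zip(probes["probe_id"], probes["gene_symbol"])):
        probe_idx.setdefault(sym, []).append(i)
    for rsid, gene, beta in list(plan.cis_effects) + list(plan.trans_effects):
        dos = gt.dosages[rsid].to_numpy(dtype=float)
        for i in probe_idx[gene]:
            expr[:, i] += beta * dos
    if plan.de_effects:
        if phen is None:
            raise ValueError("de_effects planted but no phenotype supplied")
        status = phen.set_index("subject").loc[gt.dosages.index, "status"].to_numpy(dtype=float)
        for gene, shift in plan.de_effects:
            if gene not in known_genes:
                raise ValueError(f"de_effect references unknown gene {gene}")
            for i in probe_idx[gene]:
                expr[:, i] += shift * status
    expr += rng.normal(0.0, plan.noise_sd, size=expr.shape)
    out = pd.DataFrame(expr, index=gt.dosages.index, columns=probe_ids)
    out.index.name = "subject"
    return out


def generate_disease_phenotype(
    gt: GenotypeMatrix, plan: SimulationPlan, seed: int | None = None
) -> pd.DataFrame:
    """Case-control status from a logistic liability with exact quotas.

    The intercept is tuned by root-finding so the expected case count
    matches ``plan.n_cases``; repeated Bernoulli passes then fill the case
    and control quotas exactly, preserving the genotype-risk gradient.
    """
    n = len(gt.dosages)
    if plan.n_cases + plan.n_controls != n:
        raise ValueError(
            f"quota ({plan.n_cases} cases + {plan.n_controls} controls) != {n} subjects"
        )
    if plan.n_cases < 1 or plan.n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = np.random.default_rng(plan.seed + 2 if seed is None else seed)
    liability = np.zeros(n)
    for rsid, log_odds in plan.disease_causal:
        if rsid not in gt.dosages.columns:
            raise ValueError(f"disease_causal references unknown SNP {rsid}")
        liability += log_odds * gt.dosages[rsid].to_numpy(dtype=float)

    target = plan.n_cases / n

    def excess(c: float) -> float:
        return float(expit(c + liability).mean() - target)

    intercept = brentq(excess, -40.0, 40.0)
    prob = expit(intercept + liability)

    status = np.full(n, -1, dtype=int)
    cases_left, controls_left = plan.n_cases, plan.n_controls
    for _ in range(10_000):
        unassigned = np.flatnonzero(status < 0)
        if unassigned.size == 0:
            break
        for i in rng.permutation(unassigned):
            draw = rng.random() < prob[i]
            if draw and cases_left > 0:
                status[i] = 1
                cases_left -= 1
            elif not draw and controls_left > 0:
                status[i] = 0
                controls_left -= 1
    # degenerate probabilities can stall the quota loop; fill by risk order
    unassigned = np.flatnonzero(status < 0)
    if unassigned.size:
        order = unassigned[np.argsort(-prob[unassigned])]
        for i in order:
            if cases_left > 0:
                status[i], cases_left = 1, cases_left - 1
            else:
                status[i], controls_left = 0, controls_left - 1
    return pd.DataFrame({"subject": gt.dosages.index, "status": status})


def generate_gwas_summary(
    panel: pd.DataFrame,
    plan: SimulationPlan,
    n_gwas: int,
    seed: int,
) -> pd.DataFrame:
    """Summary statistics from an independent cohort under the same disease model.

    A fresh cohort of ``n_gwas`` subjects is simulated from the panel,
    status is drawn from the logistic liability (intercept tuned to a
    balanced design), and each SNP is tested with the allelic logistic
    score test. Monomorphic SNPs are flagged and given p = 1.
    """
    if n_gwas < 100:
        raise ValueError("n_gwas must be at least 100")
    rng = np.random.default_rng(seed)
    gt = generate_genotypes(panel, n_gwas, plan.ld_block_size, plan.ld_rho, seed=int(rng.integers(2**31)))
    liability = np.zeros(n_gwas)
    for rsid, log_odds in plan.disease_causal:
        liability += log_odds * gt.dosages[rsid].to_numpy(dtype=float)

    def excess(c: float) -> float:
        return float(expit(c + liability).mean() - 0.5)

    intercept = brentq(excess, -40.0, 40.0)
    status = (rng.random(n_gwas) < expit(intercept + liability)).astype(int)
    if status.sum() < 2 or status.sum() > n_gwas - 2:  # pragma: no cover
        status[:2], status[-2:] = 1, 0
    return assoc_table(panel, gt.dosages.to_numpy(), status)


def _calibrated_latent_mean(target: float, sigma: float) -> float:
    """Latent-normal mean whose expit-transformed expectation hits target."""
    if not 0.0 < target < 1.0:
        raise ValueError(f"methylation mean {target} outside (0, 1)")
    if sigma == 0.0:
        return float(logit(target))
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)

    def mean_beta(mu: float) -> float:
        return float(weights @ expit(mu + sigma * nodes) / weights.sum())

    return brentq(lambda mu: mean_beta(mu) - target, -60.0, 60.0)


def generate_methylation(
    phen: pd.DataFrame,
    plan: SimulationPlan,
    cpgs: pd.DataFrame,
    seed: int | None = None,
) -> pd.DataFrame:
    """Beta values in [0,1] via a logistic transform of a Gaussian latent.

    Latent means are calibrated (Gauss-Hermite quadrature + root finding)
    so the expected case-control difference on the beta scale equals the
    planted effect despite the nonlinear transform.
    """
    rng = np.random.default_rng(plan.seed + 3 if seed is None else seed)
    known = set(cpgs["cpg_id"])
    dm = dict(plan.dm_effects)
    unknown = set(dm) - known
    if unknown:
        raise ValueError(f"dm_effects reference unknown CpGs: {sorted(unknown)[:3]}")
    status = phen["status"].to_numpy(dtype=int)
    n = len(status)
    sigma = plan.meth_latent_sd
    beta = np.empty((n, len(cpgs)))
    for j, (cpg, base) in enumerate(zip(cpgs["cpg_id"], cpgs["base_mean"])):
        diff = dm.get(cpg, 0.0)
        m_control, m_case = float(base), float(base) + diff
        if not (0.0 < m_case < 1.0):
            raise ValueError(f"planned difference pushes {cpg} case mean to {m_case}")
        mu_control = _calibrated_latent_mean(m_control, sigma)
        mu_case = mu_control if diff == 0.0 else _calibrated_latent_mean(m_case, sigma)
        mu = np.where(status == 1, mu_case, mu_control)
        beta[:, j] = expit(mu + sigma * rng.standard_normal(n)) if sigma > 0 else expit(mu)
    out = pd.DataFrame(beta, index=phen["subject"].to_numpy(), columns=cpgs["cpg_id"].tolist())
    out.index.name = "subject"
    return out


def default_plan(seed: int = 0) -> StudyDesign:
    """The default study design: 86 cases / 31 controls, 2000 SNPs, 200
    genes, 500 CpGs, with 30 cis-eGenes, 8 trans effects, 5 "shared" genes
    whose eSNPs also carry disease risk, and methylation shifts on the
    shared genes' CpGs.
    """
    rng = np.random.default_rng(seed)
    panel = make_snp_panel(n_snps=2000, seed=seed)
    probes = make_probe_annotation(panel, n_genes=200, seed=seed)
    genes = list(dict.fromkeys(probes["gene_symbol"]))
    cpgs = make_cpg_annotation(500, genes, seed=seed)

    gene_iv = probes.drop_duplicates("gene_symbol").set_index("gene_symbol")
    cis_genes = [genes[i] for i in np.linspace(0, len(genes) - 1, 30, dtype=int)]
    cis_effects, trans_effects = [], []
    used_snps: set[str] = set()
    for gene in cis_genes:
        row = gene_iv.loc[gene]
        near = panel[
            (panel["chrom"] == row["chrom"])
            & (panel["pos"] >= row["start"] - 400_000)
            & (panel["pos"] <= row["end"] + 400_000)
            & (~panel["rsid"].isin(used_snps))
        ]
        snp = near.iloc[int(rng.integers(len(near)))]
        used_snps.add(snp["rsid"])
        beta = float(rng.uniform(0.8, 1.2)) * (1 if rng.random() < 0.5 else -1)
        cis_effects.append((snp["rsid"], gene, beta))
    trans_genes = [g for g in genes if g not in cis_genes][:8]
    for gene in trans_genes:
        row = gene_iv.loc[gene]
        far = panel[(panel["chrom"] != row["chrom"]) & (~panel["rsid"].isin(used_snps))]
        snp = far.iloc[int(rng.integers(len(far)))]
        used_snps.add(snp["rsid"])
        trans_effects.append((snp["rsid"], gene, 0.8))

    shared_genes = cis_genes[:5]
    shared_snps = [rs for rs, g, _ in cis_effects if g in shared_genes]
    disease_causal = [(rs, 0.5) for rs in shared_snps]
    de_effects = [(g, 0.5) for g in shared_genes]
    dm_effects = []
    cpg_by_gene = cpgs.groupby("gene_symbol")["cpg_id"].apply(list)
    for gene in shared_genes:
        for cpg in cpg_by_gene.get(gene, [])[:3]:
            dm_effects.append((cpg, float(rng.uniform(0.08, 0.12))))

    plan = SimulationPlan(
        cis_effects=cis_effects,
        trans_effects=trans_effects,
        disease_causal=disease_causal,
        de_effects=de_effects,
        dm_effects=dm_effects,
        seed=seed,
    )
    return StudyDesign(plan=plan, panel=panel, probes=probes, cpgs=cpgs)


def shared_gene_design(
    seed: int = 0,
    n_shared: int = 5,
    n_expression_only: int = 45,
    beta: float = 1.2,
    log_odds: float = 0.5,
) -> StudyDesign:
    """Design for the shared-vs-expression-only gene recovery experiment.

    Every gene gets one strong planted cis eSNP (|beta| = 1.2 residual SD
    per allele at a common variant, maf >= 0.25, one eSNP per LD block so
    signals do not tag each other); the first ``n_shared`` genes' eSNPs
    additionally carry disease risk. Recovery here probes the gene
    ranking, not scan power, hence the deliberately strong cis effects.
    """
    rng = np.random.default_rng(seed)
    n_genes = n_shared + n_expression_only
    panel = make_snp_panel(n_snps=1000, seed=seed)
    probes = make_probe_annotation(panel, n_genes=n_genes, seed=seed, multi_probe_every=10**9)
    genes = list(dict.fromkeys(probes["gene_symbol"]))
    cpgs = make_cpg_annotation(2 * n_genes, genes, seed=seed)
    gene_iv = probes.drop_duplicates("gene_symbol").set_index("gene_symbol")
    block = 10
    used_blocks: set[tuple[str, int]] = set()
    cis_effects = []
    panel_idx = {rs: i for i, rs in enumerate(panel["rsid"])}
    for gene in genes:
        row = gene_iv.loc[gene]
        near = panel[
            (panel["chrom"] == row["chrom"])
            & (panel["pos"] >= row["start"] - 400_000)
            & (panel["pos"] <= row["end"] + 400_000)
            & (panel["maf"] >= 0.25)
        ]
        near = near[
            [
                (r["chrom"], panel_idx[r["rsid"]] // block) not in used_blocks
                for _, r in near.iterrows()
            ]
        ]
        snp = near.iloc[int(rng.integers(len(near)))]
        used_blocks.add((snp["chrom"], panel_idx[snp["rsid"]] // block))
        sign = 1 if rng.random() < 0.5 else -1
        cis_effects.append((snp["rsid"], gene, sign * beta))
    shared = genes[:n_shared]
    disease_causal = [(rs, log_odds) for rs, g, _ in cis_effects if g in shared]
    plan = SimulationPlan(
        n_snps=len(panel),
        n_genes=n_genes,
        n_cpgs=len(cpgs),
        cis_effects=cis_effects,
        disease_causal=disease_causal,
        seed=seed,
    )
    return StudyDesign(plan=plan, panel=panel, probes=probes, cpgs=cpgs)


def simulate_cohort(design: StudyDesign, n_gwas: int = 5000, seed: int | None = None) -> Cohort:
    """Run every generator with sub-seeds derived from one master seed."""
    plan = design.plan
    master = plan.seed if seed is None else seed
    sub = np.random.SeedSequence(master).generate_state(6) % (2**31)
    gt = generate_genotypes(design.panel, plan.n_subjects, plan.ld_block_size, plan.ld_rho, seed=int(sub[0]))
    cov = generate_covariates(plan.n_subjects, seed=int(sub[1]))
    phen = generate_disease_phenotype(gt, plan, seed=int(sub[2]))
    expr = generate_expression(gt, plan, cov, design.probes, phen=phen, seed=int(sub[3]))
    meth = generate_methylation(phen, plan, design.cpgs, seed=int(sub[4]))
    gwas = generate_gwas_summary(design.panel, plan, n_gwas=n_gwas, seed=int(sub[5]))
    return Cohort(
        design=design,
        genotypes=gt,
        covariates=cov,
        expression=expr,
        phenotype=phen,
        methylation=meth,
        gwas=gwas,
    )
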