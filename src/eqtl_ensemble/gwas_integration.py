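"""GWAS summary handling, eQTL intersection, enrichment and permutation nulls.

The intersection reproduces the ensemble workflow's first integration
step: take GWAS variants at a suggestive threshold (default p < 1e-4),
keep those that are significant eSNPs (eQTL q below the FDR threshold),
and report each with its best eGene. Enrichment of the overlap is
quantified with an upper-tail hypergeometric test over the universe of
SNPs present in both analyses. Permutation-null GWAS summaries are built
by shuffling case-control labels and re-running the same association
test used for the observed summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from eqtl_ensemble._association import assoc_table

GWAS_COLUMNS = ["SNP", "CHR", "BP", "P"]
GENOME_WIDE_P = 5e-8


def write_gwas_summary(gwas: pd.DataFrame, path) -> None:
    """Write in the whitespace-delimited PLINK-assoc-like dialect."""
    out = pd.DataFrame(
        {"SNP": gwas["rsid"], "CHR": gwas["chrom"], "BP": gwas["pos"], "P": gwas["p"]}
    )
    with open(path, "w") as fh:
        fh.write(" ".join(GWAS_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fh.write(f"{row.SNP} {row.CHR} {row.BP} {row.P:.6g}\n")


def load_gwas_summary(path) -> pd.DataFrame:
    """Parse a PLINK-assoc-like summary; invalid rows are rejected loudly.

    Rows whose p is non-numeric or outside (0, 1] raise with their line
    numbers; duplicate rsIDs are an error naming the variant.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if header[:4] != GWAS_COLUMNS:
            raise ValueError(f"malformed header {header!r}; expected {GWAS_COLUMNS}")
        rsids, chroms, poss, ps, bad = [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                bad.append((lineno, "too few fields"))
                continue
            try:
                p = float(parts[3])
                pos = int(parts[2])
            except ValueError:
                bad.append((lineno, "non-numeric field"))
                continue
            if not (0.0 < p <= 1.0):
                bad.append((lineno, f"p={parts[3]} outside (0, 1]"))
                continue
            rsids.append(parts[0])
            chroms.append(parts[1])
            poss.append(pos)
            ps.append(p)
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:5])
        raise ValueError(f"rejected {len(bad)} row(s): {detail}")
    gwas = pd.DataFrame({"rsid": rsids, "chrom": chroms, "pos": poss, "p": ps})
    dup = gwas.loc[gwas["rsid"].duplicated(), "rsid"]
    if len(dup):
        raise ValueError(f"duplicate rsID {dup.iloc[0]}")
    return gwas


def intersect_eqtl_gwas(
    eqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    gwas_thresh: float = 1e-4,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Suggestive GWAS SNPs that are significant eSNPs, with best eGene.

    Best eGene = minimum eQTL p among the SNP's records; ties broken by
    probe_id. Flags mark genome-wide significant versus sub-threshold
    GWAS hits. An empty result is returned (not raised) when nothing
    passes.
    """
    hits = gwas[gwas["p"] < gwas_thresh]
    sig = eqtl[eqtl["q"] < fdr]
    if hits.empty or sig.empty:
        return pd.DataFrame(
            columns=["rsid", "gwas_p", "best_eqtl_probe", "best_gene_symbol", "best_eqtl_p", "q", "flag"]
        )
    sig = sig.sort_values(["p", "probe_id"], kind="mergesort").drop_duplicates("rsid")
    merged = hits.merge(
        sig[["rsid", "probe_id", "gene_symbol", "p", "q"]].rename(
            columns={"probe_id": "best_eqtl_probe", "gene_symbol": "best_gene_symbol", "p": "best_eqtl_p"}
        ),
        on="rsid",
        how="inner",
    )
    merged["flag"] = np.where(merged["p"] < GENOME_WIDE_P, "genome_wide", "sub_threshold")
    out = merged.rename(columns={"p": "gwas_p"})[
        ["rsid", "gwas_p", "best_eqtl_probe", "best_gene_symbol", "best_eqtl_p", "q", "flag"]
    ]
    return out.sort_values("gwas_p", kind="mergesort").reset_index(drop=True)


def hypergeometric_enrichment(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Fold enrichment and upper-tail hypergeometric p of an overlap.

    k = overlap, n = GWAS hits in the universe, K = eSNPs in the
    universe, N = universe size (SNPs tested in both analyses).
    fold = (k/n) / (K/N); p = P(X >= k), X ~ Hypergeom(N, K, n).
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N and n > 0 and N > 0):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    fold = (k / n) / (K / N) if K > 0 else np.inf if k > 0 else np.nan
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return float(fold), min(p, 1.0)


def permute_phenotype_gwas(
    gt, phen: pd.DataFrame, n_perm: int = 50, seed: int = 0
) -> list[pd.DataFrame]:
    """Null GWAS summaries from case-control label permutations.

    Each permutation shuffles the status labels (exact case/control
    totals preserved) and recomputes per-SNP p-values with the same
    allelic score test as the observed summary. Deterministic under seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    status = phen.set_index("subject").loc[gt.dosages.index, "status"].to_numpy(dtype=int)
    if status.sum() < 2 or (status == 0).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    rng = np.random.default_rng(seed)
    G = gt.dosages.to_numpy(dtype=float)
    out = []
    for _ in range(n_perm):
        out.append(assoc_table(gt.panel, G, rng.permutation(status)))
    return out


def write_permutations(perms: list[pd.DataFrame], outdir) -> list[str]:
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = []
    for i, perm in enumerate(perms, start=1):
        path = os.path.join(outdir, f"perm_{i:03d}.assoc")
        write_gwas_summary(perm, path)
        paths.append(path)
    return paths
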