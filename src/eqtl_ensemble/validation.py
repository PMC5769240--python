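"""Community-level disease validation by Fisher meta-analysis.

Differential expression and differential methylation are tested per
feature with a covariate-adjusted linear model on case-control status.
For each network community, the member genes' probe p-values are combined
with Fisher's method, as are the CpG p-values surviving the 5%
methylation-effect filter (raw case-control beta difference strictly
above 0.05 in absolute value). A community is ``validated_both`` when
both meta-p values fall below 0.05.

Fisher's method assumes independent p-values; probes within a community
are correlated, so the combined value is reported as a meta-analysis
p-value with that caveat rather than corrected for (a Brown-style scaled
chi-square option is available but off by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def differential_test(
    matrix: pd.DataFrame,
    phen: pd.DataFrame,
    cov: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-feature linear model of value on status plus covariates.

    Returns feature_id, gene_symbol (if an annotation maps features to
    symbols), effect (covariate-adjusted status coefficient), raw_diff
    (unadjusted case-control mean difference; the methylation filter
    operates on this) and the two-sided t-test p on status.
    """
    status = phen.set_index("subject").loc[matrix.index, "status"].to_numpy(dtype=float)
    n_case, n_ctrl = int(status.sum()), int((1 - status).sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need at least 2 subjects per class")
    Y = matrix.to_numpy(dtype=float)
    n = Y.shape[0]
    C = np.ones((n, 1)) if cov is None or cov.shape[1] == 0 else np.column_stack(
        [np.ones(n), cov.loc[matrix.index].to_numpy(dtype=float)]
    )
    Q, _ = np.linalg.qr(C)
    sr = status - Q @ (Q.T @ status)
    Yr = Y - Q @ (Q.T @ Y)
    ss_s = float(sr @ sr)
    if ss_s <= 0:
        raise ValueError("status is collinear with the covariates")
    df = n - np.linalg.matrix_rank(C) - 1
    # features numerically constant after covariate adjustment are null fits
    flat = (Yr**2).sum(axis=0) <= 1e-20 * np.maximum((Y**2).sum(axis=0), 1.0)
    beta = np.where(flat, 0.0, (sr @ Yr) / ss_s)
    rss = np.clip((Yr**2).sum(axis=0) - beta**2 * ss_s, 0.0, None)
    se = np.sqrt(rss / df / ss_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.sign(beta) * np.inf))
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)
    p = np.where(flat, 1.0, p)
    raw_diff = Y[status == 1].mean(axis=0) - Y[status == 0].mean(axis=0)
    out = pd.DataFrame(
        {
            "feature_id": matrix.columns,
            "effect": beta,
            "raw_diff": raw_diff,
            "p": p,
        }
    )
    if annotation is not None:
        key = "probe_id" if "probe_id" in annotation.columns else "cpg_id"
        out["gene_symbol"] = out["feature_id"].map(
            annotation.set_index(key)["gene_symbol"]
        )
    return out


def fisher_meta(p_list) -> float:
    """Fisher's method: X = -2 sum ln p_i ~ chi-square with 2k df.

    Exact identity meta_p = p at k = 1. Survival values that underflow
    are clipped to the smallest positive float so the result stays in
    (0, 1].
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(max(stats.chi2.sf(x, df=2 * p.size), np.finfo(float).tiny))


def brown_meta(p_list, corr: np.ndarray) -> float:
    """Brown's method for correlated p-values (Kost-McDermott moments).

    Requires the correlation matrix of the underlying test statistics
    (estimable from the feature matrix, not from p-values alone). The
    Fisher statistic X = -2 sum ln p is referred to a scaled chi-square
    c * chi2(f') with c and f' matched to E[X] = 2k and
    Var[X] = 4k + 2 sum_{i<j} cov_ij, cov_ij ~= rho (3.25 + 0.75 rho).
    Off by default; Fisher matches the field's standard usage.
    """
    p = np.asarray(list(p_list), dtype=float)
    corr = np.asarray(corr, dtype=float)
    k = p.size
    if corr.shape != (k, k):
        raise ValueError("corr must be k x k for k p-values")
    x = -2.0 * np.log(p).sum()
    iu = np.triu_indices(k, 1)
    rho = corr[iu]
    var = 4.0 * k + 2.0 * np.sum(rho * (3.25 + 0.75 * rho))
    mean = 2.0 * k
    c = var / (2.0 * mean)
    f = 2.0 * mean**2 / var
    return float(max(stats.chi2.sf(x / c, df=f), np.finfo(float).tiny))


def methylation_effect_filter(dm: pd.DataFrame, min_effect: float = 0.05) -> pd.DataFrame:
    """Keep CpGs whose |raw case-control beta difference| is strictly > 5%."""
    return dm[dm["raw_diff"].abs() > min_effect].reset_index(drop=True)


def community_meta(
    roster_genes,
    de: pd.DataFrame,
    dm: pd.DataFrame,
    alpha: float = 0.05,
    min_effect: float = 0.05,
    method=fisher_meta,
) -> dict:
    """Meta-analyse one community's DE probes and effect-filtered DM CpGs.

    expression_meta_p combines ALL probes of member genes; the
    methylation side first applies the effect filter. Communities with no
    qualifying features on a side get a None meta-p on that side (shown
    as missing downstream). status: validated_both iff both meta-p exist
    and are < alpha; validated_one if exactly one side qualifies.
    """
    genes = set(roster_genes)
    de_rows = de[de["gene_symbol"].isin(genes)]
    dm_rows = methylation_effect_filter(dm[dm["gene_symbol"].isin(genes)], min_effect)
    expr_meta = method(de_rows["p"]) if len(de_rows) else None
    meth_meta = method(dm_rows["p"]) if len(dm_rows) else None
    n_de = int((de_rows["p"] < alpha).sum())
    n_dm = int((dm_rows["p"] < alpha).sum())
    ok_e = expr_meta is not None and expr_meta < alpha
    ok_m = meth_meta is not None and meth_meta < alpha
    status = "validated_both" if (ok_e and ok_m) else ("validated_one" if (ok_e or ok_m) else "not_validated")
    return {
        "n_genes": len(genes),
        "n_de_genes": n_de,
        "n_dm_genes": n_dm,
        "expression_meta_p": expr_meta,
        "methylation_meta_p": meth_meta,
        "status": status,
    }


def validate_communities(
    assign,
    de: pd.DataFrame,
    dm: pd.DataFrame,
    alpha: float = 0.05,
    min_effect: float = 0.05,
    seed_genes: list | None = None,
    gwas: pd.DataFrame | None = None,
    gwas_subthresh: float = 1e-4,
) -> pd.DataFrame:
    """Validation table over every community of an assignment.

    Columns mirror the community report: id, seed genes present, SNP and
    gene counts, sub-threshold SNP count, DE/DM feature counts, both
    meta-p values and the validation status.
    """
    seed_set = set(seed_genes or [])
    sub_p = set(gwas.loc[gwas["p"] < gwas_subthresh, "rsid"]) if gwas is not None else None
    rows = []
    tab = assign.to_table()
    for cid, grp in tab.groupby("community"):
        genes = grp.loc[grp["side"] == "gene", "node"].tolist()
        snps = grp.loc[grp["side"] == "snp", "node"].tolist()
        rec = {"community": cid, "seed_genes": ",".join(sorted(seed_set & set(genes))) or "-"}
        rec["n_snps"] = len(snps)
        rec["n_subthreshold_snps"] = (
            sum(1 for s in snps if s in sub_p) if sub_p is not None else np.nan
        )
        rec.update(community_meta(genes, de, dm, alpha=alpha, min_effect=min_effect))
        rows.append(rec)
    out = pd.DataFrame(rows)
    return out.sort_values("community").reset_index(drop=True)
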