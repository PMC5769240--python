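"""Genotype-dosage x expression association scan.

Each eSNP-eGene pair is tested by ordinary least squares of expression on
dosage plus covariates (age, sex, pack-years, ancestry PCs and expression
PCs in the default workflow). Pairs are cis when the SNP lies within a
window of the annotated gene interval (default 500 kb each side, a 1 Mb
total window) and trans otherwise; BH-FDR is applied separately within
the cis and trans analyses.

The full scan uses Frisch-Waugh-Lovell residualisation: expression and
dosage are residualised against the covariates once, then every pair's
coefficient, standard error and t-test follow from cross-products with
the covariate-adjusted degrees of freedom. ``fit_association`` is the
independent per-pair solver used to verify the vectorised route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_WINDOW_BP = 500_000


class MonomorphicError(ValueError):
    """Dosage vector is constant; the association model is undefined."""


class CollinearCovariatesError(ValueError):
    """A covariate column is linearly dependent on the preceding ones."""


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0.0) or np.any(p > 1.0) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_cis_pairs(
    panel: pd.DataFrame, probes: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP
) -> pd.DataFrame:
    """All (rsid, probe_id) pairs that are cis under the window rule.

    A pair is cis iff the SNP is on the probe's chromosome and its
    position falls in [start - window_bp, end + window_bp], boundaries
    inclusive (1-based coordinates). Everything else is trans.
    """
    panel_chroms = set(panel["chrom"].astype(str))
    unknown = set(probes["chrom"].astype(str)) - panel_chroms
    if unknown:
        raise ValueError(f"unknown chromosome label(s) in probe annotation: {sorted(unknown)}")
    out = []
    by_chrom = {str(c): g for c, g in panel.groupby(panel["chrom"].astype(str))}
    for probe_id, chrom, start, end in zip(
        probes["probe_id"], probes["chrom"].astype(str), probes["start"], probes["end"]
    ):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        mask = (pos >= start - window_bp) & (pos <= end + window_bp)
        for rsid in sub["rsid"].to_numpy()[mask]:
            out.append((rsid, probe_id))
    return pd.DataFrame(out, columns=["rsid", "probe_id"])


def _design_matrix(n: int, dosage: np.ndarray, cov: pd.DataFrame | None) -> tuple[np.ndarray, list]:
    cols = [np.ones(n), dosage]
    names = ["intercept", "dosage"]
    if cov is not None and cov.shape[1] > 0:
        for name in cov.columns:
            cols.append(cov[name].to_numpy(dtype=float))
            names.append(str(name))
    return np.column_stack(cols), names


def fit_association(
    expr_row: np.ndarray, dosage_row: np.ndarray, cov: pd.DataFrame | None = None
) -> dict:
    """OLS of one expression vector on one dosage vector plus covariates.

    Returns beta, se, t and the two-sided p for the dosage coefficient
    with residual degrees of freedom. A perfect fit reports the smallest
    representable p rather than raising.
    """
    y = np.asarray(expr_row, dtype=float)
    g = np.asarray(dosage_row, dtype=float)
    n = y.shape[0]
    if g.shape[0] != n:
        raise ValueError("expression and dosage lengths differ")
    if np.ptp(g) == 0.0:
        raise MonomorphicError("dosage is constant (monomorphic SNP)")
    X, names = _design_matrix(n, g, cov)
    if n <= X.shape[1]:
        raise ValueError("not enough subjects for the number of covariates")
    # incremental rank check names the first collinear column
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
            raise CollinearCovariatesError(f"column '{names[j]}' is collinear with earlier columns")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - X.shape[1]
    rss = float(resid @ resid)
    if rss <= 1e-24 * float(y @ y):  # numerically perfect fit
        rss = 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    sigma2 = rss / df
    se = float(np.sqrt(max(sigma2, 0.0) * xtx_inv[1, 1]))
    beta = float(coef[1])
    if se == 0.0:
        if beta == 0.0:
            t, p = 0.0, 1.0
        else:
            t = np.inf if beta > 0 else -np.inf
            p = float(np.finfo(float).tiny)
    else:
        t = beta / se
        p = float(max(2.0 * stats.t.sf(abs(t), df), np.finfo(float).tiny))
    return {"beta": beta, "se": se, "t": t, "p": p, "df": df}


def compute_expression_pcs(expr: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k principal-component scores of the subjects x probes matrix.

    Columns are centred first. Sign convention: within each component the
    probe loading of largest magnitude is made positive, so results are
    deterministic across SVD implementations. ``k=0`` returns an empty
    block (scan runs unadjusted); negative k is an error.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return pd.DataFrame(index=expr.index)
    if k >= min(expr.shape):
        raise ValueError("k must be below min(n_subjects, n_probes)")
    X = expr.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(scores, index=expr.index, columns=[f"expr_pc{j + 1}" for j in range(k)])


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


@dataclass
class ScanResult:
    """EqtlTable plus run bookkeeping (test counts, drops, thresholds)."""

    table: pd.DataFrame
    provenance: dict


def run_scan(
    gt,
    expr: pd.DataFrame,
    probes: pd.DataFrame,
    cov: pd.DataFrame | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
    cis_alpha: float = 0.05,
    trans_alpha: float = 0.05,
) -> ScanResult:
    """Test every SNP x probe pair; BH-FDR within cis and within trans.

    Monomorphic SNPs and zero-variance probes are dropped (counted in
    provenance). Output is sorted by p with columns rsid, probe_id,
    gene_symbol, beta, se, t, p, q, mode.
    """
    dosages = gt.dosages
    subjects = list(expr.index)
    if list(dosages.index) != subjects or (cov is not None and list(cov.index) != subjects):
        raise ValueError("subject IDs are not aligned across genotype/expression/covariates")

    G = dosages.to_numpy(dtype=float)
    Y = expr.to_numpy(dtype=float)
    snp_keep = np.ptp(G, axis=0) > 0
    probe_keep = np.ptp(Y, axis=0) > 0
    n_mono = int((~snp_keep).sum())
    n_flat = int((~probe_keep).sum())
    G = G[:, snp_keep]
    Y = Y[:, probe_keep]
    snp_ids = dosages.columns.to_numpy()[snp_keep]
    probe_ids = expr.columns.to_numpy()[probe_keep]
    if G.shape[1] == 0 or Y.shape[1] == 0:
        raise ValueError("empty pair set after dropping monomorphic SNPs / flat probes")

    n = G.shape[0]
    C = np.ones((n, 1)) if cov is None or cov.shape[1] == 0 else np.column_stack(
        [np.ones(n), cov.to_numpy(dtype=float)]
    )
    rank_c = np.linalg.matrix_rank(C)
    if rank_c < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    df = n - rank_c - 1
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    Q, _ = np.linalg.qr(C)
    Gr = _residualize(G, Q)
    Yr = _residualize(Y, Q)

    ssg = (Gr**2).sum(axis=0)
    ssy = (Yr**2).sum(axis=0)
    cross = Gr.T @ Yr  # SNPs x probes
    beta = cross / ssg[:, None]
    rss = np.clip(ssy[None, :] - beta * cross, 0.0, None)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / ssg[:, None])
        # zero residual with zero slope is a perfect null fit (t=0), not a signal
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.sign(beta) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    cis_pairs = assign_cis_pairs(
        gt.panel[gt.panel["rsid"].isin(snp_ids)],
        probes[probes["probe_id"].isin(probe_ids)],
        window_bp,
    )
    snp_pos = {rs: i for i, rs in enumerate(snp_ids)}
    probe_pos = {pid: j for j, pid in enumerate(probe_ids)}
    cis_mask = np.zeros((len(snp_ids), len(probe_ids)), dtype=bool)
    if len(cis_pairs):
        cis_mask[
            [snp_pos[r] for r in cis_pairs["rsid"]],
            [probe_pos[pid] for pid in cis_pairs["probe_id"]],
        ] = True

    gene_of = dict(zip(probes["probe_id"], probes["gene_symbol"]))
    S, P = len(snp_ids), len(probe_ids)
    table = pd.DataFrame(
        {
            "rsid": np.repeat(snp_ids, P),
            "probe_id": np.tile(probe_ids, S),
            "beta": beta.ravel(),
            "se": se.ravel(),
            "t": t.ravel(),
            "p": p.ravel(),
            "mode": np.where(cis_mask.ravel(), "cis", "trans"),
        }
    )
    table["gene_symbol"] = table["probe_id"].map(gene_of)
    table["q"] = np.nan
    for mode in ("cis", "trans"):
        m = table["mode"].to_numpy() == mode
        if m.any():
            table.loc[m, "q"] = bh_fdr(table.loc[m, "p"].to_numpy())
    table = table.sort_values(["p", "rsid", "probe_id"], kind="mergesort").reset_index(drop=True)
    table = table[["rsid", "probe_id", "gene_symbol", "beta", "se", "t", "p", "q", "mode"]]

    provenance = {
        "n_subjects": n,
        "n_snps_tested": S,
        "n_probes_tested": P,
        "n_cis_tests": int(cis_mask.sum()),
        "n_trans_tests": int(S * P - cis_mask.sum()),
        "n_total_tests": int(S * P),
        "n_monomorphic_snps_dropped": n_mono,
        "n_zero_variance_probes_dropped": n_flat,
        "residual_df": int(df),
        "n_covariate_columns": int(C.shape[1] - 1),
        "window_bp": int(window_bp),
        "cis_fdr_alpha": float(cis_alpha),
        "trans_fdr_alpha": float(trans_alpha),
        "n_cis_significant": int(((table["mode"] == "cis") & (table["q"] < cis_alpha)).sum()),
        "n_trans_significant": int(((table["mode"] == "trans") & (table["q"] < trans_alpha)).sum()),
    }
    return ScanResult(table=table, provenance=provenance)


def write_eqtl_table(result: ScanResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def read_eqtl_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
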