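"""Per-SNP case-control association score test.

Shared by the synthetic GWAS generator and the phenotype-permutation
machinery so observed and null summaries are computed by the identical
test (keeping them exchangeable under the null).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def score_test_pvalues(dosages: np.ndarray, status: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Logistic score test (Armitage trend test) of dosage against status.

    Parameters
    ----------
    dosages : (n_subjects, n_snps) array of allele dosages in [0, 2].
    status : (n_subjects,) 0/1 vector.

    Returns
    -------
    p : per-SNP two-sided p-values; monomorphic SNPs get p = 1.
    monomorphic : boolean flag per SNP.

    The score statistic for the dosage coefficient in a logistic model
    with intercept only under H0 is U = sum (y - ybar) g with variance
    ybar (1 - ybar) * sum (g - gbar)^2; U^2/V ~ chi^2(1).
    """
    G = np.asarray(dosages, dtype=float)
    y = np.asarray(status, dtype=float)
    if G.ndim != 2:
        raise ValueError("dosages must be 2-D (subjects x SNPs)")
    if y.shape[0] != G.shape[0]:
        raise ValueError("status length does not match dosage rows")
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("status must contain both cases and controls")
    gc = G - G.mean(axis=0)
    ss = (gc**2).sum(axis=0)
    monomorphic = ss <= 0.0
    U = (y - ybar) @ gc
    V = ybar * (1.0 - ybar) * ss
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(monomorphic, 0.0, U**2 / np.where(V > 0, V, 1.0))
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(monomorphic, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return p, monomorphic


def assoc_table(panel: pd.DataFrame, dosages: np.ndarray, status: np.ndarray) -> pd.DataFrame:
    """Run the score test and package results as a GWAS summary table."""
    p, mono = score_test_pvalues(dosages, status)
    return pd.DataFrame(
        {
            "rsid": panel["rsid"].to_numpy(),
            "chrom": panel["chrom"].to_numpy(),
            "pos": panel["pos"].to_numpy(),
            "p": p,
            "monomorphic": mono,
        }
    )
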