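"""MAGMA-style gene-level association and competitive gene-set regression.

The gene statistic is the sum of squared variant z-scores with a
Satterthwaite scaled-chi-square null that accounts for LD: for ``m`` variants
with correlation matrix R, E[T] = m and Var[T] = 2 * sum_jk R_jk^2, giving
T/g ~ chi2_h with g = Var/(2E), h = 2E^2/Var.  Competitive set association
regresses probit-transformed genic p-values on set membership with gene-size
covariates and reports a one-sided test of the membership coefficient.
Numerical parity with any particular external implementation is not claimed;
calibration is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: genic boundary extensions in bp: (upstream, downstream)
BOUNDARIES = {"conservative": (5000, 1500), "liberal": (35000, 10000)}


@dataclass
class GeneAssoc:
    gene_id: str
    n_snps: int
    stat_T: float
    p_gene: float
    z_gene: float
    length_bp: int


@dataclass
class SetAssoc:
    set_name: str
    beta_s: float
    se: float
    p_one_sided: float
    n_set_genes: int
    boundary: str


def gene_windows(genes, boundary: str) -> pd.DataFrame:
    """Strand-aware annotation windows, 1-based inclusive.

    On the + strand the window is [start - up, end + down]; on the - strand
    upstream lies beyond ``end`` so the window mirrors to
    [start - down, end + up].
    """
    up, down = BOUNDARIES[boundary]
    df = genes.df
    plus = df["strand"] == "+"
    start = np.where(plus, df["start"] - up, df["start"] - down)
    end = np.where(plus, df["end"] + down, df["end"] + up)
    return pd.DataFrame({
        "gene_id": df["gene_id"], "chrom": df["chrom"],
        "window_start": np.maximum(start, 1).astype(int),
        "window_end": end.astype(int),
        "length_bp": (df["end"] - df["start"] + 1).astype(int),
    })


def annotate_snps(stats, genes, boundary: str) -> dict[str, list[str]]:
    """Map each gene to the variant_ids inside its boundary window.

    Bounds are inclusive; a variant may annotate to several genes.  ``stats``
    may be a SummaryStats or any DataFrame-bearing object with variant_id,
    chrom, pos.
    """
    vdf = stats.df if hasattr(stats, "df") else stats
    windows = gene_windows(genes, boundary)
    out: dict[str, list[str]] = {}
    for chrom, wgrp in windows.groupby("chrom"):
        v = vdf[vdf["chrom"] == chrom].sort_values("pos")
        pos = v["pos"].to_numpy()
        ids = v["variant_id"].to_numpy()
        for w in wgrp.itertuples(index=False):
            lo = np.searchsorted(pos, w.window_start, side="left")
            hi = np.searchsorted(pos, w.window_end, side="right")
            out[w.gene_id] = list(ids[lo:hi])
    # genes on chromosomes absent from the stats still get an entry
    for g in windows["gene_id"]:
        out.setdefault(g, [])
    return out


def gene_stat(gene_id: str, z_scores: np.ndarray, ld: np.ndarray,
              length_bp: int) -> GeneAssoc:
    """Aggregate variant z-scores into a gene-level association p-value."""
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValueError(f"gene_stat {gene_id}: no variants")
    R = np.atleast_2d(np.asarray(ld, dtype=float))
    if not np.all(np.isfinite(R)) or np.max(np.abs(R)) > 1.0 + 1e-8:
        raise ValueError(f"gene_stat {gene_id}: invalid LD matrix")
    m = z.size
    T = float(np.sum(z ** 2))
    var = 2.0 * float(np.sum(R ** 2))
    g = var / (2.0 * m)          # scale
    h = 2.0 * m * m / var        # effective df
    p = float(sps.chi2.sf(T / g, h))
    p = min(max(p, np.nextafter(0, 1)), 1.0 - 1e-16)
    z_gene = float(sps.norm.isf(p))
    return GeneAssoc(gene_id, m, T, p, z_gene, length_bp)


def competitive_set_test(gene_assocs: list[GeneAssoc],
                         set_members: set[str],
                         set_name: str = "set",
                         boundary: str = "conservative",
                         use_covariates: bool = True) -> SetAssoc:
    """One-sided competitive regression: are set genes more associated?

    OLS of z_gene on a membership indicator plus log gene length and log
    variant count; the reported p is the upper-tail t probability of the
    membership coefficient.  Without covariates and with balanced groups this
    reduces to a one-sided two-sample t-test.
    """
    df = pd.DataFrame([vars(a) for a in gene_assocs])
    df["in_set"] = df["gene_id"].isin(set_members).astype(float)
    n_in = int(df["in_set"].sum())
    if n_in == 0:
        raise ValueError("competitive_set_test: set does not intersect genes")
    if len(df) - n_in < 10:
        raise ValueError("competitive_set_test: fewer than 10 genes outside "
                         "the set (no contrast)")
    cols = ["in_set"]
    X = [df["in_set"].to_numpy()]
    if use_covariates:
        X.append(np.log(df["length_bp"].to_numpy(dtype=float)))
        X.append(np.log(df["n_snps"].to_numpy(dtype=float)))
        cols += ["log_length", "log_nsnps"]
    X = np.column_stack([np.ones(len(df))] + X)
    y = df["z_gene"].to_numpy()
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(df) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    beta_s = float(coef[1])
    p = float(sps.t.sf(beta_s / se, dof))
    return SetAssoc(set_name, beta_s, se, p, n_in, boundary)
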