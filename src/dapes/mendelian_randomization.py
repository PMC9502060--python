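"""Two-sample Mendelian randomization of expression on disease using QTL instruments.

Instrument selection follows a deliberately strict recipe: genome-wide
significant QTLs (p < 5e-8) hitting at most three genes, thinned to
independence by greedy 1-megabase clumping at r² < 0.001, with trans-acting
QTLs excluded by default.  Effects are estimated per SD of expression with
the Wald ratio (one instrument) or a fixed-effect inverse-variance-weighted
pool (several instruments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_formats import LDReference

logger = logging.getLogger("dapes")

GW_SIGNIFICANCE = 5e-8


@dataclass
class InstrumentSet:
    """Validated instruments for one gene model; may be empty ("no IV")."""

    gene_id: str
    tissue: str
    instruments: pd.DataFrame  # variant_id, chrom, pos, beta_qtl, se_qtl, p_qtl

    @property
    def n_iv(self) -> int:
        return len(self.instruments)


@dataclass
class MrResult:
    gene_id: str
    beta_mr: float
    se_mr: float
    p: float
    method: str  # "wald" | "ivw_fixed"
    n_iv: int
    significant: bool = False


def select_instruments(gene_id: str, tissue: str, qtl_table: pd.DataFrame,
                       ld: LDReference | None,
                       clump_kb: float = 1000.0, clump_r2: float = 0.001,
                       pleiotropy_max: int = 3,
                       p_threshold: float = GW_SIGNIFICANCE,
                       include_trans: bool = False) -> InstrumentSet:
    """Filter and clump a QTL table into an instrument set for one gene.

    ``qtl_table`` columns: variant_id, chrom, pos, beta_qtl, se_qtl, p_qtl,
    n_genes_hit and optionally is_trans.  Variants hitting more than
    ``pleiotropy_max`` genes are removed before significance filtering; the
    survivors are greedily clumped (ascending p; ties broken by position then
    variant_id) so retained instruments are pairwise independent at
    ``clump_r2`` within ``clump_kb`` windows.  An empty set is a valid result
    (the gene simply has no suitable IV).
    """
    q = qtl_table.copy()
    if not include_trans and "is_trans" in q.columns:
        q = q[~q["is_trans"].astype(bool)]
    q = q[(q["n_genes_hit"] <= pleiotropy_max)
          & (q["p_qtl"] < p_threshold)]
    q = q.sort_values(["p_qtl", "pos", "variant_id"]).reset_index(drop=True)

    kept: list[int] = []
    for i in range(len(q)):
        row = q.iloc[i]
        independent = True
        for j in kept:
            other = q.iloc[j]
            if row["chrom"] == other["chrom"] and \
                    abs(row["pos"] - other["pos"]) <= clump_kb * 1000:
                r2 = 1.0 if ld is None else \
                    ld.r2(row["variant_id"], other["variant_id"])
                if r2 >= clump_r2:
                    independent = False
                    break
        if independent:
            kept.append(i)
    out = q.iloc[kept].reset_index(drop=True)
    if out.empty:
        logger.info("select_instruments: no suitable IV for %s/%s",
                    gene_id, tissue)
    cols = [c for c in ("variant_id", "chrom", "pos", "beta_qtl", "se_qtl",
                        "p_qtl", "n_genes_hit") if c in out.columns]
    return InstrumentSet(gene_id, tissue, out[cols])


def wald_ratio(beta_gwas: float, se_gwas: float, beta_qtl: float,
               se_qtl: float, gene_id: str = "") -> MrResult:
    """Single-instrument causal estimate beta_gwas / beta_qtl.

    The standard error is the first-order delta-method value
    |se_gwas / beta_qtl| (the QTL uncertainty term is second order).
    """
    if beta_qtl == 0:
        raise ValueError("wald_ratio: beta_qtl must be nonzero")
    beta = beta_gwas / beta_qtl
    se = abs(se_gwas / beta_qtl)
    p = 2.0 * sps.norm.sf(abs(beta / se)) if se > 0 else np.nan
    return MrResult(gene_id, beta, se, p, method="wald", n_iv=1)


def ivw_fixed(ratios: list[MrResult], gene_id: str = "",
              allow_single: bool = False) -> MrResult:
    """Fixed-effect inverse-variance-weighted pool of per-instrument ratios.

    Requires >= 2 instruments (use the Wald ratio for one) unless
    ``allow_single`` forces the degenerate pool, which then equals the Wald
    ratio exactly.
    """
    if len(ratios) < 2 and not allow_single:
        raise ValueError("ivw_fixed requires >= 2 instruments; "
                         "use wald_ratio for a single IV")
    b = np.array([r.beta_mr for r in ratios])
    w = np.array([r.se_mr for r in ratios], dtype=float) ** -2.0
    finite = np.isfinite(w)
    b, w = b[finite], w[finite]
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = 2.0 * sps.norm.sf(abs(beta / se))
    return MrResult(gene_id or ratios[0].gene_id, beta, se, p,
                    method="ivw_fixed", n_iv=int(finite.sum()))


def mr_estimate(instruments: InstrumentSet,
                gwas_effects: pd.DataFrame) -> MrResult | None:
    """Wald ratio or fixed-effect IVW depending on the number of instruments.

    ``gwas_effects`` columns: variant_id, beta, se (harmonized to the QTL
    effect allele).  Returns None when the set is empty.
    """
    merged = instruments.instruments.merge(gwas_effects, on="variant_id")
    if merged.empty:
        return None
    ratios = [wald_ratio(r.beta, r.se, r.beta_qtl, r.se_qtl,
                         gene_id=instruments.gene_id)
              for r in merged.itertuples(index=False)]
    if len(ratios) == 1:
        return ratios[0]
    return ivw_fixed(ratios, gene_id=instruments.gene_id)


def format_percent_change(beta_mr: float, se_mr: float) -> str:
    """Report a log-odds MR estimate as a percent change with 95% Wald CI."""
    lo = (abs(beta_mr) - 1.96 * se_mr) * 100
    hi = (abs(beta_mr) + 1.96 * se_mr) * 100
    word = "decrease" if beta_mr < 0 else "increase"
    return f"{abs(beta_mr) * 100:.2f}% (95% CI: {lo:.2f}%, {hi:.2f}%) {word}"


def mr_phewas(beta_qtl: float, se_qtl: float,
              trait_effects: pd.DataFrame,
              fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Phenome scan: Wald ratio of one instrument against many trait GWASs.

    ``trait_effects`` columns: trait, beta, se (the instrument SNP's effect
    on each trait).  Adds Benjamini-Hochberg flags at ``fdr_alpha``.
    """
    if trait_effects.empty:
        raise ValueError("mr_phewas: empty trait table")
    rows = []
    for r in trait_effects.itertuples(index=False):
        res = wald_ratio(r.beta, r.se, beta_qtl, se_qtl, gene_id=str(r.trait))
        rows.append({"trait": r.trait, "beta_mr": res.beta_mr,
                     "se_mr": res.se_mr, "p": res.p})
    out = pd.DataFrame(rows)
    reject, _, _, _ = multipletests(out["p"], alpha=fdr_alpha, method="fdr_bh")
    out["fdr_significant"] = reject
    return out


def bonferroni_flag(results: list[MrResult], alpha: float = 0.05,
                    n_models: int | None = None) -> list[MrResult]:
    """Bonferroni flagging across tissues/models, matching the TWAS behavior."""
    from .grex_twas import multiple_test_correct

    return multiple_test_correct(results, alpha=alpha, n_models=n_models)
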