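"""Validated in-memory tables and readers/writers for every file the pipeline touches.

All tab-delimited formats carry a header row.  Coordinates are 1-based
inclusive throughout (VCF convention); interval arithmetic on genic windows is
documented at each API boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dapes")

VALID_BASES = {"A", "C", "G", "T"}
#: Strand-ambiguous allele pairs that cannot be oriented without frequency info.
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class FormatError(ValueError):
    """A file does not conform to the expected column layout."""


class ValidationError(ValueError):
    """A table parsed correctly but violates an invariant."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing mandatory column(s) {missing}")


def _check_unique(values: pd.Series, what: str) -> None:
    dup = values[values.duplicated()]
    if len(dup):
        raise ValidationError(
            f"{what}: duplicate identifiers {sorted(set(dup))[:10]}"
            + ("..." if dup.nunique() > 10 else "")
        )


# ---------------------------------------------------------------------------
# SummaryStats
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Per-variant GWAS effects: the z-scores consumed by every downstream stage.

    Columns: variant_id, chrom, pos, effect_allele, other_allele, beta, se,
    pvalue and optionally eaf / n.  ``beta`` is on the log-odds (binary trait)
    or SD (continuous trait) scale.
    """

    df: pd.DataFrame

    REQUIRED = ("variant_id", "chrom", "pos", "effect_allele",
                "other_allele", "beta", "se", "pvalue")

    def __post_init__(self) -> None:
        _require_columns(self.df, self.REQUIRED, "SummaryStats")
        _check_unique(self.df["variant_id"], "SummaryStats.variant_id")
        bad_p = ~((self.df["pvalue"] > 0) & (self.df["pvalue"] <= 1))
        if bad_p.any():
            raise ValidationError(
                f"SummaryStats: {int(bad_p.sum())} p-values outside (0, 1]")
        self.df = self.df.reset_index(drop=True)

    @property
    def z(self) -> np.ndarray:
        return (self.df["beta"] / self.df["se"]).to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_summary_stats(path, column_map: Mapping[str, str] | None = None,
                       beta_is_odds_ratio: bool = False) -> SummaryStats:
    """Read a tab-delimited GWAS summary-statistics file.

    Parameters
    ----------
    column_map
        mapping from canonical names (variant_id, chrom, pos, effect_allele,
        other_allele, beta, se, pvalue, eaf, n) to the file's column names.
    beta_is_odds_ratio
        if True the mapped beta column holds odds ratios and is stored as
        ln(OR).

    Rows with non-finite or non-positive standard errors, or non-finite betas,
    are dropped with the count logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    _require_columns(df, SummaryStats.REQUIRED, f"summary stats {path}")
    keep = [c for c in df.columns
            if c in SummaryStats.REQUIRED + ("eaf", "n")]
    df = df[keep].copy()
    df["chrom"] = df["chrom"].astype(str)
    if beta_is_odds_ratio:
        df["beta"] = np.log(df["beta"].astype(float))
    for col in ("beta", "se", "pvalue"):
        df[col] = df[col].astype(float)
    ok = np.isfinite(df["beta"]) & np.isfinite(df["se"]) & (df["se"] > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("read_summary_stats: dropped %d rows with non-finite "
                       "beta/se or se <= 0", n_dropped)
    return SummaryStats(df[ok].reset_index(drop=True))


# ---------------------------------------------------------------------------
# GeneTable
# ---------------------------------------------------------------------------

@dataclass
class GeneTable:
    """Genic coordinates (1-based inclusive) used for variant annotation."""

    df: pd.DataFrame

    REQUIRED = ("gene_id", "chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        _require_columns(self.df, self.REQUIRED, "GeneTable")
        _check_unique(self.df["gene_id"], "GeneTable.gene_id")
        if (self.df["start"] > self.df["end"]).any():
            raise ValidationError("GeneTable: start > end")
        bad = ~self.df["strand"].isin(["+", "-"])
        if bad.any():
            logger.warning("GeneTable: %d genes with unknown strand treated "
                           "as '+'", int(bad.sum()))
            self.df = self.df.copy()
            self.df.loc[bad, "strand"] = "+"
        self.df = self.df.reset_index(drop=True)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> GeneTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneTable(df)


def write_bed(gene_windows: pd.DataFrame, path) -> None:
    """Export annotated genic windows as BED (0-based half-open intervals).

    Expects columns chrom, window_start, window_end, gene_id with 1-based
    inclusive windows; converts to the BED convention on write.
    """
    out = pd.DataFrame({
        "chrom": gene_windows["chrom"],
        "start": gene_windows["window_start"].astype(int) - 1,
        "end": gene_windows["window_end"].astype(int),
        "name": gene_windows["gene_id"],
    })
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# WeightPanel
# ---------------------------------------------------------------------------

@dataclass
class WeightPanel:
    """Per-gene variant weights defining genetically regulated expression.

    ``weights`` has one row per (gene, variant): gene_id, tissue, variant_id,
    effect_allele, weight; ``genes`` has one row per gene model: gene_id,
    tissue, cis_h2_p (significance of multivariate cis-heritability).
    """

    weights: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.weights,
                         ("gene_id", "tissue", "variant_id", "effect_allele",
                          "weight"), "WeightPanel.weights")
        _require_columns(self.genes, ("gene_id", "tissue", "cis_h2_p"),
                         "WeightPanel.genes")
        if not np.isfinite(self.weights["weight"]).all():
            raise ValidationError("WeightPanel: non-finite weights")
        counts = self.weights.groupby(["gene_id", "tissue"]).size()
        empty = set(map(tuple, self.genes[["gene_id", "tissue"]].to_numpy())) \
            - set(counts.index)
        if empty:
            raise ValidationError(
                f"WeightPanel: gene models with no variants: {sorted(empty)[:5]}")

    def gene_weights(self, gene_id: str, tissue: str) -> pd.DataFrame:
        w = self.weights
        return w[(w["gene_id"] == gene_id) & (w["tissue"] == tissue)] \
            .reset_index(drop=True)

    def models(self):
        """Iterate over (gene_id, tissue, cis_h2_p) model records."""
        return self.genes.itertuples(index=False)

    def write(self, weights_path, genes_path) -> None:
        self.weights.to_csv(weights_path, sep="\t", index=False)
        self.genes.to_csv(genes_path, sep="\t", index=False)


def read_weight_panel(weights_path, genes_path) -> WeightPanel:
    return WeightPanel(pd.read_csv(weights_path, sep="\t"),
                       pd.read_csv(genes_path, sep="\t"))


# ---------------------------------------------------------------------------
# EdgeTable
# ---------------------------------------------------------------------------

EDGE_CHANNELS = ("experimental", "database", "other")


@dataclass
class EdgeTable:
    """Undirected protein-protein interaction edges with confidence scores.

    Self-loops are removed on load and (a, b)/(b, a) duplicates collapsed to a
    canonical ordering keeping the maximum confidence.
    """

    df: pd.DataFrame

    REQUIRED = ("gene_a", "gene_b", "confidence", "channel")

    def __post_init__(self) -> None:
        _require_columns(self.df, self.REQUIRED, "EdgeTable")
        df = self.df.copy()
        bad_conf = ~((df["confidence"] >= 0) & (df["confidence"] <= 1))
        if bad_conf.any():
            raise ValidationError("EdgeTable: confidence outside [0, 1]")
        bad_chan = ~df["channel"].isin(EDGE_CHANNELS)
        if bad_chan.any():
            raise ValidationError(
                f"EdgeTable: unknown channel values "
                f"{sorted(df.loc[bad_chan, 'channel'].unique())}")
        n_self = int((df["gene_a"] == df["gene_b"]).sum())
        if n_self:
            logger.info("EdgeTable: removed %d self-loops", n_self)
            df = df[df["gene_a"] != df["gene_b"]]
        a = df["gene_a"].astype(str).to_numpy()
        b = df["gene_b"].astype(str).to_numpy()
        df = df.assign(gene_a=np.where(a <= b, a, b),
                       gene_b=np.where(a <= b, b, a))
        df = (df.sort_values("confidence", ascending=False)
                .drop_duplicates(["gene_a", "gene_b", "channel"])
                .sort_values(["gene_a", "gene_b"])
                .reset_index(drop=True))
        self.df = df

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_edge_table(path) -> EdgeTable:
    return EdgeTable(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# DrugGeneTable
# ---------------------------------------------------------------------------

INTERACTION_TYPES = ("agonist", "activator", "antagonist", "inhibitor",
                     "blocker", "other")


@dataclass
class DrugGeneTable:
    """Drug-gene interactions; ``sources`` is a comma-joined list on disk."""

    df: pd.DataFrame

    REQUIRED = ("drug", "gene_id", "interaction_type", "sources")

    def __post_init__(self) -> None:
        _require_columns(self.df, self.REQUIRED, "DrugGeneTable")
        df = self.df.copy()
        bad = ~df["interaction_type"].isin(INTERACTION_TYPES)
        if bad.any():
            raise ValidationError(
                f"DrugGeneTable: unknown interaction types "
                f"{sorted(df.loc[bad, 'interaction_type'].unique())}")
        df["sources"] = df["sources"].apply(_as_source_list)
        if (df["sources"].str.len() == 0).any():
            raise ValidationError("DrugGeneTable: empty source lists")
        self.df = df.reset_index(drop=True)

    def write(self, path) -> None:
        out = self.df.copy()
        out["sources"] = out["sources"].str.join(",")
        out.to_csv(path, sep="\t", index=False)


def _as_source_list(value):
    if isinstance(value, (list, tuple)):
        return [str(v) for v in value]
    return [s for s in str(value).split(",") if s]


def read_drug_gene_table(path) -> DrugGeneTable:
    return DrugGeneTable(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# CohortTable
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Individual-level dosages plus phenotype/covariates.

    dosages: (n_samples, n_variants) float array in [0, 2];
    variants: DataFrame(variant_id, chrom, pos, effect_allele, other_allele);
    phenotype: 0/1 or float Series indexed like sample_ids (optional);
    covariates: DataFrame indexed like sample_ids (optional).
    """

    sample_ids: list[str]
    dosages: np.ndarray
    variants: pd.DataFrame
    phenotype: pd.Series | None = None
    covariates: pd.DataFrame | None = None
    imputed_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if not np.issubdtype(self.dosages.dtype, np.floating):
            self.dosages = self.dosages.astype(np.float32)
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValidationError("CohortTable: sample_ids/dosages mismatch")
        if m != len(self.variants):
            raise ValidationError("CohortTable: variants/dosages mismatch")
        if np.nanmin(self.dosages, initial=0.0) < 0 or \
                np.nanmax(self.dosages, initial=0.0) > 2:
            raise ValidationError("CohortTable: dosages outside [0, 2]")
        _check_unique(self.variants["variant_id"], "CohortTable.variant_id")
        if self.covariates is not None and self.covariates.isna().any().any():
            raise ValidationError("CohortTable: missing covariate values")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self) -> pd.Series:
        return pd.Series(np.arange(self.n_variants),
                         index=self.variants["variant_id"])

    def subset_samples(self, idx) -> "CohortTable":
        idx = np.asarray(idx)
        return CohortTable(
            [self.sample_ids[i] for i in idx],
            self.dosages[idx],
            self.variants,
            None if self.phenotype is None else
            self.phenotype.iloc[idx].reset_index(drop=True),
            None if self.covariates is None else
            self.covariates.iloc[idx].reset_index(drop=True),
        )


def read_genotypes(path, region: str | None = None) -> CohortTable:
    """Load genotypes from a VCF into a CohortTable fragment (no phenotype).

    Dosage is the DS field where present, otherwise the alternate-allele count
    from GT.  Missing genotypes are mean-imputed per variant and flagged in
    ``imputed_mask``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_cols, imputed_cols = [], [], []
    iterator = vcf(region) if region else vcf
    for var in iterator:
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            miss = ~np.isfinite(d)
        else:
            gt = np.asarray(var.genotypes)[:, :2]
            miss = (gt < 0).any(axis=1)
            d = gt.clip(min=0).sum(axis=1).astype(float)
        if miss.any():
            mean = d[~miss].mean() if (~miss).any() else 0.0
            d[miss] = mean
        rows.append({
            "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
            "chrom": str(var.CHROM), "pos": int(var.POS),
            "effect_allele": var.ALT[0] if var.ALT else ".",
            "other_allele": var.REF,
        })
        dosage_cols.append(d)
        imputed_cols.append(miss)
    if not rows:
        raise FormatError(f"{path}: no variants parsed"
                          + (f" in region {region}" if region else ""))
    return CohortTable(samples, np.column_stack(dosage_cols),
                       pd.DataFrame(rows),
                       imputed_mask=np.column_stack(imputed_cols))


class LDReference:
    """Pairwise LD (Pearson r / r²) computed from reference genotype dosages.

    ``max_samples`` caps the number of reference individuals used (the first
    rows, deterministically) — a few hundred to a couple of thousand gives
    LD-panel-grade precision at a fraction of the cost.
    """

    def __init__(self, cohort: CohortTable, max_samples: int | None = None):
        self.cohort = cohort
        X = cohort.dosages
        if max_samples is not None and X.shape[0] > max_samples:
            X = X[:max_samples]
        sd = X.std(axis=0)
        sd = np.where(sd == 0, np.nan, sd)
        self._std = np.asfortranarray((X - X.mean(axis=0)) / sd,
                                      dtype=np.float32)
        self._index = {v: i for i, v in
                       enumerate(cohort.variants["variant_id"])}
        self.positions = cohort.variants.set_index("variant_id")["pos"]

    def corr(self, variant_ids: Sequence[str]) -> np.ndarray:
        cols = [self._index[v] for v in variant_ids]
        Z = self._std[:, cols].astype(np.float64)
        R = np.nan_to_num(Z.T @ Z / Z.shape[0])
        np.fill_diagonal(R, 1.0)
        return np.clip(R, -1.0, 1.0)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        za = self._std[:, self._index[a]]
        zb = self._std[:, self._index[b]]
        r = float(np.nan_to_num(za @ zb / len(za)))
        return min(r * r, 1.0)

    def r2_many(self, a: str, others: Sequence[str]) -> np.ndarray:
        """r² of one variant against many (vectorized)."""
        za = self._std[:, self._index[a]]
        cols = [self._index[v] for v in others]
        r = np.nan_to_num(za @ self._std[:, cols] / len(za))
        return np.minimum(r * r, 1.0)


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizeReport:
    n_matched: int
    n_flipped: int
    n_palindromic: int
    n_mismatched: int


def is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    pairs = list(zip(a1, a2))
    return pd.Series([p in PALINDROMIC_PAIRS for p in pairs], index=a1.index)


def harmonize_alleles(stats: SummaryStats, panel: pd.DataFrame,
                      drop_palindromic: bool = True,
                      ) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Join GWAS effects onto a variant panel, orienting betas to the panel's
    effect allele.

    ``panel`` needs columns variant_id and effect_allele (other_allele
    optional); any payload columns (e.g. ``weight``) pass through unchanged.
    Records whose stats alleles are the reverse of the panel's coding get
    their beta negated and eaf reflected (1 - eaf).  Strand-ambiguous
    palindromic variants (A/T, C/G) are dropped by default; allele pairs that
    are neither a match nor a flip are dropped and counted.
    """
    s = stats.df.set_index("variant_id")
    s = s[["effect_allele", "other_allele", "beta", "se", "pvalue"]
          + (["eaf"] if "eaf" in s.columns else [])]
    s = s.rename(columns={"effect_allele": "effect_allele_stats",
                          "other_allele": "other_allele_stats"})
    joined = panel.merge(s, left_on="variant_id", right_index=True,
                         how="inner")

    same = joined["effect_allele"] == joined["effect_allele_stats"]
    flipped = joined["effect_allele"] == joined["other_allele_stats"]
    if "other_allele" in panel.columns:
        same &= joined["other_allele"] == joined["other_allele_stats"]
        flipped &= joined["other_allele"] == joined["effect_allele_stats"]
    palindromic = is_palindromic(joined["effect_allele_stats"],
                                 joined["other_allele_stats"]).to_numpy()

    keep = (same | flipped).to_numpy()
    n_mismatched = int((~keep).sum())
    if drop_palindromic:
        keep &= ~palindromic
    out = joined[keep].copy()
    flip = flipped[keep].to_numpy()
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    if "eaf" in out.columns:
        out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
    out = out.drop(columns=["effect_allele_stats", "other_allele_stats"])
    report = HarmonizeReport(
        n_matched=int(same[keep].sum()), n_flipped=int(flip.sum()),
        n_palindromic=int(palindromic.sum()) if drop_palindromic else 0,
        n_mismatched=n_mismatched)
    if report.n_palindromic or report.n_mismatched:
        logger.info("harmonize_alleles: %d palindromic and %d mismatched "
                    "variants dropped", report.n_palindromic,
                    report.n_mismatched)
    return out.reset_index(drop=True), report
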