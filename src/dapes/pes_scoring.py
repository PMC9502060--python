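"""Construction and application of pharmagenic enrichment scores (PES) and
genome-wide polygenic risk scores (PRS).

A PES for individual *i* over gene set *M* is the dosage-weighted sum of GWAS
effect sizes of the variants annotated to at least one gene in *M*:

    PES_i = sum_j beta_hat_j * G_ij,        G_ij in [0, 2],

and a genome-wide PRS is the special case where *M* is the whole genome.
Two model builders are provided: LD clumping + p-value thresholding (C+T)
and a summary-statistic penalized regression that minimizes

    f(beta) = beta'((1-s)R + sI)beta - 2 beta'r + 2 lambda ||beta||_1,

with r = z/sqrt(n), by cyclic coordinate descent — the lassosum formulation,
with the constraint parameter s chosen from an a-priori grid and lambda tuned
by the training-cohort score/phenotype correlation.

Determinism: every ordering tie is broken by (p, position, variant_id)
lexicographically so rebuilds are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CohortTable, LDReference, SummaryStats

logger = logging.getLogger("dapes")

CT_THRESHOLDS = (0.005, 0.05, 0.5, 1.0)
LASSO_S_GRID = (0.2, 0.5, 0.9, 1.0)


@dataclass
class ScoreModel:
    """A (variant, effect allele, coefficient) triple list defining a score."""

    name: str
    variants: pd.DataFrame  # variant_id, effect_allele, coefficient
    method: str             # "ct" | "lasso"
    params: dict = field(default_factory=dict)
    gene_set: list[str] | None = None
    boundary: str | None = None

    def __post_init__(self) -> None:
        v = self.variants
        if v["variant_id"].duplicated().any():
            raise ValueError(f"ScoreModel {self.name}: duplicate variants")
        if not np.isfinite(v["coefficient"]).all():
            raise ValueError(f"ScoreModel {self.name}: non-finite coefficients")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def write(self, path) -> None:
        self.variants.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, name: str, method: str = "ct") -> "ScoreModel":
        return cls(name, pd.read_csv(path, sep="\t"), method)


@dataclass
class ScoreVector:
    """Raw and standardized (mean 0, SD 1 over the scoring cohort) scores."""

    sample_ids: list[str]
    raw: np.ndarray
    scaled: np.ndarray

    @classmethod
    def from_raw(cls, sample_ids, raw: np.ndarray) -> "ScoreVector":
        raw = np.asarray(raw, dtype=float)
        sd = raw.std()
        if sd == 0:
            raise ValueError("ScoreVector: degenerate score (zero variance)")
        return cls(list(sample_ids), raw, (raw - raw.mean()) / sd)


def _clump_order(df: pd.DataFrame) -> np.ndarray:
    return df.sort_values(["pvalue", "pos", "variant_id"],
                          kind="mergesort").index.to_numpy()


def clump(stats: SummaryStats, ld: LDReference,
          window_kb: float = 250.0, r2_max: float = 0.1,
          restrict_to: set[str] | None = None) -> list[str]:
    """Greedy LD clumping: retained variants are pairwise near-independent.

    Variants are visited in ascending p (ties: position, then variant_id);
    each retained index variant removes all not-yet-retained variants within
    ``window_kb`` whose r² with it exceeds ``r2_max``.
    """
    df = stats.df
    if restrict_to is not None:
        df = df[df["variant_id"].isin(restrict_to)]
    df = df.reset_index(drop=True)
    order = _clump_order(df)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    vid = df["variant_id"].to_numpy()
    removed = np.zeros(len(df), dtype=bool)
    retained: list[str] = []
    window = window_kb * 1000
    for i in order:
        if removed[i]:
            continue
        retained.append(vid[i])
        removed[i] = True
        near = np.flatnonzero((chrom == chrom[i])
                              & (np.abs(pos - pos[i]) <= window)
                              & ~removed)
        if near.size:
            r2 = ld.r2_many(vid[i], list(vid[near]))
            removed[near[r2 > r2_max]] = True
    return retained


def build_ct_model(stats: SummaryStats, clumped: list[str],
                   p_threshold: float, name: str,
                   gene_set: list[str] | None = None,
                   boundary: str | None = None) -> ScoreModel:
    """Clumping + thresholding model: GWAS betas of clumped variants with
    p <= threshold."""
    df = stats.df.set_index("variant_id").loc[clumped].reset_index()
    df = df[df["pvalue"] <= p_threshold]
    if df.empty:
        raise ValueError(f"build_ct_model {name}: no variants survive "
                         f"p <= {p_threshold}")
    variants = df[["variant_id", "effect_allele"]].copy()
    variants["coefficient"] = df["beta"].to_numpy()
    return ScoreModel(name, variants.reset_index(drop=True), "ct",
                      params={"p_threshold": p_threshold},
                      gene_set=gene_set, boundary=boundary)


# ---------------------------------------------------------------------------
# Penalized regression (lassosum-style)
# ---------------------------------------------------------------------------

def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def lasso_objective(beta: np.ndarray, R: np.ndarray, r: np.ndarray,
                    s: float, lam: float) -> float:
    A = (1.0 - s) * R + s * np.eye(len(r))
    return float(beta @ A @ beta - 2.0 * beta @ r
                 + 2.0 * lam * np.abs(beta).sum())


def coordinate_descent(R: np.ndarray, r: np.ndarray, s: float, lam: float,
                       beta0: np.ndarray | None = None,
                       max_sweeps: int = 200, tol: float = 1e-8,
                       ) -> tuple[np.ndarray, bool]:
    """Cyclic coordinate descent on the penalized summary-statistic objective.

    At s = 1 each update is the closed-form soft threshold of r_j.  The
    objective is non-increasing over sweeps (asserted in debug mode).
    Returns (beta, converged); non-convergence yields the best iterate with a
    warning.
    """
    m = len(r)
    beta = np.zeros(m) if beta0 is None else beta0.copy()
    diag = (1.0 - s) * np.diag(R) + s
    prev_obj = lasso_objective(beta, R, r, s, lam)
    converged = False
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(m):
            old = beta[j]
            partial = (1.0 - s) * (R[j] @ beta - R[j, j] * old)
            beta[j] = _soft(r[j] - partial, lam) / diag[j]
            max_delta = max(max_delta, abs(beta[j] - old))
        if __debug__:
            obj = lasso_objective(beta, R, r, s, lam)
            assert obj <= prev_obj + 1e-9, "objective increased"
            prev_obj = obj
        if max_delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("coordinate_descent: no convergence after %d sweeps "
                       "(s=%.2f, lambda=%.4g); using best iterate",
                       max_sweeps, s, lam)
    return beta, converged


def _position_blocks(pos: np.ndarray, chrom: np.ndarray,
                     gap_kb: float = 250.0,
                     max_size: int = 256) -> list[np.ndarray]:
    """Contiguous index runs separated by > gap_kb (or a chromosome change).

    Off-block LD is treated as zero, so the objective separates across blocks
    and memory stays bounded.  Runs longer than ``max_size`` variants are cut
    (LD-block-style windowing) to keep the per-block solve quadratic in a
    small constant.
    """
    blocks, current = [], [0]
    for i in range(1, len(pos)):
        if chrom[i] != chrom[i - 1] or pos[i] - pos[i - 1] > gap_kb * 1000 \
                or len(current) >= max_size:
            blocks.append(np.array(current))
            current = [i]
        else:
            current.append(i)
    blocks.append(np.array(current))
    return blocks


def default_lambda_grid(r: np.ndarray, n_points: int = 20) -> np.ndarray:
    hi = max(np.abs(r).max(), 2e-4)
    return np.geomspace(1e-4, hi, n_points)


def build_lasso_model(stats: SummaryStats, ld: LDReference,
                      training: CohortTable, phenotype: np.ndarray,
                      name: str,
                      s_grid=LASSO_S_GRID,
                      lambda_grid: np.ndarray | None = None,
                      restrict_to: set[str] | None = None,
                      gene_set: list[str] | None = None,
                      boundary: str | None = None,
                      block_gap_kb: float = 250.0,
                      max_sweeps: int = 200) -> tuple[ScoreModel, pd.DataFrame]:
    """Penalized-regression score with (s, lambda) tuned on a training cohort.

    For every s in the a-priori grid and every lambda (20 log-spaced points
    up to max|r| by default), solve the block-wise coordinate descent, score
    the training cohort, and keep the solution whose score has the highest
    absolute Pearson correlation with the phenotype.  Returns the winning
    model (non-zero coefficients only) and the full tuning surface.
    """
    df = stats.df
    if restrict_to is not None:
        df = df[df["variant_id"].isin(restrict_to)]
    df = df.sort_values(["chrom", "pos", "variant_id"]).reset_index(drop=True)
    if df.empty:
        raise ValueError(f"build_lasso_model {name}: no variants")
    if "n" in df.columns and df["n"].notna().all():
        n_gwas = df["n"].to_numpy(dtype=float)
    else:
        n_gwas = np.full(len(df), 1e5)
    z = (df["beta"] / df["se"]).to_numpy()
    r = z / np.sqrt(n_gwas)
    vids = df["variant_id"].tolist()
    blocks = _position_blocks(df["pos"].to_numpy(),
                              df["chrom"].to_numpy(), block_gap_kb)
    Rs = [ld.corr([vids[i] for i in b]) for b in blocks]

    # training dosages aligned to the candidate variants
    tidx = training.variant_index()
    cols = tidx[vids].to_numpy()
    G = training.dosages[:, cols]
    y = np.asarray(phenotype, dtype=float)
    yc = y - y.mean()

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(r)
    lambda_grid = np.sort(np.asarray(lambda_grid))[::-1]  # warm-start path

    records = []
    best = None
    for s in s_grid:
        warm = [np.zeros(len(b)) for b in blocks]
        for lam in lambda_grid:
            beta = np.zeros(len(vids))
            for k, b in enumerate(blocks):
                warm[k], _ = coordinate_descent(
                    Rs[k], r[b], s, lam, beta0=warm[k],
                    max_sweeps=max_sweeps)
                beta[b] = warm[k]
            nz = int(np.count_nonzero(beta))
            score = G @ beta
            sd = score.std()
            corr = 0.0 if sd == 0 else \
                float(np.abs((score - score.mean()) @ yc)
                      / (len(y) * sd * yc.std()))
            records.append({"s": s, "lambda": lam, "n_nonzero": nz,
                            "abs_corr": corr})
            if nz and (best is None or corr > best[0] + 1e-15):
                best = (corr, s, lam, beta.copy())
    if best is None:
        raise ValueError(f"build_lasso_model {name}: all candidate models "
                         "empty")
    corr, s_best, lam_best, beta = best
    keep = np.flatnonzero(beta)
    variants = df.iloc[keep][["variant_id", "effect_allele"]].copy()
    variants["coefficient"] = beta[keep]
    model = ScoreModel(name, variants.reset_index(drop=True), "lasso",
                       params={"s": s_best, "lambda": float(lam_best),
                               "n_nonzero": len(keep),
                               "train_abs_corr": corr},
                       gene_set=gene_set, boundary=boundary)
    return model, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score(model: ScoreModel, cohort: CohortTable,
          max_missing: float = 0.5) -> ScoreVector:
    """Apply a score model to cohort dosages (Equation-1 sum).

    Model variants absent from the cohort are skipped with a log line; more
    than ``max_missing`` of them missing is an error.  Alleles are
    harmonized: where the cohort's effect allele is the model's other
    orientation the dosage contribution uses 2 - G.
    """
    cv = cohort.variants.set_index("variant_id")
    have = model.variants["variant_id"].isin(cv.index)
    n_missing = int((~have).sum())
    if n_missing > max_missing * len(model.variants):
        raise ValueError(f"score {model.name}: {n_missing}/"
                         f"{len(model.variants)} model variants missing")
    if n_missing:
        logger.info("score %s: skipped %d missing model variants",
                    model.name, n_missing)
    mv = model.variants[have]
    idx = cohort.variant_index()[mv["variant_id"]].to_numpy()
    coef = mv["coefficient"].to_numpy(dtype=float)
    flipped = (mv["effect_allele"].to_numpy()
               != cv.loc[mv["variant_id"], "effect_allele"].to_numpy())
    G = cohort.dosages[:, idx].astype(np.float64)
    if flipped.any():
        G[:, flipped] = 2.0 - G[:, flipped]
    raw = G @ coef
    if raw.std() == 0:
        # legitimate degenerate case (e.g. all dosages zero): no rescaling
        logger.warning("score %s: zero-variance raw score", model.name)
        return ScoreVector(list(cohort.sample_ids), raw, np.zeros_like(raw))
    return ScoreVector.from_raw(cohort.sample_ids, raw)
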