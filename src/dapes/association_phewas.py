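"""Case-control evaluation of polygenic scores and phenome-wide scans.

Covers: logistic score/trait association with Nagelkerke R² converted to the
liability scale, PRS-adjusted nested deviance tests, elevated-PES (top
decile) analyses including the low-PRS stratum, residualized scores, a
biochemical/mental-health pheWAS grid with sensitivity refits, and a
sex-dimorphism contrast of stratified estimates.

Liability conversion (case-control ascertainment, prevalence K, sample case
proportion P, threshold density z = phi(Phi^-1(1-K))):

    R²_liab = R²_obs * K(1-K)/z² * K(1-K)/(P(1-P)).

Quantiles are type-7 (linear interpolation) and ties at an elevation
threshold count as elevated, for determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .pes_scoring import ScoreVector

logger = logging.getLogger("dapes")


@dataclass
class LiabilityParams:
    K: float  # population prevalence (e.g. 0.007 SZ, 0.01 BIP)
    P: float  # sample case proportion

    def __post_init__(self) -> None:
        if not (0 < self.K < 1 and 0 < self.P < 1):
            raise ValueError("K and P must be in (0, 1)")

    @property
    def z_density(self) -> float:
        return float(sps.norm.pdf(sps.norm.ppf(1.0 - self.K)))


def liability_r2(r2_obs: float, K: float, P: float) -> float:
    """Observed-scale case-control R² converted to the liability scale."""
    lp = LiabilityParams(K, P)
    z2 = lp.z_density ** 2
    factor = (K * (1 - K) / z2) * (K * (1 - K) / (P * (1 - P)))
    return float(np.clip(r2_obs * factor, 0.0, 1.0))


@dataclass
class AssocResult:
    score_name: str
    beta_per_sd: float
    se: float
    p: float
    nagelkerke_r2_obs: float
    r2_liability: float
    n_cases: int
    n_controls: int
    separation_flag: bool = False


@dataclass
class DimorphismResult:
    trait: str
    beta_m: float
    se_m: float
    beta_f: float
    se_f: float
    z_diff: float
    p_diff: float


# ---------------------------------------------------------------------------
# Logistic fitting with Firth fallback
# ---------------------------------------------------------------------------

@dataclass
class _Fit:
    params: np.ndarray
    bse: np.ndarray
    llf: float
    separated: bool


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                   tol: float = 1e-8) -> _Fit:
    """Jeffreys-penalized logistic regression (stable under separation)."""
    n, p = X.shape
    beta = np.zeros(p)
    Iinv = np.eye(p)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        W = mu * (1.0 - mu)
        XW = X * W[:, None]
        info = X.T @ XW
        Iinv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, Iinv, XW)
        U = X.T @ (y - mu + h * (0.5 - mu))
        step = Iinv @ U
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(X @ beta)
    ll = float(np.sum(y * np.log(mu + 1e-300)
                      + (1 - y) * np.log(1 - mu + 1e-300)))
    return _Fit(beta, np.sqrt(np.diag(Iinv)), ll, separated=True)


def fit_logistic(X: np.ndarray, y: np.ndarray) -> _Fit:
    """Maximum-likelihood logistic fit; Firth-style refit on separation."""
    import statsmodels.api as sm

    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        if (np.isfinite(res.params).all() and np.isfinite(res.bse).all()
                and np.abs(res.params).max() < 30):
            return _Fit(np.asarray(res.params), np.asarray(res.bse),
                        float(res.llf), separated=False)
    except Exception:  # noqa: BLE001 - statsmodels raises several types here
        pass
    logger.warning("fit_logistic: separation suspected; Firth-style refit")
    return firth_logistic(X, y)


def _design(*columns) -> np.ndarray:
    n = len(columns[0])
    return np.column_stack([np.ones(n)] + [np.asarray(c, float)
                                           for c in columns if c is not None])


def _cov_matrix(covariates: pd.DataFrame | None) -> list[np.ndarray]:
    if covariates is None or covariates.shape[1] == 0:
        return []
    return [covariates[c].to_numpy(float) for c in covariates.columns]


def nagelkerke_r2(ll0: float, ll1: float, n: int) -> float:
    num = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    den = 1.0 - np.exp(2.0 * ll0 / n)
    return float(num / den) if den > 0 else 0.0


def assoc_score(score: ScoreVector, phenotype: np.ndarray,
                covariates: pd.DataFrame | None, prevalence: float,
                ) -> AssocResult:
    """Logistic association of a standardized score with case status.

    The reported Nagelkerke R² is the increment of the score over the
    covariate-only model; the liability-scale value uses the stated
    population prevalence and the sample case proportion.
    """
    y = np.asarray(phenotype, float)
    covs = _cov_matrix(covariates)
    X1 = _design(score.scaled, *covs)
    X0 = _design(*covs) if covs else _design(np.zeros(len(y)))[:, :1]
    fit1 = fit_logistic(X1, y)
    fit0 = fit_logistic(X0, y)
    r2_obs = max(nagelkerke_r2(fit0.llf, fit1.llf, len(y)), 0.0)
    P = y.mean()
    beta, se = float(fit1.params[1]), float(fit1.bse[1])
    p = 2.0 * sps.norm.sf(abs(beta / se))
    return AssocResult(
        score_name="score", beta_per_sd=beta, se=se, p=p,
        nagelkerke_r2_obs=r2_obs,
        r2_liability=liability_r2(r2_obs, prevalence, P),
        n_cases=int(y.sum()), n_controls=int((1 - y).sum()),
        separation_flag=fit1.separated)


def nested_prs_test(pes: ScoreVector, prs: ScoreVector,
                    phenotype: np.ndarray,
                    covariates: pd.DataFrame | None) -> dict:
    """Does the PES improve fit over covariates + genome-wide PRS?

    Likelihood-ratio (residual-deviance) chi-square on one degree of freedom.
    """
    r = float(np.corrcoef(pes.scaled, prs.scaled)[0, 1])
    if abs(r) > 0.99:
        raise ValueError(f"nested_prs_test: PES/PRS nearly collinear "
                         f"(r = {r:.3f})")
    y = np.asarray(phenotype, float)
    covs = _cov_matrix(covariates)
    fit0 = fit_logistic(_design(prs.scaled, *covs), y)
    fit1 = fit_logistic(_design(prs.scaled, pes.scaled, *covs), y)
    dev_diff = max(2.0 * (fit1.llf - fit0.llf), 0.0)
    return {"deviance_diff": dev_diff, "df": 1,
            "p": float(sps.chi2.sf(dev_diff, 1)),
            "pes_prs_corr": r,
            "beta_pes": float(fit1.params[2])}


def elevated_indicator(scores: list[ScoreVector],
                       decile: float = 0.9) -> np.ndarray:
    """1 if any score is at or above its cohort ``decile`` quantile (type-7;
    ties at the threshold count as elevated)."""
    if not scores:
        raise ValueError("elevated_indicator: need at least one score")
    flags = np.zeros(len(scores[0].raw), dtype=bool)
    for s in scores:
        thr = np.quantile(s.scaled, decile)  # type-7 linear interpolation
        flags |= s.scaled >= thr
    return flags.astype(float)


def elevated_pes(scores: list[ScoreVector], phenotype: np.ndarray,
                 prs: ScoreVector, covariates: pd.DataFrame | None = None,
                 decile: float = 0.9) -> dict:
    """Elevated-PES analyses: cohort-wide association with and without PRS
    adjustment, plus the low-PRS (lowest decile) stratum.

    The low-PRS stratum is defined over the full cohort (cases + controls).
    Reports the fraction of stratum cases carrying at least one elevated PES
    and the stratum association p (two-sided and one-sided for an excess).
    """
    y = np.asarray(phenotype, float)
    ind = elevated_indicator(scores, decile)
    covs = _cov_matrix(covariates)
    fit_plain = fit_logistic(_design(ind, *covs), y)
    fit_adj = fit_logistic(_design(ind, prs.scaled, *covs), y)
    out = {
        "indicator_prevalence": float(ind.mean()),
        "beta": float(fit_plain.params[1]),
        "se": float(fit_plain.bse[1]),
        "p": 2.0 * sps.norm.sf(abs(fit_plain.params[1] / fit_plain.bse[1])),
        "beta_prs_adjusted": float(fit_adj.params[1]),
        "p_prs_adjusted": 2.0 * sps.norm.sf(
            abs(fit_adj.params[1] / fit_adj.bse[1])),
        "case_fraction_elevated": float(ind[y == 1].mean())
        if (y == 1).any() else np.nan,
        "control_fraction_elevated": float(ind[y == 0].mean())
        if (y == 0).any() else np.nan,
    }

    low_thr = np.quantile(prs.scaled, 0.1)
    stratum = prs.scaled <= low_thr
    ys, inds = y[stratum], ind[stratum]
    if inds.std() == 0 or ys.std() == 0:
        out["low_prs"] = {"p": np.nan,
                          "reason": "constant indicator or phenotype in "
                                    "low-PRS stratum"}
        return out
    fit_s = fit_logistic(_design(inds), ys)
    zs = float(fit_s.params[1] / fit_s.bse[1])
    out["low_prs"] = {
        "n": int(stratum.sum()),
        "n_cases": int(ys.sum()),
        "case_fraction_elevated": float(inds[ys == 1].mean())
        if (ys == 1).any() else np.nan,
        "control_fraction_elevated": float(inds[ys == 0].mean())
        if (ys == 0).any() else np.nan,
        "beta": float(fit_s.params[1]),
        "p": 2.0 * sps.norm.sf(abs(zs)),
        "p_one_sided": float(sps.norm.sf(zs)),
    }
    return out


def residualize_pes(score: ScoreVector, prs: ScoreVector,
                    covariates: pd.DataFrame | None = None) -> ScoreVector:
    """Score with PRS (and PCs/batch) regressed out, then re-standardized."""
    covs = _cov_matrix(covariates)
    X = _design(prs.scaled, *covs)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("residualize_pes: rank-deficient design")
    coef, _, _, _ = np.linalg.lstsq(X, score.scaled, rcond=None)
    resid = score.scaled - X @ coef
    if resid.std() < 1e-8:
        raise ValueError("residualize_pes: score is fully explained by the "
                         "regressors (degenerate residual SD)")
    return ScoreVector.from_raw(score.sample_ids, resid)


def compute_dimorphism(trait: str, beta_m: float, se_m: float,
                       beta_f: float, se_f: float) -> DimorphismResult:
    """Contrast of sex-specific regression estimates on their joint SE."""
    z = (beta_m - beta_f) / np.sqrt(se_m ** 2 + se_f ** 2)
    return DimorphismResult(trait, beta_m, se_m, beta_f, se_f, float(z),
                            float(2.0 * sps.norm.sf(abs(z))))


def inverse_rank_normal(x: np.ndarray) -> np.ndarray:
    """Blom-offset inverse-rank-normal transform."""
    ranks = sps.rankdata(x)
    return sps.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def _fit_linear(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 * np.linalg.pinv(X.T @ X)[1, 1]))
    beta = float(coef[1])
    p = 2.0 * sps.t.sf(abs(beta / se), dof)
    return beta, se, p


def phewas(scores: dict[str, ScoreVector], traits: pd.DataFrame,
           covariates: pd.DataFrame | None = None,
           prs: ScoreVector | None = None,
           statin: np.ndarray | None = None,
           sex: np.ndarray | None = None,
           sensitivity: bool = False,
           alpha: float = 0.05) -> pd.DataFrame:
    """Score x trait association grid over a (controls-only) cohort.

    Continuous traits use linear models, 0/1 traits logistic.  FDR and
    Bonferroni flags are computed over the primary grid, with the Bonferroni
    threshold recomputed from the actual number of score-trait pairs.  With
    ``sensitivity=True`` each pair is refit with a PRS covariate, a
    log-transformed outcome, an inverse-rank-normal residual outcome, and a
    statin-use indicator (where supplied).  With ``sex`` given, sex-stratified
    fits feed a dimorphism contrast per pair.
    """
    covs = _cov_matrix(covariates)
    rows = []
    for trait in traits.columns:
        yt = traits[trait].to_numpy(float)
        if len(np.unique(yt[np.isfinite(yt)])) < 2:
            logger.info("phewas: trait %s constant; skipped", trait)
            continue
        binary = set(np.unique(yt[np.isfinite(yt)])) <= {0.0, 1.0}
        for name, sv in scores.items():
            rows.extend(_phewas_pair(name, sv, trait, yt, binary, covs,
                                     prs, statin, sex, sensitivity))
    out = pd.DataFrame(rows)
    primary = out["analysis"] == "primary"
    n_pairs = int(primary.sum())
    bonf_threshold = alpha / max(n_pairs, 1)
    out["bonf_threshold"] = bonf_threshold
    out["fdr_flag"] = False
    out["bonf_flag"] = False
    if n_pairs:
        rej, _, _, _ = multipletests(out.loc[primary, "p"], alpha=alpha,
                                     method="fdr_bh")
        out.loc[primary, "fdr_flag"] = rej
        out.loc[primary, "bonf_flag"] = \
            out.loc[primary, "p"] < bonf_threshold
    return out


def _phewas_pair(name, sv, trait, yt, binary, covs, prs, statin, sex,
                 sensitivity):
    def one(y, x, extra, analysis, stratum="all", mask=None):
        if mask is not None:
            y, x = y[mask], x[mask]
            extra = [e[mask] for e in extra]
        ok = np.isfinite(y)
        y, x = y[ok], x[ok]
        extra = [e[ok] for e in extra]
        if len(np.unique(y)) < 2 or len(y) < 10:
            return None
        X = _design(x, *extra)
        if binary:
            fit = fit_logistic(X, y)
            beta, se = float(fit.params[1]), float(fit.bse[1])
            p = 2.0 * sps.norm.sf(abs(beta / se))
        else:
            beta, se, p = _fit_linear(X, y)
        return {"score": name, "trait": trait, "estimate": beta, "se": se,
                "p": p, "analysis": analysis, "stratum": stratum}

    x = sv.scaled
    rows = [one(yt, x, covs, "primary")]
    if sensitivity:
        if prs is not None:
            rows.append(one(yt, x, covs + [prs.scaled], "prs_adjusted"))
        if not binary and np.nanmin(yt) > 0:
            rows.append(one(np.log(yt), x, covs, "ln_outcome"))
        if not binary:
            ok = np.isfinite(yt)
            y_int = np.full_like(yt, np.nan)
            y_int[ok] = inverse_rank_normal(yt[ok])
            rows.append(one(y_int, x, covs, "int_outcome"))
        if statin is not None:
            rows.append(one(yt, x, covs + [np.asarray(statin, float)],
                            "statin_adjusted"))
    if sex is not None:
        sex = np.asarray(sex, float)
        fit_m = one(yt, x, covs, "sex_stratified", "male", sex == 1)
        fit_f = one(yt, x, covs, "sex_stratified", "female", sex == 0)
        rows.extend([fit_m, fit_f])
        if fit_m and fit_f:
            dim = compute_dimorphism(trait, fit_m["estimate"], fit_m["se"],
                                     fit_f["estimate"], fit_f["se"])
            rows.append({"score": name, "trait": trait,
                         "estimate": dim.z_diff, "se": np.nan,
                         "p": dim.p_diff, "analysis": "dimorphism",
                         "stratum": "contrast"})
    return [r for r in rows if r is not None]


def split_train_validation(labels: np.ndarray, seed: int,
                           train_frac: float = 0.7,
                           controls_per_case: int = 2,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic disjoint train/validation split with 2:1 control:case.

    Cases are shuffled and split ``train_frac``/(1 - train_frac); each split
    receives ``controls_per_case`` times its case count in controls, drawn
    without overlap.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    cases = rng.permutation(np.flatnonzero(labels == 1))
    controls = rng.permutation(np.flatnonzero(labels == 0))
    n_train = int(round(train_frac * len(cases)))
    tr_cases, va_cases = cases[:n_train], cases[n_train:]
    need_tr = controls_per_case * len(tr_cases)
    need_va = controls_per_case * len(va_cases)
    if need_tr + need_va > len(controls):
        raise ValueError("split_train_validation: not enough controls for "
                         f"{controls_per_case}:1 ratio")
    tr_controls = controls[:need_tr]
    va_controls = controls[need_tr:need_tr + need_va]
    train = np.sort(np.concatenate([tr_cases, tr_controls]))
    valid = np.sort(np.concatenate([va_cases, va_controls]))
    return train, valid
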