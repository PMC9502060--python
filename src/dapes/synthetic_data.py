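"""Synthetic genotype/phenotype generator with LD structure and network-localized risk.

Every downstream stage of the pipeline (TWAS, MR, network scoring, pheWAS) is
testable against data from this module; nothing requires an external download.

Genotype model: within each LD block a latent multivariate Gaussian with
compound-symmetry correlation ``within_block_rho`` is drawn per haplotype and
thresholded at the allele-frequency quantile, so genotypes are the sum of two
Hardy-Weinberg haplotypes and realized dosage correlation decays toward the
latent value.  Randomness uses ``numpy.random.default_rng`` (PCG64); results
are reproducible bit-for-bit for a fixed seed and numpy generation.

Disease model: liability threshold.  Liability is the sum of per-set genetic
components (each scaled to its requested variance share on standardized
dosages) plus Gaussian noise; an individual is a case iff liability exceeds
the ``1 - K`` quantile of the standard normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import CohortTable, DrugGeneTable, EdgeTable, GeneTable, \
    SummaryStats, WeightPanel

logger = logging.getLogger("dapes")


@dataclass
class LDBlockSpec:
    """Layout of an LD reference: blocks of exchangeably correlated variants."""

    n_variants: int
    block_sizes: list[int]
    within_block_rho: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    chrom: str = "1"
    start_pos: int = 1
    spacing_bp: int = 5000

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_variants:
            raise ValueError("block_sizes must sum to n_variants")
        if not (0 <= self.within_block_rho < 1):
            raise ValueError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf bounds must lie in (0, 0.5]")


@dataclass
class CausalSet:
    name: str
    genes: list[str]
    variance_share: float


@dataclass
class ArchitectureSpec:
    """Liability-threshold architecture with risk localized in gene sets."""

    causal_sets: list[CausalSet]
    h2_liability: float
    prevalence: float
    n_cases: int = 0
    n_controls: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(s.variance_share for s in self.causal_sets)
        if total > self.h2_liability + 1e-12:
            raise ValueError("variance shares exceed h2_liability")
        if not (0 < self.h2_liability < 1) and self.h2_liability != 0:
            raise ValueError("h2_liability must be in [0, 1)")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")


def simulate_genotypes(spec: LDBlockSpec, n: int, seed: int) -> CohortTable:
    """Draw ``n`` individuals' dosages under the latent-Gaussian block model."""
    if n < 2:
        raise ValueError("need n >= 2 individuals")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*spec.maf_range, size=spec.n_variants)
    thresholds = sps.norm.ppf(1.0 - mafs)

    dosage = np.empty((n, spec.n_variants), dtype=np.float32)
    start = 0
    for size in spec.block_sizes:
        sl = slice(start, start + size)
        # thresholding attenuates the latent correlation; the arcsine
        # (tetrachoric, maf = 0.5) inversion calibrates the latent value so
        # realized genotype r approaches within_block_rho
        rho = float(np.sin(spec.within_block_rho * np.pi / 2.0))
        hap = np.zeros((n, size), dtype=np.float32)
        thr = thresholds[sl].astype(np.float32)
        for _ in range(2):  # two haplotypes per individual
            shared = rng.standard_normal((n, 1), dtype=np.float32)
            latent = np.float32(np.sqrt(rho)) * shared + \
                np.float32(np.sqrt(1.0 - rho)) * \
                rng.standard_normal((n, size), dtype=np.float32)
            hap += latent > thr
        dosage[:, sl] = hap
        start += size

    pos = spec.start_pos + spec.spacing_bp * np.arange(spec.n_variants)
    variants = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(spec.n_variants)],
        "chrom": spec.chrom,
        "pos": pos.astype(int),
        "effect_allele": "A",
        "other_allele": "G",
    })
    return CohortTable([f"S{i + 1}" for i in range(n)], dosage, variants)


@dataclass
class PhenotypeResult:
    labels: np.ndarray          # 0/1 case status for every individual
    liability: np.ndarray
    true_betas: np.ndarray      # per-variant liability-scale effect (dosage units)
    genetic_values: dict = field(default_factory=dict)  # per causal set


def simulate_phenotypes(cohort: CohortTable, arch: ArchitectureSpec,
                        gene_to_variants: Mapping[str, Sequence[str]],
                        ) -> PhenotypeResult:
    """Assign case/control labels under the liability-threshold model.

    ``gene_to_variants`` maps every gene named in the architecture's causal
    sets to the variant_ids it spans.  Per-set genetic components are built
    from standardized dosages with iid normal raw effects, then rescaled so
    each realized component variance equals the requested share.  Returns the
    true per-variant effects for recovery tests.
    """
    rng = np.random.default_rng(arch.seed)
    vidx = cohort.variant_index()
    X = cohort.dosages
    col_mean = X.mean(axis=0, dtype=np.float64)
    sd = np.sqrt(np.maximum(
        np.einsum("ij,ij->j", X, X, dtype=np.float64) / X.shape[0]
        - col_mean ** 2, 0.0))
    true_betas = np.zeros(cohort.n_variants)
    liability = np.zeros(cohort.n_samples)
    components: dict[str, np.ndarray] = {}

    for cset in arch.causal_sets:
        ids: list[str] = []
        for g in cset.genes:
            if g not in gene_to_variants:
                raise ValueError(f"causal gene {g} has no mapped variants")
            ids.extend(gene_to_variants[g])
        cols = np.unique(vidx[ids].to_numpy())
        cols = cols[sd[cols] > 0]
        u = rng.standard_normal(len(cols))
        # standardized-dosage component without materializing X[:, cols];
        # weight vector matches X's dtype to avoid an upcasting copy
        w_full = np.zeros(cohort.n_variants)
        w_full[cols] = u / sd[cols]
        g_raw = (X @ w_full.astype(X.dtype)).astype(np.float64) \
            - float(col_mean @ w_full)
        v = g_raw.var()
        scale = np.sqrt(cset.variance_share / v) if v > 0 else 0.0
        g = g_raw * scale
        components[cset.name] = g
        liability += g
        true_betas[cols] += u * scale / sd[cols]

    env_var = max(1.0 - sum(s.variance_share for s in arch.causal_sets), 0.0)
    liability = liability + np.sqrt(env_var) * \
        rng.standard_normal(cohort.n_samples)
    threshold = sps.norm.ppf(1.0 - arch.prevalence)
    labels = (liability > threshold).astype(int)
    return PhenotypeResult(labels, liability, true_betas, components)


def sample_case_control(labels: np.ndarray, n_cases: int, n_controls: int,
                        seed: int) -> np.ndarray:
    """Random indices of an ascertained case/control cohort.

    Mirrors the training-set design in which controls number double the cases;
    raises if the population cannot supply the requested counts.
    """
    rng = np.random.default_rng(seed)
    cases = np.flatnonzero(labels == 1)
    controls = np.flatnonzero(labels == 0)
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ValueError(
            f"cannot ascertain {n_cases} cases / {n_controls} controls from "
            f"{len(cases)} / {len(controls)} available")
    picked = np.concatenate([rng.choice(cases, n_cases, replace=False),
                             rng.choice(controls, n_controls, replace=False)])
    return np.sort(picked)


def logistic_score_test(X: np.ndarray, y: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-column intercept-only logistic score test.

    Returns (beta, se) where beta = U/V and se = V**-0.5 with
    U_j = x_j'(y - ybar), V_j = ybar(1-ybar) * sum((x_j - xbar_j)^2).
    Columns with zero variance yield se = inf.
    """
    ybar = y.mean()
    yc = y - ybar
    U = yc @ X
    xbar = X.mean(axis=0, dtype=np.float64)
    ssq = np.einsum("ij,ij->j", X, X, dtype=np.float64) \
        - X.shape[0] * xbar ** 2
    V = ybar * (1.0 - ybar) * ssq
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(V > 0, U / V, np.nan)
        se = np.where(V > 0, V ** -0.5, np.inf)
    return beta, se


def emit_gwas_sumstats(cohort: CohortTable, labels: np.ndarray,
                       ) -> SummaryStats:
    """GWAS summary statistics from a per-variant logistic score test.

    Monomorphic variants are dropped (they have no defined effect).
    """
    if labels.sum() < 50 or (1 - labels).sum() < 50:
        raise ValueError("need at least 50 cases and 50 controls")
    beta, se = logistic_score_test(cohort.dosages, labels.astype(float))
    z = np.where(np.isfinite(se), beta / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    keep = np.isfinite(beta) & np.isfinite(se) & (se > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("emit_gwas_sumstats: dropped %d monomorphic variants",
                    n_dropped)
    df = cohort.variants.loc[keep, ["variant_id", "chrom", "pos",
                                    "effect_allele", "other_allele"]].copy()
    df["beta"] = beta[keep]
    df["se"] = se[keep]
    df["pvalue"] = np.clip(p[keep], np.nextafter(0, 1), 1.0)
    df["eaf"] = cohort.dosages[:, keep].mean(axis=0) / 2.0
    df["n"] = cohort.n_samples
    return SummaryStats(df.reset_index(drop=True))


def emit_weight_panel(cohort: CohortTable, gene_table: GeneTable,
                      expression_weights: Mapping[tuple[str, str],
                                                  Sequence[tuple[str, float]]],
                      cis_h2_p: float = 1e-6) -> WeightPanel:
    """Build a WeightPanel from explicit per-model sparse weights.

    ``expression_weights`` maps (gene_id, tissue) to [(variant_id, weight)].
    Genes with no usable variants are skipped with a log line.
    """
    known = set(cohort.variants["variant_id"])
    allele = cohort.variants.set_index("variant_id")["effect_allele"]
    w_rows, g_rows = [], []
    for (gene, tissue), pairs in expression_weights.items():
        pairs = [(v, w) for v, w in pairs if v in known]
        if not pairs:
            logger.info("emit_weight_panel: skipping empty model %s/%s",
                        gene, tissue)
            continue
        for v, w in pairs:
            w_rows.append({"gene_id": gene, "tissue": tissue,
                           "variant_id": v, "effect_allele": allele[v],
                           "weight": float(w)})
        g_rows.append({"gene_id": gene, "tissue": tissue,
                       "cis_h2_p": cis_h2_p})
    return WeightPanel(pd.DataFrame(w_rows), pd.DataFrame(g_rows))


def random_weight_panel(cohort: CohortTable, gene_table: GeneTable,
                        tissue: str, n_variants_per_gene: int,
                        seed: int) -> WeightPanel:
    """Sparse random-sign weights over each gene's spanned variants."""
    rng = np.random.default_rng(seed)
    v = cohort.variants
    spec: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for rec in gene_table.df.itertuples(index=False):
        inside = v[(v["chrom"] == rec.chrom) & (v["pos"] >= rec.start)
                   & (v["pos"] <= rec.end)]["variant_id"].to_numpy()
        if len(inside) == 0:
            continue
        take = rng.choice(inside, min(n_variants_per_gene, len(inside)),
                          replace=False)
        spec[(rec.gene_id, tissue)] = [
            (vid, float(rng.normal(0.0, 1.0))) for vid in take]
    return emit_weight_panel(cohort, gene_table, spec)


@dataclass
class AnchorScenario:
    """All inputs for the anchor-discovery workflow with one planted anchor.

    The planted gene has strongly risk-increasing imputed expression (TWAS
    z > 0, protective direction = decreased expression), a genome-wide
    significant eQTL instrument, and one high-confidence antagonist; decoy
    drugs (wrong direction, single-source, wrong gene) and decoy QTLs
    (pleiotropic or sub-significant) exercise every filter.
    """

    gene_table: GeneTable
    gwas_stats: SummaryStats
    weights: WeightPanel
    expr_assoc: dict            # gene_id -> DataFrame(variant_id, beta, se)
    qtl_table: pd.DataFrame
    edge_table: EdgeTable
    drug_table: DrugGeneTable
    ld_cohort: CohortTable
    planted_anchor: str
    planted_drug: str
    protective_direction: str
    anchor_members: dict


def planted_anchor_scenario(seed: int, n_genes: int = 10,
                            variants_per_gene: int = 5,
                            n_gwas: int = 6000, n_ref: int = 800,
                            anchor_share: float = 0.05,
                            prevalence: float = 0.2,
                            flip_weights: bool = False) -> AnchorScenario:
    """Build the planted-anchor study: one causal gene among decoys.

    Each gene occupies its own LD block (within-block rho 0.3) separated by
    wide gaps.  Disease liability is driven by the anchor gene's variants
    (``anchor_share`` of liability variance); expression models are correct
    for every gene, so the anchor's TWAS z is large while decoys stay null.
    ``flip_weights`` negates every expression weight, which must flip the
    called protective direction (antisymmetry checks).
    """
    rng = np.random.default_rng(seed)
    m = n_genes * variants_per_gene
    spec = LDBlockSpec(m, [variants_per_gene] * n_genes,
                       within_block_rho=0.3, spacing_bp=2000)
    genes = [f"G{i + 1}" for i in range(n_genes)]
    anchor = genes[0]

    gene_rows = []
    for i, g in enumerate(genes):
        lo = spec.start_pos + i * variants_per_gene * spec.spacing_bp
        hi = lo + (variants_per_gene - 1) * spec.spacing_bp
        gene_rows.append({"gene_id": g, "chrom": spec.chrom, "start": lo,
                          "end": hi, "strand": "+"})
    gene_table = GeneTable(pd.DataFrame(gene_rows))

    gwas_cohort = simulate_genotypes(spec, n_gwas, seed)
    ref_cohort = simulate_genotypes(spec, n_ref, seed + 10_000)
    gene_to_variants = {
        g: [f"rs{i * variants_per_gene + j + 1}"
            for j in range(variants_per_gene)]
        for i, g in enumerate(genes)}

    arch = ArchitectureSpec(
        causal_sets=[CausalSet("anchor", [anchor], anchor_share)],
        h2_liability=anchor_share, prevalence=prevalence, seed=seed + 1)
    pheno = simulate_phenotypes(gwas_cohort, arch, gene_to_variants)
    stats = emit_gwas_sumstats(gwas_cohort, pheno.labels)

    # correct expression models: anchor weights proportional to true effects
    # (oriented so higher expression raises disease odds); decoys random
    sign = -1.0 if flip_weights else 1.0
    vidx = gwas_cohort.variant_index()
    weight_spec = {}
    for g in genes:
        ids = gene_to_variants[g]
        if g == anchor:
            w = pheno.true_betas[vidx[ids].to_numpy()]
            w = w / np.sqrt((w ** 2).sum())
        else:
            w = rng.standard_normal(len(ids))
            w = w / np.sqrt((w ** 2).sum())
        weight_spec[(g, "brain")] = list(zip(ids, sign * w))
    weights = emit_weight_panel(gwas_cohort, gene_table, weight_spec)

    # per-variant expression association in the reference cohort
    expr_assoc: dict = {}
    qtl_rows = []
    X = ref_cohort.dosages
    for g in genes:
        ids = gene_to_variants[g]
        cols = vidx[ids].to_numpy()
        w = np.array([dict(weight_spec[(g, "brain")])[v] for v in ids])
        gval = X[:, cols] @ w
        gval = (gval - gval.mean()) / max(gval.std(), 1e-12)
        expr = gval + rng.standard_normal(n_ref)
        beta, se = _linear_assoc(X[:, cols], expr)
        expr_assoc[g] = pd.DataFrame({"variant_id": ids, "beta": beta,
                                      "se": se})
        p_qtl = 2.0 * sps.norm.sf(np.abs(beta / se))
        top = int(np.argmin(p_qtl))
        qtl_rows.append({
            "gene_id": g, "tissue": "brain", "variant_id": ids[top],
            "chrom": spec.chrom,
            "pos": int(ref_cohort.variants["pos"].iloc[cols[top]]),
            "beta_qtl": beta[top], "se_qtl": se[top],
            "p_qtl": p_qtl[top],
            # decoys carry unusable instruments: pleiotropic or weak
            "n_genes_hit": 1 if g == anchor else 4,
            "is_trans": False})
    qtl_table = pd.DataFrame(qtl_rows)

    members = [f"N{i + 1}" for i in range(4)]
    background = genes[1:] + [f"B{i + 1}" for i in range(20)]
    drug_direction = "agonist" if flip_weights else "antagonist"
    wrong_direction = "antagonist" if flip_weights else "agonist"
    edge_table, drug_table = emit_fixture_tables(
        {anchor: members}, background,
        {
            "planted_drug": (anchor, drug_direction,
                             ["DrugBank", "ChEMBL"]),
            "wrong_direction_drug": (anchor, wrong_direction,
                                     ["DrugBank", "ChEMBL"]),
            "single_source_drug": (anchor, drug_direction, ["DrugBank"]),
            "decoy_gene_drug": (genes[1], drug_direction,
                                ["DrugBank", "ChEMBL"]),
        },
        seed=seed + 2)
    return AnchorScenario(
        gene_table, stats, weights, expr_assoc, qtl_table, edge_table,
        drug_table, ref_cohort, anchor, "planted_drug",
        "increased" if flip_weights else "decreased",
        {anchor: members})


def _linear_assoc(X: np.ndarray, y: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-column simple linear regression beta and se."""
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ssx = (xc ** 2).sum(axis=0)
    beta = xc.T @ yc / ssx
    resid_var = np.maximum(
        ((yc ** 2).sum() - beta ** 2 * ssx) / (n - 2), 1e-12)
    se = np.sqrt(resid_var / ssx)
    return beta, se


@dataclass
class NetworkScenario:
    """Inputs for the PES workflow: risk localized in six anchor networks."""

    gene_table: GeneTable
    gwas_stats: SummaryStats
    target_cohort: CohortTable      # ascertained cases + controls, phenotype set
    edge_table: EdgeTable
    networks: dict                  # anchor -> member genes (incl. anchor)
    prevalence: float
    true_component_share: float


def planted_network_scenario(seed: int,
                             n_networks: int = 6,
                             genes_per_network: int = 5,
                             variants_per_gene: int = 6,
                             n_background_genes: int = 640,
                             network_share: float = 0.01,
                             background_share: float = 0.30,
                             prevalence: float = 0.1,
                             n_gwas: int = 11000,
                             n_target_pop: int = 24000,
                             n_cases: int = 2000,
                             n_controls: int = 4000) -> NetworkScenario:
    """Planted-network architecture mirroring the six-anchor study design.

    Each network's genes jointly carry ``network_share`` of liability
    variance (1% by default); a diffuse background set carries
    ``background_share``.  The GWAS and target cohorts are independent draws
    from the same genotype model; the target cohort is ascertained to a
    2:1 control:case design.
    """
    rng = np.random.default_rng(seed)
    n_net_genes = n_networks * genes_per_network
    n_genes = n_net_genes + n_background_genes
    m = n_genes * variants_per_gene
    spec = LDBlockSpec(m, [variants_per_gene] * n_genes,
                       within_block_rho=0.25, spacing_bp=2000)

    genes, gene_rows, gene_to_variants = [], [], {}
    for i in range(n_genes):
        g = f"G{i + 1}"
        genes.append(g)
        lo = spec.start_pos + i * variants_per_gene * spec.spacing_bp
        hi = lo + (variants_per_gene - 1) * spec.spacing_bp
        gene_rows.append({"gene_id": g, "chrom": spec.chrom, "start": lo,
                          "end": hi, "strand": "+"})
        gene_to_variants[g] = [f"rs{i * variants_per_gene + j + 1}"
                               for j in range(variants_per_gene)]
    gene_table = GeneTable(pd.DataFrame(gene_rows))

    networks = {}
    causal_sets = []
    for k in range(n_networks):
        members = genes[k * genes_per_network:(k + 1) * genes_per_network]
        networks[members[0]] = members
        causal_sets.append(CausalSet(f"net{k + 1}", members, network_share))
    background = genes[n_net_genes:]
    causal_sets.append(CausalSet("background", background, background_share))
    arch = ArchitectureSpec(causal_sets,
                            h2_liability=n_networks * network_share
                            + background_share,
                            prevalence=prevalence, seed=seed + 1)

    gwas_cohort = simulate_genotypes(spec, n_gwas, seed)
    gwas_pheno = simulate_phenotypes(gwas_cohort, arch, gene_to_variants)
    stats = emit_gwas_sumstats(gwas_cohort, gwas_pheno.labels)
    del gwas_cohort

    target = simulate_genotypes(spec, n_target_pop, seed + 20_000)
    arch_t = ArchitectureSpec(causal_sets, arch.h2_liability, prevalence,
                              seed=seed + 1)  # same true betas (same seed)
    t_pheno = simulate_phenotypes(target, arch_t, gene_to_variants)
    idx = sample_case_control(t_pheno.labels, n_cases, n_controls,
                              seed + 3)
    cohort = target.subset_samples(idx)
    n = cohort.n_samples
    cohort.phenotype = pd.Series(t_pheno.labels[idx], name="phenotype")
    cohort.covariates = pd.DataFrame({
        "sex": rng.integers(0, 2, n).astype(float),
        "age": rng.normal(50.0, 8.0, n),
        "batch": rng.integers(0, 2, n).astype(float),
        **{f"PC{i + 1}": rng.standard_normal(n) for i in range(5)},
    })
    # planted module edges so build_network recovers each network exactly
    anchor_members = {a: [g for g in mem if g != a]
                      for a, mem in networks.items()}
    edge_table, _ = emit_fixture_tables(
        anchor_members, background,
        {"placeholder": (next(iter(networks)), "antagonist",
                         ["DrugBank", "ChEMBL"])},
        seed=seed + 4)
    return NetworkScenario(gene_table, stats, cohort, edge_table,
                           networks, prevalence, network_share)


def emit_fixture_tables(anchor_members: Mapping[str, Sequence[str]],
                        background_genes: Sequence[str],
                        drug_spec: Mapping[str, tuple[str, str, Sequence[str]]],
                        seed: int,
                        module_confidence: float = 0.9,
                        n_noise_edges: int = 50,
                        ) -> tuple[EdgeTable, DrugGeneTable]:
    """Planted interaction and drug tables for end-to-end tests.

    Each anchor gets a high-confidence module: anchor-member edges at
    ``module_confidence`` on the experimental channel plus a ring of
    member-member edges.  Noise edges among background genes are drawn below
    the 0.7 confidence threshold or on the "other" channel so a correct
    network build recovers exactly the planted modules.

    ``drug_spec`` maps a drug name to (gene_id, interaction_type, sources).
    """
    rng = np.random.default_rng(seed)
    edges = []
    for anchor, members in anchor_members.items():
        for m in members:
            edges.append((anchor, m, module_confidence, "experimental"))
        members = list(members)
        for a, b in zip(members, members[1:]):
            edges.append((a, b, module_confidence, "database"))
    pool = list(background_genes)
    for _ in range(n_noise_edges):
        a, b = rng.choice(pool, 2, replace=False)
        if rng.random() < 0.5:
            edges.append((a, b, float(rng.uniform(0.15, 0.65)),
                          rng.choice(["experimental", "database"])))
        else:
            edges.append((a, b, float(rng.uniform(0.7, 0.95)), "other"))
    edge_table = EdgeTable(pd.DataFrame(
        edges, columns=["gene_a", "gene_b", "confidence", "channel"]))

    drug_rows = [{"drug": drug, "gene_id": gene, "interaction_type": itype,
                  "sources": list(sources)}
                 for drug, (gene, itype, sources) in drug_spec.items()]
    drug_table = DrugGeneTable(pd.DataFrame(drug_rows))
    return edge_table, drug_table
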