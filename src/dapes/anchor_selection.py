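"""Combine TWAS/PWAS, finemapping, colocalization and MR evidence into
directional-anchor-gene calls, and match each call to repurposing candidates
that reverse the risk direction of expression.

A directional anchor (DA) gene is one whose disease-associated direction of
genetically predicted expression could be counteracted by an approved drug:
if higher imputed expression raises the odds of disease, an antagonist is the
candidate; if lower expression raises the odds, an agonist is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grex_twas import ColocResult, FinemapResult, TwasResult
from .io_formats import DrugGeneTable
from .mendelian_randomization import MrResult

logger = logging.getLogger("dapes")

#: interaction types expected to increase / decrease target activity
UP_TYPES = {"agonist", "activator"}
DOWN_TYPES = {"antagonist", "inhibitor", "blocker"}


@dataclass
class AnchorCall:
    gene_id: str
    disorder: str
    protective_direction: str  # "increased" | "decreased" expression
    evidence_tier: str         # high_pip | moderate_pip_coloc | mr_supported
    mr_supported: bool = False
    supporting: dict = field(default_factory=dict)
    drugs: list[tuple[str, str]] = field(default_factory=list)


def _twas_direction(z: float) -> str:
    # negative genetic covariance: higher expression, lower odds
    return "increased" if z < 0 else "decreased"


def call_anchors(twas: list[TwasResult],
                 finemap: list[FinemapResult],
                 coloc: dict[str, ColocResult],
                 mr: list[MrResult],
                 disorder: str,
                 pip_high: float = 0.8, pip_moderate: float = 0.4,
                 coloc_h4_min: float = 0.8,
                 exclude: set[str] | None = None) -> list[AnchorCall]:
    """Tiered anchor-gene calls for one disorder.

    Tiers: ``high_pip`` for Bonferroni-significant TWAS genes with PIP > 0.8;
    ``moderate_pip_coloc`` for significant genes with PIP > 0.4 additionally
    supported by colocalization (PP_H4 > 0.8).  Bonferroni-significant MR
    results in a concordant direction annotate existing calls
    (``mr_supported``) or add new genes at the ``mr_supported`` tier.  Genes
    whose significant tissue results disagree in direction are suppressed;
    ``exclude`` holds manually vetoed genes (e.g. poorly performing imputed
    models).
    """
    exclude = exclude or set()
    pip_by_gene: dict[str, float] = {}
    for fm in finemap:
        for g, p in zip(fm.gene_ids, fm.pips):
            pip_by_gene[g] = max(pip_by_gene.get(g, 0.0), float(p))

    calls: dict[str, AnchorCall] = {}
    sig = [r for r in twas if r.significant]
    for gene in sorted({r.gene_id for r in sig}):
        if gene in exclude:
            continue
        results = [r for r in sig if r.gene_id == gene]
        directions = {_twas_direction(r.z_twas) for r in results}
        if len(directions) > 1:
            logger.warning("call_anchors: %s has conflicting directions "
                           "across tissues; call suppressed", gene)
            continue
        pip = pip_by_gene.get(gene, 0.0)
        h4 = coloc[gene].pp_h4 if gene in coloc else 0.0
        if pip > pip_high:
            tier = "high_pip"
        elif pip > pip_moderate and h4 > coloc_h4_min:
            tier = "moderate_pip_coloc"
        else:
            continue
        calls[gene] = AnchorCall(
            gene, disorder, directions.pop(), tier,
            supporting={"twas": results, "pip": pip, "pp_h4": h4})

    for r in mr:
        if not r.significant or r.gene_id in exclude:
            continue
        mr_dir = "increased" if r.beta_mr < 0 else "decreased"
        if r.gene_id in calls:
            call = calls[r.gene_id]
            if call.protective_direction == mr_dir:
                call.mr_supported = True
                call.supporting["mr"] = r
            else:
                logger.warning("call_anchors: MR direction for %s conflicts "
                               "with TWAS; annotation withheld", r.gene_id)
        else:
            calls[r.gene_id] = AnchorCall(
                r.gene_id, disorder, mr_dir, "mr_supported",
                mr_supported=True, supporting={"mr": r})
    return list(calls.values())


def is_high_confidence(sources: list[str]) -> bool:
    """DrugBank plus at least one other database or literature source."""
    norm = {s.strip().lower() for s in sources}
    return "drugbank" in norm and len(norm) >= 2


def match_drugs(call: AnchorCall, drug_table: DrugGeneTable) -> AnchorCall:
    """Attach high-confidence drugs whose action matches the protective direction.

    Agonists/activators match a protective direction of *increased*
    expression; antagonists/inhibitors/blockers match *decreased*.  Only
    interactions reported in DrugBank plus at least one further source
    qualify.  A call with no matching drug keeps an empty list (and is
    excluded from the final anchor table).
    """
    wanted = UP_TYPES if call.protective_direction == "increased" \
        else DOWN_TYPES
    rows = drug_table.df[drug_table.df["gene_id"] == call.gene_id]
    matched = [(r.drug, r.interaction_type) for r in
               rows.itertuples(index=False)
               if r.interaction_type in wanted
               and is_high_confidence(r.sources)]
    call.drugs = sorted(matched)
    if not call.drugs:
        logger.info("match_drugs: no matching high-confidence drug for %s; "
                    "call excluded from final table", call.gene_id)
    return call


def anchor_table(calls: list[AnchorCall]) -> pd.DataFrame:
    """Final anchor summary (one row per called gene with >= 1 matched drug)."""
    rows = []
    for c in calls:
        if not c.drugs:
            continue
        tier = c.evidence_tier + (", further supported by MR"
                                  if c.mr_supported
                                  and c.evidence_tier != "mr_supported"
                                  else "")
        rows.append({
            "gene_id": c.gene_id,
            "disorder": c.disorder,
            "protective_direction": f"{c.protective_direction} expression",
            "repurposing_candidates": ", ".join(d for d, _ in c.drugs),
            "evidence": tier,
        })
    return pd.DataFrame(
        rows, columns=["gene_id", "disorder", "protective_direction",
                       "repurposing_candidates", "evidence"])
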