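"""End-to-end driver: evidence + catalog + expression -> decision report."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .expression import induction_table
from .io import ProteinCatalog
from .prioritize import Thresholds, apply_cascade, enrichment_table, rank_and_report
from .quantify import NsafTable, build_nsaf_table, coverage_table


@dataclass
class PipelineResult:
    nsaf_table: NsafTable
    enrichments: pd.DataFrame
    inductions: pd.DataFrame
    decisions: pd.DataFrame
    coverage: pd.Series
    report: pd.DataFrame


def run_pipeline(
    catalog: ProteinCatalog,
    evidence: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    annotations: set[str] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> PipelineResult:
    """Quantify, filter and report one fractionation experiment.

    Coverage is computed for the final candidates only (it is a
    reporting quantity, not a filter criterion).
    """
    nsaf = build_nsaf_table(evidence, catalog, thresholds.min_confidence)
    proteins = sorted(set(nsaf.summary["protein_id"]))
    enrichments = enrichment_table(nsaf, proteins)
    if expression is not None and len(expression):
        inductions = induction_table(expression, thresholds.expression_fold)
    else:
        inductions = pd.DataFrame(
            columns=["gene_id", "fpkm_replete", "fpkm_starved_3d", "fold_change", "induced"]
        )
    decisions = apply_cascade(nsaf, evidence, enrichments, inductions, annotations, thresholds)
    candidates = list(decisions.loc[decisions["final"], "protein_id"])
    coverage = coverage_table(evidence, catalog, candidates, thresholds.min_confidence)
    report = rank_and_report(decisions, nsaf, coverage, enrichments, inductions)
    return PipelineResult(nsaf, enrichments, inductions, decisions, coverage, report)
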