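"""The candidate filter cascade.

A protein enters the candidate stage only if it was detected in the LB
fraction in all three technical replicates with at least two distinct
medium/high-confidence peptides.  It becomes a lipid-body-protein (LBP)
candidate if it then fulfils at least one of four criteria:

(i)   fold enrichment of the mean LB NSAF over the mean NSAF of at least
      one control fraction > 10, or exclusive presence in the LB sample
      (control mean 0);
(ii)  membership in the most abundant 10% of presence-filtered proteins
      by mean LB NSAF;
(iii) transcriptional induction > 5x after 3 d of nitrogen starvation;
(iv)  an externally supplied homology/annotation flag (the judgement the
      original screen applied by expert knowledge, e.g. "lipase").

Comparisons are strict, "any control" is existential, and the abundance
decile takes the top ``ceil(0.10 * n)`` proteins with ties at the cut
broken lexicographically by protein id so the selection is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import gene_for_protein
from .io import CONTROL_SAMPLES, REPORT_COLUMNS
from .quantify import NsafTable, admissible_confidences

logger = logging.getLogger(__name__)

#: Sentinel for proteins never seen in a control fraction.
EXCLUSIVE = math.inf


@dataclass(frozen=True)
class Thresholds:
    """Filter-cascade thresholds; defaults are the published screen values."""

    n_replicates_required: int = 3
    min_distinct_peptides: int = 2
    enrichment_fold: float = 10.0
    top_fraction: float = 0.10
    expression_fold: float = 5.0
    min_confidence: str = "medium"

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must lie in (0, 1]")
        if min(self.n_replicates_required, self.min_distinct_peptides) <= 0:
            raise ValueError("replicate and peptide requirements must be positive")
        if min(self.enrichment_fold, self.expression_fold) <= 0:
            raise ValueError("fold thresholds must be positive")


def presence_filter(
    nsaf_table: NsafTable,
    evidence: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> set[str]:
    """Proteins detected in every LB replicate with enough distinct
    medium/high-confidence peptides.

    The peptide requirement is evaluated over the LB sample across its
    replicates (distinctness by peptide sequence).
    """
    lb = nsaf_table.replicate_nsaf("LB")
    if lb.empty:
        return set()
    present = set(lb.index[(lb > 0).sum(axis=1) >= thresholds.n_replicates_required])
    admissible = admissible_confidences(thresholds.min_confidence)
    lb_rows = evidence[
        (evidence["sample"] == "LB")
        & evidence["confidence"].isin(admissible)
        & (evidence["spectra"] > 0)
    ]
    peptide_counts = lb_rows.groupby("protein_id")["peptide"].nunique()
    enough_peptides = set(
        peptide_counts.index[peptide_counts >= thresholds.min_distinct_peptides]
    )
    return present & enough_peptides


def fold_enrichment(mean_lb: float, mean_control: float) -> float:
    """Mean LB NSAF over mean control NSAF; ``EXCLUSIVE`` (inf) when the
    protein never appeared in the control."""
    if mean_lb <= 0:
        raise ValueError("fold enrichment requires a positive LB mean NSAF")
    if mean_control < 0:
        raise ValueError("control mean NSAF cannot be negative")
    if mean_control == 0:
        return EXCLUSIVE
    return mean_lb / mean_control


def enrichment_table(nsaf_table: NsafTable, proteins: list[str]) -> pd.DataFrame:
    """Fold enrichment vs each control plus incomplete-control flags.

    ``control_incomplete_<c>`` mirrors the asterisk annotation: the
    control fraction did not contain the protein in all of its technical
    replicates.  Its mean NSAF still includes those zeros, so partially
    detected controls yield finite (larger) enrichment rather than the
    exclusivity sentinel.
    """
    lb = nsaf_table.sample_summary("LB")["mean_nsaf"]
    out = pd.DataFrame(index=pd.Index(sorted(proteins), name="protein_id"))
    for control in CONTROL_SAMPLES:
        summary = nsaf_table.sample_summary(control)
        mean_c = summary["mean_nsaf"].reindex(out.index).fillna(0.0)
        n_det = summary["n_replicates_detected"].reindex(out.index).fillna(0).astype(int)
        out[f"fe_{control}"] = [
            fold_enrichment(lb.get(pid, 0.0), mc) if lb.get(pid, 0.0) > 0 else np.nan
            for pid, mc in mean_c.items()
        ]
        out[f"exclusive_{control}"] = mean_c.to_numpy() == 0.0
        out[f"control_incomplete_{control}"] = (n_det < 3).to_numpy()
    return out


def criterion_enrichment(
    enrichments: pd.Series | dict[str, float],
    threshold: float = 10.0,
) -> bool:
    """True iff at least one control shows fold enrichment > threshold or
    the protein is exclusive to the LB sample (enrichment = inf)."""
    values = list(pd.Series(enrichments).astype(float))
    return any(math.isinf(v) or v > threshold for v in values if not math.isnan(v))


def criterion_abundance(
    mean_lb_nsaf: pd.Series, top_fraction: float = 0.10
) -> set[str]:
    """The most abundant ``ceil(top_fraction * n)`` proteins by mean LB NSAF.

    Ties spanning the cut are resolved lexicographically by protein id,
    which keeps the selection a deterministic function of the input.
    """
    if mean_lb_nsaf.empty:
        return set()
    k = math.ceil(top_fraction * len(mean_lb_nsaf))
    order = sorted(mean_lb_nsaf.items(), key=lambda item: (-item[1], item[0]))
    return {pid for pid, _ in order[:k]}


def apply_cascade(
    nsaf_table: NsafTable,
    evidence: pd.DataFrame,
    enrichments: pd.DataFrame,
    inductions: pd.DataFrame,
    annotations: set[str] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Evaluate all criteria and the final verdict for every protein that
    passes the presence filter.

    ``inductions`` is gene-keyed (see :func:`~lbproteome.expression.induction_table`);
    protein ids are mapped onto gene ids by stripping the protein-model
    suffix.  A protein without an expression record fails criterion (iii)
    with a log note rather than an error.  The result is ranked by
    descending mean LB NSAF.
    """
    passing = sorted(presence_filter(nsaf_table, evidence, thresholds))
    mean_lb = nsaf_table.sample_summary("LB")["mean_nsaf"].reindex(passing)
    return cascade_from_summaries(mean_lb, enrichments, inductions, annotations, thresholds)


def cascade_from_summaries(
    mean_lb: pd.Series,
    enrichments: pd.DataFrame,
    inductions: pd.DataFrame,
    annotations: set[str] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Criteria (i)-(iv) over an already presence-filtered protein set.

    Entry point for data that arrives at the post-NSAF stage (mean LB
    NSAF per protein, fold enrichments, gene-level inductions) without
    peptide-level evidence; the abundance decile (ii) is computed over
    the supplied set.
    """
    annotations = annotations or set()
    passing = list(mean_lb.index)
    abundant = criterion_abundance(mean_lb, thresholds.top_fraction)
    induction_by_gene = inductions.set_index("gene_id") if len(inductions) else pd.DataFrame()

    decisions = []
    for pid in passing:
        fe = enrichments.loc[pid, [f"fe_{c}" for c in CONTROL_SAMPLES]]
        crit_i = criterion_enrichment(fe, thresholds.enrichment_fold)
        crit_ii = pid in abundant
        gene = gene_for_protein(pid)
        if len(induction_by_gene) and gene in induction_by_gene.index:
            fold = float(induction_by_gene.loc[gene, "fold_change"])
            crit_iii = (not math.isnan(fold)) and fold > thresholds.expression_fold
        else:
            logger.info("no expression record for %s (gene %s); criterion iii = False", pid, gene)
            fold = math.nan
            crit_iii = False
        crit_iv = pid in annotations
        decisions.append(
            {
                "protein_id": pid,
                "present_all_reps": True,
                "min_peptides_ok": True,
                "crit_enrichment": crit_i,
                "crit_abundance": crit_ii,
                "crit_expression": crit_iii,
                "crit_annotation": crit_iv,
                "expression_fold": fold,
                "final": crit_i or crit_ii or crit_iii or crit_iv,
                "mean_nsaf_LB": mean_lb[pid],
            }
        )
    table = pd.DataFrame(decisions)
    if table.empty:
        return pd.DataFrame(
            columns=[
                "protein_id", "present_all_reps", "min_peptides_ok",
                "crit_enrichment", "crit_abundance", "crit_expression",
                "crit_annotation", "expression_fold", "final", "mean_nsaf_LB", "rank",
            ]
        )
    table = table.sort_values(
        ["mean_nsaf_LB", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranks = np.full(len(table), -1, dtype=int)
    ranks[table["final"].to_numpy()] = np.arange(1, int(table["final"].sum()) + 1)
    table["rank"] = ranks
    return table


def rank_and_report(
    decisions: pd.DataFrame,
    nsaf_table: NsafTable,
    coverage: pd.Series,
    enrichments: pd.DataFrame,
    inductions: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-candidate report (one row per passing protein).

    Columns mirror the published per-protein summary: mean NSAF +/- SD for
    every fraction, coverage %, fold enrichment vs each control (with
    exclusivity and incomplete-control flags), the FPKM pair and induction
    fold, the criterion flags and the final verdict.  The
    ``lb_localization`` column is an empty annotation slot for downstream
    experimental verification; it is never computed here.
    """
    final = decisions[decisions["final"]].copy()
    if final.empty:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    rows = final.set_index("protein_id")
    out = pd.DataFrame(index=rows.index)
    out["rank"] = rows["rank"]
    for sample in ("LB", "total", "membrane", "soluble"):
        summary = nsaf_table.sample_summary(sample)
        out[f"mean_nsaf_{sample}"] = summary["mean_nsaf"].reindex(out.index).fillna(0.0)
        out[f"sd_nsaf_{sample}"] = summary["sd_nsaf"].reindex(out.index).fillna(0.0)
    out["coverage_pct"] = coverage.reindex(out.index)
    for col in enrichments.columns:
        out[col] = enrichments[col].reindex(out.index)
    induction_by_gene = inductions.set_index("gene_id") if len(inductions) else pd.DataFrame()
    genes = [gene_for_protein(pid) for pid in out.index]
    for col in ("fpkm_replete", "fpkm_starved_3d"):
        out[col] = [
            float(induction_by_gene.loc[g, col])
            if len(induction_by_gene) and g in induction_by_gene.index
            else math.nan
            for g in genes
        ]
    for col in (
        "present_all_reps", "min_peptides_ok", "crit_enrichment", "crit_abundance",
        "crit_expression", "crit_annotation", "expression_fold", "final",
    ):
        out[col] = rows[col]
    out["lb_localization"] = ""
    out = out.sort_values("rank").reset_index(names="protein_id")
    return out[[c for c in REPORT_COLUMNS if c in out.columns]]
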