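"""Spectral-count quantitation: SAF/NSAF, replicate aggregates, coverage.

The abundance of protein *i* in one MS run is estimated from its spectral
count ``SpC_i`` (number of MS/MS spectra matched to its peptides) via the
Normalized Spectral Abundance Factor

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)

where ``L_i`` is the protein length in residues and the sum runs over all
proteins identified in that sample-replicate at admissible peptide
confidence.  NSAF values therefore sum to 1 within a run and are
invariant under rescaling of all counts.

Sequence coverage is the percentage of residues touched by the union of
matched peptide positions (exact substring placement, all occurrences).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .io import CONFIDENCE_LEVELS, REPLICATES, SAMPLES, ProteinCatalog

logger = logging.getLogger(__name__)

_CONF_RANK = {level: rank for rank, level in enumerate(CONFIDENCE_LEVELS)}


def admissible_confidences(min_confidence: str) -> set[str]:
    """Confidence classes at or above ``min_confidence`` (``medium`` ->
    ``{medium, high}``)."""
    if min_confidence not in _CONF_RANK:
        raise ValueError(f"unknown confidence class {min_confidence!r}")
    floor = _CONF_RANK[min_confidence]
    return {c for c, r in _CONF_RANK.items() if r >= floor}


def spectral_counts(
    evidence: pd.DataFrame,
    sample: str,
    replicate: int,
    min_confidence: str = "medium",
) -> pd.DataFrame:
    """Per-protein total spectra and distinct peptides for one run.

    Only evidence rows at admissible confidence contribute to either
    number; proteins without admissible evidence (or with zero admissible
    spectra) are absent from the result.  Distinctness is by peptide
    sequence, so the same peptide reported in several rows counts once.
    """
    if sample not in SAMPLES:
        raise ValueError(f"unknown sample {sample!r}; expected one of {SAMPLES}")
    if replicate not in REPLICATES:
        raise ValueError(f"unknown replicate {replicate}; expected one of {REPLICATES}")
    admissible = admissible_confidences(min_confidence)
    mask = (
        (evidence["sample"] == sample)
        & (evidence["replicate"] == replicate)
        & evidence["confidence"].isin(admissible)
    )
    rows = evidence.loc[mask]
    if rows.empty:
        return pd.DataFrame(columns=["spc", "distinct_peptides"], dtype=int)
    grouped = rows.groupby("protein_id").agg(
        spc=("spectra", "sum"), distinct_peptides=("peptide", "nunique")
    )
    return grouped[grouped["spc"] > 0]


def compute_nsaf(counts: Mapping[str, int] | pd.Series, catalog: ProteinCatalog) -> pd.Series:
    """NSAF per protein from spectral counts and catalog lengths.

    Raises if a counted protein is missing from the catalog or if no
    protein has a positive count (NSAF is defined over the identified set).
    """
    counts = pd.Series(counts, dtype=float)
    missing = [pid for pid in counts.index if pid not in catalog]
    if missing:
        raise KeyError(f"proteins absent from catalog: {missing[:5]}")
    if counts.empty or not (counts > 0).any():
        raise ValueError("all-zero spectral counts: NSAF undefined")
    saf = counts / catalog.lengths.reindex(counts.index)
    nsaf = saf / saf.sum()
    nsaf.name = "nsaf"
    return nsaf


def aggregate_replicates(
    nsaf_by_replicate: Mapping[int, pd.Series], n_replicates: int = 3
) -> pd.DataFrame:
    """Replicate mean, SD and detection count per protein for one sample.

    A protein absent from a replicate contributes NSAF 0 to both mean and
    SD (population SD, n = number of replicates), which makes "control
    mean = 0" equivalent to "exclusively present in the LB sample".
    ``n_replicates_detected`` counts replicates with NSAF > 0; a value
    below the replicate count corresponds to the asterisk annotation used
    for incompletely detected control proteins.
    """
    if len(nsaf_by_replicate) == 0:
        raise ValueError("no replicates supplied")
    matrix = pd.DataFrame(nsaf_by_replicate).fillna(0.0)
    if matrix.shape[1] != n_replicates:
        raise ValueError(
            f"expected {n_replicates} replicates, got {sorted(nsaf_by_replicate)}"
        )
    values = matrix.to_numpy()
    return pd.DataFrame(
        {
            "mean_nsaf": values.mean(axis=1),
            "sd_nsaf": values.std(axis=1, ddof=0),
            "n_replicates_detected": (values > 0).sum(axis=1),
        },
        index=matrix.index,
    )


def build_nsaf_table(
    evidence: pd.DataFrame,
    catalog: ProteinCatalog,
    min_confidence: str = "medium",
    samples: tuple[str, ...] = SAMPLES,
    n_replicates: int = 3,
) -> "NsafTable":
    """Quantify a whole fractionation experiment.

    Returns per-run NSAF values together with the per-(sample, protein)
    replicate summary over the union of all proteins identified anywhere
    in the experiment (absences count as zero).
    """
    per_run: list[pd.DataFrame] = []
    summaries: dict[str, pd.DataFrame] = {}
    all_proteins: set[str] = set()
    for sample in samples:
        by_rep: dict[int, pd.Series] = {}
        for rep in range(1, n_replicates + 1):
            counts = spectral_counts(evidence, sample, rep, min_confidence)
            if counts.empty:
                by_rep[rep] = pd.Series(dtype=float)
                continue
            nsaf = compute_nsaf(counts["spc"], catalog)
            by_rep[rep] = nsaf
            run = counts.copy()
            run["nsaf"] = nsaf
            run["sample"] = sample
            run["replicate"] = rep
            per_run.append(run.reset_index(names="protein_id"))
            all_proteins.update(nsaf.index)
        summaries[sample] = aggregate_replicates(by_rep, n_replicates)
    index = sorted(all_proteins)
    summary_rows = []
    for sample in samples:
        summary = summaries[sample].reindex(index).fillna(
            {"mean_nsaf": 0.0, "sd_nsaf": 0.0, "n_replicates_detected": 0}
        )
        summary["n_replicates_detected"] = summary["n_replicates_detected"].astype(int)
        summary["sample"] = sample
        summary_rows.append(summary.reset_index(names="protein_id"))
    replicates = (
        pd.concat(per_run, ignore_index=True)
        if per_run
        else pd.DataFrame(columns=["protein_id", "spc", "distinct_peptides", "nsaf", "sample", "replicate"])
    )
    return NsafTable(replicates, pd.concat(summary_rows, ignore_index=True))


class NsafTable:
    """Per-run NSAF values plus replicate summaries for one experiment."""

    def __init__(self, replicates: pd.DataFrame, summary: pd.DataFrame) -> None:
        #: columns: protein_id, spc, distinct_peptides, nsaf, sample, replicate
        self.replicates = replicates
        #: columns: protein_id, mean_nsaf, sd_nsaf, n_replicates_detected, sample
        self.summary = summary

    def sample_summary(self, sample: str) -> pd.DataFrame:
        out = self.summary[self.summary["sample"] == sample]
        return out.set_index("protein_id")

    def replicate_nsaf(self, sample: str) -> pd.DataFrame:
        """Protein x replicate NSAF matrix for one sample (absences = 0)."""
        rows = self.replicates[self.replicates["sample"] == sample]
        return rows.pivot_table(
            index="protein_id", columns="replicate", values="nsaf", fill_value=0.0
        )


def peptide_positions(protein_seq: str, peptide: str) -> list[int]:
    """All 0-based start offsets of ``peptide`` in ``protein_seq``
    (overlapping occurrences included)."""
    positions = []
    start = protein_seq.find(peptide)
    while start != -1:
        positions.append(start)
        start = protein_seq.find(peptide, start + 1)
    return positions


def compute_coverage(
    evidence: pd.DataFrame,
    catalog: ProteinCatalog,
    protein_id: str,
    min_confidence: str = "medium",
    intersect_samples: bool = False,
) -> float:
    """Sequence coverage (%) of one protein by its matched peptides.

    By default the union of admissible peptides across all samples and
    replicates is used; ``intersect_samples=True`` restricts to peptides
    seen in every sample the protein was detected in (the stricter reading
    of "detected in all samples").  Peptides that are not substrings of
    the catalog sequence are skipped with a log warning.
    """
    if protein_id not in catalog:
        raise KeyError(f"protein {protein_id!r} not in catalog")
    seq = catalog[protein_id]
    admissible = admissible_confidences(min_confidence)
    rows = evidence[
        (evidence["protein_id"] == protein_id)
        & evidence["confidence"].isin(admissible)
        & (evidence["spectra"] > 0)
    ]
    if intersect_samples:
        by_sample = rows.groupby("sample")["peptide"].apply(set)
        peptides = set.intersection(*by_sample) if len(by_sample) else set()
    else:
        peptides = set(rows["peptide"])
    mask = np.zeros(len(seq), dtype=bool)
    for peptide in peptides:
        starts = peptide_positions(seq, peptide)
        if not starts:
            logger.warning(
                "peptide %r not found in protein %s; skipped", peptide, protein_id
            )
            continue
        for start in starts:
            mask[start : start + len(peptide)] = True
    return 100.0 * mask.sum() / len(seq)


def coverage_table(
    evidence: pd.DataFrame,
    catalog: ProteinCatalog,
    protein_ids: list[str] | None = None,
    min_confidence: str = "medium",
) -> pd.Series:
    """:func:`compute_coverage` over many proteins."""
    if protein_ids is None:
        protein_ids = sorted(set(evidence["protein_id"]) & set(catalog.protein_ids))
    values = {
        pid: compute_coverage(evidence, catalog, pid, min_confidence)
        for pid in protein_ids
    }
    return pd.Series(values, name="coverage_pct")
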