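"""Nitrogen-starvation expression analysis.

Two small computations support the candidate filter: the RNA-seq
induction ratio FPKM(3 d -N) / FPKM(+N) with its ``> 5x`` induction call,
and the comparative-Ct (delta-delta-Ct) conversion of qPCR threshold
cycles into expression relative to a reference gene and time point 0.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Strict fold-change threshold for calling a gene nitrogen-starvation induced.
DEFAULT_EXPRESSION_THRESHOLD = 5.0

_PROTEIN_SUFFIX = re.compile(r"\.p\d+$")


def gene_for_protein(protein_id: str) -> str:
    """Map a protein model id onto its gene id (``g555.p1`` -> ``g555``)."""
    return _PROTEIN_SUFFIX.sub("", protein_id)


@dataclass(frozen=True)
class InductionRecord:
    gene_id: str
    fold_change: float  # math.inf when the +N baseline is zero
    induced: bool


def induction_ratio(
    fpkm_starved: float,
    fpkm_replete: float,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> tuple[float, bool]:
    """Fold change of expression after 3 d of nitrogen starvation.

    Returns ``(fold_change, induced)`` where ``induced`` uses a strict
    ``>`` comparison.  A zero +N baseline with non-zero starved signal is
    reported as ``inf`` (induced) rather than through an arbitrary
    pseudocount; a gene silent under both conditions yields ``(0, False)``.
    """
    if fpkm_starved < 0 or fpkm_replete < 0:
        raise ValueError("FPKM values must be non-negative")
    if fpkm_replete == 0:
        if fpkm_starved == 0:
            return 0.0, False
        return math.inf, True
    fold = fpkm_starved / fpkm_replete
    return fold, fold > threshold


def induction_table(
    expression: pd.DataFrame, threshold: float = DEFAULT_EXPRESSION_THRESHOLD
) -> pd.DataFrame:
    """Vectorised :func:`induction_ratio` over an expression table.

    ``expression`` must carry columns ``gene_id``, ``fpkm_replete`` and
    ``fpkm_starved_3d``; rows with a NaN FPKM yield a NaN fold change and
    ``induced = False`` (missing evidence never counts as induction).
    """
    replete = expression["fpkm_replete"].to_numpy(dtype=float)
    starved = expression["fpkm_starved_3d"].to_numpy(dtype=float)
    if np.nanmin(replete, initial=0.0) < 0 or np.nanmin(starved, initial=0.0) < 0:
        raise ValueError("FPKM values must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = starved / replete
    fold = np.where((replete == 0) & (starved == 0), 0.0, fold)
    fold = np.where((replete == 0) & (starved > 0), np.inf, fold)
    induced = np.where(np.isnan(fold), False, fold > threshold)
    return pd.DataFrame(
        {
            "gene_id": expression["gene_id"].to_numpy(),
            "fpkm_replete": replete,
            "fpkm_starved_3d": starved,
            "fold_change": fold,
            "induced": induced.astype(bool),
        }
    )


def ddct_relative(series: pd.DataFrame, efficiency: float = 2.0) -> pd.Series:
    """Comparative-Ct relative expression, normalised to time point 0.

    ``series`` must have columns ``timepoint``, ``ct_target`` and
    ``ct_reference``.  For each time point t,

        relative(t) = efficiency ** -[(CtT(t) - CtR(t)) - (CtT(0) - CtR(0))]

    i.e. expression of the target normalised to the reference gene and
    expressed relative to t = 0, which is exactly 1 by construction.  A
    fixed amplification efficiency of 2 (perfect doubling per cycle) is
    assumed unless per-primer efficiencies are supplied.
    """
    required = {"timepoint", "ct_target", "ct_reference"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"qPCR series lacks columns: {sorted(missing)}")
    if not np.isfinite(series[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    dct = series["ct_target"] - series["ct_reference"]
    at_zero = series["timepoint"] == 0
    if not at_zero.any():
        raise ValueError("qPCR series must contain time point 0")
    ddct = dct - dct[at_zero].iloc[0]
    rel = np.power(float(efficiency), -ddct)
    return pd.Series(rel.to_numpy(), index=series["timepoint"].to_numpy(), name="relative_expression")
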