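"""Readers and writers for the external table formats.

Canonical formats: a FASTA protein catalog, a peptide-level long evidence
TSV (one row per protein x sample x replicate x peptide), an FPKM
expression TSV, a qPCR Ct TSV and the decision report (TSV or JSON).
Everything is validated on read; the pipeline core never touches
spreadsheets (an XLSX converter maps supplementary-style workbooks onto
the canonical evidence TSV via a user-supplied column mapping).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Fixed fraction labels of the four samples taken during LB isolation.
SAMPLES: tuple[str, ...] = ("LB", "total", "membrane", "soluble")
#: Control fractions the LB sample is compared against.
CONTROL_SAMPLES: tuple[str, ...] = ("total", "membrane", "soluble")
#: Peptide identification confidence classes, worst to best.
CONFIDENCE_LEVELS: tuple[str, ...] = ("low", "medium", "high")
#: Technical replicates per fraction.
REPLICATES: tuple[int, ...] = (1, 2, 3)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

EVIDENCE_COLUMNS = ["protein_id", "sample", "replicate", "peptide", "confidence", "spectra"]
EXPRESSION_COLUMNS = ["gene_id", "fpkm_replete", "fpkm_starved_3d"]
QPCR_COLUMNS = ["timepoint", "ct_target", "ct_reference"]

#: Column order of the decision report; deterministic across writes.
REPORT_COLUMNS = [
    "rank", "protein_id",
    "mean_nsaf_LB", "sd_nsaf_LB",
    "mean_nsaf_total", "sd_nsaf_total",
    "mean_nsaf_membrane", "sd_nsaf_membrane",
    "mean_nsaf_soluble", "sd_nsaf_soluble",
    "coverage_pct",
    "fe_total", "fe_membrane", "fe_soluble",
    "exclusive_total", "exclusive_membrane", "exclusive_soluble",
    "control_incomplete_total", "control_incomplete_membrane", "control_incomplete_soluble",
    "fpkm_replete", "fpkm_starved_3d", "expression_fold",
    "present_all_reps", "min_peptides_ok",
    "crit_enrichment", "crit_abundance", "crit_expression", "crit_annotation",
    "final", "lb_localization",
]


@dataclass
class ProteinCatalog:
    """Protein identifier -> amino-acid sequence, the NSAF length basis."""

    sequences: dict[str, str]
    lengths: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for pid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for protein {pid!r}")
            bad = set(seq) - _AA_ALPHABET
            if bad:
                raise ValueError(
                    f"protein {pid!r} contains non-standard residues {sorted(bad)}"
                )
        self.lengths = pd.Series(
            {pid: len(seq) for pid, seq in self.sequences.items()}, name="length", dtype=int
        )

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.sequences

    def __getitem__(self, protein_id: str) -> str:
        return self.sequences[protein_id]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.sequences)


def read_fasta(path: str | Path) -> ProteinCatalog:
    """Read a FASTA catalog; the identifier is the header token before
    the first whitespace and duplicates are a hard error."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        if pid in sequences:
            raise ValueError(f"duplicate protein identifier {pid!r} in {path}")
        sequences[pid] = str(record.seq).upper()
    return ProteinCatalog(sequences)


def write_fasta(catalog: ProteinCatalog, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in catalog.sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read and validate the peptide-level evidence TSV."""
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "peptide": str})
    missing = set(EVIDENCE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"evidence table lacks columns: {sorted(missing)}")
    table = table[EVIDENCE_COLUMNS]
    if table.empty:
        return table.assign(replicate=table.get("replicate", pd.Series(dtype=int)),
                            spectra=table.get("spectra", pd.Series(dtype=int)))
    return validate_evidence(table)


def validate_evidence(table: pd.DataFrame) -> pd.DataFrame:
    """Enforce the evidence invariants (labels, replicate range, counts)."""
    bad_sample = set(table["sample"]) - set(SAMPLES)
    if bad_sample:
        raise ValueError(f"unknown sample labels {sorted(bad_sample)}; expected {SAMPLES}")
    bad_conf = set(table["confidence"]) - set(CONFIDENCE_LEVELS)
    if bad_conf:
        raise ValueError(f"unknown confidence classes {sorted(bad_conf)}")
    reps = table["replicate"].astype(int)
    if not reps.isin(REPLICATES).all():
        raise ValueError("replicate outside 1..3")
    spectra = table["spectra"].astype(int)
    if (spectra < 0).any():
        raise ValueError("negative spectral counts")
    out = table.copy()
    out["replicate"] = reps
    out["spectra"] = spectra
    return out


def write_evidence(table: pd.DataFrame, path: str | Path) -> None:
    table[EVIDENCE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(EXPRESSION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"expression table lacks columns: {sorted(missing)}")
    values = table[["fpkm_replete", "fpkm_starved_3d"]].to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError("FPKM values must be non-negative")
    return table[EXPRESSION_COLUMNS]


def write_expression(table: pd.DataFrame, path: str | Path) -> None:
    table[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_qpcr(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(QPCR_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table lacks columns: {sorted(missing)}")
    return table[QPCR_COLUMNS]


def write_report(report: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a decision report as TSV or JSON with fixed column order.

    Infinite fold enrichments (proteins exclusive to the LB sample) are
    serialised as the string ``exclusive`` in TSV and as ``null`` plus the
    ``exclusive_*`` flag in JSON, so a round trip is lossless.
    """
    cols = [c for c in REPORT_COLUMNS if c in report.columns]
    out = report[cols].copy()
    if format == "tsv":
        for col in ("fe_total", "fe_membrane", "fe_soluble"):
            if col in out.columns:
                out[col] = [
                    "exclusive" if isinstance(v, float) and math.isinf(v) else v
                    for v in out[col]
                ]
        out.to_csv(path, sep="\t", index=False)
    elif format == "json":
        records = []
        for _, row in out.iterrows():
            rec = {}
            for key, value in row.items():
                if isinstance(value, float) and math.isinf(value):
                    value = None
                elif isinstance(value, (np.floating, np.integer, np.bool_)):
                    value = value.item()
                if isinstance(value, float) and math.isnan(value):
                    value = None
                rec[key] = value
            records.append(rec)
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        table = pd.read_csv(path, sep="\t")
        for col in ("fe_total", "fe_membrane", "fe_soluble"):
            if col in table.columns:
                table[col] = [
                    math.inf if v == "exclusive" else float(v) for v in table[col]
                ]
        return table
    if format == "json":
        with open(path) as fh:
            records = json.load(fh)
        table = pd.DataFrame(records)
        for col in ("fe_total", "fe_membrane", "fe_soluble"):
            if col in table.columns:
                flag = table[f"exclusive_{col[3:]}"]
                table[col] = [
                    math.inf if f else v for v, f in zip(table[col], flag)
                ]
        return table
    raise ValueError(f"unknown report format {format!r}")


def convert_xlsx(
    xlsx_path: str | Path,
    out_path: str | Path,
    column_map: dict[str, str] | None = None,
    sheet: str | int = 0,
) -> pd.DataFrame:
    """Convert a supplementary-style XLSX workbook to the canonical
    evidence TSV.

    ``column_map`` maps workbook column headers onto the canonical names
    (``protein_id``, ``sample``, ``replicate``, ``peptide``, ``confidence``,
    ``spectra``); identity mapping is assumed for canonical headers already
    present.  The published layout of such workbooks varies, hence the
    explicit mapping rather than guessed heuristics.
    """
    raw = pd.read_excel(xlsx_path, sheet_name=sheet)
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = set(EVIDENCE_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(
            f"converted workbook lacks columns {sorted(missing)}; "
            "provide a column mapping"
        )
    table = validate_evidence(raw[EVIDENCE_COLUMNS])
    write_evidence(table, out_path)
    return table


def read_config(path: str | Path) -> dict[str, object]:
    """Read a flat ``key=value`` or YAML config carrying thresholds."""
    text = Path(path).read_text()
    config: dict[str, object] = {}
    stripped = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.strip().startswith("#")]
    if stripped and all("=" in ln for ln in stripped):
        for ln in stripped:
            key, _, value = ln.partition("=")
            config[key.strip()] = _coerce(value.strip())
        return config
    import yaml  # optional structured form

    loaded = yaml.safe_load(text) or {}
    if not isinstance(loaded, dict):
        raise ValueError(f"config {path} must be a mapping")
    return loaded


def _coerce(value: str) -> object:
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value
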