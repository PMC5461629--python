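"""Synthetic fractionation experiments with planted ground truth.

The generator emulates the data model behind an LB-proteome screen: a
protein catalog, peptide-level spectral evidence for four fractions (LB,
total extract, total membranes, soluble fraction) in three technical
replicates, and an FPKM table with a planted nitrogen-starvation-induced
subset.  Each protein belongs to one of four compartment classes:

``lb_resident``
    genuinely lipid-body associated, strongly concentrated in the LB
    fraction (the planted positives);
``membrane_contaminant`` / ``soluble_contaminant``
    abundant in their home fraction and the total extract, absent from
    the LB surface — they reach the LB fraction only through carry-over;
``ubiquitous``
    present in every fraction including, at a low level, the LB float
    (adhering cellular machinery).

Carry-over models contamination of the floated LB layer during
fractionation: the expected LB concentration of protein *i* is
``a_i(LB) + kappa * mean(a_i over the three bulk fractions)``, while the
bulk control fractions keep their true composition.  Expected spectra
scale with protein length (the standard spectral-counting length bias),
so NSAF — which divides the count by length — recovers the relative
concentrations.  Counts are Poisson per run (technical replicates; an
optional negative-binomial dispersion knob exists but is off by
default), with an abundance-dependent detection dropout emulating
data-dependent acquisition missing low-abundance proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SAMPLES, ProteinCatalog, validate_evidence

CLASSES = ("lb_resident", "membrane_contaminant", "soluble_contaminant", "ubiquitous")

#: Background amino-acid frequencies (approximate Swiss-Prot composition).
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array([
    0.083, 0.014, 0.055, 0.067, 0.039, 0.071, 0.023, 0.059, 0.058, 0.097,
    0.024, 0.040, 0.047, 0.039, 0.055, 0.066, 0.053, 0.069, 0.011, 0.029,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic fractionation experiment.

    Defaults describe the documented benchmark scenario: 500 proteins, 10
    planted LB residents whose realized LB enrichment is >= the 50-fold
    the screen is meant to recover, 2% carry-over into the LB float and
    20,000 expected spectra per fraction-replicate.
    """

    n_proteins: int = 500
    n_replicates: int = 3
    depth: float = 20_000.0
    carryover: float = 0.02  # kappa, fraction of bulk material carried into the LB float

    #: class proportions over CLASSES, summing to 1
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "lb_resident": 0.02,
            "membrane_contaminant": 0.34,
            "soluble_contaminant": 0.34,
            "ubiquitous": 0.30,
        }
    )
    #: relative concentration per fraction (LB, total, membrane, soluble)
    class_profiles: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "lb_resident": (160.0, 1.0, 1.0, 1.0),
            "membrane_contaminant": (0.0, 2.0, 3.0, 0.0),
            "soluble_contaminant": (0.0, 2.0, 0.0, 3.0),
            "ubiquitous": (0.5, 1.0, 1.0, 1.0),
        }
    )
    #: per-protein abundance scalar ~ lognormal with this sigma (mean 1)
    abundance_sigma: float = 0.8

    # protein lengths, residues (lognormal, clamped)
    length_meanlog: float = math.log(350.0)
    length_sdlog: float = 0.45
    min_length: int = 60
    max_length: int = 3000

    # detection dropout: P(missed | expected count mu) = d0 * exp(-mu / mu0)
    dropout_max: float = 0.3
    dropout_scale: float = 10.0
    #: optional negative-binomial dispersion (None = Poisson technical noise)
    dispersion: float | None = None

    # peptide-level evidence
    peptide_min_len: int = 7
    peptide_max_len: int = 25
    confidence_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)  # high, medium, low

    # expression table
    induced_fraction: float = 0.10
    induction_meanlog: float = math.log(15.0)
    induction_sdlog: float = 0.4
    noninduced_sdlog: float = 0.3
    fpkm_meanlog: float = math.log(50.0)
    fpkm_sdlog: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.carryover < 1):
            raise ValueError("carry-over rate must lie in [0, 1)")
        for cls, profile in self.class_profiles.items():
            if min(profile) < 0:
                raise ValueError(f"negative abundance in profile for {cls}")
        if all(max(p) == 0 for p in self.class_profiles.values()):
            raise ValueError("degenerate config: all abundance profiles are zero")


@dataclass
class ExperimentBundle:
    """One complete synthetic experiment plus its planted truth."""

    catalog: ProteinCatalog
    evidence: pd.DataFrame
    expression: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of class sizes."""
    exact = {c: config.class_proportions.get(c, 0.0) * config.n_proteins for c in CLASSES}
    counts = {c: int(math.floor(v)) for c, v in exact.items()}
    remainder = config.n_proteins - sum(counts.values())
    by_frac = sorted(CLASSES, key=lambda c: (exact[c] - counts[c]), reverse=True)
    for c in by_frac[:remainder]:
        counts[c] += 1
    return counts


def _tryptic_peptides(seq: str, config: SimulationConfig) -> list[str]:
    """Observable in-silico tryptic peptides (cut after K/R, not before P),
    length-filtered and capped at floor(L/10) in sequence order."""
    peptides: list[str] = []
    start = 0
    for i, residue in enumerate(seq):
        if residue in "KR" and not (i + 1 < len(seq) and seq[i + 1] == "P"):
            peptides.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        peptides.append(seq[start:])
    observable = [
        p for p in peptides if config.peptide_min_len <= len(p) <= config.peptide_max_len
    ]
    capacity = max(1, len(seq) // 10)
    if not observable:
        # pathological composition: fall back to consecutive 15-mers
        observable = [seq[i : i + 15] for i in range(0, len(seq) - 14, 15)] or [seq]
    return observable[:capacity]


def expected_intensities(config: SimulationConfig, abundance: np.ndarray) -> np.ndarray:
    """Expected relative concentration per fraction after carry-over.

    ``abundance`` is the (n, 4) true-concentration matrix in fraction
    order LB, total, membrane, soluble; only the LB column receives the
    carry-over term (contamination of the floated LB layer)."""
    tilde = abundance.astype(float).copy()
    tilde[:, 0] += config.carryover * abundance[:, 1:].mean(axis=1)
    return tilde


def generate_experiment(config: SimulationConfig) -> ExperimentBundle:
    """Draw one full synthetic experiment; reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    counts_by_class = _class_counts(config)
    classes = np.repeat(
        [c for c in CLASSES for _ in range(counts_by_class[c])], 1
    )[:n]

    protein_ids = [f"g{i + 1:04d}.p1" for i in range(n)]
    gene_ids = [f"g{i + 1:04d}" for i in range(n)]

    lengths = np.clip(
        np.round(rng.lognormal(config.length_meanlog, config.length_sdlog, size=n)),
        config.min_length,
        config.max_length,
    ).astype(int)
    sequences = {
        pid: "".join(rng.choice(list(_AA), size=length, p=_AA_FREQ))
        for pid, length in zip(protein_ids, lengths)
    }
    catalog = ProteinCatalog(sequences)
    peptides = {pid: _tryptic_peptides(seq, config) for pid, seq in sequences.items()}

    scalar = rng.lognormal(-config.abundance_sigma**2 / 2, config.abundance_sigma, size=n)
    profile_matrix = np.array([config.class_profiles[c] for c in classes])
    abundance = profile_matrix * scalar[:, None]
    if abundance.sum() == 0:
        raise ValueError("degenerate config: every protein has zero abundance")
    tilde = expected_intensities(config, abundance)

    rows_protein: list[str] = []
    rows_sample: list[str] = []
    rows_rep: list[int] = []
    rows_peptide: list[str] = []
    rows_spectra: list[int] = []

    for f_idx, sample in enumerate(SAMPLES):
        weights = tilde[:, f_idx] * lengths
        total = weights.sum()
        if total == 0:
            continue
        mu = config.depth * weights / total
        for rep in range(1, config.n_replicates + 1):
            if config.dispersion is None:
                counts = rng.poisson(mu)
            else:
                r = config.dispersion
                counts = rng.negative_binomial(r, r / (r + np.where(mu > 0, mu, 1e-12)))
                counts = np.where(mu > 0, counts, 0)
            drop = rng.random(n) < config.dropout_max * np.exp(-mu / config.dropout_scale)
            counts = np.where(drop, 0, counts)
            detected = np.nonzero(counts)[0]
            for i in detected:
                peps = peptides[protein_ids[i]]
                split = rng.multinomial(counts[i], np.full(len(peps), 1.0 / len(peps)))
                for pep, spc in zip(peps, split):
                    if spc > 0:
                        rows_protein.append(protein_ids[i])
                        rows_sample.append(sample)
                        rows_rep.append(rep)
                        rows_peptide.append(pep)
                        rows_spectra.append(int(spc))

    # each MS/MS spectrum carries its own identification confidence, so the
    # spectra of one peptide row are split multinomially over the classes
    base = pd.DataFrame(
        {
            "protein_id": rows_protein,
            "sample": rows_sample,
            "replicate": rows_rep,
            "peptide": rows_peptide,
        }
    )
    split = rng.multinomial(rows_spectra, list(config.confidence_probs))
    parts = []
    for j, label in enumerate(("high", "medium", "low")):
        mask = split[:, j] > 0
        if mask.any():
            part = base.loc[mask].copy()
            part["confidence"] = label
            part["spectra"] = split[mask, j]
            parts.append(part)
    if parts:
        evidence = pd.concat(parts, ignore_index=True).sort_values(
            ["sample", "replicate", "protein_id", "peptide", "confidence"],
            ignore_index=True,
            kind="mergesort",
        )
        evidence = validate_evidence(evidence)
    else:
        evidence = pd.DataFrame(
            columns=["protein_id", "sample", "replicate", "peptide", "confidence", "spectra"]
        )

    induced = rng.random(n) < config.induced_fraction
    fpkm_replete = rng.lognormal(config.fpkm_meanlog, config.fpkm_sdlog, size=n)
    fold = np.where(
        induced,
        rng.lognormal(config.induction_meanlog, config.induction_sdlog, size=n),
        rng.lognormal(0.0, config.noninduced_sdlog, size=n),
    )
    expression = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "fpkm_replete": fpkm_replete,
            "fpkm_starved_3d": fpkm_replete * fold,
        }
    )

    truth = _build_truth(
        config, protein_ids, gene_ids, classes, lengths, scalar, abundance, tilde,
        induced, fold,
    )
    return ExperimentBundle(catalog, evidence, expression, truth, config)


def _build_truth(
    config: SimulationConfig,
    protein_ids: list[str],
    gene_ids: list[str],
    classes: np.ndarray,
    lengths: np.ndarray,
    scalar: np.ndarray,
    abundance: np.ndarray,
    tilde: np.ndarray,
    induced: np.ndarray,
    fold: np.ndarray,
) -> pd.DataFrame:
    """Planted truth plus noise-free expected cascade flags.

    Expected flags are a deterministic reference oracle evaluated at the
    Poisson-mean level: a protein counts as "expected present" in the LB
    fraction when its expected spectral count per replicate is >= 1, and
    expected NSAF shares are the relative concentrations (length cancels
    by construction).
    """
    shares = tilde / tilde.sum(axis=0, keepdims=True)
    weights = tilde * lengths[:, None]
    mu_lb = config.depth * weights[:, 0] / weights[:, 0].sum()
    expected_present = mu_lb >= 1.0

    fe = np.empty((len(protein_ids), 3))
    for j in range(3):
        with np.errstate(divide="ignore", invalid="ignore"):
            fe[:, j] = shares[:, 0] / shares[:, j + 1]
        fe[shares[:, j + 1] == 0, j] = np.inf
    fe[shares[:, 0] == 0, :] = 0.0
    expected_crit_i = expected_present & (np.nanmax(fe, axis=1) > 10.0)

    present_idx = np.nonzero(expected_present)[0]
    k = math.ceil(0.10 * len(present_idx)) if len(present_idx) else 0
    order = sorted(present_idx, key=lambda i: (-shares[i, 0], protein_ids[i]))
    top = set(order[:k])
    expected_crit_ii = np.array([i in top for i in range(len(protein_ids))])

    expected_crit_iii = expected_present & induced & (fold > 5.0)
    expected_final = expected_present & (
        expected_crit_i | expected_crit_ii | expected_crit_iii
    )

    return pd.DataFrame(
        {
            "protein_id": protein_ids,
            "gene_id": gene_ids,
            "class": classes,
            "length": lengths,
            "abundance_scalar": scalar,
            "a_LB": abundance[:, 0],
            "a_total": abundance[:, 1],
            "a_membrane": abundance[:, 2],
            "a_soluble": abundance[:, 3],
            "expected_lb_spectra": mu_lb,
            "induced": induced,
            "true_fold": fold,
            "expected_present": expected_present,
            "expected_crit_enrichment": expected_crit_i,
            "expected_crit_abundance": expected_crit_ii,
            "expected_crit_expression": expected_crit_iii,
            "expected_final": expected_final,
        }
    )


@dataclass
class RecoveryMetrics:
    """Recovery of the planted LB residents by the decision cascade."""

    recall: float
    precision: float
    precision_zero_denominator: bool
    n_planted: int
    n_candidates: int
    false_pass_rate: dict[str, float]
    confusion: pd.DataFrame  # per criterion: tp, fp, fn, tn over all proteins


def evaluate_recovery(decisions: pd.DataFrame, truth: pd.DataFrame) -> RecoveryMetrics:
    """Score the cascade output against the planted truth.

    ``recall`` is the fraction of planted LB residents with a final
    positive verdict; ``precision`` the fraction of final positives that
    are planted residents (reported as 1.0 with a flag when nothing
    passed).  ``false_pass_rate`` gives, per criterion, the fraction of
    non-resident proteins that passed it.
    """
    unknown = set(decisions["protein_id"]) - set(truth["protein_id"])
    if unknown:
        raise ValueError(f"decisions contain proteins absent from truth: {sorted(unknown)[:5]}")
    planted = set(truth.loc[truth["class"] == "lb_resident", "protein_id"])
    nulls = set(truth["protein_id"]) - planted
    final = set(decisions.loc[decisions["final"], "protein_id"])

    recall = len(final & planted) / len(planted) if planted else 0.0
    zero_denom = len(final) == 0
    precision = 1.0 if zero_denom else len(final & planted) / len(final)

    crit_cols = ["crit_enrichment", "crit_abundance", "crit_expression", "crit_annotation", "final"]
    false_pass: dict[str, float] = {}
    confusion_rows = []
    for col in crit_cols:
        passed = set(decisions.loc[decisions[col], "protein_id"])
        tp = len(passed & planted)
        fp = len(passed & nulls)
        confusion_rows.append(
            {
                "criterion": col,
                "tp": tp,
                "fp": fp,
                "fn": len(planted) - tp,
                "tn": len(nulls) - fp,
            }
        )
        false_pass[col] = fp / len(nulls) if nulls else 0.0
    return RecoveryMetrics(
        recall=recall,
        precision=precision,
        precision_zero_denominator=zero_denom,
        n_planted=len(planted),
        n_candidates=len(final),
        false_pass_rate=false_pass,
        confusion=pd.DataFrame(confusion_rows).set_index("criterion"),
    )
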