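import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lbproteome import (
    aggregate_replicates,
    build_nsaf_table,
    compute_coverage,
    compute_nsaf,
    spectral_counts,
)
from lbproteome.io import ProteinCatalog
from lbproteome.quantify import peptide_positions
from conftest import make_evidence


# ------------------------------------------------------- spectral counts

def test_spectral_counts_confidence_filter_and_distinctness():
    evidence = make_evidence(
        [
            ("g1", "LB", 1, "PEPA", "high", 3),
            ("g1", "LB", 1, "PEPB", "medium", 2),
            ("g2", "LB", 1, "PEPC", "low", 9),
            ("g3", "LB", 1, "PEPD", "medium", 2),
            ("g3", "LB", 1, "PEPD", "high", 3),  # same peptide twice
        ]
    )
    counts = spectral_counts(evidence, "LB", 1, "medium")
    assert counts.loc["g1", "spc"] == 5 and counts.loc["g1", "distinct_peptides"] == 2
    assert "g2" not in counts.index  # low-confidence evidence inadmissible
    assert counts.loc["g3", "spc"] == 5 and counts.loc["g3", "distinct_peptides"] == 1


def test_spectral_counts_rejects_unknown_run():
    evidence = make_evidence([("g1", "LB", 1, "PEPA", "high", 3)])
    with pytest.raises(ValueError):
        spectral_counts(evidence, "pellet", 1)
    with pytest.raises(ValueError):
        spectral_counts(evidence, "LB", 7)


# ------------------------------------------------------------------ NSAF

def test_nsaf_single_protein_normalises_to_one(catalog):
    nsaf = compute_nsaf({"p1": 17}, catalog)
    assert nsaf["p1"] == 1.0


def test_nsaf_hand_oracle():
    catalog = ProteinCatalog({"a": "A" * 100, "b": "C" * 100, "c": "D" * 300})
    nsaf = compute_nsaf({"a": 10, "b": 20, "c": 10}, catalog)
    # SAFs 0.1, 0.2, 0.0333... -> normalised 0.3, 0.6, 0.1
    assert np.allclose(nsaf[["a", "b", "c"]], [0.3, 0.6, 0.1])


def test_nsaf_errors(catalog):
    with pytest.raises(KeyError):
        compute_nsaf({"missing": 5}, catalog)
    with pytest.raises(ValueError):
        compute_nsaf({"p1": 0, "p2": 0}, catalog)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=4),
    scale=st.integers(min_value=1, max_value=50),
)
def test_nsaf_invariant_under_count_rescaling(counts, scale):
    ids = ["p1", "p2", "p3", "p4"][: len(counts)]
    if sum(counts) == 0:
        counts[0] = 1
    catalog = ProteinCatalog({"p1": "MKVRST", "p2": "MKVRSTACDEFGHIKLMNPQ", "p3": "A" * 100, "p4": "MKVR" * 75})
    base = compute_nsaf(dict(zip(ids, counts)), catalog)
    scaled = compute_nsaf({k: v * scale for k, v in zip(ids, counts)}, catalog)
    assert np.allclose(base, scaled)
    assert abs(base.sum() - 1.0) < 1e-12


def test_nsaf_monotone_in_length_and_counts():
    catalog = ProteinCatalog({"a": "A" * 100, "b": "C" * 100, "longer": "D" * 200})
    base = compute_nsaf({"a": 10, "b": 10}, catalog)
    # same counts, longer protein -> smaller NSAF
    vs_long = compute_nsaf({"longer": 10, "b": 10}, catalog)
    assert vs_long["longer"] < base["a"]
    # more counts at fixed lengths -> larger NSAF
    more = compute_nsaf({"a": 20, "b": 10}, catalog)
    assert more["a"] > base["a"]


def test_nsaf_sums_to_one_per_run_on_synthetic_experiment(bundle):
    nsaf = build_nsaf_table(bundle.evidence, bundle.catalog)
    sums = nsaf.replicates.groupby(["sample", "replicate"])["nsaf"].sum()
    assert len(sums) == 12
    assert np.allclose(sums, 1.0, atol=1e-9)


# ------------------------------------------------------------ aggregates

def test_aggregate_replicates_mean_sd_detection():
    agg = aggregate_replicates(
        {
            1: pd.Series({"a": 0.2, "b": 0.3}),
            2: pd.Series({"a": 0.2}),
            3: pd.Series({"a": 0.2, "b": 0.3}),
        }
    )
    assert agg.loc["a", "mean_nsaf"] == pytest.approx(0.2)
    assert agg.loc["a", "sd_nsaf"] == pytest.approx(0.0, abs=1e-15)
    assert agg.loc["a", "n_replicates_detected"] == 3
    # absence counts as zero in mean and SD (population convention)
    assert agg.loc["b", "mean_nsaf"] == pytest.approx(0.2)
    assert agg.loc["b", "sd_nsaf"] == pytest.approx(np.std([0.3, 0.0, 0.3]))
    assert agg.loc["b", "n_replicates_detected"] == 2


def test_aggregate_replicates_errors():
    with pytest.raises(ValueError):
        aggregate_replicates({})
    with pytest.raises(ValueError):
        aggregate_replicates({1: pd.Series({"a": 1.0})}, n_replicates=3)


# -------------------------------------------------------------- coverage

@pytest.mark.parametrize(
    "peptides, expected",
    [
        (["MKV"], 50.0),          # 3 of 6 residues
        (["MKV", "KVR"], 400 / 6),  # union covers residues 1..4
        (["MKVRST"], 100.0),
    ],
)
def test_coverage_examples(catalog, peptides, expected):
    evidence = make_evidence(
        [("p1", "LB", 1, pep, "high", 1) for pep in peptides]
    )
    assert compute_coverage(evidence, catalog, "p1") == pytest.approx(expected)


def test_coverage_skips_unmatched_peptide(catalog, caplog):
    evidence = make_evidence(
        [("p1", "LB", 1, "MKV", "high", 1), ("p1", "LB", 1, "WWWW", "high", 1)]
    )
    with caplog.at_level("WARNING"):
        value = compute_coverage(evidence, catalog, "p1")
    assert value == pytest.approx(50.0)
    assert "WWWW" in caplog.text


def test_coverage_counts_repeated_matches_once_each():
    catalog = ProteinCatalog({"rep": "MKVR" * 3})  # MKVR repeated
    evidence = make_evidence([("rep", "LB", 1, "MKVR", "high", 1)])
    # peptide matches at all three positions -> full coverage
    assert compute_coverage(evidence, catalog, "rep") == pytest.approx(100.0)


def _coverage_oracle(seq, peptides):
    mask = [False] * len(seq)
    for pep in peptides:
        for start in range(len(seq) - len(pep) + 1):
            if seq[start : start + len(pep)] == pep:
                for k in range(start, start + len(pep)):
                    mask[k] = True
    return 100.0 * sum(mask) / len(seq)


def test_coverage_matches_boolean_mask_oracle():
    rng = np.random.default_rng(7)
    alphabet = list("ACDGKMRSTV")
    for _ in range(200):
        seq = "".join(rng.choice(alphabet, size=rng.integers(10, 40)))
        peptides = []
        for _ in range(rng.integers(1, 5)):
            start = rng.integers(0, len(seq) - 3)
            peptides.append(seq[start : start + rng.integers(3, 8)])
        catalog = ProteinCatalog({"x": seq})
        evidence = make_evidence([("x", "LB", 1, p, "high", 1) for p in peptides])
        assert compute_coverage(evidence, catalog, "x") == pytest.approx(
            _coverage_oracle(seq, set(peptides))
        )


def test_peptide_positions_finds_overlapping_matches():
    assert peptide_positions("AAAA", "AA") == [0, 1, 2]
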