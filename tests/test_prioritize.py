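import math

import numpy as np
import pandas as pd
import pytest

from lbproteome import (
    SimulationConfig,
    Thresholds,
    apply_cascade,
    build_nsaf_table,
    criterion_abundance,
    criterion_enrichment,
    enrichment_table,
    fold_enrichment,
    generate_experiment,
    induction_table,
    presence_filter,
    rank_and_report,
    run_pipeline,
)
from lbproteome.prioritize import EXCLUSIVE
from conftest import make_evidence


# -------------------------------------------------------- presence filter

def _presence_evidence():
    rows = []
    for rep in (1, 2, 3):
        rows += [
            ("p3", "LB", rep, "AAAAA", "high", 4),
            ("p3", "LB", rep, "AAAAAAA", "medium", 2),
            ("p1", "LB", rep, "MKV", "high", 3),  # only one distinct peptide
        ]
    for rep in (1, 3):  # p2 misses replicate 2
        rows.append(("p2", "LB", rep, "MKVRST", "high", 5))
        rows.append(("p2", "LB", rep, "ACDEF", "high", 1))
    return make_evidence(rows)


def test_presence_filter_requires_all_replicates_and_two_peptides(catalog):
    evidence = _presence_evidence()
    nsaf = build_nsaf_table(evidence, catalog)
    assert presence_filter(nsaf, evidence) == {"p3"}


def test_presence_filter_low_confidence_peptides_do_not_count(catalog):
    rows = []
    for rep in (1, 2, 3):
        rows.append(("p3", "LB", rep, "AAAAA", "high", 4))
        rows.append(("p3", "LB", rep, "AAAAAA", "low", 9))
    evidence = make_evidence(rows)
    nsaf = build_nsaf_table(evidence, catalog)
    assert presence_filter(nsaf, evidence) == set()


# -------------------------------------------------------- fold enrichment

def test_fold_enrichment_values():
    assert fold_enrichment(2.0e-3, 2.0e-3) == 1.0
    assert fold_enrichment(3.0e-3, 1.0e-3) == pytest.approx(3.0)
    assert math.isinf(fold_enrichment(3.0e-3, 0.0))
    with pytest.raises(ValueError):
        fold_enrichment(0.0, 1.0e-3)


@pytest.mark.parametrize(
    "enrichments, expected",
    [
        ((31.3, 26.6, 47.8), True),   # strongly enriched candidate
        ((5.5, 7.3, 9.2), False),     # all below 10x
        ((2.2, 25.6, 7.3), True),     # a single control above 10x suffices
        ((EXCLUSIVE, 0.5, 0.5), True),
        ((10.0, 10.0, 10.0), False),  # strict comparison
    ],
)
def test_criterion_enrichment(enrichments, expected):
    assert criterion_enrichment(pd.Series(enrichments)) is expected


# ------------------------------------------------------- abundance decile

def test_abundance_decile_distinct_values():
    nsaf = pd.Series({f"p{i:02d}": (i + 1) / 100 for i in range(10)})
    assert criterion_abundance(nsaf) == {"p09"}


def test_abundance_decile_tie_at_cut_is_lexicographic():
    values = {f"p{i:02d}": 0.01 for i in range(17)}
    values.update({"tieA": 0.5, "tieB": 0.5, "tieC": 0.5})  # 3-way tie spans the cut
    selected = criterion_abundance(pd.Series(values), 0.10)  # k = ceil(2.0) = 2
    assert selected == {"tieA", "tieB"}


def test_abundance_decile_empty():
    assert criterion_abundance(pd.Series(dtype=float)) == set()


def test_abundance_decile_matches_sort_oracle():
    rng = np.random.default_rng(42)
    for _ in range(300):
        n = int(rng.integers(1, 51))
        values = rng.choice([0.1, 0.2, 0.3, 0.5], size=n)  # deliberate ties
        nsaf = pd.Series(values, index=[f"p{i:03d}" for i in range(n)])
        k = math.ceil(0.10 * n)
        oracle = sorted(nsaf.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        assert criterion_abundance(nsaf) == {pid for pid, _ in oracle}


# ------------------------------------------------------------ full cascade

@pytest.fixture(scope="module")
def small_run():
    bundle = generate_experiment(SimulationConfig(n_proteins=80, seed=3))
    return bundle, run_pipeline(bundle.catalog, bundle.evidence, bundle.expression)


def test_candidates_subset_of_presence_subset_of_catalog(small_run):
    bundle, result = small_run
    nsaf = result.nsaf_table
    passing = presence_filter(nsaf, bundle.evidence)
    final = set(result.decisions.loc[result.decisions["final"], "protein_id"])
    assert final <= set(result.decisions["protein_id"]) == passing
    assert passing <= set(bundle.catalog.protein_ids)


def test_missing_expression_record_fails_criterion_iii_quietly(small_run):
    bundle, result = small_run
    truncated = bundle.expression.iloc[:0]
    decisions = apply_cascade(
        result.nsaf_table, bundle.evidence, result.enrichments,
        induction_table(truncated),
    )
    assert not decisions["crit_expression"].any()


def test_degenerate_thresholds_bound_the_candidate_set(small_run):
    """With every ratio criterion unattainable the candidate set collapses to
    the abundance decile plus LB-exclusive proteins (exclusivity is part of
    criterion (i) and independent of the fold threshold); with the enrichment
    threshold at ~0 every presence-filtered protein is a candidate."""
    bundle, result = small_run
    strict = Thresholds(enrichment_fold=1e12, expression_fold=1e12, top_fraction=0.10)
    decisions = apply_cascade(
        result.nsaf_table, bundle.evidence, result.enrichments, result.inductions,
        thresholds=strict,
    )
    final = set(decisions.loc[decisions["final"], "protein_id"])
    abundant = set(decisions.loc[decisions["crit_abundance"], "protein_id"])
    fe_cols = ["fe_total", "fe_membrane", "fe_soluble"]
    exclusive = {
        pid
        for pid in decisions["protein_id"]
        if np.isinf(result.enrichments.loc[pid, fe_cols].astype(float)).any()
    }
    assert final == abundant | exclusive
    assert len(abundant) == math.ceil(0.10 * len(decisions))

    lax = Thresholds(enrichment_fold=1e-12)
    decisions = apply_cascade(
        result.nsaf_table, bundle.evidence, result.enrichments, result.inductions,
        thresholds=lax,
    )
    assert decisions["final"].all()


def test_more_lb_spectra_never_flip_enrichment_or_abundance_to_fail(small_run):
    bundle, result = small_run
    before = result.decisions.set_index("protein_id")
    target = before.index[len(before) // 2]
    boosted = bundle.evidence.copy()
    lb_rows = (boosted["protein_id"] == target) & (boosted["sample"] == "LB")
    boosted.loc[lb_rows, "spectra"] *= 5
    after = run_pipeline(bundle.catalog, boosted, bundle.expression).decisions
    after = after.set_index("protein_id")
    for crit in ("crit_enrichment", "crit_abundance"):
        if before.loc[target, crit]:
            assert after.loc[target, crit], f"{crit} flipped pass->fail for {target}"


def test_partially_detected_control_yields_finite_enrichment(catalog):
    rows = []
    for rep in (1, 2, 3):
        rows += [
            ("p3", "LB", rep, "AAAAA", "high", 6),
            ("p3", "LB", rep, "AAAAAA", "high", 6),
            ("p1", "LB", rep, "MKV", "high", 2),
            ("p1", "total", rep, "MKV", "high", 4),
        ]
    rows.append(("p3", "total", 1, "AAAAA", "high", 2))  # control sees p3 once
    evidence = make_evidence(rows)
    nsaf = build_nsaf_table(evidence, catalog)
    enr = enrichment_table(nsaf, ["p3", "p1"])
    assert np.isfinite(enr.loc["p3", "fe_total"])
    assert enr.loc["p3", "control_incomplete_total"]
    assert math.isinf(enr.loc["p3", "fe_membrane"])  # never seen -> exclusive
    assert enr.loc["p3", "exclusive_membrane"]


# ----------------------------------------------------------------- report

def test_report_empty_and_deterministic(small_run):
    bundle, result = small_run
    empty = rank_and_report(
        result.decisions.iloc[:0], result.nsaf_table, result.coverage,
        result.enrichments, result.inductions,
    )
    assert empty.empty
    again = rank_and_report(
        result.decisions, result.nsaf_table, result.coverage,
        result.enrichments, result.inductions,
    )
    pd.testing.assert_frame_equal(again, result.report)


def test_report_rows_are_final_candidates_with_populated_columns(small_run):
    _, result = small_run
    n_final = int(result.decisions["final"].sum())
    assert len(result.report) == n_final
    assert list(result.report["rank"]) == list(range(1, n_final + 1))
    assert result.report["mean_nsaf_LB"].gt(0).all()
    assert result.report["coverage_pct"].between(0, 100).all()
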