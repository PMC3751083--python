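"""Carriage profiles, cut-off fitting, classification and the allelic test."""

import numpy as np
import pytest
from scipy import stats

from causalpie.classifier import (
    CarriageProfile,
    allelic_association_test,
    bonferroni,
    carriage_profiles,
    classify,
    fit_cutoffs,
)
from causalpie.io import pooled_dose_coding


def _prof(sid, pct_carried, measurable, case, hub="H", **kw):
    meta = dict(dataset="d", ethnic_group="e", platform="p")
    meta.update(kw)
    return CarriageProfile(sid, hub, pct_carried, measurable, case, **meta)


# ---------------------------------------------------------------------------
# fit_cutoffs / classify
# ---------------------------------------------------------------------------


def test_cutoff_perfect_separation_takes_case_percentage():
    profiles = [_prof(f"h{i}", 6, 10, True) for i in range(5)] + [
        _prof(f"n{i}", 4, 10, False) for i in range(5)
    ]
    rule = fit_cutoffs(profiles, "S1")
    assert rule.cutoffs[("H", "e")] == pytest.approx(60.0)
    assert rule.er[("H", "e")] == 0.0


def test_cutoff_identical_distributions_degenerate_error():
    profiles = [_prof(f"h{i}", 5, 10, True) for i in range(4)] + [
        _prof(f"n{i}", 5, 10, False) for i in range(6)
    ]
    rule = fit_cutoffs(profiles, "S1")
    # candidates are observed case percentages only, so with identical
    # distributions the single candidate predicts everyone a case and the
    # error is the control share among identified subjects
    assert rule.cutoffs[("H", "e")] == pytest.approx(50.0)
    assert rule.er[("H", "e")] == pytest.approx(6 / 10)


def test_classify_boundary_is_predicted_case():
    profiles = [_prof("h1", 6, 10, True), _prof("n1", 6, 10, False)]
    rule = fit_cutoffs(profiles, "S1")
    pred, rep = classify(profiles, rule)
    assert pred["n1"] is True  # >= convention at the cut-off
    assert rep.tp + rep.fn == 1 and rep.tn + rep.fp == 1


def test_classify_counts_cross_platform_subject_once():
    profiles = [
        _prof("s1", 8, 10, True, dataset="d1", platform="p1"),
        _prof("s1", 2, 10, True, dataset="d2", platform="p2"),
        _prof("n1", 2, 10, False, dataset="d1", platform="p1"),
    ]
    rule = fit_cutoffs(profiles, "S2")
    pred, rep = classify(profiles, rule)
    assert len(pred) == 2
    assert rep.tp + rep.fn == 1


def test_classify_invariant_to_profile_order():
    rng = np.random.default_rng(3)
    profiles = []
    for i in range(30):
        case = bool(rng.integers(2))
        profiles.append(
            _prof(f"s{i}", int(rng.integers(1, 11)), 10, case,
                  hub=f"H{rng.integers(2)}")
        )
    rule = fit_cutoffs(profiles, "S1")
    p1, r1 = classify(profiles, rule)
    p2, r2 = classify(list(reversed(profiles)), rule)
    assert p1 == p2 and r1 == r2


def test_raising_cutoff_never_raises_sensitivity():
    rng = np.random.default_rng(7)
    profiles = [
        _prof(f"s{i}", int(rng.integers(1, 11)), 10, bool(rng.integers(2)))
        for i in range(40)
    ]
    rule = fit_cutoffs(profiles, "S1")
    key = ("H", "e")
    base = rule.cutoffs[key]
    _, rep_lo = classify(profiles, rule)
    rule.cutoffs[key] = base + 10
    _, rep_hi = classify(profiles, rule)
    assert rep_hi.sensitivity <= rep_lo.sensitivity or np.isnan(rep_hi.sensitivity)
    assert rep_hi.specificity >= rep_lo.specificity or np.isnan(rep_lo.specificity)


def test_stratum_without_cases_is_inert():
    profiles = [_prof("n1", 5, 10, False)]
    rule = fit_cutoffs(profiles, "S1")
    assert rule.cutoffs == {}
    pred, rep = classify(profiles, rule)
    assert pred["n1"] is False


# ---------------------------------------------------------------------------
# carriage profiles on planted data
# ---------------------------------------------------------------------------


def test_profiles_only_for_identified_subjects(default_sim, default_result):
    datasets, _, truth = default_sim
    coding = pooled_dose_coding(datasets)
    profiles = carriage_profiles(default_result.clusters, datasets[0], coding)
    assert profiles, "no identified subjects"
    assert all(p.carried >= 1 and 0 < p.percentage <= 100 for p in profiles)
    # planted targets carry every member pair of their own cluster
    by_hub_subject = {(p.cluster_hub, p.subject_id): p for p in profiles}
    for pie in truth.pies:
        for t in pie.target_ids:
            if t not in datasets[0].subject_ids:
                continue
            prof = by_hub_subject[(pie.hub_gene, t)]
            assert prof.percentage == pytest.approx(100.0)


def test_planted_cases_outrank_identified_controls(default_sim, default_result):
    datasets, _, _ = default_sim
    coding = pooled_dose_coding(datasets)
    profiles = [
        p for ds in datasets
        for p in carriage_profiles(default_result.clusters, ds, coding)
    ]
    ht = [p.percentage for p in profiles if p.is_case]
    nc = [p.percentage for p in profiles if not p.is_case]
    assert nc, "no identified controls (leak produced none)"
    u = stats.mannwhitneyu(ht, nc, alternative="greater")
    assert u.pvalue < 1e-6


# ---------------------------------------------------------------------------
# allelic association test
# ---------------------------------------------------------------------------


def test_allelic_test_reproduces_published_worked_example():
    """Printed genotype counts of the strongest major-gene SNP give the
    published allelic p-value of 4.97e-24."""
    chi2, p, table = allelic_association_test(
        {"AA": 346, "AG": 123, "GG": 26, "missing": 10},
        {"AA": 2596, "AG": 412, "GG": 28, "missing": 29},
    )
    assert table.loc["case"].sum() == 2 * (346 + 123 + 26)
    assert p == pytest.approx(4.97e-24, rel=0.02)


def test_allelic_test_identical_frequencies_null():
    chi2, p, _ = allelic_association_test(
        {"AA": 50, "AG": 30, "GG": 20}, {"AA": 100, "AG": 60, "GG": 40}
    )
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_allelic_test_matches_hand_coded_chi_square():
    rng = np.random.default_rng(11)
    for _ in range(25):
        cases = {g: int(rng.integers(1, 200)) for g in ("AA", "AG", "GG")}
        ctls = {g: int(rng.integers(1, 200)) for g in ("AA", "AG", "GG")}
        chi2, p, table = allelic_association_test(cases, ctls)
        # independent formula: chi2 = N (ad - bc)^2 / (r1 r2 c1 c2)
        a, b = table.iloc[0, 0], table.iloc[0, 1]
        c, d = table.iloc[1, 0], table.iloc[1, 1]
        n = a + b + c + d
        expect = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(expect, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expect, 1), rel=1e-10)


def test_allelic_test_rejects_empty_group_and_triallelic():
    with pytest.raises(ValueError):
        allelic_association_test({"AA": 0}, {"AA": 10, "AG": 5})
    with pytest.raises(ValueError):
        allelic_association_test({"AA": 5, "CT": 5}, {"AA": 5})


def test_bonferroni_caps_at_one():
    assert bonferroni([0.01, 0.5], 3) == [0.03, 1.0]
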