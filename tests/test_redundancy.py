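"""D-prime estimation, LD member reduction, minimal-gene-set search."""

import numpy as np
import pytest

from causalpie.cluster import run_pipeline
from causalpie.io import pooled_dose_coding
from causalpie.redundancy import (
    GaConfig,
    estimate_dprime,
    ld_reduce,
    ld_reduce_with_report,
    minimal_gene_set,
)
from causalpie.simulate import PlantedPieSpec, generate_training_datasets

from conftest import make_dataset_from_doses


def _dataset_from_haplotypes(hap_pairs, n_copies=1):
    """Subjects built from explicit two-locus haplotype pairs (1 = minor)."""
    rows = []
    for h1, h2 in hap_pairs * n_copies:
        rows.append([h1[0] + h2[0], h1[1] + h2[1]])
    doses = np.array(rows)
    labels = np.zeros(len(rows), dtype=bool)
    labels[0] = True  # at least one case for dataset validity
    return make_dataset_from_doses(doses, labels)


def test_dprime_identical_columns_is_one():
    rng = np.random.default_rng(0)
    col = rng.binomial(2, 0.3, size=200)
    doses = np.stack([col, col], axis=1)
    labels = np.zeros(200, dtype=bool)
    labels[:50] = True
    ds = make_dataset_from_doses(doses, labels)
    est = estimate_dprime(ds, "rs0001", "rs0002", pooled_dose_coding([ds]))
    assert est.defined and est.converged
    assert est.d_prime == pytest.approx(1.0, abs=1e-6)


def test_dprime_independent_snps_near_zero():
    rng = np.random.default_rng(1)
    doses = np.stack(
        [rng.binomial(2, 0.3, size=10000), rng.binomial(2, 0.4, size=10000)], axis=1
    )
    labels = np.zeros(10000, dtype=bool)
    labels[:100] = True
    ds = make_dataset_from_doses(doses, labels)
    est = estimate_dprime(ds, "rs0001", "rs0002", pooled_dose_coding([ds]))
    assert est.defined and abs(est.d_prime) < 0.1


def test_dprime_em_matches_phased_counting_oracle():
    """A toy with no double heterozygotes is phase-unambiguous, so D' from
    direct haplotype counting must match the EM estimate."""
    # haplotypes over (A,B): minor-minor coupling excess
    haps = [
        ((1, 1), (1, 1)),  # dose (2,2)
        ((1, 1), (0, 0)),
        ((0, 0), (0, 0)),
        ((0, 0), (0, 0)),
        ((1, 1), (1, 1)),
        ((0, 0), (1, 1)),  # dose (0,2): repulsion
        ((0, 0), (0, 0)),
        ((1, 1), (1, 1)),
    ]
    ds = _dataset_from_haplotypes(haps, n_copies=3)
    est = estimate_dprime(ds, "rs0001", "rs0002", pooled_dose_coding([ds]))
    # direct counting over the 16 explicit haplotypes per copy
    flat = [h for pair in haps for h in pair]
    n = len(flat)
    p_ab = sum(1 for h in flat if h == (1, 1)) / n
    p_a = sum(1 for h in flat if h[0] == 1) / n
    p_b = sum(1 for h in flat if h[1] == 1) / n
    d = p_ab - p_a * p_b
    dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b) if d >= 0 else min(
        p_a * p_b, (1 - p_a) * (1 - p_b)
    )
    assert est.defined
    assert est.d_prime == pytest.approx(abs(d) / dmax, abs=1e-6)


def test_dprime_symmetric_and_monomorphic_flagged():
    rng = np.random.default_rng(2)
    doses = np.stack(
        [rng.binomial(2, 0.25, 300), rng.binomial(2, 0.35, 300), np.zeros(300, int)],
        axis=1,
    )
    labels = np.zeros(300, dtype=bool)
    labels[:60] = True
    ds = make_dataset_from_doses(doses, labels)
    coding = pooled_dose_coding([ds])
    ab = estimate_dprime(ds, "rs0001", "rs0002", coding)
    ba = estimate_dprime(ds, "rs0002", "rs0001", coding)
    assert ab.d_prime == pytest.approx(ba.d_prime, abs=1e-9)
    mono = estimate_dprime(ds, "rs0001", "rs0003", coding)
    assert not mono.defined and np.isnan(mono.d_prime)


def test_dprime_haplotype_freqs_sum_to_one(default_sim):
    datasets, _, truth = default_sim
    coding = pooled_dose_coding(datasets)
    pie = truth.pies[0]
    est = estimate_dprime(
        datasets[0], pie.pairs[0][0], pie.pairs[1][0], coding
    )
    assert est.defined
    assert sum(est.hap_freqs) == pytest.approx(1.0, abs=1e-9)
    assert 0.0 <= est.d_prime <= 1.0


# ---------------------------------------------------------------------------
# LD reduction on planted duplicates
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def ld_sim():
    datasets, ann, truth = generate_training_datasets(
        200, 400, 600,
        [PlantedPieSpec("HUB1", n_pairs=6, ld_duplicates=4)],
        seed=3, sizes=[(300, 2400), (200, 400)],
    )
    res = run_pipeline(datasets, ann)
    return datasets, truth, res


def test_ld_reduce_removes_planted_duplicates_er_unchanged(ld_sim):
    datasets, truth, res = ld_sim
    cluster = res.clusters[0]
    assert cluster.hub == "HUB1"
    coding = pooled_dose_coding(datasets)
    reduced, report = ld_reduce_with_report(cluster, datasets, coding, threshold=0.9)
    dup_partners = set(truth.pies[0].duplicate_of)
    kept_partners = {p.partner_of("HUB1") for p in reduced.members}
    assert not (kept_partners & dup_partners)
    assert report.pairs_after == report.pairs_before - len(dup_partners)
    assert report.error_after == report.error_before
    assert report.pair_reduction_pct == pytest.approx(
        100.0 * len(dup_partners) / report.pairs_before
    )


def test_ld_reduce_idempotent(ld_sim):
    datasets, _, res = ld_sim
    coding = pooled_dose_coding(datasets)
    once = ld_reduce(res.clusters[0], datasets[0], coding, 0.9)
    twice = ld_reduce(once, datasets[0], coding, 0.9)
    assert once.member_keys == twice.member_keys


def test_ld_reduce_independent_partners_unchanged(default_sim, default_result):
    datasets, _, _ = default_sim
    coding = pooled_dose_coding(datasets)
    c = default_result.clusters[0]
    reduced = ld_reduce(c, datasets[0], coding, 0.9)
    assert reduced.member_keys == c.member_keys


# ---------------------------------------------------------------------------
# minimal gene set
# ---------------------------------------------------------------------------


def test_minimal_gene_set_exact_keeps_hub_and_shrinks(ld_sim):
    datasets, truth, res = ld_sim
    coding = pooled_dose_coding(datasets)
    cluster = res.clusters[0]
    result = minimal_gene_set(cluster, datasets, coding)
    assert result.method == "exact"
    assert "HUB1" in result.genes
    assert result.error <= result.baseline_error
    # planted duplicates are pure redundancy: the minimum is below the full set
    assert len(result.genes) < len(cluster.genes)


def test_minimal_gene_set_ga_matches_exact_optimum(ld_sim):
    datasets, _, res = ld_sim
    coding = pooled_dose_coding(datasets)
    cluster = res.clusters[0]
    exact = minimal_gene_set(cluster, datasets, coding)
    forced_ga = minimal_gene_set(
        cluster, datasets, coding,
        ga_config=GaConfig(exact_max=0, population=40, generations=60, seed=17),
    )
    assert forced_ga.method == "ga"
    assert forced_ga.error <= forced_ga.baseline_error  # constraint re-verified
    assert len(forced_ga.genes) == len(exact.genes)
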