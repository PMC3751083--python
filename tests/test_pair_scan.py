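"""Threshold logic, risky-set subset search, and scan/oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalpie.io import pooled_dose_coding
from causalpie.pair_scan import (
    ConfigurationError,
    ScanContext,
    best_genotype_subset,
    compute_thresholds,
    exhaustive_pair_scan,
    find_single_disease_genes,
    thresholds_for,
)

from _naive import naive_best_subset, naive_pair_scan, random_instance
from conftest import annotation_for, make_dataset_from_doses


@pytest.mark.parametrize(
    "s_ht,s_nc,c_ht,c_nc,t_ht0,t_nc0",
    [
        (305, 2881, 2.0, 0.1, 7, 3),
        (200, 184, 2.0, 0.1, 4, 1),
        (10, 10, 10.0, 0.0, 1, 0),
    ],
)
def test_ceiling_thresholds(s_ht, s_nc, c_ht, c_nc, t_ht0, t_nc0):
    th = compute_thresholds(s_ht, s_nc, c_ht, c_nc)
    assert (th.t_ht0, th.t_nc0) == (t_ht0, t_nc0)
    assert (th.t_ht, th.t_nc) == (t_ht0, t_nc0)


def test_thresholds_require_cht_above_cnc():
    with pytest.raises(ConfigurationError):
        compute_thresholds(100, 100, 0.1, 0.1)


def test_best_subset_single_cell_paper_counts():
    # a lone CC genotype carried by 4 cases and 1 control at budget 1
    cells, ht, nc = best_genotype_subset({2: 4}, {2: 1, 0: 150}, t_nc=1)
    assert cells == frozenset({2}) and (ht, nc) == (4, 1)


def test_best_subset_infeasible_budget_empty():
    cells, ht, nc = best_genotype_subset({0: 3, 1: 2}, {0: 1, 1: 1}, t_nc=0)
    assert cells == frozenset() and ht == 0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_best_subset_matches_independent_brute_force(data):
    rng_counts = data.draw(
        st.lists(st.tuples(st.integers(0, 10), st.integers(0, 6)),
                 min_size=9, max_size=9)
    )
    t_nc = data.draw(st.integers(0, 4))
    mono = data.draw(st.booleans())
    ht = {c: h for c, (h, _) in zip([(a, b) for a in range(3) for b in range(3)], rng_counts) if h}
    nc = {c: n for c, (_, n) in zip([(a, b) for a in range(3) for b in range(3)], rng_counts) if n}
    assert best_genotype_subset(ht, nc, t_nc, mono) == naive_best_subset(ht, nc, t_nc, mono)


def _context(doses_list, labels_list, c_ht=2.0, c_nc=0.1, genes=None, names=None):
    datasets = []
    for k, (doses, labels) in enumerate(zip(doses_list, labels_list)):
        name = names[k] if names else f"ds{k}"
        datasets.append(make_dataset_from_doses(doses, labels, name=name))
    snp_ids = datasets[0].snp_ids
    ann = annotation_for(snp_ids, genes or [f"G{j}" for j in range(len(snp_ids))])
    th = thresholds_for(datasets, c_ht, c_nc)
    return datasets, ScanContext.build(datasets, th, ann), th


def _single_snp_doses(n_cases, n_controls, carriers_ht, carriers_nc, dose=2):
    col = np.zeros((n_cases + n_controls, 1), dtype=int)
    col[:carriers_ht, 0] = dose
    col[n_cases: n_cases + carriers_nc, 0] = dose
    labels = np.zeros(n_cases + n_controls, dtype=bool)
    labels[:n_cases] = True
    return col, labels


def test_single_gene_requires_every_training_dataset():
    """A SNP passing the Taiwan-like counts (4/200 cases, 1/184 controls)
    but only 3/305 cases in the larger cohort is not a single disease
    gene under multi-dataset qualification."""
    d_tw, l_tw = _single_snp_doses(200, 184, carriers_ht=4, carriers_nc=1)
    d_us, l_us = _single_snp_doses(305, 2881, carriers_ht=3, carriers_nc=0)
    # Taiwan alone qualifies
    _, ctx_tw, _ = _context([d_tw], [l_tw])
    assert [r.snp_id for r in find_single_disease_genes(ctx_tw)] == ["rs0001"]
    # both training datasets together do not (3 < t_HT=7 in the large cohort)
    _, ctx_both, _ = _context([d_tw, d_us], [l_tw, l_us])
    assert find_single_disease_genes(ctx_both) == []


def test_monomorphic_snp_never_single_gene():
    doses = np.zeros((50, 1), dtype=int)
    labels = np.zeros(50, dtype=bool)
    labels[:20] = True
    _, ctx, _ = _context([doses], [labels], c_ht=5.0, c_nc=1.0)
    assert find_single_disease_genes(ctx) == []


@pytest.mark.parametrize("dose_monotone", [False, True])
@pytest.mark.parametrize("n_datasets", [1, 2])
def test_scan_equals_naive_reference(dose_monotone, n_datasets):
    """The vectorized exhaustive scan is set-identical to the per-pair
    naive reference, including chosen genotype subsets and carrier sets."""
    rng = np.random.default_rng(1234 + n_datasets)
    for rep in range(10):
        n_snps = int(rng.integers(8, 26))
        doses_list, labels_list = [], []
        for _ in range(n_datasets):
            n_subj = int(rng.integers(60, 160))
            n_cases = int(rng.integers(20, n_subj - 20))
            d, l = random_instance(rng, n_snps, n_subj, n_cases)
            doses_list.append(d)
            labels_list.append(l)
        c_ht = float(rng.uniform(2.0, 8.0))
        c_nc = float(rng.uniform(0.1, 2.0))
        datasets, ctx, th = _context(doses_list, labels_list, c_ht, c_nc)
        coding = pooled_dose_coding(datasets)
        got = exhaustive_pair_scan(ctx, dose_monotone=dose_monotone)
        want = naive_pair_scan(datasets, th, coding, dose_monotone=dose_monotone)
        assert {p.key for p in got} == set(want)
        for p in got:
            for name, ev in p.per_dataset:
                cells, ht_ids, nc_ids = want[p.key][name]
                assert ev.genotype_set == cells, (p.key, name)
                assert ev.ht_carriers == ht_ids
                assert ev.nc_carriers == nc_ids


def test_scan_excludes_pairs_with_single_disease_snp():
    rng = np.random.default_rng(5)
    doses, labels = random_instance(rng, 10, 120, 40, missing_rate=0.0)
    # make rs0001 a blatant single disease gene and rs0002 its perfect partner
    doses[:, 0] = 0
    doses[:6, 0] = 2
    doses[:, 1] = 0
    doses[:6, 1] = 2
    datasets, ctx, th = _context([doses], [labels], c_ht=5.0, c_nc=0.5)
    singles = {s.snp_id for s in find_single_disease_genes(ctx)}
    assert "rs0001" in singles
    pairs = exhaustive_pair_scan(ctx, excluded_snps=singles)
    assert all("rs0001" not in p.key and "rs0002" not in p.key for p in pairs)


def test_scan_monotone_in_threshold_relaxation():
    rng = np.random.default_rng(9)
    doses, labels = random_instance(rng, 15, 150, 50)
    datasets, ctx, th = _context([doses], [labels], c_ht=4.0, c_nc=0.5)
    strict = {p.key for p in exhaustive_pair_scan(ctx)}
    relaxed_th = {k: v.relaxed(1) for k, v in th.items()}
    relaxed = {
        p.key for p in exhaustive_pair_scan(ctx.with_thresholds(relaxed_th))
    }
    assert strict <= relaxed


def test_all_missing_genotypes_yield_no_pairs():
    doses = np.full((80, 6), -1, dtype=int)
    labels = np.zeros(80, dtype=bool)
    labels[:30] = True
    datasets, ctx, _ = _context([doses], [labels], c_ht=2.0, c_nc=0.1)
    assert exhaustive_pair_scan(ctx) == []
    assert find_single_disease_genes(ctx) == []


def test_reported_pairs_reverify_carrier_invariants(default_result, default_sim):
    datasets, _, _ = default_sim
    th = default_result.thresholds
    coding = pooled_dose_coding(datasets)
    from causalpie.io import dose_matrix

    doses = {ds.name: dose_matrix(ds, coding) for ds in datasets}
    for p in default_result.stringent_pairs[:40]:
        for ds in datasets:
            ev = p.evidence[ds.name]
            dm = doses[ds.name]
            ja = ds.snp_ids.index(p.snp_a)
            jb = ds.snp_ids.index(p.snp_b)
            ht, nc = set(), set()
            for i, sid in enumerate(ds.subject_ids):
                if (dm[i, ja], dm[i, jb]) in ev.genotype_set:
                    (ht if ds.labels[i] else nc).add(sid)
            assert frozenset(ht) == ev.ht_carriers
            assert frozenset(nc) == ev.nc_carriers
            assert len(ht) >= th[ds.name].t_ht
            assert len(nc) <= th[ds.name].t_nc
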