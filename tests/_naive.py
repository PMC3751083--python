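"""Independent naive reference for the risky-set criteria.

Deliberately written without touching the package's scan machinery beyond
the dose recode: per SNP pair, tally the 9 joint genotype cells by looping
over subjects, then enumerate every nonempty cell subset by bitmask and
keep the feasible one maximizing case carriers (ties: fewer cells, then
lexicographically smallest cell tuple).  Used as the oracle that the
vectorized exhaustive scan must reproduce exactly.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations

import numpy as np

from causalpie.io import GenotypeDataset, dose_matrix

CELLS = [(a, b) for a in range(3) for b in range(3)]


def naive_best_subset(ht_counts, nc_counts, t_nc, dose_monotone=False):
    cells = sorted(set(ht_counts) | set(nc_counts))
    best = (frozenset(), 0, 0)
    best_key = None
    for size in range(1, len(cells) + 1):
        for combo in combinations(cells, size):
            if dose_monotone:
                ok = True
                for c in combo:
                    for d in cells:
                        dom = (
                            all(x >= y for x, y in zip(d, c))
                            if isinstance(c, tuple)
                            else d >= c
                        )
                        if dom and d not in combo:
                            ok = False
                if not ok:
                    continue
            nc_tot = sum(nc_counts.get(c, 0) for c in combo)
            if nc_tot > t_nc:
                continue
            ht_tot = sum(ht_counts.get(c, 0) for c in combo)
            key = (-ht_tot, size, combo)
            if best_key is None or key < best_key:
                best_key = key
                best = (frozenset(combo), ht_tot, nc_tot)
    return best if best[1] > 0 else (frozenset(), 0, 0)


def naive_pair_scan(
    datasets: list[GenotypeDataset],
    thresholds: dict,
    coding,
    excluded: set[str] = frozenset(),
    dose_monotone: bool = False,
):
    """All qualifying pairs as {(snp_a, snp_b): {ds: (cells, ht_ids, nc_ids)}}."""
    common = [
        s
        for s in datasets[0].snp_ids
        if all(s in ds.snp_ids for ds in datasets)
        and s not in coding.conflicts
        and s not in excluded
    ]
    doses = {ds.name: dose_matrix(ds, coding) for ds in datasets}
    out = {}
    for ai, snp_a in enumerate(common):
        for snp_b in common[ai + 1:]:
            a_key, b_key = sorted((snp_a, snp_b))
            per_ds = {}
            ok = True
            for ds in datasets:
                th = thresholds[ds.name]
                dm = doses[ds.name]
                ja = ds.snp_ids.index(a_key)
                jb = ds.snp_ids.index(b_key)
                ht_counts: Counter = Counter()
                nc_counts: Counter = Counter()
                for i in range(ds.n_subjects):
                    da, db = int(dm[i, ja]), int(dm[i, jb])
                    if da < 0 or db < 0:
                        continue
                    if ds.labels[i]:
                        ht_counts[(da, db)] += 1
                    else:
                        nc_counts[(da, db)] += 1
                cells, ht_tot, _ = naive_best_subset(
                    dict(ht_counts), dict(nc_counts), th.t_nc, dose_monotone
                )
                if ht_tot < th.t_ht or not cells:
                    ok = False
                    break
                ht_ids, nc_ids = set(), set()
                for i in range(ds.n_subjects):
                    da, db = int(dm[i, ja]), int(dm[i, jb])
                    if (da, db) in cells:
                        (ht_ids if ds.labels[i] else nc_ids).add(ds.subject_ids[i])
                per_ds[ds.name] = (cells, frozenset(ht_ids), frozenset(nc_ids))
            if ok:
                out[(a_key, b_key)] = per_ds
    return out


def random_instance(rng: np.random.Generator, n_snps, n_subjects, n_cases,
                    missing_rate=0.02, name="rnd"):
    """A random genotype dataset in dose space (valid pooled minor coding)."""
    doses = np.zeros((n_subjects, n_snps), dtype=int)
    for j in range(n_snps):
        q = rng.uniform(0.05, 0.45)
        doses[:, j] = rng.binomial(2, q, size=n_subjects)
    miss = rng.random(doses.shape) < missing_rate
    doses[miss] = -1
    labels = np.zeros(n_subjects, dtype=bool)
    labels[:n_cases] = True
    return doses, labels
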