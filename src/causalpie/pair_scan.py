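"""Exhaustive detection of risky genotype sets and risky combinatory sets.

A *risky genotype set* of one SNP is a set of genotypes carried by at least
C_HT% of cases and at most C_NC% of controls; a *risky combinatory genotype
set* of a SNP pair is the same criterion applied to the 9 joint genotype
cells.  Percentages are turned into integer carrier thresholds with the
ceiling rule t = ceil(S * C%), applied per dataset.  A SNP (pair) qualifies
only if it passes in *every* training dataset.

The genotype subset attached to a qualifying SNP (pair) is the subset of
genotype cells maximizing total case carriers subject to the control budget,
found by exact enumeration of all nonempty subsets (at most 2^9 - 1 = 511).
Genotype classes are disjoint, so subset totals are sums of cell counts, and
a subject with a missing genotype at either SNP is never a carrier.

The pairwise scan is vectorized (one-hot dose matrices and BLAS products
yield all 9 joint cell counts for every pair at once; a cell-feasibility
upper bound prunes pairs before the exact subset step) but is required to be
set-identical to a naive per-pair reference — the test suite enforces this.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from fractions import Fraction
from math import ceil
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .io import DoseCoding, GenotypeDataset, SnpAnnotation, dose_matrix, pooled_dose_coding


class ConfigurationError(ValueError):
    """Inconsistent scan configuration (e.g. C_HT <= C_NC)."""


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Thresholds:
    """Integer carrier thresholds for one dataset.

    ``t_ht0``/``t_nc0`` are the stringent (stage-1) values fixed by the
    ceiling rule; ``t_ht``/``t_nc`` are the current, possibly relaxed values
    used during cluster growth.
    """

    c_ht: float
    c_nc: float
    s_ht: int
    s_nc: int
    t_ht0: int
    t_nc0: int
    t_ht: int
    t_nc: int

    def relaxed(self, steps: int) -> "Thresholds":
        """Thresholds after ``steps`` rounds of t_HT -= 1, t_NC += 1."""
        return replace(self, t_ht=self.t_ht0 - steps, t_nc=self.t_nc0 + steps)


def _ceil_pct(count: int, pct: float) -> int:
    # exact ceiling of count * pct / 100 without float round-off
    return int(ceil(Fraction(count) * Fraction(str(pct)) / 100))


def compute_thresholds(s_ht: int, s_nc: int, c_ht: float, c_nc: float) -> Thresholds:
    if s_ht < 1 or s_nc < 1:
        raise ConfigurationError("need at least one case and one control")
    if not c_ht > c_nc >= 0:
        raise ConfigurationError(f"require C_HT > C_NC >= 0, got {c_ht}, {c_nc}")
    t_ht0 = _ceil_pct(s_ht, c_ht)
    t_nc0 = _ceil_pct(s_nc, c_nc)
    return Thresholds(c_ht, c_nc, s_ht, s_nc, t_ht0, t_nc0, t_ht0, t_nc0)


def thresholds_for(datasets: Sequence[GenotypeDataset], c_ht: float,
                   c_nc: float) -> dict[str, Thresholds]:
    return {
        ds.name: compute_thresholds(ds.n_cases, ds.n_controls, c_ht, c_nc)
        for ds in datasets
    }


# ---------------------------------------------------------------------------
# Best genotype subset under the control budget
# ---------------------------------------------------------------------------


def _is_upper_set(cells: tuple, all_cells: Sequence) -> bool:
    # upper set of the allele-dose lattice (componentwise >=)
    def geq(x, y):
        if isinstance(x, tuple):
            return all(a >= b for a, b in zip(x, y))
        return x >= y

    chosen = set(cells)
    for c in cells:
        for d in all_cells:
            if geq(d, c) and d not in chosen:
                return False
    return True


def best_genotype_subset(
    ht_counts: Mapping[Hashable, int],
    nc_counts: Mapping[Hashable, int],
    t_nc: int,
    dose_monotone: bool = False,
) -> tuple[frozenset, int, int]:
    """Exact search over genotype-cell subsets.

    Returns ``(cells, ht_total, nc_total)`` maximizing the case carrier total
    subject to control carriers <= ``t_nc``.  Ties prefer fewer genotypes,
    then the lexicographically smallest dose-coded cell tuple.  An empty
    feasible set yields ``(frozenset(), 0, 0)``.

    With ``dose_monotone=True`` candidate subsets are restricted to upper
    sets of the dose lattice (the "disease allele" framing).
    """
    cells = sorted(set(ht_counts) | set(nc_counts))
    best: tuple[frozenset, int, int] = (frozenset(), 0, 0)
    best_ht = -1
    for size in range(1, len(cells) + 1):
        for combo in itertools.combinations(cells, size):
            if dose_monotone and not _is_upper_set(combo, cells):
                continue
            nc_tot = sum(nc_counts.get(c, 0) for c in combo)
            if nc_tot > t_nc:
                continue
            ht_tot = sum(ht_counts.get(c, 0) for c in combo)
            if ht_tot > best_ht:
                best_ht = ht_tot
                best = (frozenset(combo), ht_tot, nc_tot)
    if best_ht <= 0:
        return (frozenset(), 0, 0)
    return best


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Evidence:
    """Per-dataset qualification record for one SNP or SNP pair."""

    genotype_set: frozenset
    ht_carriers: frozenset
    nc_carriers: frozenset

    @property
    def ht_count(self) -> int:
        return len(self.ht_carriers)

    @property
    def nc_count(self) -> int:
        return len(self.nc_carriers)


@dataclass(frozen=True)
class RiskyGenotypeSet:
    snp_id: str
    gene: str | None
    per_dataset: tuple[tuple[str, Evidence], ...]

    @property
    def evidence(self) -> dict[str, Evidence]:
        return dict(self.per_dataset)

    @property
    def genotype_set(self) -> frozenset:
        out: frozenset = frozenset()
        for _, ev in self.per_dataset:
            out = out | ev.genotype_set
        return out


@dataclass(frozen=True)
class RiskyPair:
    """A SNP pair with a qualifying risky combinatory genotype set.

    ``snp_a`` < ``snp_b`` lexicographically.  ``per_dataset`` records the
    optimal combinatory genotype subset and the identified case/control
    subjects for each training dataset; the canonical ``combo_set`` (used
    for carriage on any platform) is the union across datasets.
    """

    snp_a: str
    snp_b: str
    gene_a: str | None
    gene_b: str | None
    per_dataset: tuple[tuple[str, Evidence], ...]

    @property
    def key(self) -> tuple[str, str]:
        return (self.snp_a, self.snp_b)

    @property
    def gene_pair(self) -> tuple[str | None, str | None]:
        return (self.gene_a, self.gene_b)

    @property
    def genes(self) -> set[str]:
        return {g for g in (self.gene_a, self.gene_b) if g is not None}

    @property
    def evidence(self) -> dict[str, Evidence]:
        return dict(self.per_dataset)

    @property
    def combo_set(self) -> frozenset:
        out: frozenset = frozenset()
        for _, ev in self.per_dataset:
            out = out | ev.genotype_set
        return out

    @property
    def ht_carriers(self) -> frozenset:
        """Cases identified in any training dataset (pooled)."""
        out: frozenset = frozenset()
        for _, ev in self.per_dataset:
            out = out | ev.ht_carriers
        return out

    @property
    def nc_carriers(self) -> frozenset:
        out: frozenset = frozenset()
        for _, ev in self.per_dataset:
            out = out | ev.nc_carriers
        return out

    def partner_of(self, hub_gene: str) -> str:
        """The member SNP not annotated to ``hub_gene``."""
        if self.gene_a == hub_gene and self.gene_b != hub_gene:
            return self.snp_b
        if self.gene_b == hub_gene and self.gene_a != hub_gene:
            return self.snp_a
        return self.snp_b  # intra-hub pair: second SNP by convention

    def hub_snp_of(self, hub_gene: str) -> str:
        return self.snp_a if self.partner_of(hub_gene) == self.snp_b else self.snp_b


# ---------------------------------------------------------------------------
# Precomputed scan context
# ---------------------------------------------------------------------------


@dataclass
class ScanContext:
    """Dose matrices and one-hot class indicators shared by all scans."""

    datasets: list[GenotypeDataset]
    thresholds: dict[str, Thresholds]
    coding: DoseCoding
    snp_ids: list[str]  # common, conflict-free SNP universe (order of 1st dataset)
    annotation: SnpAnnotation | None = None
    _dose: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _onehot: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict, repr=False)
    _counts: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict, repr=False)

    @classmethod
    def build(
        cls,
        datasets: Sequence[GenotypeDataset],
        thresholds: Mapping[str, Thresholds],
        annotation: SnpAnnotation | None = None,
        coding: DoseCoding | None = None,
    ) -> "ScanContext":
        datasets = list(datasets)
        if coding is None:
            coding = pooled_dose_coding(datasets)
        panels = [set(ds.snp_ids) for ds in datasets]
        common = [
            s
            for s in datasets[0].snp_ids
            if all(s in p for p in panels) and s not in coding.conflicts
        ]
        ctx = cls(datasets, dict(thresholds), coding, common, annotation)
        for ds in datasets:
            col = [ds.snp_ids.index(s) for s in common]
            dose = dose_matrix(ds, coding)[:, col]
            ctx._dose[ds.name] = dose
            case = np.stack(
                [(dose[ds.labels] == g) for g in range(3)]
            ).astype(np.float32)
            ctl = np.stack(
                [(dose[~ds.labels] == g) for g in range(3)]
            ).astype(np.float32)
            ctx._onehot[ds.name] = (case, ctl)
        return ctx

    def dose(self, name: str) -> np.ndarray:
        return self._dose[name]

    def with_thresholds(self, thresholds: Mapping[str, Thresholds]) -> "ScanContext":
        """Shallow copy sharing dose caches but with different thresholds."""
        new = ScanContext(self.datasets, dict(thresholds), self.coding,
                          self.snp_ids, self.annotation)
        new._dose = self._dose
        new._onehot = self._onehot
        new._counts = self._counts
        return new

    def cell_counts(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Joint genotype cell counts for all SNP pairs, computed once.

        Returns (case, control) arrays of shape (9, S, S) where cell
        a*3+b counts subjects with dose a at the row SNP and dose b at
        the column SNP.  Thresholds play no role here, so the cache is
        shared by the stringent scan and every growth round.
        """
        if name not in self._counts:
            case_oh, ctl_oh = self._onehot[name]
            s = len(self.snp_ids)
            ht = np.empty((9, s, s), dtype=np.int32)
            nc = np.empty((9, s, s), dtype=np.int32)
            for a in range(3):
                for b in range(3):
                    cell = a * 3 + b
                    ht[cell] = np.rint(case_oh[a].T @ case_oh[b]).astype(np.int32)
                    nc[cell] = np.rint(ctl_oh[a].T @ ctl_oh[b]).astype(np.int32)
            self._counts[name] = (ht, nc)
        return self._counts[name]

    def gene_of(self, snp: str) -> str | None:
        return self.annotation.gene_of(snp) if self.annotation is not None else None

    # -- single-pair helpers -------------------------------------------------

    def pair_cell_counts(self, ds: GenotypeDataset, i: int, j: int) -> tuple[dict, dict]:
        """9-cell joint genotype counts (cases, controls) for SNP indices i, j."""
        dose = self._dose[ds.name]
        da, db = dose[:, i], dose[:, j]
        ht: dict[tuple[int, int], int] = {}
        nc: dict[tuple[int, int], int] = {}
        valid = (da >= 0) & (db >= 0)
        for a in range(3):
            for b in range(3):
                mask = valid & (da == a) & (db == b)
                ht_n = int((mask & ds.labels).sum())
                nc_n = int((mask & ~ds.labels).sum())
                if ht_n:
                    ht[(a, b)] = ht_n
                if nc_n:
                    nc[(a, b)] = nc_n
        return ht, nc

    def pair_carriers(
        self, ds: GenotypeDataset, i: int, j: int, combo: frozenset
    ) -> tuple[frozenset, frozenset]:
        dose = self._dose[ds.name]
        da, db = dose[:, i], dose[:, j]
        mask = np.zeros(ds.n_subjects, dtype=bool)
        for a, b in combo:
            mask |= (da == a) & (db == b)
        ids = np.array(ds.subject_ids, dtype=object)
        return (
            frozenset(ids[mask & ds.labels].tolist()),
            frozenset(ids[mask & ~ds.labels].tolist()),
        )

    def snp_carriers(
        self, ds: GenotypeDataset, i: int, genos: frozenset
    ) -> tuple[frozenset, frozenset]:
        dose = self._dose[ds.name]
        mask = np.isin(dose[:, i], list(genos))
        ids = np.array(ds.subject_ids, dtype=object)
        return (
            frozenset(ids[mask & ds.labels].tolist()),
            frozenset(ids[mask & ~ds.labels].tolist()),
        )


# ---------------------------------------------------------------------------
# Single disease genes
# ---------------------------------------------------------------------------


def find_single_disease_genes(
    ctx: ScanContext, dose_monotone: bool = False
) -> list[RiskyGenotypeSet]:
    """SNPs whose own genotypes form a risky set in every training dataset."""
    out: list[RiskyGenotypeSet] = []
    for i, snp in enumerate(ctx.snp_ids):
        per_ds: list[tuple[str, Evidence]] = []
        ok = True
        for ds in ctx.datasets:
            th = ctx.thresholds[ds.name]
            dose = ctx.dose(ds.name)[:, i]
            ht_counts: dict[int, int] = {}
            nc_counts: dict[int, int] = {}
            for g in range(3):
                m = dose == g
                h = int((m & ds.labels).sum())
                n = int((m & ~ds.labels).sum())
                if h:
                    ht_counts[g] = h
                if n:
                    nc_counts[g] = n
            genos, ht_tot, _ = best_genotype_subset(
                ht_counts, nc_counts, th.t_nc, dose_monotone
            )
            if ht_tot < th.t_ht or not genos:
                ok = False
                break
            ht_ids, nc_ids = ctx.snp_carriers(ds, i, genos)
            per_ds.append((ds.name, Evidence(genos, ht_ids, nc_ids)))
        if ok:
            out.append(RiskyGenotypeSet(snp, ctx.gene_of(snp), tuple(per_ds)))
    return out


# ---------------------------------------------------------------------------
# Exhaustive pair scan
# ---------------------------------------------------------------------------

_CELLS = [(a, b) for a in range(3) for b in range(3)]


def _subset_tables() -> tuple[np.ndarray, np.ndarray, list[frozenset]]:
    """All 511 nonempty cell subsets, ranked by (size, lexicographic cells).

    Returns the membership matrix (in rank order), the "upward closure
    minus self" matrix (cells dominating a member but outside the subset —
    if any of those is observed, the subset is not an upper set of the
    observed cells), and the cell sets.  Picking the feasible subset with
    maximal case total and minimal rank reproduces the tie-break of
    :func:`best_genotype_subset` exactly.
    """
    subsets = []
    for size in range(1, 10):
        for combo in itertools.combinations(range(9), size):
            subsets.append(combo)
    member = np.zeros((len(subsets), 9), dtype=np.int32)
    updiff = np.zeros((len(subsets), 9), dtype=np.int32)
    cells: list[frozenset] = []
    for r, combo in enumerate(subsets):
        member[r, list(combo)] = 1
        cell_set = frozenset(_CELLS[c] for c in combo)
        cells.append(cell_set)
        for c, (a, b) in enumerate(_CELLS):
            dominates = any(a >= sa and b >= sb for sa, sb in cell_set)
            if dominates and (a, b) not in cell_set:
                updiff[r, c] = 1
    return member, updiff, cells


_SUBSETS, _SUBSETS_UPDIFF, _SUBSET_CELLS = _subset_tables()


def exhaustive_pair_scan(
    ctx: ScanContext,
    excluded_snps: Iterable[str] = (),
    hub_snps: Iterable[str] | None = None,
    dose_monotone: bool = False,
    skip_pairs: Iterable[tuple[str, str]] = (),
    chunk: int = 512,
) -> list[RiskyPair]:
    """All SNP pairs with a risky combinatory genotype set in every dataset.

    ``excluded_snps`` are SNPs that are single disease genes (a disease gene
    pair must not contain one).  If ``hub_snps`` is given, only pairs with at
    least one member in it are scanned (used during cluster growth).
    ``skip_pairs`` suppresses pairs already known (existing cluster members).
    """
    excluded = set(excluded_snps)
    skip = {tuple(sorted(p)) for p in skip_pairs}
    snps = ctx.snp_ids
    idx = {s: k for k, s in enumerate(snps)}
    active = [k for k, s in enumerate(snps) if s not in excluded]
    if hub_snps is not None:
        rows = [idx[s] for s in hub_snps if s in idx and s not in excluded]
    else:
        rows = active
    if not rows or not active:
        return []
    rows_arr = np.array(sorted(rows))
    cols_arr = np.array(sorted(active))

    # Candidate mask via per-dataset feasibility bound, AND-ed across datasets.
    n_all = len(snps)
    identity = len(rows_arr) == n_all and len(cols_arr) == n_all
    cand = np.ones((len(rows_arr), len(cols_arr)), dtype=bool)
    counts_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ds in ctx.datasets:
        th = ctx.thresholds[ds.name]
        ht_full, nc_full = ctx.cell_counts(ds.name)
        if identity:
            ht, nc = ht_full, nc_full
        else:
            ht = ht_full[:, rows_arr[:, None], cols_arr[None, :]]
            nc = nc_full[:, rows_arr[:, None], cols_arr[None, :]]
        feasible = nc <= th.t_nc
        bound = np.where(feasible, ht, 0).sum(axis=0)
        cand &= bound >= th.t_ht
        counts_cache[ds.name] = (ht, nc)

    # keep i < j in global SNP index; drop explicit skips
    ri, ci = np.nonzero(cand)
    gi = rows_arr[ri]
    gj = cols_arr[ci]
    order = gi < gj
    cand_pairs = list(zip(gi[order].tolist(), gj[order].tolist(),
                          ri[order].tolist(), ci[order].tolist()))
    if hub_snps is not None:
        # a pair of two hub SNPs appears twice (once per orientation); dedup
        seen: set[tuple[int, int]] = set()
        uniq = []
        for g_i, g_j, r, c in cand_pairs:
            if (g_i, g_j) in seen:
                continue
            seen.add((g_i, g_j))
            uniq.append((g_i, g_j, r, c))
        cand_pairs = uniq
        # hub-vs-hub pairs where the smaller index is only in cols: recover
        hubset = set(rows_arr.tolist())
        extra = []
        for g_i, g_j, r, c in zip(gi[~order].tolist(), gj[~order].tolist(),
                                  ri[~order].tolist(), ci[~order].tolist()):
            if g_j not in hubset and (g_j, g_i) not in seen:
                seen.add((g_j, g_i))
                extra.append((g_j, g_i, r, c))
        cand_pairs.extend(extra)

    # Exact subset optimum per candidate, vectorized per dataset.  The
    # score encodes the enumeration tie-break of best_genotype_subset:
    # maximize case total, then minimize subset rank (size, lexicographic);
    # subsets touching unobserved cells are excluded to match it exactly.
    if not cand_pairs:
        return []
    ncand = len(cand_pairs)
    qual = np.ones(ncand, dtype=bool)
    r_sel = np.array([p[2] for p in cand_pairs])
    c_sel = np.array([p[3] for p in cand_pairs])
    rank_bonus = (510 - np.arange(_SUBSETS.shape[0])).astype(np.int64)
    choice: dict[str, np.ndarray] = {}
    for ds in ctx.datasets:
        th = ctx.thresholds[ds.name]
        ht9, nc9 = counts_cache[ds.name]
        H = ht9[:, r_sel, c_sel].T.astype(np.int64)  # (ncand, 9)
        N = nc9[:, r_sel, c_sel].T.astype(np.int64)
        best_h = np.full(ncand, -1, dtype=np.int64)
        best_idx = np.zeros(ncand, dtype=np.int64)
        for lo in range(0, ncand, chunk * 8):
            hi = min(lo + chunk * 8, ncand)
            tot_h = H[lo:hi] @ _SUBSETS.T.astype(np.int64)
            tot_n = N[lo:hi] @ _SUBSETS.T.astype(np.int64)
            ok = tot_n <= th.t_nc
            absent = (H[lo:hi] == 0) & (N[lo:hi] == 0)
            ok &= (absent @ _SUBSETS.T) == 0
            if dose_monotone:
                # upper set w.r.t. the observed cells: no observed cell may
                # dominate a member from outside the subset
                ok &= ((~absent).astype(np.int64) @ _SUBSETS_UPDIFF.T.astype(np.int64)) == 0
            score = np.where(ok, tot_h * 512 + rank_bonus[None, :], -1)
            bi = score.argmax(axis=1)
            rows = np.arange(hi - lo)
            feas = score[rows, bi] >= 0
            best_idx[lo:hi] = bi
            best_h[lo:hi] = np.where(feas, tot_h[rows, bi], -1)
        qual &= best_h >= max(th.t_ht, 1)
        choice[ds.name] = best_idx

    out: list[RiskyPair] = []
    for k in np.nonzero(qual)[0].tolist():
        g_i, g_j, r, c = cand_pairs[k]
        snp_a, snp_b = sorted((snps[g_i], snps[g_j]))
        if (snp_a, snp_b) in skip:
            continue
        ia, ib = idx[snp_a], idx[snp_b]
        flipped = (snps[g_i], snps[g_j]) != (snp_a, snp_b)
        per_ds: list[tuple[str, Evidence]] = []
        for ds in ctx.datasets:
            if not flipped:
                cells = _SUBSET_CELLS[choice[ds.name][k]]
            else:
                # counts were tallied in (g_i, g_j) orientation; redo the
                # tie-break in canonical orientation so results match the
                # naive reference exactly
                ht9, nc9 = counts_cache[ds.name]
                ht_counts = {
                    (cell % 3, cell // 3): int(ht9[cell, r, c])
                    for cell in range(9)
                    if ht9[cell, r, c]
                }
                nc_counts = {
                    (cell % 3, cell // 3): int(nc9[cell, r, c])
                    for cell in range(9)
                    if nc9[cell, r, c]
                }
                cells, _, _ = best_genotype_subset(
                    ht_counts, nc_counts, ctx.thresholds[ds.name].t_nc, dose_monotone
                )
            ht_ids, nc_ids = ctx.pair_carriers(ds, ia, ib, cells)
            per_ds.append((ds.name, Evidence(cells, ht_ids, nc_ids)))
        out.append(
            RiskyPair(snp_a, snp_b, ctx.gene_of(snp_a), ctx.gene_of(snp_b), tuple(per_ds))
        )
    out.sort(key=lambda p: p.key)
    return out
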