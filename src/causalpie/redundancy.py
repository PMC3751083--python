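"""Redundancy reduction within gene clusters.

Two mechanisms make a cluster larger than its causal content: linkage
disequilibrium between partner SNPs (two member pairs that are the same
signal seen through correlated markers) and genes whose pairs never change
the cluster's classification.  ``ld_reduce`` collapses members whose
partner SNPs are in strong LD (D' >= 0.9 by default), keeping the member
with the larger case carrier count; ``minimal_gene_set`` searches for the
smallest set of partner genes that preserves the cluster's training
classification error, exactly for small clusters and with a genetic
algorithm for large ones.

D' is estimated from unphased genotypes by the standard two-locus EM: the
double heterozygote is split between the coupling and repulsion diplotypes
in proportion to the current haplotype-frequency products; everything else
contributes haplotypes unambiguously.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifier import CarriageProfile, fit_cutoffs
from .cluster import GeneCluster
from .io import DoseCoding, GenotypeDataset, dose_matrix


@dataclass(frozen=True)
class LdEstimate:
    snp_a: str
    snp_b: str
    d_prime: float
    hap_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab), A/B = minor
    converged: bool
    defined: bool  # False when either SNP is monomorphic among used subjects


def estimate_dprime(
    data: GenotypeDataset,
    snp_a: str,
    snp_b: str,
    coding: DoseCoding,
    controls_only: bool = False,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> LdEstimate:
    """EM estimate of two-locus haplotype frequencies and D'.

    Subjects missing either genotype are excluded.  With
    ``controls_only=True`` only control subjects enter the estimate
    (controls approximate population LD).
    """
    dm = dose_matrix(data, coding)
    ia, ib = data.snp_ids.index(snp_a), data.snp_ids.index(snp_b)
    da, db = dm[:, ia].astype(int), dm[:, ib].astype(int)
    use = (da >= 0) & (db >= 0)
    if controls_only:
        use &= ~data.labels
    da, db = da[use], db[use]
    n = np.zeros((3, 3), dtype=float)
    for i in range(3):
        for j in range(3):
            n[i, j] = np.sum((da == i) & (db == j))
    total = n.sum()
    if total == 0:
        return LdEstimate(snp_a, snp_b, float("nan"), (0, 0, 0, 0), False, False)
    p_a = (2 * n[2].sum() + n[1].sum()) / (2 * total)
    p_b = (2 * n[:, 2].sum() + n[:, 1].sum()) / (2 * total)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LdEstimate(snp_a, snp_b, float("nan"), (0, 0, 0, 0), False, False)

    # haplotype freqs (AB, Ab, aB, ab); start from linkage equilibrium
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    converged = False
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        x = 0.5 if denom == 0 else f[0] * f[3] / denom
        n_ab = 2 * n[2, 2] + n[2, 1] + n[1, 2] + n[1, 1] * x
        n_aB = 2 * n[2, 0] + n[2, 1] + n[1, 0] + n[1, 1] * (1 - x)
        n_bA = 2 * n[0, 2] + n[1, 2] + n[0, 1] + n[1, 1] * (1 - x)
        n_00 = 2 * n[0, 0] + n[0, 1] + n[1, 0] + n[1, 1] * x
        new = np.array([n_ab, n_aB, n_bA, n_00]) / (2 * total)
        if np.max(np.abs(new - f)) < tol:
            f = new
            converged = True
            break
        f = new
    d = f[0] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    return LdEstimate(snp_a, snp_b, float(min(d_prime, 1.0)), tuple(f.tolist()),
                      converged, True)


# ---------------------------------------------------------------------------
# LD-based member reduction
# ---------------------------------------------------------------------------


def ld_reduce(
    cluster: GeneCluster,
    data: GenotypeDataset,
    coding: DoseCoding,
    threshold: float = 0.9,
    controls_only: bool = True,
) -> GeneCluster:
    """Collapse member pairs whose partner SNPs are in LD at D' >= threshold.

    Members are visited in order of decreasing pooled case carrier count
    (ties by SNP ids); a member is dropped when its partner SNP is in LD
    with an already kept member's partner SNP.  Idempotent at a fixed
    threshold.
    """
    hub = cluster.hub or ""
    order = sorted(
        range(len(cluster.members)),
        key=lambda i: (-len(cluster.members[i].ht_carriers), cluster.members[i].key),
    )
    cache: dict[tuple[str, str], float] = {}

    def dprime(sa: str, sb: str) -> float:
        key = tuple(sorted((sa, sb)))
        if sa == sb:
            return 1.0
        if key not in cache:
            est = estimate_dprime(data, key[0], key[1], coding, controls_only)
            cache[key] = est.d_prime if est.defined else 0.0
        return cache[key]

    kept_idx: list[int] = []
    kept_partners: list[str] = []
    for i in order:
        partner = cluster.members[i].partner_of(hub)
        if partner not in data.snp_ids:
            kept_idx.append(i)  # not assayable here: cannot assess LD, keep
            continue
        in_ld = any(
            kp in data.snp_ids and dprime(partner, kp) >= threshold
            for kp in kept_partners
        )
        if not in_ld:
            kept_idx.append(i)
            kept_partners.append(partner)
    kept_idx.sort()
    return GeneCluster(
        hub=cluster.hub,
        members=[cluster.members[i] for i in kept_idx],
        relaxation_level=cluster.relaxation_level,
        provenance=[cluster.provenance[i] for i in kept_idx],
        identification_counts=dict(cluster.identification_counts),
        mfis=cluster.mfis,
        fis=cluster.fis,
    )


# ---------------------------------------------------------------------------
# Minimal gene set preserving classification accuracy
# ---------------------------------------------------------------------------


@dataclass
class GaConfig:
    population: int = 100
    generations: int = 200
    crossover: float = 0.8
    mutation: float | None = None  # default 1 / n_genes
    tournament: int = 3
    seed: int = 17
    exact_max: int = 20  # exhaustive search up to this many partner genes


class _ClusterEvaluator:
    """Training classification error of a cluster under a member subset."""

    def __init__(
        self,
        cluster: GeneCluster,
        datasets: Sequence[GenotypeDataset],
        coding: DoseCoding,
        scenario: str = "S1",
    ) -> None:
        self.cluster = cluster
        self.scenario = scenario
        self.per_ds: list[tuple[GenotypeDataset, np.ndarray, np.ndarray]] = []
        for ds in datasets:
            snp_idx = {s: j for j, s in enumerate(ds.snp_ids)}
            dm = dose_matrix(ds, coding)
            present = np.array(
                [p.snp_a in snp_idx and p.snp_b in snp_idx for p in cluster.members]
            )
            carr = np.zeros((ds.n_subjects, len(cluster.members)), dtype=bool)
            for k, p in enumerate(cluster.members):
                if not present[k]:
                    continue
                da = dm[:, snp_idx[p.snp_a]]
                db = dm[:, snp_idx[p.snp_b]]
                hit = np.zeros(ds.n_subjects, dtype=bool)
                for a, b in p.combo_set:
                    hit |= (da == a) & (db == b)
                carr[:, k] = hit
            self.per_ds.append((ds, present, carr))

    def profiles(self, member_mask: np.ndarray) -> list[CarriageProfile]:
        out: list[CarriageProfile] = []
        for ds, present, carr in self.per_ds:
            sel = member_mask & present
            measurable = int(sel.sum())
            if measurable == 0:
                continue
            carried = carr[:, sel].sum(axis=1)
            for i in np.nonzero(carried)[0]:
                out.append(
                    CarriageProfile(
                        subject_id=ds.subject_ids[i],
                        cluster_hub=self.cluster.hub or "",
                        carried=int(carried[i]),
                        measurable=measurable,
                        is_case=bool(ds.labels[i]),
                        dataset=ds.name,
                        ethnic_group=ds.ethnic_group,
                        platform=ds.platform,
                    )
                )
        return out

    def error(self, member_mask: np.ndarray) -> float | None:
        """Pooled training misclassification rate; None if nothing identified."""
        profs = self.profiles(member_mask)
        if not any(p.is_case for p in profs):
            return None
        rule = fit_cutoffs(profs, self.scenario)
        errors = 0
        total = 0
        for p in profs:
            key = (p.cluster_hub, p.ethnic_group if self.scenario == "S1" else p.platform)
            cut = rule.cutoffs.get(key)
            pred = cut is not None and p.percentage >= cut
            errors += int(pred != p.is_case)
            total += 1
        return errors / total


@dataclass
class MinimalGeneSetResult:
    genes: set[str]  # includes the hub
    error: float
    baseline_error: float
    method: str  # "exact" | "ga" | "full"


def minimal_gene_set(
    cluster: GeneCluster,
    datasets: Sequence[GenotypeDataset],
    coding: DoseCoding,
    scenario: str = "S1",
    ga_config: GaConfig | None = None,
    strict: bool = False,
) -> MinimalGeneSetResult:
    """Smallest partner-gene subset whose training error is preserved.

    Feasibility: reduced-cluster error <= baseline (strict mode: ==).  The
    hub gene is always included (every member pair contains it).  Partner
    sets of at most ``exact_max`` genes are searched exhaustively smallest
    first; larger clusters use a seeded genetic algorithm (binary inclusion
    masks, tournament selection, uniform crossover, bit-flip mutation).
    Returns the full gene set if no strict subset is feasible.
    """
    cfg = ga_config or GaConfig()
    hub = cluster.hub or ""
    partner_genes = sorted(
        {g for p in cluster.members for g in p.genes if g != hub}
    )
    ev = _ClusterEvaluator(cluster, datasets, coding, scenario)
    full_mask = np.ones(len(cluster.members), dtype=bool)
    baseline = ev.error(full_mask)
    if baseline is None:
        raise ValueError("cluster identifies no case on the fitting data")

    member_gene = [
        (p.gene_a if p.gene_a != hub else p.gene_b) or hub for p in cluster.members
    ]

    def member_mask(genes: set[str]) -> np.ndarray:
        allowed = genes | {hub}
        return np.array([g in allowed for g in member_gene])

    def feasible(err: float | None) -> bool:
        if err is None:
            return False
        return err == baseline if strict else err <= baseline

    if len(partner_genes) <= cfg.exact_max:
        for k in range(0, len(partner_genes) + 1):
            for combo in itertools.combinations(partner_genes, k):
                err = ev.error(member_mask(set(combo)))
                if feasible(err):
                    return MinimalGeneSetResult(
                        genes=set(combo) | {hub}, error=err,
                        baseline_error=baseline, method="exact",
                    )
        return MinimalGeneSetResult(set(partner_genes) | {hub}, baseline, baseline, "full")

    # genetic algorithm on binary inclusion masks over partner genes
    rng = np.random.default_rng(cfg.seed)
    L = len(partner_genes)
    p_mut = cfg.mutation if cfg.mutation is not None else 1.0 / L
    pop = rng.random((cfg.population, L)) < 0.5
    pop[0] = True  # seed with the full (always feasible) mask

    def fitness(mask: np.ndarray) -> tuple[int, int]:
        genes = {partner_genes[i] for i in np.nonzero(mask)[0]}
        err = ev.error(member_mask(genes))
        return (0 if feasible(err) else 1, int(mask.sum()))

    fits = [fitness(ind) for ind in pop]
    best_i = min(range(len(pop)), key=lambda i: fits[i])
    best, best_fit = pop[best_i].copy(), fits[best_i]
    for _ in range(cfg.generations):
        new_pop = []
        for _ in range(cfg.population):
            contenders = rng.integers(0, cfg.population, cfg.tournament)
            winner = min(contenders, key=lambda i: fits[i])
            new_pop.append(pop[winner].copy())
        pop = np.array(new_pop)
        for i in range(0, cfg.population - 1, 2):
            if rng.random() < cfg.crossover:
                swap = rng.random(L) < 0.5
                a, b = pop[i].copy(), pop[i + 1].copy()
                pop[i][swap], pop[i + 1][swap] = b[swap], a[swap]
        flips = rng.random(pop.shape) < p_mut
        pop ^= flips
        fits = [fitness(ind) for ind in pop]
        gen_best = min(range(len(pop)), key=lambda i: fits[i])
        if fits[gen_best] < best_fit:
            best, best_fit = pop[gen_best].copy(), fits[gen_best]
    if best_fit[0] != 0:
        return MinimalGeneSetResult(set(partner_genes) | {hub}, baseline, baseline, "full")
    genes = {partner_genes[i] for i in np.nonzero(best)[0]}
    err = ev.error(member_mask(genes))
    return MinimalGeneSetResult(genes | {hub}, err, baseline, "ga")


@dataclass
class LdReductionReport:
    pairs_before: int
    pairs_after: int
    snps_before: int
    snps_after: int
    error_before: float | None
    error_after: float | None

    @property
    def pair_reduction_pct(self) -> float:
        if self.pairs_before == 0:
            return 0.0
        return 100.0 * (self.pairs_before - self.pairs_after) / self.pairs_before

    @property
    def snp_reduction_pct(self) -> float:
        if self.snps_before == 0:
            return 0.0
        return 100.0 * (self.snps_before - self.snps_after) / self.snps_before


def ld_reduce_with_report(
    cluster: GeneCluster,
    datasets: Sequence[GenotypeDataset],
    coding: DoseCoding,
    threshold: float = 0.9,
    scenario: str = "S1",
    controls_only: bool = True,
) -> tuple[GeneCluster, LdReductionReport]:
    """LD-reduce on the first dataset and recompute the training error.

    Reduction is reported both in member pairs and in distinct SNPs.
    """
    reduced = ld_reduce(cluster, datasets[0], coding, threshold, controls_only)
    ev_full = _ClusterEvaluator(cluster, datasets, coding, scenario)
    ev_red = _ClusterEvaluator(reduced, datasets, coding, scenario)

    def snps_of(c: GeneCluster) -> set[str]:
        return {s for p in c.members for s in (p.snp_a, p.snp_b)}

    report = LdReductionReport(
        pairs_before=len(cluster.members),
        pairs_after=len(reduced.members),
        snps_before=len(snps_of(cluster)),
        snps_after=len(snps_of(reduced)),
        error_before=ev_full.error(np.ones(len(cluster.members), dtype=bool)),
        error_after=ev_red.error(np.ones(len(reduced.members), dtype=bool)),
    )
    return reduced, report
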