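"""Three-stage construction of gene clusters resembling causal pies.

Stage 1 (cluster selection) groups the stringent-scan risky pairs by shared
gene: every gene shared by at least two pairs anchors a cluster; a pair
sharing no gene with any other pair forms a singleton, which is later grown
twice, once with each of its genes as the hub.

Stage 2 (component growth) repeatedly relaxes the thresholds one step
(t_HT -= 1, t_NC += 1), rescans pairs involving the hub gene, and admits the
newly qualifying pairs while they keep identifying the cluster's frequently
identified subjects (FIS).  Growth stops when fewer than ``stop_overlap`` of
a round's new pairs touch the current FIS (that round's pairs are
discarded), when t_HT would reach 0, or at the configured t_NC cap.

Stage 3 (component pruning) keeps clusters with at least t_HT0 FIS and
drops member pairs whose identified cases fall outside the FIS (fractional
rule by default, literal subset rule in strict mode).

The probability that a spurious cluster of k non-LD pairs identifies m fixed
subjects out of n is bounded by (m/n)^k; ``false_positive_bound`` exposes
the bound and the test suite checks it by Monte Carlo on label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import numpy as np

from .io import GenotypeDataset, SnpAnnotation
from .pair_scan import (
    RiskyPair,
    ScanContext,
    Thresholds,
    exhaustive_pair_scan,
    find_single_disease_genes,
    thresholds_for,
)


@dataclass
class BuildConfig:
    """Pipeline configuration; defaults mirror the study conditions."""

    c_ht: float = 2.0
    c_nc: float = 0.1
    stop_overlap: float = 0.5
    keep_fraction: float = 0.5
    prune_strict: bool = False
    max_nc_steps: int = 10
    dose_monotone: bool = True  # upper-set ("disease allele") risky sets
    top: int | None = None


@dataclass
class GeneCluster:
    """A hub (shared) gene, its member pairs and FIS bookkeeping."""

    hub: str | None
    members: list[RiskyPair]
    relaxation_level: int = 0
    provenance: list[dict[str, tuple[int, int]]] = field(default_factory=list)
    identification_counts: dict[str, int] = field(default_factory=dict)
    mfis: frozenset = frozenset()
    fis: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [{} for _ in self.members]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        if self.hub is not None:
            out.add(self.hub)
        for p in self.members:
            out |= p.genes
        return out

    @property
    def member_keys(self) -> set[tuple[str, str]]:
        return {p.key for p in self.members}

    def identified_cases(self) -> frozenset:
        out: frozenset = frozenset()
        for p in self.members:
            out = out | p.ht_carriers
        return out

    def refresh_counts(self, t_ht: int) -> None:
        counts: dict[str, int] = {}
        for p in self.members:
            for s in p.ht_carriers:
                counts[s] = counts.get(s, 0) + 1
        self.identification_counts = counts
        self.mfis, self.fis = compute_fis(counts, t_ht)


def compute_fis(counts: Mapping[str, int], t_ht: int) -> tuple[frozenset, frozenset]:
    """MFIS and FIS from per-subject identification counts.

    FIS = subjects identified at least ``ceil(max/4)`` times; if fewer than
    ``t_ht`` subjects qualify, the ``t_ht`` most frequently identified are
    taken instead (ties by subject id).
    """
    if not counts:
        return frozenset(), frozenset()
    mx = max(counts.values())
    mfis = frozenset(s for s, c in counts.items() if c == mx)
    thr = ceil(mx / 4)
    fis = {s for s, c in counts.items() if c >= thr}
    if len(fis) < t_ht:
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        fis = {s for s, _ in ranked[:t_ht]}
    return mfis, frozenset(fis)


# ---------------------------------------------------------------------------
# Stage 1: cluster selection
# ---------------------------------------------------------------------------


def select_clusters(pairs: Sequence[RiskyPair]) -> list[GeneCluster]:
    """Group stringent pairs by shared gene.

    Genes shared by >= 2 pairs each anchor a cluster (a pair whose two genes
    are both shared belongs to both); pairs sharing no gene become singleton
    clusters with an undecided hub (``hub=None``), to be grown twice.
    """
    by_gene: dict[str, list[RiskyPair]] = {}
    for p in pairs:
        for g in sorted(p.genes):
            by_gene.setdefault(g, []).append(p)
    shared = {g for g, ps in by_gene.items() if len(ps) >= 2}
    clusters = [
        GeneCluster(hub=g, members=sorted(by_gene[g], key=lambda p: p.key))
        for g in sorted(shared)
    ]
    for p in sorted(pairs, key=lambda p: p.key):
        if not (p.genes & shared):
            clusters.append(GeneCluster(hub=None, members=[p]))
    return clusters


# ---------------------------------------------------------------------------
# Stage 2: component growth
# ---------------------------------------------------------------------------


def _fis_t_ht(thresholds: Mapping[str, Thresholds]) -> int:
    # FIS is pooled over training cases; pad with the largest per-dataset t_HT
    return max(th.t_ht for th in thresholds.values())


def grow_cluster(
    cluster: GeneCluster,
    ctx: ScanContext,
    excluded_snps: set[str],
    stop_overlap: float = 0.5,
    max_nc_steps: int = 10,
    dose_monotone: bool = False,
    align_fraction: float = 0.5,
) -> GeneCluster:
    """Relax thresholds stepwise and admit hub-involving pairs aligned with FIS.

    A new pair is FIS-aligned when at least ``align_fraction`` of its
    identified cases lie in the current FIS; a relaxation round whose
    aligned fraction of new pairs falls below ``stop_overlap`` stops the
    growth and is discarded.
    """
    if cluster.hub is None:
        raise ValueError("singleton clusters must be assigned a hub before growth")
    if ctx.annotation is not None:
        hub_snps = set(ctx.annotation.snps_of_gene(cluster.hub))
    else:
        hub_snps = set()
    for p in cluster.members:
        hub_snps.add(p.hub_snp_of(cluster.hub))
    hub_snps &= set(ctx.snp_ids)

    members = list(cluster.members)
    provenance = [dict(d) for d in cluster.provenance]
    base = ctx.thresholds
    grown = GeneCluster(cluster.hub, members, 0, provenance)
    grown.refresh_counts(_fis_t_ht(base))

    step = 0
    while True:
        step += 1
        relaxed = {name: th.relaxed(step) for name, th in base.items()}
        if any(th.t_ht < 1 for th in relaxed.values()):
            break
        if step > max_nc_steps:
            break
        sub_ctx = ctx.with_thresholds(relaxed)
        new_pairs = exhaustive_pair_scan(
            sub_ctx,
            excluded_snps=excluded_snps,
            hub_snps=sorted(hub_snps),
            dose_monotone=dose_monotone,
            skip_pairs=grown.member_keys,
        )
        grown.relaxation_level = step
        if not new_pairs:
            continue

        def aligned(p: RiskyPair) -> bool:
            carriers = p.ht_carriers
            return bool(carriers) and len(carriers & grown.fis) / len(carriers) >= align_fraction

        overlapping = sum(1 for p in new_pairs if aligned(p))
        if overlapping / len(new_pairs) < stop_overlap:
            grown.relaxation_level = step - 1
            break  # this round's pairs identify different patients: discard
        prov = {name: (th.t_ht, th.t_nc) for name, th in relaxed.items()}
        for p in new_pairs:
            grown.members.append(p)
            grown.provenance.append(prov)
        grown.refresh_counts(_fis_t_ht(relaxed))
    return grown


# ---------------------------------------------------------------------------
# Stage 3: component pruning
# ---------------------------------------------------------------------------


def prune_cluster(
    cluster: GeneCluster,
    t_ht0: int,
    keep_fraction: float = 0.5,
    strict: bool = False,
) -> GeneCluster | None:
    """Drop discordant members; drop the cluster itself if FIS is too small.

    A member is kept when the fraction of its identified cases lying in the
    cluster FIS is >= ``keep_fraction`` (strict mode: all of them must).
    Counts and FIS are intentionally not recomputed afterwards.
    """
    if len(cluster.fis) < t_ht0:
        return None
    keep_members: list[RiskyPair] = []
    keep_prov: list[dict[str, tuple[int, int]]] = []
    for p, prov in zip(cluster.members, cluster.provenance):
        carriers = p.ht_carriers
        if not carriers:
            continue
        inside = len(carriers & cluster.fis)
        ok = (inside == len(carriers)) if strict else (inside / len(carriers) >= keep_fraction)
        if ok:
            keep_members.append(p)
            keep_prov.append(prov)
    return GeneCluster(
        hub=cluster.hub,
        members=keep_members,
        relaxation_level=cluster.relaxation_level,
        provenance=keep_prov,
        identification_counts=dict(cluster.identification_counts),
        mfis=cluster.mfis,
        fis=cluster.fis,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class BuildResult:
    """Clusters plus the intermediates each stage produced."""

    clusters: list[GeneCluster]
    stringent_pairs: list[RiskyPair]
    single_disease_snps: set[str]
    thresholds: dict[str, Thresholds]
    context: ScanContext


def run_pipeline(
    datasets: Sequence[GenotypeDataset],
    annotation: SnpAnnotation,
    config: BuildConfig | None = None,
) -> BuildResult:
    config = config or BuildConfig()
    th = thresholds_for(datasets, config.c_ht, config.c_nc)
    ctx = ScanContext.build(datasets, th, annotation)
    singles = find_single_disease_genes(ctx, config.dose_monotone)
    excluded = {s.snp_id for s in singles}
    pairs = exhaustive_pair_scan(ctx, excluded, dose_monotone=config.dose_monotone)
    selected = select_clusters(pairs)

    candidates: list[GeneCluster] = []
    for c in selected:
        if c.hub is not None:
            candidates.append(c)
        else:  # singleton: grow twice, once per gene as hub
            for g in sorted(c.members[0].genes):
                candidates.append(GeneCluster(hub=g, members=list(c.members)))

    t_ht0 = max(t.t_ht0 for t in th.values())
    finished: list[GeneCluster] = []
    for c in candidates:
        g = grow_cluster(
            c, ctx, excluded,
            stop_overlap=config.stop_overlap,
            max_nc_steps=config.max_nc_steps,
            dose_monotone=config.dose_monotone,
        )
        p = prune_cluster(g, t_ht0, config.keep_fraction, config.prune_strict)
        if p is not None and p.members:
            finished.append(p)
    finished.sort(key=lambda c: (-len(c.members), c.hub or ""))
    if config.top is not None:
        finished = finished[: config.top]
    return BuildResult(finished, pairs, excluded, th, ctx)


def build_all(
    datasets: Sequence[GenotypeDataset],
    annotation: SnpAnnotation,
    config: BuildConfig | None = None,
) -> list[GeneCluster]:
    """Run the three stages end to end; clusters ranked by member count."""
    return run_pipeline(datasets, annotation, config).clusters


# ---------------------------------------------------------------------------
# False-positive bound and cluster overlap
# ---------------------------------------------------------------------------


def false_positive_bound(k: int, m: int, n: int) -> float:
    """Upper bound (m/n)^k on the spurious-cluster probability."""
    if n < 1:
        raise ValueError("population size n must be >= 1")
    if not 0 <= m <= n:
        raise ValueError("require 0 <= m <= n")
    if k < 0:
        raise ValueError("require k >= 0")
    return (m / n) ** k


def cluster_gene_overlap(clusters: Sequence[GeneCluster]) -> np.ndarray:
    """Pairwise gene-overlap percentages (Jaccard * 100; diagonal 100)."""
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    gene_sets = [c.genes for c in clusters]
    n = len(gene_sets)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 100.0
                continue
            union = gene_sets[i] | gene_sets[j]
            inter = gene_sets[i] & gene_sets[j]
            out[i, j] = 100.0 * len(inter) / len(union) if union else 0.0
    return out
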