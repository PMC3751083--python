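"""Synthetic case-control genotype and expression data with planted pies.

The generator emulates the structure the clustering pipeline is built to
find: background SNPs drawn under Hardy-Weinberg equilibrium at uniform
MAF, plus "pies" — clusters of SNP pairs that share a hub gene and write a
risky combinatory genotype into a designated subset of cases (the pie's
target group) with a given per-pair carriage probability, and into controls
at a small leak rate.  Planted SNPs get moderate MAF so that each planted
genotype is common enough marginally to fail the single-SNP criteria in
controls but jointly rare enough to qualify as a pair: riskiness lives in
the combination, not in either SNP.

Optionally a pie carries near-perfect-LD duplicate partner SNPs (to
exercise LD reduction) and matched expression data with a mean shift on
designated genes for the pie's carriers (to exercise influential-gene
selection).  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionDataset, GenotypeDataset, SnpAnnotation

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


class SimulationConfigError(ValueError):
    pass


@dataclass
class PlantedPieSpec:
    """What to plant for one causal-pie-like cluster.

    The risky combinatory genotype of a pair is the dose-lattice upper set
    ``{(a, b): a >= combo[0], b >= combo[1]}``.  With the default
    ``combo=(1, 1)`` and MAF in 0.25-0.35 each planted genotype is common
    marginally (so no planted SNP is informative alone) while the joint
    region is carried only by the pie's targets: every non-target subject
    falling into the region by chance is moved out of it (one dose knocked
    below threshold), leaving control carriage to the leak rate — the
    case-control signature of a high-penetrance component cause.
    """

    hub_gene: str
    n_pairs: int = 10
    combo: tuple[int, int] = (1, 1)  # minimal minor-allele doses of carriers
    n_targets: int = 12
    penetrance: float = 1.0  # per-pair carriage probability among targets
    leak: float = 0.0005  # per-pair carriage probability among controls
    maf_range: tuple[float, float] = (0.25, 0.35)
    ld_duplicates: int = 0  # extra members copying an existing partner SNP
    ld_epsilon: float = 0.0  # per-subject probability a copy is resampled


@dataclass
class PlantedPie:
    """Realized planted cluster: SNP ids, targets and per-pair carriage."""

    hub_gene: str
    partner_genes: list[str]
    pairs: list[tuple[str, str]]  # (hub SNP, partner SNP)
    combo: tuple[int, int]
    target_ids: list[str]
    carriage: dict[tuple[str, str], frozenset]  # pair -> planted case carriers
    leaked: dict[tuple[str, str], frozenset]  # pair -> leaked control carriers
    duplicate_of: dict[str, str] = field(default_factory=dict)  # dup SNP -> original


@dataclass
class TruthRecord:
    pies: list[PlantedPie]
    minor_alleles: dict[str, str]
    major_alleles: dict[str, str]
    seed: int
    n_cases: int
    n_controls: int
    effect_genes: list[str] = field(default_factory=list)
    corrupted_subjects: list[str] = field(default_factory=list)
    primary_subjects: list[str] = field(default_factory=list)

    @property
    def hub_genes(self) -> list[str]:
        return [p.hub_gene for p in self.pies]

    def carriers_of(self, pie_index: int) -> frozenset:
        out: frozenset = frozenset()
        for ids in self.pies[pie_index].carriage.values():
            out = out | ids
        return out


def _sample_doses(rng: np.random.Generator, q: float, n: int) -> np.ndarray:
    # binomial(2, q) is exactly the Hardy-Weinberg genotype distribution
    return rng.binomial(2, q, size=n).astype(np.int8)


def _doses_to_alleles(doses: np.ndarray, minor: str, major: str) -> np.ndarray:
    out = np.empty((doses.shape[0], 2), dtype="<U1")
    lut = {0: (major, major), 1: tuple(sorted((major, minor))), 2: (minor, minor)}
    for d, pair in lut.items():
        out[doses == d] = pair
    return out


@dataclass
class _Layout:
    """The SNP panel shared by all simulated datasets: ids, genes, alleles,
    per-SNP MAF and the pie -> SNP-pair assignment."""

    snp_ids: list[str]
    genes: list[str]
    minor: dict[str, str]
    major: dict[str, str]
    maf: dict[str, float]
    pies: list[tuple[PlantedPieSpec, list[tuple[str, str]], dict[str, str], list[str]]]
    # (spec, [(hub SNP, partner SNP), ...] incl. duplicates, dup->source, partner genes)


def _make_layout(
    n_snps: int,
    pies: list[PlantedPieSpec],
    rng: np.random.Generator,
    maf_range: tuple[float, float],
    snps_per_gene: int,
) -> _Layout:
    n_planted = sum(2 * p.n_pairs + p.ld_duplicates for p in pies)
    if n_planted > n_snps:
        raise SimulationConfigError(f"{n_planted} planted SNPs exceed n_snps={n_snps}")
    snp_ids = [f"rs{i + 1:06d}" for i in range(n_snps)]
    genes: list[str] = [""] * n_snps
    minor: dict[str, str] = {}
    major: dict[str, str] = {}
    maf: dict[str, float] = {}
    allele_choice = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    flip = rng.random(n_snps) < 0.5
    for j, snp in enumerate(snp_ids):
        a, b = _ALLELE_PAIRS[allele_choice[j]]
        minor[snp], major[snp] = (a, b) if flip[j] else (b, a)

    cursor = 0
    realized: list[tuple[PlantedPieSpec, list[tuple[str, str]], dict[str, str], list[str]]] = []
    for spec in pies:
        pairs: list[tuple[str, str]] = []
        dup_of: dict[str, str] = {}
        partner_genes: list[str] = []
        for m in range(spec.n_pairs):
            j_hub, j_par = cursor, cursor + 1
            cursor += 2
            genes[j_hub] = spec.hub_gene
            pg = f"{spec.hub_gene}_P{m + 1:02d}"
            genes[j_par] = pg
            partner_genes.append(pg)
            for j in (j_hub, j_par):
                maf[snp_ids[j]] = rng.uniform(*spec.maf_range)
            pairs.append((snp_ids[j_hub], snp_ids[j_par]))
        for d in range(spec.ld_duplicates):
            src = pairs[d % spec.n_pairs]
            j_dup = cursor
            cursor += 1
            pg = f"{spec.hub_gene}_D{d + 1:02d}"
            genes[j_dup] = pg
            partner_genes.append(pg)
            maf[snp_ids[j_dup]] = maf[src[1]]
            dup_of[snp_ids[j_dup]] = src[1]
            pairs.append((src[0], snp_ids[j_dup]))
        realized.append((spec, pairs, dup_of, partner_genes))

    bg_index = 0
    for j in range(cursor, n_snps):
        genes[j] = f"BG{bg_index // snps_per_gene + 1:04d}"
        bg_index += 1
        maf[snp_ids[j]] = rng.uniform(*maf_range)
    return _Layout(snp_ids, genes, minor, major, maf, realized)


def _simulate_dataset(
    layout: _Layout,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    prefix: str,
    name: str,
    ethnic_group: str,
    platform: str,
) -> tuple[GenotypeDataset, list[PlantedPie]]:
    if sum(spec.n_targets for spec, *_ in layout.pies) > n_cases:
        raise SimulationConfigError("pie target subsets exceed the case count")
    case_ids = [f"{prefix}HT{i + 1:04d}" for i in range(n_cases)]
    control_ids = [f"{prefix}NC{i + 1:04d}" for i in range(n_controls)]
    subject_ids = case_ids + control_ids
    labels = np.array([True] * n_cases + [False] * n_controls)
    n_subj = len(subject_ids)
    snp_index = {s: j for j, s in enumerate(layout.snp_ids)}

    doses = np.empty((n_subj, len(layout.snp_ids)), dtype=np.int8)
    for j, snp in enumerate(layout.snp_ids):
        doses[:, j] = _sample_doses(rng, layout.maf[snp], n_subj)

    target_cursor = 0
    realized: list[PlantedPie] = []
    for spec, pairs, dup_of, partner_genes in layout.pies:
        targets = case_ids[target_cursor: target_cursor + spec.n_targets]
        target_cursor += spec.n_targets
        target_idx = np.arange(target_cursor - spec.n_targets, target_cursor)
        for hub_snp, par_snp in pairs:
            if par_snp in dup_of:
                continue  # duplicates inherit the source pair's planting
            j_hub, j_par = snp_index[hub_snp], snp_index[par_snp]
            hit = target_idx[rng.random(len(target_idx)) < spec.penetrance]
            doses[hit, j_hub] = spec.combo[0]
            doses[hit, j_par] = spec.combo[1]
            leak_idx = np.nonzero(rng.random(n_controls) < spec.leak)[0] + n_cases
            doses[leak_idx, j_hub] = spec.combo[0]
            doses[leak_idx, j_par] = spec.combo[1]
            # deplete the risky region among everyone else: a non-target in
            # the region would have developed the disease (or is a leak),
            # so knock one dose below threshold, side chosen at random
            in_region = (doses[:, j_hub] >= spec.combo[0]) & (
                doses[:, j_par] >= spec.combo[1]
            )
            keep = np.zeros(n_subj, dtype=bool)
            keep[hit] = True
            keep[leak_idx] = True
            out = np.nonzero(in_region & ~keep)[0]
            side = rng.random(len(out)) < 0.5
            doses[out[side], j_hub] = spec.combo[0] - 1 if spec.combo[0] else 0
            doses[out[~side], j_par] = spec.combo[1] - 1 if spec.combo[1] else 0
        # re-apply duplicate copy after planting so copies carry the combo
        for dup, src in dup_of.items():
            col = doses[:, snp_index[src]].copy()
            if spec.ld_epsilon > 0:
                resample = rng.random(n_subj) < spec.ld_epsilon
                col[resample] = _sample_doses(rng, layout.maf[dup], int(resample.sum()))
            doses[:, snp_index[dup]] = col
        carriage: dict[tuple[str, str], frozenset] = {}
        leaked: dict[tuple[str, str], frozenset] = {}
        for hub_snp, par_snp in pairs:
            da = doses[:, snp_index[hub_snp]]
            db = doses[:, snp_index[par_snp]]
            hit = (da >= spec.combo[0]) & (db >= spec.combo[1])
            carriage[(hub_snp, par_snp)] = frozenset(
                subject_ids[i] for i in np.nonzero(hit & labels)[0]
            )
            leaked[(hub_snp, par_snp)] = frozenset(
                subject_ids[i] for i in np.nonzero(hit & ~labels)[0]
            )
        realized.append(
            PlantedPie(spec.hub_gene, list(partner_genes), list(pairs), spec.combo,
                       targets, carriage, leaked, dict(dup_of))
        )

    alleles = np.empty((n_subj, len(layout.snp_ids), 2), dtype="<U1")
    for j, snp in enumerate(layout.snp_ids):
        alleles[:, j, :] = _doses_to_alleles(
            doses[:, j], layout.minor[snp], layout.major[snp]
        )
    dataset = GenotypeDataset(
        subject_ids, labels, layout.snp_ids, alleles,
        name=name, ethnic_group=ethnic_group, platform=platform,
    )
    return dataset, realized


def _merge_pies(per_dataset: list[list[PlantedPie]]) -> list[PlantedPie]:
    merged: list[PlantedPie] = []
    for parts in zip(*per_dataset):
        first = parts[0]
        carriage = {
            pair: frozenset().union(*(p.carriage[pair] for p in parts))
            for pair in first.carriage
        }
        leaked = {
            pair: frozenset().union(*(p.leaked[pair] for p in parts))
            for pair in first.leaked
        }
        targets = [t for p in parts for t in p.target_ids]
        merged.append(
            PlantedPie(first.hub_gene, list(first.partner_genes), list(first.pairs),
                       first.combo, targets, carriage, leaked,
                       dict(first.duplicate_of))
        )
    return merged


def _annotation_of(layout: _Layout) -> SnpAnnotation:
    return SnpAnnotation(
        pd.DataFrame(
            {
                "snp_id": layout.snp_ids,
                "gene": layout.genes,
                "chromosome": ["1"] * len(layout.snp_ids),
                "position": [(j + 1) * 1000 for j in range(len(layout.snp_ids))],
            }
        )
    )


def generate_training_datasets(
    n_cases: int,
    n_controls: int,
    n_snps: int,
    pies: list[PlantedPieSpec],
    seed: int,
    n_datasets: int = 2,
    sizes: list[tuple[int, int]] | None = None,
    maf_range: tuple[float, float] = (0.05, 0.5),
    snps_per_gene: int = 4,
    name: str = "sim",
    platform: str = "simchip",
) -> tuple[list[GenotypeDataset], SnpAnnotation, TruthRecord]:
    """Simulate multiple case-control datasets on one shared SNP panel.

    Mirrors the two-training-population design: every dataset draws its own
    subjects from the same SNP panel and MAFs, and each pie is planted into
    a disjoint target subset of each dataset's cases.  Qualification in
    *every* dataset — and in particular in a control-rich dataset — is what
    makes the stringent criteria stringent.  ``sizes`` gives per-dataset
    (cases, controls); by default every dataset uses
    ``(n_cases, n_controls)``.  Truth carriage is the recount of actual
    carriers at generation time.
    """
    rng = np.random.default_rng(seed)
    layout = _make_layout(n_snps, pies, rng, maf_range, snps_per_gene)
    if sizes is None:
        sizes = [(n_cases, n_controls)] * n_datasets
    datasets: list[GenotypeDataset] = []
    realized: list[list[PlantedPie]] = []
    for k, (nc_k, nn_k) in enumerate(sizes):
        single = len(sizes) == 1
        prefix = "" if single else chr(ord("A") + k) + "_"
        suffix = "" if single else "_" + chr(ord("A") + k)
        ds, pies_k = _simulate_dataset(
            layout, nc_k, nn_k, rng,
            prefix=prefix, name=f"{name}{suffix}",
            ethnic_group=f"pop{chr(ord('A') + k)}" if not single else "simpop",
            platform=platform,
        )
        datasets.append(ds)
        realized.append(pies_k)
    truth = TruthRecord(
        _merge_pies(realized), dict(layout.minor), dict(layout.major), seed,
        sizes[0][0], sizes[0][1],
        primary_subjects=list(datasets[0].subject_ids),
    )
    return datasets, _annotation_of(layout), truth


def generate_genotypes(
    n_cases: int,
    n_controls: int,
    n_snps: int,
    pies: list[PlantedPieSpec],
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    snps_per_gene: int = 4,
    name: str = "sim",
    ethnic_group: str = "simpop",
    platform: str = "simchip",
) -> tuple[GenotypeDataset, SnpAnnotation, TruthRecord]:
    """Simulate one case-control dataset with planted pies.

    Pies' target case subsets are disjoint, allocated in order.  Returns the
    dataset, its SNP-gene annotation, and the truth record needed to verify
    recovery.
    """
    datasets, ann, truth = generate_training_datasets(
        n_cases, n_controls, n_snps, pies, seed, n_datasets=1,
        maf_range=maf_range, snps_per_gene=snps_per_gene, name=name,
        platform=platform,
    )
    ds = datasets[0]
    ds.ethnic_group = ethnic_group
    return ds, ann, truth


def default_simulation(
    seed: int, **overrides
) -> tuple[list[GenotypeDataset], SnpAnnotation, TruthRecord]:
    """The desk-scale reference simulation.

    Two training datasets on a shared 2000-SNP panel, mirroring the
    training design of the original study: a control-rich dataset of
    300 cases / 2400 controls and a balanced desk-scale dataset of
    200 cases / 400 controls, with three planted pies of 10/8/12 pairs and
    deterministic carriage (penetrance 1, leak within the t_NC budget).
    The control-rich dataset is what keeps control-splitting chance pairs
    out of the stringent scan.
    """
    pies = [
        PlantedPieSpec(hub_gene="HUB1", n_pairs=10),
        PlantedPieSpec(hub_gene="HUB2", n_pairs=8),
        PlantedPieSpec(hub_gene="HUB3", n_pairs=12),
    ]
    params = dict(n_cases=200, n_controls=400, n_snps=2000, pies=pies,
                  seed=seed, sizes=[(300, 2400), (200, 400)])
    params.update(overrides)
    return generate_training_datasets(**params)


# ---------------------------------------------------------------------------
# Two partially overlapping platforms
# ---------------------------------------------------------------------------


def generate_two_platforms(
    dataset: GenotypeDataset,
    annotation: SnpAnnotation,
    truth: TruthRecord,
    shared_gene_fraction: float,
    seed: int,
) -> tuple[GenotypeDataset, GenotypeDataset, SnpAnnotation, TruthRecord]:
    """Split a simulated dataset into two platforms with partial SNP overlap.

    Each planted pair is either shared (both platforms assay the same two
    SNPs, probability ``shared_gene_fraction``) or platform-specific: the
    original SNPs stay on platform A while platform B receives freshly
    simulated SNPs in the same two genes, planted into a *different* group
    of cases — emulating the observation that the same gene pair assayed
    through different SNPs identifies different patients.  Background SNPs
    appear on both platforms.
    """
    rng = np.random.default_rng(seed)
    n_subj = dataset.n_subjects
    labels = dataset.labels

    drop_from_b: set[str] = set()
    extra_ids: list[str] = []
    extra_cols: list[np.ndarray] = []
    extra_rows: list[dict] = []
    new_pies: list[PlantedPie] = []
    minor = dict(truth.minor_alleles)
    major = dict(truth.major_alleles)
    counter = 0
    for pie in truth.pies:
        new_pairs: list[tuple[str, str]] = []
        carriage = dict(pie.carriage)
        leaked = dict(pie.leaked)
        for hub_snp, par_snp in pie.pairs:
            if rng.random() < shared_gene_fraction:
                new_pairs.append((hub_snp, par_snp))
                continue
            drop_from_b.update((hub_snp, par_snp))
            counter += 1
            alt_ids = (f"rsB{counter:05d}h", f"rsB{counter:05d}p")
            orig_targets = pie.carriage[(hub_snp, par_snp)] & set(dataset.subject_ids)
            pool = [
                s for s, lab in zip(dataset.subject_ids, labels)
                if lab and s not in orig_targets
            ]
            n_alt = min(len(orig_targets), len(pool))
            targets = sorted(rng.choice(pool, size=n_alt, replace=False).tolist())
            tgt_idx = np.array([dataset.subject_ids.index(t) for t in targets], dtype=int)
            pair_cols = []
            for which, alt in enumerate(alt_ids):
                q = rng.uniform(0.25, 0.35)
                col = rng.binomial(2, q, size=n_subj).astype(np.int8)
                if tgt_idx.size:
                    col[tgt_idx] = pie.combo[which]
                a, b = _ALLELE_PAIRS[rng.integers(0, len(_ALLELE_PAIRS))]
                minor[alt], major[alt] = a, b
                pair_cols.append(col)
                extra_ids.append(alt)
                extra_cols.append(col)
                gene = (
                    pie.hub_gene
                    if which == 0
                    else annotation.gene_of(par_snp) or f"{pie.hub_gene}_ALT{counter}"
                )
                extra_rows.append(
                    {"snp_id": alt, "gene": gene, "chromosome": "1",
                     "position": 10_000_000 + counter * 10 + which}
                )
            # deplete the risky region among non-targets (see _simulate_dataset)
            in_region = (pair_cols[0] >= pie.combo[0]) & (pair_cols[1] >= pie.combo[1])
            keep = np.zeros(n_subj, dtype=bool)
            if tgt_idx.size:
                keep[tgt_idx] = True
            out = np.nonzero(in_region & ~keep)[0]
            side = rng.random(len(out)) < 0.5
            pair_cols[0][out[side]] = max(pie.combo[0] - 1, 0)
            pair_cols[1][out[~side]] = max(pie.combo[1] - 1, 0)
            new_pairs.append(alt_ids)
            carriage[alt_ids] = frozenset(targets)
            leaked[alt_ids] = frozenset()
        new_pies.append(
            PlantedPie(pie.hub_gene, list(pie.partner_genes), new_pairs,
                       pie.combo, list(pie.target_ids), carriage, leaked,
                       dict(pie.duplicate_of))
        )

    ds_a = GenotypeDataset(
        list(dataset.subject_ids), labels.copy(), list(dataset.snp_ids),
        dataset.alleles.copy(), name=f"{dataset.name}_A",
        ethnic_group=dataset.ethnic_group, platform="platA",
    )
    keep_b = [s for s in dataset.snp_ids if s not in drop_from_b]
    base_b = dataset.subset_snps(keep_b)
    if extra_ids:
        cols = np.stack(
            [
                _doses_to_alleles(col, minor[sid], major[sid])
                for sid, col in zip(extra_ids, extra_cols)
            ],
            axis=1,
        )
        alleles_b = np.concatenate([base_b.alleles, cols], axis=1)
        snps_b = base_b.snp_ids + extra_ids
    else:
        alleles_b, snps_b = base_b.alleles, base_b.snp_ids
    ds_b = GenotypeDataset(
        list(dataset.subject_ids), labels.copy(), snps_b, alleles_b,
        name=f"{dataset.name}_B", ethnic_group=dataset.ethnic_group,
        platform="platB",
    )
    ann2 = SnpAnnotation(
        pd.concat([annotation.table, pd.DataFrame(extra_rows)], ignore_index=True)
        if extra_rows
        else annotation.table
    )
    truth2 = TruthRecord(new_pies, minor, major, seed, truth.n_cases,
                         truth.n_controls, list(truth.effect_genes),
                         list(truth.corrupted_subjects),
                         list(truth.primary_subjects))
    return ds_a, ds_b, ann2, truth2


# ---------------------------------------------------------------------------
# Matched expression data
# ---------------------------------------------------------------------------


def generate_expression(
    truth: TruthRecord,
    n_genes: int,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    replicate_sd: float = 0.1,
    seed: int = 0,
    corrupt_fraction: float = 0.0,
    n_replicates: int = 3,
    effect_pie: int = 0,
    subjects: list[str] | None = None,
) -> tuple[ExpressionDataset, TruthRecord]:
    """Expression profiles correlated with planted carrier status.

    Effect genes are the hub and partner genes of ``pies[effect_pie]``;
    carriers of that pie get a ``+effect_size`` shift (log2 scale) on them.
    ``corrupt_fraction`` of subjects get one replicate scrambled so the
    0.9-correlation filter has something to drop.  Updates and returns a
    copy of the truth record with effect genes and corrupted subjects.
    """
    rng = np.random.default_rng(seed)
    pie = truth.pies[effect_pie]
    effect_genes = [pie.hub_gene] + list(pie.partner_genes)
    if len(effect_genes) > n_genes:
        raise SimulationConfigError("n_genes smaller than the effect gene set")
    gene_ids = effect_genes + [
        f"EXPRG{i + 1:04d}" for i in range(n_genes - len(effect_genes))
    ]
    if subjects is None:
        subjects = list(truth.primary_subjects) or [
            f"HT{i + 1:04d}" for i in range(truth.n_cases)
        ] + [f"NC{i + 1:04d}" for i in range(truth.n_controls)]
    carriers = truth.carriers_of(effect_pie)

    baseline = rng.normal(8.0, 1.0, size=n_genes)
    replicates: dict[str, np.ndarray] = {}
    n_corrupt = int(round(corrupt_fraction * len(subjects)))
    corrupted = sorted(rng.choice(len(subjects), size=n_corrupt, replace=False).tolist())
    corrupted_ids = [subjects[i] for i in corrupted]
    for si, sid in enumerate(subjects):
        v = baseline + rng.normal(0.0, noise_sd, size=n_genes)
        if sid in carriers:
            v = v.copy()
            v[: len(effect_genes)] += effect_size
        reps = np.stack(
            [
                np.power(2.0, v + rng.normal(0.0, replicate_sd, size=n_genes))
                for _ in range(n_replicates)
            ]
        )
        if si in corrupted:
            reps[0] = np.power(2.0, rng.normal(8.0, 1.5, size=n_genes))
        replicates[sid] = reps

    expr = ExpressionDataset(list(subjects), gene_ids, replicates)
    truth2 = TruthRecord(truth.pies, truth.minor_alleles, truth.major_alleles,
                         truth.seed, truth.n_cases, truth.n_controls,
                         effect_genes, corrupted_ids, list(truth.primary_subjects))
    return expr, truth2
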