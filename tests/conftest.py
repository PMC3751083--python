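"""Shared fixtures: the desk-scale planted simulation and small helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from causalpie import (
    SnpAnnotation,
    default_simulation,
    run_pipeline,
)
from causalpie.io import GenotypeDataset


def make_dataset_from_doses(
    doses: np.ndarray,
    labels: np.ndarray,
    name: str = "toy",
    minor: str = "G",
    major: str = "A",
    snp_ids: list[str] | None = None,
    **meta,
) -> GenotypeDataset:
    """Build a dataset whose minor-allele doses are exactly ``doses``.

    ``doses`` may contain -1 for missing.  Caller must keep per-SNP minor
    counts below major counts for the pooled recode to match.
    """
    doses = np.asarray(doses, dtype=int)
    n, m = doses.shape
    if snp_ids is None:
        snp_ids = [f"rs{j + 1:04d}" for j in range(m)]
    alleles = np.empty((n, m, 2), dtype="<U1")
    lut = {
        -1: ("0", "0"),
        0: (major, major),
        1: tuple(sorted((major, minor))),
        2: (minor, minor),
    }
    for d, pair in lut.items():
        alleles[doses == d] = pair
    return GenotypeDataset(
        [f"{name}S{i + 1:04d}" for i in range(n)],
        np.asarray(labels, dtype=bool),
        snp_ids,
        alleles,
        name=name,
        **meta,
    )


def annotation_for(snp_ids: list[str], genes: list[str]) -> SnpAnnotation:
    return SnpAnnotation(
        pd.DataFrame(
            {
                "snp_id": snp_ids,
                "gene": genes,
                "chromosome": ["1"] * len(snp_ids),
                "position": list(range(1, len(snp_ids) + 1)),
            }
        )
    )


def planted_pair_keys(truth) -> set[tuple[str, str]]:
    keys = set()
    for pie in truth.pies:
        keys |= {tuple(sorted(p)) for p in pie.pairs}
    return keys


def planted_selection_setup(effect_size, seed=21, n_targets=100,
                            n_cases=200, n_controls=400, leak=0.05,
                            n_pairs=5, n_genes=150):
    """A cluster + merged expression + group partition with planted
    expression effects, ~100 subjects in each case group."""
    import warnings

    from causalpie.cluster import GeneCluster
    from causalpie.expression import make_partition, merge_replicates
    from causalpie.pair_scan import Evidence, RiskyPair
    from causalpie.simulate import (
        PlantedPieSpec,
        generate_expression,
        generate_genotypes,
    )

    data, ann, truth = generate_genotypes(
        n_cases, n_controls, 2 * n_pairs + 10,
        [PlantedPieSpec("HUB1", n_pairs=n_pairs, n_targets=n_targets, leak=leak)],
        seed=seed,
    )
    expr, truth = generate_expression(
        truth, n_genes=n_genes, effect_size=effect_size, seed=seed + 1,
        subjects=data.subject_ids,
    )
    with __import__("warnings").catch_warnings():
        warnings.simplefilter("ignore")
        merged = merge_replicates(expr)
    pie = truth.pies[0]
    members = [
        RiskyPair(*sorted(pair),
                  gene_a=ann.gene_of(sorted(pair)[0]),
                  gene_b=ann.gene_of(sorted(pair)[1]),
                  per_dataset=((data.name, Evidence(
                      frozenset({(1, 1), (1, 2), (2, 1), (2, 2)}),
                      pie.carriage[pair], pie.leaked[pair])),))
        for pair in pie.pairs
    ]
    cluster = GeneCluster("HUB1", members)
    identified = set()
    for pair in pie.pairs:
        identified |= pie.carriage[pair] | pie.leaked[pair]
    part = make_partition(identified, data.case_ids, data.control_ids,
                          set(merged.merged_subjects))
    return cluster, merged, part, truth


@pytest.fixture(scope="session")
def default_sim():
    """The reference desk-scale simulation (two training datasets, 3 pies)."""
    datasets, ann, truth = default_simulation(seed=1)
    return datasets, ann, truth


@pytest.fixture(scope="session")
def default_result(default_sim):
    datasets, ann, _ = default_sim
    return run_pipeline(datasets, ann)
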