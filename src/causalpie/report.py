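"""Cluster-subject matrices, carriage box-plot summaries and robustness runs.

The cluster-subject matrix is the visualization substrate: a binary matrix
with one row per member pair and one column per identified subject, a cell
set when the subject carries that pair's risky combinatory genotype.  Rows
are ordered by carrier count, columns by total carriage; pairs that cannot
be assayed on the dataset's platform are flagged rather than silently
dropped.  Box-plot data summarize per-(cluster, dataset) carriage
percentage distributions for cases and controls together with the fitted
cut-off and training error.

The robustness experiment reruns the whole pipeline on subsampled data
(both groups, or cases only to vary prevalence, or over a grid of C_HT)
and reports how much of the full-data top-K hub list is recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import CarriageProfile, ClassifierRule, carriage_profiles
from .cluster import BuildConfig, GeneCluster, run_pipeline
from .io import DoseCoding, GenotypeDataset, SnpAnnotation, dose_matrix


@dataclass
class ClusterSubjectMatrix:
    cluster_hub: str
    matrix: np.ndarray  # bool, member pairs x identified subjects
    pair_keys: list[tuple[str, str]]
    subject_ids: list[str]
    platform_missing: np.ndarray  # bool per pair: not assayable on this dataset


def cluster_subject_matrix(
    cluster: GeneCluster, data: GenotypeDataset, coding: DoseCoding
) -> ClusterSubjectMatrix:
    """Binary pair-by-subject carriage matrix with deterministic ordering."""
    dm = dose_matrix(data, coding)
    snp_idx = {s: j for j, s in enumerate(data.snp_ids)}
    rows = []
    missing = []
    for p in cluster.members:
        if p.snp_a in snp_idx and p.snp_b in snp_idx:
            da = dm[:, snp_idx[p.snp_a]]
            db = dm[:, snp_idx[p.snp_b]]
            hit = np.zeros(data.n_subjects, dtype=bool)
            for a, b in p.combo_set:
                hit |= (da == a) & (db == b)
            rows.append(hit)
            missing.append(False)
        else:
            rows.append(np.zeros(data.n_subjects, dtype=bool))
            missing.append(True)
    mat = np.array(rows) if rows else np.zeros((0, data.n_subjects), dtype=bool)
    col_mask = mat.any(axis=0)
    sub_idx = np.nonzero(col_mask)[0]
    mat = mat[:, sub_idx]
    subject_ids = [data.subject_ids[i] for i in sub_idx]
    # rows by carrier count desc, stable with pair-key ties
    row_order = sorted(
        range(len(rows)), key=lambda r: (-int(mat[r].sum()), cluster.members[r].key)
    )
    col_order = sorted(
        range(len(subject_ids)),
        key=lambda c: (-int(mat[:, c].sum()), subject_ids[c]),
    )
    return ClusterSubjectMatrix(
        cluster_hub=cluster.hub or "",
        matrix=mat[np.ix_(row_order, col_order)],
        pair_keys=[cluster.members[r].key for r in row_order],
        subject_ids=[subject_ids[c] for c in col_order],
        platform_missing=np.array([missing[r] for r in row_order]),
    )


# ---------------------------------------------------------------------------
# Carriage box-plot summaries
# ---------------------------------------------------------------------------


def carriage_boxplot_data(
    clusters: Sequence[GeneCluster],
    datasets: Sequence[GenotypeDataset],
    rule: ClassifierRule,
    coding: DoseCoding,
) -> pd.DataFrame:
    """Quartiles of carriage percentages per (cluster, dataset), with the
    fitted cut-off and training ER from the classifier rule."""
    records = []
    for ds in datasets:
        profiles = carriage_profiles(clusters, ds, coding)
        by_cluster: dict[str, list[CarriageProfile]] = {}
        for p in profiles:
            by_cluster.setdefault(p.cluster_hub, []).append(p)
        for hub in sorted(by_cluster):
            ps = by_cluster[hub]
            stratum = ds.ethnic_group if rule.scenario == "S1" else ds.platform
            ht = np.array([p.percentage for p in ps if p.is_case])
            nc = np.array([p.percentage for p in ps if not p.is_case])
            rec = {
                "cluster": hub,
                "dataset": ds.name,
                "n_ht": int(ht.size),
                "n_nc": int(nc.size),
                "cutoff": rule.cutoffs.get((hub, stratum), np.nan),
                "er": rule.er.get((hub, stratum), np.nan),
            }
            for label, arr in (("ht", ht), ("nc", nc)):
                if arr.size:
                    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
                    rec.update({f"{label}_q1": q1, f"{label}_median": q2, f"{label}_q3": q3})
                else:
                    rec.update({f"{label}_q1": np.nan, f"{label}_median": np.nan,
                                f"{label}_q3": np.nan})
            records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Robustness experiments
# ---------------------------------------------------------------------------


def _subsample(
    ds: GenotypeDataset, fraction: float, mode: str, rng: np.random.Generator
) -> GenotypeDataset:
    cases = ds.case_ids
    controls = ds.control_ids
    if mode == "sample-size":
        n_ht = max(1, int(round(fraction * len(cases))))
        n_nc = max(1, int(round(fraction * len(controls))))
        keep = sorted(rng.choice(cases, n_ht, replace=False).tolist()) + sorted(
            rng.choice(controls, n_nc, replace=False).tolist()
        )
    elif mode == "prevalence":
        n_ht = max(1, int(round(fraction * len(cases))))
        keep = sorted(rng.choice(cases, n_ht, replace=False).tolist()) + controls
    else:
        raise ValueError(f"unknown subsampling mode {mode!r}")
    return ds.subset_subjects(keep)


def robustness_experiment(
    datasets: Sequence[GenotypeDataset],
    annotation: SnpAnnotation,
    config: BuildConfig,
    fractions: Sequence[float],
    n_reps: int,
    seed: int,
    mode: str = "sample-size",
    top_k: int = 15,
) -> pd.DataFrame:
    """Top-K hub-gene recovery under subsampling or criteria changes.

    ``mode`` is ``"sample-size"`` (subsample cases and controls),
    ``"prevalence"`` (subsample cases only) or ``"criteria"`` (``fractions``
    is then a grid of C_HT values, no subsampling).  Similarity is the
    fraction of the full-run top-K hub genes recovered in the rerun's
    top-K.  Deterministic replicate runs (fraction 1.0, criteria mode) are
    executed once.
    """
    full_hubs = [
        c.hub for c in run_pipeline(datasets, annotation, config).clusters[:top_k]
    ]
    if not full_hubs:
        raise ValueError("full-data run produced no clusters; nothing to compare")
    rng = np.random.default_rng(seed)
    records = []
    for frac in fractions:
        deterministic = mode == "criteria" or frac >= 1.0
        reps = 1 if deterministic else n_reps
        for rep in range(reps):
            if mode == "criteria":
                cfg = dc_replace(config, c_ht=frac)
                subs = list(datasets)
            else:
                cfg = config
                subs = [_subsample(ds, frac, mode, rng) for ds in datasets]
            hubs = [
                c.hub for c in run_pipeline(subs, annotation, cfg).clusters[:top_k]
            ]
            sim = 100.0 * len(set(hubs) & set(full_hubs)) / len(full_hubs)
            records.append({"fraction": frac, "rep": rep, "similarity": sim})
    df = pd.DataFrame.from_records(records)
    return df.groupby("fraction", as_index=False)["similarity"].mean().merge(
        df, on="fraction", suffixes=("_mean", "")
    )
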