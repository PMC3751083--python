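"""Expression replicate QC and influential-gene selection per cluster.

Each subject contributes up to three replicate arrays of raw intensities.
QC/merging: (i) subjects with any pairwise replicate Pearson correlation
below 0.9 are dropped; (ii) per gene, if the minimum replicate value is
below 60% of the maximum the gene is set missing for that subject;
(iii) surviving replicates are median-merged; (iv) the merged matrix is
log2-transformed and globally Z-scored over non-missing entries;
(v) normalized values above 6 are treated as outliers and set missing.
Missing values are encoded as 0 in the merged matrix.

Influential genes of a cluster are chosen by greedy forward selection
starting from the hub gene: at each step every remaining cluster gene is
scored by the worst (largest) of the three Welch-test p-values contrasting
case carriers against case non-carriers, control carriers and control
non-carriers on the mean expression of the candidate gene set, Bonferroni
adjusted by the number of candidates at that step; the best candidate is
added while it improves the worst adjusted p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .cluster import GeneCluster
from .io import ExpressionDataset

MISSING = 0.0


@dataclass(frozen=True)
class GroupPartition:
    """The four disjoint carrier/label groups a cluster induces."""

    ht_carrier: frozenset
    ht_noncarrier: frozenset
    nc_carrier: frozenset
    nc_noncarrier: frozenset

    def __post_init__(self) -> None:
        groups = [self.ht_carrier, self.ht_noncarrier, self.nc_carrier, self.nc_noncarrier]
        for a, b in combinations(groups, 2):
            if a & b:
                raise ValueError("carrier/label groups must be disjoint")


def make_partition(
    identified: set[str], case_ids: Sequence[str], control_ids: Sequence[str],
    with_expression: set[str],
) -> GroupPartition:
    cases = set(case_ids) & with_expression
    controls = set(control_ids) & with_expression
    return GroupPartition(
        ht_carrier=frozenset(cases & identified),
        ht_noncarrier=frozenset(cases - identified),
        nc_carrier=frozenset(controls & identified),
        nc_noncarrier=frozenset(controls - identified),
    )


# ---------------------------------------------------------------------------
# Replicate QC and merging
# ---------------------------------------------------------------------------


def merge_replicates(
    raw: ExpressionDataset,
    min_correlation: float = 0.9,
    min_max_ratio: float = 0.6,
    outlier_cap: float = 6.0,
) -> ExpressionDataset:
    """Run the replicate QC pipeline and fill ``merged``.

    Order-invariant in replicate labelling.  Subjects with fewer than two
    replicates skip the correlation check (flagged with a warning).
    """
    kept_subjects: list[str] = []
    merged_rows: list[np.ndarray] = []
    for sid in raw.subject_ids:
        reps = np.asarray(raw.replicates[sid], dtype=float)
        if reps.ndim == 1:
            reps = reps[None, :]
        if reps.shape[0] < 2:
            warnings.warn(
                f"subject {sid}: <2 replicates, correlation check skipped",
                stacklevel=2,
            )
        else:
            drop = False
            for i, j in combinations(range(reps.shape[0]), 2):
                r = np.corrcoef(reps[i], reps[j])[0, 1]
                if not np.isfinite(r) or r < min_correlation:
                    drop = True
                    break
            if drop:
                continue
        # per-gene consistency: min < ratio * max => missing
        mx = reps.max(axis=0)
        mn = reps.min(axis=0)
        merged = np.median(reps, axis=0)
        with np.errstate(invalid="ignore"):
            inconsistent = mn < min_max_ratio * mx
        merged[inconsistent] = np.nan
        merged[merged <= 0] = np.nan  # not log-transformable
        kept_subjects.append(sid)
        merged_rows.append(merged)

    mat = np.array(merged_rows) if merged_rows else np.empty((0, raw.n_genes))
    valid = np.isfinite(mat)
    logged = np.full_like(mat, np.nan)
    logged[valid] = np.log2(mat[valid])
    vals = logged[valid]
    if vals.size:
        mu, sd = vals.mean(), vals.std()
        if sd > 0:
            logged[valid] = (logged[valid] - mu) / sd
    logged[np.isfinite(logged) & (logged > outlier_cap)] = np.nan
    out = np.nan_to_num(logged, nan=MISSING)
    return ExpressionDataset(
        subject_ids=list(raw.subject_ids),
        gene_ids=list(raw.gene_ids),
        replicates=dict(raw.replicates),
        merged=out,
        merged_subjects=kept_subjects,
    )


# ---------------------------------------------------------------------------
# Influential-gene forward selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionStep:
    gene: str
    worst_adjusted_p: float


@dataclass
class SelectionResult:
    genes: list[str]
    trajectory: list[SelectionStep]

    @property
    def final_p(self) -> float:
        return self.trajectory[-1].worst_adjusted_p if self.trajectory else float("nan")


def _gene_set_scores(
    expr: ExpressionDataset, genes: Sequence[str]
) -> dict[str, float]:
    """Per-subject mean normalized expression over ``genes`` (missing excluded)."""
    assert expr.merged is not None and expr.merged_subjects is not None
    idx = [expr.gene_ids.index(g) for g in genes]
    sub = expr.merged[:, idx]
    scores: dict[str, float] = {}
    for row, sid in zip(sub, expr.merged_subjects):
        vals = row[row != MISSING]
        if vals.size:
            scores[sid] = float(vals.mean())
    return scores


def _worst_contrast_p(
    scores: dict[str, float], part: GroupPartition
) -> float:
    """Worst of the three Welch p-values: HT-carrier vs each other group."""
    focal = np.array([scores[s] for s in sorted(part.ht_carrier) if s in scores])
    if focal.size < 2:
        return 1.0
    worst = 0.0
    any_contrast = False
    for other in (part.ht_noncarrier, part.nc_carrier, part.nc_noncarrier):
        vals = np.array([scores[s] for s in sorted(other) if s in scores])
        if vals.size < 2:
            warnings.warn("empty/degenerate contrast group skipped", stacklevel=2)
            continue
        any_contrast = True
        p = stats.ttest_ind(focal, vals, equal_var=False).pvalue
        worst = max(worst, float(p) if np.isfinite(p) else 1.0)
    return worst if any_contrast else 1.0


def select_influential_genes(
    cluster: GeneCluster,
    expr: ExpressionDataset,
    part: GroupPartition,
    alpha: float = 1e-5,
) -> SelectionResult:
    """Greedy forward selection of cluster genes discriminating the groups.

    Starts from the hub gene; each step adds the candidate minimizing the
    worst Bonferroni-adjusted contrast p-value, stopping when no candidate
    improves it.  Deterministic: ties break by gene id.  ``alpha`` is the
    significance level reported against the final worst adjusted p.
    """
    if expr.merged is None:
        raise ValueError("expression data must be merged/normalized first")
    hub = cluster.hub or ""
    cluster_genes = sorted(g for g in cluster.genes if g in expr.gene_ids)
    if hub not in expr.gene_ids:
        raise ValueError(f"hub gene {hub!r} absent from expression data")

    selected = [hub]
    current_p = _worst_contrast_p(_gene_set_scores(expr, selected), part)
    trajectory = [SelectionStep(hub, current_p)]
    remaining = [g for g in cluster_genes if g != hub]
    while remaining:
        m = len(remaining)
        best_gene, best_p = None, None
        for g in remaining:
            p = _worst_contrast_p(_gene_set_scores(expr, selected + [g]), part)
            p_adj = min(1.0, p * m)
            if best_p is None or p_adj < best_p:
                best_gene, best_p = g, p_adj
        if best_p is None or best_p >= current_p:
            break
        selected.append(best_gene)
        remaining.remove(best_gene)
        current_p = best_p
        trajectory.append(SelectionStep(best_gene, best_p))
    result = SelectionResult(genes=selected, trajectory=trajectory)
    if result.final_p >= alpha:
        warnings.warn(
            f"final worst adjusted p {result.final_p:.3g} does not reach alpha={alpha}",
            stacklevel=2,
        )
    return result
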