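"""Carriage-percentage classification of subjects by gene clusters.

A subject *identified* by a cluster carries the risky combinatory genotype
of at least one member pair.  The subject's carriage percentage is
``carried / measurable * 100`` where ``measurable`` counts the member pairs
whose two SNPs are assayed on the subject's platform — pairs absent from
the platform are excluded from the denominator so percentages are
comparable across platforms.

A per-(cluster, stratum) cut-off percentage is chosen from the observed
case percentages minimizing the classification error among identified
subjects; scenario S1 stratifies by ethnic group, S2 by genotyping
platform.  A subject is predicted a case when its percentage reaches the
cut-off in at least one cluster; subjects present on several platforms are
counted once.

``allelic_association_test`` is the standard 1-df allelic chi-square on the
2x2 allele-count table (two alleles per subject, missing excluded), used to
show that a cluster's major gene is not itself predictive.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import GeneCluster
from .io import DoseCoding, GenotypeDataset, dose_matrix


@dataclass(frozen=True)
class CarriageProfile:
    subject_id: str
    cluster_hub: str
    carried: int
    measurable: int
    is_case: bool
    dataset: str
    ethnic_group: str
    platform: str

    @property
    def percentage(self) -> float:
        return 100.0 * self.carried / self.measurable


def carriage_profiles(
    clusters: Sequence[GeneCluster],
    data: GenotypeDataset,
    coding: DoseCoding,
) -> list[CarriageProfile]:
    """One profile per (identified subject, cluster) on one dataset."""
    dm = dose_matrix(data, coding)
    snp_idx = {s: j for j, s in enumerate(data.snp_ids)}
    out: list[CarriageProfile] = []
    for cl in clusters:
        present = [
            p for p in cl.members if p.snp_a in snp_idx and p.snp_b in snp_idx
        ]
        if not present:
            warnings.warn(
                f"cluster {cl.hub}: no member pair measurable on {data.name}; skipped",
                stacklevel=2,
            )
            continue
        carried = np.zeros(data.n_subjects, dtype=np.int32)
        for p in present:
            da = dm[:, snp_idx[p.snp_a]]
            db = dm[:, snp_idx[p.snp_b]]
            hit = np.zeros(data.n_subjects, dtype=bool)
            for a, b in p.combo_set:
                hit |= (da == a) & (db == b)
            carried += hit
        for i in np.nonzero(carried)[0]:
            out.append(
                CarriageProfile(
                    subject_id=data.subject_ids[i],
                    cluster_hub=cl.hub or "",
                    carried=int(carried[i]),
                    measurable=len(present),
                    is_case=bool(data.labels[i]),
                    dataset=data.name,
                    ethnic_group=data.ethnic_group,
                    platform=data.platform,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Cut-off fitting (scenarios S1 / S2)
# ---------------------------------------------------------------------------


def _stratum(p: CarriageProfile, scenario: str) -> str:
    if scenario == "S1":
        return p.ethnic_group
    if scenario == "S2":
        return p.platform
    raise ValueError(f"scenario must be S1 or S2, got {scenario!r}")


@dataclass
class ClassifierRule:
    """Per-(cluster hub, stratum) cut-off percentages and training errors."""

    scenario: str
    cutoffs: dict[tuple[str, str], float] = field(default_factory=dict)
    er: dict[tuple[str, str], float] = field(default_factory=dict)


def fit_cutoffs(profiles: Sequence[CarriageProfile], scenario: str = "S1") -> ClassifierRule:
    """Pick, per (cluster, stratum), the case percentage minimizing error.

    Candidate cut-offs are the observed case carriage percentages in the
    stratum; prediction uses ``percentage >= cutoff``.  Ties prefer the
    higher cut-off (higher specificity).  Strata with no identified case
    get no cut-off (the cluster is inert there).
    """
    rule = ClassifierRule(scenario=scenario)
    groups: dict[tuple[str, str], list[CarriageProfile]] = defaultdict(list)
    for p in profiles:
        groups[(p.cluster_hub, _stratum(p, scenario))].append(p)
    for key in sorted(groups):
        ps = groups[key]
        ht = np.array([p.percentage for p in ps if p.is_case])
        nc = np.array([p.percentage for p in ps if not p.is_case])
        if ht.size == 0:
            continue
        best_cut, best_err = None, None
        for cut in sorted(set(ht.tolist())):
            err = int((ht < cut).sum()) + int((nc >= cut).sum())
            if best_err is None or err < best_err or (err == best_err and cut > best_cut):
                best_cut, best_err = cut, err
        rule.cutoffs[key] = float(best_cut)
        rule.er[key] = best_err / (ht.size + nc.size)
    return rule


@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_identified_ht(self) -> int:
        return self.tp + self.fn

    @property
    def n_identified_nc(self) -> int:
        return self.tn + self.fp


def classify(
    profiles: Sequence[CarriageProfile], rule: ClassifierRule
) -> tuple[dict[str, bool], EvalReport]:
    """Predict case status for identified subjects and evaluate.

    A subject is predicted a case when its percentage is >= the cut-off in
    at least one (cluster, stratum) with a fitted cut-off.  Subjects
    appearing in several datasets are counted once.
    """
    predicted: dict[str, bool] = {}
    truth: dict[str, bool] = {}
    for p in sorted(profiles, key=lambda p: (p.subject_id, p.cluster_hub, p.dataset)):
        truth[p.subject_id] = p.is_case
        key = (p.cluster_hub, _stratum(p, rule.scenario))
        cut = rule.cutoffs.get(key)
        hit = cut is not None and p.percentage >= cut
        predicted[p.subject_id] = predicted.get(p.subject_id, False) or hit
    tp = sum(1 for s, yhat in predicted.items() if yhat and truth[s])
    fp = sum(1 for s, yhat in predicted.items() if yhat and not truth[s])
    fn = sum(1 for s, yhat in predicted.items() if not yhat and truth[s])
    tn = sum(1 for s, yhat in predicted.items() if not yhat and not truth[s])
    total = tp + fp + tn + fn
    report = EvalReport(
        accuracy=(tp + tn) / total if total else float("nan"),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )
    return predicted, report


# ---------------------------------------------------------------------------
# Allelic association test
# ---------------------------------------------------------------------------

_MISSING_KEYS = {"missing", "NN", "00", "0"}


def allelic_association_test(
    case_counts: Mapping[str, int], control_counts: Mapping[str, int]
) -> tuple[float, float, pd.DataFrame]:
    """1-df allelic chi-square on a biallelic SNP's genotype counts.

    Genotype keys are two-character strings such as ``"AA"``/``"AG"``;
    ``"missing"`` entries are ignored.  Each subject contributes two
    alleles to the 2x2 allele table.
    """

    def allele_totals(counts: Mapping[str, int]) -> dict[str, int]:
        tot: dict[str, int] = {}
        for g, c in counts.items():
            if g in _MISSING_KEYS:
                continue
            if len(g) != 2:
                raise ValueError(f"genotype key {g!r} is not a 2-allele string")
            for a in g:
                tot[a] = tot.get(a, 0) + c
        return tot

    ca = allele_totals(case_counts)
    co = allele_totals(control_counts)
    alleles = sorted(set(ca) | set(co))
    if len(alleles) > 2:
        raise ValueError(f"more than 2 alleles in counts: {alleles}")
    if len(alleles) < 2:
        raise ValueError("monomorphic table: allelic test undefined")
    if sum(ca.values()) == 0 or sum(co.values()) == 0:
        raise ValueError("a group has zero typed alleles")
    table = pd.DataFrame(
        [[ca.get(a, 0) for a in alleles], [co.get(a, 0) for a in alleles]],
        index=["case", "control"],
        columns=alleles,
    )
    obs = table.to_numpy()
    if (obs.sum(axis=0) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p), table


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment (the only multiple-testing correction offered)."""
    m = len(p_values) if m is None else m
    return [min(1.0, p * m) for p in p_values]
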