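"""JSON round-tripping for risky pairs, clusters and classifier rules."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

from .classifier import ClassifierRule
from .cluster import GeneCluster
from .pair_scan import Evidence, RiskyPair


def _evidence_to_dict(ev: Evidence) -> dict[str, Any]:
    return {
        "genotype_set": sorted(
            list(g) if isinstance(g, tuple) else [g] for g in ev.genotype_set
        ),
        "ht_carriers": sorted(ev.ht_carriers),
        "nc_carriers": sorted(ev.nc_carriers),
    }


def _evidence_from_dict(d: dict[str, Any], pairwise: bool) -> Evidence:
    cells = frozenset(
        tuple(g) if pairwise else g[0] for g in d["genotype_set"]
    )
    return Evidence(cells, frozenset(d["ht_carriers"]), frozenset(d["nc_carriers"]))


def pair_to_dict(p: RiskyPair) -> dict[str, Any]:
    return {
        "snp_a": p.snp_a,
        "snp_b": p.snp_b,
        "gene_a": p.gene_a,
        "gene_b": p.gene_b,
        "per_dataset": {name: _evidence_to_dict(ev) for name, ev in p.per_dataset},
    }


def pair_from_dict(d: dict[str, Any]) -> RiskyPair:
    per_ds = tuple(
        (name, _evidence_from_dict(ev, pairwise=True))
        for name, ev in sorted(d["per_dataset"].items())
    )
    return RiskyPair(d["snp_a"], d["snp_b"], d.get("gene_a"), d.get("gene_b"), per_ds)


def cluster_to_dict(c: GeneCluster) -> dict[str, Any]:
    return {
        "hub": c.hub,
        "members": [pair_to_dict(p) for p in c.members],
        "relaxation_level": c.relaxation_level,
        "provenance": [
            {k: list(v) for k, v in prov.items()} for prov in c.provenance
        ],
        "identification_counts": dict(sorted(c.identification_counts.items())),
        "mfis": sorted(c.mfis),
        "fis": sorted(c.fis),
    }


def cluster_from_dict(d: dict[str, Any]) -> GeneCluster:
    return GeneCluster(
        hub=d["hub"],
        members=[pair_from_dict(m) for m in d["members"]],
        relaxation_level=d.get("relaxation_level", 0),
        provenance=[
            {k: tuple(v) for k, v in prov.items()} for prov in d.get("provenance", [])
        ],
        identification_counts=dict(d.get("identification_counts", {})),
        mfis=frozenset(d.get("mfis", [])),
        fis=frozenset(d.get("fis", [])),
    )


def save_clusters(clusters: Sequence[GeneCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"clusters": [cluster_to_dict(c) for c in clusters]}, fh, indent=1)


def load_clusters(path: str | Path) -> list[GeneCluster]:
    with open(path) as fh:
        data = json.load(fh)
    return [cluster_from_dict(d) for d in data["clusters"]]


def rule_to_dict(rule: ClassifierRule) -> dict[str, Any]:
    return {
        "scenario": rule.scenario,
        "cutoffs": [
            {"cluster": k[0], "stratum": k[1], "cutoff": v}
            for k, v in sorted(rule.cutoffs.items())
        ],
        "er": [
            {"cluster": k[0], "stratum": k[1], "er": v}
            for k, v in sorted(rule.er.items())
        ],
    }


def rule_from_dict(d: dict[str, Any]) -> ClassifierRule:
    rule = ClassifierRule(scenario=d["scenario"])
    for rec in d["cutoffs"]:
        rule.cutoffs[(rec["cluster"], rec["stratum"])] = rec["cutoff"]
    for rec in d["er"]:
        rule.er[(rec["cluster"], rec["stratum"])] = rec["er"]
    return rule
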