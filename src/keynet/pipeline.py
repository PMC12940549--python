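"""End-to-end per-condition analysis with config, logging and report bundling.

A single YAML/JSON config drives the full pipeline per condition:
topology report -> permutation null -> quantile classes + key-protein
selection -> multi-set overlaps -> enrichment (optional GMT) -> focal
subnetworks (optional focal symbols). Reports are deterministic given the
inputs and seed; timestamps live only in the run manifest.

Config schema (YAML)::

    seed: 7
    out_dir: results/
    conditions:
      NH: {gene_list: nh.txt, edges: nh_edges.tsv}
      AS: {gene_list: as.txt, edges: as_edges.tsv}
    annotations: anno.gmt          # optional
    focal:                         # optional
      Tin: {symbols: [NTRK1, NTRK3], mode: percentile, percentile: 90}
    analysis: {hdp_count: 3, hsip_percentile: 90, permutations: 1000}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .datatypes import AnalysisConfig
from .enrichment import enrich, top_terms
from .io import dump_json, read_edge_table, read_gene_list, read_gmt
from .overlap import venn
from .permutation import permutation_pvalue
from .selection import (
    class_level_correlation,
    degree_class_score_points,
    key_proteins,
    network_class_tables,
)
from .subnetworks import focal_partners
from .topology import build_condition_network, topology_report

logger = logging.getLogger("keynet")

__all__ = ["RunManifest", "run_all", "load_config"]


@dataclasses.dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    outputs: dict[str, str]
    version: str
    seed: int
    started: str
    finished: str

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage and condition names."""

    def __init__(self, stage: str, condition: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for condition {condition!r}: {cause}")
        self.stage = stage
        self.condition = condition


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _analysis_config(cfg: dict, seed: int) -> AnalysisConfig:
    block = dict(cfg.get("analysis", {}))
    block.setdefault("seed", seed)
    return AnalysisConfig(**block)


def run_all(config: str | Path | dict, out_dir: str | Path | None = None) -> RunManifest:
    """Execute every configured stage and write the report bundle."""
    started = datetime.now(timezone.utc).isoformat()
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    if not cfg.get("conditions"):
        raise ValueError("config must name at least one condition")
    out = Path(out_dir or cfg.get("out_dir", "keynet_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    acfg = _analysis_config(cfg, seed)

    digests: dict[str, str] = {}
    outputs: dict[str, str] = {}

    networks = {}
    topo_rows = []
    perm_rows = []
    keysets = {}
    class_corr_pairs = []
    for cond, block in cfg["conditions"].items():
        for key in ("gene_list", "edges"):
            if key not in block:
                raise ValueError(f"condition {cond!r}: config missing {key!r}")
        try:
            glist = read_gene_list(block["gene_list"], dialect=block.get("dialect", "plain"), label=cond)
            edges = read_edge_table(block["edges"], score_scale=block.get("score_scale", "int1000"))
            digests[str(block["gene_list"])] = _sha256(block["gene_list"])
            digests[str(block["edges"])] = _sha256(block["edges"])
            net = build_condition_network(glist, edges)
            networks[cond] = net
        except StageError:
            raise
        except Exception as err:
            raise StageError("network_construction", cond, err) from err

        try:
            rep = topology_report(net)
            topo_rows.append({"condition": cond, **rep.as_dict()})
        except Exception as err:
            raise StageError("topology", cond, err) from err

        try:
            perm = permutation_pvalue(
                net, "clustering_coefficient", n=acfg.permutations, seed=seed
            )
            perm_rows.append(
                {
                    "condition": cond,
                    "statistic": perm.statistic_name,
                    "observed": perm.observed,
                    "null_mean": sum(perm.null_values) / len(perm.null_values),
                    "p_value": perm.p_value,
                    "n_permutations": perm.n_permutations,
                }
            )
        except Exception as err:
            raise StageError("permutation_test", cond, err) from err

        try:
            keysets[cond] = key_proteins(
                net, cond, k=acfg.hdp_count, hsip_percentile=acfg.hsip_percentile
            )
            class_corr_pairs.append(degree_class_score_points(net))
        except Exception as err:
            raise StageError("key_protein_selection", cond, err) from err
        logger.info("condition %s: %d key proteins", cond, len(keysets[cond].unique_members))

    # topology criteria per condition
    dump_json(topo_rows, out / "topology.json")
    outputs["topology"] = str(out / "topology.json")
    dump_json(perm_rows, out / "permutation_tests.json")
    outputs["permutation_tests"] = str(out / "permutation_tests.json")

    # key proteins per condition
    key_report = {
        cond: {
            "cs_threshold": ks.cs_threshold,
            "hdps": [{"symbol": h.symbol, "degree": h.degree} for h in ks.hdps],
            "hsips": [
                {"hub": r.hub, "partner": r.partner, "combined_score": r.combined_score}
                for r in ks.hsips
            ],
            "unique_members": sorted(ks.unique_members),
        }
        for cond, ks in keysets.items()
    }
    dump_json(key_report, out / "key_proteins.json")
    outputs["key_proteins"] = str(out / "key_proteins.json")

    # quantile classes and pooled degree-score correlation
    class_report: dict = {}
    for cond, net in networks.items():
        deg_table, score_table = network_class_tables(net)
        class_report[cond] = {
            t.variable: [dataclasses.asdict(c) for c in t.classes]
            for t in (deg_table, score_table)
        }
    if sum(len(g) for g in class_corr_pairs) >= 3:
        r, p = class_level_correlation(class_corr_pairs)
        class_report["pooled_degree_score_correlation"] = {"r": r, "p": p}
    dump_json(class_report, out / "quantile_classes.json")
    outputs["quantile_classes"] = str(out / "quantile_classes.json")

    # key-protein overlap across conditions (needs 2-3 conditions)
    if 2 <= len(keysets) <= 3:
        ov = venn({c: ks.unique_members for c, ks in keysets.items()})
        dump_json(
            {
                "set_labels": list(ov.set_labels),
                "regions": {"+".join(sorted(k)): list(v) for k, v in ov.regions.items()},
                "union_size": ov.union_size,
            },
            out / "key_protein_overlap.json",
        )
        outputs["key_protein_overlap"] = str(out / "key_protein_overlap.json")

    # enrichment
    if cfg.get("annotations"):
        anno = read_gmt(cfg["annotations"])
        digests[str(cfg["annotations"])] = _sha256(cfg["annotations"])
        enr_report = {}
        for cond, ks in keysets.items():
            try:
                rows = enrich(ks.unique_members, anno, acfg)
            except ValueError as err:
                raise StageError("enrichment", cond, err) from err
            enr_report[cond] = [
                dataclasses.asdict(r) for r in top_terms(rows, acfg.top_terms)
            ]
        dump_json(enr_report, out / "enrichment.json")
        outputs["enrichment"] = str(out / "enrichment.json")

    # focal subnetworks
    if cfg.get("focal"):
        sub_report = {}
        for cond, block in cfg["focal"].items():
            if cond not in networks:
                raise ValueError(f"focal block names unknown condition {cond!r}")
            try:
                res = focal_partners(
                    networks[cond],
                    block["symbols"],
                    mode=block.get("mode", "median"),
                    percentile=block.get("percentile"),
                )
            except ValueError as err:
                raise StageError("focal_subnetworks", cond, err) from err
            sub_report[cond] = {
                "focal": sorted(res.focal_symbols),
                "threshold_mode": res.threshold_mode,
                "threshold_value": res.threshold_value,
                "members": dict(sorted(res.members.items())),
                "member_degrees": dict(sorted(res.member_degrees.items())),
            }
        dump_json(sub_report, out / "focal_subnetworks.json")
        outputs["focal_subnetworks"] = str(out / "focal_subnetworks.json")

    manifest = RunManifest(
        config=cfg,
        input_digests=digests,
        outputs=outputs,
        version=__version__,
        seed=seed,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.as_dict(), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
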