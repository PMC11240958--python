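"""Full analysis pipeline: distances -> similarity -> TMFG -> centralities
-> community detection -> partition comparison -> descriptor tests.

The entry point :func:`run_full_pipeline` takes a configuration mapping
and returns a JSON-serialisable report with one section per distance
metric (graph summary, community counts and sorted sizes, the five
agreement metrics, and the non-parametric test battery), plus run
metadata.  Descriptor tests always use the 12-descriptor table — the same
values the Euclidean network is built from — whichever metric defined the
network.
"""

from __future__ import annotations

import json
import logging
import os
import time
import traceback
from typing import Any, Mapping, Optional

import numpy as np

from .communities import (
    Partition,
    leading_eigenvector_partition,
    leiden_partition,
    modularity,
)
from .compare import adjusted_rand_index, compare_partitions
from .distances import (
    DistanceMatrix,
    euclidean_matrix,
    hamming_matrix,
    levenshtein_matrix,
    tanimoto_matrix,
)
from .graph_metrics import compute_centralities
from .group_tests import community_descriptor_tests
from .io import (
    DescriptorTable,
    RDKitAdapter,
    compute_descriptor_table,
    compute_fingerprints,
    read_molecule_table,
)
from .network import distance_to_similarity, tmfg_filter
from .synthetic import SyntheticSpec, generate_synthetic_molecules

logger = logging.getLogger(__name__)

DEFAULT_METRICS = ("euclidean", "tanimoto", "hamming", "levenshtein")


def _pkg_version() -> str:
    import molnet

    return molnet.__version__

DEFAULT_CONFIG: dict[str, Any] = {
    "metrics": list(DEFAULT_METRICS),
    "scaling": "zscore",
    "sim_mode": "linear",
    "entropy_base": float(np.e),
    "fingerprint_kind": "morgan",
    "fingerprint_length": 2048,
    "leiden_resolution": 1.0,
    "min_group_size": 2,
    "seed": 0,
}


class _Inputs:
    """Resolved pipeline inputs: ids, strings, fingerprints, descriptors,
    and (for synthetic data) the planted partition."""

    def __init__(self, ids, smiles, fingerprints, table: DescriptorTable,
                 planted: Optional[Partition] = None):
        self.ids = list(ids)
        self.smiles = list(smiles)
        self.fingerprints = fingerprints
        self.table = table
        self.planted = planted


def _resolve_inputs(config: Mapping[str, Any]) -> _Inputs:
    if "synthetic" in config:
        syn_cfg = dict(config["synthetic"])
        syn_cfg.setdefault("seed", config.get("seed", 0))
        spec = SyntheticSpec(**syn_cfg)
        data = generate_synthetic_molecules(spec)
        return _Inputs(data.ids, data.smiles, data.fingerprints,
                       data.descriptor_table(), planted=data.planted)
    if "csv" in config:
        records = read_molecule_table(
            config["csv"],
            smiles_column=config.get("smiles_column", "mol"),
            id_column=config.get("id_column"),
        )
        adapter = RDKitAdapter(conformer_seed=config.get("seed", 0))
        table = compute_descriptor_table(
            records, adapter, entropy_base=config.get("entropy_base", float(np.e)))
        fps = compute_fingerprints(
            records, adapter,
            kind=config.get("fingerprint_kind", "morgan"),
            length=config.get("fingerprint_length", 2048),
        )
        return _Inputs([r.id for r in records], [r.smiles for r in records],
                       fps, table)
    raise ValueError("config must provide either 'csv' or 'synthetic' input")


def _distance_for(metric: str, inputs: _Inputs, config: Mapping[str, Any]) -> DistanceMatrix:
    if metric == "euclidean":
        return euclidean_matrix(inputs.table, scaling=config.get("scaling", "zscore"))
    if metric == "tanimoto":
        return tanimoto_matrix(inputs.fingerprints, ids=inputs.ids)
    if metric == "hamming":
        return hamming_matrix(inputs.fingerprints, ids=inputs.ids)
    if metric == "levenshtein":
        return levenshtein_matrix(inputs.smiles, ids=inputs.ids,
                                  canonicalize=config.get("canonicalize_smiles", False))
    raise ValueError(f"unknown metric {metric!r}")


def _analyse_metric(metric: str, inputs: _Inputs, config: Mapping[str, Any],
                    out_dir: Optional[str]) -> dict:
    t0 = time.perf_counter()
    d = _distance_for(metric, inputs, config)
    s = distance_to_similarity(d, mode=config.get("sim_mode", "linear"))
    g = tmfg_filter(s, ids=inputs.ids, distances=d)
    section: dict[str, Any] = {
        "graph": {"n": g.n, "edges": g.m, "is_planar": bool(g.is_planar),
                  "connected": bool(g.is_connected())},
    }
    cent = compute_centralities(g)
    section["centrality_summary"] = {
        "max_eigenvector": float(cent.eigenvector.max()),
        "leading_eigenvalue": float(cent.leading_eigenvalue),
        "max_betweenness": float(cent.betweenness.max()),
        "mean_constraint": float(np.nanmean(cent.constraint)),
    }

    seed = int(config.get("seed", 0))
    p_le = leading_eigenvector_partition(g)
    p_leiden = leiden_partition(g, resolution=config.get("leiden_resolution", 1.0),
                                seed=seed)
    section["communities"] = {
        "leading_eigenvector": {**p_le.summary(),
                                "modularity": modularity(g, p_le)},
        "leiden": {**p_leiden.summary(),
                   "modularity": modularity(g, p_leiden)},
    }
    section["comparison"] = compare_partitions(p_le, p_leiden).to_dict()
    section["comparison"]["reference"] = "leading_eigenvector vs leiden"
    if inputs.planted is not None:
        section["planted_ari"] = {
            "leading_eigenvector": adjusted_rand_index(p_le, inputs.planted),
            "leiden": adjusted_rand_index(p_leiden, inputs.planted),
        }

    tests = {}
    for name, part in (("leading_eigenvector", p_le), ("leiden", p_leiden)):
        report = community_descriptor_tests(
            inputs.table, part, partition_name=f"{metric}/{name}",
            min_group_size=config.get("min_group_size", 2))
        if report.skipped:
            tests[name] = {"skipped": report.skipped_reason}
        else:
            tests[name] = {"skipped": None,
                           "results": report.to_dataframe().to_dict("records")}
    section["descriptor_tests"] = tests
    section["wall_time_s"] = round(time.perf_counter() - t0, 3)

    if out_dir is not None:
        g.write_graphml(os.path.join(out_dir, f"{metric}_tmfg.graphml"))
        cent.to_csv(os.path.join(out_dir, f"{metric}_centrality.csv"))
        p_le.to_csv(os.path.join(out_dir, f"{metric}_leading_eigenvector.csv"))
        p_leiden.to_csv(os.path.join(out_dir, f"{metric}_leiden.csv"))
    return section


def run_full_pipeline(config: Mapping[str, Any],
                      out_dir: Optional[str] = None) -> dict:
    """Run every enabled metric end to end and assemble the report.

    A stage failure for one metric marks that section failed with
    diagnostics and skips its downstream stages; other metrics still run.
    Identical config + seed give an identical report (timestamps aside).
    """
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    inputs = _resolve_inputs(cfg)
    report: dict[str, Any] = {
        "metadata": {
            "version": _pkg_version(),
            "n_molecules": len(inputs.ids),
            "seed": cfg["seed"],
            "config": {k: v for k, v in cfg.items() if k != "synthetic"},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "networks": {},
    }
    if "synthetic" in cfg:
        report["metadata"]["synthetic"] = {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in dict(cfg["synthetic"]).items() if k != "centroid_ranges"
        }
    for metric in cfg["metrics"]:
        logger.info("pipeline: analysing %s network", metric)
        try:
            report["networks"][metric] = _analyse_metric(metric, inputs, cfg, out_dir)
        except Exception as exc:
            logger.error("pipeline: %s stage failed: %s", metric, exc)
            report["networks"][metric] = {
                "failed": str(exc),
                "traceback": traceback.format_exc(),
            }
    if out_dir is not None:
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
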