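"""Readers and writers for the package's plain-text formats.

All artifacts are text: TSV for tables (degree tables, size
distributions, edge lists, manifold samples) and JSON for structured
objects (moment summaries, asymptote coefficient bundles).  Floats are
written in shortest round-trip representation, so write/read cycles are
lossless at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .degree_model import DegreeDistribution, MomentSummary, tabulate

__all__ = [
    "read_distribution_tsv", "write_distribution_tsv",
    "read_moments_json", "write_moments_json",
    "read_matrix_json",
    "read_edge_list_tsv", "write_edge_list_tsv",
    "write_size_distribution_tsv", "read_size_distribution_tsv",
    "write_manifold_tsv",
    "load_generator_config",
]

# floats are written via repr (pandas default) for lossless round trips


def write_distribution_tsv(dist: DegreeDistribution, path) -> None:
    """TSV with header ``k_1 ... k_N probability``."""
    n = dist.n_colours
    df = pd.DataFrame(dist.counts, columns=[f"k_{i + 1}" for i in range(n)])
    df["probability"] = dist.probs
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def read_distribution_tsv(path, truncation_tol: float = 1e-8,
                          ) -> DegreeDistribution:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    kcols = [c for c in df.columns if c.startswith("k_")]
    if not kcols or "probability" not in df.columns:
        raise ValueError(f"{path}: expected columns k_1..k_N and probability")
    return DegreeDistribution(
        df[kcols].to_numpy(dtype=np.int64),
        df["probability"].to_numpy(dtype=float),
        truncation_tol, provenance=str(path),
    )


def write_moments_json(summary: MomentSummary, path) -> None:
    payload = {
        "schema": "chromperc/moments/1",
        "version": __version__,
        "mu0": summary.mu0.tolist(),
        "M": summary.M.tolist(),
        "T": summary.T.tolist(),
        "meta": _jsonable(summary.meta),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_moments_json(path) -> MomentSummary:
    payload = json.loads(Path(path).read_text())
    return MomentSummary(np.array(payload["mu0"]), np.array(payload["M"]),
                         np.array(payload["T"]), payload.get("meta", {}))


def read_matrix_json(path) -> np.ndarray:
    """Square matrix from JSON: either a bare nested list, or an object
    with an ``M``/``matrix`` key (a moments file also qualifies)."""
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, list):
        return np.asarray(payload, dtype=float)
    for key in ("M", "matrix"):
        if key in payload:
            return np.asarray(payload[key], dtype=float)
    raise ValueError(f"{path}: no matrix found")


def write_edge_list_tsv(graph, path) -> None:
    """Edge list TSV: 0-based node ids, 1-based colour ids (see header)."""
    with open(path, "w") as fh:
        fh.write("# chromperc edge list: node ids 0-based, colours 1-based\n")
        fh.write(f"# n_nodes={graph.n_nodes}\tn_colours={graph.n_colours}\n")
        fh.write("node_u\tnode_v\tcolour\n")
        for u, v, c in graph.edges:
            fh.write(f"{u}\t{v}\t{c + 1}\n")


def read_edge_list_tsv(path):
    """Returns (n_nodes, edges) with colours converted back to 0-based."""
    from .simulator import ColouredGraph

    n_nodes = None
    n_colours = None
    with open(path) as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
                for tok in line[1:].split():
                    if tok.startswith("n_nodes="):
                        n_nodes = int(tok.split("=")[1])
                    if tok.startswith("n_colours="):
                        n_colours = int(tok.split("=")[1])
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    edges = df[["node_u", "node_v", "colour"]].to_numpy(dtype=np.int64)
    edges[:, 2] -= 1
    if n_nodes is None:
        n_nodes = int(edges[:, :2].max()) + 1 if len(edges) else 0
    if n_colours is None:
        n_colours = int(edges[:, 2].max()) + 1 if len(edges) else 1
    states = np.zeros((n_nodes, n_colours), dtype=np.int64)
    if len(edges):
        np.add.at(states, (edges[:, 0], edges[:, 2]), 1)
        np.add.at(states, (edges[:, 1], edges[:, 2]), 1)
    return ColouredGraph(n_nodes, edges, states, meta={"source": str(path)})


def write_size_distribution_tsv(sd, path, asymptote=None) -> None:
    """TSV of n, w(n); optional overlay column with the tail asymptote."""
    df = pd.DataFrame({"n": sd.sizes, "w": sd.probabilities})
    if asymptote is not None:
        df["w_asymptote"] = asymptote.w_inf(sd.sizes)
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def read_size_distribution_tsv(path):
    from .exact_components import SizeDistribution

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    n_max = int(df["n"].max())
    w = np.zeros(n_max + 1)
    w[df["n"].to_numpy(dtype=int)] = df["w"].to_numpy(dtype=float)
    return SizeDistribution(w, n_max, meta={"source": str(path)})


def write_manifold_tsv(sample, path) -> None:
    n = sample.points.shape[1] if len(sample) else 0
    df = pd.DataFrame(sample.points, columns=[f"p_{i + 1}" for i in range(n)])
    df["residual"] = sample.residuals
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def load_generator_config(path) -> DegreeDistribution:
    """Tabulate a generator from a YAML/JSON config:
    ``{generator: name, params: {...}, truncation_tol: tol}``."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if "generator" not in cfg:
        raise ValueError(f"{path}: missing 'generator' key")
    return tabulate(cfg["generator"],
                    truncation_tol=float(cfg.get("truncation_tol", 1e-12)),
                    **(cfg.get("params") or {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
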