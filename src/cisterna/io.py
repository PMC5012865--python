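"""Serialization: rule matrices, orbits, networks, and tables.

JSON is the canonical lossless format for every object. Rule matrices are
additionally stored as sparse triplets (CSV or MatrixMarket) next to a JSON
header carrying N, A and sampling provenance; networks export to GraphML
and DOT for visualization. Compositions serialize as integer indices plus N,
with a readable bit-string alongside.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy.sparse import coo_matrix

from .boolean_core import Composition, Orbit, RuleSet
from .network_analysis import TrafficNetwork

__all__ = [
    "save_rules", "load_rules",
    "orbit_to_dict", "orbit_from_dict", "save_orbit", "load_orbit",
    "network_to_dict", "network_from_dict", "save_network", "load_network",
    "write_graphml", "write_dot",
]


def _matrix_to_triplets(mat: np.ndarray) -> pd.DataFrame:
    rows, cols = np.nonzero(mat)
    return pd.DataFrame({"row": rows, "col": cols, "value": 1})


def _triplets_to_matrix(df: pd.DataFrame, size: int) -> np.ndarray:
    mat = np.zeros((size, size), dtype=bool)
    mat[df["row"].to_numpy(), df["col"].to_numpy()] = df["value"].to_numpy() != 0
    return mat


def save_rules(rules: RuleSet, prefix, fmt: str = "csv") -> None:
    """Write ``<prefix>.G.<fmt>``, ``<prefix>.F.<fmt>`` and ``<prefix>.json``.

    ``fmt`` is ``csv`` (triplet CSV) or ``mtx`` (MatrixMarket).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    header = {"N": rules.N, "A": rules.A, "format": fmt, **rules.meta}
    prefix.with_suffix(prefix.suffix + ".json").write_text(
        json.dumps(header, indent=1, default=float))
    for name, mat in (("G", rules.G), ("F", rules.F)):
        path = Path(f"{prefix}.{name}.{fmt}")
        if fmt == "csv":
            _matrix_to_triplets(mat).to_csv(path, index=False)
        elif fmt == "mtx":
            spio.mmwrite(path, coo_matrix(mat.astype(np.int8)))
        else:
            raise ValueError(f"unknown rules format: {fmt!r}")


def load_rules(prefix) -> RuleSet:
    prefix = Path(prefix)
    header_path = prefix.with_suffix(prefix.suffix + ".json")
    try:
        header = json.loads(header_path.read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{header_path}: line {err.lineno}: invalid JSON header") from err
    for key in ("N", "A", "format"):
        if key not in header:
            raise ValueError(f"{header_path}: missing field {key!r}")
    N, A, fmt = int(header["N"]), int(header["A"]), header["format"]
    size = 1 << N
    mats = {}
    for name in ("G", "F"):
        path = Path(f"{prefix}.{name}.{fmt}")
        if fmt == "csv":
            mats[name] = _triplets_to_matrix(pd.read_csv(path), size)
        else:
            mats[name] = np.asarray(spio.mmread(path).todense()) != 0
    meta = {k: v for k, v in header.items() if k not in ("N", "A", "format")}
    return RuleSet(N=N, G=mats["G"], F=mats["F"], A=A, meta=meta)


def _comp_str(i: int, N: int) -> str:
    return str(Composition(i, N))


def orbit_to_dict(orbit: Orbit, N: int) -> dict:
    return {
        "N": N,
        "states": [list(s) for s in orbit.states],
        "states_bits": [[_comp_str(i, N) for i in s] for s in orbit.states],
        "period": orbit.period,
        "steps_to_orbit": orbit.steps_to_orbit,
        "reached": orbit.reached,
        "homotypic_types": sorted(orbit.homotypic_types),
    }


def orbit_from_dict(d: dict) -> Orbit:
    return Orbit(states=[tuple(s) for s in d["states"]], period=d["period"],
                 steps_to_orbit=d["steps_to_orbit"], reached=d["reached"],
                 homotypic_types=frozenset(d["homotypic_types"]))


def save_orbit(orbit: Orbit, N: int, path) -> None:
    Path(path).write_text(json.dumps(orbit_to_dict(orbit, N), indent=1))


def load_orbit(path) -> Orbit:
    return orbit_from_dict(json.loads(Path(path).read_text()))


def network_to_dict(net: TrafficNetwork) -> dict:
    return {
        "N": net.N,
        "nodes": list(net.nodes),
        "nodes_bits": [_comp_str(i, net.N) for i in net.nodes],
        "vesicle_edges": [[a, b, sorted(js)]
                          for (a, b), js in sorted(net.vesicle_edges.items())],
        "creation_edges": sorted(list(e) for e in net.creation_edges),
        "maturation_edges": sorted([a, b] for a, b in net.maturation_edges.items()),
        "homotypic_types": sorted(net.homotypic_types),
        "updates": sorted([a, b] for a, b in net.updates.items())
                   if net.updates is not None else None,
        "meta": {k: v for k, v in net.meta.items()},
    }


def network_from_dict(d: dict) -> TrafficNetwork:
    for key in ("N", "nodes", "vesicle_edges", "creation_edges", "maturation_edges"):
        if key not in d:
            raise ValueError(f"network JSON: missing field {key!r}")
    return TrafficNetwork(
        N=int(d["N"]), nodes=tuple(d["nodes"]),
        vesicle_edges={(a, b): frozenset(js) for a, b, js in d["vesicle_edges"]},
        creation_edges=frozenset((a, b) for a, b in d["creation_edges"]),
        maturation_edges={a: b for a, b in d["maturation_edges"]},
        homotypic_types=frozenset(d.get("homotypic_types", ())),
        updates={a: b for a, b in d["updates"]} if d.get("updates") is not None else None,
        meta=d.get("meta", {}))


def save_network(net: TrafficNetwork, path) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net), indent=1, default=float))


def load_network(path) -> TrafficNetwork:
    path = Path(path)
    try:
        return network_from_dict(json.loads(path.read_text()))
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: line {err.lineno}: invalid JSON") from err


def write_graphml(net: TrafficNetwork, path) -> None:
    """GraphML export; vesicle composition sets flatten to comma strings
    (topology and edge kinds re-import losslessly, compositions as text)."""
    g = net.to_networkx()
    for _u, _v, data in g.edges(data=True):
        if "vesicles" in data:
            data["vesicles"] = ",".join(map(str, data["vesicles"]))
    nx.write_graphml(g, path)


_DOT_STYLE = {"vesicle": "color=black",
              "creation": "color=brown",
              "maturation": "color=blue"}


def write_dot(net: TrafficNetwork, path, positions=None) -> None:
    lines = ["digraph traffic {"]
    for k, node in enumerate(net.nodes):
        attrs = f'label="{_comp_str(node, net.N)}"'
        if positions is not None:
            attrs += f', pos="{positions[k][0]:.4f},{positions[k][1]:.4f}!"'
        lines.append(f"  n{node} [{attrs}];")
    for (a, b), js in sorted(net.vesicle_edges.items()):
        label = ",".join(_comp_str(j, net.N) for j in sorted(js))
        lines.append(f'  n{a} -> n{b} [{_DOT_STYLE["vesicle"]}, label="{label}"];')
    for a, b in sorted(net.creation_edges):
        lines.append(f'  n{a} -> n{b} [{_DOT_STYLE["creation"]}];')
    for a, b in sorted(net.maturation_edges.items()):
        lines.append(f'  n{a} -> n{b} [{_DOT_STYLE["maturation"]}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
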