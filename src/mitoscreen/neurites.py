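"""Neuronal morphology metrics from SWC reconstructions.

Reconstructed neurons arrive as standard 7-column SWC text (id, type, x,
y, z, radius, parent; parent -1 marks the soma/root).  Metrics follow the
polyline convention of reconstruction tools: edges are straight segments
between node coordinates, without radius or taper weighting.

* total length — sum of parent-child Euclidean segment lengths (um);
* terminal points — non-root nodes with no children;
* Sholl profile — for each radius r of a sphere centered at the soma, the
  number of segments whose endpoint distances from the soma straddle r
  (one endpoint < r <= the other); each segment counts at most once per
  sphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NeuronNode",
    "NeuronTree",
    "SwcFormatError",
    "read_swc",
    "write_swc",
    "total_length",
    "terminal_points",
    "sholl_profile",
    "neurite_metrics",
]


class SwcFormatError(ValueError):
    pass


@dataclass(frozen=True)
class NeuronNode:
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for the root


@dataclass
class NeuronTree:
    """A validated rooted tree of reconstruction nodes."""

    nodes: dict[int, NeuronNode]
    root_id: int
    children: dict[int, list[int]]

    @classmethod
    def from_nodes(cls, nodes: Sequence[NeuronNode]) -> "NeuronTree":
        by_id: dict[int, NeuronNode] = {}
        for n in nodes:
            if n.id in by_id:
                raise SwcFormatError(f"duplicate node id {n.id}")
            by_id[n.id] = n
        roots = [n.id for n in nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SwcFormatError(f"expected exactly one root, found ids {roots}")
        children: dict[int, list[int]] = {n.id: [] for n in nodes}
        for n in nodes:
            if n.parent_id == -1:
                continue
            if n.parent_id not in by_id:
                raise SwcFormatError(
                    f"node {n.id} references missing parent {n.parent_id}"
                )
            children[n.parent_id].append(n.id)
        # cycle/reachability check by traversal from the root
        seen = set()
        stack = [roots[0]]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise SwcFormatError(f"cycle detected at node {nid}")
            seen.add(nid)
            stack.extend(children[nid])
        if len(seen) != len(by_id):
            orphans = sorted(set(by_id) - seen)
            raise SwcFormatError(f"nodes unreachable from root: {orphans}")
        return cls(nodes=by_id, root_id=roots[0], children=children)

    @property
    def root(self) -> NeuronNode:
        return self.nodes[self.root_id]

    def coords(self, nid: int) -> np.ndarray:
        n = self.nodes[nid]
        return np.array([n.x, n.y, n.z])


def read_swc(path) -> NeuronTree:
    nodes: list[NeuronNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcFormatError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nodes.append(
                    NeuronNode(
                        id=int(parts[0]),
                        type_code=int(parts[1]),
                        x=float(parts[2]),
                        y=float(parts[3]),
                        z=float(parts[4]),
                        radius=float(parts[5]),
                        parent_id=int(parts[6]),
                    )
                )
            except ValueError as e:
                raise SwcFormatError(f"line {lineno}: {e}") from e
    if not nodes:
        raise SwcFormatError(f"{path}: no nodes")
    return NeuronTree.from_nodes(nodes)


def write_swc(tree: NeuronTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid in sorted(tree.nodes):
            n = tree.nodes[nid]
            fh.write(
                f"{n.id} {n.type_code} {n.x!r} {n.y!r} {n.z!r} {n.radius!r} {n.parent_id}\n"
            )


def total_length(tree: NeuronTree) -> float:
    """Total neurite length (um): sum of parent-child segment lengths."""
    return float(
        sum(
            np.linalg.norm(tree.coords(n.id) - tree.coords(n.parent_id))
            for n in tree.nodes.values()
            if n.parent_id != -1
        )
    )


def terminal_points(tree: NeuronTree, type_codes: set[int] | None = None) -> int:
    """Count non-root leaf nodes; optionally restrict to SWC type codes."""
    count = 0
    for nid, kids in tree.children.items():
        if nid == tree.root_id or kids:
            continue
        if type_codes is not None and tree.nodes[nid].type_code not in type_codes:
            continue
        count += 1
    return count


def sholl_profile(tree: NeuronTree, radii: Sequence[float]) -> list[int]:
    """Sholl intersection counts: per radius, segments whose endpoint
    distances from the soma straddle the sphere (d_near < r <= d_far)."""
    radii = list(radii)
    if any(r <= 0 for r in radii) or any(
        b <= a for a, b in zip(radii, radii[1:])
    ):
        raise ValueError("radii must be strictly increasing and > 0")
    soma = tree.coords(tree.root_id)
    dist = {nid: float(np.linalg.norm(tree.coords(nid) - soma)) for nid in tree.nodes}
    counts = []
    for r in radii:
        c = 0
        for n in tree.nodes.values():
            if n.parent_id == -1:
                continue
            d1, d2 = dist[n.parent_id], dist[n.id]
            lo, hi = (d1, d2) if d1 <= d2 else (d2, d1)
            if lo < r <= hi:
                c += 1
        counts.append(c)
    return counts


def neurite_metrics(tree: NeuronTree, sholl_radii: Sequence[float] | None = None) -> dict:
    out = {
        "total_length_um": total_length(tree),
        "n_terminals": terminal_points(tree),
    }
    if sholl_radii is not None:
        out["sholl_radii_um"] = list(sholl_radii)
        out["sholl_counts"] = sholl_profile(tree, sholl_radii)
    return out


def metrics_frame(trees: dict[str, NeuronTree], sholl_radii=None) -> pd.DataFrame:
    rows = []
    for name, tree in sorted(trees.items()):
        m = neurite_metrics(tree, sholl_radii)
        rows.append({"neuron": name, **{k: v for k, v in m.items() if not isinstance(v, list)}})
    return pd.DataFrame(rows)
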