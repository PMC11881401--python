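"""Format plumbing: TIFF stacks with spacing metadata, SWC graph export,
and sidecar YAML for generated data."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .tracing import VesselGraph

__all__ = ["write_stack", "read_stack", "write_swc", "write_graph_csv", "read_graph_csv"]


def write_stack(path: str | Path, stack: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a 3D stack as multi-page TIFF with (z, y, x) µm spacing in the
    ImageJ-style metadata plus a sidecar ``<name>.yaml``."""
    path = Path(path)
    z, y, x = (float(s) for s in spacing)
    tifffile.imwrite(
        path,
        np.asarray(stack, dtype=np.float32),
        imagej=True,
        resolution=(1.0 / x, 1.0 / y),
        metadata={"spacing": z, "unit": "um", "axes": "ZYX"},
    )
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump({"spacing_um_zyx": [z, y, x], "shape": list(stack.shape)}, fh)


def read_stack(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a stack written by :func:`write_stack`; spacing comes from the
    sidecar YAML when present, else defaults to 1 µm isotropic."""
    path = Path(path)
    stack = tifffile.imread(path).astype(np.float64)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    spacing = (1.0, 1.0, 1.0)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        spacing = tuple(float(v) for v in meta["spacing_um_zyx"])
    return stack, spacing


def write_graph_csv(graph: VesselGraph, nodes_path: str | Path, edges_path: str | Path) -> None:
    nodes, edges = graph.to_frames()
    nodes.to_csv(nodes_path, index=False)
    edges.to_csv(edges_path, index=False)


def read_graph_csv(nodes_path: str | Path, edges_path: str | Path) -> VesselGraph:
    return VesselGraph.from_frames(pd.read_csv(nodes_path), pd.read_csv(edges_path))


def write_swc(graph: VesselGraph, path: str | Path) -> None:
    """Export the centerline graph in SWC format (tracing-community
    standard).  Node type is fixed at 7 ("custom"); SWC is a forest, so the
    heavier edge at any node with multiple parents is kept and the rest are
    dropped (SWC cannot represent cycles)."""
    import networkx as nx

    g = graph.to_networkx()
    lines = ["# id type x y z radius parent"]
    parent = {}
    for comp in nx.connected_components(g):
        root = min(comp)
        for u, v in nx.bfs_edges(g, root):
            parent.setdefault(v, u)
        parent.setdefault(root, -1)
    for nid in range(graph.n_nodes):
        z, y, x = graph.positions[nid]
        p = parent.get(nid, -1)
        lines.append(
            f"{nid + 1} 7 {x:.3f} {y:.3f} {z:.3f} {graph.radii[nid]:.3f} "
            f"{p + 1 if p >= 0 else -1}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
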