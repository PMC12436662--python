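"""Shared helpers: truth-layout graphs and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from caq.network import SkeletonGraph


def graph_from_segments(
    segments, pixel_size_um: float = 0.1, samples_per_px: float = 1.0
) -> SkeletonGraph:
    """Build a SkeletonGraph directly from planted line segments.

    Each segment becomes one edge whose path is sampled at roughly one
    point per pixel, mimicking a traced pixel path without any image step.
    """
    nodes = []
    edges = []
    paths = {}
    for i, (p0, p1) in enumerate(segments):
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        length = float(np.hypot(*(p1 - p0)))
        n = max(int(round(length * samples_per_px)), 2)
        t = np.linspace(0.0, 1.0, n)
        path = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        a, b = 2 * i, 2 * i + 1
        nodes.append({"node_id": a, "y": p0[0], "x": p0[1], "degree": 1, "kind": "endpoint"})
        nodes.append({"node_id": b, "y": p1[0], "x": p1[1], "degree": 1, "kind": "endpoint"})
        edges.append({"edge_id": i, "node_a": a, "node_b": b,
                      "length_px": length, "length_um": length * pixel_size_um})
        paths[i] = path
    return SkeletonGraph(
        nodes=pd.DataFrame(nodes),
        edges=pd.DataFrame(edges),
        paths=paths,
        pixel_size_um=pixel_size_um,
    )


def brute_force_sholl(graph: SkeletonGraph, center, radii_um) -> np.ndarray:
    """Independent per-pixel-pair crossing enumerator (pure python loops)."""
    counts = np.zeros(len(radii_um), dtype=int)
    px = graph.pixel_size_um
    for path in graph.paths.values():
        dists = [
            ((p[0] - center[0]) ** 2 + (p[1] - center[1]) ** 2) ** 0.5 * px
            for p in path
        ]
        for k, r in enumerate(radii_um):
            c = 0
            for d0, d1 in zip(dists[:-1], dists[1:]):
                if (d0 < r) != (d1 < r):
                    c += 1
            counts[k] += c
    return counts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
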