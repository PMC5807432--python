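"""Functional ROI labels on source meshes and label time-course extraction.

A functional label is grown from a condition-independent activation map: the
peak vertex within an anatomical constraint, together with the connected
region of neighbors (also within the constraint) whose activation reaches at
least a fraction (default 60%) of the peak.  "Neighboring" is read as spatial
contiguity with the peak: suprathreshold vertices disconnected from the peak
are not part of the label.

Label time courses are the per-trial mean over label vertices after sign
alignment: source orientations can flip across a sulcal wall, so each
vertex's series is negated when it correlates negatively with the peak
vertex's series, preserving signal rather than letting opposite-polarity
sources cancel.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .synth import SourceMesh


@dataclass(frozen=True)
class FunctionalLabel:
    """A grown label: peak vertex plus its connected >=threshold neighbors."""

    vertices: tuple[int, ...]  # sorted
    peak_vertex: int
    fraction_threshold: float
    n_mesh_vertices: int

    def __post_init__(self):
        if self.peak_vertex not in self.vertices:
            raise ValueError("peak vertex must belong to the label")


def grow_functional_label(mesh: SourceMesh, fraction: float = 0.60) -> FunctionalLabel:
    """Grow the connected >=fraction-of-peak region around the activation peak.

    The peak is the highest-activation vertex inside the anatomical mask
    (ties broken by lowest vertex index).  Membership requires being inside
    the mask, reaching ``fraction`` of the peak activation, and being
    connected to the peak through the mesh adjacency within those vertices.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    mask = set(int(v) for v in np.asarray(mesh.anatomical_mask).ravel())
    if not mask:
        raise ValueError("empty anatomical mask")
    act = mesh.activation
    peak = min(mask, key=lambda v: (-act[v], v))
    if act[peak] <= 0:
        raise ValueError("activation is zero everywhere inside the mask")
    threshold = fraction * act[peak]

    eligible = {v for v in mask if act[v] >= threshold}
    seen = {peak}
    queue = deque([peak])
    while queue:
        v = queue.popleft()
        for u in mesh.adjacency[v]:
            if u in eligible and u not in seen:
                seen.add(u)
                queue.append(u)
    return FunctionalLabel(
        vertices=tuple(sorted(seen)),
        peak_vertex=peak,
        fraction_threshold=fraction,
        n_mesh_vertices=mesh.n_vertices,
    )


def extract_label_timecourse(vertex_epochs: np.ndarray, label: FunctionalLabel) -> np.ndarray:
    """Sign-aligned mean over label vertices; input (trials, vertices, samples).

    Each vertex's series is flipped, if needed, so that it correlates
    non-negatively with the peak vertex's series (sign of the pooled inner
    product across all trials); the aligned series are then averaged.
    Returns an array of shape (trials, samples).
    """
    data = np.asarray(vertex_epochs, float)
    if data.ndim != 3:
        raise ValueError("vertex_epochs must be (trials, vertices, samples)")
    n_vertices = data.shape[1]
    missing = [v for v in label.vertices if v >= n_vertices]
    if missing:
        raise ValueError(f"label vertices missing from the data: {missing}")

    peak_series = data[:, label.peak_vertex, :]
    members = np.array(label.vertices, dtype=int)
    series = data[:, members, :]
    # pooled correlation sign against the peak, one sign per vertex
    inner = np.einsum("tvs,ts->v", series, peak_series)
    signs = np.where(inner < 0, -1.0, 1.0)
    return (series * signs[None, :, None]).mean(axis=1)


def label_to_dict(label: FunctionalLabel) -> dict:
    return {
        "vertices": list(map(int, label.vertices)),
        "peak_vertex": int(label.peak_vertex),
        "fraction_threshold": float(label.fraction_threshold),
        "n_mesh_vertices": int(label.n_mesh_vertices),
    }


def label_from_dict(d: dict) -> FunctionalLabel:
    return FunctionalLabel(
        vertices=tuple(int(v) for v in d["vertices"]),
        peak_vertex=int(d["peak_vertex"]),
        fraction_threshold=float(d["fraction_threshold"]),
        n_mesh_vertices=int(d["n_mesh_vertices"]),
    )
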