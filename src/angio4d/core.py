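"""Core domain types shared across the pipeline.

The central image container is :class:`Volume4D`, a spatio-temporal array in
``[X, Y, Z, T]`` axis order with anisotropic voxel spacing (mm) and a frame
duration (ms).  Synthetic subjects carry, next to the 4D signal, the binary
vessel mask and the per-voxel arterial transit time (ATT) that generated them.
Voxel indices are 0-based throughout; voxel *centers* sit at
``(i + 0.5) * spacing`` in mm and frame *centers* at ``(k + 0.5) *
frame_duration`` in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "Volume4D",
    "VesselTree",
    "SignalParams",
    "LabeledSubject",
    "DEFAULT_SPACING",
    "DEFAULT_FRAME_DURATION",
]

#: in-plane 1 mm, through-plane 1.5 mm — the acquisition grid this tool targets
DEFAULT_SPACING: tuple[float, float, float] = (1.0, 1.0, 1.5)
#: ms per dynamic frame
DEFAULT_FRAME_DURATION: float = 100.0


@dataclass
class Volume4D:
    """A spatio-temporal volume ``[X, Y, Z, T]`` with physical metadata.

    Parameters
    ----------
    data:
        4D float array, axis order ``X, Y, Z, T``.
    spacing:
        Voxel edge lengths in mm for the three spatial axes.
    frame_duration:
        Duration of one dynamic frame in ms.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    frame_duration: float = DEFAULT_FRAME_DURATION

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D expects a 4D [X,Y,Z,T] array, got shape {self.data.shape}")
        if self.data.shape[3] < 1:
            raise ValueError("Volume4D needs at least one frame")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive (ms)")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def frame_times(self) -> np.ndarray:
        """Frame-center times in ms: ``(k + 0.5) * frame_duration``."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return replace(self, data=data)


@dataclass
class VesselTree:
    """Centerline tree: nodes with mm positions, radii, and path length from root.

    ``nodes`` maps node id -> dict with keys ``position`` (3-vector, mm),
    ``radius`` (mm), ``path_length`` (mm from the root along the centerline).
    ``edges`` is a list of (parent_id, child_id) pairs; consecutive nodes of a
    segment are connected, so the tree is a connected acyclic polyline forest
    rooted at ``root``.
    """

    nodes: dict[int, dict[str, Any]]
    edges: list[tuple[int, int]]
    root: int

    def positions(self) -> np.ndarray:
        return np.array([self.nodes[i]["position"] for i in sorted(self.nodes)], dtype=float)

    def n_nodes(self) -> int:
        return len(self.nodes)

    def children(self, node_id: int) -> list[int]:
        return [c for p, c in self.edges if p == node_id]

    def leaves(self) -> list[int]:
        parents = {p for p, _ in self.edges}
        return [i for i in self.nodes if i not in parents]

    def validate(self) -> None:
        if self.root not in self.nodes:
            raise ValueError("root id missing from nodes")
        for p, c in self.edges:
            if self.nodes[c]["path_length"] <= self.nodes[p]["path_length"]:
                raise ValueError("child path_length must exceed parent path_length")
        for i, n in self.nodes.items():
            if n["radius"] <= 0:
                raise ValueError(f"node {i} has non-positive radius")
        # connectivity + acyclicity: reachable set from root must cover all nodes
        seen = {self.root}
        stack = [self.root]
        while stack:
            cur = stack.pop()
            for c in self.children(cur):
                if c in seen:
                    raise ValueError("cycle detected in vessel tree")
                seen.add(c)
                stack.append(c)
        if seen != set(self.nodes):
            raise ValueError("vessel tree is not connected from the root")


@dataclass
class SignalParams:
    """Physical parameters of the pulsed-ASL bolus-passage signal model.

    The labeled bolus reaches a voxel at its arterial transit time (ATT),
    stays for ``bolus_duration`` while relaxing with the longitudinal
    relaxation time of blood ``t1_blood``, and leaves. ``transit_speed``
    converts centerline path length to ATT. Amplitudes are in arbitrary
    signal units; the static tissue floor is ``background_level`` and
    measurement noise is zero-mean Gaussian with ``noise_sigma``.
    """

    amplitude: float = 1.0
    t1_blood: float = 1650.0  # ms, arterial blood at 3T
    bolus_duration: float = 700.0  # ms
    transit_speed: float = 0.05  # mm/ms, ~5 cm/s effective through the tree
    frame_duration: float = DEFAULT_FRAME_DURATION  # ms
    n_frames: int = 24
    noise_sigma: float = 0.05
    background_level: float = 0.02
    temporal_dispersion: float = 0.0  # frames of Gaussian blur; 0 = off

    def __post_init__(self) -> None:
        for name in ("amplitude", "t1_blood", "bolus_duration", "transit_speed", "frame_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.noise_sigma < 0 or self.background_level < 0:
            raise ValueError("noise_sigma and background_level must be non-negative")


@dataclass
class LabeledSubject:
    """One synthetic participant: 4D signal plus the truth that generated it."""

    volume: Volume4D
    truth_mask: np.ndarray  # binary [X,Y,Z]
    truth_att: np.ndarray  # ms, NaN outside the mask
    params: SignalParams = field(default_factory=SignalParams)
    seed: int = 0
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.truth_mask = np.asarray(self.truth_mask)
        self.truth_att = np.asarray(self.truth_att, dtype=float)
        if self.truth_mask.shape != self.volume.spatial_shape:
            raise ValueError("truth_mask dims must match the volume's spatial dims")
        if self.truth_att.shape != self.truth_mask.shape:
            raise ValueError("truth_att dims must match truth_mask dims")
        if not self.truth_mask.any():
            raise ValueError("truth_mask must contain at least one vessel voxel")
        on = self.truth_mask.astype(bool)
        if np.isnan(self.truth_att[on]).any():
            raise ValueError("truth_att must be defined on the mask support")
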