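"""Synthetic pulsed-ASL 4D MRA phantoms with known vessel truth.

Real dynamic-angiography cohorts cannot be redistributed, so this module is
the canonical test input for the whole pipeline: it grows tortuous branching
centerline trees, rasterizes them onto an anisotropic voxel grid, and plays a
bolus-passage signal model over them.  Every voxel of the result carries known
truth — the binary vessel mask and the arterial transit time (ATT) — so the
ground-truth generator, the networks, and the evaluation metrics can all be
checked against exact references.

Signal model per vessel voxel::

    s(t) = amplitude * exp(-t / t1_blood)   for att <= t < att + bolus_duration
    s(t) = 0                                otherwise

sampled at frame centers ``t = (k + 0.5) * frame_duration``.  Background
voxels hold a static tissue level; zero-mean Gaussian noise is added
everywhere.  The rectangular-window bolus with T1 decay is deliberately the
simplest model with the right level-crossing structure: a vessel time course
crosses any level strictly between baseline and peak exactly twice (wash-in
and wash-out), while static background crosses at most once.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    DEFAULT_SPACING,
    LabeledSubject,
    SignalParams,
    VesselTree,
    Volume4D,
)

__all__ = [
    "generate_vessel_tree",
    "rasterize_tree",
    "simulate_dynamics",
    "make_cohort",
    "tree_segment_counts",
]

DEFAULT_DIMS = (64, 64, 16)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 1.0, 0.0])


def _perturb_direction(direction: np.ndarray, max_turn: float, rng: np.random.Generator) -> np.ndarray:
    """Random small rotation of a unit vector, turn angle bounded by max_turn (rad)."""
    axis = rng.normal(size=3)
    axis -= axis.dot(direction) * direction
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return direction
    axis /= norm
    angle = rng.uniform(0.0, max_turn)
    return _unit(np.cos(angle) * direction + np.sin(angle) * axis)


def _rotate_about(direction: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    return _unit(
        direction * np.cos(angle)
        + np.cross(axis, direction) * np.sin(angle)
        + axis * axis.dot(direction) * (1 - np.cos(angle))
    )


def generate_vessel_tree(
    depth: int,
    branch_prob: float = 0.85,
    *,
    fov_mm: tuple[float, float, float] = (64.0, 64.0, 24.0),
    seed: int = 0,
    step_mm: float = 1.5,
    steps_per_segment: tuple[int, int] = (6, 12),
    max_turn: float = 0.3,
    branch_angle: float = 0.6,
    root_radius: float = 2.5,
    radius_taper: float = 0.72,
    margin_mm: float = 3.0,
) -> VesselTree:
    """Grow a tortuous branching centerline tree inside a field of view.

    Segments are random walks of ``step_mm`` steps with per-step turn angle
    bounded by ``max_turn``; at the end of each segment of generation
    ``g < depth`` the tree bifurcates with probability ``branch_prob`` into
    two children whose initial directions open by ``±branch_angle``.  Radius
    is constant along a segment and tapers by ``radius_taper`` per
    generation.  Deterministic for a fixed seed.

    With ``branch_prob=1`` and depth ``d`` the result is a complete binary
    tree of ``2**d - 1`` segments.
    """
    if depth < 1:
        raise ValueError("depth must be at least 1")
    if not 0.0 <= branch_prob <= 1.0:
        raise ValueError("branch_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fov = np.asarray(fov_mm, dtype=float)
    lo = np.full(3, margin_mm)
    hi = fov - margin_mm

    nodes: dict[int, dict] = {}
    edges: list[tuple[int, int]] = []
    next_id = 0

    def add_node(pos: np.ndarray, radius: float, path_length: float) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        nodes[nid] = {
            "position": np.clip(pos, lo, hi).copy(),
            "radius": float(radius),
            "path_length": float(path_length),
        }
        return nid

    # root enters through the low-Y face, roughly mid-plane
    start = np.array(
        [
            fov[0] * rng.uniform(0.35, 0.65),
            margin_mm,
            fov[2] * rng.uniform(0.4, 0.6),
        ]
    )
    start = np.clip(start, lo, hi)
    root = add_node(start, root_radius, 0.0)

    # stack of segments to grow: (start node id, direction, generation)
    stack = [(root, np.array([0.0, 1.0, 0.0]), 1)]
    while stack:
        node_id, direction, gen = stack.pop()
        radius = root_radius * radius_taper ** (gen - 1)
        n_steps = int(rng.integers(steps_per_segment[0], steps_per_segment[1] + 1))
        cur = node_id
        pos = nodes[node_id]["position"].copy()
        plen = nodes[node_id]["path_length"]
        for _ in range(n_steps):
            direction = _perturb_direction(direction, max_turn, rng)
            # steer back inside the margin box
            nxt = pos + direction * step_mm
            for ax in range(3):
                if nxt[ax] < lo[ax] or nxt[ax] > hi[ax]:
                    direction[ax] = -direction[ax]
            direction = _unit(direction)
            pos = pos + direction * step_mm
            pos = np.clip(pos, lo, hi)
            plen += step_mm
            new_id = add_node(pos, radius, plen)
            edges.append((cur, new_id))
            cur = new_id
        if gen < depth and rng.random() < branch_prob:
            axis = rng.normal(size=3)
            for sign in (1.0, -1.0):
                child_dir = _rotate_about(direction, axis, sign * branch_angle)
                stack.append((cur, child_dir, gen + 1))

    tree = VesselTree(nodes=nodes, edges=edges, root=root)
    tree.validate()
    return tree


def tree_segment_counts(tree: VesselTree) -> dict[str, int]:
    """Count segments, bifurcation nodes, and leaf tips of a centerline tree.

    A bifurcation is a node with two children; every segment ends at either a
    bifurcation or a leaf, so ``segments = bifurcations + leaves``.
    """
    n_children = {i: 0 for i in tree.nodes}
    for p, _ in tree.edges:
        n_children[p] += 1
    bif = sum(1 for i, c in n_children.items() if c == 2)
    leaves = sum(1 for i, c in n_children.items() if c == 0)
    return {"segments": bif + leaves, "bifurcations": bif, "leaves": leaves}


def _edge_radius(tree: VesselTree, parent: int, child: int) -> float:
    return min(tree.nodes[parent]["radius"], tree.nodes[child]["radius"])


def rasterize_tree(
    tree: VesselTree,
    dims: tuple[int, int, int] = DEFAULT_DIMS,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    transit_speed: float = 0.05,
    att_offset: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize a centerline tree into a binary mask and an ATT map (ms).

    A voxel is vessel iff its center lies within the edge radius of some
    centerline segment (Euclidean distance in mm, honoring anisotropic
    spacing), or it contains a centerline point (so sub-voxel radii still
    leave an unbroken nearest-voxel chain).  The ATT at a vessel voxel is
    ``att_offset + path_length / transit_speed`` of the nearest centerline
    point — the offset models the labeling-plane-to-volume transit delay of
    pulsed ASL, so even the tree root has a nonzero arrival time; outside
    the mask the ATT map is NaN.
    """
    if any(d < 8 for d in dims):
        raise ValueError("grid dims must be at least 8 per axis")
    sp = np.asarray(spacing, dtype=float)
    dims = tuple(int(d) for d in dims)
    best_dist = np.full(dims, np.inf, dtype=float)
    best_att = np.full(dims, np.nan, dtype=float)
    mask = np.zeros(dims, dtype=bool)

    if tree is None or not tree.edges:
        warnings.warn("vessel tree has no segments; returning an empty mask")
        return mask.astype(np.uint8), best_att

    half_diag = 0.5 * float(np.linalg.norm(sp))
    fov = np.asarray(dims) * sp
    any_inside = False

    for parent, child in tree.edges:
        a = np.asarray(tree.nodes[parent]["position"], dtype=float)
        b = np.asarray(tree.nodes[child]["position"], dtype=float)
        r = _edge_radius(tree, parent, child)
        t0 = att_offset + tree.nodes[parent]["path_length"] / transit_speed
        t1 = att_offset + tree.nodes[child]["path_length"] / transit_speed
        margin = max(r, half_diag) + float(sp.max())
        bb_lo = np.minimum(a, b) - margin
        bb_hi = np.maximum(a, b) + margin
        if (bb_hi < 0).any() or (bb_lo > fov).any():
            continue
        i_lo = np.maximum(np.floor(bb_lo / sp - 0.5).astype(int), 0)
        i_hi = np.minimum(np.ceil(bb_hi / sp - 0.5).astype(int) + 1, dims)
        if (i_lo >= i_hi).any():
            continue
        any_inside = True
        grids = np.meshgrid(
            *[(np.arange(i_lo[ax], i_hi[ax]) + 0.5) * sp[ax] for ax in range(3)],
            indexing="ij",
        )
        pts = np.stack(grids, axis=-1)  # (nx,ny,nz,3) voxel centers in mm
        ab = b - a
        ab2 = float(ab.dot(ab))
        if ab2 == 0.0:
            s = np.zeros(pts.shape[:-1])
        else:
            s = np.clip(np.einsum("...k,k->...", pts - a, ab) / ab2, 0.0, 1.0)
        closest = a + s[..., None] * ab
        dist = np.linalg.norm(pts - closest, axis=-1)
        att = t0 + s * (t1 - t0)
        sl = tuple(slice(i_lo[ax], i_hi[ax]) for ax in range(3))
        upd = dist < best_dist[sl]
        best_dist[sl] = np.where(upd, dist, best_dist[sl])
        best_att[sl] = np.where(upd, att, best_att[sl])
        mask[sl] |= dist <= r
        # nearest-voxel chain: the voxels containing the segment endpoints and
        # finely sampled interior points are always labeled
        n_samp = max(2, int(np.ceil(np.linalg.norm(ab) / (0.25 * sp.min()))) + 1)
        samp_s = np.linspace(0.0, 1.0, n_samp)
        samp = a + samp_s[:, None] * ab
        idx = np.floor(samp / sp).astype(int)
        inside = ((idx >= 0) & (idx < np.asarray(dims))).all(axis=1)
        idx = idx[inside]
        if len(idx):
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    if not any_inside or not mask.any():
        warnings.warn("vessel tree lies outside the grid; mask is empty")
        return np.zeros(dims, dtype=np.uint8), np.full(dims, np.nan)

    att_out = np.where(mask, best_att, np.nan)
    return mask.astype(np.uint8), att_out


def simulate_dynamics(
    mask: np.ndarray,
    att_truth: np.ndarray,
    params: SignalParams,
    seed: int = 0,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> Volume4D:
    """Play the bolus-passage signal model over a rasterized phantom.

    Vessel voxels follow the rectangular-window T1-decay pulse delayed by
    their ATT; background voxels hold ``background_level``; zero-mean
    Gaussian noise with ``noise_sigma`` is added everywhere.  Seeded and
    deterministic.
    """
    mask = np.asarray(mask).astype(bool)
    att = np.asarray(att_truth, dtype=float)
    if mask.shape != att.shape:
        raise ValueError("mask and att_truth must share dims")
    rng = np.random.default_rng(seed)
    t = (np.arange(params.n_frames) + 0.5) * params.frame_duration  # frame centers, ms

    data = np.full(mask.shape + (params.n_frames,), params.background_level, dtype=np.float32)
    att_v = att[mask][:, None]
    in_window = (t[None, :] >= att_v) & (t[None, :] < att_v + params.bolus_duration)
    signal = params.amplitude * np.exp(-t[None, :] / params.t1_blood) * in_window
    data[mask] = signal.astype(np.float32)

    if params.temporal_dispersion > 0:
        from scipy.ndimage import gaussian_filter1d

        data = gaussian_filter1d(data, params.temporal_dispersion, axis=-1, mode="nearest")

    if params.noise_sigma > 0:
        data = data + rng.normal(0.0, params.noise_sigma, size=data.shape).astype(np.float32)

    return Volume4D(data=data, spacing=spacing, frame_duration=params.frame_duration)


def make_cohort(
    n_subjects: int,
    dims: tuple[int, int, int] = DEFAULT_DIMS,
    params: SignalParams | None = None,
    seed: int = 0,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    tree_depth: int = 4,
    branch_prob: float = 0.85,
) -> list[LabeledSubject]:
    """Generate a cohort of synthetic participants with derived per-subject seeds."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    params = params or SignalParams()
    fov = tuple(float(d * s) for d, s in zip(dims, spacing))
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_subjects) % (2**31)
    subjects = []
    for i in range(n_subjects):
        tree_seed = int(child_seeds[2 * i])
        noise_seed = int(child_seeds[2 * i + 1])
        tree = generate_vessel_tree(tree_depth, branch_prob, fov_mm=fov, seed=tree_seed)
        mask, att = rasterize_tree(tree, dims, spacing, transit_speed=params.transit_speed)
        volume = simulate_dynamics(mask, att, params, seed=noise_seed, spacing=spacing)
        subjects.append(
            LabeledSubject(
                volume=volume,
                truth_mask=mask,
                truth_att=att,
                params=params,
                seed=tree_seed,
                subject_id=f"sub-{i:02d}",
            )
        )
    return subjects
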