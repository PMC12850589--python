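"""Vascular segmentation evaluation: overlap, topology, distance, tolerance,
graph, and dynamics-binned metrics.

All metrics are computed per subject on the restitched full-volume masks:

* binary Dice and centerline Dice (clDice: the harmonic mean of the
  topology precision — fraction of the prediction's skeleton inside the
  truth — and topology sensitivity — fraction of the truth's skeleton
  inside the prediction);
* the symmetric Hausdorff distance between mask voxel sets;
* confusion-matrix scores (sensitivity, specificity, accuracy, precision)
  with a configurable voxel tolerance, realized by morphological dilation of
  the reference set before mismatches are counted;
* skeleton-graph statistics (total centerline length in mm, branch-point
  and endpoint counts) after false-positive removal, isotropic resampling,
  and 3D thinning;
* SNR and arterial-transit-time (ATT) maps with sensitivity binned by them,
  to quantify where in the dynamic range a model loses vessels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .core import Volume4D
from .preprocess import tmip

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "dice_binary",
    "cl_dice",
    "hausdorff",
    "tolerant_confusion",
    "graph_metrics",
    "snr_map",
    "att_map",
    "binned_sensitivity",
    "evaluate_subject",
    "summarize_cohort",
    "SNR_BINS",
    "ATT_BINS_MS",
]

# half-open bin edges reproducing the integer-labelled ranges 1-10, 11-20, >=21
SNR_BINS: tuple[tuple[float, float], ...] = ((1.0, 11.0), (11.0, 21.0), (21.0, np.inf))
# ms; 100-400, 500-800, >=900 on a 100 ms frame grid
ATT_BINS_MS: tuple[tuple[float, float], ...] = ((100.0, 500.0), (500.0, 900.0), (900.0, np.inf))


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    tolerance: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else np.nan

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else np.nan


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def dice_binary(pred: np.ndarray, gt: np.ndarray) -> float:
    """Binary Dice overlap 2|P∩G| / (|P|+|G|); 1.0 when both masks are empty."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def _skeleton(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    return skeletonize(mask.astype(np.uint8)).astype(bool)


def cl_dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Centerline Dice: harmonic mean of skeleton precision and sensitivity."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError("mask shapes differ")
    if not p.any() and not g.any():
        return 1.0
    sp, sg = _skeleton(p), _skeleton(g)
    if not sp.any() or not sg.any():
        return 0.0
    tprec = (sp & g).sum() / sp.sum()
    tsens = (sg & p).sum() / sg.sum()
    if tprec + tsens == 0:
        return 0.0
    return float(2.0 * tprec * tsens / (tprec + tsens))


def hausdorff(pred: np.ndarray, gt: np.ndarray, spacing=None) -> float:
    """Symmetric Hausdorff distance between mask voxel sets.

    Euclidean on the index grid by default; pass ``spacing`` for distances
    in mm on the anisotropic grid.
    """
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError("mask shapes differ")
    if not p.any() or not g.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    scale = np.ones(p.ndim) if spacing is None else np.asarray(spacing, dtype=float)
    pa = np.argwhere(p) * scale
    ga = np.argwhere(g) * scale
    d_pg = cKDTree(ga).query(pa, k=1)[0].max()
    d_gp = cKDTree(pa).query(ga, k=1)[0].max()
    return float(max(d_pg, d_gp))


def _dilate(mask: np.ndarray, iterations: int) -> np.ndarray:
    if iterations <= 0:
        return mask
    struct = np.ones((3,) * mask.ndim, dtype=bool)  # full 26-neighborhood
    return ndimage.binary_dilation(mask, structure=struct, iterations=iterations)


def tolerant_confusion(pred: np.ndarray, gt: np.ndarray, tolerance: int = 1) -> ConfusionCounts:
    """Confusion counts with a voxel tolerance.

    A truth voxel counts as found if the prediction reaches within
    ``tolerance`` voxels of it (26-neighborhood dilation), and a predicted
    voxel counts as correct if it lies within ``tolerance`` of the truth.
    ``tolerance=0`` reduces to the strict voxelwise confusion matrix.
    """
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError("mask shapes differ")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    total = p.size
    fn = int((g & ~_dilate(p, tolerance)).sum())
    tp = int(g.sum()) - fn
    fp = int((p & ~_dilate(g, tolerance)).sum())
    tn = total - int(g.sum()) - fp
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, tolerance=tolerance)


def _resample_to_isotropic(mask: np.ndarray, spacing) -> tuple[np.ndarray, float]:
    """Upsample the coarse axes (nearest neighbor) to the finest spacing."""
    sp = np.asarray(spacing, dtype=float)
    iso = sp.min()
    zoom = sp / iso
    if np.allclose(zoom, 1.0):
        return mask.astype(bool), float(iso)
    out = ndimage.zoom(mask.astype(np.uint8), zoom, order=0)
    return out.astype(bool), float(iso)


def _skeleton_graph(skel: np.ndarray, voxel_mm: float) -> nx.Graph:
    """Minimum-spanning forest over 26-adjacent skeleton voxels (mm edge weights)."""
    coords = np.argwhere(skel)
    graph = nx.Graph()
    for c in coords:
        graph.add_node(tuple(c))
    if len(coords) == 0:
        return graph
    tree = cKDTree(coords)
    # 26-neighbors are within sqrt(3) index distance
    pairs = tree.query_pairs(np.sqrt(3) + 1e-6)
    for i, j in pairs:
        a, b = coords[i], coords[j]
        graph.add_edge(tuple(a), tuple(b), weight=float(np.linalg.norm((a - b) * voxel_mm)))
    # spanning forest removes the spurious triangle chords of diagonal steps
    return nx.minimum_spanning_tree(graph, weight="weight")


def graph_metrics(
    pred: np.ndarray,
    gt: np.ndarray,
    spacing=(1.0, 1.0, 1.5),
    threshold: float = 0.5,
    skeletonize_first: bool = False,
) -> dict[str, float]:
    """Skeleton-graph statistics of a prediction, conditioned on the truth.

    Pipeline: remove false positives by multiplying with the binary ground
    truth, binarize at ``threshold``, resample to an isotropic grid
    (upsampling the slice axis to the in-plane resolution), thin to a 3D
    skeleton, and build the centerline graph.  Returns total length (mm,
    sum of spanning-forest edge lengths), the number of branch points
    (clusters of adjacent degree >= 3 skeleton voxels count once), and the
    number of endpoints (degree-1 voxels).

    ``skeletonize_first=True`` thins before resampling instead; thinness is
    not preserved by the resampling, so the default order is
    resample-then-skeletonize.
    """
    p = np.asarray(pred, dtype=float)
    g = _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError("mask shapes differ")
    masked = (p * g) >= threshold
    if not masked.any():
        warnings.warn("no predicted vessel voxels after FP removal; graph metrics are zero")
        return {"total_length_mm": 0.0, "n_branches": 0, "n_endpoints": 0}
    if skeletonize_first:
        skel = _skeleton(masked)
        iso_skel, iso = _resample_to_isotropic(skel, spacing)
    else:
        iso_mask, iso = _resample_to_isotropic(masked, spacing)
        iso_skel = _skeleton(iso_mask)
    forest = _skeleton_graph(iso_skel, iso)
    total_len = float(sum(d["weight"] for _, _, d in forest.edges(data=True)))
    degrees = dict(forest.degree())
    endpoints = [n for n, d in degrees.items() if d == 1]
    branch_voxels = [n for n, d in degrees.items() if d >= 3]
    # adjacent branch voxels (thick junctions) collapse to a single branch point
    branch_graph = nx.Graph()
    branch_graph.add_nodes_from(branch_voxels)
    bset = set(branch_voxels)
    for n in branch_voxels:
        for m in forest.neighbors(n):
            if m in bset:
                branch_graph.add_edge(n, m)
    n_branches = nx.number_connected_components(branch_graph)
    return {
        "total_length_mm": total_len,
        "n_branches": int(n_branches),
        "n_endpoints": len(endpoints),
    }


def snr_map(
    tmip_vol: np.ndarray,
    background_roi: np.ndarray,
    noise_sigma: float | None = None,
) -> np.ndarray:
    """Voxelwise SNR: tMIP signal divided by the background noise std.

    Pass ``noise_sigma`` measured on the *dynamic* background samples when
    available (the std of the projected tMIP underestimates the frame noise,
    because a maximum over frames compresses the noise distribution);
    otherwise the std of the tMIP over the ROI is used.
    """
    roi = _as_bool(background_roi)
    if not roi.any():
        raise ValueError("background ROI is empty")
    sigma = float(np.std(tmip_vol[roi])) if noise_sigma is None else float(noise_sigma)
    if sigma == 0:
        raise ValueError("background ROI has zero variance; SNR undefined")
    return np.asarray(tmip_vol, dtype=float) / sigma


def att_map(volume: Volume4D, background_roi: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Bolus-arrival map: first frame exceeding ``k`` background noise stds.

    Returns ms on a 1-based frame convention (arrival in the first frame
    maps to one frame duration); voxels never exceeding the threshold are
    NaN.
    """
    roi = _as_bool(background_roi)
    if not roi.any():
        raise ValueError("background ROI is empty")
    sigma = float(np.std(volume.data[roi]))
    if sigma == 0:
        raise ValueError("background ROI has zero variance; ATT undefined")
    above = volume.data > k * sigma
    any_above = above.any(axis=-1)
    first = above.argmax(axis=-1)
    att = (first + 1.0) * volume.frame_duration
    return np.where(any_above, att, np.nan)


def binned_sensitivity(
    pred: np.ndarray,
    gt: np.ndarray,
    value_map: np.ndarray,
    bins: tuple[tuple[float, float], ...],
    tolerance: int = 1,
) -> list[float]:
    """Sensitivity restricted to truth voxels whose map value falls in each bin.

    Bins are half-open ``[low, high)``; empty bins report NaN.  The
    prediction is dilated by ``tolerance`` voxels before the hit test, the
    same relaxation used by the global confusion scores.
    """
    p, g = _as_bool(pred), _as_bool(gt)
    vm = np.asarray(value_map, dtype=float)
    hit = _dilate(p, tolerance)
    out = []
    for lo, hi in bins:
        sel = g & (vm >= lo) & (vm < hi) & np.isfinite(vm)
        n = int(sel.sum())
        out.append(float((hit & sel).sum() / n) if n else float("nan"))
    return out


@dataclass
class MetricsReport:
    """Per-subject metric values, serializable to a flat CSV/JSON row."""

    subject_id: str
    values: dict[str, float] = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.subject_id)


def evaluate_subject(
    pred: np.ndarray,
    gt: np.ndarray,
    volume: Volume4D,
    background_roi: np.ndarray,
    subject_id: str = "subject",
    tolerance: int = 1,
    spacing=None,
) -> MetricsReport:
    """Aggregate every metric for one subject into a single report."""
    spacing = spacing if spacing is not None else volume.spacing
    conf = tolerant_confusion(pred, gt, tolerance=tolerance)
    graph = graph_metrics(pred, gt, spacing=spacing)
    proj = tmip(volume)
    snr = snr_map(proj, background_roi, noise_sigma=float(np.std(volume.data[_as_bool(background_roi)])))
    att = att_map(volume, background_roi)
    snr_bins = binned_sensitivity(pred, gt, snr, SNR_BINS, tolerance=tolerance)
    att_bins = binned_sensitivity(pred, gt, att, ATT_BINS_MS, tolerance=tolerance)
    values = {
        "dsc": dice_binary(pred, gt),
        "cl_dice": cl_dice(pred, gt),
        "hausdorff": hausdorff(pred, gt) if _as_bool(pred).any() and _as_bool(gt).any() else np.nan,
        "sensitivity": conf.sensitivity,
        "specificity": conf.specificity,
        "accuracy": conf.accuracy,
        "precision": conf.precision,
        "total_length_mm": graph["total_length_mm"],
        "n_branches": graph["n_branches"],
        "n_endpoints": graph["n_endpoints"],
    }
    for (lo, hi), v in zip(SNR_BINS, snr_bins):
        hi_label = "inf" if not np.isfinite(hi) else f"{hi - 1:g}"
        values[f"sens_snr_{lo:g}_{hi_label}"] = v
    for (lo, hi), v in zip(ATT_BINS_MS, att_bins):
        hi_label = "inf" if not np.isfinite(hi) else f"{hi - 100:g}"
        values[f"sens_att_{lo:g}_{hi_label}"] = v
    return MetricsReport(subject_id=subject_id, values=values)


def summarize_cohort(reports: list[MetricsReport]) -> pd.DataFrame:
    """Per-subject table plus cohort mean and std rows."""
    df = pd.DataFrame([r.to_series() for r in reports])
    df.loc["mean"] = df.mean()
    df.loc["std"] = df.std(ddof=0)
    return df
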