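"""Segmentation-quality metrics: Dice overlap and Hausdorff boundary distance.

Conventions: the reference set ``M`` is the expert/ground-truth region, the
predicted set ``N`` the model's.  The Dice similarity coefficient
``DSC = 2|M ∩ N| / (|M| + |N|)`` is computed on filled pixel regions; the
Hausdorff distance ``HD(M, N) = max(h(M, N), h(N, M))`` with
``h(A, B) = max_{a in A} min_{b in B} ||a - b||`` is computed on boundary
pixels (foreground pixels with at least one non-foreground 4-neighbour),
which is the standard surface-distance practice.  Distances are Euclidean
and reported in pixel units; pass ``pixel_spacing`` to convert to mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial.distance import cdist

__all__ = [
    "SegMetrics",
    "dice",
    "directed_hausdorff",
    "hausdorff",
    "boundary_pixels",
    "evaluate_segmentation",
]


@dataclass
class SegMetrics:
    """Dice and Hausdorff results for one prediction/reference pair."""

    dsc: float
    hd: float
    hd_forward: float  # h(reference, prediction)
    hd_backward: float  # h(prediction, reference)
    per_class: dict[int, float] | None = None
    macro_dsc: float | None = None


def _as_point_set(points) -> set[tuple[int, int]]:
    if isinstance(points, np.ndarray):
        if points.size == 0:
            return set()
        if points.ndim != 2 or points.shape[1] != 2:
            raise ValueError("point arrays must have shape (k, 2)")
        return {(int(r), int(c)) for r, c in points}
    return {(int(r), int(c)) for r, c in points}


def dice(m, n) -> float:
    """Dice similarity coefficient between two pixel sets, in [0, 1].

    1 exactly when the sets are equal (and non-empty), 0 exactly when they
    are disjoint.  Both sets empty is undefined (0/0) and raises.
    """
    ms, ns = _as_point_set(m), _as_point_set(n)
    if not ms and not ns:
        raise ValueError("Dice is undefined when both sets are empty")
    return 2.0 * len(ms & ns) / (len(ms) + len(ns))


def _points_array(points) -> np.ndarray:
    pts = np.asarray(sorted(_as_point_set(points)), dtype=np.float64)
    return pts


def directed_hausdorff(a, b) -> float:
    """Directed Hausdorff distance h(A, B) = max_a min_b ||a - b||.

    Exact (no approximation); asymmetric in general.  Raises on empty input.
    """
    pa, pb = _points_array(a), _points_array(b)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("directed Hausdorff distance requires non-empty sets")
    return float(cdist(pa, pb).min(axis=1).max())


def hausdorff(m, n) -> float:
    """Symmetric Hausdorff distance max(h(M, N), h(N, M)); 0 iff M == N."""
    return max(directed_hausdorff(m, n), directed_hausdorff(n, m))


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def boundary_pixels(foreground: np.ndarray) -> np.ndarray:
    """Coordinates (k, 2) of foreground pixels with a non-foreground 4-neighbour.

    Pixels on the image border count as boundary (the outside is background).
    """
    fg = np.asarray(foreground, dtype=bool)
    interior = binary_erosion(fg, structure=_CROSS, border_value=0)
    return np.argwhere(fg & ~interior)


def evaluate_segmentation(
    pred: np.ndarray,
    ref: np.ndarray,
    mode: str = "foreground",
    pixel_spacing: float | None = None,
) -> SegMetrics:
    """Score a predicted label mask against a reference label mask.

    ``foreground`` mode treats the gland (classes 1 and 2 merged) as the
    region of interest: Dice on the filled regions, Hausdorff on their
    boundary pixel sets.  ``per_class`` mode additionally reports a Dice per
    class plus the macro average (classes absent from both masks are
    skipped).  Raises if mask shapes differ or the reference foreground is
    empty.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    if mode not in ("foreground", "per_class"):
        raise ValueError(f"unknown mode {mode!r}")

    ref_fg = ref > 0
    pred_fg = pred > 0
    if not ref_fg.any():
        raise ValueError("reference foreground is empty")

    inter = int(np.count_nonzero(ref_fg & pred_fg))
    dsc = 2.0 * inter / (int(ref_fg.sum()) + int(pred_fg.sum()))

    ref_b = boundary_pixels(ref_fg)
    if pred_fg.any():
        pred_b = boundary_pixels(pred_fg)
        hd_f = directed_hausdorff(ref_b, pred_b)
        hd_b = directed_hausdorff(pred_b, ref_b)
    else:
        hd_f = hd_b = float("inf")
    scale = pixel_spacing if pixel_spacing is not None else 1.0

    per_class = None
    macro = None
    if mode == "per_class":
        per_class = {}
        for cls in sorted(set(np.unique(ref)) | set(np.unique(pred))):
            a = ref == cls
            b = pred == cls
            if not a.any() and not b.any():
                continue
            per_class[int(cls)] = 2.0 * int(np.count_nonzero(a & b)) / (
                int(a.sum()) + int(b.sum())
            )
        macro = float(np.mean(list(per_class.values())))

    return SegMetrics(
        dsc=dsc,
        hd=max(hd_f, hd_b) * scale,
        hd_forward=hd_f * scale,
        hd_backward=hd_b * scale,
        per_class=per_class,
        macro_dsc=macro,
    )
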