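"""Segmentation losses and evaluation metrics.

Evaluation uses the two headline radiotherapy metrics:

* DSC, the Dice similarity coefficient ``2|A n B| / (|A| + |B|)`` between a
  predicted and a reference mask, computed per patient over the whole 3D
  volume.
* HD95, a robust Hausdorff variant: the mean of the two directed 95th
  percentile surface distances, ``0.5 * (P95_{z in S_B} d(z, S_A) +
  P95_{z in S_A} d(z, S_B))``, with surfaces taken as foreground voxels
  that have a 6-neighborhood background voxel and distances measured
  center-to-center in physical mm via an exact Euclidean distance
  transform.

Training uses the summed loss: soft Dice averaged over classes plus mean
voxelwise cross-entropy, both consuming the network's softmax
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, ShapeError
from .nd import functional as F
from .nd.tensor import Tensor
from .volume import Mask

Spacing = Tuple[float, float, float]

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# overlap and surface metrics (NumPy, evaluation side)
# ---------------------------------------------------------------------------

def dsc(a: np.ndarray | Mask, b: np.ndarray | Mask) -> float:
    """Dice similarity coefficient between two aligned binary masks."""
    a = a.data if isinstance(a, Mask) else np.asarray(a)
    b = b.data if isinstance(b, Mask) else np.asarray(b)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise EmptyMaskError("DSC undefined for two empty masks (0/0)")
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def extract_surface(mask: np.ndarray | Mask) -> np.ndarray:
    """Boolean array marking foreground voxels with a 6-neighbor background.

    Voxels outside the array count as background, so a foreground region
    touching the border contributes its border faces to the surface.
    """
    m = mask.data if isinstance(mask, Mask) else np.asarray(mask)
    m = m.astype(bool)
    if not m.any():
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(m, structure=_SIX_CONN, border_value=0)
    return m & ~interior


def _directed_p95(from_surface: np.ndarray, to_surface: np.ndarray,
                  spacing: Spacing) -> float:
    """95th percentile over ``from_surface`` voxels of the exact Euclidean
    mm distance to the nearest ``to_surface`` voxel."""
    dist_map = ndimage.distance_transform_edt(~to_surface, sampling=spacing)
    dists = dist_map[from_surface]
    return float(np.percentile(dists, 95.0))  # linear interpolation between order stats


def hd95(a: np.ndarray | Mask, b: np.ndarray | Mask,
         spacing_mm: Spacing | None = None, case_id: str = "") -> float:
    """Symmetrized 95th percentile Hausdorff distance in mm."""
    if spacing_mm is None:
        if isinstance(a, Mask):
            spacing_mm = a.spacing_mm
        else:
            raise ShapeError("hd95 requires spacing_mm when given raw arrays")
    a_arr = a.data if isinstance(a, Mask) else np.asarray(a)
    b_arr = b.data if isinstance(b, Mask) else np.asarray(b)
    if a_arr.shape != b_arr.shape:
        raise ShapeError(f"mask shapes differ: {a_arr.shape} vs {b_arr.shape}")
    tag = f" (case {case_id})" if case_id else ""
    if not a_arr.any() or not b_arr.any():
        raise EmptyMaskError(f"HD95 undefined for an empty mask{tag}")
    sa = extract_surface(a_arr)
    sb = extract_surface(b_arr)
    return 0.5 * (_directed_p95(sb, sa, spacing_mm) + _directed_p95(sa, sb, spacing_mm))


# ---------------------------------------------------------------------------
# losses (differentiable, on Tensors)
# ---------------------------------------------------------------------------

def one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    """(N,D,H,W) integer labels -> (N,C,D,H,W) float32 one-hot."""
    eye = np.eye(n_classes, dtype=np.float32)
    return np.moveaxis(eye[target.astype(np.int64)], -1, 1)


def dice_loss(probs: Tensor, target: np.ndarray, eps: float = 1e-5) -> Tensor:
    """1 - mean over classes of the soft Dice coefficient.

    ``probs``: (N,C,D,H,W) softmax output; ``target``: (N,D,H,W) labels.
    Per class c: ``(2 sum(p_c t_c) + eps) / (sum(p_c) + sum(t_c) + eps)``.
    """
    n_classes = probs.shape[1]
    t = Tensor(one_hot(target, n_classes))
    axes = (0, 2, 3, 4)
    inter = F.sum_(F.mul(probs, t), axis=axes)
    denom = F.add(F.sum_(probs, axis=axes), Tensor(one_hot(target, n_classes).sum(axis=axes)))
    # (2*inter + eps) / (denom + eps), done with a differentiable reciprocal
    num = F.add(F.scale(inter, 2.0), Tensor(np.full(n_classes, eps, np.float32)))
    den = F.add(denom, Tensor(np.full(n_classes, eps, np.float32)))
    dice_per_class = F.mul(num, _reciprocal(den))
    return F.add(Tensor(1.0), F.scale(F.mean_(dice_per_class), -1.0))


def _reciprocal(x: Tensor) -> Tensor:
    out_data = 1.0 / x.data

    def backward(g):
        x.accumulate(-g * out_data * out_data)

    return Tensor._make(out_data, (x,), backward)


def cross_entropy_loss(probs: Tensor, target: np.ndarray) -> Tensor:
    """Mean voxelwise cross-entropy, -mean log p(target class)."""
    n_classes = probs.shape[1]
    t = Tensor(one_hot(target, n_classes))
    logp = F.clipped_log(probs)
    picked = F.sum_(F.mul(logp, t), axis=1)  # (N,D,H,W)
    return F.scale(F.mean_(picked), -1.0)


def total_loss(probs: Tensor, target: np.ndarray) -> Tensor:
    """Summed training loss: average soft Dice loss + cross-entropy."""
    return F.add(dice_loss(probs, target), cross_entropy_loss(probs, target))


# ---------------------------------------------------------------------------
# case-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricsResult:
    case_id: str
    dsc: float
    hd95_mm: float


@dataclass
class MetricsSummary:
    results: List[MetricsResult]
    dsc_mean: float
    dsc_sd: float
    hd95_mean: float
    hd95_sd: float


def evaluate_cases(preds: Sequence[Mask], refs: Sequence[Mask],
                   case_ids: Sequence[str] | None = None) -> MetricsSummary:
    """Whole-volume DSC and HD95 per case plus mean and sample sd.

    The sample standard deviation uses ddof=1; for a single case it is
    reported as 0.0 by convention.
    """
    if len(preds) != len(refs):
        raise ShapeError(f"got {len(preds)} predictions for {len(refs)} references")
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(preds))]
    results = []
    for cid, p, r in zip(case_ids, preds, refs):
        results.append(MetricsResult(cid, dsc(p, r),
                                     hd95(p, r, r.spacing_mm, case_id=cid)))
    d = np.array([r.dsc for r in results])
    h = np.array([r.hd95_mm for r in results])
    sd = (float(d.std(ddof=1)), float(h.std(ddof=1))) if len(results) > 1 else (0.0, 0.0)
    return MetricsSummary(results, float(d.mean()), sd[0], float(h.mean()), sd[1])
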