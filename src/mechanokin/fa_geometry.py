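"""Focal-adhesion geometry and intensity quantification on segmented masks.

The cell body is segmented from an actin image by Otsu thresholding (largest
connected component), and its equivalent radius is r = sqrt(area / pi).
Segmented adhesion label masks are filtered by size (objects strictly larger
than 0.3 um^2 survive), located by the shortest distance between their
centroid and the cell edge (exact Euclidean distance transform), normalized
by r, and classified central when the normalized distance strictly exceeds
0.3.  Adhesion intensities are background-subtracted using a local annulus
around each object, excluding pixels outside the cell and inside other
adhesions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "CellMask",
    "ADHESION_COLUMNS",
    "segment_cell",
    "filter_adhesions",
    "classify_adhesions",
    "adhesion_intensity",
    "synthetic_cell_fixture",
]

ADHESION_COLUMNS = [
    "fa_id", "area_um2", "centroid_row", "centroid_col",
    "dist_um", "dist_norm", "class", "flagged",
]

#: Normalized edge distance above which an adhesion counts as central.
CENTRAL_DISTANCE_FRACTION = 0.3
#: Minimum adhesion area (um^2), strict lower bound.
MIN_ADHESION_AREA_UM2 = 0.3


@dataclass(frozen=True)
class CellMask:
    """Binary cell-body mask with its physical pixel size."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2

    @property
    def equivalent_radius_um(self) -> float:
        """r = sqrt(area / pi)."""
        return math.sqrt(self.area_um2 / math.pi)


def segment_cell(actin_image: np.ndarray, pixel_size_um: float = 1.0) -> CellMask:
    """Otsu-threshold the actin image and keep the largest component."""
    img = np.asarray(actin_image)
    if img.max() == img.min():
        raise ValueError("constant image cannot be thresholded")
    thresh = threshold_otsu(img)
    binary = img > thresh
    labels = cc_label(binary)
    if labels.max() == 0:
        raise ValueError("no foreground after thresholding")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return CellMask(labels == int(np.argmax(sizes)), pixel_size_um)


def filter_adhesions(
    label_mask: np.ndarray,
    pixel_size_um: float = 1.0,
    min_area_um2: float = MIN_ADHESION_AREA_UM2,
) -> np.ndarray:
    """Drop labeled objects not strictly larger than ``min_area_um2``.

    Labels of survivors are preserved; the returned mask has the same dtype.
    """
    labels = np.asarray(label_mask)
    if labels.min() < 0:
        raise ValueError("labels must be non-negative integers")
    counts = np.bincount(labels.ravel())
    areas = counts * pixel_size_um**2
    keep = np.zeros_like(counts, dtype=bool)
    # strict "larger than", robust to float rounding at the exact threshold
    keep[1:] = areas[1:] > min_area_um2 * (1 + 1e-9)
    out = np.where(keep[labels], labels, 0)
    return out.astype(labels.dtype)


def classify_adhesions(
    label_mask: np.ndarray,
    cell: CellMask,
    intensity_image: np.ndarray | None = None,
) -> pd.DataFrame:
    """Edge distance, normalized distance and central/peripheral class per object.

    The distance to the cell edge is the exact Euclidean distance transform
    of the cell mask evaluated (bilinearly) at each object's centroid --
    intensity-weighted when an intensity image is supplied, binary otherwise.
    Central means normalized distance strictly above 0.3.  Objects whose
    centroid falls outside the cell are flagged with distance 0.
    """
    labels = np.asarray(label_mask)
    ids = [i for i in np.unique(labels) if i != 0]
    dist = ndi.distance_transform_edt(cell.mask) * cell.pixel_size_um
    r = cell.equivalent_radius_um

    rows = []
    for i in ids:
        obj = labels == i
        if intensity_image is not None:
            wsum = float(np.asarray(intensity_image, dtype=float)[obj].sum())
            if wsum > 0:
                rr, cc = np.nonzero(obj)
                wts = np.asarray(intensity_image, dtype=float)[rr, cc] / wsum
                cr, ccol = float((rr * wts).sum()), float((cc * wts).sum())
            else:
                cr, ccol = ndi.center_of_mass(obj)
        else:
            cr, ccol = ndi.center_of_mass(obj)
        inside = cell.mask[int(round(cr)), int(round(ccol))]
        d = float(
            ndi.map_coordinates(dist, [[cr], [ccol]], order=1, mode="nearest")[0]
        ) if inside else 0.0
        d_norm = d / r
        rows.append(
            {
                "fa_id": int(i),
                "area_um2": float(obj.sum()) * cell.pixel_size_um**2,
                "centroid_row": cr,
                "centroid_col": ccol,
                "dist_um": d,
                "dist_norm": d_norm,
                "class": "central"
                if d_norm > CENTRAL_DISTANCE_FRACTION
                else "peripheral",
                "flagged": not bool(inside),
            }
        )
    return pd.DataFrame(rows, columns=ADHESION_COLUMNS)


def adhesion_intensity(
    label_mask: np.ndarray,
    intensity_image: np.ndarray,
    cell: CellMask,
    annulus_px: int = 5,
) -> pd.DataFrame:
    """Mean background-subtracted intensity per adhesion.

    The local background of each object is the mean intensity in a dilation
    annulus of ``annulus_px`` pixels around it, restricted to pixels inside
    the cell and outside every adhesion.  If that annulus is empty the
    whole-cell non-adhesion mean is used and the record flagged.
    """
    labels = np.asarray(label_mask)
    img = np.asarray(intensity_image, dtype=float)
    any_adhesion = labels > 0
    cell_free = cell.mask & ~any_adhesion
    global_bg = float(img[cell_free].mean()) if cell_free.any() else 0.0
    struct = ndi.generate_binary_structure(2, 1)

    rows = []
    for i in (j for j in np.unique(labels) if j != 0):
        obj = labels == i
        ring = ndi.binary_dilation(obj, struct, iterations=annulus_px) & ~obj
        ring &= cell_free
        fallback = not ring.any()
        bg = global_bg if fallback else float(img[ring].mean())
        rows.append(
            {
                "fa_id": int(i),
                "intensity_bgsub": float(img[obj].mean()) - bg,
                "background": bg,
                "flagged": fallback,
            }
        )
    return pd.DataFrame(rows, columns=["fa_id", "intensity_bgsub", "background", "flagged"])


def synthetic_cell_fixture(
    shape: tuple[int, int] = (256, 256),
    n_adhesions: int = 8,
    central_fraction: float = 0.5,
    seed: int = 0,
    pixel_size_um: float = 0.1,
    adhesion_amplitude: float = 100.0,
):
    """Synthetic disk cell with planted elliptical adhesions.

    Central adhesions are planted at normalized edge distances in
    (0.35, 0.85), peripheral ones in (0.05, 0.25), at random angles.
    Returns (actin_image, label_mask, intensity_image, truth) where truth is
    a DataFrame of planted normalized distances, classes and amplitudes.
    """
    if not (0 <= central_fraction <= 1):
        raise ValueError("central_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    center = (h // 2, w // 2)
    cell_r_px = int(0.42 * min(h, w))

    actin = np.full(shape, 10.0)
    rr, cc = draw_disk(center, cell_r_px, shape=shape)
    actin[rr, cc] = 200.0
    actin += rng.normal(0, 2.0, size=shape)

    labels = np.zeros(shape, dtype=np.int32)
    intensity = np.full(shape, 5.0)
    intensity[rr, cc] = 20.0  # intra-cell background

    n_central = int(round(n_adhesions * central_fraction))
    truth_rows = []
    for i in range(n_adhesions):
        is_central = i < n_central
        d_norm = rng.uniform(0.35, 0.85) if is_central else rng.uniform(0.05, 0.25)
        rho = cell_r_px * (1.0 - d_norm)  # disk: edge distance = R - radial pos
        theta = rng.uniform(0, 2 * math.pi)
        ar = center[0] + rho * math.sin(theta)
        ac = center[1] + rho * math.cos(theta)
        amp = adhesion_amplitude * rng.uniform(0.8, 1.2)
        err, ecc = draw_ellipse(ar, ac, 6, 3, shape=shape, rotation=rng.uniform(0, math.pi))
        labels[err, ecc] = i + 1
        intensity[err, ecc] = 20.0 + amp
        truth_rows.append(
            {
                "fa_id": i + 1,
                "dist_norm_true": d_norm,
                "class_true": "central" if is_central else "peripheral",
                "amplitude": amp,
            }
        )
    intensity += rng.normal(0, 1.0, size=shape)
    truth = pd.DataFrame(truth_rows)
    return actin, labels, intensity, truth
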