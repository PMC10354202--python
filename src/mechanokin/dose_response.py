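"""Actin-bundling quantification: bundle-pixel ratio and Hill-Langmuir fits.

A field of fluorescently labeled actin filaments contains single filaments
and bundles; bundles carry roughly integer multiples of the single-filament
fluorescence.  After background subtraction, pixel gray values (binned to
256 levels over the 16-bit range) are classified as single-filament or
bundled by an intensity threshold calibrated on single filaments, and the
bundle ratio is the bundled fraction of all filament pixels.  Bundle ratios
measured across a concentration series of the talin VBS1 activator are
fitted with the four-parameter Hill-Langmuir dose-response

    Y = b + X^h (a - b) / (X^h + EC50^h)

optionally with the saturation plateau ``a`` shared across datasets
(vinculin variants), which stabilizes EC50 comparison when no dataset
reaches saturation on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit
from skimage.draw import line
from skimage.restoration import rolling_ball

__all__ = [
    "GRAY_BIN", "HillFit", "bundle_ratio", "hill_fit", "hill_curve",
    "synthetic_filament_image",
]

#: Gray-value binning of the 16-bit range: 256 levels of width 256.
GRAY_BIN = 256


def _bin_gray(values):
    return np.floor_divide(np.asarray(values, dtype=float), GRAY_BIN)


def bundle_ratio(
    image: np.ndarray,
    single_filament_calibration: tuple[float, float],
    bundle_threshold_factor: float = 1.5,
    subtract_background: bool = True,
    background_radius: int = 50,
) -> float:
    """Fraction of filament pixels classified as bundled, in [0, 1].

    The single-filament intensity is calibrated as the mean of the supplied
    (min, max) intensities; pixels brighter than
    ``bundle_threshold_factor`` times that mean count as bundled, pixels
    between the calibration minimum and the threshold as single filaments.
    Gray values are binned at 256 levels before classification.  A
    rolling-ball background subtraction is applied first (disable for
    pre-subtracted images).
    """
    cal_min, cal_max = single_filament_calibration
    if not (cal_min < cal_max):
        raise ValueError("calibration requires min < max")
    img = np.asarray(image, dtype=float)
    if subtract_background:
        img = img - rolling_ball(img, radius=background_radius)
    binned = _bin_gray(img)
    single_mean = _bin_gray([(cal_min + cal_max) / 2.0])[0]
    threshold = bundle_threshold_factor * single_mean
    foreground = binned >= _bin_gray([cal_min])[0]
    bundled = int(np.count_nonzero(foreground & (binned > threshold)))
    single = int(np.count_nonzero(foreground & (binned <= threshold)))
    if bundled + single == 0:
        raise ValueError("no filament pixels above the calibration floor")
    return bundled / (bundled + single)


@dataclass
class HillFit:
    """Per-dataset Hill-Langmuir parameters (percent units)."""

    dataset: str
    a: float  # saturation plateau
    b: float  # baseline plateau
    hill_slope: float
    ec50_uM: float
    ec50_se_uM: float
    r_squared: float
    shared_a: bool
    ec50_outside_range: bool = False


def hill_curve(x, a, b, hill_slope, ec50):
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, b, dtype=float)
    pos = x > 0
    xh = np.power(x[pos], hill_slope)
    out[pos] = b + xh * (a - b) / (xh + ec50**hill_slope)
    return out


def hill_fit(points: pd.DataFrame, share_saturation: bool = True) -> list[HillFit]:
    """Four-parameter Hill-Langmuir fit per dataset.

    ``points`` columns: ``dataset``, ``conc_uM``, ``bundle_ratio_pct`` and
    optionally ``se``.  EC50, HillSlope and the baseline ``b`` are free per
    dataset; the saturation plateau ``a`` is shared across datasets when
    ``share_saturation`` (single global parameter), otherwise free per
    dataset.  Returns one fit per dataset with its R^2; an EC50 outside the
    sampled concentration range is flagged, not rejected.
    """
    req = {"dataset", "conc_uM", "bundle_ratio_pct"}
    if not req.issubset(points.columns):
        raise ValueError(f"points must have columns {sorted(req)}")
    datasets = list(dict.fromkeys(points["dataset"]))
    for ds in datasets:
        sub = points[points["dataset"] == ds]
        if len(sub) < 4:
            raise ValueError(f"dataset {ds!r} has < 4 points")
        if np.count_nonzero(sub["conc_uM"] > 0) < 2:
            raise ValueError(f"dataset {ds!r} needs >= 2 positive concentrations")

    params = lmfit.Parameters()
    if share_saturation:
        params.add("a_shared", value=float(points["bundle_ratio_pct"].max()), min=0)
    for i, ds in enumerate(datasets):
        sub = points[points["dataset"] == ds]
        tag = f"d{i}"
        if share_saturation:
            params.add(f"a_{tag}", expr="a_shared")
        else:
            params.add(f"a_{tag}", value=float(sub["bundle_ratio_pct"].max()), min=0)
        params.add(f"b_{tag}", value=float(sub["bundle_ratio_pct"].min()), min=0)
        params.add(f"h_{tag}", value=1.0, min=0.05, max=20)
        pos = sub.loc[sub["conc_uM"] > 0, "conc_uM"]
        params.add(f"ec50_{tag}", value=float(np.median(pos)), min=1e-9)

    def residuals(p):
        res = []
        for i, ds in enumerate(datasets):
            sub = points[points["dataset"] == ds]
            tag = f"d{i}"
            model = hill_curve(
                sub["conc_uM"].to_numpy(),
                p[f"a_{tag}"].value,
                p[f"b_{tag}"].value,
                p[f"h_{tag}"].value,
                p[f"ec50_{tag}"].value,
            )
            r = sub["bundle_ratio_pct"].to_numpy() - model
            if "se" in sub and np.all(sub["se"].to_numpy() > 0):
                r = r / sub["se"].to_numpy()
            res.append(r)
        return np.concatenate(res)

    result = lmfit.minimize(residuals, params, method="leastsq", max_nfev=20000)
    if not result.success:
        raise RuntimeError(f"Hill fit did not converge: {result.message}")

    fits = []
    for i, ds in enumerate(datasets):
        sub = points[points["dataset"] == ds]
        tag = f"d{i}"
        p = result.params
        y = sub["bundle_ratio_pct"].to_numpy()
        yhat = hill_curve(
            sub["conc_uM"].to_numpy(),
            p[f"a_{tag}"].value, p[f"b_{tag}"].value,
            p[f"h_{tag}"].value, p[f"ec50_{tag}"].value,
        )
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ec50 = p[f"ec50_{tag}"].value
        pos = sub.loc[sub["conc_uM"] > 0, "conc_uM"]
        fits.append(
            HillFit(
                dataset=str(ds),
                a=p[f"a_{tag}"].value,
                b=p[f"b_{tag}"].value,
                hill_slope=p[f"h_{tag}"].value,
                ec50_uM=ec50,
                ec50_se_uM=p[f"ec50_{tag}"].stderr or float("nan"),
                r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
                shared_a=share_saturation,
                ec50_outside_range=not (pos.min() <= ec50 <= pos.max()),
            )
        )
    return fits


def synthetic_filament_image(
    n_filaments: int = 20,
    bundle_fraction: float = 0.25,
    intensity: float = 8000.0,
    noise: str | float = "poisson",
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    background: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a synthetic filament field; bundles at twice the intensity.

    Returns (image, labels) with labels 0 = background, 1 = single filament,
    2 = bundle.  Filaments are random straight segments; the image is uint16
    with Poisson (or Gaussian, pass a float sd) noise on top.
    """
    if not (0 <= bundle_fraction <= 1):
        raise ValueError("bundle_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, background, dtype=float)
    labels = np.zeros(shape, dtype=np.uint8)
    n_bundles = int(round(n_filaments * bundle_fraction))
    kinds = [2] * n_bundles + [1] * (n_filaments - n_bundles)
    for kind in kinds:
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        angle = rng.uniform(0, math.pi)
        length = rng.integers(40, 100)
        r1 = int(np.clip(r0 + length * math.sin(angle), 0, h - 1))
        c1 = int(np.clip(c0 + length * math.cos(angle), 0, w - 1))
        rr, cc = line(int(r0), int(c0), r1, c1)
        amp = intensity * kind
        img[rr, cc] = background + amp
        labels[rr, cc] = np.maximum(labels[rr, cc], kind)
    if noise == "poisson":
        img = rng.poisson(img).astype(float)
    elif isinstance(noise, (int, float)) and noise > 0:
        img = img + rng.normal(0, float(noise), size=shape)
    return np.clip(img, 0, 65535).astype(np.uint16), labels
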