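"""Segmentation and per-cell feature extraction from multi-channel images.

This is the quantification stage of the pipeline: maximum-intensity
projection of z-stacks, nucleus-seeded cell segmentation, multiscale
Laplacian-of-Gaussian (LoG) spot detection for DiI-LDL organelles and
lipid droplets, and assembly of the per-cell feature table (CellRecord).

Conventions: coordinates are 0-based row-major pixel indices; areas are
pixel counts times ``pixel_size**2`` in um^2; label images use positive
integers with background 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops_table
from skimage.segmentation import watershed

#: channel order used in multi-page TIFFs and rendered stacks
CHANNEL_ORDER = ("nuclei", "cytoplasm", "dii", "ld")

#: column order of the per-cell feature table (CellRecord)
CELL_RECORD_COLUMNS = (
    "cell_id",
    "cytoplasm_area_um2",
    "mean_dii_intensity",
    "dii_organelle_count",
    "ld_count",
    "ld_total_area_um2",
    "ldlr_surface_intensity",
    "nucleus_row",
    "nucleus_col",
)


@dataclass
class ImageStack:
    """Multi-channel field: named 2D images or (z, y, x) stacks."""

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")

    @property
    def is_stack(self) -> bool:
        return any(np.asarray(a).ndim == 3 for a in self.channels.values())


def max_project(stack):
    """Maximum-intensity projection over z.

    Accepts an :class:`ImageStack` (returns a projected copy) or a bare
    (z, y, x) array (returns the 2D projection).  2D inputs pass through
    unchanged.
    """
    if isinstance(stack, ImageStack):
        return ImageStack(
            channels={k: max_project(np.asarray(v)) for k, v in stack.channels.items()},
            pixel_size_um=stack.pixel_size_um,
        )
    arr = np.asarray(stack)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("expected a 2D image or a (z, y, x) stack with >= 1 slice")
    return arr.max(axis=0)


def _robust_background(values: np.ndarray) -> tuple[float, float]:
    """(median, MAD) of a sample; MAD floored to avoid zero thresholds."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, max(mad, 1e-12)


@dataclass
class SegmentationParams:
    smooth_sigma: float = 2.0
    min_nucleus_area_px: int = 30
    k_mad: float = 5.0  # robust-background multiple gating the threshold


def segment_cells(
    nuclei_channel: np.ndarray,
    cytoplasm_channel: np.ndarray,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Segment nuclei and grow one cytoplasm region per nucleus.

    Nuclei: Gaussian smoothing, a global Otsu threshold floored at
    median + k*MAD of the smoothed image (so a blank field yields no
    objects), small-object removal and connected components.  Cytoplasm:
    foreground by the same thresholding of the cytoplasm channel, then a
    watershed on the inverted smoothed intensity seeded by the nuclei, so
    touching cells split along the ridge between their seeds.  Cytoplasm
    labels match their nucleus labels.

    Returns ``(nuclei_labels, cytoplasm_labels, status)`` where status is
    ``"ok"`` or ``"no-nuclei"`` (empty masks, with a warning).
    """
    p = params or SegmentationParams()
    nuc = np.asarray(nuclei_channel, dtype=float)
    cyt = np.asarray(cytoplasm_channel, dtype=float)
    if nuc.shape != cyt.shape:
        raise ValueError("nuclei and cytoplasm channels must share a shape")

    sm_n = ndimage.gaussian_filter(nuc, p.smooth_sigma)
    med, mad = _robust_background(sm_n)
    floor = med + p.k_mad * mad
    try:
        thr = max(threshold_otsu(sm_n), floor)
    except ValueError:  # constant image
        thr = floor
    mask_n = sm_n > thr
    lab = cc_label(mask_n)
    if lab.max():
        sizes = np.bincount(lab.ravel())
        mask_n = sizes[lab] >= p.min_nucleus_area_px
        mask_n &= lab > 0
    mask_n = ndimage.binary_fill_holes(mask_n)
    nuclei_labels = cc_label(mask_n)

    if nuclei_labels.max() == 0:
        warnings.warn("no nuclei found; returning empty masks", stacklevel=2)
        return nuclei_labels, np.zeros_like(nuclei_labels), "no-nuclei"

    sm_c = ndimage.gaussian_filter(cyt, p.smooth_sigma)
    med_c, mad_c = _robust_background(sm_c)
    try:
        thr_c = max(threshold_otsu(sm_c), med_c + p.k_mad * mad_c)
    except ValueError:
        thr_c = med_c + p.k_mad * mad_c
    fg = (sm_c > thr_c) | mask_n
    cyto_labels = watershed(-sm_c, markers=nuclei_labels, mask=fg)
    return nuclei_labels, cyto_labels, "ok"


@dataclass
class SpotParams:
    """Multiscale LoG detector settings.

    ``sigmas`` is the band-pass scale grid in pixels (matched to punctum
    size); candidate maxima are kept when their scale-normalized LoG
    response exceeds median + ``k_mad``*MAD of the response over the
    region outside all cells (robust background).
    """

    sigmas: tuple[float, ...] = (1.2, 1.6, 2.1, 2.8)
    k_mad: float = 10.0
    min_distance: int = 2

    def validate(self) -> None:
        if any(s <= 0 for s in self.sigmas) or not self.sigmas:
            raise ValueError("sigmas must be positive")
        if self.k_mad <= 0:
            raise ValueError("k_mad must be > 0")


def _spot_area_um2(
    channel: np.ndarray, r: int, c: int, sigma: float, pixel_size_um: float,
) -> float:
    """Half-max support area of a detected punctum, in um^2.

    The local background is the median of the border of a window around the
    peak; the support is the connected component above halfway between
    background and peak that contains the peak.
    """
    R = max(3, int(np.ceil(3.0 * sigma)))
    y0, y1 = max(0, r - R), min(channel.shape[0], r + R + 1)
    x0, x1 = max(0, c - R), min(channel.shape[1], c + R + 1)
    patch = channel[y0:y1, x0:x1]
    border = np.concatenate([patch[0, :], patch[-1, :], patch[:, 0], patch[:, -1]])
    bg = float(np.median(border))
    level = bg + 0.5 * (float(channel[r, c]) - bg)
    lab = cc_label(patch >= level)
    comp = lab[r - y0, c - x0]
    if comp == 0:
        return pixel_size_um**2
    return float(np.sum(lab == comp)) * pixel_size_um**2


def detect_spots(
    channel: np.ndarray,
    cytoplasm_mask: np.ndarray | None = None,
    params: SpotParams | None = None,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Detect puncta by multiscale LoG and assign them to cells.

    Returns a DataFrame with one row per punctum: ``row, col, sigma_px,
    response, area_um2, cell_label``.  When ``cytoplasm_mask`` (a label
    image) is given, puncta whose center falls outside every cell are
    discarded and ``cell_label`` holds the containing cell; otherwise
    ``cell_label`` is 0 for all spots.
    """
    p = params or SpotParams()
    p.validate()
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a 2D channel (project stacks first)")

    # Anscombe transform: photon-counting noise becomes ~unit-variance
    # everywhere, so one robust background threshold is valid across the
    # field regardless of local brightness
    stab = 2.0 * np.sqrt(np.maximum(img, 0.0) + 0.375)

    resp = np.full(img.shape, -np.inf)
    scale = np.zeros(img.shape)
    for s in p.sigmas:
        r_s = -(s**2) * ndimage.gaussian_laplace(stab, s)
        better = r_s > resp
        resp[better] = r_s[better]
        scale[better] = s

    if cytoplasm_mask is not None:
        bg_region = resp[np.asarray(cytoplasm_mask) == 0]
        if bg_region.size == 0:
            bg_region = resp.ravel()
    else:
        bg_region = resp.ravel()
    med, mad = _robust_background(bg_region)
    thr = med + p.k_mad * mad

    # the LoG response is unreliable within ~2 sigma of the border
    border = int(np.ceil(2.0 * max(p.sigmas)))
    peaks = peak_local_max(
        resp, min_distance=p.min_distance, threshold_abs=thr, exclude_border=border
    )
    rows = []
    for r, c in peaks:
        if cytoplasm_mask is not None:
            lab = int(cytoplasm_mask[r, c])
            if lab == 0:
                continue
        else:
            lab = 0
        s = float(scale[r, c])
        rows.append(
            {
                "row": int(r),
                "col": int(c),
                "sigma_px": s,
                "response": float(resp[r, c]),
                "area_um2": _spot_area_um2(img, int(r), int(c), s, pixel_size_um),
                "cell_label": lab,
            }
        )
    return pd.DataFrame(
        rows, columns=["row", "col", "sigma_px", "response", "area_um2", "cell_label"]
    )


def extract_features(
    nuclei_labels: np.ndarray,
    cytoplasm_labels: np.ndarray,
    channels: Mapping[str, np.ndarray],
    spots: Mapping[str, pd.DataFrame],
    pixel_size_um: float,
    surface_channel: np.ndarray | None = None,
    background_channel: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the per-cell feature table (CellRecord).

    Per cytoplasm label: area (pixel count * pixel_size^2), mean DiI
    intensity over cytoplasm pixels, DiI spot count, LD spot count and
    summed LD area, nucleus centroid.  If a surface channel is given the
    per-cell LDLR surface intensity is mean(surface) - mean(background),
    floored at 0 (per-cell background subtraction).
    """
    labels = np.asarray(cytoplasm_labels)
    present = np.unique(labels)
    present = present[present > 0]
    for name, df in spots.items():
        if len(df) and not np.isin(df["cell_label"].to_numpy(), present).all():
            raise ValueError(f"{name} spots reference labels absent from the mask")

    if len(present) == 0:
        return pd.DataFrame(columns=CELL_RECORD_COLUMNS)

    props = regionprops_table(
        labels,
        intensity_image=np.asarray(channels["dii"], dtype=float),
        properties=("label", "area", "intensity_mean"),
    )
    rec = pd.DataFrame(
        {
            "cell_id": props["label"],
            "cytoplasm_area_um2": props["area"] * pixel_size_um**2,
            "mean_dii_intensity": props["intensity_mean"],
        }
    ).set_index("cell_id")

    dii = spots.get("dii", pd.DataFrame(columns=["cell_label"]))
    ld = spots.get("ld", pd.DataFrame(columns=["cell_label", "area_um2"]))
    rec["dii_organelle_count"] = dii.groupby("cell_label").size().reindex(rec.index, fill_value=0)
    rec["ld_count"] = ld.groupby("cell_label").size().reindex(rec.index, fill_value=0)
    rec["ld_total_area_um2"] = (
        ld.groupby("cell_label")["area_um2"].sum().reindex(rec.index, fill_value=0.0)
    )

    if surface_channel is not None:
        surf = regionprops_table(
            labels, intensity_image=np.asarray(surface_channel, dtype=float),
            properties=("label", "intensity_mean"),
        )
        ldlr = pd.Series(surf["intensity_mean"], index=surf["label"])
        if background_channel is not None:
            bg = regionprops_table(
                labels, intensity_image=np.asarray(background_channel, dtype=float),
                properties=("label", "intensity_mean"),
            )
            ldlr = ldlr - pd.Series(bg["intensity_mean"], index=bg["label"])
        rec["ldlr_surface_intensity"] = np.maximum(ldlr.reindex(rec.index), 0.0)
    else:
        rec["ldlr_surface_intensity"] = np.nan

    nuc = regionprops_table(
        np.asarray(nuclei_labels), properties=("label", "centroid")
    )
    cent = pd.DataFrame(
        {"nucleus_row": nuc["centroid-0"], "nucleus_col": nuc["centroid-1"]},
        index=nuc["label"],
    )
    rec = rec.join(cent, how="left")
    return rec.reset_index()[list(CELL_RECORD_COLUMNS)]
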