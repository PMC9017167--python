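"""Population classification, well aggregation and control normalization.

PBMCs spread differently on coated imaging plates: lymphocytes stay small
while monocytes flatten out, so a cytoplasmic-area cutoff at 115 um^2
separates a lymphocyte-enriched from a monocyte-enriched fraction.
Single-cell records are averaged per population and well; uptake readouts
are then expressed as % of the mean of the two internal control samples
carried on every plate (controls average exactly 100%), which also removes
multiplicative plate effects.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

AREA_THRESHOLD_UM2 = 115.0

#: uptake readouts normalized to plate controls
UPTAKE_READOUTS = ("ly_dii_int", "ly_dii_no", "mo_dii_int", "mo_dii_no")

CONTROL_ROLES = ("control1", "control2")


def classify_population(area_um2, threshold: float = AREA_THRESHOLD_UM2):
    """Classify cells by cytoplasmic area: <= threshold um^2 -> lymphocyte.

    The boundary value itself is assigned to the lymphocyte fraction.
    Accepts a scalar or array; returns a string or string array.
    """
    arr = np.asarray(area_um2, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("cytoplasm area must be positive and non-missing")
    out = np.where(arr <= threshold, "lymphocyte", "monocyte")
    return out.item() if np.isscalar(area_um2) or arr.ndim == 0 else out


def add_population(cells: pd.DataFrame, threshold: float = AREA_THRESHOLD_UM2) -> pd.DataFrame:
    """Return a copy of a CellRecord table with a ``population`` column."""
    cells = cells.copy()
    if len(cells):
        cells["population"] = classify_population(
            cells["cytoplasm_area_um2"].to_numpy(float), threshold
        )
    else:
        cells["population"] = pd.Series(dtype=object)
    return cells


def aggregate_well(
    cells: pd.DataFrame,
    platemap_row: Mapping,
    min_cells_per_population: int = 50,
) -> dict:
    """Aggregate one well's CellRecords to a WellAggregate row.

    Per population: cell count and means of DiI intensity and organelle
    count.  Monocyte LD readouts follow the LD-positive convention: the
    LD-positive fraction is over all monocytes, while mean LD count and
    mean total LD area are over LD-positive monocytes only (NaN when there
    are none, rather than 0, to keep mobilization ratios unbiased).  QC
    passes when both populations reach ``min_cells_per_population``.
    """
    if "population" not in cells.columns:
        cells = add_population(cells)
    agg = {
        "well_id": platemap_row["well_id"],
        "subject_id": platemap_row["subject_id"],
        "plate_id": platemap_row["plate_id"],
        "treatment": platemap_row["treatment"],
        "role": platemap_row.get("role", "sample"),
    }
    pops = {p: cells[cells["population"] == p] for p in ("lymphocyte", "monocyte")}
    agg["n_cells"] = int(len(cells))
    for short, pop in (("ly", "lymphocyte"), ("mo", "monocyte")):
        sub = pops[pop]
        agg[f"n_{short}"] = int(len(sub))
        agg[f"{short}_dii_int"] = float(sub["mean_dii_intensity"].mean()) if len(sub) else np.nan
        agg[f"{short}_dii_no"] = float(sub["dii_organelle_count"].mean()) if len(sub) else np.nan
        pos = sub[sub["ld_count"] >= 1]
        agg[f"{short}_ld_pos_fraction"] = (
            100.0 * len(pos) / len(sub) if len(sub) else np.nan
        )
        if short == "mo":
            agg["mo_ld_no"] = float(pos["ld_count"].mean()) if len(pos) else np.nan
            agg["mo_ld_area"] = float(pos["ld_total_area_um2"].mean()) if len(pos) else np.nan
    agg["qc_pass"] = bool(
        agg["n_ly"] >= min_cells_per_population
        and agg["n_mo"] >= min_cells_per_population
    )
    return agg


def normalize_to_controls(
    aggregates: pd.DataFrame,
    readouts: Iterable[str] = UPTAKE_READOUTS,
) -> pd.DataFrame:
    """Express readouts as % of the plate's control mean, per treatment.

    Within each (plate, treatment) the named readouts are divided by the
    mean of the same readout over the QC-passing control wells and
    multiplied by 100, so the controls themselves average exactly 100%.
    A plate/treatment with a missing control sample or a non-positive
    control mean is marked unnormalizable (``normalized`` False, values
    NaN) instead of raising.
    """
    readouts = list(readouts)
    out = aggregates.copy()
    out["normalized"] = False
    for (_, _), idx in out.groupby(["plate_id", "treatment"]).groups.items():
        block = out.loc[idx]
        ctrl = block[block["role"].isin(CONTROL_ROLES) & block["qc_pass"]]
        ok = set(ctrl["role"]) >= set(CONTROL_ROLES)
        means = ctrl[readouts].mean() if ok else None
        if not ok or means.isna().any() or (means <= 0).any():
            out.loc[idx, readouts] = np.nan
            continue
        out.loc[idx, readouts] = 100.0 * block[readouts] / means
        out.loc[idx, "normalized"] = True
    return out


def correct_plate_effect(
    aggregates: pd.DataFrame,
    readouts: Iterable[str] = UPTAKE_READOUTS,
) -> pd.DataFrame:
    """Rescale raw readouts so control levels agree across plates.

    Each plate's values are multiplied by (global control mean)/(plate
    control mean), per treatment and readout.  This is an alternative to
    :func:`normalize_to_controls` for keeping values on the raw intensity
    scale — apply exactly one of the two (after percent-of-control
    normalization the plate factor is already unity and this is a no-op).
    A single-plate input is returned unchanged.
    """
    readouts = list(readouts)
    out = aggregates.copy()
    if out["plate_id"].nunique() <= 1:
        return out
    ctrl = out[out["role"].isin(CONTROL_ROLES) & out["qc_pass"]]
    for treatment, tidx in out.groupby("treatment").groups.items():
        tc = ctrl[ctrl["treatment"] == treatment]
        if not len(tc):
            warnings.warn(f"no control wells for treatment {treatment!r}; left uncorrected")
            continue
        global_mean = tc[readouts].mean()
        plate_means = tc.groupby("plate_id")[readouts].mean()
        for plate, pidx in out.loc[tidx].groupby("plate_id").groups.items():
            if plate not in plate_means.index:
                warnings.warn(f"plate {plate!r} has no controls; left uncorrected")
                continue
            factor = global_mean / plate_means.loc[plate]
            out.loc[pidx, readouts] = out.loc[pidx, readouts] * factor
    return out
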