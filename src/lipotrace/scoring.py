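"""Subject-level scores: LDL uptake, lipid mobilization, LDLR surface.

Uptake: the four parameters Mo DiI-Int, Ly DiI-Int, Mo DiI-No and Ly
DiI-No are means over a subject's replicate starved wells of the
control-normalized readouts; pan-uptake is their average.

Mobilization: how efficiently a subject's monocytes deplete lipid stores.
For each LD readout (LD-Pos, LD-No, LD-Area) the control-medium results
are first averaged over duplicate wells, then divided by the per-well
results after lipid starvation; pan-mobilization is the per-well average
of the three ratios, then averaged over starved wells.

LDLR surface: additive scale — the subject's mean background-subtracted
surface intensity minus the mean of the two plate controls.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UPTAKE_FIELDS = ("mo_dii_int", "ly_dii_int", "mo_dii_no", "ly_dii_no")

#: mobilization score -> WellAggregate readout it is computed from
MOBILIZATION_READOUTS = {
    "mob_ld_pos": "mo_ld_pos_fraction",
    "mob_ld_no": "mo_ld_no",
    "mob_ld_area": "mo_ld_area",
}


def _nanmean(values: Iterable[float]) -> float:
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.mean()) if arr.size else np.nan


def uptake_scores(lp_aggregates: pd.DataFrame) -> dict:
    """Uptake parameters of one subject from normalized starved wells.

    Each parameter is the mean over QC-passing replicate wells; pan-uptake
    averages the parameters that are defined, with ``uptake_complete``
    flagging whether all four were.  All wells failing QC yields missing
    scores.
    """
    ok = lp_aggregates[lp_aggregates["qc_pass"]]
    scores = {f: _nanmean(ok[f]) if len(ok) else np.nan for f in UPTAKE_FIELDS}
    defined = [v for v in scores.values() if np.isfinite(v)]
    scores["pan_uptake"] = float(np.mean(defined)) if defined else np.nan
    scores["uptake_complete"] = len(defined) == len(UPTAKE_FIELDS)
    return scores


def mobilization_scores(
    cm_aggregates: pd.DataFrame,
    lp_aggregates: pd.DataFrame,
    ratio_mode: str = "per-well",
) -> dict:
    """Mobilization scores of one subject from CM and LP wells.

    ``per-well`` (default): CM readouts are averaged over duplicate wells;
    each starved well then yields ratios CM-mean / LP-value and a per-well
    pan-mobilization (mean of its defined ratios); subject scores average
    over starved wells.  ``of-means`` divides CM means by LP means
    directly.  A zero or missing LP readout drops that ratio for that
    well; a score with no defined ratio anywhere is missing.
    """
    if ratio_mode not in ("per-well", "of-means"):
        raise ValueError("ratio_mode must be 'per-well' or 'of-means'")
    cm = cm_aggregates[cm_aggregates["qc_pass"]]
    lp = lp_aggregates[lp_aggregates["qc_pass"]]
    cm_means = {k: _nanmean(cm[col]) if len(cm) else np.nan
                for k, col in MOBILIZATION_READOUTS.items()}

    scores: dict = {}
    if ratio_mode == "of-means":
        for k, col in MOBILIZATION_READOUTS.items():
            lp_mean = _nanmean(lp[col]) if len(lp) else np.nan
            scores[k] = (
                cm_means[k] / lp_mean
                if np.isfinite(cm_means[k]) and np.isfinite(lp_mean) and lp_mean > 0
                else np.nan
            )
        defined = [scores[k] for k in MOBILIZATION_READOUTS if np.isfinite(scores[k])]
        scores["pan_mobilization"] = float(np.mean(defined)) if defined else np.nan
    else:
        per_well = {k: [] for k in MOBILIZATION_READOUTS}
        pans = []
        for _, well in lp.iterrows():
            ratios = {}
            for k, col in MOBILIZATION_READOUTS.items():
                v = well[col]
                if np.isfinite(cm_means[k]) and np.isfinite(v) and v > 0:
                    ratios[k] = cm_means[k] / v
                    per_well[k].append(ratios[k])
            if ratios:
                pans.append(float(np.mean(list(ratios.values()))))
        for k in MOBILIZATION_READOUTS:
            scores[k] = _nanmean(per_well[k])
        scores["pan_mobilization"] = _nanmean(pans)
    scores["mobilization_complete"] = all(
        np.isfinite(scores[k]) for k in MOBILIZATION_READOUTS
    )
    return scores


def ldlr_surface_score(subject_mean: float, control_means: Sequence[float]) -> float:
    """Subject mean LDLR surface intensity minus the mean of the controls.

    Kept on the additive scale (control-subtracted, not percent-of-control).
    """
    ctrl = np.asarray(control_means, dtype=float)
    if ctrl.size == 0 or not np.all(np.isfinite(ctrl)):
        raise ValueError("control means are required and must be finite")
    return float(subject_mean - ctrl.mean())


def subject_scores_table(
    aggregates: pd.DataFrame,
    ratio_mode: str = "per-well",
) -> pd.DataFrame:
    """SubjectScores for every sample subject in a WellAggregate table.

    Uptake parameters come from normalized LP wells, mobilization from raw
    CM and LP wells (the CM/LP ratio is scale-free, so normalization is
    irrelevant to it).
    """
    rows = []
    samples = aggregates[aggregates["role"] == "sample"]
    for subject_id, sub in samples.groupby("subject_id", sort=False):
        cm = sub[sub["treatment"] == "CM"]
        lp = sub[sub["treatment"] == "LP"]
        row = {"subject_id": subject_id}
        row.update(uptake_scores(lp))
        row.update(mobilization_scores(cm, lp, ratio_mode=ratio_mode))
        rows.append(row)
    return pd.DataFrame(rows)


def ldlr_scores_table(per_subject_means: pd.DataFrame) -> pd.DataFrame:
    """Control-subtracted LDLR surface score per sample subject.

    Expects columns ``subject_id, role, ldlr_surface_intensity``; the two
    control roles define the reference level (averaged across plates when
    present on several).
    """
    ctrl = per_subject_means[per_subject_means["role"].isin(("control1", "control2"))]
    if ctrl["role"].nunique() < 2:
        raise ValueError("both control samples are required")
    ctrl_means = ctrl.groupby("role")["ldlr_surface_intensity"].mean()
    samples = per_subject_means[per_subject_means["role"] == "sample"]
    return pd.DataFrame(
        {
            "subject_id": samples["subject_id"].to_numpy(),
            "ldlr_surface": [
                ldlr_surface_score(v, ctrl_means.to_numpy())
                for v in samples["ldlr_surface_intensity"]
            ],
        }
    )
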