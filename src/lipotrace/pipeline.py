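"""End-to-end helpers: image -> CellRecords -> WellAggregates.

These wire the stages together the way an analysis run uses them:
project, segment, detect puncta in the DiI and LD channels, extract
per-cell features, classify populations and aggregate per well.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import imaging, simulate, wells


def quantify_stack(
    stack: imaging.ImageStack,
    seg_params: imaging.SegmentationParams | None = None,
    spot_params: imaging.SpotParams | None = None,
) -> pd.DataFrame:
    """Quantify one field into a CellRecord table.

    Z-stacks are max-projected first.  DiI organelles and LDs are detected
    in their channels with the same LoG detector and assigned to the
    segmented cytoplasm regions.
    """
    if stack.is_stack:
        stack = imaging.max_project(stack)
    ch = stack.channels
    nuclei_labels, cyto_labels, status = imaging.segment_cells(
        ch["nuclei"], ch["cytoplasm"], seg_params
    )
    if status != "ok":
        return pd.DataFrame(columns=imaging.CELL_RECORD_COLUMNS)
    spots = {
        name: imaging.detect_spots(
            ch[name], cyto_labels, spot_params, pixel_size_um=stack.pixel_size_um
        )
        for name in ("dii", "ld")
        if name in ch
    }
    return imaging.extract_features(
        nuclei_labels, cyto_labels, ch, spots, stack.pixel_size_um
    )


def simulate_and_quantify_well(
    subject: simulate.SubjectTruth,
    treatment: str,
    config: simulate.SimConfig,
    rng: np.random.Generator,
    cells_per_well: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, simulate.RenderTruth]:
    """Simulate, render and re-quantify one well.

    Returns ``(measured_cells, true_cells, render_truth)`` where the
    measured table went through the full image pipeline (render, segment,
    detect, extract) and carries a ``population`` column from the
    115 um^2 classification of the *measured* cytoplasm area.
    """
    true_cells = simulate.simulate_well_cells(
        subject, treatment, config, rng, cells_per_well=cells_per_well
    )
    stack, truth = simulate.render_image(true_cells, config, rng)
    measured = quantify_stack(stack)
    measured = wells.add_population(measured)
    return measured, true_cells, truth
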