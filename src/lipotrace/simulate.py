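"""Synthetic PBMC lipid-trafficking assay generator.

Everything downstream of the wet lab is testable against this module: it
draws subject cohorts with latent LDL-uptake and lipid-mobilization
capacities, per-well single-cell feature tables, and rendered multi-channel
fluorescence images with full ground truth.

The defaults encode the study conditions of the assay this package models:

* ~700 monocytes and ~2,300 lymphocytes quantified per well, duplicate
  wells per treatment;
* cytoplasmic-area mixture straddling the 115 um^2 lymphocyte/monocyte
  boundary (lymphocyte mode below, monocyte mode above);
* in lipid-rich medium (CM) 25% of monocytes and 9% of lymphocytes carry
  lipid droplets (LDs); after overnight lipid starvation (LP) these drop
  to 12% and 6%;
* LD-positive monocytes carry on average 2.9 LDs (total LD area
  1.35 um^2) in CM and 1.8 LDs (0.8 um^2) in LP;
* DiI-LDL organelle counts are ~10-fold higher in monocytes than
  lymphocytes and rise ~5-fold upon lipid starvation;
* two internal control samples (pooled healthy-donor PBMCs with latent
  capacities fixed at the reference value 1) on every plate, plus a
  multiplicative plate effect.

Per-cell distributions are chosen for positivity and overdispersion:
lognormal intensities and areas, negative-binomial organelle counts,
Bernoulli LD occurrence with shifted-Poisson counts and gamma droplet
areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import CHANNEL_ORDER, ImageStack

POPULATIONS = ("monocyte", "lymphocyte")
TREATMENTS = ("CM", "LP")
GROUPS = ("nLDL-c", "hLDL-c")


@dataclass
class SimConfig:
    """Parameters of the synthetic assay.

    All rates and folds are expressed for a reference subject with latent
    uptake capacity ``u = 1`` and mobilization capacity ``m = 1``;
    subject-level capacities scale them multiplicatively.
    """

    seed: int = 0

    # -- study design ---------------------------------------------------
    n_subjects_per_group: int = 19
    wells_per_treatment: int = 2
    cells_per_well: Mapping[str, int] = field(
        default_factory=lambda: {"monocyte": 700, "lymphocyte": 2300}
    )
    samples_per_plate: int = 18  # plus two control samples per plate
    plate_effect_sigma_log: float = 0.15
    intraindividual_cv: float = 0.10  # well-to-well multiplicative CV

    # -- cytoplasmic area mixture (um^2) --------------------------------
    area_median_um2: Mapping[str, float] = field(
        default_factory=lambda: {"lymphocyte": 70.0, "monocyte": 230.0}
    )
    area_sigma_log: Mapping[str, float] = field(
        default_factory=lambda: {"lymphocyte": 0.18, "monocyte": 0.18}
    )

    # -- DiI-LDL uptake -------------------------------------------------
    # organelle counts: negative binomial, mean = base * u * fold(LP)
    dii_no_mean_cm: Mapping[str, float] = field(
        default_factory=lambda: {"lymphocyte": 0.3, "monocyte": 3.0}
    )
    dii_no_dispersion: float = 5.0  # NB size parameter k
    starvation_fold_dii_no: float = 5.0
    # diffuse cellular DiI intensity (a.u. above background): lognormal
    dii_int_mean_cm: Mapping[str, float] = field(
        default_factory=lambda: {"lymphocyte": 10.0, "monocyte": 13.0}
    )
    starvation_fold_dii_int: float = 2.0
    dii_int_sigma_log: float = 0.2

    # -- lipid droplets -------------------------------------------------
    ld_pos_cm: Mapping[str, float] = field(
        default_factory=lambda: {"lymphocyte": 0.09, "monocyte": 0.25}
    )
    ld_pos_lp: Mapping[str, float] = field(
        default_factory=lambda: {"lymphocyte": 0.06, "monocyte": 0.12}
    )
    ld_no_mean_cm: float = 2.9  # mean LD count among LD-positive cells
    ld_no_mean_lp: float = 1.8
    ld_droplet_area_mean_cm: float = 1.35 / 2.9  # per-droplet mean, um^2
    ld_droplet_area_mean_lp: float = 0.8 / 1.8
    ld_area_shape: float = 2.0  # gamma shape of per-droplet areas

    # -- subject-level latents ------------------------------------------
    sigma_log_u: float = 0.25
    sigma_log_m: float = 0.20
    rho: float = 0.4  # corr(ln u, ln m)
    group_uptake_mult: Mapping[str, float] = field(
        default_factory=lambda: {"nLDL-c": 1.0, "hLDL-c": 0.85}
    )
    group_mobilization_mult: Mapping[str, float] = field(
        default_factory=lambda: {"nLDL-c": 1.0, "hLDL-c": 0.80}
    )
    prs_mean: Mapping[str, float] = field(
        default_factory=lambda: {"nLDL-c": 0.0, "hLDL-c": 1.0}
    )
    prs_sd: float = 1.0
    # LDL-c (mmol/L) = base(group) * exp(a*PRS - b*ln u - c*ln m + eps)
    ldl_c_base: Mapping[str, float] = field(
        default_factory=lambda: {"nLDL-c": 2.25, "hLDL-c": 5.5}
    )
    ldl_c_prs_coef: float = 0.05
    ldl_c_u_coef: float = 0.25
    ldl_c_m_coef: float = 0.25
    ldl_c_noise_sd: float = 0.06
    age_mobilization_coef: float = 0.15  # ln m decreases with age z-score
    bmi_uptake_coef: float = 0.10  # ln u decreases with BMI z-score
    ldlr_surface_mean: float = 100.0  # a.u., scales with u
    ldlr_surface_sigma_log: float = 0.15

    # -- optics / rendering ---------------------------------------------
    pixel_size_um: float = 0.4
    psf_sigma_px: float = 1.3
    background: float = 8.0
    noise: str = "poisson"  # "poisson" | "none"
    nucleus_area_frac: float = 0.35
    nucleus_level: float = 120.0
    cyto_level: float = 30.0
    punctum_peak: float = 120.0
    dii_diffuse_blur_px: float = 2.5
    min_punctum_sep_px: float = 6.0
    packing_fraction: float = 0.33
    n_slices: int = 1
    max_place_attempts: int = 2000

    def validate(self) -> None:
        if self.n_subjects_per_group < 0:
            raise ValueError("n_subjects_per_group must be >= 0")
        if self.wells_per_treatment <= 0 or self.samples_per_plate <= 0:
            raise ValueError("counts must be > 0")
        if any(v < 0 for v in self.cells_per_well.values()):
            raise ValueError("cells_per_well must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("|rho| must be <= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        for cv in (self.intraindividual_cv, self.sigma_log_u, self.sigma_log_m):
            if cv < 0:
                raise ValueError("dispersions must be >= 0")
        for p in (*self.ld_pos_cm.values(), *self.ld_pos_lp.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("LD occurrence probabilities must be in [0, 1]")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")


@dataclass
class SubjectTruth:
    """Latent state of one (pseudo-)subject."""

    subject_id: str
    group: str
    role: str  # "sample" | "control1" | "control2"
    plate_id: int
    u: float  # uptake capacity (reference = 1)
    m: float  # mobilization capacity (reference = 1)


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort."""

    subjects: pd.DataFrame  # one row per (subject, plate) incl. controls
    plate_effects: pd.DataFrame  # plate_id, effect


def reference_subject(plate_id: int = 0) -> SubjectTruth:
    """The internal-control pseudo-subject: both latents fixed at 1."""
    return SubjectTruth("control1", "control", "control1", plate_id, 1.0, 1.0)


# ---------------------------------------------------------------------------
# cohort level
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw a two-group cohort with latent capacities and phenotypes.

    Returns
    -------
    cohort : DataFrame
        One row per real subject: ``subject_id, group, ldl_c_mmol_l,
        ldl_prs, age, bmi, waist_cm, statin, plate_id``.
    truth : CohortTruth
        Latent ``u``/``m`` per subject, the control pseudo-subjects placed
        on every plate (latents fixed at 1), and per-plate multiplicative
        effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_subjects_per_group
    rows = []
    for group in GROUPS:
        for i in range(n):
            rows.append({"subject_id": f"{group}-{i:03d}", "group": group})
    cohort = pd.DataFrame(rows, columns=["subject_id", "group"])

    n_total = len(cohort)
    n_plates = max(0, math.ceil(n_total / config.samples_per_plate))
    if n_total:
        # interleave groups across plates
        order = rng.permutation(n_total)
        plate_ids = np.repeat(np.arange(n_plates), config.samples_per_plate)[:n_total]
        cohort["plate_id"] = 0
        cohort.loc[cohort.index[order], "plate_id"] = plate_ids
    else:
        cohort["plate_id"] = pd.Series(dtype=int)

    # latent capacities: bivariate lognormal with corr(ln u, ln m) = rho,
    # built from two independent standard normals (valid for degenerate
    # zero-dispersion settings where a covariance factorization would fail)
    z1 = rng.standard_normal(n_total)
    z2 = rng.standard_normal(n_total)
    ln_u = config.sigma_log_u * z1
    ln_m = config.sigma_log_m * (
        config.rho * z1 + math.sqrt(1.0 - config.rho**2) * z2
    )

    # covariates
    age = np.clip(rng.normal(55.0, 8.0, n_total), 25.0, 75.0)
    bmi = np.clip(rng.normal(27.0, 4.0, n_total), 17.0, 45.0)
    waist = 88.0 + 2.5 * (bmi - 27.0) + rng.normal(0.0, 6.0, n_total)
    ln_m -= config.age_mobilization_coef * (age - 55.0) / 8.0
    ln_u -= config.bmi_uptake_coef * (bmi - 27.0) / 4.0

    gmu = cohort["group"].map(dict(config.group_uptake_mult)).to_numpy(float)
    gmm = cohort["group"].map(dict(config.group_mobilization_mult)).to_numpy(float)
    u = np.exp(ln_u) * gmu
    m = np.exp(ln_m) * gmm

    prs = rng.normal(
        cohort["group"].map(dict(config.prs_mean)).to_numpy(float),
        config.prs_sd,
        n_total,
    )
    base = cohort["group"].map(dict(config.ldl_c_base)).to_numpy(float)
    ldl_c = base * np.exp(
        config.ldl_c_prs_coef * prs
        - config.ldl_c_u_coef * np.log(u)
        - config.ldl_c_m_coef * np.log(m)
        + rng.normal(0.0, config.ldl_c_noise_sd, n_total)
    )

    cohort["ldl_c_mmol_l"] = ldl_c
    cohort["ldl_prs"] = prs
    cohort["age"] = age
    cohort["bmi"] = bmi
    cohort["waist_cm"] = waist
    cohort["statin"] = False
    cohort = cohort[
        ["subject_id", "group", "ldl_c_mmol_l", "ldl_prs", "age", "bmi",
         "waist_cm", "statin", "plate_id"]
    ]

    subj_rows = cohort[["subject_id", "group", "plate_id"]].copy()
    subj_rows["role"] = "sample"
    subj_rows["u"] = u
    subj_rows["m"] = m
    ctrl_rows = [
        {"subject_id": role, "group": "control", "plate_id": p,
         "role": role, "u": 1.0, "m": 1.0}
        for p in range(n_plates)
        for role in ("control1", "control2")
    ]
    subjects = pd.concat(
        [subj_rows, pd.DataFrame(ctrl_rows, columns=subj_rows.columns)],
        ignore_index=True,
    )
    plate_effects = pd.DataFrame(
        {
            "plate_id": np.arange(n_plates),
            "effect": np.exp(rng.normal(0.0, config.plate_effect_sigma_log, n_plates)),
        }
    )
    return cohort, CohortTruth(subjects=subjects, plate_effects=plate_effects)


# ---------------------------------------------------------------------------
# well level (single-cell feature tables)
# ---------------------------------------------------------------------------

def _lp_param(default_lp: float, m: float, cap: float | None = None) -> float:
    """Starved-condition parameter for a subject with mobilization m.

    The reference subject (m = 1) gets the configured LP default; stronger
    mobilizers (m > 1) depress the starved value further, so that the
    CM/LP mobilization ratio scales with m.
    """
    v = default_lp / max(m, 1e-9)
    if cap is not None:
        v = min(v, cap)
    return v


def simulate_well_cells(
    subject: SubjectTruth,
    treatment: str,
    config: SimConfig,
    rng: np.random.Generator,
    cells_per_well: Mapping[str, int] | None = None,
    well_factor: float = 1.0,
) -> pd.DataFrame:
    """Draw the single-cell feature table of one well.

    Columns match the measured CellRecord schema so the table can flow
    straight into :func:`lipotrace.wells.aggregate_well`, plus a
    ``ld_droplet_areas_um2`` object column used by :func:`render_image`.

    ``well_factor`` is an optional multiplicative well-level factor on the
    uptake/LD rate parameters (used by the cohort-level feature simulator
    to model intraindividual variation); the default 1.0 draws features at
    exactly the configured subject rates.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    counts = dict(config.cells_per_well if cells_per_well is None else cells_per_well)

    u = subject.u * well_factor
    m = subject.m
    lp = treatment == "LP"

    frames = []
    for pop in POPULATIONS:
        n = int(counts.get(pop, 0))
        if n == 0:
            continue
        area = config.area_median_um2[pop] * np.exp(
            rng.normal(0.0, config.area_sigma_log[pop], n)
        )

        dii_mean = config.dii_no_mean_cm[pop] * u
        if lp:
            dii_mean *= config.starvation_fold_dii_no
        k = config.dii_no_dispersion
        if dii_mean > 0:
            dii_no = rng.negative_binomial(k, k / (k + dii_mean), n)
        else:
            dii_no = np.zeros(n, dtype=int)

        int_mean = config.dii_int_mean_cm[pop] * u
        if lp:
            int_mean *= config.starvation_fold_dii_int
        s = config.dii_int_sigma_log
        dii_int = int_mean * np.exp(rng.normal(-0.5 * s * s, s, n))

        if lp:
            p_pos = _lp_param(config.ld_pos_lp[pop], m, cap=0.99)
            ld_mean = max(1.0 + 1e-9, _lp_param(config.ld_no_mean_lp, m))
            a_mean = _lp_param(config.ld_droplet_area_mean_lp, m)
        else:
            p_pos = config.ld_pos_cm[pop]
            ld_mean = config.ld_no_mean_cm
            a_mean = config.ld_droplet_area_mean_cm
        p_pos = min(1.0, p_pos * well_factor)
        positive = rng.random(n) < p_pos
        ld_count = np.zeros(n, dtype=int)
        # LD count among positives: 1 + Poisson(mean - 1)
        ld_count[positive] = 1 + rng.poisson(ld_mean - 1.0, int(positive.sum()))
        shape = config.ld_area_shape
        droplet_areas = [
            rng.gamma(shape, a_mean / shape, c) if c else np.empty(0)
            for c in ld_count
        ]
        ld_total = np.array([a.sum() for a in droplet_areas])

        frames.append(
            pd.DataFrame(
                {
                    "population_true": pop,
                    "cytoplasm_area_um2": area,
                    "mean_dii_intensity": dii_int,
                    "dii_organelle_count": dii_no,
                    "ld_count": ld_count,
                    "ld_total_area_um2": ld_total,
                    "ld_droplet_areas_um2": droplet_areas,
                }
            )
        )
    if frames:
        cells = pd.concat(frames, ignore_index=True)
    else:
        cells = pd.DataFrame(
            columns=[
                "population_true", "cytoplasm_area_um2", "mean_dii_intensity",
                "dii_organelle_count", "ld_count", "ld_total_area_um2",
                "ld_droplet_areas_um2",
            ]
        )
    cells.insert(0, "cell_id", np.arange(1, len(cells) + 1))
    return cells


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderTruth:
    """Everything that was stamped into a rendered field."""

    cells: pd.DataFrame  # cell_id, population_true, row, col, radius_px, area
    puncta: pd.DataFrame  # channel, cell_id, row, col, sigma_px, area_um2


def _place_cells(
    radii: np.ndarray, shape: tuple[int, int], rng: np.random.Generator,
    max_attempts: int, margin: float = 2.0,
) -> np.ndarray:
    """Non-overlapping circle placement by grid-accelerated rejection sampling."""
    n = len(radii)
    centers = np.zeros((n, 2))
    if n == 0:
        return centers
    cell = 2.0 * radii.max() + margin
    grid: dict[tuple[int, int], list[int]] = {}
    order = np.argsort(-radii)  # large first packs better
    for idx in order:
        r = radii[idx]
        placed = False
        for _ in range(max_attempts):
            y = rng.uniform(r + margin, shape[0] - r - margin)
            x = rng.uniform(r + margin, shape[1] - r - margin)
            gy, gx = int(y // cell), int(x // cell)
            ok = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for j in grid.get((gy + dy, gx + dx), ()):
                        oy, ox = centers[j]
                        if (y - oy) ** 2 + (x - ox) ** 2 < (r + radii[j] + margin) ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                centers[idx] = (y, x)
                grid.setdefault((gy, gx), []).append(idx)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "field too small: could not place all cells without overlap; "
                "increase the field or lower packing_fraction"
            )
    return centers


def _stamp_disk(img: np.ndarray, cy: float, cx: float, r: float, level: float) -> None:
    y0, y1 = int(max(0, cy - r - 1)), int(min(img.shape[0], cy + r + 2))
    x0, x1 = int(max(0, cx - r - 1)), int(min(img.shape[1], cx + r + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += level * (((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r)


def _stamp_gaussian(img: np.ndarray, cy: float, cx: float, sigma: float, peak: float) -> None:
    R = int(math.ceil(4.0 * sigma))
    y0, y1 = int(max(0, round(cy) - R)), int(min(img.shape[0], round(cy) + R + 1))
    x0, x1 = int(max(0, round(cx) - R)), int(min(img.shape[1], round(cx) + R + 1))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += peak * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma * sigma)
    )


def _scatter_in_disk(
    n: int, r_eff: float, min_sep: float, rng: np.random.Generator,
) -> np.ndarray:
    """Dart-throwing placement of n points inside a disk of radius r_eff.

    The separation constraint is relaxed geometrically if the disk is too
    crowded, so the requested number of points is always returned.
    """
    pts = np.zeros((n, 2))
    sep = min_sep
    placed = 0
    while placed < n:
        for _ in range(200):
            rr = r_eff * math.sqrt(rng.random())
            th = rng.uniform(0.0, 2.0 * math.pi)
            y, x = rr * math.sin(th), rr * math.cos(th)
            if placed == 0 or np.all(
                (pts[:placed, 0] - y) ** 2 + (pts[:placed, 1] - x) ** 2 >= sep * sep
            ):
                pts[placed] = (y, x)
                placed += 1
                break
        else:
            sep *= 0.7  # crowded cell: relax separation, never drop a punctum
    return pts


def render_image(
    cell_table: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    field_shape: tuple[int, int] | None = None,
) -> tuple[ImageStack, RenderTruth]:
    """Render a well's cells into a 4-channel field with ground truth.

    Channels (in :data:`lipotrace.imaging.CHANNEL_ORDER`): nuclei (DAPI-like
    disks), cytoplasm (cell-mask disks), DiI (diffuse cellular signal plus
    one Gaussian punctum per internalized-LDL organelle) and LD (one
    Gaussian punctum per droplet, width set by droplet size and the PSF).
    A constant background and, by default, Poisson noise are added.

    With ``config.n_slices > 1`` a small z-stack is produced (puncta are
    assigned to single slices; extended structures span the stack with
    reduced intensity off-focus) to exercise maximum-intensity projection.
    """
    config.validate()
    px = config.pixel_size_um
    radii = np.sqrt(cell_table["cytoplasm_area_um2"].to_numpy(float) / math.pi) / px

    if field_shape is None:
        if len(radii):
            total = float(np.sum(math.pi * radii**2))
            side = int(math.ceil(math.sqrt(total / config.packing_fraction)))
            side = max(side, int(4 * (radii.max() + 4)), 128)
        else:
            side = 128
        field_shape = (side, side)
    shape = field_shape

    centers = _place_cells(radii, shape, rng, config.max_place_attempts)

    sharp = {name: np.zeros(shape) for name in CHANNEL_ORDER}
    psf = config.psf_sigma_px
    dii_sigma = math.sqrt(psf**2 + 0.5**2)  # endosomes: near point sources

    puncta_rows = []
    for i, (_, cell) in enumerate(cell_table.iterrows()):
        cy, cx = centers[i]
        r = radii[i]
        _stamp_disk(sharp["nuclei"], cy, cx, r * math.sqrt(config.nucleus_area_frac),
                    config.nucleus_level)
        _stamp_disk(sharp["cytoplasm"], cy, cx, r, config.cyto_level)
        _stamp_disk(sharp["dii"], cy, cx, r, float(cell["mean_dii_intensity"]))

        r_eff = max(1.0, r - 3.0)
        n_dii = int(cell["dii_organelle_count"])
        if n_dii:
            for dy, dx in _scatter_in_disk(n_dii, r_eff, config.min_punctum_sep_px, rng):
                puncta_rows.append(
                    ("dii", cell["cell_id"], cy + dy, cx + dx, dii_sigma, np.nan)
                )
        areas = cell["ld_droplet_areas_um2"]
        if len(areas):
            pts = _scatter_in_disk(len(areas), r_eff, config.min_punctum_sep_px, rng)
            for (dy, dx), a in zip(pts, areas):
                # droplet half-max support ~ its physical area
                r_d = math.sqrt(a / math.pi) / px
                sigma = math.sqrt(psf**2 + (r_d / 1.177) ** 2)
                puncta_rows.append(
                    ("ld", cell["cell_id"], cy + dy, cx + dx, sigma, a)
                )

    puncta = pd.DataFrame(
        puncta_rows, columns=["channel", "cell_id", "row", "col", "sigma_px", "area_um2"]
    )

    # blur extended structures by the PSF; diffuse DiI gets extra spread
    # (cell thickness) which keeps cytoplasm edges from mimicking puncta
    smooth = {
        "nuclei": ndimage.gaussian_filter(sharp["nuclei"], psf),
        "cytoplasm": ndimage.gaussian_filter(sharp["cytoplasm"], psf),
        "dii": ndimage.gaussian_filter(
            sharp["dii"], math.sqrt(psf**2 + config.dii_diffuse_blur_px**2)
        ),
        "ld": np.zeros(shape),
    }

    n_z = max(1, int(config.n_slices))
    if n_z > 1:
        zw = np.exp(-0.5 * ((np.arange(n_z) - (n_z - 1) / 2.0) / (n_z / 3.0)) ** 2)
        zw /= zw.max()
    else:
        zw = np.ones(1)
    planes = {
        name: np.stack([smooth[name] * w for w in zw]) for name in CHANNEL_ORDER
    }

    if len(puncta):
        z_idx = rng.integers(0, n_z, len(puncta))
        for (row, z) in zip(puncta.itertuples(index=False), z_idx):
            _stamp_gaussian(
                planes[row.channel][z], row.row, row.col, row.sigma_px,
                config.punctum_peak,
            )
    channels = {}
    for name in CHANNEL_ORDER:
        img = planes[name] + config.background
        if config.noise == "poisson":
            img = rng.poisson(img).astype(np.float64)
        if n_z == 1:
            img = img[0]
        channels[name] = img

    cells_truth = pd.DataFrame(
        {
            "cell_id": cell_table["cell_id"].to_numpy(),
            "population_true": cell_table["population_true"].to_numpy(),
            "row": centers[:, 0],
            "col": centers[:, 1],
            "radius_px": radii,
            "cytoplasm_area_um2": cell_table["cytoplasm_area_um2"].to_numpy(float),
        }
    )
    stack = ImageStack(channels=channels, pixel_size_um=px)
    return stack, RenderTruth(cells=cells_truth, puncta=puncta)


# ---------------------------------------------------------------------------
# cohort-level feature simulator (no rendering)
# ---------------------------------------------------------------------------

def simulate_well_aggregates(
    truth: CohortTruth,
    config: SimConfig,
    rng: np.random.Generator,
    cells_per_well: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Simulate the full plate layout at the single-cell feature level.

    For every (subject, treatment, replicate well) a single-cell table is
    drawn with :func:`simulate_well_cells` under an intraindividual
    well-level factor, the plate's multiplicative effect is applied to the
    DiI readouts, and the well is aggregated with
    :func:`lipotrace.wells.aggregate_well`.  Much faster than rendering and
    re-detecting images; used for cohort-scale statistics.
    """
    from .wells import add_population, aggregate_well

    effects = dict(zip(truth.plate_effects["plate_id"], truth.plate_effects["effect"]))
    out = []
    for subj in truth.subjects.itertuples(index=False):
        plate_eff = effects.get(subj.plate_id, 1.0)
        for treatment in TREATMENTS:
            for w in range(config.wells_per_treatment):
                wf = float(np.exp(rng.normal(0.0, config.intraindividual_cv)))
                cells = simulate_well_cells(
                    SubjectTruth(subj.subject_id, subj.group, subj.role,
                                 subj.plate_id, subj.u, subj.m),
                    treatment, config, rng,
                    cells_per_well=cells_per_well, well_factor=wf,
                )
                cells["mean_dii_intensity"] *= plate_eff
                cells = add_population(cells)
                agg = aggregate_well(
                    cells,
                    {
                        "well_id": f"{subj.subject_id}-{treatment}-w{w}",
                        "subject_id": subj.subject_id,
                        "plate_id": subj.plate_id,
                        "treatment": treatment,
                        "role": subj.role if subj.role != "sample" else "sample",
                    },
                )
                out.append(agg)
    return pd.DataFrame(out)


def simulate_ldlr_surface(
    truth: CohortTruth, config: SimConfig, rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-subject mean background-subtracted LDLR surface intensity.

    Scales with the latent uptake capacity, so LDLR surface levels and
    measured LDL uptake are positively coupled as in real monocytes.
    """
    s = config.ldlr_surface_sigma_log
    rows = []
    for subj in truth.subjects.itertuples(index=False):
        mean = config.ldlr_surface_mean * subj.u * float(np.exp(rng.normal(-0.5 * s * s, s)))
        rows.append(
            {"subject_id": subj.subject_id, "role": subj.role,
             "plate_id": subj.plate_id, "ldlr_surface_intensity": mean}
        )
    return pd.DataFrame(rows)


#: intraindividual coefficients of variation of the measured scores
#: (well-replicate reproducibility of the assay, per readout)
SCORE_CV = {
    "mo_dii_int": 0.12,
    "ly_dii_int": 0.15,
    "mo_dii_no": 0.076,
    "ly_dii_no": 0.21,
    "pan_uptake": 0.13,
    "mob_ld_pos": 0.10,
    "mob_ld_no": 0.11,
    "mob_ld_area": 0.13,
    "pan_mobilization": 0.08,
}


def simulate_measured_scores(
    truth: CohortTruth,
    config: SimConfig,
    rng: np.random.Generator,
    score_cv: Mapping[str, float] = SCORE_CV,
) -> pd.DataFrame:
    """Draw subject-level measured scores directly from the latents.

    Score-level shortcut of the full well pipeline for cohort-scale Monte
    Carlo: measured uptake parameters are ``100 * u`` (percent of the
    reference control) and mobilization scores are the reference CM/LP
    ratio times ``m``, each under multiplicative lognormal measurement
    noise at the assay's intraindividual CV for that readout.
    """
    ref_ratios = {
        "mob_ld_pos": np.mean(
            [config.ld_pos_cm[p] / config.ld_pos_lp[p] for p in POPULATIONS]
        ),
        "mob_ld_no": config.ld_no_mean_cm / config.ld_no_mean_lp,
        "mob_ld_area": (config.ld_no_mean_cm * config.ld_droplet_area_mean_cm)
        / (config.ld_no_mean_lp * config.ld_droplet_area_mean_lp),
    }
    samples = truth.subjects[truth.subjects["role"] == "sample"]
    n = len(samples)
    out = pd.DataFrame({"subject_id": samples["subject_id"].to_numpy()})
    u = samples["u"].to_numpy(float)
    m = samples["m"].to_numpy(float)

    def noisy(base: np.ndarray, key: str) -> np.ndarray:
        cv = score_cv.get(key, 0.0)
        return base * np.exp(rng.normal(0.0, cv, n))

    for key in ("mo_dii_int", "ly_dii_int", "mo_dii_no", "ly_dii_no"):
        out[key] = noisy(100.0 * u, key)
    out["pan_uptake"] = noisy(100.0 * u, "pan_uptake")
    for key, ratio in ref_ratios.items():
        out[key] = noisy(ratio * m, key)
    out["pan_mobilization"] = noisy(float(np.mean(list(ref_ratios.values()))) * m,
                                    "pan_mobilization")
    return out


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
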