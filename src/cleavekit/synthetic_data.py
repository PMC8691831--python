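"""Seeded generator of blastomere-like cells with known ground truth.

Emulates the measured populations of 4-cell-stage ascidian embryos: each
synthetic cell gets an anisotropic contour (elongated along the
animal-vegetal axis, one lateral side flattened by a cell-cell contact),
a metaphase and an anaphase spindle pose built from sampled true tilt and
centering values, and Gaussian coordinate jitter on the pose landmarks.
"Measured" quantities are then recomputed from the jittered poses through
:mod:`cleavekit.spindle_metrics`, so recovery tests exercise the whole
measurement pipeline rather than the generator alone.

Lineage defaults follow the reported stage means: the posterior B3 pair
(sagittal view) tilts 9.6 deg at metaphase and 21.3 deg at anaphase onset
with the spindle off-centring toward the vegetal pole; the anterior A3
pair (transversal view) is untilted at metaphase and tilts 5.67 deg at
anaphase with slight animal-ward off-centring; "isolated" blastomeres
keep the B3 tilt/centering program but are nearly round (mitotic shape
outside embryo confinement). Tilt spreads and centering/shape
distributions are not printed in the source data and are package defaults
(see docs/methods.md); every value is configurable.

Contours are generated with the flat contact on the negative
``sign_reference`` side, so a positive sampled tilt (vegetal pole moving
away from the contact) produces the vegetal-larger divisions seen in
embryos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .geometry2d import Contour, circularity, polygon_area
from .shape_models import ShapeSpec, make_shape, shape_anisotropy
from .spindle_metrics import (
    SpindlePose,
    centering_ratio,
    division_prediction,
    line_contour_intersections,
    spindle_angle,
)
from .virtual_experiments import POLE_FRACTION, apply_tilt_centered, reposition_centered

STAGES = ("metaphase", "anaphase")
LINEAGES = ("A3_transversal", "B3_sagittal", "isolated")


@dataclass(frozen=True)
class GeneratorConfig:
    """Population parameters of one synthetic experiment.

    Tilt and centering models are per-stage normals (mean, sd); shape
    parameters are normals truncated to their valid ranges. ``noise_sd``
    is the coordinate jitter (um) applied to pose landmarks.
    """

    n_cells: int = 50
    lineage: str = "B3_sagittal"
    seed: int = 0
    # shape distribution
    elongation_mean: float = 1.6
    elongation_sd: float = 0.15
    flattening_mean: float = 0.35
    flattening_sd: float = 0.08
    radius_mean: float = 25.0
    radius_sd: float = 2.5
    n_vertices: int = 256
    # tilt model (degrees)
    tilt_mean: dict = field(default_factory=lambda: {"metaphase": 9.6,
                                                     "anaphase": 21.3})
    tilt_sd: dict = field(default_factory=lambda: {"metaphase": 4.0,
                                                   "anaphase": 6.0})
    # centering model (dimensionless, 0.5 = centred)
    centering_mean: dict = field(default_factory=lambda: {"metaphase": 0.5,
                                                          "anaphase": 0.52})
    centering_sd: dict = field(default_factory=lambda: {"metaphase": 0.03,
                                                        "anaphase": 0.04})
    noise_sd: float = 0.5

    def __post_init__(self):
        if self.lineage not in LINEAGES:
            raise ParameterError(f"unknown lineage {self.lineage!r}")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        sds = [self.elongation_sd, self.flattening_sd, self.radius_sd,
               self.noise_sd, *self.tilt_sd.values(), *self.centering_sd.values()]
        if any(s < 0 for s in sds):
            raise ParameterError("standard deviations must be non-negative")
        if any(not 0.0 < m < 1.0 for m in self.centering_mean.values()):
            raise ParameterError("centering means must lie in (0, 1)")

    @classmethod
    def defaults(cls, lineage: str, n_cells: int = 50,
                 seed: int = 0, **overrides) -> "GeneratorConfig":
        """Lineage presets with the reported stage means."""
        presets = {
            "B3_sagittal": dict(
                tilt_mean={"metaphase": 9.6, "anaphase": 21.3},
                centering_mean={"metaphase": 0.5, "anaphase": 0.52},
            ),
            "A3_transversal": dict(
                tilt_mean={"metaphase": 0.0, "anaphase": 5.67},
                centering_mean={"metaphase": 0.5, "anaphase": 0.48},
            ),
            "isolated": dict(
                tilt_mean={"metaphase": 9.6, "anaphase": 21.3},
                centering_mean={"metaphase": 0.5, "anaphase": 0.52},
                elongation_mean=1.05, elongation_sd=0.05,
                flattening_mean=0.02, flattening_sd=0.02,
            ),
        }
        kwargs = presets[lineage] | overrides
        return cls(n_cells=n_cells, lineage=lineage, seed=seed, **kwargs)


@dataclass(frozen=True)
class SyntheticCell:
    """One cell: ground-truth parameters, contour, and observed poses."""

    cell_id: str
    lineage: str
    shape_spec: ShapeSpec
    contour: Contour
    true_tilt: dict
    true_centering: dict
    observed_pose: dict  # stage -> SpindlePose (jittered)
    true_pose: dict  # stage -> SpindlePose (noise-free)


@dataclass(frozen=True)
class SyntheticDataset:
    """Seed-reproducible population of synthetic cells."""

    config: GeneratorConfig
    cells: tuple

    def __len__(self):
        return len(self.cells)


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    # per-cell substream keyed by index: growing n_cells never reshuffles
    # earlier cells
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(np.clip(mean, lo + 1e-9, hi - 1e-9))


def _pose_with_centering(contour: Contour, tilted_pose: SpindlePose,
                         target: float) -> SpindlePose:
    """Move the plate along the tilted axis so the centering ratio = target."""
    line = tilted_pose.axis_line  # oriented vegetal -> animal
    ts = sorted(line.coordinate(p)
                for p in line_contour_intersections(contour, line))
    t_lo, t_hi = ts[0], ts[-1]  # vegetal-most, animal-most chord ends
    edge_animal = tilted_pose.plate + t_hi * line.direction
    edge_vegetal = tilted_pose.plate + t_lo * line.direction
    plate = edge_animal + target * (edge_vegetal - edge_animal)
    half = 0.5 * POLE_FRACTION * (t_hi - t_lo)
    return SpindlePose(pole_animal=plate + half * line.direction,
                       pole_vegetal=plate - half * line.direction,
                       plate=plate)


def _jitter_pose(pose: SpindlePose, sd: float,
                 rng: np.random.Generator) -> SpindlePose:
    if sd == 0:
        return pose
    pa = pose.pole_animal + rng.normal(0.0, sd, 2)
    pv = pose.pole_vegetal + rng.normal(0.0, sd, 2)
    plate = pose.plate + rng.normal(0.0, sd, 2)
    # the plate stays on the (jittered) pole axis: project and clamp
    seg = pv - pa
    t = float(np.clip(np.dot(plate - pa, seg) / np.dot(seg, seg), 0.01, 0.99))
    return SpindlePose(pole_animal=pa, pole_vegetal=pv, plate=pa + t * seg)


def generate_population(config: GeneratorConfig) -> SyntheticDataset:
    """Sample a full population of cells per the configured distributions."""
    cells = []
    for i in range(config.n_cells):
        rng = _cell_rng(config.seed, i)
        spec = ShapeSpec(
            kind="blastomere",
            radius=_truncated_normal(rng, config.radius_mean, config.radius_sd,
                                     5.0, np.inf),
            elongation=_truncated_normal(rng, config.elongation_mean,
                                         config.elongation_sd, 0.5, 5.0),
            contact_flattening=_truncated_normal(rng, config.flattening_mean,
                                                 config.flattening_sd,
                                                 0.0, 0.9),
            n_vertices=config.n_vertices,
        )
        # the contact sits on the -x side; tilt toward +x = away from it
        contour = make_shape(spec)
        frame = contour.axis_frame
        centered = reposition_centered(contour, frame)
        true_tilt, true_centering = {}, {}
        observed, true_pose = {}, {}
        for stage in STAGES:
            tilt = rng.normal(config.tilt_mean[stage], config.tilt_sd[stage])
            tilt = float(np.clip(tilt, -85.0, 85.0))
            cen = _truncated_normal(rng, config.centering_mean[stage],
                                    config.centering_sd[stage], 0.02, 0.98)
            pose = apply_tilt_centered(contour, centered, tilt, frame=frame)
            pose = _pose_with_centering(contour, pose, cen)
            true_tilt[stage] = tilt
            true_centering[stage] = cen
            true_pose[stage] = pose
            observed[stage] = _jitter_pose(pose, config.noise_sd, rng)
        cells.append(SyntheticCell(
            cell_id=f"{config.lineage}_{i:04d}", lineage=config.lineage,
            shape_spec=spec, contour=contour,
            true_tilt=true_tilt, true_centering=true_centering,
            observed_pose=observed, true_pose=true_pose,
        ))
    return SyntheticDataset(config=config, cells=tuple(cells))


def ground_truth_table(dataset: SyntheticDataset) -> pd.DataFrame:
    """Tidy table, one row per cell x stage, with true and measured values.

    Measured columns are recomputed from the jittered observed poses via
    the spindle metrics, including the division prediction.
    """
    rows = []
    for cell in dataset.cells:
        frame = cell.contour.axis_frame
        for stage in STAGES:
            pose = cell.observed_pose[stage]
            rows.append({
                "cell_id": cell.cell_id,
                "lineage": cell.lineage,
                "stage": stage,
                "true_tilt": cell.true_tilt[stage],
                "measured_tilt": spindle_angle(pose, frame),
                "true_centering": cell.true_centering[stage],
                "measured_centering": centering_ratio(cell.contour, pose).value,
                "relative_animal":
                    division_prediction(cell.contour, pose).relative_animal,
                "circularity": circularity(cell.contour),
                "anisotropy": shape_anisotropy(cell.contour, frame),
                "area": polygon_area(cell.contour),
            })
    return pd.DataFrame(rows)


def rounding_ucd_sweep(rounding_levels=None, tilt_deg: float = 21.3,
                       n_vertices: int = 256) -> pd.DataFrame:
    """Deterministic sweep of mother-cell roundness vs division asymmetry.

    Interpolates the default anisotropic blastomere shape toward the
    circle (``rounding`` 0 = fully anisotropic, 1 = round), applies a
    fixed centred tilt, and records the 2D circularity together with
    |relative_animal - 0.5|. Reproduces, at the contour level, the
    observation that rounder mother cells divide more equally at the same
    spindle tilt.
    """
    if rounding_levels is None:
        rounding_levels = np.linspace(0.0, 1.0, 9)
    rows = []
    for r in np.asarray(rounding_levels, dtype=float):
        spec = ShapeSpec(kind="blastomere", radius=25.0,
                         elongation=1.0 + 0.6 * (1.0 - r),
                         contact_flattening=0.4 * (1.0 - r),
                         n_vertices=n_vertices)
        contour = make_shape(spec)
        frame = contour.axis_frame
        pose = apply_tilt_centered(contour, reposition_centered(contour, frame),
                                   tilt_deg, frame=frame)
        rel = division_prediction(contour, pose).relative_animal
        rows.append({
            "rounding": float(r),
            "circularity": circularity(contour),
            "relative_animal": rel,
            "abs_ucd": abs(rel - 0.5),
        })
    return pd.DataFrame(rows)
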