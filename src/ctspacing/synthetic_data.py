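"""Synthetic inputs for the whole pipeline: phantom series and measurement tables.

Two generators, each emulating one input of the study design:

* :func:`make_series` builds a DICOM-ready slice stack whose positions follow
  a V x m sub-volume pattern — V acquisition blocks of m slices, gap w inside
  a block and gap b between blocks — optionally with an ellipsoid phantom and
  two bright point fiducials at known physical positions.  The problem case
  of the studied collection is V=51, m=6, w=0.60 mm, b=0.50 mm with a stated
  spacing of 0.60 mm; clean series are V=1 at 0.60 or 0.75 mm.

* :func:`make_measurement_table` builds a long-format repeated-measurement
  table with the study's structure: three specimen groups (true spacings
  0.75 / 0.58360656 / 0.60 mm), 10 replicates per specimen per modality,
  additive Gaussian measurement noise, a single offset Microscribe value per
  specimen, and the multiplicative axial distortion
  D * sqrt((1-f) + f*(s_assigned/s_true)^2) whenever a CT modality's assigned
  spacing differs from the group's true spacing.

Determinism: one seed governs a generator call; per-specimen substreams are
derived from (seed, group index, specimen index), so adding specimens never
perturbs the draws of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dicom_io import SeriesGeometry, SliceRecord
from .errors import FiducialOutOfBoundsError
from .validation_stats import MICROSCRIBE, MeasurementTable

PHANTOM_NONE = "NONE"
PHANTOM_ELLIPSOID = "ELLIPSOID_WITH_FIDUCIALS"

#: the regularized spacing of the study's canonical problem series
#: (51 blocks x 6 slices, 0.60 within, 0.50 between): 178 / 305 mm
REGULARIZED_058 = 178.0 / 305.0


@dataclass
class SyntheticSeriesSpec:
    """Recipe for one phantom series (see module docstring for the pattern)."""

    specimen_id: str = "SYN001"
    n_volumes: int = 1
    slices_per_volume: int = 10
    within_gap_mm: float = 0.60
    between_gap_mm: float = 0.50
    stated_spacing_mm: float = 0.60
    pixel_spacing_mm: tuple[float, float] = (0.5, 0.5)
    n_rows: int = 32
    n_cols: int = 32
    phantom: str = PHANTOM_NONE
    fiducial_positions_mm: Optional[tuple] = None  # pair of (x, y, z) vectors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 1 or self.slices_per_volume < 1:
            raise ValueError("need n_volumes >= 1 and slices_per_volume >= 1")
        if self.n_volumes * self.slices_per_volume < 2:
            raise ValueError("series must contain at least 2 slices")
        if self.within_gap_mm <= 0 or self.between_gap_mm <= 0:
            raise ValueError("gaps must be positive")
        if self.stated_spacing_mm <= 0 or min(self.pixel_spacing_mm) <= 0:
            raise ValueError("spacings must be positive")
        if self.phantom not in (PHANTOM_NONE, PHANTOM_ELLIPSOID):
            raise ValueError(f"unknown phantom: {self.phantom}")

    @property
    def n_slices(self) -> int:
        return self.n_volumes * self.slices_per_volume

    def gap_pattern(self) -> list[float]:
        """The V x m / w / b gap sequence, length n_slices - 1."""
        gaps: list[float] = []
        for v in range(self.n_volumes):
            gaps.extend([self.within_gap_mm] * (self.slices_per_volume - 1))
            if v < self.n_volumes - 1:
                gaps.append(self.between_gap_mm)
        return gaps


def w584_series_spec(phantom: str = PHANTOM_NONE, seed: int = 0) -> SyntheticSeriesSpec:
    """The canonical problem series: 51 blocks of 6 slices, 0.60 mm within,
    0.50 mm between, stated spacing 0.60 mm (regularizes to 0.58360656)."""
    return SyntheticSeriesSpec(
        specimen_id="W584",
        n_volumes=51,
        slices_per_volume=6,
        within_gap_mm=0.60,
        between_gap_mm=0.50,
        stated_spacing_mm=0.60,
        phantom=phantom,
        seed=seed,
    )


def uniform_series_spec(
    spacing_mm: float = 0.75, n_slices: int = 10, specimen_id: str = "SYN001",
    seed: int = 0,
) -> SyntheticSeriesSpec:
    """A clean single-block series with matching metadata."""
    return SyntheticSeriesSpec(
        specimen_id=specimen_id,
        n_volumes=1,
        slices_per_volume=n_slices,
        within_gap_mm=spacing_mm,
        stated_spacing_mm=spacing_mm,
        seed=seed,
    )


def _extent(spec: SyntheticSeriesSpec, offsets: np.ndarray) -> tuple[float, float, float]:
    x_max = (spec.n_cols - 1) * spec.pixel_spacing_mm[1]
    y_max = (spec.n_rows - 1) * spec.pixel_spacing_mm[0]
    return x_max, y_max, float(offsets[-1])


def _phantom_stack(
    spec: SyntheticSeriesSpec, offsets: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, int, int]], list[np.ndarray]]:
    """Ellipsoid + fiducial pixel stack; returns (volume, fiducial voxel
    indices, fiducial physical positions snapped to voxel centres)."""
    rng = np.random.default_rng(spec.seed)
    x_max, y_max, z_max = _extent(spec, offsets)
    ps_row, ps_col = spec.pixel_spacing_mm
    if spec.fiducial_positions_mm is None:
        fiducials = [
            np.array([x_max / 2, y_max / 2, 0.05 * z_max]),
            np.array([x_max / 2, y_max / 2, 0.95 * z_max]),
        ]
    else:
        fiducials = [np.asarray(p, dtype=float) for p in spec.fiducial_positions_mm]
    for p in fiducials:
        if not (0 <= p[0] <= x_max and 0 <= p[1] <= y_max and 0 <= p[2] <= z_max):
            raise FiducialOutOfBoundsError(f"fiducial out of bounds: {p}")

    n = spec.n_slices
    vol = rng.integers(0, 10, size=(n, spec.n_rows, spec.n_cols)).astype(float)
    # bright ellipsoid filling ~70% of each extent, centred in the volume
    cols = np.arange(spec.n_cols) * ps_col
    rows = np.arange(spec.n_rows) * ps_row
    zz = offsets[:, None, None]
    yy = rows[None, :, None]
    xx = cols[None, None, :]
    semi = (0.35 * max(x_max, ps_col), 0.35 * max(y_max, ps_row), 0.35 * max(z_max, 1.0))
    inside = (
        ((xx - x_max / 2) / semi[0]) ** 2
        + ((yy - y_max / 2) / semi[1]) ** 2
        + ((zz - z_max / 2) / semi[2]) ** 2
    ) <= 1.0
    vol[inside] = 400.0

    voxels = []
    snapped = []
    for p in fiducials:
        col = int(round(p[0] / ps_col))
        row = int(round(p[1] / ps_row))
        k = int(np.argmin(np.abs(offsets - p[2])))
        vol[k, row, col] = 1000.0
        voxels.append((row, col, k))
        snapped.append(np.array([col * ps_col, row * ps_row, offsets[k]]))
    return vol, voxels, snapped


def make_series(spec: SyntheticSeriesSpec) -> tuple[SeriesGeometry, dict]:
    """Realize the spec as an in-memory geometry plus a ground-truth record.

    The ground truth carries the generating parameters, the exact offsets,
    and — for fiducial phantoms — the snapped physical fiducial positions
    and their true separation.
    """
    offsets = np.concatenate([[0.0], np.cumsum(spec.gap_pattern())])
    truth: dict = {
        "specimen_id": spec.specimen_id,
        "n_volumes": spec.n_volumes,
        "slices_per_volume": spec.slices_per_volume,
        "within_gap_mm": spec.within_gap_mm,
        "between_gap_mm": spec.between_gap_mm,
        "stated_spacing_mm": spec.stated_spacing_mm,
        "n_slices": spec.n_slices,
        "offsets_mm": offsets.tolist(),
    }
    pixel_stack: Optional[np.ndarray] = None
    if spec.phantom == PHANTOM_ELLIPSOID:
        pixel_stack, voxels, positions = _phantom_stack(spec, offsets)
        truth["fiducial_voxels"] = [list(v) for v in voxels]
        truth["fiducial_positions_mm"] = [p.tolist() for p in positions]
        truth["fiducial_distance_mm"] = float(
            np.linalg.norm(positions[1] - positions[0])
        )
    slices = []
    for i, z in enumerate(offsets):
        slices.append(
            SliceRecord(
                specimen_id=spec.specimen_id,
                instance_index=i + 1,
                acquisition_index=i // spec.slices_per_volume + 1,
                position_mm=np.array([0.0, 0.0, z]),
                row_dir=np.array([1.0, 0.0, 0.0]),
                col_dir=np.array([0.0, 1.0, 0.0]),
                pixel_spacing_mm=spec.pixel_spacing_mm,
                stated_spacing_mm=spec.stated_spacing_mm,
                n_rows=spec.n_rows,
                n_cols=spec.n_cols,
                pixels=None if pixel_stack is None else pixel_stack[i],
            )
        )
    return SeriesGeometry.from_slices(slices, spec.specimen_id), truth


def find_fiducials(geometry: SeriesGeometry) -> list[tuple[int, int, int]]:
    """Locate the two brightest voxels of a phantom stack as (row, col, slice)
    indices in slice-sorted order."""
    vol = np.stack([s.pixels for s in geometry.slices])
    flat = np.argsort(vol, axis=None)[-2:]
    out = []
    for idx in flat:
        k, row, col = np.unravel_index(idx, vol.shape)
        out.append((int(row), int(col), int(k)))
    return sorted(out, key=lambda v: v[2])


@dataclass
class SyntheticMeasurementSpec:
    """Recipe for a repeated-measurement table with the study's structure.

    Noise levels and the Microscribe offset are this package's defaults,
    chosen to reproduce interval widths of roughly 1-3 mm and the tendency of
    digitizer values to sit slightly high; they are not published quantities
    and are all configurable.
    """

    n_specimens: dict = field(default_factory=lambda: {"G1": 10, "G2": 5, "G3": 5})
    true_distance_range_mm: tuple[float, float] = (110.0, 155.0)
    axial_fraction: float = 1.0
    group_true_spacing_mm: dict = field(
        default_factory=lambda: {"G1": 0.75, "G2": 0.60, "G3": REGULARIZED_058}
    )
    group_ct_modalities: dict = field(
        default_factory=lambda: {
            "G1": {"CT_0.75": 0.75},
            "G2": {"CT_0.60": 0.60, "CT_0.58": REGULARIZED_058},
            "G3": {"CT_0.58": REGULARIZED_058, "CT_0.60": 0.60},
        }
    )
    noise_sd_mm: dict = field(
        default_factory=lambda: {"Original": 0.4, "CT": 0.3, "Microscribe": 0.3}
    )
    microscribe_offset_mm: float = 0.5
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if not (0.0 <= self.axial_fraction <= 1.0):
            raise ValueError("axial_fraction must lie in [0, 1]")
        if any(v < 0 for v in self.noise_sd_mm.values()):
            raise ValueError("noise sds must be non-negative")
        if any(s <= 0 for s in self.group_true_spacing_mm.values()):
            raise ValueError("spacings must be positive")


def _ct_mean(D: float, f: float, s_assigned: float, s_true: float) -> float:
    return D * np.sqrt((1.0 - f) + f * (s_assigned / s_true) ** 2)


def make_measurement_table(
    spec: SyntheticMeasurementSpec, with_truth: bool = False
):
    """Draw a full measurement table; optionally also the ground-truth frame.

    Per specimen: true distance D ~ U(range); caliper replicates
    N(D, sd_Original); CT replicates N(D * sqrt((1-f)+f*(s_a/s_t)^2), sd_CT);
    one Microscribe value N(D + offset, sd_Microscribe).
    """
    rows = []
    truth_rows = []
    for gi, (group, count) in enumerate(sorted(spec.n_specimens.items())):
        s_true = spec.group_true_spacing_mm[group]
        for si in range(count):
            rng = np.random.default_rng([spec.seed, gi, si])
            specimen = f"{group}S{si + 1:02d}"
            D = float(rng.uniform(*spec.true_distance_range_mm))
            truth_rows.append(
                {
                    "specimen_id": specimen,
                    "group": group,
                    "true_distance_mm": D,
                    "true_spacing_mm": s_true,
                }
            )
            for r, v in enumerate(
                rng.normal(D, spec.noise_sd_mm["Original"], spec.replicates)
            ):
                rows.append((specimen, group, "Original", r + 1, float(v)))
            for modality, s_a in sorted(spec.group_ct_modalities[group].items()):
                mean = _ct_mean(D, spec.axial_fraction, s_a, s_true)
                for r, v in enumerate(
                    rng.normal(mean, spec.noise_sd_mm["CT"], spec.replicates)
                ):
                    rows.append((specimen, group, modality, r + 1, float(v)))
            ms = float(
                rng.normal(
                    D + spec.microscribe_offset_mm, spec.noise_sd_mm["Microscribe"]
                )
            )
            rows.append((specimen, group, MICROSCRIBE, 1, ms))
    table = MeasurementTable(
        pd.DataFrame(
            rows,
            columns=["specimen_id", "group", "modality", "replicate", "distance_mm"],
        )
    )
    if with_truth:
        return table, pd.DataFrame(truth_rows)
    return table
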