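"""Organoid-aggregation quantification from micromold scans.

Each microwell gets a circular ROI; particles are thresholded connected
components inside the ROI, assigned to the well containing their centroid.
Particles with area strictly greater than 300 um^2 count as organoids; the
headline statistic is aggregates per microwell = organoid count / visible
wells (higher = poorer aggregation). Per-condition particles-per-well
histograms are compared as kernel-smoothed frequency curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import match_template, peak_local_max
from skimage.filters import threshold_otsu

from .images import MultiChannelImage

__all__ = [
    "WellGrid",
    "ParticleTable",
    "AggregationSummary",
    "detect_wells",
    "count_particles",
    "summarize_aggregation",
    "particle_count_distribution",
    "curve_l1_distance",
    "ORGANOID_MIN_AREA_UM2",
]

ORGANOID_MIN_AREA_UM2 = 300.0


@dataclass
class WellGrid:
    """Circular ROIs over the microwell lattice."""

    wells: pd.DataFrame  # well_id, center_row, center_col (px)
    radius_px: float
    pixel_size: float
    excluded: dict[int, str] = field(default_factory=dict)

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    @property
    def n_visible_wells(self) -> int:
        return len(self.wells) - len(self.excluded)

    def visible_ids(self) -> list[int]:
        return [int(w) for w in self.wells["well_id"] if int(w) not in self.excluded]

    def exclude(self, well_id: int, reason: str = "manual") -> None:
        self.excluded[int(well_id)] = reason


@dataclass
class ParticleTable:
    """Per-particle records plus per-well counts."""

    particles: pd.DataFrame  # particle_id, well_id, center_row, center_col, area_um2, is_organoid
    well_counts: pd.DataFrame  # well_id, particle_count, organoid_count
    organoid_min_area_um2: float = ORGANOID_MIN_AREA_UM2

    def counts_per_well(self, organoids_only: bool = False) -> np.ndarray:
        col = "organoid_count" if organoids_only else "particle_count"
        return self.well_counts[col].to_numpy()


@dataclass
class AggregationSummary:
    n_visible_wells: int
    organoid_count: int
    aggregates_per_microwell: float
    mean_organoid_area_um2: float
    timepoint: str = ""


def _lattice_offset(coords: np.ndarray, pitch: float) -> float:
    """Offset of a 1D lattice from peak coordinates, robust to wrap-around."""
    phase = 2.0 * np.pi * (coords % pitch) / pitch
    mean_angle = math.atan2(np.sin(phase).mean(), np.cos(phase).mean()) % (2.0 * np.pi)
    return mean_angle / (2.0 * np.pi) * pitch


def detect_wells(
    image: MultiChannelImage,
    grid: tuple[int, int],
    well_diameter_um: float,
    well_pitch_um: float,
    mode: str = "auto",
    exclude: list[int] | None = None,
) -> WellGrid:
    """Place microwell ROIs on a scan.

    ``mode="auto"`` locates wells by normalized cross-correlation with a ring
    template and snaps them to the stated lattice (error if fewer than half
    the expected wells respond); ``mode="spec"`` places the lattice purely
    geometrically, centered in the image — usable even on a blank scan.
    """
    chan = image.data[:, :, 0]
    n_rows, n_cols = grid
    pitch_px = well_pitch_um / image.pixel_size
    well_r_px = 0.5 * well_diameter_um / image.pixel_size

    if mode == "spec" or chan.max() - chan.min() < 1e-12:
        r0 = (chan.shape[0] - n_rows * pitch_px) / 2.0 + 0.5 * pitch_px
        c0 = (chan.shape[1] - n_cols * pitch_px) / 2.0 + 0.5 * pitch_px
        centers = [
            (i * n_cols + j, r0 + i * pitch_px, c0 + j * pitch_px)
            for i in range(n_rows)
            for j in range(n_cols)
        ]
    elif mode == "auto":
        size = int(2 * (well_r_px + 4)) | 1
        yy, xx = np.mgrid[0:size, 0:size] - size // 2
        dist = np.hypot(yy, xx)
        template = ((dist >= well_r_px - 2) & (dist <= well_r_px + 2)).astype(float)
        corr = match_template(chan, template, pad_input=True)
        peaks = peak_local_max(
            corr,
            min_distance=max(int(0.6 * pitch_px), 1),
            threshold_abs=0.15,
            num_peaks=4 * n_rows * n_cols,
        )
        if len(peaks) < 0.5 * n_rows * n_cols:
            raise ValueError(
                f"well auto-detection found {len(peaks)} of {n_rows * n_cols} expected wells"
            )
        r_off = _lattice_offset(peaks[:, 0].astype(float), pitch_px)
        c_off = _lattice_offset(peaks[:, 1].astype(float), pitch_px)
        row_pos = _snap_lattice(peaks[:, 0], r_off, pitch_px, n_rows, chan.shape[0])
        col_pos = _snap_lattice(peaks[:, 1], c_off, pitch_px, n_cols, chan.shape[1])
        centers = [
            (i * n_cols + j, row_pos[i], col_pos[j])
            for i in range(n_rows)
            for j in range(n_cols)
        ]
    else:
        raise ValueError(f"unknown mode '{mode}'")

    wells = pd.DataFrame(centers, columns=["well_id", "center_row", "center_col"])
    wg = WellGrid(wells=wells, radius_px=well_r_px, pixel_size=image.pixel_size)
    for w in exclude or []:
        wg.exclude(w, "manual")
    return wg


def _snap_lattice(coords: np.ndarray, offset: float, pitch: float, n: int, extent: int) -> np.ndarray:
    """Choose n consecutive lattice positions best covered by the peaks."""
    k_max = int(extent // pitch) + 1
    candidates = offset + np.arange(-1, k_max + 1) * pitch
    candidates = candidates[(candidates > 0) & (candidates < extent)]
    hits = np.array([np.sum(np.abs(coords[:, None] - candidates[None, :]) < pitch / 4, axis=0)]).ravel()
    if len(candidates) < n:
        raise ValueError("lattice does not fit in the image")
    best, best_score = 0, -1
    for s in range(len(candidates) - n + 1):
        score = hits[s : s + n].sum()
        if score > best_score:
            best, best_score = s, score
    return candidates[best : best + n]


def count_particles(
    image: MultiChannelImage,
    grid: WellGrid,
    threshold: str | float = "auto",
    min_particle_area_um2: float = 20.0,
    organoid_min_area_um2: float = ORGANOID_MIN_AREA_UM2,
) -> ParticleTable:
    """Count thresholded particles per microwell ROI.

    Each ROI (the well interior, ring excluded) is thresholded by Otsu
    (``threshold="auto"``) or a fixed value; 8-connected components above the
    debris floor ``min_particle_area_um2`` become particles, assigned to the
    well containing their centroid, and flagged as organoids when their area
    strictly exceeds ``organoid_min_area_um2``. A saturated ROI (nearly all
    foreground) is flagged and excluded.
    """
    chan = image.data[:, :, 0]
    px2 = image.pixel_size**2
    interior_r = grid.radius_px - 3.0
    global_range = chan.max() - chan.min()

    rows = []
    counts = []
    pid = 0
    for _, w in grid.wells.iterrows():
        wid = int(w["well_id"])
        if wid in grid.excluded:
            counts.append({"well_id": wid, "particle_count": 0, "organoid_count": 0})
            continue
        cy, cx = w["center_row"], w["center_col"]
        r0 = max(int(cy - interior_r) - 1, 0)
        r1 = min(int(cy + interior_r) + 2, chan.shape[0])
        c0 = max(int(cx - interior_r) - 1, 0)
        c1 = min(int(cx + interior_r) + 2, chan.shape[1])
        win = chan[r0:r1, c0:c1]
        yy, xx = np.mgrid[r0:r1, c0:c1]
        roi = np.hypot(yy - cy, xx - cx) <= interior_r
        vals = win[roi]
        n_part, n_org = 0, 0
        if vals.size:
            local_range = vals.max() - vals.min()
            if isinstance(threshold, str):
                thr = threshold_otsu(vals) if (global_range > 0 and local_range > 0.1 * global_range) else None
            else:
                thr = float(threshold)
            if thr is not None:
                fg = roi & (win > thr)
                if fg[roi].mean() > 0.99:
                    grid.exclude(wid, "saturated")
                    counts.append({"well_id": wid, "particle_count": 0, "organoid_count": 0})
                    continue
                labels, n_obj = ndi.label(fg, structure=np.ones((3, 3)))
                for p in range(1, n_obj + 1):
                    sel = labels == p
                    area = float(sel.sum()) * px2
                    if area < min_particle_area_um2:
                        continue
                    cr, cc = ndi.center_of_mass(sel)
                    cr, cc = cr + r0, cc + c0
                    if math.hypot(cr - cy, cc - cx) > grid.radius_px:
                        continue
                    is_org = area > organoid_min_area_um2
                    rows.append(
                        {
                            "particle_id": pid,
                            "well_id": wid,
                            "center_row": cr,
                            "center_col": cc,
                            "area_um2": area,
                            "is_organoid": is_org,
                        }
                    )
                    pid += 1
                    n_part += 1
                    n_org += int(is_org)
        counts.append({"well_id": wid, "particle_count": n_part, "organoid_count": n_org})

    particles = pd.DataFrame(
        rows, columns=["particle_id", "well_id", "center_row", "center_col", "area_um2", "is_organoid"]
    )
    visible = set(grid.visible_ids())
    well_counts = pd.DataFrame(counts)
    well_counts = well_counts[well_counts["well_id"].isin(visible)].reset_index(drop=True)
    return ParticleTable(
        particles=particles, well_counts=well_counts, organoid_min_area_um2=organoid_min_area_um2
    )


def summarize_aggregation(table: ParticleTable, grid: WellGrid, timepoint: str = "") -> AggregationSummary:
    """Organoid count / visible wells, and mean area per organoid."""
    n_visible = grid.n_visible_wells
    if n_visible < 1:
        raise ValueError("no visible wells")
    org = table.particles[table.particles["is_organoid"]]
    n_org = len(org)
    return AggregationSummary(
        n_visible_wells=n_visible,
        organoid_count=n_org,
        aggregates_per_microwell=n_org / n_visible,
        mean_organoid_area_um2=float(org["area_um2"].mean()) if n_org else float("nan"),
        timepoint=timepoint,
    )


def particle_count_distribution(
    counts_by_condition: dict[str, np.ndarray],
    bandwidth: float = 0.5,
    n_points: int = 512,
) -> pd.DataFrame:
    """Kernel-smoothed particles-per-well frequency curves on a shared support.

    Each condition's integer histogram is convolved with a Gaussian kernel of
    sd ``bandwidth`` (counts); every curve is renormalized to unit area so
    conditions with different numbers of wells are comparable. Returns a
    DataFrame with a ``count`` support column and one column per condition.
    """
    if not counts_by_condition:
        raise ValueError("no conditions supplied")
    max_count = max(int(np.max(c)) if len(c) else 0 for c in counts_by_condition.values())
    support = np.linspace(-1.0, max_count + 4.0 * bandwidth + 1.0, n_points)
    out = pd.DataFrame({"count": support})
    for name, counts in counts_by_condition.items():
        counts = np.asarray(counts, dtype=float)
        if len(counts) == 0:
            raise ValueError(f"condition '{name}' has no wells")
        curve = np.zeros_like(support)
        for c in counts:
            curve += np.exp(-0.5 * ((support - c) / bandwidth) ** 2)
        curve /= len(counts) * bandwidth * math.sqrt(2.0 * math.pi)
        area = np.trapezoid(curve, support)
        out[name] = curve / area
    return out


def curve_l1_distance(curves: pd.DataFrame, a: str, b: str) -> float:
    """L1 distance between two smoothed frequency curves on their support."""
    return float(np.trapezoid(np.abs(curves[a] - curves[b]), curves["count"]))
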