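"""Per-cell morphological parameter extraction from label masks.

For each cell the catalog covers, per compartment (nucleus, cell): size
(area, perimeter, equivalent/Feret diameters), shape (aspect ratio,
eccentricity, circularity 4*pi*A/P^2, solidity, convexity, extent), boundary
radial-distance and curvature statistics from a smoothed closed contour,
bending energy, low-order Fourier boundary-harmonic amplitudes, and the 7 Hu
invariant moments; cross-compartment features (N:C area ratio, nucleus-cell
centroid offset) and, when an intensity table is supplied, per-channel
intensity and texture columns. Perimeters use the Crofton estimator to keep
raster bias (and hence circularity) controlled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from skimage import measure

from .images import LabelMask

__all__ = [
    "FeatureDescriptor",
    "FeatureCatalog",
    "FeatureMatrix",
    "extract_features",
    "nc_ratio_summary",
]

_FOURIER_HARMONICS = tuple(range(2, 10))


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    compartment: str  # nucleus | cell | cross | intensity
    definition: str = ""
    units: str = ""
    strictly_positive: bool = False


@dataclass
class FeatureCatalog:
    """Ordered, documented list of feature descriptors."""

    descriptors: list[FeatureDescriptor] = field(default_factory=list)

    @classmethod
    def from_columns(cls, compartments: dict[str, str]) -> "FeatureCatalog":
        return cls([FeatureDescriptor(name=n, compartment=c) for n, c in compartments.items()])

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def __len__(self) -> int:
        return len(self.descriptors)

    def validate(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names in catalog: {dupes}")

    def content_hash(self) -> str:
        """Stable hash of feature names and order, recorded in output metadata."""
        h = hashlib.sha256("\n".join(self.names).encode())
        return h.hexdigest()[:16]

    def to_records(self) -> list[dict]:
        return [vars(d) | {} for d in self.descriptors]


@dataclass
class FeatureMatrix:
    """Cells x features numeric table with per-cell metadata and a catalog."""

    features: pd.DataFrame
    metadata: pd.DataFrame
    catalog: FeatureCatalog
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.features) != len(self.metadata):
            raise ValueError("features and metadata row counts differ")
        self.catalog.validate()
        missing = set(self.features.columns) - set(self.catalog.names)
        if missing:
            raise ValueError(f"feature columns not in catalog: {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return len(self.features)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def subset(self, mask) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(
            features=self.features.loc[mask].reset_index(drop=True),
            metadata=self.metadata.loc[mask].reset_index(drop=True),
            catalog=self.catalog,
            n_dropped=self.n_dropped,
        )

    def with_columns(self, labels: np.ndarray, name: str) -> pd.DataFrame:
        out = self.metadata.copy()
        out[name] = labels
        return out


# ---------------------------------------------------------------------------
# contour analysis
# ---------------------------------------------------------------------------

def _main_contour(mask: np.ndarray) -> np.ndarray | None:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len) - 1.0  # undo pad
    if len(contour) < 8:
        return None
    return contour


def _smooth_contour(contour: np.ndarray) -> np.ndarray:
    n = len(contour)
    window = max(3.0, 0.05 * n)
    sigma = window / 4.0
    sm = np.column_stack(
        [gaussian_filter1d(contour[:, k], sigma, mode="wrap") for k in (0, 1)]
    )
    return sm


def _curvature_stats(contour: np.ndarray, pixel_size: float) -> dict[str, float]:
    y, x = contour[:, 0], contour[:, 1]

    def cgrad(v):
        return (np.roll(v, -1) - np.roll(v, 1)) / 2.0

    dx, dy = cgrad(x), cgrad(y)
    ddx, ddy = cgrad(dx), cgrad(dy)
    speed2 = dx**2 + dy**2
    speed2 = np.maximum(speed2, 1e-12)
    kappa_px = (dx * ddy - dy * ddx) / speed2**1.5
    kappa = kappa_px / pixel_size  # 1/um
    ds = np.sqrt(speed2) * pixel_size  # um
    return {
        "curvature_mean_abs": float(np.mean(np.abs(kappa))),
        "curvature_sd": float(np.std(kappa)),
        "curvature_max_abs": float(np.max(np.abs(kappa))),
        "curvature_mean": float(np.mean(kappa)),
        "bending_energy": float(np.sum(kappa**2 * ds)),
    }


def _radial_profile(contour: np.ndarray, centroid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = contour - centroid
    r = np.hypot(d[:, 0], d[:, 1])
    theta = np.arctan2(d[:, 0], d[:, 1])
    order = np.argsort(theta)
    return theta[order], r[order]


def _fourier_amplitudes(theta: np.ndarray, r: np.ndarray, harmonics=_FOURIER_HARMONICS) -> dict[str, float]:
    """Amplitudes of boundary harmonics, normalized by the mean radius."""
    grid = np.linspace(-np.pi, np.pi, 256, endpoint=False)
    theta_ext = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r_ext = np.concatenate([r, r, r])
    r_grid = np.interp(grid, theta_ext, r_ext)
    coeffs = np.fft.rfft(r_grid) / len(r_grid)
    rbar = max(float(np.mean(r_grid)), 1e-12)
    return {f"fourier_amp_{h}": float(2.0 * np.abs(coeffs[h]) / rbar) for h in harmonics}


def _compartment_features(mask: np.ndarray, pixel_size: float) -> dict[str, float] | None:
    """All geometric features for one compartment mask; None if degenerate."""
    if mask.sum() < 4:
        return None
    props = measure.regionprops(mask.astype(np.uint8))[0]
    contour = _main_contour(mask)
    if contour is None:
        return None
    sm = _smooth_contour(contour)
    centroid = np.array(props.centroid)
    theta, r_px = _radial_profile(sm, centroid)
    r = r_px * pixel_size
    rbar = float(np.mean(r))
    rmin = float(np.min(r))

    px2 = pixel_size**2
    area = props.area * px2
    # arc length of the smoothed contour: near-free of raster orientation
    # bias, so circularity stays rotation-stable; the Crofton estimate is
    # kept as its own feature
    seg = np.diff(np.vstack([sm, sm[:1]]), axis=0)
    perim = max(float(np.hypot(seg[:, 0], seg[:, 1]).sum()), 1e-12) * pixel_size
    perim_crofton = max(props.perimeter_crofton, 1e-12) * pixel_size
    convex_img = props.image_convex
    convex_perim = max(measure.perimeter_crofton(convex_img), 1e-12) * pixel_size
    minor = max(props.axis_minor_length, 1e-12) * pixel_size
    major = props.axis_major_length * pixel_size

    out = {
        "area": area,
        "perimeter": perim,
        "perimeter_crofton": perim_crofton,
        "equivalent_diameter": props.equivalent_diameter_area * pixel_size,
        "major_axis_length": major,
        "minor_axis_length": minor,
        "aspect_ratio": major / minor,
        "eccentricity": props.eccentricity,
        "circularity": 4.0 * np.pi * area / perim**2,
        "solidity": props.solidity,
        "convexity": convex_perim / perim_crofton,
        "roughness": perim_crofton / convex_perim,
        "extent": props.extent,
        "orientation": props.orientation,
        "bbox_area": props.area_bbox * px2,
        "convex_area": props.area_convex * px2,
        "feret_diameter_max": props.feret_diameter_max * pixel_size,
        "radial_mean": rbar,
        "radial_sd": float(np.std(r)),
        "radial_cv": float(np.std(r) / max(rbar, 1e-12)),
        "radial_max": float(np.max(r)),
        "radial_min": rmin,
        "radial_max_min_ratio": float(np.max(r) / max(rmin, 1e-12)),
        "perimeter_area_ratio": perim / area,
    }
    out.update(_curvature_stats(sm, pixel_size))
    out.update(_fourier_amplitudes(theta, r_px))
    for i, hu in enumerate(props.moments_hu, start=1):
        out[f"hu_{i}"] = float(hu)
    out["_centroid_rc"] = tuple(props.centroid)
    return out


def _build_catalog(intensity_columns: list[str]) -> FeatureCatalog:
    desc: list[FeatureDescriptor] = []
    geom = [
        ("area", "pixel count x pixel_size^2", "um^2", True),
        ("perimeter", "arc length of the smoothed boundary contour", "um", True),
        ("perimeter_crofton", "Crofton perimeter estimate", "um", True),
        ("equivalent_diameter", "diameter of the equal-area disk", "um", True),
        ("major_axis_length", "major axis of the equal-moments ellipse", "um", True),
        ("minor_axis_length", "minor axis of the equal-moments ellipse", "um", True),
        ("aspect_ratio", "major/minor axis ratio", "", True),
        ("eccentricity", "eccentricity of the equal-moments ellipse", "", False),
        ("circularity", "4*pi*A/P^2", "", True),
        ("solidity", "area / convex area", "", True),
        ("convexity", "convex perimeter / perimeter", "", True),
        ("roughness", "perimeter / convex perimeter", "", True),
        ("extent", "area / bounding-box area", "", True),
        ("orientation", "equal-moments ellipse orientation", "rad", False),
        ("bbox_area", "bounding-box area", "um^2", True),
        ("convex_area", "convex-hull area", "um^2", True),
        ("feret_diameter_max", "maximum caliper diameter", "um", True),
        ("radial_mean", "mean boundary distance from centroid", "um", True),
        ("radial_sd", "sd of boundary distance", "um", False),
        ("radial_cv", "cv of boundary distance", "", False),
        ("radial_max", "max boundary distance", "um", True),
        ("radial_min", "min boundary distance", "um", True),
        ("radial_max_min_ratio", "max/min boundary distance", "", True),
        ("perimeter_area_ratio", "perimeter / area", "1/um", True),
        ("curvature_mean_abs", "mean |curvature| of smoothed contour", "1/um", False),
        ("curvature_sd", "sd of curvature", "1/um", False),
        ("curvature_max_abs", "max |curvature|", "1/um", False),
        ("curvature_mean", "mean signed curvature", "1/um", False),
        ("bending_energy", "integral of curvature^2 along the contour", "1/um", False),
    ]
    for h in _FOURIER_HARMONICS:
        geom.append((f"fourier_amp_{h}", f"boundary harmonic {h} amplitude / mean radius", "", False))
    for i in range(1, 8):
        geom.append((f"hu_{i}", f"Hu invariant moment {i}", "", False))
    for comp in ("nucleus", "cell"):
        for name, definition, units, pos in geom:
            desc.append(FeatureDescriptor(f"{comp}_{name}", comp, definition, units, pos))
    desc += [
        FeatureDescriptor("nc_area_ratio", "cross", "nuclear area / cellular area", "", True),
        FeatureDescriptor("nc_perimeter_ratio", "cross", "nuclear / cellular perimeter", "", True),
        FeatureDescriptor("nc_equivalent_diameter_ratio", "cross", "nuclear / cellular equivalent diameter", "", True),
        FeatureDescriptor("centroid_offset_um", "cross", "nucleus-cell centroid distance", "um", False),
        FeatureDescriptor("centroid_offset_frac", "cross", "centroid offset / cell equivalent radius", "", False),
        FeatureDescriptor("orientation_alignment", "cross", "|cos(nucleus orientation - cell orientation)|", "", False),
    ]
    for c in intensity_columns:
        desc.append(FeatureDescriptor(c, "intensity", "per-cell intensity statistic", "a.u.", False))
    return FeatureCatalog(desc)


def extract_features(
    index,
    nuclei: LabelMask,
    cells: LabelMask,
    intensity: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Extract the full morphological catalog for every curated cell.

    ``index`` is a :class:`~ovomorph.segmentation.CellIndex`. ``intensity``
    (optional) is a per-cell table indexed by cell_id whose columns are
    appended as intensity features. Cells whose contour is degenerate or
    whose features contain non-finite values are dropped and counted in
    ``FeatureMatrix.n_dropped``.
    """
    px = cells.pixel_size
    intensity_cols = list(intensity.columns) if intensity is not None else []
    catalog = _build_catalog(intensity_cols)

    rows = []
    meta_rows = []
    n_dropped = 0
    for rec in index.records:
        nuc_mask = nuclei.labels == rec.nucleus_label
        cell_mask = cells.labels == rec.cell_label
        nf = _compartment_features(nuc_mask, px)
        cf = _compartment_features(cell_mask, px)
        if nf is None or cf is None:
            n_dropped += 1
            continue
        nc_rc = nf.pop("_centroid_rc")
        cc_rc = cf.pop("_centroid_rc")
        row: dict[str, float] = {}
        row.update({f"nucleus_{k}": v for k, v in nf.items()})
        row.update({f"cell_{k}": v for k, v in cf.items()})
        row["nc_area_ratio"] = nf["area"] / cf["area"]
        row["nc_perimeter_ratio"] = nf["perimeter"] / cf["perimeter"]
        row["nc_equivalent_diameter_ratio"] = nf["equivalent_diameter"] / cf["equivalent_diameter"]
        offset = float(np.hypot(nc_rc[0] - cc_rc[0], nc_rc[1] - cc_rc[1])) * px
        row["centroid_offset_um"] = offset
        row["centroid_offset_frac"] = offset / (cf["equivalent_diameter"] / 2.0)
        row["orientation_alignment"] = abs(np.cos(nf["orientation"] - cf["orientation"]))
        if intensity is not None:
            if rec.cell_id not in intensity.index:
                n_dropped += 1
                continue
            for c in intensity_cols:
                row[c] = float(intensity.loc[rec.cell_id, c])
        if not all(np.isfinite(v) for v in row.values()):
            n_dropped += 1
            continue
        rows.append(row)
        meta_rows.append(
            {"cell_id": rec.cell_id, "age": rec.age, "treatment": rec.treatment, "replicate": rec.replicate}
        )

    features = pd.DataFrame(rows, columns=catalog.names)
    metadata = pd.DataFrame(meta_rows, columns=["cell_id", "age", "treatment", "replicate"])
    return FeatureMatrix(features=features, metadata=metadata, catalog=catalog, n_dropped=n_dropped)


def nc_ratio_summary(features: FeatureMatrix, group_field: str = "group") -> dict:
    """Per-group mean/sd of nuclear area, cellular area and N:C ratio.

    When exactly two groups are present, a Welch two-sample t-test is run per
    metric. Groups with a single cell have their sd flagged as undefined
    (NaN).
    """
    metrics = ["nucleus_area", "cell_area", "nc_area_ratio"]
    df = features.features[metrics].copy()
    groups = features.metadata[group_field].to_numpy()
    df[group_field] = groups

    summary = df.groupby(group_field)[metrics].agg(["count", "mean", "std"])
    result: dict = {"summary": summary, "tests": {}}
    names = list(pd.unique(groups))
    if len(names) == 2:
        a = df[df[group_field] == names[0]]
        b = df[df[group_field] == names[1]]
        for m in metrics:
            t, p = stats.ttest_ind(a[m], b[m], equal_var=False)
            result["tests"][m] = {
                "groups": (names[0], names[1]),
                "t": float(t),
                "p": float(p),
                "direction": f"{names[0]} {'>' if a[m].mean() > b[m].mean() else '<'} {names[1]}",
            }
    return result
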