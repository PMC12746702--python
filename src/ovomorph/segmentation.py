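"""Nuclear/cellular segmentation, curation, and per-cell intensity/texture.

Nuclei are found by Otsu thresholding of the Gaussian-blurred DNA channel
followed by an h-maxima distance-transform watershed that splits touching
nuclei; cells by a seeded watershed from the nucleus labels over the
thresholded cytoplasm (or membrane) channel. Curation then removes
border-touching, crowded, size-outlier and nucleus-mismatched objects so
that every retained cell has exactly one nucleus strictly inside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .images import LabelMask, MultiChannelImage

logger = logging.getLogger(__name__)

__all__ = [
    "CellRecord",
    "CellIndex",
    "CurationParams",
    "CurationReport",
    "segment_nuclei",
    "segment_cells",
    "curate",
    "quantify_intensity",
    "texture_infomeas",
    "positive_area_fraction",
]


@dataclass
class CellRecord:
    cell_id: int
    nucleus_label: int
    cell_label: int
    age: str = ""
    treatment: str = ""
    replicate: str = ""


@dataclass
class CellIndex:
    """Curated 1:1 pairing of nucleus and cell labels with group metadata."""

    records: list[CellRecord]
    nuclei: LabelMask
    cells: LabelMask

    def __len__(self) -> int:
        return len(self.records)

    def with_metadata(self, age: str = "", treatment: str = "", replicate: str = "") -> "CellIndex":
        for r in self.records:
            r.age, r.treatment, r.replicate = age, treatment, replicate
        return self

    def validate(self) -> None:
        """Check the bijection and nucleus-inside-cell invariants."""
        nuc_labels = [r.nucleus_label for r in self.records]
        cell_labels = [r.cell_label for r in self.records]
        if len(set(nuc_labels)) != len(nuc_labels) or len(set(cell_labels)) != len(cell_labels):
            raise ValueError("cell/nucleus label mapping is not bijective")
        for r in self.records:
            nuc = self.nuclei.labels == r.nucleus_label
            cell = self.cells.labels == r.cell_label
            if not np.all(cell[nuc]):
                raise ValueError(f"nucleus {r.nucleus_label} extends outside cell {r.cell_label}")


@dataclass
class CurationParams:
    """Rule thresholds for single-cell curation."""

    min_area_um2: float = 30.0
    max_area_um2: float = 1.0e4
    max_neighbors: int = 4
    neighbor_radius_diameters: float = 3.0  # x median cell equivalent diameter


@dataclass
class CurationReport:
    detected: int = 0
    removed_border: int = 0
    removed_confluent: int = 0
    removed_area: int = 0
    removed_unmatched: int = 0
    retained: int = 0
    removed_labels: dict = field(default_factory=dict)

    @property
    def removed(self) -> int:
        return self.removed_border + self.removed_confluent + self.removed_area + self.removed_unmatched

    def validate(self) -> None:
        if self.removed + self.retained != self.detected:
            raise ValueError(
                f"curation counts do not reconcile: {self.removed} removed + "
                f"{self.retained} retained != {self.detected} detected"
            )


def segment_nuclei(
    image: MultiChannelImage,
    dna_channel: str = "dna",
    sigma: float = 1.0,
    min_size_px: int = 20,
    threshold: float | None = None,
) -> LabelMask:
    """Label nuclei in the DNA channel.

    Otsu on the Gaussian-blurred channel (``threshold`` overrides), small
    objects removed, then touching nuclei are split by a watershed seeded at
    the h-maxima of the distance transform (h = 20% of the median object
    in-radius, so mild boundary roughness does not over-split).
    """
    chan = image.channel(dna_channel)
    blurred = gaussian(chan, sigma=sigma, preserve_range=True)
    if threshold is None:
        if blurred.max() - blurred.min() < 1e-12:
            logger.warning("blank DNA channel: returning empty nucleus mask")
            return LabelMask(np.zeros(image.shape, np.int32), "nucleus", image.pixel_size)
        threshold = threshold_otsu(blurred)
    binary = blurred > threshold
    comp0 = cc_label(binary, connectivity=2)
    sizes = np.bincount(comp0.ravel())
    binary &= sizes[comp0] >= min_size_px
    if not binary.any():
        logger.warning("no foreground after threshold: returning empty nucleus mask")
        return LabelMask(np.zeros(image.shape, np.int32), "nucleus", image.pixel_size)

    dist = ndi.distance_transform_edt(binary)
    comp = cc_label(binary, connectivity=2)
    # per-component h: deep enough (35% of the in-radius) that boundary
    # roughness never splits a lone nucleus, while the saddle between two
    # genuinely merged nuclei still does
    markers = np.zeros_like(comp)
    next_label = 1
    for p in regionprops(comp):
        sl = p.slice
        local = (comp[sl] == p.label)
        d = np.where(local, dist[sl], 0.0)
        h = max(1.0, 0.25 * float(d.max()))
        # regional maxima of the h-reconstruction: equal-height ridge peaks
        # stay one connected plateau, while saddles deeper than h still split
        rec = morphology.reconstruction(d - h, d, method="dilation")
        peaks = morphology.local_maxima(rec, connectivity=2) & local
        mk = cc_label(peaks, connectivity=2)
        mk[mk > 0] += next_label - 1
        markers[sl] = np.where(local & (mk > 0), mk, markers[sl])
        next_label = max(next_label, int(mk.max()) + 1)
    labels = watershed(-dist, markers=markers, mask=binary, connectivity=2)
    return LabelMask(labels.astype(np.int32), "nucleus", image.pixel_size)


def segment_cells(
    image: MultiChannelImage,
    cytoplasm_channel: str,
    nuclei: LabelMask,
    sigma: float = 1.0,
    threshold: float | None = None,
) -> LabelMask:
    """Label cells by seeded watershed from the nuclei over the thresholded
    cytoplasm channel; each cell label equals its seed nucleus label."""
    if nuclei.labels.shape != image.shape:
        raise ValueError("nuclei mask geometry does not match image")
    if nuclei.n_objects == 0:
        return LabelMask(np.zeros(image.shape, np.int32), "cell", image.pixel_size)
    chan = image.channel(cytoplasm_channel)
    blurred = gaussian(chan, sigma=sigma, preserve_range=True)
    if threshold is None:
        threshold = threshold_otsu(blurred)
    binary = blurred > threshold
    dropped = [int(l) for l in nuclei.ids if not binary[nuclei.labels == l].any()]
    if dropped:
        logger.info("%d nuclei fall outside cytoplasm foreground; cells dropped: %s", len(dropped), dropped)
    binary = binary | (nuclei.labels > 0)  # seeds always inside the mask
    markers = np.where(np.isin(nuclei.labels, dropped), 0, nuclei.labels)
    dist = ndi.distance_transform_edt(markers == 0)
    labels = watershed(dist, markers=markers, mask=binary, connectivity=2)
    return LabelMask(labels.astype(np.int32), "cell", image.pixel_size)


def curate(
    nuclei: LabelMask,
    cells: LabelMask,
    params: CurationParams | None = None,
) -> tuple[CellIndex, CurationReport]:
    """Keep single, well-segmented cells.

    Removal rules, applied in order (a cell is counted under the first rule
    it violates): (a) touches the image border; (b) confluent — the cell mask
    is 8-adjacent to another cell mask, or more than ``max_neighbors`` other
    cell centroids lie within ``neighbor_radius_diameters`` median equivalent
    diameters; (c) outside [min_area, max_area]; (d) not exactly one nucleus
    mostly inside the cell. Retained nuclei are clipped to their cell raster.
    """
    if params is None:
        params = CurationParams()
    if nuclei.labels.shape != cells.labels.shape:
        raise ValueError("masks share no common geometry")
    px2 = cells.pixel_size**2
    props = {p.label: p for p in regionprops(cells.labels)}
    report = CurationReport(detected=len(props))
    if not props:
        empty = CellIndex([], _relabelled(nuclei, {}), _relabelled(cells, {}))
        report.validate()
        return empty, report

    centroids = {l: np.array(p.centroid) for l, p in props.items()}
    eq_diam = np.median([p.equivalent_diameter_area for p in props.values()])
    radius_px = params.neighbor_radius_diameters * eq_diam

    border_labels = set(np.unique(cells.labels[0, :])) | set(np.unique(cells.labels[-1, :])) | \
        set(np.unique(cells.labels[:, 0])) | set(np.unique(cells.labels[:, -1]))
    border_labels.discard(0)

    # label pairs that share an 8-adjacent boundary are confluent
    touching: set[int] = set()
    lab = cells.labels
    H, W = lab.shape
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = lab[max(-dr, 0): H - max(dr, 0), max(-dc, 0): W - max(dc, 0)]
        b = lab[max(dr, 0): H - max(-dr, 0), max(dc, 0): W - max(-dc, 0)]
        contact = (a > 0) & (b > 0) & (a != b)
        touching.update(np.unique(a[contact]).tolist())
        touching.update(np.unique(b[contact]).tolist())

    # nucleus -> cell assignment by majority overlap
    nuc_assign: dict[int, list[int]] = {l: [] for l in props}
    for p in regionprops(nuclei.labels):
        mask = nuclei.labels == p.label
        overlap = cells.labels[mask]
        vals, counts = np.unique(overlap[overlap > 0], return_counts=True)
        if len(vals) and counts.max() > 0.5 * mask.sum():
            host = int(vals[counts.argmax()])
            if host in nuc_assign:
                nuc_assign[host].append(int(p.label))

    keep: dict[int, int] = {}  # cell label -> nucleus label
    for l, p in sorted(props.items()):
        if l in border_labels:
            report.removed_border += 1
            report.removed_labels[l] = "border"
            continue
        n_close = sum(
            1 for m, c in centroids.items() if m != l and np.hypot(*(c - centroids[l])) <= radius_px
        )
        if l in touching or n_close > params.max_neighbors:
            report.removed_confluent += 1
            report.removed_labels[l] = "confluent"
            continue
        area = p.area * px2
        if not (params.min_area_um2 <= area <= params.max_area_um2):
            report.removed_area += 1
            report.removed_labels[l] = "area"
            continue
        if len(nuc_assign.get(l, [])) != 1:
            report.removed_unmatched += 1
            report.removed_labels[l] = "unmatched"
            continue
        keep[l] = nuc_assign[l][0]

    report.retained = len(keep)
    report.validate()

    new_cells = _relabelled(cells, {l: l for l in keep})
    nuc_map = {n: c for c, n in keep.items()}  # nucleus label -> output label (= cell label)
    new_nuclei = _relabelled(nuclei, nuc_map)
    new_nuclei.labels[new_cells.labels == 0] = 0  # clip nuclei to their cells
    for c in keep:
        sel = (new_nuclei.labels == c) & (new_cells.labels != c)
        new_nuclei.labels[sel] = 0

    records = [CellRecord(cell_id=c, nucleus_label=c, cell_label=c) for c in sorted(keep)]
    index = CellIndex(records=records, nuclei=new_nuclei, cells=new_cells)
    return index, report


def _relabelled(mask: LabelMask, mapping: dict[int, int]) -> LabelMask:
    out = np.zeros_like(mask.labels)
    for src, dst in mapping.items():
        out[mask.labels == src] = dst
    return LabelMask(out, mask.compartment, mask.pixel_size)


def quantify_intensity(
    image: MultiChannelImage,
    index: CellIndex,
    channels: list[str],
    compartment: str = "cell",
) -> pd.DataFrame:
    """Sum, mean and sd of each requested channel within each cell (or
    nucleus) mask; indexed by cell_id with columns ``{channel}_{stat}``."""
    for ch in channels:
        if ch not in image.channels:
            raise KeyError(f"no channel '{ch}' in image")
    mask_img = index.cells if compartment == "cell" else index.nuclei
    prefix = "" if compartment == "cell" else "nucleus_"
    rows = []
    for rec in index.records:
        label = rec.cell_label if compartment == "cell" else rec.nucleus_label
        m = mask_img.labels == label
        row: dict = {"cell_id": rec.cell_id}
        for ch in channels:
            vals = image.channel(ch)[m]
            row[f"{prefix}{ch}_sum"] = float(vals.sum())
            row[f"{prefix}{ch}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{prefix}{ch}_sd"] = float(vals.std()) if vals.size else np.nan
        rows.append(row)
    cols = ["cell_id"] + [f"{prefix}{ch}_{s}" for ch in channels for s in ("sum", "mean", "sd")]
    return pd.DataFrame(rows, columns=cols).set_index("cell_id")


_GLCM_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def texture_infomeas(
    channel: np.ndarray,
    mask: np.ndarray,
    levels: int = 8,
    distance: int = 1,
) -> float:
    """Information measure of correlation 1 from a masked co-occurrence matrix.

    Intensities inside the mask are quantized to ``levels`` bins over the
    in-mask range (so the value is invariant to constant offsets); symmetric
    co-occurrence matrices at the given pixel ``distance`` are averaged over
    the four principal directions; returns (HXY - HXY1)/max(HX, HY), with 0
    for a constant region and NaN for masks under 2 pixels.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        return float("nan")
    vals = np.asarray(channel, dtype=float)
    vmin, vmax = vals[mask].min(), vals[mask].max()
    if vmax - vmin < 1e-12:
        return 0.0
    quant = np.zeros(vals.shape, dtype=np.int64)
    quant[mask] = np.minimum(
        (levels * (vals[mask] - vmin) / (vmax - vmin)).astype(np.int64), levels - 1
    )

    mats = []
    for dr, dc in _GLCM_OFFSETS:
        dr, dc = dr * distance, dc * distance
        p = _cooccurrence(quant, mask, dr, dc, levels)
        if p is not None:
            mats.append(p)
    if not mats:
        return 0.0
    p = np.mean(mats, axis=0)
    return _infomeas1(p)


def _cooccurrence(quant: np.ndarray, mask: np.ndarray, dr: int, dc: int, levels: int) -> np.ndarray | None:
    nr, nc = quant.shape
    r0s, r0e = max(0, -dr), min(nr, nr - dr)
    c0s, c0e = max(0, -dc), min(nc, nc - dc)
    a = quant[r0s:r0e, c0s:c0e]
    b = quant[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    if not valid.any():
        return None
    pairs = np.bincount(a[valid] * levels + b[valid], minlength=levels * levels).reshape(levels, levels)
    sym = pairs + pairs.T
    return sym / sym.sum()


def _infomeas1(p: np.ndarray) -> float:
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hx, hy = ent(px), ent(py)
    if max(hx, hy) < 1e-12:
        return 0.0
    hxy = ent(p.ravel())
    outer = np.outer(px, py)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-(p[nz] * np.log(outer[nz])).sum())
    return (hxy - hxy1) / max(hx, hy)


def positive_area_fraction(channel: np.ndarray, roi: np.ndarray, threshold: float) -> float:
    """Fraction of in-ROI pixels strictly above ``threshold``."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    vals = np.asarray(channel, dtype=float)[roi]
    return float((vals > threshold).mean())
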