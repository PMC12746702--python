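"""Seeded synthetic microscopy: cell scenes, micromold scans, feature tables.

Every generator here carries a known ground truth, so segmentation, feature
extraction, clustering and aggregation statistics can all be tested for
recovery without any raw microscopy. Cell outlines are star-convex:

    r(theta) = R * f_ellipse(theta) * (1 + sum_{h=2..6} a_h cos(h*theta + phi_h))

with the harmonic amplitudes ``a_h`` scaled by the subtype's
``boundary_irregularity``, which yields controllable boundary roughness and
curvature without self-intersection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from skimage.draw import polygon as draw_polygon

from .images import MultiChannelImage
from .specs import (
    LogNormalParam,
    MicromoldSpec,
    PopulationSpec,
    SceneSpec,
    SubtypeSpec,
)

__all__ = [
    "sample_population",
    "render_scene",
    "simulate_micromold",
    "simulate_feature_table",
    "CellTruth",
    "SceneTruth",
    "PlacementError",
    "young_population",
    "old_population",
    "lata_population",
    "jasp_population",
]

# Per-pixel amplitudes of the rendered stains (arbitrary units).
DNA_PIXEL_VALUE = 150.0
MEMBRANE_PIXEL_VALUE = 120.0

_N_BOUNDARY = 256  # boundary samples per synthetic outline
_HARMONICS = (2, 3, 4, 5, 6)


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed at the requested density."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} cells within the retry budget; "
            "reduce n_cells or enlarge the image"
        )


# ---------------------------------------------------------------------------
# study-condition populations
# ---------------------------------------------------------------------------

def _subtype(name, nuc, cell, el, irr, actin, vim, offset=0.08) -> SubtypeSpec:
    return SubtypeSpec(
        name=name,
        nuclear_radius=LogNormalParam(nuc, 1.08),
        cell_radius=LogNormalParam(cell, 1.08),
        elongation=LogNormalParam(el, 1.10),
        boundary_irregularity=irr,
        actin_intensity=LogNormalParam(actin, 1.25),
        vimentin_intensity=LogNormalParam(vim, 1.25),
        nucleus_offset_frac=offset,
    )


def _base_subtypes() -> tuple[SubtypeSpec, ...]:
    """Eight morphological subtypes spanning the fibroblast-to-epithelial
    range: a heterogeneous primary stromal isolate resolves into about eight
    morphological modes of widely varying abundance, separated jointly in
    size, elongation, boundary roughness and stain content."""
    return (
        _subtype("fibroblast_large", 9.8, 28.0, 2.6, 0.22, 1.4e5, 9.5e4, 0.12),
        _subtype("fibroblast", 8.8, 22.0, 1.9, 0.14, 9.5e4, 6.5e4, 0.10),
        _subtype("myofibroblast_like", 8.0, 19.0, 1.6, 0.24, 8.0e4, 4.5e4, 0.10),
        _subtype("spread_intermediate", 7.2, 16.0, 1.45, 0.10, 5.0e4, 3.5e4),
        _subtype("compact_intermediate", 6.6, 13.5, 1.35, 0.09, 3.5e4, 2.8e4),
        _subtype("stellate", 6.0, 12.0, 2.1, 0.30, 2.5e4, 3.5e4, 0.10),
        _subtype("stromal_round", 6.0, 11.0, 1.15, 0.05, 2.0e4, 1.2e4, 0.06),
        _subtype("small_round", 5.3, 9.0, 1.06, 0.03, 1.1e4, 7.0e3, 0.05),
    )


def young_population() -> PopulationSpec:
    """Reference population from reproductively young animals."""
    return PopulationSpec(
        name="young",
        subtypes=_base_subtypes(),
        subtype_weights=(0.30, 0.20, 0.12, 0.10, 0.08, 0.03, 0.10, 0.07),
    )


def old_population() -> PopulationSpec:
    """Aged population: 20% smaller cells, slightly smaller nuclei (hence a
    larger nuclear-to-cellular area ratio), and the small-round subtype
    over-represented."""
    base = _base_subtypes()
    shrunk = tuple(
        SubtypeSpec(
            name=st.name,
            nuclear_radius=LogNormalParam(st.nuclear_radius.median * 0.90, st.nuclear_radius.gsd),
            cell_radius=LogNormalParam(st.cell_radius.median * 0.80, st.cell_radius.gsd),
            elongation=st.elongation,
            boundary_irregularity=st.boundary_irregularity,
            actin_intensity=st.actin_intensity,
            vimentin_intensity=st.vimentin_intensity,
            nucleus_offset_frac=st.nucleus_offset_frac,
        )
        for st in base
    )
    return PopulationSpec(
        name="old",
        subtypes=shrunk,
        subtype_weights=(0.12, 0.11, 0.11, 0.08, 0.09, 0.04, 0.18, 0.27),
    )


def lata_population(name: str = "lata") -> PopulationSpec:
    """Actin-depolymerized condition: a common small, round, low-actin
    distribution regardless of the age the cells came from."""
    treated = SubtypeSpec(
        name="lata_round",
        nuclear_radius=LogNormalParam(6.5, 1.10),
        cell_radius=LogNormalParam(11.0, 1.12),
        elongation=LogNormalParam(1.15, 1.08),
        boundary_irregularity=0.05,
        actin_intensity=LogNormalParam(8.0e3, 1.30),
        vimentin_intensity=LogNormalParam(2.0e4, 1.30),
        nucleus_offset_frac=0.05,
    )
    residual = SubtypeSpec(
        name="lata_spread",
        nuclear_radius=LogNormalParam(7.0, 1.10),
        cell_radius=LogNormalParam(14.0, 1.12),
        elongation=LogNormalParam(1.3, 1.10),
        boundary_irregularity=0.08,
        actin_intensity=LogNormalParam(1.2e4, 1.30),
        vimentin_intensity=LogNormalParam(2.5e4, 1.30),
        nucleus_offset_frac=0.06,
    )
    return PopulationSpec(name=name, subtypes=(treated, residual), subtype_weights=(0.7, 0.3))


def jasp_population(name: str = "jasp") -> PopulationSpec:
    """Actin-stabilized condition: compact cells with high actin and punctate
    (rough) boundaries, again shared across ages."""
    stabilized = SubtypeSpec(
        name="jasp_compact",
        nuclear_radius=LogNormalParam(6.8, 1.10),
        cell_radius=LogNormalParam(13.0, 1.15),
        elongation=LogNormalParam(1.3, 1.12),
        boundary_irregularity=0.20,
        actin_intensity=LogNormalParam(9.0e4, 1.35),
        vimentin_intensity=LogNormalParam(3.0e4, 1.30),
        nucleus_offset_frac=0.08,
    )
    spread = SubtypeSpec(
        name="jasp_spread",
        nuclear_radius=LogNormalParam(7.5, 1.10),
        cell_radius=LogNormalParam(17.0, 1.15),
        elongation=LogNormalParam(1.6, 1.15),
        boundary_irregularity=0.15,
        actin_intensity=LogNormalParam(7.0e4, 1.35),
        vimentin_intensity=LogNormalParam(3.5e4, 1.30),
        nucleus_offset_frac=0.08,
    )
    return PopulationSpec(name=name, subtypes=(stabilized, spread), subtype_weights=(0.6, 0.4))


# ---------------------------------------------------------------------------
# latent-parameter sampling
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, p: LogNormalParam, n: int) -> np.ndarray:
    return rng.lognormal(mean=math.log(p.median), sigma=math.log(p.gsd), size=n)


def sample_population(spec: PopulationSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` cells' latent morphological parameters from a population.

    Returns one row per cell with its subtype assignment, radii (um),
    elongation, boundary irregularity, stain totals and nucleus offset.
    Identical (spec, n, seed) yield byte-identical tables.
    """
    spec.validate()
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    subtype_idx = rng.choice(spec.n_subtypes, size=n, p=np.asarray(spec.subtype_weights))

    cols = {
        "group": np.repeat(spec.name, n),
        "subtype": subtype_idx,
        "subtype_name": np.array([spec.subtypes[i].name for i in subtype_idx]),
    }
    draws = {
        "nuclear_radius_um": np.empty(n),
        "cell_radius_um": np.empty(n),
        "elongation": np.empty(n),
        "boundary_irregularity": np.empty(n),
        "actin_intensity": np.empty(n),
        "vimentin_intensity": np.empty(n),
        "nucleus_offset_frac": np.empty(n),
    }
    # one substream per subtype keeps draws reproducible regardless of mixing
    for i, st in enumerate(spec.subtypes):
        sel = subtype_idx == i
        m = int(sel.sum())
        if m == 0:
            continue
        sub_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(spec.n_subtypes + 1)[i + 1])
        draws["nuclear_radius_um"][sel] = _lognormal(sub_rng, st.nuclear_radius, m)
        draws["cell_radius_um"][sel] = _lognormal(sub_rng, st.cell_radius, m)
        draws["elongation"][sel] = np.maximum(_lognormal(sub_rng, st.elongation, m), 1.0)
        draws["boundary_irregularity"][sel] = np.clip(
            st.boundary_irregularity * sub_rng.lognormal(0.0, 0.2, m), 0.0, 0.5
        )
        # total stain content scales with cell area around the subtype's
        # median concentration, as for a roughly uniform cytoplasmic stain
        size_factor = (draws["cell_radius_um"][sel] / st.cell_radius.median) ** 2
        draws["actin_intensity"][sel] = _lognormal(sub_rng, st.actin_intensity, m) * size_factor
        draws["vimentin_intensity"][sel] = _lognormal(sub_rng, st.vimentin_intensity, m) * size_factor
        draws["nucleus_offset_frac"][sel] = np.clip(
            st.nucleus_offset_frac * sub_rng.uniform(0.0, 2.0, m), 0.0, 0.499
        )
    # nucleus must fit inside the cell even after elongation squeezes the
    # minor axis: cap the nuclear radius at 85% of the cell minor semi-axis
    minor = draws["cell_radius_um"] / np.sqrt(draws["elongation"])
    draws["nuclear_radius_um"] = np.minimum(draws["nuclear_radius_um"], 0.85 * minor)
    cols.update(draws)
    df = pd.DataFrame(cols)
    df.insert(0, "cell_id", np.arange(n))
    return df


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

@dataclass
class CellTruth:
    """Ground truth for a single rendered cell."""

    cell_id: int
    label: int
    group: str
    subtype: int
    center_rc: tuple[float, float]
    nucleus_pixels: tuple[np.ndarray, np.ndarray]
    cell_pixels: tuple[np.ndarray, np.ndarray]
    dna_sum: float
    actin_sum: float
    vimentin_sum: float
    confluent: bool

    @property
    def nucleus_area_px(self) -> int:
        return len(self.nucleus_pixels[0])

    @property
    def cell_area_px(self) -> int:
        return len(self.cell_pixels[0])


@dataclass
class SceneTruth:
    """Ground truth for a whole scene: per-cell records plus label images."""

    cells: list[CellTruth]
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    pixel_size: float

    def __len__(self) -> int:
        return len(self.cells)

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c.cell_id,
                "label": c.label,
                "group": c.group,
                "subtype": c.subtype,
                "center_row": c.center_rc[0],
                "center_col": c.center_rc[1],
                "nucleus_area_um2": c.nucleus_area_px * self.pixel_size**2,
                "cell_area_um2": c.cell_area_px * self.pixel_size**2,
                "dna_sum": c.dna_sum,
                "actin_sum": c.actin_sum,
                "vimentin_sum": c.vimentin_sum,
                "confluent": c.confluent,
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)


def _star_outline(
    rng: np.random.Generator,
    radius_px: float,
    elongation: float,
    irregularity: float,
    orientation: float,
    center_rc: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary (rows, cols) of a star-convex outline around ``center_rc``."""
    theta = np.linspace(0.0, 2.0 * np.pi, _N_BOUNDARY, endpoint=False)
    a = radius_px * math.sqrt(elongation)
    b = radius_px / math.sqrt(elongation)
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if irregularity > 0:
        raw = rng.uniform(0.5, 1.0, len(_HARMONICS)) / np.asarray(_HARMONICS)
        amps = 0.9 * irregularity * raw / raw.sum()
        phases = rng.uniform(0.0, 2.0 * np.pi, len(_HARMONICS))
        pert = np.zeros_like(theta)
        for h, a_h, ph in zip(_HARMONICS, amps, phases):
            pert += a_h * np.cos(h * theta + ph)
        r = r * (1.0 + pert)
    rows = center_rc[0] + r * np.sin(theta + orientation)
    cols = center_rc[1] + r * np.cos(theta + orientation)
    return rows, cols


def _rasterize(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return draw_polygon(rows, cols, shape=shape)


def render_scene(params: pd.DataFrame, scene: SceneSpec) -> tuple[MultiChannelImage, SceneTruth]:
    """Render a latent-parameter table into a multi-channel image with truth.

    Channels: ``dna`` (nuclear stain), ``actin``, ``vimentin``; a fourth
    ``membrane`` channel with per-cell amplitude independent of actin content
    is added when ``scene.include_membrane`` — it mimics a plasma-membrane
    counterstain usable for cell-boundary segmentation when F-actin is
    depleted. Stain totals are spread uniformly over the compartment so that
    per-cell intensity sums are conserved exactly when noise is off.
    """
    scene.validate()
    n = len(params)
    if n != scene.n_cells:
        raise ValueError(f"params has {n} rows but scene.n_cells = {scene.n_cells}")
    shape = tuple(scene.image_shape)
    channels = ["dna", "actin", "vimentin"] + (["membrane"] if scene.include_membrane else [])
    img = np.full(shape + (len(channels),), float(scene.background_level))

    rng = np.random.default_rng(np.random.SeedSequence(scene.seed).spawn(2)[0])
    noise_rng = np.random.default_rng(np.random.SeedSequence(scene.seed).spawn(2)[1])

    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    truths: list[CellTruth] = []

    if n > 0:
        # effective placement radius = furthest possible outline point
        radii_px = (
            params["cell_radius_um"].to_numpy()
            * np.sqrt(params["elongation"].to_numpy())
            * (1.0 + params["boundary_irregularity"].to_numpy())
            / scene.pixel_size
        )
        contact_px = params["cell_radius_um"].to_numpy() / scene.pixel_size
        centers, confluent_flags = _place_cells(
            rng, radii_px, contact_px, shape, scene.confluency_fraction
        )

        for i in range(n):
            row = params.iloc[i]
            label = i + 1
            center = centers[i]
            orientation = rng.uniform(0.0, 2.0 * np.pi)
            r_cell_px = row["cell_radius_um"] / scene.pixel_size
            r_nuc_px = row["nuclear_radius_um"] / scene.pixel_size

            crows, ccols = _star_outline(
                rng, r_cell_px, row["elongation"], row["boundary_irregularity"], orientation, center
            )
            cell_rr, cell_cc = _rasterize(crows, ccols, shape)
            cell_mask = np.zeros(shape, dtype=bool)
            cell_mask[cell_rr, cell_cc] = True

            off_dir = rng.uniform(0.0, 2.0 * np.pi)
            off = row["nucleus_offset_frac"] * r_cell_px
            nuc_center = (center[0] + off * math.sin(off_dir), center[1] + off * math.cos(off_dir))
            nrows, ncols = _star_outline(
                rng, r_nuc_px, 1.0 + 0.3 * (row["elongation"] - 1.0),
                0.3 * row["boundary_irregularity"], orientation, nuc_center,
            )
            nuc_rr, nuc_cc = _rasterize(nrows, ncols, shape)
            nuc_mask = np.zeros(shape, dtype=bool)
            nuc_mask[nuc_rr, nuc_cc] = True
            # keep the nucleus strictly interior to the cell raster
            nuc_mask &= binary_erosion(cell_mask)
            nuc_rr, nuc_cc = np.nonzero(nuc_mask)

            cell_n_px = int(cell_mask.sum())
            nuc_n_px = int(nuc_mask.sum())
            if cell_n_px == 0 or nuc_n_px == 0:
                continue

            actin_per_px = row["actin_intensity"] / cell_n_px
            vim_per_px = row["vimentin_intensity"] / cell_n_px
            img[:, :, channels.index("dna")][nuc_mask] += DNA_PIXEL_VALUE
            img[:, :, channels.index("actin")][cell_mask] += actin_per_px
            img[:, :, channels.index("vimentin")][cell_mask] += vim_per_px
            if scene.include_membrane:
                img[:, :, channels.index("membrane")][cell_mask] += MEMBRANE_PIXEL_VALUE

            cell_labels[cell_mask] = label
            nucleus_labels[nuc_mask] = label
            truths.append(
                CellTruth(
                    cell_id=int(row["cell_id"]),
                    label=label,
                    group=str(row["group"]),
                    subtype=int(row["subtype"]),
                    center_rc=(float(center[0]), float(center[1])),
                    nucleus_pixels=(nuc_rr, nuc_cc),
                    cell_pixels=(cell_rr, cell_cc),
                    dna_sum=DNA_PIXEL_VALUE * nuc_n_px,
                    actin_sum=actin_per_px * cell_n_px,
                    vimentin_sum=vim_per_px * cell_n_px,
                    confluent=bool(confluent_flags[i]),
                )
            )

    if scene.poisson_noise:
        img = noise_rng.poisson(np.maximum(img, 0.0)).astype(float)
    if scene.noise_sd > 0:
        img = img + noise_rng.normal(0.0, scene.noise_sd, img.shape)
    img = np.maximum(img, 0.0)

    mci = MultiChannelImage(data=img, channels=tuple(channels), pixel_size=scene.pixel_size)
    truth = SceneTruth(
        cells=truths,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        pixel_size=scene.pixel_size,
    )
    return mci, truth


def _place_cells(
    rng: np.random.Generator,
    radii_px: np.ndarray,
    contact_px: np.ndarray,
    shape: tuple[int, int],
    confluency_fraction: float,
) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Place cell centres: isolated cells well separated (``radii_px`` are the
    worst-case outline radii), a chosen fraction deliberately placed as
    touching pairs at mean-outline-radius (``contact_px``) distance."""
    n = len(radii_px)
    n_confluent = int(round(confluency_fraction * n))
    n_confluent -= n_confluent % 2  # pairs
    confluent = np.zeros(n, dtype=bool)
    confluent[:n_confluent] = True

    centers: list[tuple[float, float] | None] = [None] * n
    placed_centers: list[tuple[float, float]] = []
    placed_radii: list[float] = []
    budget = 400 * max(n, 1)
    tries = 0

    def fits(r: float, c: float, rad: float, sep_scale: float) -> bool:
        margin = rad + 2
        if not (margin <= r < shape[0] - margin and margin <= c < shape[1] - margin):
            return False
        for (pr, pc), prad in zip(placed_centers, placed_radii):
            if math.hypot(r - pr, c - pc) < sep_scale * (rad + prad):
                return False
        return True

    # isolated cells largest-first (easier packing), then the confluent pairs
    isolated = sorted(range(n_confluent, n), key=lambda i: -radii_px[i])
    order = isolated + list(range(n_confluent))
    i_ptr = 0
    while i_ptr < len(order):
        i = order[i_ptr]
        rad = float(radii_px[i])
        if confluent[i] and i % 2 == 1:
            # partner of the previous confluent cell: touch it
            partner = centers[i - 1]
            ok = False
            for _ in range(200):
                tries += 1
                ang = rng.uniform(0.0, 2.0 * np.pi)
                # close enough that even elongation-narrowed outlines overlap
                d = 0.65 * (contact_px[i] + contact_px[i - 1])
                r = partner[0] + d * math.sin(ang)
                c = partner[1] + d * math.cos(ang)
                margin = rad + 2
                if margin <= r < shape[0] - margin and margin <= c < shape[1] - margin:
                    ok = True
                    break
            if not ok:
                raise PlacementError(len(placed_centers), n)
        else:
            ok = False
            while tries < budget:
                tries += 1
                r = rng.uniform(0, shape[0])
                c = rng.uniform(0, shape[1])
                if fits(r, c, rad, sep_scale=1.05):
                    ok = True
                    break
            if not ok:
                raise PlacementError(len(placed_centers), n)
        centers[i] = (r, c)
        placed_centers.append((r, c))
        placed_radii.append(rad)
        i_ptr += 1
    return [c for c in centers], confluent  # type: ignore[misc]


# ---------------------------------------------------------------------------
# micromold scans
# ---------------------------------------------------------------------------

WELL_RING_VALUE = 40.0
PARTICLE_VALUE = 200.0
MOLD_BACKGROUND = 10.0


def simulate_micromold(spec: MicromoldSpec) -> tuple[MultiChannelImage, pd.DataFrame, pd.DataFrame]:
    """Render a micromold scan with seeded particles in each well.

    Returns ``(image, particle_truth, well_truth)``. ``particle_truth`` has
    one row per particle (well id, centroid in px, area in um^2);
    ``well_truth`` has one row per well (well id, center, true count). Wells
    are drawn as faint rings; particles as bright disks, so a per-well
    threshold separates them cleanly at zero noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols = spec.grid
    pitch_px = spec.well_pitch / spec.pixel_size
    well_r_px = 0.5 * spec.well_diameter / spec.pixel_size
    margin = pitch_px / 2.0
    shape = (
        int(math.ceil(n_rows * pitch_px + 2 * margin)),
        int(math.ceil(n_cols * pitch_px + 2 * margin)),
    )
    img = np.full(shape, MOLD_BACKGROUND)

    def _local_disk(cy, cx, radius):
        """Boolean disk as (row-slice, col-slice, patch-mask)."""
        r0 = max(int(cy - radius) - 2, 0)
        r1 = min(int(cy + radius) + 3, shape[0])
        c0 = max(int(cx - radius) - 2, 0)
        c1 = min(int(cx + radius) + 3, shape[1])
        yy, xx = np.mgrid[r0:r1, c0:c1]
        return slice(r0, r1), slice(c0, c1), np.hypot(yy - cy, xx - cx)

    wells = []
    particles = []
    pid = 0
    for i in range(n_rows):
        for j in range(n_cols):
            wid = i * n_cols + j
            cr = margin + (i + 0.5) * pitch_px
            cc = margin + (j + 0.5) * pitch_px
            rs, cs, dist = _local_disk(cr, cc, well_r_px + 3)
            ring = (dist >= well_r_px - 1.5) & (dist <= well_r_px + 1.5)
            img[rs, cs][ring] = WELL_RING_VALUE

            if spec.count_law == "poisson":
                k = int(rng.poisson(spec.count_mean))
            elif spec.count_law == "nbinom":
                r = spec.count_overdispersion
                p = r / (r + spec.count_mean)
                k = int(rng.negative_binomial(r, p)) if spec.count_mean > 0 else 0
            else:  # constant
                k = int(round(spec.count_mean))

            placed: list[tuple[float, float, float]] = []
            for _ in range(k):
                area = float(
                    rng.lognormal(math.log(spec.particle_area.median), math.log(spec.particle_area.gsd))
                )
                pr_px = math.sqrt(area / math.pi) / spec.pixel_size
                ok = False
                for _attempt in range(300):
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(0, max(well_r_px - pr_px - 3.0, 0.0))
                    py = cr + rad * math.sin(ang)
                    px = cc + rad * math.cos(ang)
                    if all(math.hypot(py - q[0], px - q[1]) > pr_px + q[2] + 2.0 for q in placed):
                        ok = True
                        break
                if not ok:
                    raise ValueError(
                        f"well {wid}: cannot place {k} particles of this size "
                        "(exceeds well capacity)"
                    )
                placed.append((py, px, pr_px))
                rs, cs, dist = _local_disk(py, px, pr_px)
                disk = dist <= pr_px
                img[rs, cs][disk] = PARTICLE_VALUE
                particles.append(
                    {
                        "particle_id": pid,
                        "well_id": wid,
                        "center_row": py,
                        "center_col": px,
                        "area_um2": float(disk.sum()) * spec.pixel_size**2,
                        "nominal_area_um2": area,
                    }
                )
                pid += 1
            wells.append({"well_id": wid, "center_row": cr, "center_col": cc, "count": k})

    image = MultiChannelImage(data=img[:, :, None], channels=("transmitted",), pixel_size=spec.pixel_size)
    return image, pd.DataFrame(particles), pd.DataFrame(wells)


# ---------------------------------------------------------------------------
# direct feature tables (fast path, no imaging)
# ---------------------------------------------------------------------------

def simulate_feature_table(
    specs: list[PopulationSpec],
    n_per_group: int,
    seed: int,
    n_redundant: int = 5,
    n_noise: int = 0,
    measurement_cv: float = 0.03,
):
    """Closed-form per-cell features for a list of populations, no rendering.

    Geometric features follow from the latent radii/elongation analytically
    (area = pi * r^2 for the geometric-mean radius, etc.), then a small
    multiplicative measurement error (``measurement_cv``) is applied.
    ``n_redundant`` noisy linear combinations of true features and
    ``n_noise`` pure-noise columns can be appended to exercise
    communality-based selection. Returns a :class:`~ovomorph.morphometry.FeatureMatrix`.
    """
    from .morphometry import FeatureCatalog, FeatureMatrix

    if len(specs) < 1:
        raise ValueError("need at least one population spec")
    frames = []
    for g, spec in enumerate(specs):
        sub_seed = int(np.random.SeedSequence(seed).spawn(len(specs))[g].generate_state(1)[0] % (2**31))
        frames.append(sample_population(spec, n_per_group, sub_seed))
    lat = pd.concat(frames, ignore_index=True)
    lat["cell_id"] = np.arange(len(lat))

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(len(specs) + 1)[-1])
    n = len(lat)

    def noisy(x):
        if measurement_cv <= 0:
            return np.asarray(x, dtype=float)
        return np.asarray(x, dtype=float) * rng.lognormal(0.0, measurement_cv, n)

    r_n = lat["nuclear_radius_um"].to_numpy()
    r_c = lat["cell_radius_um"].to_numpy()
    el = lat["elongation"].to_numpy()
    irr = lat["boundary_irregularity"].to_numpy()

    feats = pd.DataFrame(index=lat.index)
    feats["nucleus_area"] = noisy(np.pi * r_n**2)
    feats["cell_area"] = noisy(np.pi * r_c**2)
    # perimeter of an ellipse with semi-axes (r*sqrt(e), r/sqrt(e)), Ramanujan,
    # inflated by boundary roughness
    a, b = r_c * np.sqrt(el), r_c / np.sqrt(el)
    h = ((a - b) / (a + b)) ** 2
    perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
    feats["cell_perimeter"] = noisy(perim * (1.0 + 1.5 * irr**2 * 10))
    feats["nucleus_perimeter"] = noisy(2 * np.pi * r_n)
    feats["cell_equivalent_diameter"] = noisy(2 * r_c)
    feats["nucleus_equivalent_diameter"] = noisy(2 * r_n)
    feats["cell_aspect_ratio"] = noisy(el)
    feats["cell_eccentricity"] = noisy(np.sqrt(1.0 - 1.0 / el**2) + 1e-6)
    feats["cell_circularity"] = 4 * np.pi * feats["cell_area"] / feats["cell_perimeter"] ** 2
    feats["cell_roughness"] = noisy(1.0 + 3.0 * irr)
    feats["nc_area_ratio"] = np.clip(feats["nucleus_area"] / feats["cell_area"], None, 1.0)
    feats["nucleus_centroid_offset_frac"] = noisy(lat["nucleus_offset_frac"].to_numpy() + 1e-3)
    feats["actin_sum"] = noisy(lat["actin_intensity"].to_numpy())
    feats["vimentin_sum"] = noisy(lat["vimentin_intensity"].to_numpy())
    feats["actin_mean"] = feats["actin_sum"] / feats["cell_area"]
    feats["vimentin_mean"] = feats["vimentin_sum"] / feats["cell_area"]

    base_cols = list(feats.columns)
    log_pool = np.column_stack(
        [np.log(feats["cell_area"]), np.log(feats["nucleus_area"]), np.log(feats["actin_sum"]),
         np.log(feats["vimentin_sum"]), np.log(feats["cell_aspect_ratio"])]
    )
    log_pool = (log_pool - log_pool.mean(0)) / log_pool.std(0)
    for i in range(n_redundant):
        w = rng.normal(size=log_pool.shape[1])
        feats[f"redundant_{i}"] = log_pool @ w + rng.normal(0.0, 0.3, n)
    for i in range(n_noise):
        feats[f"noise_{i}"] = rng.normal(0.0, 1.0, n)

    catalog = FeatureCatalog.from_columns(
        {c: ("cross" if c.startswith(("redundant", "noise", "nc_")) else "cell") for c in feats.columns}
    )
    meta = lat[["cell_id", "group", "subtype", "subtype_name"]].copy()
    return FeatureMatrix(features=feats, metadata=meta, catalog=catalog)
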