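"""Parameter specifications for the synthetic-data generators.

All positive-valued cell parameters (radii, intensities) are log-normal,
parameterized by *median* and *geometric standard deviation* (``gsd``): if
``X ~ LogNormal(mu, sigma)`` then ``median = exp(mu)`` and ``gsd = exp(sigma)``.
This keeps every draw strictly positive and reproduces the right-skew of
biological size distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "LogNormalParam",
    "SubtypeSpec",
    "PopulationSpec",
    "SceneSpec",
    "MicromoldSpec",
    "SpecValidationError",
]


class SpecValidationError(ValueError):
    """Raised when a generator spec is invalid; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"invalid spec field '{field_name}': {message}")


@dataclass(frozen=True)
class LogNormalParam:
    """Log-normal law given by its median and geometric sd (both > 0, gsd >= 1)."""

    median: float
    gsd: float = 1.2

    def validate(self, name: str) -> None:
        if not self.median > 0:
            raise SpecValidationError(name, f"median must be > 0, got {self.median}")
        if not self.gsd >= 1.0:
            raise SpecValidationError(name, f"gsd must be >= 1, got {self.gsd}")


@dataclass(frozen=True)
class SubtypeSpec:
    """One morphological subtype within a population.

    ``elongation`` is the major/minor axis ratio (>= 1);
    ``boundary_irregularity`` scales the Fourier perturbation of the cell
    outline (0 = smooth ellipse, 0.5 = maximal roughness without
    self-intersection under the star-convex construction).
    """

    name: str = "subtype"
    nuclear_radius: LogNormalParam = field(default_factory=lambda: LogNormalParam(7.0, 1.15))
    cell_radius: LogNormalParam = field(default_factory=lambda: LogNormalParam(18.0, 1.25))
    elongation: LogNormalParam = field(default_factory=lambda: LogNormalParam(1.4, 1.15))
    boundary_irregularity: float = 0.08
    actin_intensity: LogNormalParam = field(default_factory=lambda: LogNormalParam(5.0e4, 1.4))
    vimentin_intensity: LogNormalParam = field(default_factory=lambda: LogNormalParam(3.0e4, 1.4))
    nucleus_offset_frac: float = 0.1

    def validate(self, prefix: str = "") -> None:
        p = f"{prefix}{self.name}." if prefix or self.name else ""
        self.nuclear_radius.validate(p + "nuclear_radius")
        self.cell_radius.validate(p + "cell_radius")
        self.elongation.validate(p + "elongation")
        self.actin_intensity.validate(p + "actin_intensity")
        self.vimentin_intensity.validate(p + "vimentin_intensity")
        if self.elongation.median < 1.0:
            raise SpecValidationError(p + "elongation", "median must be >= 1")
        if not (0.0 <= self.boundary_irregularity <= 0.5):
            raise SpecValidationError(
                p + "boundary_irregularity",
                f"must be in [0, 0.5], got {self.boundary_irregularity}",
            )
        if not (0.0 <= self.nucleus_offset_frac < 0.5):
            raise SpecValidationError(
                p + "nucleus_offset_frac",
                f"must be in [0, 0.5), got {self.nucleus_offset_frac}",
            )
        if not self.nuclear_radius.median < self.cell_radius.median:
            raise SpecValidationError(
                p + "nuclear_radius",
                "median nuclear radius must be smaller than median cell radius "
                f"({self.nuclear_radius.median} >= {self.cell_radius.median})",
            )


@dataclass(frozen=True)
class PopulationSpec:
    """A cell population: a weighted mixture of morphological subtypes."""

    name: str
    subtypes: tuple[SubtypeSpec, ...]
    subtype_weights: tuple[float, ...]

    @property
    def n_subtypes(self) -> int:
        return len(self.subtypes)

    def validate(self) -> None:
        if len(self.subtypes) < 1:
            raise SpecValidationError("subtypes", "need at least one subtype")
        if len(self.subtype_weights) != len(self.subtypes):
            raise SpecValidationError(
                "subtype_weights",
                f"{len(self.subtype_weights)} weights for {len(self.subtypes)} subtypes",
            )
        if any(w < 0 for w in self.subtype_weights):
            raise SpecValidationError("subtype_weights", "weights must be >= 0")
        total = sum(self.subtype_weights)
        if abs(total - 1.0) > 1e-9:
            raise SpecValidationError("subtype_weights", f"must sum to 1, got {total}")
        for st in self.subtypes:
            st.validate(prefix=f"{self.name}.")

    def scaled(self, name: str, radius_factor: float = 1.0, intensity_factor: float = 1.0) -> "PopulationSpec":
        """Derived population with all size medians and/or intensity medians rescaled."""
        new = []
        for st in self.subtypes:
            new.append(
                replace(
                    st,
                    nuclear_radius=replace(st.nuclear_radius, median=st.nuclear_radius.median * radius_factor),
                    cell_radius=replace(st.cell_radius, median=st.cell_radius.median * radius_factor),
                    actin_intensity=replace(st.actin_intensity, median=st.actin_intensity.median * intensity_factor),
                    vimentin_intensity=replace(st.vimentin_intensity, median=st.vimentin_intensity.median * intensity_factor),
                )
            )
        return PopulationSpec(name=name, subtypes=tuple(new), subtype_weights=self.subtype_weights)


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, density and noise of one synthetic multi-channel field of view.

    Defaults follow the acquisition geometry the features are calibrated for:
    1024 x 1024 pixels at 0.568 um per pixel.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.568
    n_cells: int = 50
    confluency_fraction: float = 0.0
    noise_sd: float = 0.0
    poisson_noise: bool = False
    background_level: float = 5.0
    include_membrane: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.pixel_size > 0:
            raise SpecValidationError("pixel_size", f"must be > 0, got {self.pixel_size}")
        if self.n_cells < 0:
            raise SpecValidationError("n_cells", f"must be >= 0, got {self.n_cells}")
        if not (0.0 <= self.confluency_fraction <= 1.0):
            raise SpecValidationError(
                "confluency_fraction", f"must be in [0,1], got {self.confluency_fraction}"
            )
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", "must be >= 0")
        if self.background_level < 0:
            raise SpecValidationError("background_level", "must be >= 0")
        if len(self.image_shape) != 2 or any(s <= 0 for s in self.image_shape):
            raise SpecValidationError("image_shape", f"must be two positive ints, got {self.image_shape}")


@dataclass(frozen=True)
class MicromoldSpec:
    """A grid of agarose microwells seeded with countable particles.

    ``count_law`` is 'poisson' or 'nbinom'; for 'nbinom' the dispersion is
    given by ``count_overdispersion`` (variance = mean * (1 + mean/r), r =
    ``count_overdispersion``).
    """

    grid: tuple[int, int] = (9, 9)
    well_diameter: float = 400.0
    well_pitch: float = 600.0
    pixel_size: float = 3.3
    count_law: str = "poisson"
    count_mean: float = 3.0
    count_overdispersion: float = 5.0
    particle_area: LogNormalParam = field(default_factory=lambda: LogNormalParam(600.0, 1.6))
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid) != 2 or any(g < 1 for g in self.grid):
            raise SpecValidationError("grid", f"must be two positive ints, got {self.grid}")
        if not self.well_diameter < self.well_pitch:
            raise SpecValidationError(
                "well_diameter",
                f"must be < well_pitch ({self.well_diameter} >= {self.well_pitch})",
            )
        if not self.well_diameter > 0:
            raise SpecValidationError("well_diameter", "must be > 0")
        if not self.pixel_size > 0:
            raise SpecValidationError("pixel_size", "must be > 0")
        if self.count_law not in ("poisson", "nbinom", "constant"):
            raise SpecValidationError("count_law", f"unknown law '{self.count_law}'")
        if self.count_mean < 0:
            raise SpecValidationError("count_mean", "must be >= 0")
        if self.count_law == "nbinom" and not self.count_overdispersion > 0:
            raise SpecValidationError("count_overdispersion", "must be > 0")
        self.particle_area.validate("particle_area")
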