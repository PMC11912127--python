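"""Synthetic hyperspectral Raman cube generator.

Emulates the statistical structure of a confocal Raman mapping study of
cortical organoids: per field of view (FOV) an H x W grid of pixels, each
carrying a raw spectrum that is the sum of

* Lorentzian (or Gaussian) biomarker bands whose amplitudes depend on the
  maturation stage of the organoid,
* a slowly varying autofluorescence baseline (low-order polynomial),
* i.i.d. Gaussian detector noise, and
* occasional single-channel cosmic-ray spikes.

Organoid- and FOV-level variability enters as multiplicative log-normal
random effects on the whole spectrum — the intensity-scale nuisance that
Frobenius/z-score normalization is designed to remove.

Everything is deterministic given the :class:`StudyDesign` seed; each cube
draws from an independent stream keyed by its (stage, organoid, FOV) indices
so cubes can be generated in any order, or lazily.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .axes import WavenumberAxis, make_axis

#: Spatial pitch of the emulated scan (micrometres per pixel).
PITCH_UM = 1.5

# Cosmic-ray spike amplitudes, in units of the detector noise SD.  Spikes are
# at least 20 noise-SD tall so a 3-sigma robust despiking rule must catch
# essentially all of them.
SPIKE_AMP_LO = 20.0
SPIKE_AMP_HI = 200.0


@dataclass(frozen=True)
class BandComponent:
    """A named vibrational band: unit-height peak of given shape.

    ``width`` is the half-width at half-maximum (HWHM) in cm**-1.
    """

    name: str
    center: float
    width: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-height peak evaluated on the given wavenumber grid."""
        d = np.asarray(wavenumbers, dtype=float) - self.center
        if self.shape == "lorentzian":
            return self.width**2 / (d**2 + self.width**2)
        return np.exp(-np.log(2.0) * (d / self.width) ** 2)


@dataclass(frozen=True)
class StageProfile:
    """Band amplitudes (arbitrary detector counts) of one maturation stage."""

    stage_weeks: int
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("band amplitudes must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Full description of a synthetic acquisition campaign.

    ``effect_scale`` multiplies the deviation of each stage's band amplitudes
    from the across-stage mean amplitude: 1 keeps the profiles as given, 0
    collapses every stage onto the mean profile (the null study).

    ``nuisance`` optionally adds a band whose amplitude is redrawn per FOV,
    independent of stage and cell line — a strong common-variance direction
    that loads on the leading principal component.
    """

    stages: tuple[StageProfile, ...]
    bands: tuple[BandComponent, ...]
    organoids_per_stage: int = 3
    fovs_per_organoid: int = 6
    fov_height: int = 50
    fov_width: int = 50
    n_channels: int = 1340
    effect_scale: float = 1.0
    noise_sd: float = 10.0
    baseline_mean_coeffs: tuple[float, ...] = (900.0, -250.0, 120.0, -40.0)
    baseline_coeff_sd: float = 60.0
    cosmic_ray_rate: float = 0.1
    organoid_sd: float = 0.10
    fov_sd: float = 0.05
    seed: int = 0
    line: str = "PGP1"
    nuisance: BandComponent | None = None
    nuisance_amp_mean: float = 0.0
    nuisance_amp_sd: float = 0.0
    axis: WavenumberAxis | None = None

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("design needs at least one stage")
        if min(self.organoids_per_stage, self.fovs_per_organoid) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.fov_height, self.fov_width) < 1:
            raise ValueError("FOV dimensions must be >= 1")
        if self.noise_sd < 0 or self.cosmic_ray_rate < 0:
            raise ValueError("noise_sd and cosmic_ray_rate must be >= 0")
        if self.organoid_sd < 0 or self.fov_sd < 0 or self.baseline_coeff_sd < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")
        if len(self.baseline_mean_coeffs) > 6:
            raise ValueError("baseline polynomial order must be <= 5")
        band_names = {b.name for b in self.bands}
        for prof in self.stages:
            unknown = set(prof.concentrations) - band_names
            if unknown:
                raise ValueError(f"profile refers to unknown bands {unknown}")

    @property
    def n_cubes(self) -> int:
        return len(self.stages) * self.organoids_per_stage * self.fovs_per_organoid

    def make_axis(self) -> WavenumberAxis:
        return self.axis if self.axis is not None else make_axis(self.n_channels)

    def effective_amplitudes(self, stage_index: int) -> dict[str, float]:
        """Stage band amplitudes after applying ``effect_scale``.

        amp = mean_over_stages + effect_scale * (amp_stage - mean), floored
        at zero so amplitudes stay physical for large scales.
        """
        means = {
            b.name: float(
                np.mean([p.concentrations.get(b.name, 0.0) for p in self.stages])
            )
            for b in self.bands
        }
        prof = self.stages[stage_index].concentrations
        return {
            name: max(0.0, mu + self.effect_scale * (prof.get(name, 0.0) - mu))
            for name, mu in means.items()
        }

    def with_(self, **changes) -> "StudyDesign":
        return replace(self, **changes)


@dataclass(frozen=True)
class HyperspectralCube:
    """One FOV: an H x W x C block of nonnegative intensities plus metadata."""

    intensities: np.ndarray = field(repr=False)
    axis: WavenumberAxis
    line: str
    organoid_id: str
    stage_weeks: int
    fov_id: str
    pitch_um: float = PITCH_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError("intensities must be H x W x C")
        if arr.shape[2] != len(self.axis):
            raise ValueError("axis length must equal the spectral dimension")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("spatial dimensions must be >= 1")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def spectra(self) -> np.ndarray:
        """Pixels flattened row-major to an (H*W, C) matrix (a view-copy)."""
        h, w, c = self.shape
        return self.intensities.reshape(h * w, c)


# ---------------------------------------------------------------------------
# random streams

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _baseline(axis: WavenumberAxis, coeffs: Sequence[float]) -> np.ndarray:
    """Low-order polynomial on the axis affinely mapped to [-1, 1]."""
    v = axis.values
    t = 2.0 * (v - v[0]) / (v[-1] - v[0]) - 1.0
    return np.polynomial.polynomial.polyval(t, np.asarray(coeffs, dtype=float))


def _inject_spikes(
    spectra: np.ndarray, rate: float, noise_sd: float, rng: np.random.Generator
) -> int:
    """Add Poisson-count single-channel positive spikes in place.

    Returns the number of spikes injected.  Spike height is uniform in
    [20, 200] x noise_sd (unit scale when noise_sd is 0, so spikes remain
    visible in noise-free test spectra).
    """
    if rate == 0:
        return 0
    n, c = spectra.shape
    counts = rng.poisson(rate, size=n)
    total = int(counts.sum())
    if total == 0:
        return 0
    rows = np.repeat(np.arange(n), counts)
    cols = rng.integers(0, c, size=total)
    scale = noise_sd if noise_sd > 0 else 1.0
    amps = rng.uniform(SPIKE_AMP_LO, SPIKE_AMP_HI, size=total) * scale
    np.add.at(spectra, (rows, cols), amps)
    return total


def synth_spectrum(
    profile: StageProfile,
    bands: Sequence[BandComponent],
    axis: WavenumberAxis,
    baseline_coeffs: Sequence[float] = (),
    noise_sd: float = 0.0,
    cosmic_ray_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    amplitude_scale: float = 1.0,
) -> np.ndarray:
    """One raw spectrum: bands + baseline + noise + cosmic rays, clipped at 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    spec = np.zeros(len(axis))
    for band in bands:
        amp = profile.concentrations.get(band.name, 0.0)
        if amp:
            spec += amplitude_scale * amp * band.profile(axis.values)
    if len(baseline_coeffs):
        spec += _baseline(axis, baseline_coeffs)
    if noise_sd > 0:
        spec += rng.normal(0.0, noise_sd, size=spec.shape)
    _inject_spikes(spec[None, :], cosmic_ray_rate, noise_sd, rng)
    return np.clip(spec, 0.0, None)


def synth_cube(
    design: StudyDesign, stage_index: int, organoid_index: int, fov_index: int
) -> HyperspectralCube:
    """Generate one FOV, deterministic given (design.seed, indices).

    All pixels of the cube share one organoid-level and one FOV-level
    multiplicative log-normal effect; only detector noise and cosmic rays
    vary pixel to pixel.
    """
    if not 0 <= stage_index < len(design.stages):
        raise IndexError("stage_index out of range")
    if not 0 <= organoid_index < design.organoids_per_stage:
        raise IndexError("organoid_index out of range")
    if not 0 <= fov_index < design.fovs_per_organoid:
        raise IndexError("fov_index out of range")

    axis = design.make_axis()
    h, w, c = design.fov_height, design.fov_width, len(axis)

    org_rng = _rng(design.seed, 0, stage_index, organoid_index)
    org_effect = float(np.exp(org_rng.normal(0.0, design.organoid_sd)))

    rng = _rng(design.seed, 1, stage_index, organoid_index, fov_index)
    fov_effect = float(np.exp(rng.normal(0.0, design.fov_sd)))
    scale = org_effect * fov_effect

    amps = design.effective_amplitudes(stage_index)
    base = np.zeros(c)
    for band in design.bands:
        amp = amps.get(band.name, 0.0)
        if amp:
            base += amp * band.profile(axis.values)
    if design.nuisance is not None:
        nuis_amp = max(
            0.0, rng.normal(design.nuisance_amp_mean, design.nuisance_amp_sd)
        )
        base += nuis_amp * design.nuisance.profile(axis.values)

    coeffs = np.asarray(design.baseline_mean_coeffs, dtype=float)
    if design.baseline_coeff_sd > 0:
        coeffs = coeffs + rng.normal(0.0, design.baseline_coeff_sd, size=coeffs.shape)
    baseline = _baseline(axis, coeffs)

    spectra = np.broadcast_to(scale * base + baseline, (h * w, c)).copy()
    if design.noise_sd > 0:
        spectra += rng.normal(0.0, design.noise_sd, size=spectra.shape)
    _inject_spikes(spectra, design.cosmic_ray_rate, design.noise_sd, rng)
    np.clip(spectra, 0.0, None, out=spectra)

    stage = design.stages[stage_index]
    return HyperspectralCube(
        intensities=spectra.reshape(h, w, c),
        axis=axis,
        line=design.line,
        organoid_id=f"{design.line}-{stage.stage_weeks}w-org{organoid_index + 1}",
        stage_weeks=stage.stage_weeks,
        fov_id=f"fov{fov_index + 1}",
    )


def iter_study(design: StudyDesign) -> Iterator[HyperspectralCube]:
    """Lazily generate every cube of the design (stage-major order)."""
    for s in range(len(design.stages)):
        for o in range(design.organoids_per_stage):
            for f in range(design.fovs_per_organoid):
                yield synth_cube(design, s, o, f)


def synth_study(design: StudyDesign) -> list[HyperspectralCube]:
    """All cubes of the design as a list (see :func:`iter_study` to stream)."""
    return list(iter_study(design))
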