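"""Frozen study designs mirroring the three organoid experiments.

* ``pgp1_4stage`` — iPSC-derived organoids at 6/12/16/20 weeks, three
  organoids per stage, six 50 x 50 px FOVs per organoid.  Band amplitudes
  encode the reported maturation trends: nucleic acids and protein (amide I)
  fall while glycogen rises with age.
* ``h1_2stage`` — ESC-derived organoids at 16/20 weeks, two organoids per
  stage, eight FOVs each; protein (amide III) and nucleic acids fall,
  polysaccharide rises.
* ``line_comparison`` — PGP1 vs H1 at matched ages; PGP1 carries more
  glycogen and lipid and less nucleic acid.  A broad "substrate" band whose
  amplitude is redrawn per FOV, identically for both lines, provides the
  line-independent nuisance direction that dominates PC1.

Amplitudes, noise and random-effect scales were calibrated once against the
full default pipeline and are frozen here; treat them as the definition of
the synthetic study conditions, not as tunables.
"""
from __future__ import annotations

from .synth import BandComponent, StageProfile, StudyDesign

#: Lorentzian biomarker bands shared by every preset (HWHM in cm**-1).
DEFAULT_BAND_COMPONENTS: tuple[BandComponent, ...] = (
    BandComponent("nucleic_acids", 788.0, 8.0),
    BandComponent("glycogen", 850.0, 9.0),
    BandComponent("polysaccharide", 940.0, 9.0),
    BandComponent("phenylalanine", 1004.0, 6.0),
    BandComponent("amide_III", 1350.0, 14.0),
    BandComponent("lipid_CH2", 1440.0, 10.0),
    BandComponent("amide_I", 1650.0, 16.0),
)

#: Broad line-independent background band used by the cell-line preset.
NUISANCE_BAND = BandComponent("substrate", 1245.0, 25.0)

_COMMON = dict(
    bands=DEFAULT_BAND_COMPONENTS,
    noise_sd=10.0,
    baseline_mean_coeffs=(900.0, -250.0, 120.0, -40.0),
    baseline_coeff_sd=12.0,
    cosmic_ray_rate=0.1,
    organoid_sd=0.03,
    fov_sd=0.015,
)

# Shared maturation coordinate of the four-stage preset: biomarker amplitudes
# are affine in this progression (one latent developmental axis, band-specific
# sensitivities), so the four stage-mean spectra are collinear in channel
# space.  The amplitudes also keep the per-spectrum channel SD stationary
# across stages (within ~3%), so per-spectrum z-scoring neither paints stage
# "echo" trends onto constant bands nor bends the stage means.
_MATURATION_T = (0.0, 1.0, 1.75, 2.25)


def pgp1_4stage(seed: int = 1234, **overrides) -> StudyDesign:
    """Four maturation stages, 3 organoids each, 6 FOVs per organoid."""
    bases = {
        "nucleic_acids": (92.0, -15.0),
        "glycogen": (50.0, 26.0),
        "amide_I": (95.0, -12.0),
        "polysaccharide": (50.0, 0.0),
        "phenylalanine": (60.0, 0.0),
        "amide_III": (70.0, 0.0),
        "lipid_CH2": (70.0, 0.0),
    }
    stages = tuple(
        StageProfile(
            weeks,
            {name: base + slope * t for name, (base, slope) in bases.items()},
        )
        for weeks, t in zip((6, 12, 16, 20), _MATURATION_T)
    )
    params = dict(
        stages=stages,
        organoids_per_stage=3,
        fovs_per_organoid=6,
        seed=seed,
        line="PGP1",
        **_COMMON,
    )
    params.update(overrides)
    return StudyDesign(**params)


def h1_2stage(seed: int = 5678, **overrides) -> StudyDesign:
    """Two late stages (16 vs 20 weeks), 2 organoids each, 8 FOVs per organoid."""
    stages = (
        StageProfile(16, {
            "nucleic_acids": 82.0, "glycogen": 55.0, "polysaccharide": 46.0,
            "phenylalanine": 60.0, "amide_III": 85.0, "lipid_CH2": 78.0,
            "amide_I": 95.0,
        }),
        StageProfile(20, {
            "nucleic_acids": 64.0, "glycogen": 55.0, "polysaccharide": 62.0,
            "phenylalanine": 60.0, "amide_III": 67.0, "lipid_CH2": 78.0,
            "amide_I": 95.0,
        }),
    )
    params = dict(
        stages=stages,
        organoids_per_stage=2,
        fovs_per_organoid=8,
        seed=seed,
        line="H1",
        **_COMMON,
    )
    params.update(overrides)
    return StudyDesign(**params)


def line_comparison(seed: int = 9012, **overrides) -> tuple[StudyDesign, StudyDesign]:
    """PGP1 vs H1 designs at matched ages with a shared per-FOV nuisance band.

    Returns one design per line; generate both and pool the cubes.  Line
    differences sit in the glycogen, lipid and nucleic-acid amplitudes; the
    ``substrate`` nuisance band varies per FOV identically for both lines and
    carries no line information.
    """
    def profiles(glycogen, lipid, nucleic):
        common = {"polysaccharide": 52.0, "phenylalanine": 60.0,
                  "amide_III": 72.0}
        return (
            StageProfile(16, {
                "nucleic_acids": nucleic, "glycogen": glycogen,
                "lipid_CH2": lipid, "amide_I": 92.0, **common,
            }),
            StageProfile(20, {
                "nucleic_acids": nucleic, "glycogen": glycogen,
                "lipid_CH2": lipid, "amide_I": 86.0, **common,
            }),
        )

    shared = dict(
        organoids_per_stage=1,
        fovs_per_organoid=6,
        bands=DEFAULT_BAND_COMPONENTS + (NUISANCE_BAND,),
        nuisance=NUISANCE_BAND,
        nuisance_amp_mean=70.0,
        nuisance_amp_sd=50.0,
        **{k: v for k, v in _COMMON.items() if k != "bands"},
    )
    shared.update(overrides)
    pgp1 = StudyDesign(
        stages=profiles(glycogen=80.0, lipid=92.0, nucleic=62.0),
        seed=seed,
        line="PGP1",
        **shared,
    )
    h1 = StudyDesign(
        stages=profiles(glycogen=56.0, lipid=74.0, nucleic=84.0),
        seed=(seed + 1) % 2**31,
        line="H1",
        **shared,
    )
    return pgp1, h1


PRESETS = {
    "pgp1-4stage": pgp1_4stage,
    "h1-2stage": h1_2stage,
    "line-comparison": line_comparison,
}
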