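import numpy as np
import pandas as pd
import pytest

from ramanstage.axes import WavenumberAxis
from ramanstage.synth import BandComponent, StageProfile, StudyDesign
from ramanstage.table import SpectrumTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_axis():
    """256-channel linear axis spanning the fingerprint region."""
    return WavenumberAxis(np.linspace(600.0, 1800.0, 256))


def make_labels(n, stage=6, line="PGP1", organoid="org1", fov="fov1"):
    return pd.DataFrame(
        {
            "stage_weeks": [stage] * n,
            "line": [line] * n,
            "organoid_id": [organoid] * n,
            "fov_id": [fov] * n,
        }
    )


@pytest.fixture
def toy_table(rng, small_axis):
    """120 random spectra over 3 stages, unit-norm rows."""
    X = rng.normal(size=(120, len(small_axis)))
    X /= np.linalg.norm(X, axis=1, keepdims=True)
    labels = pd.concat(
        [make_labels(40, stage=s, organoid=f"org{s}") for s in (6, 12, 16)],
        ignore_index=True,
    )
    return SpectrumTable(X, small_axis, labels)


def tiny_design(**overrides):
    """Small, fast study design for structural tests."""
    bands = (
        BandComponent("nucleic_acids", 788.0, 8.0),
        BandComponent("glycogen", 850.0, 9.0),
        BandComponent("amide_I", 1650.0, 16.0),
    )
    stages = (
        StageProfile(6, {"nucleic_acids": 90.0, "glycogen": 30.0, "amide_I": 100.0}),
        StageProfile(12, {"nucleic_acids": 60.0, "glycogen": 70.0, "amide_I": 80.0}),
    )
    params = dict(
        stages=stages,
        bands=bands,
        organoids_per_stage=1,
        fovs_per_organoid=1,
        fov_height=10,
        fov_width=10,
        n_channels=256,
        axis=WavenumberAxis(np.linspace(600.0, 1800.0, 256)),
        noise_sd=5.0,
        baseline_mean_coeffs=(300.0, -80.0, 40.0),
        baseline_coeff_sd=20.0,
        cosmic_ray_rate=0.05,
        organoid_sd=0.05,
        fov_sd=0.03,
        seed=7,
    )
    params.update(overrides)
    return StudyDesign(**params)
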