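"""End-to-end orchestration: generation -> preprocessing -> classification ->
interpretation -> separability, with every artifact written to a run
directory together with a manifest that reproduces the run."""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, io, presets
from .classify import ClassifierConfig
from .interpret import BandDefinition, DEFAULT_BANDS, band_results_frame
from .model import RamanMaturationModel
from .preprocess import PreprocessConfig, preprocess_pipeline
from .separability import DEFAULT_THRESHOLD
from .synth import BandComponent, StageProfile, StudyDesign, iter_study
from .table import SpectrumTable

log = logging.getLogger("ramanstage")


@dataclass
class RunConfig:
    """Everything one reproducible analysis run needs."""

    designs: tuple[StudyDesign, ...] = ()
    input_paths: tuple[str, ...] = ()  # alternative: directories of cube files
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    label: str = "stage_weeks"
    separability_pc_indices: tuple[int, ...] = (1, 2, 4)
    separability_threshold: float = DEFAULT_THRESHOLD
    seed: int = 0
    name: str = "run"

    def __post_init__(self) -> None:
        if not self.designs and not self.input_paths:
            raise ValueError("config needs designs or input paths")


def preset_config(name: str, seed: int | None = None, **kwargs) -> RunConfig:
    """RunConfig for one of the shipped experiment presets."""
    if name not in presets.PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets.PRESETS)}")
    built = presets.PRESETS[name]() if seed is None else presets.PRESETS[name](seed)
    designs = built if isinstance(built, tuple) else (built,)
    cfg = dict(
        designs=designs,
        seed=designs[0].seed,
        name=name,
    )
    if name == "line-comparison":
        cfg["label"] = "line"
        cfg["classifier"] = ClassifierConfig(pc_indices=tuple(range(2, 21)))
        cfg["separability_pc_indices"] = (2, 3, 4)
    elif name == "pgp1-4stage":
        cfg["classifier"] = ClassifierConfig(k_folds=30)
    cfg.update(kwargs)
    return RunConfig(**cfg)


# ---------------------------------------------------------------------------
# JSON (de)serialization of configs

def _asdict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def config_to_json(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_asdict(config), indent=2, default=str))


def config_from_json(path: str | Path) -> RunConfig:
    raw = json.loads(Path(path).read_text())

    def design(d: dict) -> StudyDesign:
        d = dict(d)
        d["stages"] = tuple(
            StageProfile(s["stage_weeks"], s["concentrations"]) for s in d["stages"]
        )
        d["bands"] = tuple(BandComponent(**b) for b in d["bands"])
        if d.get("nuisance"):
            d["nuisance"] = BandComponent(**d["nuisance"])
        if d.get("axis"):
            raise ValueError("explicit axes are not JSON-serializable")
        d.pop("axis", None)
        d["baseline_mean_coeffs"] = tuple(d["baseline_mean_coeffs"])
        return StudyDesign(**d)

    return RunConfig(
        designs=tuple(design(d) for d in raw.get("designs", [])),
        input_paths=tuple(raw.get("input_paths", [])),
        preprocess=PreprocessConfig(**raw["preprocess"]),
        classifier=ClassifierConfig(
            **{
                **raw["classifier"],
                "pc_indices": tuple(raw["classifier"]["pc_indices"])
                if raw["classifier"].get("pc_indices")
                else None,
            }
        ),
        bands=tuple(BandDefinition(**b) for b in raw["bands"]),
        label=raw.get("label", "stage_weeks"),
        separability_pc_indices=tuple(raw.get("separability_pc_indices", (1, 2, 4))),
        separability_threshold=raw.get("separability_threshold", DEFAULT_THRESHOLD),
        seed=raw.get("seed", 0),
        name=raw.get("name", "run"),
    )


# ---------------------------------------------------------------------------
# run orchestration

def load_table(config: RunConfig) -> SpectrumTable:
    """Generate (or read) the cubes and run the preprocessing chain."""
    def cubes():
        for design in config.designs:
            yield from iter_study(design)
        for path in config.input_paths:
            yield from io.iter_study_files(path)

    return preprocess_pipeline(cubes(), config.preprocess)


def run_experiment(
    config: RunConfig, outdir: str | Path, boruta: bool = True
) -> Path:
    """Execute the full pipeline and persist every artifact.

    Writes ``spectra.csv``, ``pca_model.h5``, ``classification_report.json``,
    ``band_results.csv``, ``separability.json``, ``confusion.csv`` and a
    ``manifest.json`` (config + version + seed) under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    table = load_table(config)
    log.info("preprocessed %d spectra x %d channels", table.n_spectra, table.n_channels)
    table.to_csv(outdir / "spectra.csv")

    model = RamanMaturationModel(table, label=config.label, config=config.classifier)
    results = model.fit(boruta=boruta)
    io.save_pca(results.pca, outdir / "pca_model.h5")
    (outdir / "classification_report.json").write_text(
        json.dumps(results.report.to_dict(), indent=2)
    )
    results.report.confusion.to_csv(outdir / "confusion.csv")
    log.info("CV accuracy %.4f +/- %.4f", results.accuracy_mean, results.accuracy_sd)

    signature = results.signature()
    pd.DataFrame(
        {"wavenumber_cm1": table.axis.values, "weighted_loading_sum": signature}
    ).to_csv(outdir / "signature.csv", index=False)

    bands = results.band_trends(config.bands)
    band_results_frame(bands).to_csv(outdir / "band_results.csv", index=False)

    sep_res = results.separability(
        config.separability_pc_indices, config.separability_threshold
    )
    (outdir / "separability.json").write_text(json.dumps(sep_res.to_dict(), indent=2))
    sep_res.distances.to_csv(outdir / "centroid_distances.csv")

    manifest = {
        "name": config.name,
        "version": __version__,
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "n_spectra": table.n_spectra,
        "n_channels": table.n_channels,
        "cv_accuracy_mean": results.accuracy_mean,
        "cv_accuracy_sd": results.accuracy_sd,
        "config": _asdict(config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (outdir / "summary.txt").write_text(results.summary() + "\n")
    return outdir
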