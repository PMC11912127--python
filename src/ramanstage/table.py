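"""Flat tables of (preprocessed) spectra with per-row sample labels."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .axes import WavenumberAxis

LABEL_COLUMNS = ["stage_weeks", "line", "organoid_id", "fov_id"]


@dataclass
class SpectrumTable:
    """N spectra x C channels plus aligned per-row labels.

    The unit handed to PCA and the classifier: one row per (binned) spectrum,
    labelled with maturation stage, cell line, organoid and FOV of origin.
    """

    spectra: np.ndarray = field(repr=False)
    axis: WavenumberAxis
    labels: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be an N x C matrix")
        if self.spectra.shape[1] != len(self.axis):
            raise ValueError("axis length must match the channel count")
        if len(self.labels) != self.spectra.shape[0]:
            raise ValueError("labels must have one row per spectrum")
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise ValueError(f"labels missing columns {missing}")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_spectra(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_channels(self) -> int:
        return self.spectra.shape[1]

    def group_values(self, key: str) -> np.ndarray:
        if key not in self.labels.columns:
            raise KeyError(f"unknown grouping key {key!r}")
        return self.labels[key].to_numpy()

    def subset(self, mask: np.ndarray) -> "SpectrumTable":
        mask = np.asarray(mask)
        return SpectrumTable(
            self.spectra[mask], self.axis, self.labels.loc[mask].reset_index(drop=True)
        )

    @staticmethod
    def concat(tables: list["SpectrumTable"]) -> "SpectrumTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        axis = tables[0].axis
        for t in tables[1:]:
            if t.axis != axis:
                raise ValueError("tables share no common axis")
        return SpectrumTable(
            np.vstack([t.spectra for t in tables]),
            axis,
            pd.concat([t.labels for t in tables], ignore_index=True),
        )

    # -- CSV round trip ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Labels first, then one column per channel named by its wavenumber."""
        chan_cols = [f"{v:.6f}" for v in self.axis.values]
        df = pd.concat(
            [
                self.labels[LABEL_COLUMNS],
                pd.DataFrame(self.spectra, columns=chan_cols),
            ],
            axis=1,
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumTable":
        df = pd.read_csv(path)
        chan_cols = [c for c in df.columns if c not in LABEL_COLUMNS]
        axis = WavenumberAxis(np.array([float(c) for c in chan_cols]))
        return cls(df[chan_cols].to_numpy(float), axis, df[LABEL_COLUMNS].copy())
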