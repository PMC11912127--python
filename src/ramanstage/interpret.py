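"""Biochemical interpretation of the trained model.

Three steps turn classifier output into biology: (1) the importance-weighted
sum of PCA loadings highlights the wavenumbers that drive the classification;
(2) trapezoidal band areas quantify individual biomarkers per spectrum; (3)
Mann-Whitney U tests compare band areas between stages or cell lines.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .axes import WavenumberAxis
from .decompose import PCAModel
from .table import SpectrumTable

#: Default biomarker bands (centers in cm**-1, literature assignments).
DEFAULT_BANDS: tuple["BandDefinition", ...]


@dataclass(frozen=True)
class BandDefinition:
    """A named wavenumber window used for band-area quantification."""

    name: str
    center: float
    window_halfwidth: float = 10.0

    def __post_init__(self) -> None:
        if self.window_halfwidth <= 0:
            raise ValueError("window_halfwidth must be > 0")

    @property
    def lo(self) -> float:
        return self.center - self.window_halfwidth

    @property
    def hi(self) -> float:
        return self.center + self.window_halfwidth


DEFAULT_BANDS = (
    BandDefinition("nucleic_acids", 788.0),
    BandDefinition("glycogen", 850.0),
    BandDefinition("polysaccharide", 940.0),
    BandDefinition("phenylalanine", 1004.0),
    BandDefinition("amide_III", 1350.0),
    BandDefinition("lipid_CH2", 1440.0),
    BandDefinition("amide_I", 1650.0),
)


@dataclass
class BandQuantResult:
    """Per-group band areas and the pairwise rank tests for one band."""

    band: BandDefinition
    group_key: str
    groups: list  # group values, in comparison order
    n: dict = field(repr=False)
    median: dict = field(repr=False)
    quartiles: dict = field(repr=False)  # group -> (q1, q3)
    areas: dict = field(repr=False)  # group -> ndarray of per-spectrum areas
    tests: pd.DataFrame = field(repr=False)  # columns: group_a, group_b, U, p, significant


def weighted_loading_sum(
    model: PCAModel,
    importances: Sequence[float],
    component_indices: Sequence[int],
) -> np.ndarray:
    """Importance-weighted sum of loadings over the requested components.

    ``W(nu) = sum_j importance_j * loading_j(nu)`` with 1-based component
    indices; the result is a channel-space signature emphasising the spectral
    regions most relevant to the classification.
    """
    imp = np.asarray(importances, dtype=float)
    idx = np.asarray(list(component_indices), dtype=int)
    if imp.shape[0] != idx.shape[0]:
        raise ValueError("importances and component_indices must align")
    if idx.size and (idx.min() < 1 or idx.max() > model.n_components):
        raise IndexError("component index out of range (1-based)")
    return imp @ model.loadings[idx - 1]


def integrate_band(
    spectra: np.ndarray, axis: WavenumberAxis, band: BandDefinition
) -> np.ndarray:
    """Trapezoidal area of each spectrum over the band window (cm**-1 units)."""
    mask = axis.window_mask(band.lo, band.hi)
    if mask.sum() < 2:
        raise ValueError(
            f"band {band.name!r} window [{band.lo}, {band.hi}] covers "
            "fewer than 2 channels"
        )
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    areas = np.trapezoid(x[:, mask], axis.values[mask], axis=1)
    return areas[0] if np.asarray(spectra).ndim == 1 else areas


def mann_whitney(
    areas_a: np.ndarray, areas_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (midrank ties).

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise.  Returns (U of the first group, p).
    """
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    cummin = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        cummin = min(cummin, p[i] * m / (rank + 1))
        adj[i] = cummin
    return adj


def band_trend_analysis(
    table: SpectrumTable,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    group_by: str = "stage_weeks",
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[BandQuantResult]:
    """Quantify every band per group and test group differences.

    Grouping by ``stage_weeks`` compares adjacent stages in time order;
    grouping by any other key (e.g. ``line``) compares all pairs.  Raw
    two-sided Mann-Whitney p-values are flagged at ``alpha``; an optional
    Benjamini-Hochberg correction is applied across the pairs of one band.
    """
    values = table.group_values(group_by)
    groups = sorted(set(values.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    if group_by == "stage_weeks":
        pairs = [(groups[i], groups[i + 1]) for i in range(len(groups) - 1)]
    else:
        pairs = [
            (groups[i], groups[j])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        ]

    results = []
    for band in bands:
        all_areas = integrate_band(table.spectra, table.axis, band)
        areas = {g: all_areas[values == g] for g in groups}
        rows = []
        for ga, gb in pairs:
            u, p = mann_whitney(areas[ga], areas[gb])
            rows.append({"group_a": ga, "group_b": gb, "U": u, "p": p})
        tests = pd.DataFrame(rows)
        if bh_correction:
            tests["p_adjusted"] = _bh_adjust(tests["p"].to_numpy())
            tests["significant"] = tests["p_adjusted"] < alpha
        else:
            tests["significant"] = tests["p"] < alpha
        results.append(
            BandQuantResult(
                band=band,
                group_key=group_by,
                groups=groups,
                n={g: int(areas[g].size) for g in groups},
                median={g: float(np.median(areas[g])) for g in groups},
                quartiles={
                    g: (
                        float(np.percentile(areas[g], 25)),
                        float(np.percentile(areas[g], 75)),
                    )
                    for g in groups
                },
                areas=areas,
                tests=tests,
            )
        )
    return results


def band_results_frame(results: Sequence[BandQuantResult]) -> pd.DataFrame:
    """Flatten band results to one row per (band, group pair) for export."""
    rows = []
    for res in results:
        for _, t in res.tests.iterrows():
            rows.append(
                {
                    "band": res.band.name,
                    "center_cm1": res.band.center,
                    "group_a": t["group_a"],
                    "group_b": t["group_b"],
                    "n_a": res.n[t["group_a"]],
                    "n_b": res.n[t["group_b"]],
                    "median_a": res.median[t["group_a"]],
                    "median_b": res.median[t["group_b"]],
                    "U": t["U"],
                    "p": t["p"],
                    "significant": bool(t["significant"]),
                }
            )
    return pd.DataFrame(rows)
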