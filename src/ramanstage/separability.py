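"""Between-group separability in PC space and minimum detectable intervals.

Group centroids are compared by Euclidean distance in a chosen subspace of
principal components.  Assuming the centroid distance between adjacent stages
grows linearly with the time separating them, the smallest time interval that
would still keep two stages separable at a distance threshold ``d0`` is

    dt_min = d0 * (t_b - t_a) / d(a, b)

for an adjacent stage pair acquired at ``t_a < t_b`` weeks with observed
distance ``d(a, b)``.  The linear distance-time scaling is an explicit
modelling assumption, printed with every report.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .decompose import select_components

#: Default separability threshold: the smallest observed separable centroid
#: distance used to anchor the extrapolation.
DEFAULT_THRESHOLD = 0.85

SCALING_ASSUMPTION = (
    "assumes centroid distance grows linearly with time between stages: "
    "dt_min = threshold * (t_b - t_a) / d(a, b)"
)


@dataclass
class SeparabilityResult:
    pc_indices: tuple[int, ...]
    centroids: pd.DataFrame = field(repr=False)  # one row per group
    distances: pd.DataFrame = field(repr=False)  # group x group Euclidean
    threshold: float = DEFAULT_THRESHOLD
    min_interval_weeks: pd.DataFrame | None = field(default=None, repr=False)
    assumption: str = SCALING_ASSUMPTION

    def to_dict(self) -> dict:
        return {
            "pc_indices": list(self.pc_indices),
            "groups": [str(g) for g in self.distances.index],
            "centroids": self.centroids.to_numpy().tolist(),
            "distances": self.distances.to_numpy().tolist(),
            "threshold": self.threshold,
            "min_interval_weeks": (
                self.min_interval_weeks.to_dict(orient="records")
                if self.min_interval_weeks is not None
                else None
            ),
            "assumption": self.assumption,
        }


def centroid_distances(
    scores: np.ndarray,
    labels: np.ndarray,
    pc_indices: Sequence[int] = (1, 2, 4),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group centroids of selected score columns and pairwise distances.

    ``pc_indices`` are 1-based.  Returns ``(centroids, distances)`` indexed by
    the sorted group values.
    """
    labels = np.asarray(labels)
    sel = select_components(np.asarray(scores, dtype=float), pc_indices)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    cent = []
    for g in groups:
        mask = labels == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        cent.append(sel[mask].mean(axis=0))
    cent = np.asarray(cent)
    diff = cent[:, None, :] - cent[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    cols = [f"PC{i}" for i in pc_indices]
    return (
        pd.DataFrame(cent, index=groups, columns=cols),
        pd.DataFrame(dist, index=groups, columns=groups),
    )


def min_detectable_interval(
    distances: pd.DataFrame,
    stage_weeks: Sequence[float] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Minimum separable time interval for each adjacent stage pair.

    A pair with zero centroid distance is flagged non-separable (its
    ``min_interval_weeks`` is NaN) rather than given a number.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if stage_weeks is None:
        stage_weeks = [float(g) for g in distances.index]
    stage_weeks = list(stage_weeks)
    if sorted(stage_weeks) != stage_weeks:
        raise ValueError("stages must be in increasing time order")
    groups = list(distances.index)
    if len(stage_weeks) != len(groups):
        raise ValueError("stage_weeks must align with the distance matrix")
    rows = []
    for i in range(len(groups) - 1):
        t_a, t_b = stage_weeks[i], stage_weeks[i + 1]
        d = float(distances.iloc[i, i + 1])
        separable = d > 0
        rows.append(
            {
                "stage_a": groups[i],
                "stage_b": groups[i + 1],
                "interval_weeks": t_b - t_a,
                "distance": d,
                "separable": separable,
                "min_interval_weeks": threshold * (t_b - t_a) / d
                if separable
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def separability_analysis(
    scores: np.ndarray,
    labels: np.ndarray,
    pc_indices: Sequence[int] = (1, 2, 4),
    stage_weeks: Sequence[float] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> SeparabilityResult:
    """Centroid distances plus, for ordered stages, minimum intervals."""
    centroids, distances = centroid_distances(scores, labels, pc_indices)
    intervals = None
    try:
        intervals = min_detectable_interval(distances, stage_weeks, threshold)
    except (ValueError, TypeError):
        intervals = None  # groups not ordered in time (e.g. cell lines)
    return SeparabilityResult(
        pc_indices=tuple(pc_indices),
        centroids=centroids,
        distances=distances,
        threshold=threshold,
        min_interval_weeks=intervals,
    )
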