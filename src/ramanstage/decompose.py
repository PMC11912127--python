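"""PCA decomposition of spectrum tables: scores, loadings, explained variance."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .axes import WavenumberAxis
from .table import SpectrumTable


@dataclass
class PCAModel:
    """Centered PCA of a spectrum table.

    ``loadings`` rows are unit-norm, mutually orthogonal channel-space
    directions; ``scores`` are the centered spectra projected on them.
    Component signs follow a fixed convention (largest-magnitude element of
    each loading is positive) so repeated fits and downstream weighted sums
    are reproducible.
    """

    mean_spectrum: np.ndarray = field(repr=False)
    loadings: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)
    explained_variance_fraction: np.ndarray
    axis: WavenumberAxis | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def fit_pca(table: SpectrumTable, n_components: int = 25) -> PCAModel:
    """Fit centered (covariance) PCA to the rows of the table."""
    X = table.spectra
    max_k = min(X.shape)
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components must be in [1, {max_k}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    # deterministic sign: largest-|.| element of every loading is positive
    idx = np.argmax(np.abs(loadings), axis=1)
    flip = np.sign(loadings[np.arange(len(idx)), idx])
    flip[flip == 0] = 1.0
    loadings *= flip[:, None]
    scores = scores * flip[None, :]
    return PCAModel(
        mean_spectrum=pca.mean_,
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        axis=table.axis,
    )


def project(model: PCAModel, table: SpectrumTable | np.ndarray) -> np.ndarray:
    """Project (possibly held-out) spectra onto the model's loadings."""
    X = table.spectra if isinstance(table, SpectrumTable) else np.atleast_2d(table)
    if X.shape[1] != model.mean_spectrum.size:
        raise ValueError("channel count does not match the PCA model")
    return (X - model.mean_spectrum) @ model.loadings.T


def select_components(
    model_or_scores: PCAModel | np.ndarray, indices: Sequence[int]
) -> np.ndarray:
    """Score columns for 1-based component indices (PC1 is index 1).

    Supports arbitrary order and exclusion of PC1 (e.g. ``range(2, 21)`` for
    the cell-line comparison).
    """
    scores = (
        model_or_scores.scores
        if isinstance(model_or_scores, PCAModel)
        else np.asarray(model_or_scores)
    )
    idx = np.asarray(list(indices), dtype=int)
    if idx.size == 0:
        raise ValueError("no components selected")
    if idx.min() < 1 or idx.max() > scores.shape[1]:
        raise IndexError(
            f"component indices must be in [1, {scores.shape[1]}] (1-based)"
        )
    return scores[:, idx - 1]
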