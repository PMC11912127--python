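"""Model/Results interface tying the pipeline stages together.

``RamanMaturationModel`` holds a preprocessed :class:`SpectrumTable` and the
analysis settings; ``fit()`` performs the PCA reduction, cross-validated
Random-Forest classification, hold-out evaluation, importance extraction and
(optionally) the Boruta relevance screen, returning a
:class:`MaturationResults` object that carries the estimates and exposes the
interpretation and separability analyses.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import classify, interpret, separability as sep
from .classify import ClassificationReport, ClassifierConfig
from .decompose import PCAModel, fit_pca, select_components
from .interpret import BandDefinition, BandQuantResult, DEFAULT_BANDS
from .preprocess import PreprocessConfig, preprocess_pipeline
from .synth import HyperspectralCube
from .table import SpectrumTable


class RamanMaturationModel:
    """Stage (or cell-line) classification model for preprocessed spectra.

    Parameters
    ----------
    table
        Preprocessed, normalized spectra with per-row labels.
    label
        Label column to classify: ``"stage_weeks"`` or ``"line"``.
    config
        Classifier settings (tree count, folds, PC selection, seed).
    """

    def __init__(
        self,
        table: SpectrumTable,
        label: str = "stage_weeks",
        config: ClassifierConfig = ClassifierConfig(),
    ) -> None:
        if label not in table.labels.columns:
            raise ValueError(f"unknown label column {label!r}")
        self.table = table
        self.label = label
        self.config = config

    @classmethod
    def from_cubes(
        cls,
        cubes: Iterable[HyperspectralCube],
        label: str = "stage_weeks",
        preprocess_config: PreprocessConfig = PreprocessConfig(),
        config: ClassifierConfig = ClassifierConfig(),
    ) -> "RamanMaturationModel":
        """Preprocess raw cubes and build the model in one step."""
        return cls(preprocess_pipeline(cubes, preprocess_config), label, config)

    def fit(self, boruta: bool = True) -> "MaturationResults":
        cfg = self.config
        pca = fit_pca(self.table, n_components=cfg.n_pcs)
        indices = cfg.selected_indices()
        scores = select_components(pca, indices)
        y = self.table.group_values(self.label)

        folds = classify.cross_validate(
            scores, y, k=cfg.k_folds, n_trees=cfg.n_trees, seed=cfg.seed
        )
        (x_tr, y_tr), (x_te, y_te) = classify.split_train_test(
            scores, y, cfg.train_fraction, seed=cfg.seed
        )
        forest = classify.train_rf(x_tr, y_tr, n_trees=cfg.n_trees, seed=cfg.seed)
        confusion, per_class = classify.evaluate(forest, x_te, y_te)
        importances = classify.feature_importance(forest)

        decisions = None
        if boruta:
            raw = classify.boruta_select(
                scores, y, iterations=cfg.boruta_iterations,
                n_trees=cfg.n_trees, seed=cfg.seed,
            )
            decisions = dict(zip(indices, raw))

        report = ClassificationReport(
            fold_accuracies=folds,
            confusion=confusion,
            per_class=per_class,
            importances=importances,
            pc_indices=indices,
            boruta_decision=decisions,
        )
        return MaturationResults(model=self, pca=pca, report=report)


@dataclass
class MaturationResults:
    """Fitted estimates plus the downstream interpretation methods."""

    model: RamanMaturationModel
    pca: PCAModel
    report: ClassificationReport
    _signature: np.ndarray | None = field(default=None, repr=False)

    # -- headline numbers ------------------------------------------------

    @property
    def accuracy_mean(self) -> float:
        return self.report.accuracy_mean

    @property
    def accuracy_sd(self) -> float:
        return self.report.accuracy_sd

    @property
    def scores(self) -> np.ndarray:
        return select_components(self.pca, self.report.pc_indices)

    def signature(self) -> np.ndarray:
        """Importance-weighted sum of the loadings of the selected PCs."""
        if self._signature is None:
            self._signature = interpret.weighted_loading_sum(
                self.pca, self.report.importances, self.report.pc_indices
            )
        return self._signature

    def band_trends(
        self,
        bands: Sequence[BandDefinition] = DEFAULT_BANDS,
        group_by: str | None = None,
        **kwargs,
    ) -> list[BandQuantResult]:
        return interpret.band_trend_analysis(
            self.model.table, bands, group_by or self.model.label, **kwargs
        )

    def separability(
        self,
        pc_indices: Sequence[int] = (1, 2, 4),
        threshold: float = sep.DEFAULT_THRESHOLD,
    ) -> sep.SeparabilityResult:
        y = self.model.table.group_values(self.model.label)
        stage_weeks = None
        if self.model.label == "stage_weeks":
            stage_weeks = sorted({float(v) for v in y})
        return sep.separability_analysis(
            self.pca.scores, y, pc_indices, stage_weeks, threshold
        )

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        r = self.report
        cfg = self.model.config
        lines = [
            "Raman maturation classification results",
            "=" * 44,
            f"label:            {self.model.label}",
            f"spectra:          {self.model.table.n_spectra} x "
            f"{self.model.table.n_channels} channels",
            f"components:       {len(r.pc_indices)} PCs "
            f"(indices {r.pc_indices[0]}..{r.pc_indices[-1]})",
            f"forest:           {cfg.n_trees} trees, seed {cfg.seed}",
            f"CV accuracy:      {100 * r.accuracy_mean:.2f}% +/- "
            f"{100 * r.accuracy_sd:.2f}% ({cfg.k_folds} folds)",
            f"hold-out accuracy: {100 * r.holdout_accuracy:.2f}% "
            f"({1 - cfg.train_fraction:.0%} test split)",
            "",
            "confusion matrix (rows true / columns predicted):",
            r.confusion.to_string(),
            "",
            "per-class metrics:",
            r.per_class.round(4).to_string(),
            "",
            "top PCs by importance:",
        ]
        order = np.argsort(r.importances)[::-1][:5]
        for j in order:
            dec = ""
            if r.boruta_decision is not None:
                dec = f"  [{r.boruta_decision[r.pc_indices[j]]}]"
            lines.append(
                f"  PC{r.pc_indices[j]:<3d} importance "
                f"{r.importances[j]:.4f}{dec}"
            )
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_signature(self, ax=None):
        """Signature W(nu) against Raman shift (optional matplotlib view)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.table.axis.values, self.signature(), lw=1)
        ax.set_xlabel("Raman shift (cm$^{-1}$)")
        ax.set_ylabel("importance-weighted loading sum")
        return ax

    def plot_confusion(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.report.confusion
        im = ax.imshow(c.to_numpy(), cmap="Blues")
        ax.set_xticks(range(len(c.columns)), [str(v) for v in c.columns])
        ax.set_yticks(range(len(c.index)), [str(v) for v in c.index])
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        plt.colorbar(im, ax=ax)
        return ax
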