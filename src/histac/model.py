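"""Model/Results interface over the hierarchical acetylation predictor.

``AcetylationModel`` is constructed from labeled training histones (plus
an optional nucleosome structure) and ``fit()`` performs every training
step: peptide extraction and merging, distance matrix, complete-linkage
tree, gain-ratio cut selection, reference sub-class construction,
intercept fitting, and region-catalog fitting.  The returned
``AcetylationResults`` carries the fitted components, a ``summary()``
table, ``predict()`` for query histones, and a dendrogram plot.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cluster import cut_tree, gain_ratio
from .io import HistoneProtein, read_histones
from .pipeline import (
    FittedComponents,
    PipelineConfig,
    evaluate_pipeline,
    records_to_frame,
    run_pipeline,
    fit_components,
)


class AcetylationModel:
    """Semi-supervised histone acetylation-site predictor.

    Parameters
    ----------
    training : list of HistoneProtein
        Histones with per-lysine P/N(/U) labels; must contain both P and
        N once unknowns are coerced.
    config : PipelineConfig, optional
        All tunables; defaults follow the package's standard settings
        (flank 12, BLOSUM62 raw distance, high cutoff 0.364).
    structure_path : path, optional
        Nucleosome PDB providing epsilon-N geometry for the third
        decision level; without it predictions stop at level 2.
    """

    def __init__(
        self,
        training: list[HistoneProtein],
        config: PipelineConfig | None = None,
        structure_path: str | Path | None = None,
    ) -> None:
        if not training:
            raise ValueError("training set is empty")
        self.training = training
        self.config = config or PipelineConfig()
        self.structure_path = structure_path

    @classmethod
    def from_files(
        cls,
        fasta_path: str | Path,
        annotation_path: str | Path,
        config: PipelineConfig | None = None,
        structure_path: str | Path | None = None,
        **read_kwargs,
    ) -> "AcetylationModel":
        read_kwargs.setdefault("filter", "strict")
        training = read_histones(fasta_path, annotation_path, **read_kwargs)
        return cls(training, config=config, structure_path=structure_path)

    def fit(self) -> "AcetylationResults":
        components = fit_components(self.training, self.config, self.structure_path)
        return AcetylationResults(self, components)


class AcetylationResults:
    """Fitted predictor: reference sub-classes, decision parameters and
    (optionally) the nucleosome region catalog."""

    def __init__(self, model: AcetylationModel, components: FittedComponents):
        self.model = model
        self.components = components

    # -- fitted quantities -------------------------------------------------
    @property
    def tree(self):
        return self.components.tree

    @property
    def reference(self):
        return self.components.reference

    @property
    def cut_height(self) -> float:
        return self.components.reference_cut_height

    @property
    def gain_ratio_(self) -> float:
        return self.components.reference_gain_ratio

    @property
    def n_subclasses(self) -> int:
        return cut_tree(self.tree, self.cut_height).n_clusters

    @property
    def classifier_params(self):
        return self.components.classifier_params

    @property
    def catalog(self):
        return self.components.catalog

    # -- use ---------------------------------------------------------------
    def predict(
        self, queries: list[HistoneProtein], as_frame: bool = True
    ):
        """Hierarchical predictions for query histones (one row per lysine
        when ``expand_merged`` is on)."""
        records = run_pipeline(
            self.model.training,
            queries,
            self.model.config,
            structure_path=self.model.structure_path,
            components=self.components,
        )
        return records_to_frame(records) if as_frame else records

    def evaluate(self, queries, truth, mode: str = "semi_supervised"):
        records = self.predict(queries, as_frame=False)
        return evaluate_pipeline(records, truth, mode=mode)

    def subclass_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subclass": sc.id,
                "label": sc.label,
                "size": len(sc.windows),
                "windows": ";".join(sc.windows),
            }
            for sc in self.reference.subclasses
        )

    def summary(self) -> str:
        comp = self.components
        labels = {p.peptide_id: p.label for p in comp.training_peptides}
        part = cut_tree(self.tree, self.cut_height)
        gr = gain_ratio(part, labels)
        n_p = sum(1 for sc in self.reference.subclasses if sc.label == "P")
        n_n = self.reference.n_features - n_p
        cp = self.classifier_params
        lines = [
            "Histone acetylation max-min classifier",
            "=" * 54,
            f"{'training peptides (after merging)':<38}{len(comp.training_peptides):>16}",
            f"{'distance mode':<38}{self.model.config.mode:>16}",
            f"{'selected cut height':<38}{self.cut_height:>16.4f}",
            f"{'sub-classes at cut':<38}{part.n_clusters:>16}",
            f"{'gain ratio at cut':<38}{gr:>16.4f}",
            f"{'reference sub-classes (P / N)':<38}{f'{n_p} / {n_n}':>16}",
            f"{'alpha / beta':<38}{f'{cp.alpha:g} / {cp.beta:g}':>16}",
            f"{'intercept I':<38}{cp.intercept:>16.4f}",
            f"{'high cutoff (level 1)':<38}{self.model.config.high_cutoff:>16.4f}",
            f"{'structure catalog':<38}"
            f"{('fitted (%d regions)' % len(self.catalog.regions)) if self.catalog else 'absent':>16}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def plot_dendrogram(self, ax=None, **kwargs):
        """Training-peptide dendrogram with the selected cut marked."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        dendrogram(
            self.tree.to_linkage_matrix(),
            labels=self.tree.leaves,
            ax=ax,
            **kwargs,
        )
        ax.axhline(self.cut_height, color="red", linestyle="--", linewidth=1)
        ax.set_ylabel("complete-linkage distance")
        return ax
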