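"""Three-level hierarchical acetylability prediction.

Level 1 (high cutoff): queries co-clustering with a unanimously labeled
training sub-class below the high cutoff height inherit that label; these
decisions are final.

Level 2 (max-min classifier): remaining queries are scored by the signed
max-min distance to the reference sub-classes.

Level 3 (spatial adjustment): level-2 *positives* whose lysines map onto
the nucleosome structure are re-decided from the epsilon-N distance to
the acetylability-associated regions; the spatial verdict replaces the
level-2 label.  Level-2 negatives and unmapped sites keep their level-2
label (a config switch can extend the adjustment to negatives).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import classifier as clf
from .classifier import ClassifierParams, EvaluationReport
from .cluster import complete_linkage, select_cut
from .geometry import (
    DEFAULT_CATALOG_SPEC,
    RegionCatalog,
    build_region_catalog,
    map_sites_to_structure,
    spatial_decision,
)
from .io import HistoneProtein, LysinePeptide, extract_peptides, merge_adjacent
from .metric import AlignmentParams, distance_matrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the hierarchical predictor (serializable)."""

    flank: int = 12
    max_gap: int = 3
    mode: str = "raw"
    transform: str = "min_self"
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    high_cutoff: float = 0.364
    reference_cut: float | str = "auto"  # height, or "auto" = gain-ratio cut
    min_subclass_size: int = 2
    alpha: float = 1.0
    beta: float = 1.0
    intercept: float | str = "fit"  # value, or "fit" = training grid fit
    coerce_u_to_n: bool = True
    expand_merged: bool = True
    level3_rescues_negatives: bool = False
    spatial_intercept: float = 0.0  # angstrom scale, separate from peptide I
    n_surface_samples: int = 4096
    structure_min_match: int = 8
    seed: int = 0
    catalog_spec: list = field(default_factory=lambda: DEFAULT_CATALOG_SPEC)

    def __post_init__(self) -> None:
        if self.high_cutoff < 0:
            raise ValueError("high_cutoff must be >= 0")

    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(
            substitution_matrix=self.substitution_matrix,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["catalog_spec"] = [
            {**g, "sites": [list(s) for s in g["sites"]]} for g in d["catalog_spec"]
        ]
        return d


@dataclass
class PredictionRecord:
    """Per-lysine (or merged-run) prediction with provenance."""

    histone_id: str
    lysine_positions: list[int]
    predicted_label: str
    decision_level: int
    peptide_score: float | None = None
    spatial_score: float | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.decision_level not in (1, 2, 3):
            raise ValueError("decision_level must be 1, 2 or 3")
        if self.decision_level == 1 and self.peptide_score is not None:
            raise ValueError("level-1 records are membership-based: no score")
        if self.decision_level == 3 and (
            self.peptide_score is None or self.spatial_score is None
        ):
            raise ValueError("level-3 records carry both scores")


def _coerce(label: str, coerce: bool) -> str:
    return "N" if (coerce and label == "U") else label


def _training_peptides(
    training: list[HistoneProtein], config: PipelineConfig
) -> list[LysinePeptide]:
    peptides = []
    for prot in training:
        labels = {
            pos: _coerce(prot.label_at(pos), config.coerce_u_to_n)
            for pos in prot.lysine_positions
        }
        relabeled = HistoneProtein(
            id=prot.id, species=prot.species, family=prot.family,
            variant=prot.variant, sequence=prot.sequence,
            labels={p: l for p, l in labels.items() if l != "U"},
        )
        peptides += merge_adjacent(
            relabeled,
            extract_peptides(relabeled, config.flank),
            max_gap=config.max_gap,
            flank=config.flank,
        )
    return peptides


def _query_peptides(
    queries: list[HistoneProtein], config: PipelineConfig
) -> list[LysinePeptide]:
    peptides = []
    for prot in queries:
        peptides += merge_adjacent(
            prot, extract_peptides(prot, config.flank),
            max_gap=config.max_gap, flank=config.flank,
        )
    return peptides


@dataclass
class FittedComponents:
    """Everything learned from training data (reused across predictions)."""

    training_peptides: list
    tree: object
    reference: object
    reference_cut_height: float
    reference_gain_ratio: float
    classifier_params: ClassifierParams
    catalog: RegionCatalog | None = None
    site_mapping: dict | None = None


def fit_components(
    training: list[HistoneProtein],
    config: PipelineConfig,
    structure_path: str | Path | None = None,
) -> FittedComponents:
    """Cluster the training peptides, build the reference sub-classes,
    fit the intercept, and (given a structure) fit the region catalog."""
    train_peps = _training_peptides(training, config)
    labels = {p.peptide_id: p.label for p in train_peps}
    if "P" not in labels.values() or "N" not in labels.values():
        raise ValueError("training must contain both P and N labels")
    params = config.alignment_params()
    dm = distance_matrix(
        train_peps, mode=config.mode, params=params, transform=config.transform
    )
    tree = complete_linkage(dm)
    if config.reference_cut == "auto":
        cut = select_cut(tree, labels)
        cut_height, gain = cut.height, cut.gain_ratio
    else:
        cut_height, gain = float(config.reference_cut), float("nan")
    windows = {p.peptide_id: p.window for p in train_peps}
    reference = clf.build_reference(
        tree, labels, windows, cut_height, min_size=config.min_subclass_size
    )
    if config.intercept == "fit":
        intercept = clf.fit_intercept(
            train_peps, reference,
            ClassifierParams(config.alpha, config.beta, 0.0),
            params, config.mode, config.transform,
        )
    else:
        intercept = float(config.intercept)
    cparams = ClassifierParams(config.alpha, config.beta, intercept)
    catalog = mapping = None
    if structure_path is not None:
        mapping = map_sites_to_structure(
            training, structure_path, min_match=config.structure_min_match
        )
        catalog = build_region_catalog(training, mapping, config.catalog_spec)
    return FittedComponents(
        training_peptides=train_peps,
        tree=tree,
        reference=reference,
        reference_cut_height=cut_height,
        reference_gain_ratio=gain,
        classifier_params=cparams,
        catalog=catalog,
        site_mapping=mapping,
    )


def run_pipeline(
    training: list[HistoneProtein],
    queries: list[HistoneProtein],
    config: PipelineConfig | None = None,
    structure_path: str | Path | None = None,
    components: FittedComponents | None = None,
) -> list[PredictionRecord]:
    """Predict acetylability for every query lysine through the hierarchy."""
    if not queries:
        raise ValueError("queries must be non-empty")
    config = config or PipelineConfig()
    if components is None:
        components = fit_components(training, config, structure_path)
    params = config.alignment_params()
    query_peps = _query_peptides(queries, config)
    query_by_id = {p.peptide_id: p for p in query_peps}

    level1 = clf.predict_high_cutoff(
        query_peps, components.training_peptides, h=config.high_cutoff,
        params=params, mode=config.mode, transform=config.transform,
    )

    # query-side structure mapping for level 3
    query_mapping = {}
    if structure_path is not None:
        query_mapping = map_sites_to_structure(
            queries, structure_path, min_match=config.structure_min_match
        )

    records = []
    for qid, pep in query_by_id.items():
        label1, note1 = level1[qid]
        if label1 is not None:
            records.append(
                PredictionRecord(
                    histone_id=pep.source,
                    lysine_positions=list(pep.lysine_positions),
                    predicted_label=label1,
                    decision_level=1,
                    notes=[note1],
                )
            )
            continue
        score2, label2 = clf.decision_score(
            pep.window, components.reference, components.classifier_params,
            params, config.mode, config.transform,
        )
        notes = [note1, "max-min-score"]
        adjust = label2 == "P" or (
            config.level3_rescues_negatives and label2 == "N"
        )
        atoms = [
            a
            for pos in pep.lysine_positions
            for a in query_mapping.get((pep.source, pos), [])
        ]
        if components.catalog is not None and adjust and atoms:
            spatial_params = ClassifierParams(
                config.alpha, config.beta, config.spatial_intercept
            )
            score3, label3 = spatial_decision(
                atoms, components.catalog, spatial_params,
                n_surface_samples=config.n_surface_samples, seed=config.seed,
            )
            records.append(
                PredictionRecord(
                    histone_id=pep.source,
                    lysine_positions=list(pep.lysine_positions),
                    predicted_label=label3,
                    decision_level=3,
                    peptide_score=score2,
                    spatial_score=score3,
                    notes=notes + ["spatial-adjustment"],
                )
            )
            continue
        if components.catalog is not None and adjust and not atoms:
            notes = notes + ["no-structure"]
        elif components.catalog is None:
            notes = notes + ["no-structure"]
        records.append(
            PredictionRecord(
                histone_id=pep.source,
                lysine_positions=list(pep.lysine_positions),
                predicted_label=label2,
                decision_level=2,
                peptide_score=score2,
                notes=notes,
            )
        )
    if config.expand_merged:
        records = _expand(records)
    return records


def _expand(records: list[PredictionRecord]) -> list[PredictionRecord]:
    out = []
    for rec in records:
        if len(rec.lysine_positions) == 1:
            out.append(rec)
            continue
        for pos in rec.lysine_positions:
            out.append(
                PredictionRecord(
                    histone_id=rec.histone_id,
                    lysine_positions=[pos],
                    predicted_label=rec.predicted_label,
                    decision_level=rec.decision_level,
                    peptide_score=rec.peptide_score,
                    spatial_score=rec.spatial_score,
                    notes=rec.notes + ["expanded-from-merged"],
                )
            )
    return out


def records_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": r.histone_id,
            "positions": ",".join(map(str, r.lysine_positions)),
            "label": r.predicted_label,
            "level": r.decision_level,
            "peptide_score": r.peptide_score,
            "spatial_score": r.spatial_score,
            "notes": ";".join(r.notes),
        }
        for r in records
    )


def evaluate_pipeline(
    records: list[PredictionRecord],
    truth: dict[tuple[str, int], str],
    mode: str = "semi_supervised",
) -> dict:
    """Overall evaluation plus a per-decision-level confusion breakdown.

    ``truth`` maps (histone id, position) to P/N/U; records covering
    merged runs are expanded per position.
    """
    per_site: dict[str, tuple[str, int]] = {}
    for rec in records:
        for pos in rec.lysine_positions:
            key = f"{rec.histone_id}:{pos}"
            per_site[key] = (rec.predicted_label, rec.decision_level)
    truth_by_key = {f"{i}:{p}": lab for (i, p), lab in truth.items()}
    common = set(per_site) & set(truth_by_key)
    missing = set(truth_by_key) - set(per_site)
    if missing:
        logger.warning("%d truth sites without predictions", len(missing))
    overall = clf.evaluate(
        {k: per_site[k][0] for k in common},
        {k: truth_by_key[k] for k in common},
        mode=mode,
    )
    by_level: dict[int, EvaluationReport] = {}
    for level in (1, 2, 3):
        keys = [k for k in common if per_site[k][1] == level]
        if keys:
            by_level[level] = clf.evaluate(
                {k: per_site[k][0] for k in keys},
                {k: truth_by_key[k] for k in keys},
                mode=mode,
            )
    return {"overall": overall, "by_level": by_level}


def write_run_manifest(
    path: str | Path,
    config: PipelineConfig,
    input_paths: list[str | Path],
) -> None:
    """JSON manifest: config, input digests and package version."""
    from . import __version__

    digests = {}
    for p in input_paths:
        p = Path(p)
        if p.exists():
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    Path(path).write_text(
        json.dumps(
            {"config": config.to_dict(), "inputs": digests, "version": __version__},
            indent=2,
        )
    )
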