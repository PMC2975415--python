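"""Max-min distance classifier built from label-pure sub-classes.

Label-pure sub-classes of size >= 2 at the selected dendrogram cut become
reference sets.  A query peptide's feature vector is its complete-linkage
distance (max over members) to each reference sub-class, and the decision
function is

    score = alpha * min_j D(x, s'_j)  -  beta * min_i D(x, s'_i)  -  I

with j ranging over un-acetylable and i over acetylable sub-classes: a
peptide far from every negative sub-class but near a positive one scores
positive and is predicted acetylable (ties go conservatively to N).

Because un-observed sites are only *semi-reliable* negatives, evaluation
in semi-supervised mode treats the false-negative rate and sensitivity as
the reliable metrics and flags the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterTree, complete_linkage, cut_tree
from .io import LysinePeptide
from .metric import AlignmentParams, distance_matrix, peptide_distance

logger = logging.getLogger(__name__)


@dataclass
class SubClass:
    id: str
    windows: list[str]
    label: str  # P (acetylable) or N (un-acetylable)


@dataclass
class ReferenceSubclasses:
    """Label-pure sub-classes used as classifier features."""

    subclasses: list[SubClass]
    source_cut_height: float

    def __post_init__(self) -> None:
        for sc in self.subclasses:
            if len(sc.windows) < 1:
                raise ValueError(f"subclass {sc.id} empty")
            if sc.label not in ("P", "N"):
                raise ValueError(f"subclass {sc.id} has label {sc.label!r}")

    @property
    def n_features(self) -> int:
        return len(self.subclasses)

    def by_label(self, label: str) -> list[int]:
        return [i for i, sc in enumerate(self.subclasses) if sc.label == label]


@dataclass(frozen=True)
class ClassifierParams:
    """Decision-function weights: alpha (negative side), beta (positive
    side) and the intercept I."""

    alpha: float = 1.0
    beta: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("weights must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")


def build_reference(
    tree: ClusterTree,
    labels: dict[str, str],
    windows: dict[str, str],
    cut_height: float,
    min_size: int = 2,
) -> ReferenceSubclasses:
    """Keep label-pure clusters of size >= min_size at the cut as features."""
    partition = cut_tree(tree, cut_height)
    subclasses = []
    for idx, cluster in enumerate(partition.clusters):
        if len(cluster) < min_size:
            continue
        labs = {labels[l] for l in cluster}
        if len(labs) != 1 or labs & {"U"}:
            continue
        subclasses.append(
            SubClass(
                id=f"S{idx}",
                windows=[windows[l] for l in sorted(cluster)],
                label=labs.pop(),
            )
        )
    if not subclasses:
        raise ValueError(
            "no label-pure subclasses of sufficient size at this cut: untrainable"
        )
    return ReferenceSubclasses(subclasses=subclasses, source_cut_height=cut_height)


def feature_vector(
    query_window: str,
    refs: ReferenceSubclasses,
    params: AlignmentParams = AlignmentParams(),
    mode: str = "raw",
    transform: str = "min_self",
) -> np.ndarray:
    """Complete-linkage distance of a peptide to each reference sub-class."""
    if refs.n_features == 0:
        raise ValueError("empty reference")
    return np.array(
        [
            max(
                peptide_distance(query_window, m, mode, params, transform)
                for m in sc.windows
            )
            for sc in refs.subclasses
        ]
    )


def decision_score(
    query_window: str,
    refs: ReferenceSubclasses,
    cparams: ClassifierParams = ClassifierParams(),
    params: AlignmentParams = AlignmentParams(),
    mode: str = "raw",
    transform: str = "min_self",
) -> tuple[float, str]:
    """Signed max-min score and predicted label (score > 0 -> P)."""
    pos = refs.by_label("P")
    neg = refs.by_label("N")
    if not pos or not neg:
        raise ValueError("reference must contain both P and N subclasses")
    fv = feature_vector(query_window, refs, params, mode, transform)
    score = (
        cparams.alpha * fv[neg].min()
        - cparams.beta * fv[pos].min()
        - cparams.intercept
    )
    return float(score), ("P" if score > 0 else "N")


def fit_intercept(
    training: list[LysinePeptide],
    refs: ReferenceSubclasses,
    cparams: ClassifierParams = ClassifierParams(),
    params: AlignmentParams = AlignmentParams(),
    mode: str = "raw",
    transform: str = "min_self",
    step: float = 0.01,
) -> float:
    """Grid-fit the intercept on training peptides.

    Scans the observed score range in ``step`` increments and returns the
    intercept minimizing the training false-negative rate, breaking ties
    toward maximal specificity (largest intercept with the same FNR).
    """
    scores, truths = [], []
    for pep in training:
        if pep.label not in ("P", "N"):
            continue
        s, _ = decision_score(
            pep.window,
            refs,
            ClassifierParams(cparams.alpha, cparams.beta, 0.0),
            params,
            mode,
            transform,
        )
        scores.append(s)
        truths.append(pep.label)
    if not scores:
        raise ValueError("no labeled training peptides to fit intercept")
    scores_arr = np.array(scores)
    truths_arr = np.array(truths)
    grid = np.arange(scores_arr.min() - step, scores_arr.max() + step, step)
    best = None
    for intercept in grid:
        pred_p = scores_arr - intercept > 0
        fn = int(np.sum((truths_arr == "P") & ~pred_p))
        tn = int(np.sum((truths_arr == "N") & ~pred_p))
        key = (fn, -tn, -intercept)
        if best is None or key < best[0]:
            best = (key, float(intercept))
    return best[1]


def predict_high_cutoff(
    queries: list[LysinePeptide],
    training: list[LysinePeptide],
    h: float = 0.364,
    params: AlignmentParams = AlignmentParams(),
    mode: str = "raw",
    transform: str = "min_self",
) -> dict[str, tuple[str | None, str]]:
    """First-level prediction by co-clustering with training sub-classes.

    A combined tree over training + queries is cut at ``h``; a query is
    predicted only when its cluster contains training peptides that
    unanimously share a label.  Returns per-query (label or None, note).
    Training-side membership preservation is verified against the
    training-only tree; violations are noted, not fatal (complete linkage
    guarantees preservation only when sub-classes are separated relative
    to the cut).
    """
    train_ids = {p.peptide_id for p in training}
    combined = list(training) + list(queries)
    dm = distance_matrix(combined, mode=mode, params=params, transform=transform)
    part = cut_tree(complete_linkage(dm), h)

    preserved = True
    if len(training) >= 2:
        dm_t = distance_matrix(training, mode=mode, params=params, transform=transform)
        part_t = cut_tree(complete_linkage(dm_t), h)
        old = part_t.cluster_of()
        new = part.cluster_of()
        ids = [p.peptide_id for p in training]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if (old[a] == old[b]) != (new[a] == new[b]):
                    preserved = False
                    break
            if not preserved:
                break
    if not preserved:
        logger.warning("insertion changed training-side subclass memberships at h=%g", h)

    train_label = {p.peptide_id: p.label for p in training}
    out: dict[str, tuple[str | None, str]] = {}
    note_suffix = "" if preserved else ";training-membership-changed"
    for cluster in part.clusters:
        t_labels = {train_label[l] for l in cluster if l in train_ids}
        for leaf in cluster:
            if leaf in train_ids:
                continue
            if not t_labels:
                out[leaf] = (None, "no-training-neighbour" + note_suffix)
            elif len(t_labels) == 1:
                out[leaf] = (next(iter(t_labels)), "tree-child" + note_suffix)
            else:
                out[leaf] = (None, "mixed-training-labels" + note_suffix)
    return out


@dataclass
class EvaluationReport:
    """Confusion counts and derived rates.

    In ``semi_supervised`` mode only the false-negative-derived
    quantities (sensitivity, FNR) are reliable, because N labels mean
    "not observed acetylable", not "un-acetylable".
    """

    tp: int
    fp: int
    tn: int
    fn: int
    mode: str = "full"
    notes: list[str] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def false_negative_rate(self) -> float:
        return self.fn / (self.fn + self.tp) if self.fn + self.tp else float("nan")

    @property
    def false_positive_rate(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "mode": self.mode,
            "sensitivity": self.sensitivity,
            "false_negative_rate": self.false_negative_rate,
            "notes": list(self.notes),
        }
        if self.mode == "full":
            d["specificity"] = self.specificity
            d["false_positive_rate"] = self.false_positive_rate
        else:
            d["notes"] = d["notes"] + [
                "semi-supervised: specificity/FPR unreliable (N = not observed)"
            ]
        return d


def evaluate(
    predictions: dict[str, str],
    truth_labels: dict[str, str],
    mode: str = "full",
) -> EvaluationReport:
    """Confusion-matrix evaluation of per-site predictions against truth.

    Sites with truth label U are non-evaluable and skipped.  Prediction
    and truth key sets must agree.
    """
    if mode not in ("full", "semi_supervised"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = set(truth_labels) ^ set(predictions)
    if missing:
        raise ValueError(f"prediction/truth id mismatch: {sorted(missing)[:5]}")
    tp = fp = tn = fn = 0
    skipped = 0
    for key, truth in truth_labels.items():
        if truth == "U":
            skipped += 1
            continue
        pred = predictions[key]
        if truth == "P":
            tp, fn = (tp + 1, fn) if pred == "P" else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pred == "P" else (fp, tn + 1)
    notes = []
    if skipped:
        notes.append(f"{skipped} U-labeled sites not evaluable")
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn, mode=mode, notes=notes)


ASA_FEATURES = ("percent", "residue", "sidechain", "atom")


def asa_association(
    asa_table: pd.DataFrame,
    labels: dict[tuple[str, int], str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum association of accessible-surface-area features with labels.

    ``asa_table`` must carry columns ``id``, ``position`` and the four ASA
    features (percent, residue, sidechain, atom).  Each feature is tested
    P vs N by a two-sided Wilcoxon rank-sum (Mann-Whitney) test; features
    with < 2 observations in either group are skipped with a warning.
    """
    required = {"id", "position", *ASA_FEATURES}
    if not required <= set(asa_table.columns):
        raise ValueError(f"ASA table must have columns {sorted(required)}")
    lab = asa_table.apply(
        lambda r: labels.get((r["id"], int(r["position"])), "U"), axis=1
    )
    rows = []
    for feat in ASA_FEATURES:
        x = asa_table.loc[lab == "P", feat].dropna().to_numpy(float)
        y = asa_table.loc[lab == "N", feat].dropna().to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            logger.warning("ASA feature %s skipped: <2 observations in a group", feat)
            continue
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append(
            {"feature": feat, "statistic": float(stat), "p_value": float(p),
             "significant": bool(p < alpha), "n_P": len(x), "n_N": len(y)}
        )
    return pd.DataFrame(rows)
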