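"""Pairwise peptide distances from Smith-Waterman local alignment.

The working hypothesis of flanking-peptide acetylation prediction is that
acetyltransferase recognition is carried by the short peptide around the
lysine, so peptide similarity is measured by the optimal local alignment
score under BLOSUM62.  Scores are mapped onto distances in [0, 1]:

raw (``min_self`` transform)
    ``d(a, b) = 1 - S(a, b) / min(S(a, a), S(b, b))``

length-normalized
    cross- and self-scores are first divided by peptide length, then the
    same transform is applied, with the cross-score divided by the shorter
    peptide's length.

An alternative ``geometric_mean_self`` transform
(``1 - S(a, b) / sqrt(S(a, a) S(b, b))``) is selectable, since the exact
score-to-distance mapping behind published dendrogram cut heights is a
modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import LysinePeptide

TRANSFORMS = ("min_self", "geometric_mean_self")
MODES = ("raw", "length_normalized")


@dataclass(frozen=True)
class AlignmentParams:
    """Smith-Waterman scoring parameters.

    ``gap_open``/``gap_extend`` are penalties (non-negative); the default
    10 / 0.5 pair is the common protein local-alignment default.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


_ALIGNERS: dict[AlignmentParams, Align.PairwiseAligner] = {}
_SCORE_CACHE: dict[tuple, float] = {}


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = _ALIGNERS.get(params)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(
            params.substitution_matrix
        )
        aligner.open_gap_score = -params.gap_open
        aligner.extend_gap_score = -params.gap_extend
        _ALIGNERS[params] = aligner
    return aligner


def clear_score_cache() -> None:
    _SCORE_CACHE.clear()


def sw_score(a: str, b: str, params: AlignmentParams = AlignmentParams()) -> float:
    """Optimal Smith-Waterman local-alignment score (0 if nothing positive)."""
    if not a or not b:
        raise ValueError("empty peptide")
    key = (a, b, params) if a <= b else (b, a, params)
    score = _SCORE_CACHE.get(key)
    if score is None:
        aligner = _aligner(params)
        alphabet = set(str(aligner.substitution_matrix.alphabet))
        unknown = (set(a) | set(b)) - alphabet
        if unknown:
            raise ValueError(f"residues {sorted(unknown)} not in substitution matrix")
        score = float(aligner.score(key[0], key[1]))
        _SCORE_CACHE[key] = score
    return score


def _self_scores(a: str, b: str, params: AlignmentParams) -> tuple[float, float]:
    saa, sbb = sw_score(a, a, params), sw_score(b, b, params)
    if saa <= 0 or sbb <= 0:
        raise ValueError("peptide with non-positive self-alignment score")
    return saa, sbb


def raw_distance(
    a: str,
    b: str,
    params: AlignmentParams = AlignmentParams(),
    transform: str = "min_self",
) -> float:
    """Raw peptide distance: 1 minus the self-score-normalized SW score."""
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    saa, sbb = _self_scores(a, b, params)
    sab = sw_score(a, b, params)
    denom = min(saa, sbb) if transform == "min_self" else float(np.sqrt(saa * sbb))
    return float(np.clip(1.0 - sab / denom, 0.0, 1.0))


def normalized_distance(
    a: str,
    b: str,
    params: AlignmentParams = AlignmentParams(),
    transform: str = "min_self",
    length_factor: float | None = None,
) -> float:
    """Length-normalized distance: per-length scores through the same transform.

    ``length_factor`` overrides the cross-score divisor min(len(a), len(b));
    permutation tests use this to shuffle normalization factors across pairs.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    saa, sbb = _self_scores(a, b, params)
    sab = sw_score(a, b, params)
    lmin = float(length_factor if length_factor is not None else min(len(a), len(b)))
    ra, rb = saa / len(a), sbb / len(b)
    denom = min(ra, rb) if transform == "min_self" else float(np.sqrt(ra * rb))
    return float(np.clip(1.0 - (sab / lmin) / denom, 0.0, 1.0))


def peptide_distance(
    a: str,
    b: str,
    mode: str = "raw",
    params: AlignmentParams = AlignmentParams(),
    transform: str = "min_self",
) -> float:
    if mode == "raw":
        return raw_distance(a, b, params, transform)
    if mode == "length_normalized":
        return normalized_distance(a, b, params, transform)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class DistanceMatrix:
    """Symmetric peptide distance matrix with a zero diagonal."""

    peptide_ids: list[str]
    values: np.ndarray
    mode: str = "raw"
    windows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.peptide_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(~np.isfinite(v)) or np.any(v < -1e-12):
            raise ValueError("matrix entries must be finite and non-negative")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("diagonal must be zero")
        self.values = v

    def __len__(self) -> int:
        return len(self.peptide_ids)

    def get(self, id_a: str, id_b: str) -> float:
        i = self.peptide_ids.index(id_a)
        j = self.peptide_ids.index(id_b)
        return float(self.values[i, j])

    def to_long(self):
        import pandas as pd

        rows = [
            (a, b, round(float(self.values[i, j]), 6))
            for i, a in enumerate(self.peptide_ids)
            for j, b in enumerate(self.peptide_ids)
            if i < j
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "distance"])


def distance_matrix(
    peptides: list[LysinePeptide],
    mode: str = "raw",
    params: AlignmentParams = AlignmentParams(),
    transform: str = "min_self",
) -> DistanceMatrix:
    """All-pairs distance matrix over a peptide set."""
    if len(peptides) < 2:
        raise ValueError("need >= 2 peptides")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    ids = [p.peptide_id for p in peptides]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate peptide ids")
    windows = {p.peptide_id: p.window for p in peptides}
    n = len(peptides)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = peptide_distance(
                peptides[i].window, peptides[j].window, mode, params, transform
            )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(peptide_ids=ids, values=values, mode=mode, windows=windows)
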