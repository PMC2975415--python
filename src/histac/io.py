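"""Histone sequence / annotation input-output and peptide generation.

Histones are read from a FASTA file whose headers carry ``key=value``
metadata (``species``, ``family``, ``variant``) plus a tab-separated
annotation table (``id<TAB>position<TAB>label``) assigning each lysine an
acetylation status:

* ``P`` -- experimentally observed acetylable,
* ``N`` -- not observed acetylable (a *semi-reliable* negative),
* ``U`` -- unknown / unannotated.

Positions use mature-protein numbering (initiator methionine removed),
the convention behind site names such as H3K56 or H4K91.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from scipy import stats

VALID_LABELS = frozenset({"P", "N", "U"})
STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}


@dataclass
class HistoneProtein:
    """One histone sequence with per-lysine acetylation labels."""

    id: str
    species: str
    family: str
    variant: str
    sequence: str
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: non-standard residues {sorted(bad)}")
        for pos, lab in self.labels.items():
            if lab not in VALID_LABELS:
                raise ValueError(f"{self.id}: invalid label {lab!r} at {pos}")
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"{self.id}: position {pos} outside sequence")
            if self.sequence[pos - 1] != "K":
                raise ValueError(
                    f"{self.id}: annotated position {pos} is "
                    f"{self.sequence[pos - 1]!r}, not K"
                )

    @property
    def lysine_positions(self) -> list[int]:
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "K"]

    def label_at(self, position: int) -> str:
        return self.labels.get(position, "U")


@dataclass
class LysinePeptide:
    """A flanking-window peptide centred on one lysine or a merged run.

    ``window_span`` is a half-open ``(start, end)`` interval in 0-based
    coordinates on the source sequence, so ``sequence[start:end] == window``.
    """

    source: str
    lysine_positions: list[int]
    window: str
    label: str
    window_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.lysine_positions:
            raise ValueError("peptide needs >=1 lysine position")
        if self.label not in VALID_LABELS:
            raise ValueError(f"invalid label {self.label!r}")
        start, end = self.window_span
        if end - start != len(self.window):
            raise ValueError("window_span inconsistent with window length")

    @property
    def peptide_id(self) -> str:
        return f"{self.source}:{'+'.join(map(str, self.lysine_positions))}"


def _parse_fasta_header(description: str) -> dict[str, str]:
    meta = {}
    for token in description.split()[1:]:
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = v
    return meta


def read_histones(
    fasta_path: str | Path,
    annotation_path: str | Path,
    *,
    filter: str = "strict",
    mature_numbering: bool = True,
    coerce_u_to_n: bool = False,
) -> list[HistoneProtein]:
    """Read histones and their acetylation annotations.

    Parameters
    ----------
    filter
        ``"strict"`` keeps only proteins with at least one P site (only
        proteins with identified acetylation enter training); ``"annotated"``
        keeps proteins with any annotation row; ``"none"`` keeps everything.
    mature_numbering
        Strip a leading initiator methionine so positions follow mature
        histone numbering (H3K4 = residue 4 of the mature chain).
    coerce_u_to_n
        Re-label every unannotated lysine as ``N`` (the semi-supervised
        convention where unobserved sites count as negatives).
    """
    if filter not in {"strict", "annotated", "none"}:
        raise ValueError(f"unknown filter {filter!r}")
    annotations: dict[str, dict[int, str]] = {}
    with open(annotation_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "position", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"annotation table must have columns {sorted(required)}")
        for row in reader:
            pid, pos, lab = row["id"], int(row["position"]), row["label"].strip()
            table = annotations.setdefault(pid, {})
            if pos in table:
                raise ValueError(f"duplicate annotation for ({pid}, {pos})")
            table[pos] = lab

    proteins = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        if mature_numbering and seq.startswith("M"):
            seq = seq[1:]
        meta = _parse_fasta_header(record.description)
        labels = dict(annotations.get(record.id, {}))
        protein = HistoneProtein(
            id=record.id,
            species=meta.get("species", "unknown"),
            family=meta.get("family", "unknown"),
            variant=meta.get("variant", record.id),
            sequence=seq,
            labels=labels,
        )
        if coerce_u_to_n:
            for pos in protein.lysine_positions:
                protein.labels.setdefault(pos, "N")
        if filter == "strict" and not any(v == "P" for v in labels.values()):
            continue
        if filter == "annotated" and not labels:
            continue
        proteins.append(protein)
    return proteins


def extract_peptides(protein: HistoneProtein, flank: int = 12) -> list[LysinePeptide]:
    """One flanking-window peptide per lysine, truncated at the termini.

    The window covers up to ``flank`` residues either side of the lysine
    (the KAT substrate footprint motivates the default of 12).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    peptides = []
    n = len(protein.sequence)
    for pos in protein.lysine_positions:
        start = max(0, pos - 1 - flank)
        end = min(n, pos + flank)
        peptides.append(
            LysinePeptide(
                source=protein.id,
                lysine_positions=[pos],
                window=protein.sequence[start:end],
                label=protein.label_at(pos),
                window_span=(start, end),
            )
        )
    return peptides


def merge_adjacent(
    protein: HistoneProtein,
    peptides: list[LysinePeptide],
    max_gap: int = 3,
    flank: int = 12,
) -> list[LysinePeptide]:
    """Merge runs of adjacent same-label lysines into single peptides.

    Neighbouring lysines almost always share acetylation status, so runs
    whose successive positions differ by at most ``max_gap`` *and* whose
    labels agree collapse to one peptide spanning ``flank`` residues left
    of the first lysine through ``flank`` right of the last.  Runs with
    discordant labels are left unmerged.  Idempotent on its own output.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    peptides = sorted(peptides, key=lambda p: p.lysine_positions[0])
    n = len(protein.sequence)
    out: list[LysinePeptide] = []
    run: list[LysinePeptide] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            positions = [p for pep in run for p in pep.lysine_positions]
            start = max(0, positions[0] - 1 - flank)
            end = min(n, positions[-1] + flank)
            out.append(
                LysinePeptide(
                    source=protein.id,
                    lysine_positions=positions,
                    window=protein.sequence[start:end],
                    label=run[0].label,
                    window_span=(start, end),
                )
            )
        run.clear()

    for pep in peptides:
        if pep.source != protein.id:
            raise ValueError("peptides must all come from the given protein")
        if run:
            gap = pep.lysine_positions[0] - run[-1].lysine_positions[-1]
            if gap <= max_gap and pep.label == run[-1].label:
                run.append(pep)
                continue
            flush()
        run.append(pep)
    flush()
    return out


def count_adjacent_pairs(protein: HistoneProtein, max_gap: int = 3) -> int:
    """Number of successive lysine pairs at most ``max_gap`` apart."""
    pos = protein.lysine_positions
    return sum(1 for a, b in zip(pos, pos[1:]) if b - a <= max_gap)


_GLOBAL_ALIGNER: Align.PairwiseAligner | None = None


def _global_aligner() -> Align.PairwiseAligner:
    global _GLOBAL_ALIGNER
    if _GLOBAL_ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -0.5
        _GLOBAL_ALIGNER = aligner
    return _GLOBAL_ALIGNER


def pairwise_identity(
    a: HistoneProtein, b: HistoneProtein
) -> tuple[float, list[int]]:
    """Fraction identity between two histones plus differing positions.

    Equal-length pairs are compared positionally; unequal lengths go
    through a global BLOSUM62 alignment.  Differing positions are given in
    the mature numbering of ``a`` (alignment columns where ``a`` is gapped
    count toward the denominator but have no reportable position).
    """
    if not a.sequence or not b.sequence:
        raise ValueError("empty sequence")
    if len(a.sequence) == len(b.sequence):
        diffs = [
            i + 1
            for i, (x, y) in enumerate(zip(a.sequence, b.sequence))
            if x != y
        ]
        return 1.0 - len(diffs) / len(a.sequence), diffs
    alignment = _global_aligner().align(a.sequence, b.sequence)[0]
    sa, sb = alignment[0], alignment[1]
    matches = 0
    diffs = []
    pos_a = 0
    for x, y in zip(sa, sb):
        if x != "-":
            pos_a += 1
        if x == y and x != "-":
            matches += 1
        elif x != "-":
            diffs.append(pos_a)
    return matches / len(sa), diffs


def count_comparison_fisher(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p-value for comparing two count fractions.

    Tests the 2x2 table ``(k1, n1-k1; k2, n2-k2)`` -- e.g. acetylated
    lysine counts out of totals in two species.
    """
    for v in (k1, n1, k2, n2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if k1 > n1 or k2 > n2:
        raise ValueError("k must not exceed n")
    _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
    return float(p)


def write_peptides(peptides: list[LysinePeptide], path: str | Path) -> None:
    """Write a peptide set as TSV: id, positions (comma-joined), window, label."""
    with open(path, "w") as fh:
        fh.write("id\tpositions\twindow\tlabel\n")
        for p in peptides:
            fh.write(
                f"{p.source}\t{','.join(map(str, p.lysine_positions))}\t"
                f"{p.window}\t{p.label}\n"
            )


def read_peptides(path: str | Path) -> list[LysinePeptide]:
    """Read a peptide set written by :func:`write_peptides`.

    Window spans are not recoverable from the TSV; they are set to
    ``(0, len(window))`` placeholders relative to the window itself.
    """
    peptides = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            window = row["window"]
            peptides.append(
                LysinePeptide(
                    source=row["id"],
                    lysine_positions=[int(x) for x in row["positions"].split(",")],
                    window=window,
                    label=row["label"],
                    window_span=(0, len(window)),
                )
            )
    return peptides
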