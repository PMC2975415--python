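"""Synthetic fixtures with the statistical and geometric structure the
method assumes, plus loaders for the bundled histone reconstruction.

Two generators cover the two halves of the method:

* :func:`generate_histone_family` emits families of proteins whose
  lysine flanking windows are mutated copies of class consensus motifs,
  so P/N labels correlate with flanking-motif classes -- the structure
  the peptide clustering exploits.
* :func:`generate_epsilon_cloud` emits 3D epsilon-N point clouds
  concentrated near configurable ellipsoid shells, and can write them as
  a minimal two-chain (symmetric-copy) PDB file -- the structure the
  region fitting exploits.

:func:`make_synthetic_nucleosome` combines both into a full synthetic
nucleosome PDB whose chains carry real histone sequences and whose
catalog-site lysines sit on designed region ellipsoids.  It is a stand-in
geometry: nucleosome-scale, two-fold symmetric, but not a crystal
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import DEFAULT_CATALOG_SPEC
from .io import HistoneProtein, read_histones

BACKGROUND_ALPHABET = "ACDEFGHILMNPQRSTVWY"  # 19 residues, no lysine

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass
class FamilySpec:
    """Recipe for a family of motif-labeled synthetic histones.

    Each lysine's flanking window is a mutated copy of one class motif
    (P motifs for acetylable, N motifs for not); ``mutation_rate`` is the
    per-residue substitution probability (never touching the central K,
    never introducing a K).
    """

    n_proteins: int = 4
    motifs_p: tuple[str, ...] = ("AAGGKSTGG",)
    motifs_n: tuple[str, ...] = ("WWTPKPLLW",)
    mutation_rate: float = 0.05
    n_lysines: int = 10
    protein_length: int = 320
    spacing: int = 28  # keeps default flank-12 windows from bleeding across sites
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.motifs_p, str):
            self.motifs_p = (self.motifs_p,)
        if isinstance(self.motifs_n, str):
            self.motifs_n = (self.motifs_n,)
        for m in (*self.motifs_p, *self.motifs_n):
            if len(m) % 2 == 0 or m[len(m) // 2] != "K":
                raise ValueError(f"motif {m!r} must be odd-length with a central K")
        if not 0 <= self.mutation_rate < 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5)")


def generate_histone_family(
    spec: FamilySpec,
) -> tuple[list[HistoneProtein], dict[tuple[str, int], str]]:
    """Generate labeled proteins plus the ground-truth site table.

    Deterministic per spec (seed included).  Lysine sites are spaced so
    motif windows never overlap; background residues exclude K, so the
    planted lysines are the only lysines.
    """
    rng = np.random.default_rng(spec.seed)
    motif_len = max(len(m) for m in (*spec.motifs_p, *spec.motifs_n))
    spacing = max(spec.spacing, motif_len + 4)
    if spec.n_lysines * spacing + motif_len > spec.protein_length:
        raise ValueError("motifs do not fit: protein too short for n_lysines")
    proteins, truth = [], {}
    bg = np.array(list(BACKGROUND_ALPHABET))
    for p in range(spec.n_proteins):
        pid = f"syn{spec.seed}_{p}"
        seq = rng.choice(bg, size=spec.protein_length).tolist()
        start = motif_len // 2 + 1
        positions = [start + i * spacing for i in range(spec.n_lysines)]
        labels = {}
        for pos in positions:
            label = "P" if rng.random() < 0.5 else "N"
            motifs = spec.motifs_p if label == "P" else spec.motifs_n
            motif = motifs[rng.integers(len(motifs))]
            half = len(motif) // 2
            for k, aa in enumerate(motif):
                idx = pos - 1 - half + k
                if k == half:
                    seq[idx] = "K"
                    continue
                if rng.random() < spec.mutation_rate:
                    seq[idx] = str(rng.choice(bg))
                else:
                    seq[idx] = aa
            labels[pos] = label
            truth[(pid, pos)] = label
        # scrub accidental lysines outside planted sites
        seq = [
            aa if (aa != "K" or (i + 1) in labels) else "R"
            for i, aa in enumerate(seq)
        ]
        proteins.append(
            HistoneProtein(
                id=pid, species="synthetic", family="SYN", variant=pid,
                sequence="".join(seq), labels=labels,
            )
        )
    return proteins, truth


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@dataclass
class CloudGroup:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    n_points: int = 30
    rotation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")


@dataclass
class CloudSpec:
    """Recipe for epsilon-N point clouds on ellipsoid shells.

    ``noise_sd`` is a *radial* displacement in angstroms: each surface
    point is pushed along its radial direction by N(0, noise_sd).
    """

    groups: list[CloudGroup] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def generate_epsilon_cloud(spec: CloudSpec) -> list[np.ndarray]:
    """Per-group points: center + R diag(radii) s + noise, s on the unit sphere."""
    rng = np.random.default_rng(spec.seed)
    clouds = []
    for group in spec.groups:
        s = rng.normal(size=(group.n_points, 3))
        s /= np.linalg.norm(s, axis=1, keepdims=True)
        rot = group.rotation if group.rotation is not None else np.eye(3)
        u = s * np.asarray(group.radii)
        if spec.noise_sd > 0:
            norms = np.linalg.norm(u, axis=1, keepdims=True)
            u = u * (1 + rng.normal(scale=spec.noise_sd, size=(len(u), 1)) / norms)
        clouds.append(np.asarray(group.center) + u @ rot.T)
    return clouds


def write_toy_pdb(
    path: str | Path,
    chains: dict[str, tuple[str, dict[int, np.ndarray]]],
) -> None:
    """Write a minimal PDB: one CA per residue plus NZ atoms for lysines.

    ``chains`` maps chain id to (sequence, {1-based position: NZ coords}).
    CA coordinates are synthetic placeholders (a 3.8-angstrom walk); only
    residue identities and NZ positions carry information.
    """
    lines = []
    serial = 1
    for ci, (chain_id, (seq, nz)) in enumerate(sorted(chains.items())):
        for i, aa in enumerate(seq):
            resname = _AA3.get(aa, "GLY")
            resseq = i + 1
            ca = (3.8 * i, 60.0 * ci, -60.0)
            lines.append(_atom_line(serial, "CA", resname, chain_id, resseq, ca, "C"))
            serial += 1
            if aa == "K" and resseq in nz:
                lines.append(
                    _atom_line(serial, "NZ", resname, chain_id, resseq,
                               tuple(np.asarray(nz[resseq], float)), "N")
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _atom_line(serial, name, resname, chain, resseq, xyz, element) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:^4s} {resname:>3s} {chain:1s}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


DEFAULT_REGION_GEOMETRY = {
    1: {"center": (32.0, 0.0, 18.0), "radii": (12.0, 8.0, 6.0)},
    2: {"center": (-30.0, 12.0, 0.0), "radii": (8.0, 6.0, 5.0)},
    3: {"center": (0.0, -36.0, 0.0), "radii": (14.0, 9.0, 7.0)},
    4: {"center": (15.0, 30.0, -12.0), "radii": (7.0, 5.0, 4.0)},
    5: {"center": (0.0, 0.0, 0.0), "radii": (5.0, 5.0, 5.0)},
}


def make_synthetic_nucleosome(
    histones: list[HistoneProtein],
    path: str | Path,
    seed: int = 0,
    catalog_spec: list[dict] | None = None,
    region_geometry: dict[int, dict] | None = None,
    noise_sd: float = 0.3,
) -> dict[int, dict]:
    """Write a synthetic nucleosome-scale PDB for the given histones.

    A stand-in for a crystal structure: each histone appears as two
    symmetric chains (copy 2 is copy 1 reflected through the z axis).
    Lysines belonging to a catalog group sit on that group's designed
    ellipsoid surface (plus ``noise_sd`` angstroms of jitter); all other
    lysines are scattered on a nucleosome-like shell of ~45 angstrom
    radius.  Returns the ground-truth region geometry used.
    """
    rng = np.random.default_rng(seed)
    spec = catalog_spec if catalog_spec is not None else DEFAULT_CATALOG_SPEC
    geometry = region_geometry if region_geometry is not None else DEFAULT_REGION_GEOMETRY
    site_group: dict[tuple[str, int], int] = {}
    for group in spec:
        for family, pos in group["sites"]:
            site_group[(family, pos)] = group["group_id"]

    def on_ellipsoid(gid: int) -> np.ndarray:
        geo = geometry[gid]
        s = rng.normal(size=3)
        s /= np.linalg.norm(s)
        return np.asarray(geo["center"]) + s * np.asarray(geo["radii"]) + rng.normal(
            scale=noise_sd, size=3
        )

    def generic_position() -> np.ndarray:
        theta = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(-22, 22)
        r = rng.uniform(38, 48)
        return np.array([r * np.cos(theta), r * np.sin(theta), z])

    chain_ids = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    chains: dict[str, tuple[str, dict[int, np.ndarray]]] = {}
    reflect = np.diag([-1.0, -1.0, 1.0])  # two-fold symmetry about z
    for prot in histones:
        nz1, nz2 = {}, {}
        for pos in prot.lysine_positions:
            gid = site_group.get((prot.family, pos))
            if gid:
                # both symmetric copies live on the same region shell (a
                # region contains the symmetric pair, like the central
                # H4K91 pair)
                nz1[pos] = on_ellipsoid(gid)
                nz2[pos] = on_ellipsoid(gid)
            else:
                nz1[pos] = generic_position()
                nz2[pos] = reflect @ nz1[pos] + rng.normal(scale=noise_sd, size=3)
        chains[next(chain_ids)] = (prot.sequence, nz1)
        chains[next(chain_ids)] = (prot.sequence, nz2)
    write_toy_pdb(path, chains)
    return geometry


def generate_asa_table(
    histones: list[HistoneProtein],
    seed: int = 0,
    shift_sd: float = 0.0,
):
    """Synthetic per-lysine accessible-surface-area table.

    With ``shift_sd`` = 0 the four ASA features are label-independent
    (mirroring the reported absence of ASA association); a positive value
    shifts the P group by that many standard deviations for power checks.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for prot in histones:
        for pos in prot.lysine_positions:
            label = prot.label_at(pos)
            bump = shift_sd if label == "P" else 0.0
            rows.append(
                {
                    "id": prot.id,
                    "position": pos,
                    "percent": rng.normal(55 + 15 * bump, 15),
                    "residue": rng.normal(110 + 30 * bump, 30),
                    "sidechain": rng.normal(90 + 25 * bump, 25),
                    "atom": rng.normal(20 + 8 * bump, 8),
                }
            )
    return pd.DataFrame(rows)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("histac").joinpath("data", name)))


def load_bundled_histones(
    species: str, *, filter: str = "none", coerce_u_to_n: bool = False
) -> list[HistoneProtein]:
    """Load the bundled histone reconstruction for one species.

    ``species`` is ``"human"`` or ``"arabidopsis"``.  See
    ``data/PROVENANCE.md`` for what is canonical and what is synthetic in
    these files.
    """
    if species not in ("human", "arabidopsis"):
        raise ValueError("species must be 'human' or 'arabidopsis'")
    stem = f"{species}_histones.reconstruction"
    return read_histones(
        _data_path(stem + ".fasta"),
        _data_path(stem + ".sites.tsv"),
        filter=filter,
        coerce_u_to_n=coerce_u_to_n,
    )
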