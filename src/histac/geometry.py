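"""Nucleosome-level geometry of lysine epsilon-N atoms.

The acetyl-acceptor atom of lysine is the side-chain terminal nitrogen
(PDB atom name NZ, "epsilon-N").  Within the nucleosome, acetylability
correlates with where a lysine sits: five spatial groups of sites are
summarized as ellipsoid regions, each fitted to the pooled epsilon-N
positions of its member sites (both copies of the two-fold symmetric
octamer).  An ellipsoid is the locus (x - c)^T A (x - c) = 1 with A
symmetric positive definite: eigenvectors of A give principal directions
and eigenvalues^(-1/2) the equatorial radii.

Point-to-ellipsoid distance has no closed form; it is computed
numerically as the minimum distance to a deterministic low-discrepancy
sample of the surface (Fibonacci lattice mapped through A^(-1/2)).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .io import HistoneProtein
from .classifier import ClassifierParams

logger = logging.getLogger(__name__)


@dataclass
class EpsilonNAtom:
    """One lysine NZ atom in the structure (one per octamer copy)."""

    chain_id: str
    residue_number: int
    coords: np.ndarray
    histone_id: str | None = None
    mature_position: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)


@dataclass
class EllipsoidRegion:
    """An acetylability-associated spatial region.

    ``matrix_A`` has units of inverse square angstroms; ``principal_radii``
    are the sorted eigenvalue^(-1/2) lengths in angstroms.
    """

    group_id: int
    polarity: str  # "acetylable" | "un_acetylable"
    center: np.ndarray
    matrix_A: np.ndarray
    member_sites: list[tuple[str, int]] = field(default_factory=list)
    fallback_sphere: bool = False

    def __post_init__(self) -> None:
        if self.polarity not in ("acetylable", "un_acetylable"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        self.center = np.asarray(self.center, float).reshape(3)
        A = np.asarray(self.matrix_A, float).reshape(3, 3)
        if not np.allclose(A, A.T, atol=1e-8):
            raise ValueError("matrix_A must be symmetric")
        if np.any(np.linalg.eigvalsh(A) <= 0):
            raise ValueError("matrix_A must be positive definite")
        self.matrix_A = A

    @property
    def principal_radii(self) -> np.ndarray:
        return np.sort(np.linalg.eigvalsh(self.matrix_A) ** -0.5)

    def surface_points(self, n: int = 4096, seed: int = 0) -> np.ndarray:
        """Quasi-uniform surface sample via a Fibonacci sphere lattice.

        The seed only rotates the lattice's azimuthal offset, keeping the
        sample deterministic and uniform.
        """
        i = np.arange(n)
        golden = (1 + 5**0.5) / 2
        offset = (seed % 997) / 997.0
        z = 1 - 2 * (i + 0.5) / n
        r = np.sqrt(np.maximum(0.0, 1 - z * z))
        phi = 2 * np.pi * ((i / golden + offset) % 1.0)
        s = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        evals, evecs = np.linalg.eigh(self.matrix_A)
        b = evecs @ np.diag(evals**-0.5) @ evecs.T  # A^(-1/2)
        return self.center + s @ b.T


def point_to_ellipsoid_distance(
    p: np.ndarray,
    region: EllipsoidRegion,
    n_surface_samples: int = 4096,
    seed: int = 0,
) -> float:
    """Minimum Euclidean distance from a point to the sampled surface."""
    pts = region.surface_points(n=n_surface_samples, seed=seed)
    return float(np.min(np.linalg.norm(pts - np.asarray(p, float), axis=1)))


def fit_ellipsoid(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares ellipsoid through a point cloud.

    Centers at the centroid, then solves (p - c)^T A (p - c) = 1 for the
    six free entries of symmetric A; eigenvalues are clamped to 1e-8
    before reassembly so A stays positive definite.  Returns (center, A).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 6:
        raise ValueError("insufficient points: need >= 6 3-vectors")
    centroid = pts.mean(axis=0)  # numerical preconditioning only
    q = pts - centroid
    x, y, z = q[:, 0], q[:, 1], q[:, 2]
    quad = np.column_stack([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z])
    if len(pts) >= 9:
        # general quadric q^T M q + b.q = 1; the center falls out as
        # -M^-1 b / 2, which (unlike the raw centroid) is exact for finite
        # surface samples
        design = np.column_stack([quad, x, y, z])
    else:
        # 6-8 points cannot pin down the 9-parameter quadric; fall back to
        # the centroid-centered 6-parameter form (exact interpolation at 6)
        design = quad
    cond = np.linalg.cond(design)
    if cond > 1e10:
        raise ValueError(
            f"rank-deficient design (condition number {cond:.3g}): "
            "points nearly coplanar after centering"
        )
    coef, *_ = np.linalg.lstsq(design, np.ones(len(pts)), rcond=None)
    a, b, c, d, e, f = coef[:6]
    M = np.array([[a, d, e], [d, b, f], [e, f, c]])
    if len(coef) == 9:
        bvec = coef[6:]
        evals, evecs = np.linalg.eigh(M)
        evals = np.where(np.abs(evals) < 1e-12, 1e-12, evals)
        M = evecs @ np.diag(evals) @ evecs.T
        offset = -0.5 * np.linalg.solve(M, bvec)
        scale = 1.0 + float(offset @ M @ offset)
        if scale <= 0:
            raise ValueError("degenerate quadric: not an ellipsoid")
        M = M / scale
    else:
        offset = np.zeros(3)
    evals, evecs = np.linalg.eigh(M)
    evals = np.maximum(evals, 1e-8)
    return centroid + offset, evecs @ np.diag(evals) @ evecs.T


def _chain_sequence(chain) -> tuple[str, list[int]]:
    seq, numbers = [], []
    for res in chain:
        if res.id[0] != " ":
            continue
        one = protein_letters_3to1.get(res.get_resname().upper())
        if one is None:
            continue
        seq.append(one)
        numbers.append(res.id[1])
    return "".join(seq), numbers


def _parse_structure(structure_path: str | Path):
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return parser.get_structure("nucleosome", str(structure_path))


def extract_epsilon_n(structure_path: str | Path) -> list[EpsilonNAtom]:
    """All lysine NZ atoms in the structure's first model.

    Lysines whose side chain is unresolved (no NZ atom) are skipped and
    counted in a log message.
    """
    structure = _parse_structure(structure_path)
    model = next(iter(structure))
    atoms, skipped = [], 0
    n_chains = 0
    for chain in model:
        n_chains += 1
        for res in chain:
            if res.id[0] != " " or res.get_resname() != "LYS":
                continue
            if "NZ" not in res:
                skipped += 1
                continue
            atoms.append(
                EpsilonNAtom(
                    chain_id=chain.id,
                    residue_number=res.id[1],
                    coords=res["NZ"].coord,
                )
            )
    if n_chains == 0:
        raise ValueError("structure has no chains")
    if skipped:
        logger.info("skipped %d lysines without resolved NZ", skipped)
    return atoms


def map_sites_to_structure(
    histones: list[HistoneProtein],
    structure_path: str | Path,
    min_match: int = 8,
) -> dict[tuple[str, int], list[EpsilonNAtom]]:
    """Locate each histone lysine on structure chains by peptide matching.

    The flanking peptide (up to ``min_match`` residues each side, shrunk
    greedily toward the lysine when no exact match is found, e.g. near
    termini or chain truncations) is searched in each chain sequence.
    Exactly one occurrence in a chain maps the site to that chain's
    residue; multiple occurrences flag the site ambiguous for that chain.
    PDB residue numbers are never trusted for the mapping.
    """
    structure = _parse_structure(structure_path)
    model = next(iter(structure))
    chains = []
    for chain in model:
        seq, numbers = _chain_sequence(chain)
        if seq:
            nz = {
                res.id[1]: res["NZ"].coord
                for res in chain
                if res.id[0] == " " and res.get_resname() == "LYS" and "NZ" in res
            }
            chains.append((chain.id, seq, numbers, nz))
    mapping: dict[tuple[str, int], list[EpsilonNAtom]] = {}
    for prot in histones:
        for pos in prot.lysine_positions:
            site = (prot.id, pos)
            hits: list[EpsilonNAtom] = []
            for chain_id, seq, numbers, nz in chains:
                found = None
                for w in range(min_match, 1, -1):
                    left = min(w, pos - 1)
                    right = min(w, len(prot.sequence) - pos)
                    if left + right < min_match:
                        break  # never match on windows shorter than the floor
                    window = prot.sequence[pos - 1 - left : pos + right]
                    occurrences = _find_all(seq, window)
                    if len(occurrences) == 1:
                        found = occurrences[0] + left  # 0-based index of the K
                        break
                    if len(occurrences) > 1:
                        logger.warning(
                            "site %s ambiguous in chain %s: excluded", site, chain_id
                        )
                        found = None
                        break
                if found is None:
                    continue
                if seq[found] != "K":
                    continue
                resnum = numbers[found]
                if resnum in nz:
                    hits.append(
                        EpsilonNAtom(
                            chain_id=chain_id,
                            residue_number=resnum,
                            coords=nz[resnum],
                            histone_id=prot.id,
                            mature_position=pos,
                        )
                    )
            if hits:
                mapping[site] = hits
    return mapping


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


# The five acetylability-associated site groups (mature numbering).  The
# H2BK31 symmetric pair sits in the inter-gyre center but lacks an
# evaluated status, so it is deliberately not a group.
DEFAULT_CATALOG_SPEC: list[dict] = [
    {"group_id": 1, "polarity": "acetylable",
     "sites": [("H3", 37), ("H3", 56), ("H4", 31), ("H4", 44), ("H4", 59)]},
    {"group_id": 2, "polarity": "un_acetylable",
     "sites": [("H3", 115), ("H3", 122)]},
    {"group_id": 3, "polarity": "un_acetylable",
     "sites": [("H2B", 40), ("H2B", 43), ("H2B", 105), ("H2B", 113),
               ("H2B", 117), ("H2B", 122)]},
    {"group_id": 4, "polarity": "acetylable",
     "sites": [("H4", 77), ("H4", 79)]},
    {"group_id": 5, "polarity": "acetylable",
     "sites": [("H4", 91)]},
]


@dataclass
class RegionCatalog:
    """The fitted collection of acetylability-associated regions."""

    regions: list[EllipsoidRegion]

    def by_polarity(self, polarity: str) -> list[EllipsoidRegion]:
        return [r for r in self.regions if r.polarity == polarity]

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "group_id": r.group_id,
                "polarity": r.polarity,
                "center": r.center.tolist(),
                "matrix_A": r.matrix_A.tolist(),
                "principal_radii": r.principal_radii.tolist(),
                "member_sites": [list(s) for s in r.member_sites],
                "fallback_sphere": r.fallback_sphere,
            }
            for r in self.regions
        ]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionCatalog":
        payload = json.loads(Path(path).read_text())
        return cls(
            regions=[
                EllipsoidRegion(
                    group_id=r["group_id"],
                    polarity=r["polarity"],
                    center=np.array(r["center"]),
                    matrix_A=np.array(r["matrix_A"]),
                    member_sites=[tuple(s) for s in r["member_sites"]],
                    fallback_sphere=r["fallback_sphere"],
                )
                for r in payload
            ]
        )


def _site_key(histones: list[HistoneProtein]) -> dict[str, list[HistoneProtein]]:
    by_family: dict[str, list[HistoneProtein]] = {}
    for h in histones:
        by_family.setdefault(h.family, []).append(h)
    return by_family


def build_region_catalog(
    histones: list[HistoneProtein],
    mapping: dict[tuple[str, int], list[EpsilonNAtom]],
    catalog_spec: list[dict] | None = None,
) -> RegionCatalog:
    """Fit one region per group from pooled mapped epsilon-N atoms.

    Catalog sites are named by (histone family, mature position); every
    mapped copy across symmetric chains is pooled into the fit.  Groups
    with fewer than 6 pooled atoms get an isotropic sphere through the
    RMS radius, flagged ``fallback_sphere``.
    """
    spec = catalog_spec if catalog_spec is not None else DEFAULT_CATALOG_SPEC
    by_family = _site_key(histones)
    regions = []
    for group in spec:
        pts, members = [], []
        for family, pos in group["sites"]:
            atoms: list[EpsilonNAtom] = []
            for prot in by_family.get(family, []):
                atoms.extend(mapping.get((prot.id, pos), []))
            if not atoms:
                raise ValueError(
                    f"catalog site {family}K{pos} is unmapped in the structure"
                )
            members.append((family, pos))
            pts.extend(a.coords for a in atoms)
        pts_arr = np.array(pts)
        if len(pts_arr) >= 6:
            try:
                center, A = fit_ellipsoid(pts_arr)
                fallback = False
            except ValueError:
                center, A = _sphere_fallback(pts_arr)
                fallback = True
        else:
            center, A = _sphere_fallback(pts_arr)
            fallback = True
        regions.append(
            EllipsoidRegion(
                group_id=group["group_id"],
                polarity=group["polarity"],
                center=center,
                matrix_A=A,
                member_sites=members,
                fallback_sphere=fallback,
            )
        )
    return RegionCatalog(regions=regions)


def _sphere_fallback(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = pts.mean(axis=0)
    rms = float(np.sqrt(np.mean(np.sum((pts - center) ** 2, axis=1))))
    radius = max(rms, 1.0)  # degenerate single-point groups get a 1 A sphere
    return center, np.eye(3) / radius**2


def spatial_decision(
    site_atoms: list[EpsilonNAtom],
    catalog: RegionCatalog,
    cparams: ClassifierParams = ClassifierParams(),
    n_surface_samples: int = 4096,
    seed: int = 0,
) -> tuple[float, str]:
    """Max-min decision over region distances (same form as the peptide one).

    The distance of a site to a region is the min over the site's
    symmetric copies; score = alpha * min(un-acetylable distances) -
    beta * min(acetylable distances) - I, positive meaning acetylable.
    """
    if not site_atoms:
        raise ValueError("no atoms for site")
    pos_regions = catalog.by_polarity("acetylable")
    neg_regions = catalog.by_polarity("un_acetylable")
    if not pos_regions or not neg_regions:
        raise ValueError("catalog must contain both polarities")

    def region_distance(region: EllipsoidRegion) -> float:
        return min(
            point_to_ellipsoid_distance(a.coords, region, n_surface_samples, seed)
            for a in site_atoms
        )

    d_pos = min(region_distance(r) for r in pos_regions)
    d_neg = min(region_distance(r) for r in neg_regions)
    score = cparams.alpha * d_neg - cparams.beta * d_pos - cparams.intercept
    return float(score), ("P" if score > 0 else "N")
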