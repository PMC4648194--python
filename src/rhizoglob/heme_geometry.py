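"""Heme-pocket geometry from PDB structure models.

Computes Fe-residue distances and side-chain chi1 dihedrals for the four
ligand-pocket roles of the myoglobin fold (proximal F8, distal E7, B10,
CD1), makes a penta-/hexacoordination call for the heme iron, and
superposes models by the Kabsch least-squares algorithm.

Geometry conventions:

* distances are Euclidean, in Angstrom;
* dihedrals follow the IUPAC sign convention, reported in (-180, 180];
* chi1 is N-CA-CB-(first gamma side-chain atom);
* the probe atom measured against Fe defaults to the functional tip of
  the side chain (His NE2, Gln NE2, Asn ND2, Tyr OH, Phe CZ); for other
  residues, or when the named atom is absent, the side-chain heavy atom
  nearest to Fe is used and reported;
* the heme Fe is called hexacoordinate when the distal probe lies within
  the coordination cutoff (default 3.0 A), pentacoordinate when only the
  proximal probe does, indeterminate otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

HEME_RESNAMES = {"HEM", "HEC", "HEB"}
ROLE_ORDER = ("proximal", "distal", "B10", "CD1")

_DEFAULT_PROBE = {
    "HIS": "NE2",
    "GLN": "NE2",
    "ASN": "ND2",
    "TYR": "OH",
    "PHE": "CZ",
}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_GAMMA_NAMES = ("CG", "CG1", "OG", "OG1", "SG")


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    x: float
    y: float
    z: float
    element: str
    het: bool

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """Parsed PDB model with exactly one heme Fe."""

    atoms: list
    fe: Atom = field(init=False)

    def __post_init__(self):
        fes = [
            a
            for a in self.atoms
            if a.resname in HEME_RESNAMES
            and (a.element == "FE" or a.name == "FE")
        ]
        if not fes:
            raise ValueError("no Fe atom found in a heme group (HEM/HEC/HEB)")
        if len(fes) > 1:
            raise ValueError(f"{len(fes)} heme Fe atoms found; expected exactly 1")
        self.fe = fes[0]

    def residue(self, resseq: int, chain: str | None = None) -> dict:
        sel = {
            a.name: a
            for a in self.atoms
            if a.resseq == resseq
            and not a.het
            and (chain is None or a.chain == chain)
        }
        if not sel:
            raise KeyError(f"no residue with number {resseq}")
        return sel

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """New model with coordinates x -> R x + t (floats kept exact)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        moved = []
        for a in self.atoms:
            nx, ny, nz = rotation @ a.xyz + translation
            moved.append(
                Atom(a.serial, a.name, a.resname, a.chain, a.resseq,
                     float(nx), float(ny), float(nz), a.element, a.het)
            )
        return StructureModel(atoms=moved)


def _parse_atom_line(line: str, lineno: int) -> Atom:
    if len(line.rstrip("\n")) < 54:
        raise ValueError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed fixed columns ({exc})") from None
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = "".join(c for c in name if c.isalpha())[:2].upper()
        if element not in ("FE",):
            element = element[:1]
    return Atom(
        serial=serial,
        name=name,
        resname=resname,
        chain=chain,
        resseq=resseq,
        x=x,
        y=y,
        z=z,
        element=element,
        het=line.startswith("HETATM"),
    )


def parse_structure(pdb_text: str) -> StructureModel:
    """Parse fixed-column PDB ATOM/HETATM records into a StructureModel."""
    atoms = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            atoms.append(_parse_atom_line(line, lineno))
    if not atoms:
        raise ValueError("no ATOM/HETATM records found")
    for a in atoms:
        if not np.isfinite([a.x, a.y, a.z]).all():
            raise ValueError(f"non-finite coordinates in atom {a.serial}")
    return StructureModel(atoms=atoms)


def format_atom_line(atom: Atom) -> str:
    record = "HETATM" if atom.het else "ATOM  "
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return (
        f"{record}{atom.serial:5d} {name}{'':1s}{atom.resname:>3s} "
        f"{atom.chain:1s}{atom.resseq:4d}{'':1s}   "
        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(model_or_atoms) -> str:
    atoms = (
        model_or_atoms.atoms
        if isinstance(model_or_atoms, StructureModel)
        else list(model_or_atoms)
    )
    lines = [format_atom_line(a) for a in atoms]
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# primitive geometry


def _coords(p) -> np.ndarray:
    if isinstance(p, Atom):
        return p.xyz
    return np.asarray(p, dtype=float)


def atom_distance(a, b) -> float:
    """Euclidean distance in Angstrom."""
    return float(np.linalg.norm(_coords(a) - _coords(b)))


def dihedral(p1, p2, p3, p4):
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180].

    Returns None for degenerate geometry (collinear central bond).
    """
    p1, p2, p3, p4 = (_coords(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return None
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0 + 1e-12:
        ang = 180.0
    return ang


# ---------------------------------------------------------------------------
# pocket geometry


@dataclass
class RoleGeometry:
    role: str
    resname: str
    resseq: int
    probe_atom: str
    distance: float
    chi1: float | None
    probe_fallback: bool = False


@dataclass
class PocketGeometry:
    roles: dict                     # role -> RoleGeometry
    coordination: str               # penta | hexa | indeterminate
    cutoff: float

    def as_rows(self) -> list:
        rows = []
        for role in ROLE_ORDER:
            if role not in self.roles:
                continue
            g = self.roles[role]
            rows.append(
                {
                    "role": role,
                    "residue": f"{g.resname}{g.resseq}",
                    "probe_atom": g.probe_atom,
                    "distance_A": round(g.distance, 3),
                    "chi1_deg": None if g.chi1 is None else round(g.chi1, 2),
                    "coordination": self.coordination,
                }
            )
        return rows


def _pick_probe(residue: dict, resname: str, requested, fe: Atom):
    fallback = False
    name = requested or _DEFAULT_PROBE.get(resname)
    if name and name in residue:
        return residue[name], fallback
    if requested:
        warnings.warn(
            f"probe atom {requested} absent from {resname}; "
            "falling back to nearest side-chain atom",
            RuntimeWarning,
            stacklevel=3,
        )
    side = [a for n, a in residue.items() if n not in _BACKBONE and n != "CB"]
    side = side or [a for n, a in residue.items() if n not in _BACKBONE]
    if not side:
        raise ValueError(f"residue {resname} has no side-chain atoms")
    probe = min(side, key=lambda a: atom_distance(a, fe))
    return probe, True


def _chi1(residue: dict):
    needed = ("N", "CA", "CB")
    if any(n not in residue for n in needed):
        return None
    gamma = next((residue[n] for n in _GAMMA_NAMES if n in residue), None)
    if gamma is None:
        return None
    return dihedral(residue["N"], residue["CA"], residue["CB"], gamma)


def pocket_geometry(
    model: StructureModel,
    roles: dict,
    coordination_cutoff: float = 3.0,
) -> PocketGeometry:
    """Measure Fe-probe distances and chi1 per pocket role.

    ``roles`` maps role name (proximal/distal/B10/CD1) to a residue
    number or a (residue number, probe atom name) tuple.
    """
    unknown = set(roles) - set(ROLE_ORDER)
    if unknown:
        raise ValueError(f"unknown pocket roles: {sorted(unknown)}")
    out = {}
    for role, spec in roles.items():
        if isinstance(spec, tuple):
            resseq, probe_name = spec
        else:
            resseq, probe_name = spec, None
        residue = model.residue(resseq)
        resname = next(iter(residue.values())).resname
        probe, fb = _pick_probe(residue, resname, probe_name, model.fe)
        out[role] = RoleGeometry(
            role=role,
            resname=resname,
            resseq=resseq,
            probe_atom=probe.name,
            distance=atom_distance(probe, model.fe),
            chi1=_chi1(residue),
            probe_fallback=fb,
        )
    prox = out.get("proximal")
    dist = out.get("distal")
    if dist is not None and dist.distance <= coordination_cutoff:
        coordination = "hexa"
    elif prox is not None and prox.distance <= coordination_cutoff:
        coordination = "penta"
    else:
        coordination = "indeterminate"
    return PocketGeometry(roles=out, coordination=coordination, cutoff=coordination_cutoff)


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(coords_a, coords_b):
    """Least-squares rigid superposition of paired coordinates.

    Returns (rotation R, translation t, rmsd) minimizing
    ||(A @ R.T + t) - B||; R is a proper rotation (det +1).  Rejects
    fewer than 3 pairs or collinear point sets.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise ValueError("at least 3 atom pairs required")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    A0 = A - ca
    B0 = B - cb
    sv_a = np.linalg.svd(A0, compute_uv=False)
    if sv_a[1] < 1e-8 * max(1.0, sv_a[0]):
        raise ValueError("collinear point set: superposition is degenerate")
    H = A0.T @ B0
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    moved = A @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1))))
    return R, t, rmsd
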