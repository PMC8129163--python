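"""Structures, bond perception and region pruning.

Trajectory snapshots are read from multi-model PDB files into lightweight
:class:`Frame` objects.  Covalent bonds are perceived geometrically from a
covalent-radius table, hydrogen bonds from donor/acceptor heavy-atom
distance (and, when hydrogens are present, the donor–H–acceptor angle).
Frames can be pruned to the tunneling-relevant region either by an explicit
residue list or by a cylinder around the donor–acceptor axis.

Conventions: coordinates in Å; residue identity is the triple
(chain, residue number, residue name); altlocs other than blank/'A' are
ignored; heavy atoms are the pathway nodes, hydrogens enter only through
hydrogen-bond geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Frame",
    "BondGraph",
    "RegionSelection",
    "HBondCriteria",
    "COVALENT_RADII",
    "default_cutoff",
    "read_structure",
    "write_frames",
    "perceive_covalent_bonds",
    "detect_hydrogen_bonds",
    "prune_to_region",
    "porphyrin_core_atoms",
    "PORPHYRIN_CORE_NAMES",
    "HEME_RESNAMES",
]

# Single-bond covalent radii (Å), Cordero et al. consensus values.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "F": 0.57,
    "CL": 1.02,
    "BR": 1.20,
    "NA": 1.66,
    "K": 2.03,
    "MG": 1.41,
    "CA": 1.76,
    "MN": 1.39,
    "FE": 1.32,
    "CO": 1.26,
    "NI": 1.24,
    "CU": 1.32,
    "ZN": 1.22,
    "SE": 1.20,
}

#: Tolerance added to the sum of covalent radii when perceiving bonds (Å).
COVALENT_TOLERANCE = 0.4

HEME_RESNAMES = frozenset({"HEM", "HEME", "HEC", "HEB", "HEA"})

#: The 24 macrocycle atoms of a standard PDB heme: 4 pyrrole nitrogens,
#: 16 pyrrole carbons, 4 meso (methine-bridge) carbons.
PORPHYRIN_CORE_NAMES: tuple[str, ...] = (
    "NA", "C1A", "C2A", "C3A", "C4A",
    "NB", "C1B", "C2B", "C3B", "C4B",
    "NC", "C1C", "C2C", "C3C", "C4C",
    "ND", "C1D", "C2D", "C3D", "C4D",
    "CHA", "CHB", "CHC", "CHD",
)

_HB_ELEMENTS = frozenset({"N", "O", "S"})


@dataclass(frozen=True)
class Atom:
    """A single atom of a snapshot.

    ``atom_index`` is unique within its frame and is preserved through
    pruning, so pathway node identities remain stable.
    """

    atom_index: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coordinates: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.atom_index} has no element")
        if not all(math.isfinite(c) for c in self.coordinates):
            raise ValueError(f"atom {self.atom_index} has non-finite coordinates")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)

    @property
    def residue_label(self) -> str:
        """Human-readable residue tag, e.g. ``Trp378``."""
        return f"{self.residue_name.capitalize()}{self.residue_number}"

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Frame:
    """One trajectory snapshot: an ordered collection of atoms."""

    frame_index: int
    atoms: list[Atom]
    time: float | None = None  # ps

    _index_map: dict[int, Atom] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"frame {self.frame_index} has no atoms")
        self._index_map = {a.atom_index: a for a in self.atoms}
        if len(self._index_map) != len(self.atoms):
            raise ValueError(f"frame {self.frame_index} has duplicate atom indices")

    def __len__(self) -> int:
        return len(self.atoms)

    def atom(self, atom_index: int) -> Atom:
        return self._index_map[atom_index]

    def coordinates(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.coordinates for a in atoms], dtype=float)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def has_hydrogens(self) -> bool:
        return any(a.is_hydrogen for a in self.atoms)

    def residues(self) -> list[tuple[str, int, str]]:
        """Residue ids in order of first appearance."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def select_residues(
        self, residue_ids: Iterable[tuple[str, int, str]]
    ) -> list[Atom]:
        wanted = set(residue_ids)
        return [a for a in self.atoms if a.residue_id in wanted]

    def distance(self, i: int, j: int) -> float:
        a = np.asarray(self.atom(i).coordinates)
        b = np.asarray(self.atom(j).coordinates)
        return float(np.linalg.norm(a - b))


@dataclass
class BondGraph:
    """Perceived connectivity of one frame.

    ``covalent_bonds`` holds unordered heavy/any-atom index pairs stored as
    sorted tuples; ``hydrogen_bonds`` holds (donor heavy atom, acceptor
    heavy atom, inter-heavy-atom distance R_H in Å).
    """

    covalent_bonds: set[tuple[int, int]] = field(default_factory=set)
    hydrogen_bonds: set[tuple[int, int, float]] = field(default_factory=set)

    def add_covalent(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-bond")
        self.covalent_bonds.add((min(i, j), max(i, j)))

    def is_covalent(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.covalent_bonds

    def neighbors(self, i: int) -> set[int]:
        out = set()
        for a, b in self.covalent_bonds:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out


@dataclass
class RegionSelection:
    """Region of interest: an explicit residue list and/or a cylinder of
    radius ``radius`` Å around the segment joining the centroids of the
    donor and acceptor residues.  Donor/acceptor residues are always kept.
    """

    residues: Sequence[tuple[str, int, str]] | None = None
    donor_residue: tuple[str, int, str] | None = None
    acceptor_residue: tuple[str, int, str] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.residues is None and self.radius is None:
            raise ValueError("selection must give a residue list or an axis radius")
        if self.radius is not None and (
            self.donor_residue is None or self.acceptor_residue is None
        ):
            raise ValueError("axis selection requires donor and acceptor residues")


def default_cutoff(element_a: str, element_b: str) -> float:
    """Covalent-bond distance cutoff for an element pair (Å)."""
    try:
        ra = COVALENT_RADII[element_a.upper()]
        rb = COVALENT_RADII[element_b.upper()]
    except KeyError as exc:
        raise KeyError(f"no covalent radius for element {exc.args[0]!r}") from None
    return ra + rb + COVALENT_TOLERANCE


def _frame_from_gemmi(model: gemmi.Model, frame_index: int) -> Frame:
    atoms: list[Atom] = []
    idx = 0
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("\x00", "", "A"):
                    continue
                element = atom.element.name
                if not element or element == "X":
                    # fall back to the leading letter of the atom name
                    stripped = atom.name.strip("0123456789 ")
                    if not stripped:
                        raise ValueError(
                            f"cannot resolve element for atom {atom.name!r}"
                        )
                    element = stripped[0]
                atoms.append(
                    Atom(
                        atom_index=idx,
                        name=atom.name,
                        element=element,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        coordinates=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
                idx += 1
    return Frame(frame_index=frame_index, atoms=atoms)


def read_structure(path: str | Path) -> list[Frame]:
    """Read a (multi-model) PDB file into a list of frames.

    MODEL/ENDMDL records delimit frames; a single-model file yields one
    frame.  Coordinates are in Å.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    frames = [_frame_from_gemmi(model, k) for k, model in enumerate(structure)]
    if not frames:
        raise ValueError(f"no models found in {path}")
    return frames


def write_frames(frames: Sequence[Frame], path: str | Path) -> None:
    """Write frames as a multi-model PDB file (inverse of read_structure)."""
    structure = gemmi.Structure()
    structure.name = "hemepath"
    for serial, frame in enumerate(frames, start=1):
        model = gemmi.Model(serial)
        chains: dict[str, gemmi.Chain] = {}
        residues: dict[tuple[str, int, str], gemmi.Residue] = {}
        for a in frame.atoms:
            if a.chain_id not in chains:
                chains[a.chain_id] = gemmi.Chain(a.chain_id)
            rid = a.residue_id
            if rid not in residues:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                res.het_flag = "H" if a.residue_name in HEME_RESNAMES else "A"
                chains[a.chain_id].add_residue(res)
                residues[rid] = chains[a.chain_id][-1]
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coordinates)
            residues[rid].add_atom(atom)
        for chain in chains.values():
            model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def perceive_covalent_bonds(
    frame: Frame,
    cutoffs: Mapping[tuple[str, str], float] | None = None,
) -> BondGraph:
    """Perceive covalent bonds geometrically.

    A pair is bonded iff its distance is at most the cutoff for its element
    pair.  The default cutoff is the sum of covalent radii plus 0.4 Å; the
    ``cutoffs`` mapping (keys are unordered element pairs, upper-case)
    overrides individual entries.  Each hydrogen is bonded only to its
    nearest heavy atom within cutoff.
    """

    def cutoff(ea: str, eb: str) -> float:
        ea, eb = ea.upper(), eb.upper()
        if cutoffs is not None:
            for key in ((ea, eb), (eb, ea)):
                if key in cutoffs:
                    return cutoffs[key]
        return default_cutoff(ea, eb)

    atoms = frame.atoms
    coords = frame.coordinates()
    elements = [a.element.upper() for a in atoms]
    max_cut = max(
        cutoff(ea, eb) for ea in set(elements) for eb in set(elements)
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=max_cut, output_type="ndarray")

    graph = BondGraph()
    hydrogen_candidates: dict[int, list[tuple[float, int]]] = {}
    for p, q in pairs:
        p, q = int(p), int(q)
        d = float(np.linalg.norm(coords[p] - coords[q]))
        if d > cutoff(elements[p], elements[q]):
            continue
        hp, hq = elements[p] == "H", elements[q] == "H"
        if hp and hq:
            continue
        if hp or hq:
            h, heavy = (p, q) if hp else (q, p)
            hydrogen_candidates.setdefault(h, []).append((d, heavy))
        else:
            graph.add_covalent(atoms[p].atom_index, atoms[q].atom_index)

    for h, cands in hydrogen_candidates.items():
        _, heavy = min(cands)
        graph.add_covalent(atoms[h].atom_index, atoms[heavy].atom_index)
    return graph


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    ``use_angle=None`` (default) enables the angle criterion iff the frame
    contains hydrogens, which keeps hydrogen-free toy systems reproducible.
    """

    distance_cutoff: float = 3.5  # inter-heavy-atom, Å
    angle_cutoff: float = 120.0  # donor-H-acceptor, degrees
    use_angle: bool | None = None


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hydrogen_bonds(
    frame: Frame,
    bonds: BondGraph,
    criteria: HBondCriteria | None = None,
) -> set[tuple[int, int, float]]:
    """Detect hydrogen bonds between N/O/S heavy atoms.

    A bond is recorded between a donor heavy atom (N/O/S carrying an
    attached hydrogen, or any N/O/S when the frame has no hydrogens) and an
    acceptor heavy atom (N/O/S) when the inter-heavy-atom distance R_H is
    within the cutoff and — if the angle criterion applies — the
    donor–H–acceptor angle meets the angle cutoff.  Covalently bonded pairs
    are excluded.  Returns (donor_index, acceptor_index, R_H) triples.
    """
    criteria = criteria or HBondCriteria()
    has_h = frame.has_hydrogens()
    use_angle = criteria.use_angle if criteria.use_angle is not None else has_h

    polar = [a for a in frame.atoms if a.element.upper() in _HB_ELEMENTS]
    attached_h: dict[int, list[int]] = {}
    if has_h:
        for a in polar:
            hs = [
                n for n in bonds.neighbors(a.atom_index)
                if frame.atom(n).is_hydrogen
            ]
            if hs:
                attached_h[a.atom_index] = hs
        donors = [a for a in polar if a.atom_index in attached_h]
    else:
        donors = polar

    out: set[tuple[int, int, float]] = set()
    for donor in donors:
        dpos = np.asarray(donor.coordinates)
        for acceptor in polar:
            if acceptor.atom_index == donor.atom_index:
                continue
            if bonds.is_covalent(donor.atom_index, acceptor.atom_index):
                continue
            apos = np.asarray(acceptor.coordinates)
            r_h = float(np.linalg.norm(dpos - apos))
            if r_h > criteria.distance_cutoff:
                continue
            if use_angle and donor.atom_index in attached_h:
                ok = any(
                    _angle_deg(
                        dpos,
                        np.asarray(frame.atom(h).coordinates),
                        apos,
                    )
                    >= criteria.angle_cutoff
                    for h in attached_h[donor.atom_index]
                )
                if not ok:
                    continue
            out.add((donor.atom_index, acceptor.atom_index, r_h))
    return out


def _residue_centroids(frame: Frame) -> dict[tuple[str, int, str], np.ndarray]:
    sums: dict[tuple[str, int, str], list[np.ndarray]] = {}
    for a in frame.atoms:
        sums.setdefault(a.residue_id, []).append(np.asarray(a.coordinates))
    return {rid: np.mean(pts, axis=0) for rid, pts in sums.items()}


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def prune_to_region(frame: Frame, selection: RegionSelection) -> Frame:
    """Restrict a frame to the tunneling-relevant region.

    Membership only: coordinates and atom indices are preserved.  Raises if
    the selection would drop the donor or acceptor residue.
    """
    keep: set[tuple[str, int, str]] = set()
    if selection.residues is not None:
        keep.update(tuple(r) for r in selection.residues)
    if selection.radius is not None:
        centroids = _residue_centroids(frame)
        if selection.donor_residue not in centroids:
            raise ValueError(f"donor residue {selection.donor_residue} not in frame")
        if selection.acceptor_residue not in centroids:
            raise ValueError(
                f"acceptor residue {selection.acceptor_residue} not in frame"
            )
        a = centroids[selection.donor_residue]
        b = centroids[selection.acceptor_residue]
        for rid in frame.residues():
            atoms = frame.select_residues([rid])
            if any(
                _point_segment_distance(np.asarray(at.coordinates), a, b)
                <= selection.radius
                for at in atoms
            ):
                keep.add(rid)
    for special in (selection.donor_residue, selection.acceptor_residue):
        if special is not None:
            keep.add(tuple(special))

    for special in (selection.donor_residue, selection.acceptor_residue):
        if special is not None and tuple(special) not in keep:
            raise ValueError(f"selection removes {special}")

    atoms = [a for a in frame.atoms if a.residue_id in keep]
    if not atoms:
        raise ValueError("selection is empty after application")
    return Frame(frame_index=frame.frame_index, atoms=atoms, time=frame.time)


def porphyrin_core_atoms(
    frame: Frame, heme_residue: tuple[str, int, str]
) -> set[int]:
    """Atom indices of the 24-atom porphyrin macrocycle of a heme residue.

    These atoms form the fully conductive core of the pathway graph.
    """
    chain, number, name = heme_residue
    if name not in HEME_RESNAMES:
        raise ValueError(f"{name!r} is not a recognized heme residue name")
    by_name = {
        a.name: a.atom_index
        for a in frame.atoms
        if a.residue_id == (chain, number, name)
    }
    if not by_name:
        raise ValueError(f"heme residue {heme_residue} not found in frame")
    missing = [n for n in PORPHYRIN_CORE_NAMES if n not in by_name]
    if missing:
        raise ValueError(
            f"heme {heme_residue} lacks macrocycle atoms: {', '.join(missing)}"
        )
    return {by_name[n] for n in PORPHYRIN_CORE_NAMES}
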