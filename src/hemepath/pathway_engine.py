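"""Semi-empirical electron-tunneling pathway model.

The electronic coupling between donor and acceptor is written as
``H_if = H_if_contact * eps_tot`` where ``eps_tot`` is the product of
per-step decay factors along the best pathway through the intervening
medium:

- covalent bond:        eps_c = 0.6
- hydrogen bond:        eps_hb = 0.36 * exp[-beta_S (R_H - 2.8)]
- through-space jump:   eps_ts = 0.6  * exp[-beta_S (R_S - 1.4)]

with ``beta_S = 1.1 Å^-1`` (the modern reparametrization; the original
1990s value was 1.7 Å^-1).  Covalent bonds inside the porphyrin macrocycle
of each heme are fully conductive (eps = 1), so results do not depend on
which macrocycle atom is taken as donor or acceptor.

The best pathway maximizes the decay product, found as a shortest path
under the additive weight ``w = -ln(eps)`` with Dijkstra from a virtual
source fanning out to all donor atoms to a virtual sink collecting all
acceptor atoms.  Ties are broken by the lexicographically smallest node
sequence, so outputs are deterministic.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from hemepath.structure_model import (
    BondGraph,
    Frame,
    HBondCriteria,
    detect_hydrogen_bonds,
    perceive_covalent_bonds,
    porphyrin_core_atoms,
    write_frames,
)

__all__ = [
    "PathwayModelParams",
    "Pathway",
    "NoPathwayError",
    "covalent_decay",
    "hbond_decay",
    "space_decay",
    "build_tunneling_graph",
    "best_pathway",
    "decompose_pathway",
    "pathway_ensemble",
    "export_path_visualization",
]

_VIRTUAL_SOURCE = "__source__"
_VIRTUAL_SINK = "__sink__"


@dataclass(frozen=True)
class PathwayModelParams:
    """Parameters of the decay model (all lengths in Å).

    ``ts_max_distance`` bounds graph construction; jumps longer than it are
    exponentially negligible anyway.  ``contact_coupling`` is the
    close-contact coupling in eV used to convert decays to couplings.
    """

    epsilon_c: float = 0.6
    hb_prefactor: float = 0.36
    hb_offset: float = 2.8
    ts_prefactor: float = 0.6
    ts_offset: float = 1.4
    beta_S: float = 1.1  # Å^-1
    ts_max_distance: float = 6.0
    contact_coupling: float = 0.177829  # eV

    def __post_init__(self) -> None:
        for name in (
            "epsilon_c", "hb_prefactor", "hb_offset", "ts_prefactor",
            "ts_offset", "beta_S", "ts_max_distance", "contact_coupling",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ts_max_distance <= self.ts_offset:
            raise ValueError("ts_max_distance must exceed ts_offset")


@dataclass
class Pathway:
    """A donor→acceptor tunneling pathway.

    ``atom_indices`` runs from a donor atom to an acceptor atom;
    ``edge_types`` has one entry per step, drawn from
    {"covalent", "hbond", "through_space", "conductive"}.
    """

    atom_indices: list[int]
    edge_types: list[str]
    edge_decays: list[float]
    epsilon_tot: float
    n_covalent: int = 0
    n_hbond: int = 0
    n_through_space: int = 0
    mediating_residues: list[str] = field(default_factory=list)
    route_label: str = "direct"
    frame_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.edge_types) != len(self.atom_indices) - 1:
            raise ValueError("edge count must be node count - 1")
        prod = math.prod(self.edge_decays)
        if not math.isclose(prod, self.epsilon_tot, rel_tol=1e-12):
            raise ValueError("epsilon_tot inconsistent with edge decays")


class NoPathwayError(RuntimeError):
    """Donor and acceptor are not connected in the tunneling graph."""


def covalent_decay(params: PathwayModelParams | None = None) -> float:
    """Per-step decay of a covalent bond (distance-independent)."""
    return (params or PathwayModelParams()).epsilon_c


def hbond_decay(r_h: float, params: PathwayModelParams | None = None) -> float:
    """Decay across a hydrogen bond of inter-heavy-atom length ``r_h`` Å.

    Capped at the covalent decay so that no hydrogen bond outperforms a
    covalent step at unphysically short distances.
    """
    params = params or PathwayModelParams()
    if r_h <= 0:
        raise ValueError("hydrogen-bond length must be positive")
    eps = params.hb_prefactor * math.exp(-params.beta_S * (r_h - params.hb_offset))
    return min(eps, params.epsilon_c)


def space_decay(r_s: float, params: PathwayModelParams | None = None) -> float:
    """Decay of a through-space jump of length ``r_s`` Å (capped at eps_c)."""
    params = params or PathwayModelParams()
    if r_s <= 0:
        raise ValueError("jump distance must be positive")
    eps = params.ts_prefactor * math.exp(-params.beta_S * (r_s - params.ts_offset))
    return min(eps, params.epsilon_c)


def build_tunneling_graph(
    frame: Frame,
    bonds: BondGraph,
    hbonds: Iterable[tuple[int, int, float]] = (),
    conductive_atom_sets: Sequence[set[int]] = (),
    params: PathwayModelParams | None = None,
) -> nx.Graph:
    """Build the decay graph over the heavy atoms of a frame.

    Edge decays: covalent bonds get eps_c; any edge with both endpoints in
    the same conductive set (a porphyrin macrocycle) gets eps = 1 exactly;
    hydrogen-bond pairs get hbond_decay(R_H); every remaining heavy-atom
    pair within ``ts_max_distance`` gets space_decay(R_S).  When a pair
    qualifies for several types the largest decay wins and the type is
    recorded accordingly.  Edges carry attributes ``decay``, ``type`` and
    ``weight`` (= -ln decay).
    """
    params = params or PathwayModelParams()
    heavy = frame.heavy_atoms()
    if not heavy:
        raise ValueError("frame has no heavy atoms")
    index_of = {a.atom_index: k for k, a in enumerate(heavy)}
    coords = np.array([a.coordinates for a in heavy], dtype=float)

    def same_conductive(i: int, j: int) -> bool:
        return any(i in s and j in s for s in conductive_atom_sets)

    # candidate decays per pair; the best (largest) is kept
    best: dict[tuple[int, int], tuple[float, str]] = {}

    def offer(i: int, j: int, eps: float, etype: str) -> None:
        key = (min(i, j), max(i, j))
        if key not in best or eps > best[key][0]:
            best[key] = (eps, etype)

    for i, j in bonds.covalent_bonds:
        if i not in index_of or j not in index_of:
            continue  # bonds to hydrogens are not pathway edges
        if same_conductive(i, j):
            offer(i, j, 1.0, "conductive")
        else:
            offer(i, j, params.epsilon_c, "covalent")

    for donor, acceptor, r_h in hbonds:
        if donor not in index_of or acceptor not in index_of:
            continue
        if same_conductive(donor, acceptor):
            offer(donor, acceptor, 1.0, "conductive")
        else:
            offer(donor, acceptor, hbond_decay(r_h, params), "hbond")

    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for p, q in tree.query_pairs(r=params.ts_max_distance, output_type="ndarray"):
        i, j = heavy[int(p)].atom_index, heavy[int(q)].atom_index
        if same_conductive(i, j):
            offer(i, j, 1.0, "conductive")
        else:
            r_s = float(np.linalg.norm(coords[int(p)] - coords[int(q)]))
            offer(i, j, space_decay(r_s, params), "through_space")

    graph = nx.Graph()
    graph.add_nodes_from(a.atom_index for a in heavy)
    for (i, j), (eps, etype) in best.items():
        graph.add_edge(i, j, decay=eps, type=etype, weight=-math.log(eps))
    if graph.number_of_edges() == 0:
        raise ValueError("tunneling graph has no edges")
    return graph


def _dijkstra_lexicographic(
    graph: nx.Graph, donor_atoms: set, acceptor_atoms: set
) -> list:
    """Min-weight path from any donor to any acceptor.

    Keys are (total weight, node sequence); among equal-weight optima the
    lexicographically smallest atom-index sequence is returned.
    """
    heap: list[tuple[float, tuple]] = []
    for d in sorted(donor_atoms):
        if d in graph:
            heapq.heappush(heap, (0.0, (d,)))
    settled: set = set()
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node in settled:
            continue
        settled.add(node)
        if node in acceptor_atoms:
            return list(path)
        for nbr, attrs in graph[node].items():
            if nbr in settled:
                continue
            heapq.heappush(heap, (dist + attrs["weight"], path + (nbr,)))
    raise NoPathwayError("no pathway connects donor and acceptor")


def best_pathway(
    graph: nx.Graph,
    donor_atoms: set[int],
    acceptor_atoms: set[int],
    frame: Frame | None = None,
    donor_residues: Sequence[tuple[str, int, str]] = (),
    acceptor_residues: Sequence[tuple[str, int, str]] = (),
) -> Pathway:
    """Best (maximum decay product) donor→acceptor pathway.

    Equivalent to a virtual-source/virtual-sink shortest path under
    ``w = -ln eps``; conductive edges have weight 0 and Dijkstra stays
    exact because all weights are nonnegative.  If ``frame`` is given the
    pathway is decomposed (counts, mediating residues, route label).
    """
    donor_atoms, acceptor_atoms = set(donor_atoms), set(acceptor_atoms)
    if not donor_atoms or not acceptor_atoms:
        raise ValueError("donor and acceptor sets must be non-empty")
    if donor_atoms & acceptor_atoms:
        raise ValueError("donor and acceptor sets must be disjoint")
    nodes = _dijkstra_lexicographic(graph, donor_atoms, acceptor_atoms)
    edge_types = [graph[u][v]["type"] for u, v in zip(nodes, nodes[1:])]
    edge_decays = [graph[u][v]["decay"] for u, v in zip(nodes, nodes[1:])]
    pathway = Pathway(
        atom_indices=nodes,
        edge_types=edge_types,
        edge_decays=edge_decays,
        epsilon_tot=math.prod(edge_decays),
    )
    _count_edges(pathway)
    if frame is not None:
        decompose_pathway(
            pathway, frame,
            cofactor_residues=tuple(donor_residues) + tuple(acceptor_residues),
        )
    return pathway


def _count_edges(pathway: Pathway) -> None:
    pathway.n_covalent = pathway.edge_types.count("covalent")
    pathway.n_hbond = pathway.edge_types.count("hbond")
    pathway.n_through_space = pathway.edge_types.count("through_space")


def decompose_pathway(
    pathway: Pathway,
    frame: Frame,
    cofactor_residues: Sequence[tuple[str, int, str]] = (),
) -> tuple[int, int, int, list[str], str]:
    """Decompose a pathway into step counts and mediating residues.

    Returns (N_c, N_hb, N_ts, mediating residue labels in path order,
    route label).  The route label names the key non-cofactor mediating
    residue (e.g. ``"Trp378"``), or ``"direct"`` when the path jumps
    straight between cofactors.  When several residues mediate, the label
    is the one hosting the most path atoms (first reached on ties).
    """
    _count_edges(pathway)
    cof = set(cofactor_residues)
    mediating: list[str] = []
    counts: dict[str, int] = {}
    for idx in pathway.atom_indices:
        atom = frame.atom(idx)
        if atom.residue_id in cof:
            continue
        label = atom.residue_label
        if label not in mediating:
            mediating.append(label)
        counts[label] = counts.get(label, 0) + 1
    pathway.mediating_residues = mediating
    if mediating:
        pathway.route_label = max(
            mediating, key=lambda lbl: (counts[lbl], -mediating.index(lbl))
        )
    else:
        pathway.route_label = "direct"
    return (
        pathway.n_covalent,
        pathway.n_hbond,
        pathway.n_through_space,
        mediating,
        pathway.route_label,
    )


def pathway_ensemble(
    frames: Sequence[Frame],
    donor_residue: tuple[str, int, str],
    acceptor_residue: tuple[str, int, str],
    params: PathwayModelParams | None = None,
    hbond_criteria: HBondCriteria | None = None,
) -> list[Pathway | None]:
    """One best pathway per frame (None where no path exists).

    Donor and acceptor atom sets are the porphyrin macrocycles of the two
    heme residues, which are also the conductive sets; the choice of
    individual atom within them is immaterial because internal edges carry
    no decay.  Raises if every frame is pathless.
    """
    if not frames:
        raise ValueError("need at least one frame")
    params = params or PathwayModelParams()
    results: list[Pathway | None] = []
    for frame in frames:
        bonds = perceive_covalent_bonds(frame)
        hbonds = detect_hydrogen_bonds(frame, bonds, hbond_criteria)
        donor = porphyrin_core_atoms(frame, donor_residue)
        acceptor = porphyrin_core_atoms(frame, acceptor_residue)
        graph = build_tunneling_graph(
            frame, bonds, hbonds,
            conductive_atom_sets=[donor, acceptor],
            params=params,
        )
        try:
            pw = best_pathway(
                graph, donor, acceptor, frame=frame,
                donor_residues=[donor_residue],
                acceptor_residues=[acceptor_residue],
            )
            pw.frame_index = frame.frame_index
            results.append(pw)
        except NoPathwayError:
            results.append(None)
    if all(p is None for p in results):
        raise NoPathwayError("no frame yields a donor-acceptor pathway")
    return results


_VMD_TEMPLATE = """\
# Load the pathway atoms and draw the route as a tube.
mol new {pdb_name} type pdb
mol modstyle 0 top Licorice 0.2 12 12
graphics top color green
{cylinders}
"""


def export_path_visualization(
    pathway: Pathway, frame: Frame, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>.pdb`` with the path atoms and ``<prefix>.vmd`` with
    viewer commands drawing the route as a tube.  Returns both paths."""
    if not pathway.atom_indices:
        raise ValueError("empty pathway")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    atoms = [frame.atom(i) for i in pathway.atom_indices]
    sub = Frame(frame_index=frame.frame_index, atoms=atoms, time=frame.time)
    pdb_path = out_prefix.with_suffix(".pdb")
    write_frames([sub], pdb_path)
    cylinders = "\n".join(
        "graphics top cylinder {{{:.3f} {:.3f} {:.3f}}} "
        "{{{:.3f} {:.3f} {:.3f}}} radius 0.15".format(*a.coordinates, *b.coordinates)
        for a, b in zip(atoms, atoms[1:])
    )
    vmd_path = out_prefix.with_suffix(".vmd")
    vmd_path.write_text(
        _VMD_TEMPLATE.format(pdb_name=pdb_path.name, cylinders=cylinders)
    )
    return pdb_path, vmd_path
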