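"""Two-site O2 cavity analysis near the terminal heme.

The putative O2-binding cavity adjacent to the distal heme (shaped by an
arginine, two histidines and the heme itself) admits two favored O2
positions: inserted in the cavity (distance to the cavity center of mass
around 2.5 Å) and on its rim (around 4.3 Å).  This module computes
O2–cavity distance series from frames, classifies them into the two sites,
measures occupancies and dwell times, and classifies heme→O2 tunneling
pathways as "short" (a direct through-space jump from the porphyrin ring
to O2) or "long" (mediated by an intervening residue, e.g. a histidine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from hemepath.pathway_engine import Pathway
from hemepath.structure_model import Atom, Frame

__all__ = [
    "DistanceSeries",
    "SiteOccupancy",
    "PathwayClassSummary",
    "com_distance_series",
    "site_occupancy",
    "distance_histogram",
    "heme_to_o2_pathways",
    "classify_o2_pathways",
    "DEFAULT_SITE_BOUNDARY",
]

#: Default near/far boundary: midpoint of the 2.5 and 4.3 Å mode centers.
DEFAULT_SITE_BOUNDARY = 3.4  # Å


@dataclass
class DistanceSeries:
    """Time series of the O2–cavity-COM distance for one redox state."""

    times: np.ndarray  # ps
    d_o2_com: np.ndarray  # Å
    state: str = "initial"
    d_o2_fe: np.ndarray | None = None  # Å, optional
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.d_o2_com = np.asarray(self.d_o2_com, dtype=float)
        if self.times.shape != self.d_o2_com.shape:
            raise ValueError("times and distances must have the same length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.d_o2_com < 0):
            raise ValueError("distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.d_o2_com)


@dataclass
class SiteOccupancy:
    """Two-site occupancy summary of a distance series."""

    boundary: float  # Å
    fraction_near: float
    fraction_far: float
    mean_dwell_near: float  # ps (nan if site never visited)
    mean_dwell_far: float  # ps
    n_transitions: int

    def as_dict(self) -> dict:
        return {
            "boundary_A": self.boundary,
            "fraction_near": self.fraction_near,
            "fraction_far": self.fraction_far,
            "mean_dwell_near_ps": self.mean_dwell_near,
            "mean_dwell_far_ps": self.mean_dwell_far,
            "n_transitions": self.n_transitions,
        }


def _center(coords: np.ndarray, masses: np.ndarray | None) -> np.ndarray:
    if masses is None:
        return coords.mean(axis=0)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


# Atomic masses for the optional mass-weighted center of mass.
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "FE": 55.845,
}


def com_distance_series(
    frames: Sequence[Frame],
    group_a: Callable[[Atom], bool],
    group_b: Callable[[Atom], bool],
    state: str = "initial",
    mass_weighted: bool = False,
) -> DistanceSeries:
    """Distance between the centers of two atom selections, per frame.

    ``group_a`` and ``group_b`` are atom predicates (e.g. cavity heavy
    atoms and the O2 molecule).  Centers are geometric by default;
    ``mass_weighted=True`` uses atomic masses.
    """
    if not frames:
        raise ValueError("need at least one frame")
    times, dists = [], []
    for k, frame in enumerate(frames):
        a = [at for at in frame.atoms if group_a(at)]
        b = [at for at in frame.atoms if group_b(at)]
        if not a or not b:
            raise ValueError(f"empty selection in frame {frame.frame_index}")

        def masses(atoms: list[Atom]) -> np.ndarray | None:
            if not mass_weighted:
                return None
            return np.array([_MASSES[x.element.upper()] for x in atoms])

        ca = _center(np.array([x.coordinates for x in a]), masses(a))
        cb = _center(np.array([x.coordinates for x in b]), masses(b))
        times.append(frame.time if frame.time is not None else float(k))
        dists.append(float(np.linalg.norm(ca - cb)))
    return DistanceSeries(
        times=np.array(times), d_o2_com=np.array(dists), state=state
    )


def _dwell_times(labels: np.ndarray, times: np.ndarray) -> tuple[list, list]:
    """Contiguous-run durations (ps) for near (True) and far (False) runs."""
    near_runs, far_runs = [], []
    dt = np.diff(times)
    step = float(np.median(dt)) if len(dt) else 1.0
    start = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start]:
            duration = times[k - 1] - times[start] + step
            (near_runs if labels[start] else far_runs).append(float(duration))
            start = k
    return near_runs, far_runs


def site_occupancy(
    series: DistanceSeries, boundary: float = DEFAULT_SITE_BOUNDARY
) -> SiteOccupancy:
    """Two-site occupancy: near = d <= boundary, far = d > boundary.

    Dwell times are measured from contiguous runs of the same label; a
    transition is counted at every label change.
    """
    if len(series) == 0:
        raise ValueError("empty distance series")
    near = series.d_o2_com <= boundary
    near_runs, far_runs = _dwell_times(near, series.times)
    n_trans = int(np.count_nonzero(near[1:] != near[:-1]))
    n = len(series)
    return SiteOccupancy(
        boundary=boundary,
        fraction_near=float(np.count_nonzero(near)) / n,
        fraction_far=float(np.count_nonzero(~near)) / n,
        mean_dwell_near=float(np.mean(near_runs)) if near_runs else float("nan"),
        mean_dwell_far=float(np.mean(far_runs)) if far_runs else float("nan"),
        n_transitions=n_trans,
    )


def distance_histogram(
    series_by_state: Sequence[DistanceSeries], bins: int = 40
) -> dict:
    """Normalized distance histograms per redox state on shared bins."""
    if not series_by_state:
        raise ValueError("no distance series given")
    pooled = np.concatenate([s.d_o2_com for s in series_by_state])
    edges = np.histogram_bin_edges(pooled, bins=bins)
    out: dict = {"bin_edges": edges.tolist(), "states": {}}
    for s in series_by_state:
        if len(s) == 0:
            raise ValueError("empty distance series")
        density, _ = np.histogram(s.d_o2_com, bins=edges, density=True)
        out["states"][s.state] = density.tolist()
    return out


@dataclass
class PathwayClassSummary:
    """Short/long classification of heme→O2 pathways for one redox state."""

    n_short: int
    n_long: int
    mean_decay_short: float  # nan if class empty
    mean_decay_long: float

    @property
    def fraction_short(self) -> float:
        total = self.n_short + self.n_long
        return self.n_short / total if total else float("nan")

    @property
    def fraction_long(self) -> float:
        total = self.n_short + self.n_long
        return self.n_long / total if total else float("nan")

    def as_dict(self) -> dict:
        return {
            "n_short": self.n_short,
            "n_long": self.n_long,
            "fraction_short": self.fraction_short,
            "fraction_long": self.fraction_long,
            "mean_decay_short": self.mean_decay_short,
            "mean_decay_long": self.mean_decay_long,
        }


def heme_to_o2_pathways(
    frames: Sequence[Frame],
    heme_residue: tuple[str, int, str],
    o2_residue: tuple[str, int, str],
    params=None,
) -> list[Pathway | None]:
    """Best pathway from a heme macrocycle to an O2 molecule, per frame.

    The heme's porphyrin core is the donor (and the conductive set); the
    O2 heavy atoms are the acceptor.  Frames with no route yield None.
    """
    from hemepath.pathway_engine import (
        NoPathwayError,
        PathwayModelParams,
        best_pathway,
        build_tunneling_graph,
    )
    from hemepath.structure_model import (
        detect_hydrogen_bonds,
        perceive_covalent_bonds,
        porphyrin_core_atoms,
    )

    if not frames:
        raise ValueError("need at least one frame")
    params = params or PathwayModelParams()
    results: list[Pathway | None] = []
    for frame in frames:
        bonds = perceive_covalent_bonds(frame)
        hbonds = detect_hydrogen_bonds(frame, bonds)
        donor = porphyrin_core_atoms(frame, heme_residue)
        acceptor = {
            a.atom_index
            for a in frame.atoms
            if a.residue_id == tuple(o2_residue) and not a.is_hydrogen
        }
        if not acceptor:
            raise ValueError(f"O2 residue {o2_residue} not in frame")
        graph = build_tunneling_graph(
            frame, bonds, hbonds, conductive_atom_sets=[donor], params=params
        )
        try:
            pw = best_pathway(
                graph, donor, acceptor, frame=frame,
                donor_residues=[heme_residue],
                acceptor_residues=[o2_residue],
            )
            pw.frame_index = frame.frame_index
            results.append(pw)
        except NoPathwayError:
            results.append(None)
    return results


def classify_o2_pathways(
    pathways: Sequence[Pathway],
) -> PathwayClassSummary:
    """Classify heme→O2 pathways as short (direct jump) or long (mediated).

    A pathway is *short* when no non-cofactor residue mediates it — the
    electron leaves the porphyrin ring and jumps through space straight to
    O2.  It is *long* when the route passes through an intervening residue
    (``route_label`` names it, e.g. ``"His317"``).  Pathways must come from
    the pathway engine with the heme as donor and O2 as acceptor.
    """
    if not pathways:
        raise ValueError("no heme→O2 pathways supplied")
    short = [p for p in pathways if p.route_label == "direct"]
    long_ = [p for p in pathways if p.route_label != "direct"]
    return PathwayClassSummary(
        n_short=len(short),
        n_long=len(long_),
        mean_decay_short=(
            float(np.mean([p.epsilon_tot for p in short])) if short else float("nan")
        ),
        mean_decay_long=(
            float(np.mean([p.epsilon_tot for p in long_])) if long_ else float("nan")
        ),
    )
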