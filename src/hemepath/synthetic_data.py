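"""Synthetic inputs for every analysis stage.

Nothing here imitates a force field; the generators produce the *statistics*
the estimators assume, with known ground truth, so that every stage of the
package can be validated without trajectory data:

- Gaussian energy-gap series consistent with the linear response picture
  (state-dependent means dA ± lambda, variance 2*lambda*kB*T), optionally
  AR(1)-correlated and decomposed over molecular components;
- bimodal gap series from a slowly switching two-regime Markov chain,
  whose mixture variance exceeds the within-regime variance (chi_G > 1);
- two-site O2–cavity distance series from a telegraph (two-state Markov
  jump) process with Gaussian jitter about each mode;
- toy molecular structures with idealized porphyrin macrocycles and
  hand-set bridge geometries whose best tunneling pathway and decay factor
  are known in closed form;
- a brute-force simple-path enumeration oracle for the Dijkstra search.

All generators are deterministic under a fixed seed, and each output
records its seed in metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from hemepath import KB_EV
from hemepath.cavity_analysis import DistanceSeries
from hemepath.marcus_estimators import GapSeries
from hemepath.pathway_engine import (
    NoPathwayError,
    Pathway,
    PathwayModelParams,
    space_decay,
)
from hemepath.structure_model import Atom, Frame, PORPHYRIN_CORE_NAMES

__all__ = [
    "LRAGeneratorSpec",
    "TelegraphSpec",
    "ToyStructure",
    "generate_lra_gaps",
    "generate_bimodal_gaps",
    "generate_two_site_distance",
    "make_toy_structure",
    "porphyrin_template",
    "sample_route_ensemble",
    "brute_force_best_path",
    "random_tunneling_graph",
]


# ---------------------------------------------------------------------------
# Energy-gap generators


@dataclass(frozen=True)
class LRAGeneratorSpec:
    """Specification of an LRA-consistent Gaussian gap generator.

    In the linear response picture the gap in the initial state is
    Normal(delta_A + lambda, 2*lambda*kB*T) and in the final state
    Normal(delta_A - lambda, 2*lambda*kB*T).  ``autocorrelation_time`` (in
    samples) adds AR(1) memory with that decay time; 0 means independent
    samples.  ``components`` optionally splits the gap over named molecular
    components as (fraction of delta_A, fraction of lambda) pairs, each set
    of fractions summing to 1; component variances are proportional to
    their lambda share, so contributions stay individually LRA-consistent.
    """

    delta_A: float  # eV
    lam: float  # eV, reorganization energy
    temperature: float = 310.0  # K
    n_samples: int = 10_000
    autocorrelation_time: float = 0.0  # samples
    seed: int = 0
    dt_ps: float = 1.0
    components: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.autocorrelation_time < 0:
            raise ValueError("autocorrelation_time must be >= 0")
        if self.components is not None:
            fa = sum(f for f, _ in self.components.values())
            fl = sum(f for _, f in self.components.values())
            if not (math.isclose(fa, 1.0, abs_tol=1e-9)
                    and math.isclose(fl, 1.0, abs_tol=1e-9)):
                raise ValueError("component fractions must each sum to 1")
            if any(f < 0 for _, f in self.components.values()):
                raise ValueError("lambda fractions must be nonnegative")

    @property
    def gap_variance(self) -> float:
        """Analytic marginal variance 2*lambda*kB*T, eV^2."""
        return 2.0 * self.lam * KB_EV * self.temperature


def _ar1(rng: np.random.Generator, n: int, sigma: float, tau: float) -> np.ndarray:
    """Zero-mean AR(1) series with marginal std ``sigma`` and decay ``tau``."""
    if sigma == 0.0:
        return np.zeros(n)
    if tau <= 0:
        return rng.normal(0.0, sigma, size=n)
    phi = math.exp(-1.0 / tau)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    innov = rng.normal(0.0, sigma * math.sqrt(1.0 - phi * phi), size=n - 1)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + innov[k - 1]
    return x


def generate_lra_gaps(spec: LRAGeneratorSpec) -> tuple[GapSeries, GapSeries]:
    """Generate an (initial, final) pair of LRA-consistent gap series."""
    times = np.arange(spec.n_samples, dtype=float) * spec.dt_ps
    out: list[GapSeries] = []
    for k, (state, sign) in enumerate((("initial", 1.0), ("final", -1.0))):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, k]))
        mean = spec.delta_A + sign * spec.lam
        if spec.components is None:
            gaps = mean + _ar1(
                rng, spec.n_samples, math.sqrt(spec.gap_variance),
                spec.autocorrelation_time,
            )
            comp = None
        else:
            cols = {}
            for name, (f_a, f_l) in spec.components.items():
                c_mean = f_a * spec.delta_A + sign * f_l * spec.lam
                c_sigma = math.sqrt(f_l * spec.gap_variance)
                cols[name] = c_mean + _ar1(
                    rng, spec.n_samples, c_sigma, spec.autocorrelation_time
                )
            comp = pd.DataFrame(cols)
            gaps = comp.sum(axis=1).to_numpy()
        out.append(
            GapSeries(
                times=times, gaps=gaps, state=state, components=comp,
                temperature=spec.temperature,
                metadata={"seed": spec.seed, "generator": "lra",
                          "delta_A": spec.delta_A, "lambda": spec.lam},
            )
        )
    return out[0], out[1]


def generate_bimodal_gaps(
    spec_a: LRAGeneratorSpec,
    spec_b: LRAGeneratorSpec,
    switch_prob: float,
    state: str = "initial",
    n_samples: int | None = None,
    seed: int = 0,
) -> GapSeries:
    """Gap series switching slowly between two Gaussian regimes.

    A symmetric two-state Markov chain with per-sample switching
    probability ``switch_prob`` selects the active regime; samples are
    drawn from that regime's LRA distribution for the requested redox
    state.  When the regime means differ, the mixture variance exceeds the
    within-regime variance, which inflates the variance reorganization
    energies relative to the Stokes one (chi_G > 1).
    """
    if not (0.0 < switch_prob < 1.0):
        raise ValueError("switch_prob must lie in (0, 1)")
    sign = {"initial": 1.0, "final": -1.0}[state]
    n = n_samples if n_samples is not None else spec_a.n_samples
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    regime = np.empty(n, dtype=int)
    regime[0] = rng.integers(2)
    flips = rng.random(n - 1) < switch_prob
    regime[1:] = (regime[0] + np.cumsum(flips)) % 2
    means = np.array([
        spec_a.delta_A + sign * spec_a.lam,
        spec_b.delta_A + sign * spec_b.lam,
    ])
    sigmas = np.array([
        math.sqrt(spec_a.gap_variance), math.sqrt(spec_b.gap_variance)
    ])
    gaps = rng.normal(means[regime], sigmas[regime])
    return GapSeries(
        times=np.arange(n, dtype=float) * spec_a.dt_ps,
        gaps=gaps,
        state=state,
        temperature=spec_a.temperature,
        metadata={"seed": seed, "generator": "bimodal",
                  "regime_fraction_a": float(np.mean(regime == 0))},
    )


# ---------------------------------------------------------------------------
# Two-site distance generator


@dataclass(frozen=True)
class TelegraphSpec:
    """Two-site telegraph process for the O2–cavity distance.

    ``rate_leave_near``/``rate_leave_far`` are switching rates in 1/ps;
    the stationary near-site occupancy is
    rate_leave_far / (rate_leave_near + rate_leave_far).
    """

    mode_near: float = 2.5  # Å
    mode_far: float = 4.3  # Å
    width_near: float = 0.25  # Å
    width_far: float = 0.25  # Å
    rate_leave_near: float = 1.0 / 3000.0  # 1/ps, few-ns dwell
    rate_leave_far: float = 1.0 / 3000.0
    n_samples: int = 5000
    dt_ps: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode_near >= self.mode_far:
            raise ValueError("mode_near must be below mode_far")
        if self.rate_leave_near <= 0 or self.rate_leave_far <= 0:
            raise ValueError("switching rates must be positive")
        if min(self.width_near, self.width_far) <= 0:
            raise ValueError("widths must be positive")

    @property
    def stationary_near_fraction(self) -> float:
        return self.rate_leave_far / (self.rate_leave_near + self.rate_leave_far)


def generate_two_site_distance(
    spec: TelegraphSpec, state: str = "initial"
) -> DistanceSeries:
    """Simulate the telegraph distance process (distances clipped at 0).

    The realized fraction of samples in the near site is stored in
    ``metadata["fraction_near_true"]`` for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    p_nf = -math.expm1(-spec.rate_leave_near * spec.dt_ps)
    p_fn = -math.expm1(-spec.rate_leave_far * spec.dt_ps)
    near = np.empty(spec.n_samples, dtype=bool)
    near[0] = rng.random() < spec.stationary_near_fraction
    u = rng.random(spec.n_samples - 1)
    for k in range(1, spec.n_samples):
        p = p_nf if near[k - 1] else p_fn
        near[k] = ~near[k - 1] if u[k - 1] < p else near[k - 1]
    modes = np.where(near, spec.mode_near, spec.mode_far)
    widths = np.where(near, spec.width_near, spec.width_far)
    d = np.abs(modes + rng.normal(0.0, 1.0, spec.n_samples) * widths)
    return DistanceSeries(
        times=np.arange(spec.n_samples, dtype=float) * spec.dt_ps,
        d_o2_com=d,
        state=state,
        metadata={
            "seed": spec.seed,
            "fraction_near_true": float(np.mean(near)),
            "n_transitions_true": int(np.count_nonzero(near[1:] != near[:-1])),
        },
    )


# ---------------------------------------------------------------------------
# Toy structures with closed-form best pathways


def porphyrin_template() -> dict[str, tuple[float, float, float]]:
    """Idealized planar porphyrin macrocycle + Fe, in the z=0 plane.

    Bond lengths are within normal ranges (N–Ca 1.35, Ca–Cb 1.41,
    Cb–Cb 1.36, Ca–meso 1.40, Fe–N 2.05 Å) and all non-bonded intra-ring
    distances exceed the covalent perception cutoffs.
    """
    coords: dict[str, tuple[float, float, float]] = {"FE": (0.0, 0.0, 0.0)}
    # local pyrrole (axis along +x): N, Ca x2, Cb x2
    local = {
        "N": (2.05, 0.0),
        "C1": (2.85, -1.09),  # alpha carbon on the -angle side
        "C4": (2.85, 1.09),
        "C2": (4.20, -0.68),  # beta carbons
        "C3": (4.20, 0.68),
    }
    for k, ring in enumerate("ABCD"):
        theta = math.radians(90.0 * k)
        c, s = math.cos(theta), math.sin(theta)
        for key, (x, y) in local.items():
            name = f"{key[0]}{ring}" if key == "N" else f"{key}{ring}"
            coords[name] = (x * c - y * s, x * s + y * c, 0.0)
    # meso carbons: CHB between rings A and B (45 deg), etc.
    meso_angle = {"CHB": 45.0, "CHC": 135.0, "CHD": 225.0, "CHA": 315.0}
    for name, deg in meso_angle.items():
        t = math.radians(deg)
        coords[name] = (3.43 * math.cos(t), 3.43 * math.sin(t), 0.0)
    return coords


def _heme_atoms(
    resnumber: int,
    chain: str,
    origin: tuple[float, float, float],
    start_index: int,
) -> list[Atom]:
    ox, oy, oz = origin
    template = porphyrin_template()
    atoms = []
    names = list(PORPHYRIN_CORE_NAMES) + ["FE"]
    for k, name in enumerate(names):
        x, y, z = template[name]
        atoms.append(
            Atom(
                atom_index=start_index + k,
                name=name,
                element="FE" if name == "FE" else name[0],
                residue_name="HEM",
                residue_number=resnumber,
                chain_id=chain,
                coordinates=(x + ox, y + oy, z + oz),
            )
        )
    return atoms


@dataclass
class ToyStructure:
    """A toy system and the closed-form ground truth of its best pathway.

    ``donor_atoms``/``acceptor_atoms`` override the residue-based atom sets
    when the blueprint needs finer control (e.g. two halves of a single
    macrocycle); ``conductive_sets`` lists the atom sets whose internal
    edges are fully conductive.
    """

    frame: Frame
    donor_residue: tuple[str, int, str]
    acceptor_residue: tuple[str, int, str]
    expected_epsilon: float
    expected_route: str
    expected_counts: tuple[int, int, int]  # (N_c, N_hb, N_ts)
    description: str = ""
    donor_atoms: set[int] | None = None
    acceptor_atoms: set[int] | None = None
    conductive_sets: list[set[int]] | None = None

    def write(self, path) -> None:
        from hemepath.structure_model import write_frames

        write_frames([self.frame], path)


_MESO_XY = (3.43 * math.cos(math.radians(45.0)),
            3.43 * math.sin(math.radians(45.0)))  # CHB position


def _bridge_atoms(
    resname: str,
    resnumber: int,
    atom_names: Sequence[str],
    zs: Sequence[float],
    start_index: int,
    xy: tuple[float, float] = _MESO_XY,
) -> list[Atom]:
    return [
        Atom(
            atom_index=start_index + k,
            name=name,
            element=name[0],
            residue_name=resname,
            residue_number=resnumber,
            chain_id="A",
            coordinates=(xy[0], xy[1], z),
        )
        for k, (name, z) in enumerate(zip(atom_names, zs))
    ]


def make_toy_structure(
    kind: str,
    params: PathwayModelParams | None = None,
    **options,
) -> ToyStructure:
    """Build a toy system with a known optimal tunneling pathway.

    Blueprints
    ----------
    ``"conductive"``
        A single heme; donor and acceptor are disjoint halves of its
        macrocycle, connected purely by conductive edges: eps_tot = 1.
    ``"bridge"``
        Two stacked hemes joined by a serine-like bridge: one hydrogen
        bond of length ``r_h`` (default 2.9 Å), two covalent steps and one
        through-space jump of length ``r_jump`` (default 3.0 Å):
        eps_tot = eps_hb(r_h) * eps_c^2 * eps_ts(r_jump).
    ``"two_route"``
        Two stacked hemes with competing two-atom bridges; ``bridges`` is
        a sequence of (resname, resnumber, jump1, jump2) and the ground
        truth is the largest closed-form product
        eps_ts(jump1) * eps_c * eps_ts(jump2).
    ``"o2_short"``
        A heme with an O2 probe a direct through-space jump away
        (``r_jump`` default 3.4205 Å, i.e. eps close to 0.065).
    ``"o2_long"``
        A heme, a histidine-like bridge, then O2: jump/covalent/jump with
        ``jump1``/``jump2`` defaults 3.2132 Å (eps close to 0.004).
    """
    params = params or PathwayModelParams()
    eps_c = params.epsilon_c

    if kind == "conductive":
        atoms = _heme_atoms(1, "A", (0.0, 0.0, 0.0), 0)
        frame = Frame(frame_index=0, atoms=atoms)
        by_name = {a.name: a.atom_index for a in atoms}
        ring_a = {by_name[n] for n in ("NA", "C1A", "C2A", "C3A", "C4A")}
        ring_c = {by_name[n] for n in ("NC", "C1C", "C2C", "C3C", "C4C")}
        core = {by_name[n] for n in PORPHYRIN_CORE_NAMES}
        return ToyStructure(
            frame=frame,
            donor_residue=("A", 1, "HEM"),
            acceptor_residue=("A", 1, "HEM"),
            expected_epsilon=1.0,
            expected_route="direct",
            expected_counts=(0, 0, 0),
            description="single macrocycle, conductive-only route",
            donor_atoms=ring_a,
            acceptor_atoms=ring_c,
            conductive_sets=[core],
        )

    if kind == "bridge":
        r_h = options.get("r_h", 2.9)
        r_jump = options.get("r_jump", 3.0)
        from hemepath.pathway_engine import hbond_decay

        heme1 = _heme_atoms(1, "A", (0.0, 0.0, 0.0), 0)
        n1 = len(heme1)
        # serine-like bridge above the NA nitrogen of heme1
        na = (2.05, 0.0)
        bridge = [
            Atom(n1, "OG", "O", "SER", 10, "A", (na[0], na[1], r_h)),
            Atom(n1 + 1, "HG", "H", "SER", 10, "A", (na[0], na[1], r_h - 0.96)),
            Atom(n1 + 2, "CB", "C", "SER", 10, "A", (na[0], na[1], r_h + 1.43)),
            Atom(n1 + 3, "CA", "C", "SER", 10, "A",
                 (na[0] + 1.08, na[1], r_h + 1.43 + 1.08)),
        ]
        ca_z = r_h + 1.43 + 1.08
        heme2_origin = (1.08, 0.0, ca_z + r_jump)
        heme2 = _heme_atoms(2, "A", heme2_origin, n1 + 4)
        frame = Frame(frame_index=0, atoms=heme1 + bridge + heme2)
        eps = hbond_decay(r_h, params) * eps_c**2 * space_decay(r_jump, params)
        return ToyStructure(
            frame=frame,
            donor_residue=("A", 1, "HEM"),
            acceptor_residue=("A", 2, "HEM"),
            expected_epsilon=eps,
            expected_route="Ser10",
            expected_counts=(2, 1, 1),
            description="H-bond + 2 covalent + 1 jump via a serine bridge",
        )

    if kind == "two_route":
        bridges = options.get(
            "bridges",
            (("TRP", 378, 3.0, 3.0), ("PHE", 348, 3.3, 3.3)),
        )
        span = options.get("span", 7.0)  # inter-heme plane separation, Å
        bond_len = 1.45
        if span <= params.ts_max_distance:
            raise ValueError("span must exceed ts_max_distance (no direct jump)")
        meso_angles = (45.0, 135.0, 225.0, 315.0)
        if len(bridges) > len(meso_angles):
            raise ValueError("at most 4 bridges supported")
        heme1 = _heme_atoms(1, "A", (0.0, 0.0, 0.0), 0)
        atoms = list(heme1)
        best_eps, best_route = -1.0, "direct"
        gap = span - bond_len  # vertical budget for the two jumps
        for (resname, resnum, j1, j2), deg in zip(bridges, meso_angles):
            # bridge column sits at horizontal offset h outward of the meso
            # carbon; h is solved so both jump lengths are met exactly:
            #   sqrt(j1^2 - h^2) + sqrt(j2^2 - h^2) = span - bond_len
            if j1 + j2 < gap:
                raise ValueError(
                    f"bridge {resname}{resnum}: jumps too short to span the "
                    "inter-heme gap"
                )
            from scipy.optimize import brentq

            def slack(h: float, j1=j1, j2=j2) -> float:
                return (math.sqrt(j1**2 - h**2) + math.sqrt(j2**2 - h**2)
                        - gap)

            h_max = min(j1, j2) * (1.0 - 1e-12)
            h = 0.0 if abs(slack(0.0)) < 1e-12 else brentq(slack, 0.0, h_max)
            z1 = math.sqrt(j1**2 - h**2)
            t = math.radians(deg)
            xy = ((3.43 + h) * math.cos(t), (3.43 + h) * math.sin(t))
            atoms += _bridge_atoms(
                resname, resnum, ("CG", "CD1"), (z1, z1 + bond_len),
                len(atoms), xy=xy,
            )
            eps = space_decay(j1, params) * eps_c * space_decay(j2, params)
            if eps > best_eps:
                best_eps, best_route = eps, f"{resname.capitalize()}{resnum}"
        atoms += _heme_atoms(2, "A", (0.0, 0.0, span), len(atoms))
        frame = Frame(frame_index=0, atoms=atoms)
        return ToyStructure(
            frame=frame,
            donor_residue=("A", 1, "HEM"),
            acceptor_residue=("A", 2, "HEM"),
            expected_epsilon=best_eps,
            expected_route=best_route,
            expected_counts=(1, 0, 2),
            description="competing jump/covalent/jump bridges between hemes",
        )

    if kind == "o2_short":
        r_jump = options.get("r_jump", 3.4205)
        heme = _heme_atoms(2, "A", (0.0, 0.0, 0.0), 0)
        n = len(heme)
        o2 = [
            Atom(n, "O1", "O", "OXY", 500, "A",
                 (_MESO_XY[0], _MESO_XY[1], r_jump)),
            Atom(n + 1, "O2", "O", "OXY", 500, "A",
                 (_MESO_XY[0], _MESO_XY[1], r_jump + 1.21)),
        ]
        frame = Frame(frame_index=0, atoms=heme + o2)
        return ToyStructure(
            frame=frame,
            donor_residue=("A", 2, "HEM"),
            acceptor_residue=("A", 500, "OXY"),
            expected_epsilon=space_decay(r_jump, params),
            expected_route="direct",
            expected_counts=(0, 0, 1),
            description="direct porphyrin-to-O2 jump (short pathway)",
        )

    if kind == "o2_long":
        j1 = options.get("jump1", 3.2132)
        j2 = options.get("jump2", 3.2132)
        heme = _heme_atoms(2, "A", (0.0, 0.0, 0.0), 0)
        n = len(heme)
        # carbon-only bridge atoms: with no hydrogens in the frame the
        # permissive H-bond rule would otherwise let a ring nitrogen
        # hydrogen-bond straight to O2
        his = _bridge_atoms("HIS", 317, ("CG", "CD2"), (j1, j1 + 1.38), n)
        o2_z = j1 + 1.38 + j2
        o2 = [
            Atom(n + 2, "O1", "O", "OXY", 500, "A",
                 (_MESO_XY[0], _MESO_XY[1], o2_z)),
            Atom(n + 3, "O2", "O", "OXY", 500, "A",
                 (_MESO_XY[0], _MESO_XY[1], o2_z + 1.21)),
        ]
        frame = Frame(frame_index=0, atoms=heme + his + o2)
        eps = space_decay(j1, params) * eps_c * space_decay(j2, params)
        return ToyStructure(
            frame=frame,
            donor_residue=("A", 2, "HEM"),
            acceptor_residue=("A", 500, "OXY"),
            expected_epsilon=eps,
            expected_route="His317",
            expected_counts=(1, 0, 2),
            description="heme -> histidine -> O2 (long pathway)",
        )

    raise ValueError(f"unknown blueprint kind {kind!r}")


def sample_route_ensemble(
    n_frames: int,
    fractions: Mapping[str, float] | None = None,
    seed: int = 0,
    jitter: float = 0.03,
    short_jump: float = 3.0,
    long_jump: float = 3.4,
) -> tuple[list[Frame], list[str]]:
    """Frames whose best route follows prescribed residue occupancies.

    Each frame is a two-heme system with one two-atom bridge per route
    label; the route drawn for the frame gets the short jumps (plus
    Gaussian jitter), the others the long ones, so the engine's best
    pathway lands on the drawn route.  Returns frames and the ground-truth
    label sequence.  Default fractions follow the strongly
    tryptophan-dominated route split characteristic of NOX5-type inter-heme
    transfer (92%/7%/1%).
    """
    fractions = dict(fractions or {"Trp378": 0.92, "Phe348": 0.07,
                                   "Trp392": 0.01})
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("route fractions must sum to 1")
    labels = list(fractions)
    resmap = {}
    for label in labels:
        resname, resnum = label[:3].upper(), int(label[3:])
        resmap[label] = (resname, resnum)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    drawn = rng.choice(len(labels), size=n_frames, p=[fractions[l] for l in labels])
    frames, truth = [], []
    for k in range(n_frames):
        winner = labels[drawn[k]]
        bridges = []
        for label in labels:
            resname, resnum = resmap[label]
            base = short_jump if label == winner else long_jump
            # keep jumps within the feasible range for the default span
            j1 = float(np.clip(base + rng.normal(0.0, jitter), 2.85, 4.5))
            j2 = float(np.clip(base + rng.normal(0.0, jitter), 2.85, 4.5))
            bridges.append((resname, resnum, j1, j2))
        toy = make_toy_structure("two_route", bridges=tuple(bridges))
        frame = Frame(frame_index=k, atoms=toy.frame.atoms, time=20.0 * k)
        frames.append(frame)
        truth.append(winner)
    return frames, truth


# ---------------------------------------------------------------------------
# Brute-force pathway oracle


def brute_force_best_path(
    graph: nx.Graph,
    donor_atoms: set,
    acceptor_atoms: set,
    max_nodes: int = 12,
) -> Pathway:
    """Exhaustive simple-path enumeration oracle for the best pathway.

    Enumerates every simple path from any donor to any acceptor, scores it
    by the additive weight sum used by the engine, and applies the same
    tie-break (lexicographically smallest node sequence).  Only feasible on
    small graphs; refuses more than ``max_nodes`` nodes.
    """
    if graph.number_of_nodes() > max_nodes:
        raise ValueError(
            f"graph has {graph.number_of_nodes()} nodes; oracle limited to "
            f"{max_nodes}"
        )
    donor_atoms, acceptor_atoms = set(donor_atoms), set(acceptor_atoms)
    best_key: tuple[float, tuple] | None = None
    for donor in sorted(donor_atoms):
        if donor not in graph:
            continue
        if donor in acceptor_atoms:
            raise ValueError("donor and acceptor sets must be disjoint")
        for acceptor in sorted(acceptor_atoms):
            if acceptor not in graph:
                continue
            for path in nx.all_simple_paths(graph, donor, acceptor):
                # score prefixes ending at the *first* acceptor on the path
                cut = next(
                    i for i, node in enumerate(path) if node in acceptor_atoms
                )
                path = path[: cut + 1]
                weight = 0.0
                for u, v in zip(path, path[1:]):
                    weight += graph[u][v]["weight"]
                key = (weight, tuple(path))
                if best_key is None or key < best_key:
                    best_key = key
    if best_key is None:
        raise NoPathwayError("no pathway connects donor and acceptor")
    nodes = list(best_key[1])
    decays = [graph[u][v]["decay"] for u, v in zip(nodes, nodes[1:])]
    types = [graph[u][v]["type"] for u, v in zip(nodes, nodes[1:])]
    pathway = Pathway(
        atom_indices=nodes,
        edge_types=types,
        edge_decays=decays,
        epsilon_tot=math.prod(decays),
    )
    pathway.n_covalent = types.count("covalent")
    pathway.n_hbond = types.count("hbond")
    pathway.n_through_space = types.count("through_space")
    return pathway


def random_tunneling_graph(
    n_nodes: int = 10,
    edge_prob: float = 0.35,
    seed: int = 0,
) -> nx.Graph:
    """Random decay graph for engine-vs-oracle equivalence tests.

    Edges get decays log-uniform in [1e-3, 1] (conductive edges, eps = 1
    exactly, appear with small probability) and the same ``weight``
    attribute the engine consumes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    graph = nx.Graph()
    graph.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() >= edge_prob:
                continue
            if rng.random() < 0.1:
                eps, etype = 1.0, "conductive"
            else:
                eps = float(10.0 ** rng.uniform(-3.0, 0.0))
                etype = str(rng.choice(
                    ["covalent", "hbond", "through_space"]
                ))
            graph.add_edge(i, j, decay=eps, type=etype,
                           weight=-math.log(eps))
    return graph
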