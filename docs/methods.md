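# Methods

This note documents the models implemented in `hemepath`, the defaults and
the numerical choices, and what the synthetic-data generators do and do not
emulate.

## Tunneling pathway model

The coupling between two heme cofactors is H_if = H_if^contact · ε_tot.
ε_tot multiplies per-step decays along one pathway: ε_c = 0.6 per covalent
bond, ε_hb = 0.36·exp[−β_S(R_H − 2.8)] per hydrogen bond (R_H = donor to
acceptor heavy-atom distance, Å), ε_ts = 0.6·exp[−β_S(R_S − 1.4)] per
through-space jump. β_S defaults to 1.1 Å⁻¹, the reparametrized value that
agrees better with quantum-chemical couplings than the original 1.7 Å⁻¹
(both available through `PathwayModelParams`). H_if^contact defaults to
0.177829 eV, the conventional close-contact coupling; the package also
exposes the exact Planck conversion h·ν for arbitrary frequencies (note
that h · 4.3×10¹³ Hz = 0.177834 eV — the 0.177829 constant corresponds to
ν = 4.29988×10¹³ Hz, and the two agree only to the 2-significant-figure
precision of the rounded frequency).

Graph construction: nodes are heavy atoms (hydrogens enter only through
hydrogen-bond geometry, since both R_H and R_S are heavy-atom distances).
Covalent edges carry ε_c; any edge whose endpoints lie in the same
conductive set — by default the 24-atom porphyrin macrocycle of each heme —
carries ε = 1 exactly; hydrogen-bond pairs carry ε_hb(R_H); all remaining
heavy-atom pairs within `ts_max_distance` (default 6.0 Å) carry ε_ts(R_S).
When one pair qualifies for several types the largest decay wins and the
type is recorded accordingly. ε_hb and ε_ts are capped at ε_c so that no
step outperforms a covalent bond at sub-offset distances; uncapped values
above 0.6 at very short range would be unphysical in this model. The iron
and Fe–N(axial His) bonds are ordinary covalent edges, not conductive ones:
the conductive region is the aromatic macrocycle only.

Best-path search: maximizing Π ε is a shortest path under w = −ln ε ≥ 0,
so Dijkstra is exact; conductive edges have weight 0. The search runs from
an implicit source fanning to all donor atoms and stops at the first
settled acceptor atom. Priority keys are (cumulative weight, node
sequence), which makes the result deterministic: among equal-weight optima
the lexicographically smallest atom-index sequence wins. The brute-force
oracle in `synthetic_data` enumerates all simple paths with the same edge
weights and the same tie-break, so engine/oracle agreement is exact
(identical node sequence and identical ε_tot floating-point value) on
every graph small enough to enumerate.

Bond perception: a pair is covalently bonded when its distance is at most
the sum of covalent radii plus 0.4 Å (per-element-pair overrides
supported); each hydrogen bonds only to its nearest heavy atom. Hydrogen
bonds are recorded between N/O/S heavy atoms within 3.5 Å; when the frame
contains hydrogens, donors must carry an attached H and the donor–H–acceptor
angle must be ≥ 120°; hydrogen-free frames (common in reduced toy systems)
fall back to a distance-only criterion with every N/O/S treated as a
potential donor. These two defaults are package decisions — force-field
topologies, where available, are the more rigorous source of connectivity.

## LRA/Marcus estimators

Sign convention, fixed package-wide: ΔE = E_f − E_i at a single nuclear
configuration. Under the linear response approximation the gap is Gaussian
in both redox states with equal curvature and

    ΔA⁰    = (⟨ΔE⟩_i + ⟨ΔE⟩_f)/2
    λ^St   = (⟨ΔE⟩_i − ⟨ΔE⟩_f)/2
    λ_x^var = var(ΔE_x)/(2 k_B T),   k_B = 8.617333×10⁻⁵ eV/K
    χ_G    = (λ_i^var + λ_f^var)/(2 λ^St)

Variances are population variances (divisor n): immaterial at trajectory
sample counts, fixed for bit-reproducibility. Default temperature 310 K.
A negative λ^St triggers a warning (LRA breakdown or swapped state labels).
χ_G ≈ 1 indicates ergodic, LRA-consistent sampling; slow conformational
switching inflates the variance estimators relative to the Stokes one and
pushes χ_G above 1.

Block analysis treats segments as independent: each segment discards its
first 20 ns (20 000 ps, configurable) as equilibration, parameters are
estimated per segment, and the report is the block mean with uncertainty
defined as 2× the standard error of the mean over blocks. "Uncertainty"
is not defined more precisely by the error-bar convention this mirrors;
2×SEM is this package's fixed definition.

Component decomposition applies the two mean-gap estimators column-wise to
a per-component decomposition of ΔE (e.g. transmembrane domain,
dehydrogenase domain, environment, cofactors); linearity of the mean makes
contributions sum to the totals exactly. Gap series loaded from CSV/TSV
accept eV or kcal/mol (1 eV = 23.0605 kcal/mol).

Inner-sphere reorganization follows the four-point scheme on cofactor
energies: λ^is = (E_gR^O − E_gO^O) + (E_gO^R − E_gR^R), the sum of the two
relaxation energies. For a single pair of identical displaced harmonic
wells (force constant k, displacement d) each relaxation energy is k·d²/2,
so λ^is = k·d² — the sum covers both chemically identical cofactors of the
self-exchange pair, each reorganizing once. Input energies are
user-supplied (typically from DFT); the package only implements the
combination rule. No mutual-polarization cross term is modelled, and no
rate constants are computed. Reorganization energies from non-polarizable
force fields are known to be overestimated by roughly 30%; a scalar rescale
is left to the user rather than applied silently.

Bimodality in gap series is reported descriptively (histogram plus an
optional two-component Gaussian-mixture summary); no automatic mode
assignment is made, since slow collective modes rarely admit a clean
structural label.

## O₂ cavity analysis

The O₂ position is summarized by the distance between the geometric center
(mass-weighted optional; geometric is the default because no convention is
established) of a cavity selection — by default the heavy atoms of the
arginine/histidine pocket residues — and the O₂ molecule. Two-site
occupancy uses a boundary of 3.4 Å, the midpoint of the 2.5/4.3 Å mode
centers; dwell times come from contiguous runs, transitions from label
changes, and dwell-time-weighted occupancy equals fraction occupancy by
construction. Heme→O₂ pathways are classified *short* when no non-cofactor
residue mediates the route (direct porphyrin-to-O₂ jump) and *long*
otherwise (e.g. mediated by a cavity histidine); short routes being
geometrically shorter, their mean decay exceeds the long-route mean
whenever the geometry says it should — the classification adds no
independent physics beyond the decay model.

## Synthetic data: what it does and does not emulate

`generate_lra_gaps` draws gaps from the exact LRA picture:
Normal(ΔA ± λ, 2λk_BT) in the initial/final state, optionally
AR(1)-correlated, optionally decomposed over named components whose means
and variances are fractions of the totals. `generate_bimodal_gaps` switches
between two such regimes with a slow symmetric Markov chain; its default
study condition is a 0.3 eV regime separation, which yields χ_G ≈ 1.4 —
the moderate non-ergodicity regime characteristic of slow membrane and
solvation modes. `generate_two_site_distance` is a two-state telegraph
process (modes 2.5/4.3 Å, widths 0.25 Å, few-ns dwell times at the 20 ps
sampling interval) with Gaussian jitter, clipped at zero distance.

Toy structures use idealized planar porphyrin macrocycles with standard
PDB heme atom names (bond lengths 1.35–1.45 Å, Fe–N 2.05 Å) and hand-set
bridge geometries, so the optimal pathway decay is available in closed
form: a serine bridge giving hydrogen-bond + covalent + jump routes,
competing two-atom bridges whose jump lengths are met exactly by solving
for a horizontal column offset, and O₂ probes placed for direct (ε ≈ 0.065)
or histidine-mediated (ε ≈ 0.004) routes.

These generators reproduce the *statistics* the estimators assume, not the
physics that produces them: no force field, no membrane, no protein
flexibility, no correlation between pathway geometry and energy gaps, and
Gaussian regimes by construction. Passing tests therefore demonstrate that
the estimators and the search are correct and unbiased under their stated
assumptions — not that those assumptions hold for any particular protein.
Real trajectories can violate LRA (χ_G far from 1), and real pathway
ensembles mix route geometries continuously rather than discretely.

## Numerical choices and limitations

- Tie-breaks: lexicographically smallest node sequence everywhere; outputs
  are byte-reproducible for identical inputs and seeds.
- All generators take integer seeds and derive independent per-stream
  `SeedSequence`s; outputs record their seed in metadata.
- `ts_max_distance` bounds graph size; jumps longer than 6 Å contribute
  decays below ~4×10⁻³ per step and never alter best paths in practice.
- Altloc handling: only blank/'A' conformers are read. Residue identity is
  (chain, number, name). PDB coordinates round-trip to 10⁻³ Å.
- The brute-force oracle refuses graphs above 12 nodes; inside conductive
  macrocycles the simple-path count grows factorially, so toy fixtures are
  validated against closed-form decay products instead of enumeration.
- Multi-path quantum interference is outside the model: R_coh is a
  classical coherence measure computed from pathway decays only.
- Solvent molecules participate in pathways only if explicitly selected.
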