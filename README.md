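# hemepath

Post-simulation analysis of transmembrane heme-to-heme electron transfer,
as in NADPH oxidases (NOX): semi-empirical electron-tunneling pathway
search on trajectory snapshots, Marcus/linear-response estimation of
electron-transfer (ET) thermodynamics from vertical energy-gap series,
coupling-coherence statistics, and two-site analysis of the O₂-binding
cavity next to the terminal heme.

The package is aimed at computational chemists who already have molecular
dynamics output (multi-model PDB snapshots, energy-gap time series,
distance series) and want the downstream ET analysis to be reproducible
and testable. A synthetic-data module generates statistically faithful
stand-ins for every input, so the whole pipeline is validated without the
original trajectories.

## The models

**Tunneling pathways.** The electronic coupling between donor and acceptor
hemes is written as H_if = H_if^contact · ε_tot, where ε_tot is the product
of per-step decay factors along a pathway through the intervening medium:

- covalent bond: ε_c = 0.6
- hydrogen bond: ε_hb = 0.36 · exp[−β_S (R_H − 2.8 Å)]
- through-space jump: ε_ts = 0.6 · exp[−β_S (R_S − 1.4 Å)]

with β_S = 1.1 Å⁻¹. Covalent bonds inside each porphyrin macrocycle are
fully conductive (ε = 1), so results do not depend on which macrocycle atom
is chosen as donor or acceptor. The best pathway maximizes Π ε, found as a
Dijkstra shortest path under the additive weight −ln ε. Over an ensemble
of snapshots the coherence ratio R_coh = ⟨ε⟩²/⟨ε²⟩ distinguishes
average-dominated (≈1) from fluctuation-dominated (≈0.5) tunneling.

**Marcus/LRA estimators.** With the vertical energy gap ΔE = E_f − E_i
sampled in both redox states, the linear response approximation gives

- reaction free energy ΔA⁰ = (⟨ΔE⟩_i + ⟨ΔE⟩_f)/2
- Stokes reorganization energy λ^St = (⟨ΔE⟩_i − ⟨ΔE⟩_f)/2
- variance reorganization energy λ_x^var = var(ΔE_x)/(2 k_B T)
- non-ergodicity factor χ_G = (λ_i^var + λ_f^var)/(2 λ^St), ≈1 when ergodic

Block analysis over independent trajectory segments (default: discard the
first 20 ns of each) reports means with 2× the standard error over blocks.

**O₂ cavity.** The distance between O₂ and the cavity's center of mass is
bimodal (modes near 2.5 and 4.3 Å); occupancies, dwell times and
transitions are measured against a 3.4 Å boundary, and heme→O₂ pathways
are classified short (direct porphyrin-to-O₂ jump) vs long (mediated by an
intervening residue such as a cavity histidine).

## Worked example

```sh
hemepath simulate structure --blueprint two_route --out demo
hemepath pathways --pdb demo/toy_two_route.pdb \
    --donor A:1:HEM --acceptor A:2:HEM --out demo/paths.tsv
hemepath coupling-stats --paths demo/paths.tsv --out demo/stats.json
```

prints

```
wrote demo/toy_two_route.pdb (expected eps_tot = 6.3935e-03)
1/1 frames with a pathway
<eps> = 6.394e-03, R_coh = 1.00
```

The toy system is two stacked hemes bridged by a tryptophan-like and a
phenylalanine-like side chain; the engine picks the tryptophan route whose
jump/covalent/jump product (ε_ts(3.0 Å) · 0.6 · ε_ts(3.0 Å) ≈ 6.39×10⁻³)
is the closed-form optimum, and with a single frame the ensemble is fully
coherent (R_coh = 1). The same flow applies to real multi-model PDB
trajectories.

For the thermodynamics:

```sh
hemepath simulate gaps --seed 5 --n 100000 --delta-a -0.28 --lambda 1.04 --out demo
hemepath marcus --initial demo/gaps_initial.csv --final demo/gaps_final.csv \
    --discard-ps 0 --out demo/et.json
```

prints

```
dA0 = -0.280 eV, lambda_St = 1.040 eV, chi_G = 1.00
```

i.e. the estimators recover the generator's ground truth (exergonic
transfer, ~1 eV outer-sphere reorganization, ergodic sampling).

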