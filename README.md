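# parabind

Quantitative analysis of cooperative ParA dimer assembly on type Ia
partition promoters.

Low-copy bacterial plasmids (the F plasmid is the canonical case) are
segregated by ParABS partition systems whose *parAB* operon is
transcriptionally autoregulated: the ParA ATPase binds hexamer motifs
(consensus 5'-CTTTGC) in its own promoter through an N-terminal winged-HTH
domain. `parabind` implements, as a tested pipeline over synthetic data,
the full quantitative chain by which such a promoter's organization and
occupancy can be analyzed:

- **Motif architecture** — scan both strands for hexamer motifs at a
  mismatch tolerance, pair plus/minus hits into inverted repeats (IRs)
  under a 26–29 bp spacer constraint, classify overlapping-IR promoter
  architectures, and quantify motif conservation with a position frequency
  matrix and per-column information content
  (IC_j = 2 + Σ_b p_bj log₂ p_bj, in bits).
- **SPR stoichiometry and kinetics** — closed-form 1:1 Langmuir sensorgram
  model, R(t) = R_eq(1 − e^(−(k_a C + k_d)t)) with
  R_eq = R_max·k_a C/(k_a C + k_d), per-concentration least-squares fits,
  and the mass-proportional stoichiometry S = R_max/[(MW_A/MW_L)·R_L]
  counting analyte monomers per immobilized DNA.
- **Equilibrium titrations** — Hill isotherm θ = P^h/(K_D^h + P^h) for
  cooperative gel-shift data, and the quadratic ligand-depletion model for
  tight binding near the probe concentration, with deterministic
  multi-start fitting and fold-stimulation ratios.
- **Curved-DNA geometry** — planar-arc B-DNA model (rise 0.34 nm/bp,
  10.5 bp/turn): total curvature, chord distance between motif centers,
  helical-face offset, and a bend-angle scan testing compatibility with the
  ~10–11 nm span between the two wHTH domains of a ParA dimer.
- **Trajectory flexibility** — weighted Kabsch superposition, backbone RMSD
  series, per-residue mass-weighted fluctuations about the iterated mean
  structure, simulated B-factors B = (8π²/3)⟨Δr²⟩, flexible-region calling
  and core-superposed marker displacement.
- **Thermal stability** — two-state van't Hoff melt curves over dual
  wavelength (330/350 nm) fluorescence channels and Tm extraction from the
  first derivative of the ratio, with condition-to-condition ΔTm tables.

A seeded synthetic-data module (`parabind.synthetic`) generates every
input the analyses consume — promoter sequences with a truth table,
dose-response sensorgrams, titrations, melt curves and coarse CA
trajectories — with defaults mirroring the F-plasmid system (73% AT
promoter, three direct hexamers at 13 bp intervals plus two inverted
half-sites, three dimers bound at SPR saturation, K_D near 100 nM).

## Worked example

```python
from parabind import synthetic, motifs, binding, geometry, thermal

arch = synthetic.default_f_architecture()
seq, truth = synthetic.build_promoter_sequence(arch, seed=42)
hits = motifs.scan_motifs(seq, arch.consensus, max_mismatch=2)
for p in motifs.find_inverted_repeats(hits):
    print(f"IR {p.irclass:10s} spacer {p.spacer} bp, centers {p.center_distance} bp apart")

scen = synthetic.default_spr_scenario(seed=42)
fit = binding.fit_kinetics(synthetic.simulate_sensorgrams(scen))
st = binding.stoichiometry(fit.params.rmax, scen.mw_analyte, scen.mw_ligand,
                           scen.rl_immobilized)
print(f"Rmax = {fit.params.rmax:.1f} RU -> {st.s_monomers:.2f} monomers "
      f"({st.s_dimers:.2f} dimers) per DNA")

chord = geometry.chord_distance(34, geometry.HelixModel(bend_per_step_deg=3.0))
print(f"chord between IR centers at 3 deg/bp: {chord:.2f} nm")

apo = thermal.extract_tm(synthetic.simulate_melt_curve(
    synthetic.default_melt_scenario("apo", noise_sd=0.0)))
adp = thermal.extract_tm(synthetic.simulate_melt_curve(
    synthetic.default_melt_scenario("adp", noise_sd=0.0)))
print(f"Tm(apo) = {apo.tm:.1f} C, Tm(+ADP) = {adp.tm:.1f} C, "
      f"delta = {thermal.delta_tm(apo, adp):+.1f} C")
```

prints

```
IR degenerate spacer 27 bp, centers 33 bp apart
IR perfect    spacer 28 bp, centers 34 bp apart
Rmax = 883.1 RU -> 6.00 monomers (3.00 dimers) per DNA
chord between IR centers at 3 deg/bp: 10.09 nm
Tm(apo) = 44.5 C, Tm(+ADP) = 46.1 C, delta = +1.6 C
```

Reading: the promoter carries one perfect inverted repeat (two exact
hexamers 28 bp apart, centers separated by 34 bp ≈ three helical turns,
hence nearly on the same DNA face) overlapped by a degenerate one; the SPR
saturation response corresponds to six ParA monomers — three dimers — per
DNA fragment; a uniform 3°/bp bend brings the IR centers to ~10 nm, inside
the dimer's wHTH span; and ADP raises the protein's melting point by
1.6 °C.

The same stages are scriptable from the shell:

```
parabind generate --seed 42 --outdir out/        # write synthetic inputs
parabind scan out/promoter.fasta                 # motif/IR architecture
parabind fit-spr out/sensorgrams.csv             # kinetics + stoichiometry
parabind fit-isotherm out/isotherm_emsa.csv      # Hill fit
parabind tm out/melt_apo.csv out/melt_adp.csv    # melting points
parabind run-all --seed 42 --outdir out/         # everything + report.json
```

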