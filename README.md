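# wingbind

Analysis toolkit for characterizing how a small winged helix–turn–helix
(wHTH) transcription factor recognizes its operator DNA. The package covers
the complete evidence chain such a study rests on:

* **Operator motif arithmetic** (`wingbind.motifs`) — scanning promoter DNA
  for a palindromic TTAA box occurring as a TTAA-N7-TTAA pair, direct-repeat
  checks, and span arithmetic in transcription-start-site (TSS) coordinates
  (the no-zero convention: …, −2, −1, +1, +2, …).
* **Secondary structure from chemical shifts** (`wingbind.csi`) — chemical
  shift index (CSI) calling from Cα/Hα deviations against random-coil
  values, producing an α/β topology string such as `αβααββα`.
* **Binding-interface mapping** (`wingbind.csp`) — combined ¹H/¹⁵N amide
  chemical shift perturbations, intensity losses and vanished peaks between
  free and DNA-bound HSQC peak lists.
* **Tumbling and hydrodynamics** (`wingbind.relaxhydro`) — exponential
  fitting of ¹⁵N R1/R2 decays, residue filtering, inversion of R2/R1 to the
  rotational correlation time τc, and the Stokes–Einstein–Debye conversion
  to a hydrodynamic radius (diagnostic for the oligomeric state).
* **Sequential two-site ITC** (`wingbind.itcseq`) — exact equilibrium
  solution of the stepwise D + P ⇌ PD, PD + P ⇌ P₂D model, thermogram
  simulation with displaced-volume correction, and multi-start least-squares
  refitting (Kd, ΔH, ΔG, ΔS per site).
* **Titration-style curves** (`wingbind.titrate`) — two-segment breakpoint
  fits for binding stoichiometry, tryptophan emission λmax blue shifts,
  duplex melting Tm by the smoothed-derivative maximum, and Hill
  cooperativity fits of fraction-bound data.
* **Ensemble structure QC** (`wingbind.structqc`) — Kabsch superposition
  (proper rotations only), iterative ensemble RMSD to the mean structure,
  backbone φ/ψ torsions.
* **Synthetic data** (`wingbind.synthdata`) — seeded generators that emit
  every input type above with known ground truth, so each estimator can be
  validated by round trip.
* **Orchestration** (`wingbind.pipeline`, `wingbind` CLI) — config-driven
  end-to-end runs that write a JSON report.

The curve-fitting analyses follow a statsmodels-style layout: a Model class
bound to the data exposes `.fit()`, which returns a Results object carrying
parameter estimates, asymptotic standard errors, derived quantities and a
`summary()` table.

## Worked example

Generate a synthetic study (default conditions: τc = 8.4 ns at 600 MHz,
site-1 Kd = 40 nM with ΔH₁ = +10 kcal/mol, a 2:1 protein:DNA breakpoint)
and analyze it with the library:

```python
from wingbind import relaxhydro, synthdata, titrate
from wingbind.itcseq import SequentialBindingModel

spec = synthdata.SynthSpec(seed=1)          # realistic noise levels

# --- ITC: sequential two-site fit ---------------------------------------
tg = synthdata.gen_itc_thermogram(spec)
res = SequentialBindingModel(tg).fit()
print(res.summary())

# --- 15N relaxation -> tau_c -> hydrodynamic radius ----------------------
r1, r2 = synthdata.gen_relaxation_series(spec)
rates, est = relaxhydro.analyze_relaxation(r1, r2,
                                           flexible=spec.flexible_termini)
print(est.summary())

# --- CD-style titration: binding stoichiometry ---------------------------
t = synthdata.gen_titration_curve(spec)
print(titrate.breakpoint_stoichiometry(t["ratio"], t["signal"]).summary())
```

Output:

```text
Sequential two-site binding fit
==============================================
injections: 20   T = 295.15 K   SSR = 1.677e-14 cal^2

                   value   std err (log10K / kcal)
Kd1              38.00 nM          0.0553
Kd2              5.522 uM          0.0936
dH1             10.012 kcal/mol      0.0711
dH2             -5.071 kcal/mol       0.491
baseline     5.862e-09 cal    2.66e-08

site 1: dG = -10.02 kcal/mol, dS = 67.9 cal/(mol K)
site 2: dG = -7.10 kcal/mol, dS = 6.9 cal/(mol K)

Rotational tumbling estimate
--------------------------------
tau_c               8.28 +/- 0.11 ns
residues used    47
1H field         600.0 MHz
r_H (SED)          2.091 nm (T = 298.15 K, eta = 0.00089 Pa s)

Two-segment titration fit
breakpoint ratio  2.0236
slope before      1.006
slope after       0.08248
SSE               2.637e-03
```

With noise, the fits recover the planted ground truth (Kd1 40 nM → 38 nM,
τc 8.4 ns → 8.28 ns, breakpoint 2.0 → 2.02); with `spec.noiseless()` the
recoveries are exact to numerical precision. Note the thermodynamic
signature of the tight site: binding is endothermic (ΔH₁ > 0) yet strongly
favorable, i.e. entropy-driven (TΔS ≈ +20 kcal/mol at 295 K).

The same analyses are available from the command line:

```bash
wingbind demo --seed 7 --outdir demo_run     # full synthetic bundle + report
wingbind synth --seed 1 --outdir data        # just the data
wingbind itc fit --thermogram data/itc.csv --design data/itc_design.json
wingbind relax --r1 data/relax_r1.csv --r2 data/relax_r2.csv --field 600
wingbind run --config my_analysis.yaml       # your own data, stage by stage
```

## Layout

```
src/wingbind/      library (one module per analysis; cli.py, pipeline.py)
tests/             pytest suite incl. test_acceptance.py
scripts/           acceptance.py — recompute headline numbers
docs/methods.md    estimator definitions, conventions and formulas
```
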