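# lipocd

Analysis of micellization and cyclodextrin host–guest complexation for
amphiphilic guests — lipophenol conjugates (e.g. resveratrol fatty-acid
esters) and their parent fatty acids — from fluorescence titration data.

## The problem

Amphiphiles self-assemble into micelles above their critical micelle
concentration (CMC), detected here as the breakpoint in the fluorescence
of a hydrophobic probe plotted against amphiphile concentration: a flat
pre-micellar baseline followed by a steep post-micellar rise. Adding a
cyclodextrin (CD) host sequesters monomers into inclusion complexes and
delays micellization, so the apparent CMC grows with CD concentration.
That growth encodes the binding equilibrium:

- **1:1 complexation** (association constant `Kc`, M⁻¹):
  `CMC([CD]) = CMC₀ (1 + Kc [CD])` — a linear micellar diagram;
- **sequential 1:2 complexation** (stepwise constants `K1`, `K2`):
  `CMC([CD]) = CMC₀ (1 + K1 [CD] + K1 K2 [CD]²)` — a quadratic one.

The package implements the full inference chain:

1. **CMC estimation** (`lipocd.breakpoint`) — exhaustive two-segment
   least-squares with the CMC read off as the intersection of the
   pre-micellar baseline and the post-micellar trend line;
2. **micellar-diagram fitting** (`lipocd.binding`) — both binding
   models, stoichiometry selection by a one-sided extra-sum-of-squares
   curvature test with a chemical-relevance floor, and residual-bootstrap
   confidence intervals;
3. **ligand efficiency** (`lipocd.ligand`) — binding energy per heavy
   (non-hydrogen) atom, the size-normalized companion metric for
   computed MM-GBSA energies;
4. **synthetic data** (`lipocd.synthetic`) — titration curves and
   diagrams with known ground truth, including presets for the published
   condition grid (pH 2.0/7.0; 15/25/35 °C; PBS vs water);
5. **I/O and reporting** (`lipocd.workbench`, `lipocd.pipeline`,
   `lipocd.cli`) — delimited-text formats, deterministic JSON/text
   reports, and a `lipocd` command-line tool.

## Worked example

Simulate titrations for the resveratrol–linoleate conjugate at its
reference condition (CMC₀ = 6 µM, Kc = 720 M⁻¹; pH 7.0, 35 °C, PBS)
across five CD levels, then run the whole chain:

```python
import lipocd as L

params, cond = L.get_preset("Resv-4'-LA")
curves = [
    L.make_titration(L.SyntheticTitrationSpec(
        binding=params, cd_conc_m=cd, seed=40 + i, noise_sd=1.0, guest="Resv-4'-LA",
    ))
    for i, cd in enumerate([0.0, 0.001, 0.0025, 0.005, 0.01])
]
report = L.analyze_titrations(curves, alpha=0.05, n_boot=1000, seed=7)
print(L.render_report(report, L.ReportFormat.TEXT_TABLE))
```

```
guest: Resv-4'-LA
condition: pH 7.0 | 35.0 degC | PBS_100mM

breakpoints (apparent CMC per CD level):
       cd_mM         cmc_uM  n_pre  n_post
           0        6.05225     12      24
           1        10.3868     12      24
         2.5        16.8982     12      24
           5        27.6368     12      24
          10        49.2416     12      24

binding model: 1:1 (CMC0 measured_at_zero)
  cmc0_um = 6.05225  [6.03881, 6.09925]
  kc_per_m = 713.716  [706.997, 716.227]
  curvature test p = 0.8314

fold changes:
  CMC at 1 mM CD vs CMC0: 10.3868 / 6.05225 = 1.7 (1 dp)
  ...
```

Reading the output: the per-level breakpoints recover the generating
CMC-shift curve (6 µM at zero CD, rising to ~49 µM at 10 mM CD); the
curvature test finds no evidence for a quadratic term (p = 0.83), so the
1:1 model is selected, and the fitted `Kc = 714 M⁻¹` sits within noise
of the generating 720 M⁻¹, with a residual-bootstrap 95% interval.

The same chain is available from the shell:

```sh
lipocd simulate --guest "Resv-4'-LA" --seed 11 --out curves.csv
lipocd fit-binding --in curves.csv --out report.json --seed 9
lipocd ligand-efficiency --in guests.csv
```

Ligand efficiency, in two lines:

```python
>>> L.ligand_efficiency(L.GuestMolecule("LA", "C18H32O2", -47.24)).le_rounded
-2.362   # kcal/mol per heavy atom (20 heavy atoms)
```

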