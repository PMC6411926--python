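# cspfit

Quantitative analysis of protein–ligand binding from NMR chemical shift
perturbation (CSP) titrations, for interactions too weak for ITC or SPR —
the regime typical of histone-reader domains such as chromodomains binding
methylated histone peptides (Kd in the 0.1–10 mM range) or, at the other
extreme, short DNA duplexes that saturate near a 1:1 molar ratio.

`cspfit` takes assigned ¹H–¹⁵N HSQC peak lists recorded along a titration,
computes normalized per-residue shift changes, classifies which resonances
are significantly perturbed, fits each of them to the exact single-site
binding isotherm with ligand depletion, and reports an outlier-filtered
global dissociation constant. It also ships a seeded synthetic-titration
generator (so the whole pipeline is testable against known ground truth)
and a small genomics module implementing the maxgap peak-overlap rule
("within 150 bp, same strand") used to compare reader-protein ChIP-seq
peaks with histone-mark and accessibility peaks.

## The model

Under fast exchange an amide peak sits at the population-weighted average
of its free and bound positions, so its normalized shift change

    Δδ = √( (ΔδH)² + (0.20·ΔδN)² )        [ppm]

is proportional to the bound fraction. With protein and ligand at
comparable concentrations the free-ligand approximation fails, and the
bound fraction follows the exact quadratic solution of the 1:1 equilibrium:

    Δδ = Δδmax · ( ([L]+[P]+Kd) − √(([L]+[P]+Kd)² − 4[P][L]) ) / (2[P])

Each significantly perturbed residue is fit independently for
(Kd, Δδmax) by bounded nonlinear least squares. Significance uses a
trimmed threshold: mean + 1 SD of the Δδ profile after discarding the 10%
largest values. The global Kd is the mean over significant residues after
a single pass removing per-residue Kd values more than 2 SD from the
initial mean; if half or more of the residues are removed the estimate is
reported as a lower limit (e.g. `>0.8 mM`). See `docs/methods.md` for the
full procedure, defaults and caveats.

## Worked example

Simulate a weak peptide-like titration (true Kd 0.7 mM, 0.1 mM protein,
molar ratios 0–10) and fit it back:

```sh
cspfit simulate --kd-mM 0.7 --seed 1 --out demo/sim
cspfit fit --manifest demo/sim/series.yaml --out demo/fit
```

which prints

```
Titration global-Kd fit
==========================================================
series:            synthetic (ligand)
points:            6  (reference index 0, endpoint index 5)
protein conc:      0.1 mM
max ligand conc:   1 mM
CSP threshold:     0.0891 ppm (trim fraction 0.1)
significant:       13 of 47 observed residues
fits converged:    13 of 13
Kd retained/removed: 12/1 (outlier rule 2 SD)
global Kd:         0.69 ± 0.21 mM
----------------------------------------------------------
 residue label  dd_ppm  kd_mM  dmax_ppm  retained
      11   Y11  0.1159 0.6071    0.1977      True
      14   T14  0.1167 0.4904    0.1767      True
      ...
```

Reading the output: 13 of the 47 observed resonances moved more than the
trimmed mean + 1 SD threshold (0.0891 ppm) at the titration endpoint; each
was fit to the depletion isotherm; one per-residue Kd (residue 27,
1.42 mM) deviated more than 2 SD from the initial mean and was removed;
the remaining 12 average to a global Kd of 0.69 ± 0.21 mM — recovering the
generating value of 0.7 mM. `demo/fit/` also receives a per-residue TSV, a
JSON summary, and a provenance block.

The same objects are available as a library, statsmodels-style:

```python
from cspfit import SimulationConfig, simulate_titration, TitrationKdModel

series, truth = simulate_titration(SimulationConfig(true_kd=0.7, seed=1))
results = TitrationKdModel(series).fit()   # or .from_manifest("series.yaml")
print(results.summary())
results.plot_profile()                     # CSP bar plot with threshold
results.plot_fit(residue=22)               # isotherm through one residue
```

For genomic peak overlaps:

```sh
cspfit overlap --query reader.bed --subject h3k27me3.bed --third dnase.bed \
    --max-gap 150 --out overlaps/
```

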