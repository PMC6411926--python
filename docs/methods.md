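# Methods

## Scope and assumptions

`cspfit` analyses fast-exchange ¹H–¹⁵N HSQC titrations of a small protein
domain with a single ligand under a strict 1:1 binding model. Fast
exchange means every cross-peak position is the population average of the
free and bound states, so the normalized shift change of a residue is
proportional to the bound fraction and saturates at a per-residue
amplitude Δδmax. The model deliberately excludes two-site and cooperative
binding, exchange-regime (lineshape) analysis, and any attempt to fit
titrations whose CSP trajectories are visibly curved — curvature signals
a departure from two-state 1:1 behaviour that a single-site isotherm
cannot represent, and such systems should be reported qualitatively
rather than forced through this pipeline.

Peak lists are assumed pre-assigned and tracked by residue label across
titration points; automated peak tracking is out of scope.

## Normalized shift change

    Δδ = √( (ΔδH)² + (w·ΔδN)² ),    w = 0.20 (dimensionless, default)

The weight compresses the ¹⁵N axis by roughly the ratio of amide ¹H to
¹⁵N shift dispersions so both dimensions contribute comparably in ppm.
`w` is configurable; 0.20 is the field's common convention for backbone
amides. Δδ is a norm: non-negative, zero only for identical positions,
symmetric in the two states, and linear under joint scaling of the two
weighted components.

## Significance classification

A resonance is significantly perturbed when its endpoint Δδ strictly
exceeds a trimmed threshold:

1. take the Δδ values of all residues observed at both the reference and
   the endpoint (broadened, missing and proline entries never enter);
2. discard the k = ⌈trim_fraction · n⌉ largest values (default
   trim_fraction = 0.10; for a typical 49-resonance domain k = 5), ties
   broken by discarding the higher residue index first so the result is
   deterministic;
3. threshold = mean + 1 sample SD (n−1 denominator) of the remaining
   values.

The trim exists to keep genuine binders from inflating the threshold that
is supposed to detect them; trimmed residues therefore remain eligible to
be called significant, and in practice almost always are. With all values
equal the SD is zero and the strict inequality marks nothing significant.
For right-skewed profiles (a minority of strongly shifted residues over a
noise floor) increasing the trim fraction can only lower the threshold;
the tests assert this monotonicity on simulated profiles.

Broadened resonances — peaks lost to intermediate exchange during the
titration — are carried through the profile with their status and
reported alongside the significant set, but they contribute no Δδ value
to the statistics and are never fit.

## Binding isotherm and per-residue fits

With ligand and protein at comparable concentrations (both 0.01–1 mM
here) the bound fraction must come from the exact quadratic root of the
1:1 equilibrium rather than the hyperbola:

    Δδ(P, L) = Δδmax · ( (L+P+Kd) − √((L+P+Kd)² − 4·P·L) ) / (2P)

This is monotone increasing in L and Δδmax, decreasing in Kd, bounded by
[0, Δδmax], and converges to the non-depleting hyperbola
Δδmax·L/(L+Kd) as P → 0 (verified to <0.1% relative error at P = Kd/1000).

Each significant residue's trajectory — (P, L, Δδ) at every point where
the residue and the reference are both observed, including the L = 0,
Δδ = 0 anchor — is fit by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective):

- parameters: log₁₀Kd ∈ [−6, 3] (Kd in mM) and Δδmax ∈ (0, 10·max Δδ_obs];
  the log parameterization conditions the nine-decade Kd range;
- initialization: Kd₀ at the ligand concentration where Δδ crosses half
  its observed maximum (linear interpolation), Δδmax₀ = 1.2·max Δδ_obs;
  one fallback start at (10·Kd₀, 2·Δδmax₀) if the first attempt does not
  converge;
- tolerances: ftol 1e-10 on the objective, xtol 1e-12; the fit is
  deterministic for a given trajectory;
- preconditions: at least three distinct ligand concentrations; a
  trajectory whose largest Δδ is below 1e-9 ppm is rejected as a
  non-binder rather than fit.

Tests hold the fitter to an independent exhaustive 200×200 log-grid
search: the fit's residual sum of squares must dominate every grid point,
its Kd must land within one grid cell of the profiled-grid argmin, and
its Δδmax within one cell of the closed-form conditional optimum at its
own Kd (the joint grid argmin slides along the Kd–Δδmax ridge by grid
quantization, so per-axis comparisons are made with the other parameter
profiled out). On noise-free data parameters are recovered to better
than 0.1%.

## Global Kd aggregation

The per-residue Kd values of converged fits over the significant set are
summarized as:

1. initial mean and sample SD over all such fits;
2. one pass (not iterated — iteration could cascade removals) removing
   fits with |Kd − mean| > 2·SD, using the initial SD;
3. mean and SD recomputed over the retained fits — this is the reported
   global Kd ± SD;
4. if the removed fraction reaches 50%, the per-residue estimates are
   mutually inconsistent and the result is rendered as a lower limit
   (`>x mM`, using the post-removal mean) instead of a point estimate.

A documented property of step 4 under this exact rule: because the sum of
squared deviations equals (n−1)·SD², fewer than (n−1)/4 points can ever
deviate by more than 2·SD from their own sample mean, so the 50% branch
cannot trigger when the SD is computed from the same finite sample. It is
retained as a guard (and its rendering is exercised directly in tests)
because alternative SD choices — e.g. per-fit standard errors from the
optimizer covariance, under which the branch is reachable — are a
plausible variant a user may configure in future; with the default rule,
lower limits for under-sampled titrations manifest instead as an inflated
Kd with a large SD, which the documentation of results should report as a
bound whenever the mean exceeds the highest sampled ligand concentration.

The aggregation is permutation-invariant and scale-equivariant
(multiplying all Kd values by c multiplies the mean by c).

## Synthetic titrations

The generator emulates the geometry of a real reader-domain titration so
that the pipeline can be validated against known ground truth:

- 49 observable backbone amides (residue numbering starting at 8, as for
  a small N-terminal domain), reference shifts drawn uniformly from
  ¹H 6.5–10.5 ppm and ¹⁵N 103–133 ppm;
- protein at 0.1 mM (0.05 mM for the DNA-like scenario), ligand ratios
  {0, 1, 2, 4, 7, 10} for peptide-like ligands and {0, 0.25, 0.5, 1, 2}
  for high-affinity DNA-like ligands;
- 30 responsive residues with Δδmax drawn uniformly from 0.05–0.25 ppm
  and a fixed random direction per residue, chosen as a unit vector in
  the weighted (ΔδH, w·ΔδN) plane so that the normalized Δδ equals the
  scalar forward model exactly and Δδmax is interpretable in
  normalized-ppm units;
- i.i.d. Gaussian noise added to every observed shift at every point
  (including the reference): SD 0.003 ppm in ¹H and 0.02 ppm in ¹⁵N,
  typical of HSQC peak-position precision at high field;
- 2 responsive residues marked broadened (peak absent) at every point
  whose bound fraction falls in [0.3, 0.7], mimicking intermediate-
  exchange loss at mid-saturation;
- everything drawn from one seeded generator: identical seeds give
  bit-identical series and byte-identical files.

The ternary variant represents titrating a second ligand into a
pre-formed binary complex: under fast exchange the forward model is
unchanged, the reference shifts simply represent the complex, and the
series metadata records that the reference is not the free protein.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: peak overlap and
misassignment, lineshape and relaxation effects, intensity attenuation in
large complexes, CSP trajectory curvature from secondary binding events,
pH/temperature drifts between points, and dilution of the protein during
the titration (the manifest format supports per-point protein
concentrations, but the generator holds it constant).

Statistical guarantees asserted by the test suite on these conditions:
median recovered global Kd within 15% of truth over 20 seeds when the top
ligand concentration reaches the Kd (and within 35%, with demonstrably
inflated spread, when it does not); non-responsive residues essentially
never called significant (≥95% of 50 seeds); recovered-Kd IQR at
Kd = 10·max[L] exceeding that at Kd = 0.5·max[L].

## Genomic peak overlaps

BED3/BED6 intervals, 0-based half-open throughout. Two peaks overlap when
they are on the same chromosome, their strands are compatible, and the
gap between them is at most `max_gap` (default 150 bp), where the gap
between [a, b) and [c, d) with c ≥ b is c − b — touching or intersecting
intervals have gap 0, so "within 150 bp" means c − b ≤ 150 exactly. An
unstranded peak (`.`) matches any strand, because ChIP-seq peak calls are
typically unstranded and a strict rule would zero out all overlaps on
BED3 input. Overlap fractions are anchored on the query set and are not
symmetric; three-way Venn counts are likewise reported per anchor set.
The implementation is a sorted sweep with a prefix-maximum over interval
ends (O((n+m) log m)); tests hold it to an all-pairs brute force on 100
seeded random instances, including the 150-vs-151 bp boundary.
`scripts/encode_overlap_example.sh` documents how to apply the module to
downloaded ChIP-seq/DNase BED files; it requires external data and is not
exercised by the test suite.

## Problem sizes and runtime

The validation suites use 20-seed batches of 49-residue, 6-point series —
enough for stable medians while keeping the full test suite under ten
seconds and the acceptance script under one minute on a single CPU.

## Known limitations

- Kd far above the highest sampled ligand concentration is weakly
  identified: Kd and Δδmax are strongly anti-correlated at low
  saturation, the per-residue estimates become heavy-tailed, and the
  global mean is upward-biased. The widened tolerance and the explicit
  spread assertion in the tests document rather than hide this.
- The outlier rule is a fixed 2·SD cut on the Kd scale; for heavy-tailed
  per-residue estimates a log-scale or MAD-based cut would be more
  robust, but the simple rule is kept as the field-standard procedure.
- The reported SD describes the scatter of per-residue Kd estimates, not
  the standard error of the global mean, and does not propagate
  per-residue fit uncertainties.
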