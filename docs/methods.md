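# Methods

This note documents the models, defaults and design choices behind
`ompakit`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, which
knobs matter, and what the synthetic-data checks do and do not demonstrate.

## Coordinate system and reference

All coordinates are 1-based positions on the mature 325-residue OmpA chain
of *E. coli* K-12 MG1655, obtained from the 346-residue precursor by
removing the 21-residue signal peptide. Precursor inputs are detected by
length (≥ 340) together with a recognizable signal region (≥ 50% identity
over the first 21 residues) and trimmed before mapping; the call is flagged
`signal-peptide-trimmed`.

Surface-loop and strand boundaries are shipped as data
(`data/reference.yaml`), not code. The literature does not fix loop
boundaries to the residue, so the bundled values are this package's
documented approximation: loops 1–4 of the 8-strand barrel at 16–32, 57–74,
100–118 and 140–155, and loops 5–8 of the minority 16-strand "large pore"
topology at 190–200, 225–235, 258–268 and 295–305. The C-terminal
classification positions 175/203/251 deliberately fall outside loops 5–8,
which is what makes the C-terminal rows of the property table identical
across alleles (see below). Repositioning any segment is a data edit.

## The allele classification scheme

Alleles are pairs (N-terminal pattern I–VII, C-terminal pattern α–δ).
N-terminal patterns are defined by the residues at one variant site per
extracellular loop; the loop-3 site is a residue *run* whose length itself
varies (7 residues in I/IV/VI/VII, 8 in II/III/V) and is compared on exact
equality, length included. C-terminal patterns are single residues at
175/203/251. Positions 93/129/161 sit in transmembrane strands and are
recorded in every variant profile but never influence the call.

The published naming convention fixes the pattern *structure* and anchors a
subset of residues (SVE vs DNI at loop 2; a loop-1 D variant and 7-residue
loop 3 jointly unique to VI and VII; the long loop 3 in II, III and V; IV
and VII differing only in loop 1; I and II differing at all four loops;
α equal to the K-12 reference with N at 203; δ differing from α at exactly
203 and 251; γ carrying the position-175 variant). Residue identities not
anchored by the text were fixed once for this package and are versioned in
`data/scheme.yaml`; loading validates every structural invariant and
rejects schemes that violate them. Because the scheme is data, corrections
never touch logic. One simplification: loop-3 runs are shared within the
7-residue and within the 8-residue groups, although the published per-loop
charge table suggests additional loop-3 diversity between alleles.

A note on numbering conventions: one external study refers to the position
called 175 here as "position 200". The implied offset (25) matches neither
mature numbering nor simple precursor numbering (offset 21); both
conventions are therefore documented rather than reconciled, and this
package uses mature numbering exclusively.

## Alignment and calling

Queries are globally aligned to the mature reference with Biopython's
`PairwiseAligner` under a documented scoring: match +1, mismatch −1, gap
open −5, gap extend −1. This is adequate for the > 70%-identity inputs the
scheme is defined for; sequences below the identity floor (default 0.70,
configurable) are rejected as not OmpA-like rather than force-binned —
OmpA of *Klebsiella*, *Yersinia* or *Salmonella* must fail here.

Single-residue sites are read through the reference→query position map.
Loop (run) sites are extracted between the nearest *mapped flanking
positions*, so insertions or deletions inside a loop are captured in the
run instead of shifting downstream sites. The two domains are called
independently; an exact pattern match is required for an assignment
(mismatch count 0 by construction), otherwise the call is "novel" with all
equidistant nearest patterns reported and an `ambiguous-*-tie` flag when
there are several — the caller never silently picks one.

Known limitation: when an allele that already carries the 8-residue loop 3
also has an indel immediately adjacent to the run's flanking anchor, the
optimal alignment can become degenerate (merging two nearby gaps costs less
than opening both), and run extraction may then differ from the planted
truth. The C-terminal sites are unaffected — indels of ≤ 2 residues inside
loop 3 never move the 175/203/251 calls, which is tested — and the
synthetic generator places indels at least two residues clear of the run
anchors, where the optimum is unique.

## Physicochemical prediction

Net charge of a segment at pH is the Henderson–Hasselbalch sum over
ionizable side chains; terminal groups contribute only on request, and the
default for loops is off (they are internal stretches of the chain).
The default pKa set (D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0,
N-term 8.0, C-term 3.1) is a Protein Calculator-style table stored as data
and swappable — the study names the tool it used, not the constants.
The default hydrophobicity scale is Kyte–Doolittle in mean mode (GRAVY),
also swappable data.

Because neither the constants nor the exact loop boundaries behind the
published per-loop table are stated, exact numeric reproduction of that
table is a calibration exercise, not a supported claim. What the package
does reproduce — and test — is its *equality structure*: C-terminal loop
rows are identical across all alleles (their edits lie outside loops 5–8),
and any loop row is shared exactly between alleles whose sequences coincide
over that loop. Two caveats discovered in the course of this work: aspartate
and glutamate differ slightly in dissociation at pH 8 (≈ 2×10⁻⁴ e), so the
loop-2 charge is equal across SVE/DNI alleles only to ~3 decimals; and N
and D share the same Kyte–Doolittle value (−3.5), so the loop-1 N/D
variant is invisible to the hydrophobicity index while contributing a full
elementary charge difference.

Predictions ignore conformation: no exposure weighting for the dimeric vs
monomeric form and no 8-strand/16-strand redistribution. pI calculation is
out of scope.

## Assay metrics

MATH hydrophobicity is implemented exactly as the source prints it, with
the *aqueous-phase* OD in the denominator:
`100·(OD_initial − OD_aqueous)/OD_aqueous`. The conventional MATH formula
divides by the initial OD instead; whether the printed denominator is
intentional cannot be decided from the text, so the printed form is the
default and `conventional_denominator=True` exposes the variant. An aqueous
OD above the initial OD is physically anomalous and returns a negative
value with a warning rather than an error.

The biofilm index is OD570/OD620. Uncertainty on ratio quantities uses
first-order Taylor propagation (quadrature of relative errors) — the source
states only that error propagation was performed "when appropriate".
Neutrophil-elastase killing is declared only when a two-tailed Student's
t-test on CFU replicates gives p < 0.005 *and* the treated mean is lower;
survival is the ratio of means.

## Growth kinetics

Curves (nominally 15 h of OD550 at 10-minute spacing) are linearized as
ln(OD_t/OD_0); μ is the least-squares slope over the detected log phase and
μ_sd its standard error from the residuals.

The end-of-log-phase rule is stated qualitatively in the source protocol
("a decrease in slope"); every quantitative element here is this package's
explicit, configurable choice, logged with each fit:

* slope floor 0.01/h — below it, "no growth detected";
* point-to-point slopes smoothed by a centered 3-point mean;
* a noise-robust reference growth rate: the maximum *secant* slope over a
  1-hour span. The maximum of the smoothed point-to-point slopes is
  inflated by roughly two noise standard deviations at a realistic 1%
  multiplicative OD noise, which makes a threshold defined against it fire
  mid-exponential; the coarse secant maximum has ~6× less noise;
* log phase = first to last smoothed interval at or above
  (1 − drop_fraction)·reference with drop_fraction 0.10, which is robust to
  isolated noise dips inside the exponential phase;
* window edges shifted by (smooth_width−1)/2 intervals to cancel the
  centered-smoothing delay, so the edges land on the transitions;
* the end additionally keeps the later of the smoothed-slope estimate and
  the last point whose *backward* 1-hour secant clears the threshold — both
  estimators are biased early under noise, the secant one far less, and
  taking the maximum removes the early-firing tail without ever overshooting
  (a backward secant one sample past the breakpoint already sits well below
  the threshold).

On noiseless exponential-then-plateau curves the detected end equals the
breakpoint; at 1% multiplicative noise the end stays within 1 sample of
truth and μ is recovered with ≈ 0.2% mean relative error over 100 simulated
curves. Logistic/Gompertz fitting and lag-time estimation beyond the start
index are out of scope.

## Cohort statistics

Conventions mirror the source study exactly and deliberately:

* t-tests are two-tailed Student's (pooled variance), not Welch;
  switchable where exposed. A zero-variance pair with equal means is
  treated as non-significant (p = 1).
* The compact letter display uses insert-and-absorb assignment; the output
  is verified against the defining biconditional (two groups share a letter
  iff their pairwise p ≥ α) on every call.
* Correlations are judged by whether the 95% CI of the least-squares slope,
  `slope ± t_{0.975,n−2}·SE`, excludes zero.
* Fisher's exact test is two-tailed under the "sum of outcomes with
  probability at most that of the observed table" convention (the common
  implementation choice; conventions differ), with the conditional
  maximum-likelihood odds ratio. A zero margin returns p = 1, flagged.
* No multiple-testing correction is applied anywhere: the study controls
  error with severe fixed cutoffs (0.005 for phenotype tests, 1×10⁻⁵ for
  enrichment), and the package mirrors that.
* r×c exact tests are not implemented; the r×c case uses the chi-square
  test of homogeneity (with the >20%-expected-counts-below-5 adequacy flag)
  or pairwise 2×2 comparisons.

Count tables can be rebuilt from printed percentage summaries. Two
percentage conventions coexist in the source tables and both are supported:
per-group frequencies (share of a cohort carrying an allele) and per-allele
shares (how an allele's carriers distribute over groups). Reconstruction
rounds half away from zero and marks the table as a reconstruction. Rare
alleles (total < 10 by default) are lumped as "other". The bundled
summaries surface, rather than hide, two internal inconsistencies of the
printed source: one allele's n appears as both 14 and 36, and the listed
allele totals plus "other" exceed the stated trimmed pool of 400.

A note on letter-display calibration: with k groups the probability that a
perfectly calibrated procedure yields a single letter under the null is
approximately (1−α)^(k(k−1)/2) — about 0.97 for four groups at α = 0.005
but only about 0.90 for seven (21 simultaneous tests). Calibration checks
therefore use a four-group null for the ≥ 95% single-letter property and
compare the seven-group rate to its own family-wise expectation.

## Synthetic data

The generators emulate the study's data shapes with known ground truth:
near-identical protein sequences planted with defined alleles (optional
background mutations away from classification sites, novel-forcing site
noise, and one-residue loop-3 indels); Gaussian replicate phenotypes around
per-allele means, including a preset with the observed 10-fold biofilm
separation between the α and the β/γ C-terminal groups (high mean 2.0,
relative SD 15%, 6 replicates); piecewise lag/exponential/plateau OD curves
(μ = 0.6/h, 1 h lag, breakpoint at 6 h, 15 h total at 10-minute spacing,
OD₀ = 0.05, 1% multiplicative noise) — values chosen once as realistic for
*E. coli* in minimal glucose medium; and multinomial allele counts per
group (default cohort sizes 78 environmental vs 412 ExPEC) with planted
odds multipliers.

All generators are pure functions of (config, seed); a single seed is split
hierarchically (one spawned child stream per generator) so adding one
generator call never perturbs another's draws.

What passing these checks shows — and does not. They demonstrate that the
implementation recovers planted truth under the stated noise models:
Gaussian replicate noise, multiplicative OD noise, uniform background
substitutions. Real data add structure the generators do not emulate:
phylogenetic correlation between sequences, plate-position and batch
effects, non-Gaussian assay tails, and OmpA expression-level differences
between strains. Recovery on synthetic data therefore validates the
machinery, not the biological conclusions.

## Acceptance quantities and problem sizes

`scripts/acceptance.py` recomputes, at run time: the three reconstructed
enrichment tests (carrier tables of 490, 312 and 251 isolates), the
trimmed-pool share (400 isolates), typing recovery on 105 planted
sequences with 30% loop-3 indel probability, growth recovery on 100 noisy
curves, slope-CI type-I calibration on 1000 null regressions of 7 points,
and the biofilm letter partition on the 7-allele preset. These sizes were
chosen to estimate each quantity well while keeping a full run in seconds.
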