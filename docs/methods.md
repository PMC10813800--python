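# Methods

## The model

The object of inference is the set of discrete chemical events (PTMs and
amino-acid substitutions) underlying the cloud of localized delta masses
that an open (wildcard) database search produces. The generative picture
is: a modification with true mass shift Δ, observed on peptides of
monoisotopic mass M, yields delta masses Δ + ε with ε ~ N(0, (σ_ppm·10⁻⁶·M)²)
— instrument mass error scales with precursor mass. A 1-Da window can hold
several such events, so each window is modelled as a univariate Gaussian
mixture over delta mass, the mixture order chosen by BIC.

"Multivariate clustering" is implemented univariately on delta mass, with
the residue composition of each cluster computed post hoc: the reported
outputs of the clustering (peak, SD, R²) are univariate quantities, and no
second clustering variable is defined anywhere in the procedure, so a
second dimension would be an invention. The per-cluster dominant-residue
fraction recovers the residue-specific information that matters downstream
(the > 50% assignment rule).

BIC is computed conventionally (−2·logL + p·ln n, minimized) and *negated*
for reporting, so that "larger BIC = stronger model" holds in all output.
Ties break toward fewer components.

## Constraints and their interpretation

Three constraints gate mixture components into accepted clusters:

* **half-width > 1 ppm** — the component SD expressed in ppm of the
  members' median peptide monoisotopic mass. The reference mass matters:
  1 ppm of a 16-Da delta would be 16 µDa, far below any instrument's
  resolution, whereas 1 ppm of the peptide mass is precisely the natural
  floor of the error model above. Components narrower than that are
  duplicate-valued artifacts, not physical peaks.
* **peak distance > 2 peak widths** — adjacent components closer than twice
  the larger SD are over-split; the window is refitted with one fewer
  component rather than deleting either (the constraint targets
  over-splitting, not bad data, and refitting preserves all observations).
  This merge loop runs before the size/width drops so it always sees the
  full component set; whether the original analysis ordered these steps
  the same way is not documented, and the choice is the package's own.
* **size > 20** — strict inequality; a 20-member component is rejected.

Surviving components are then individually regressed: member deltas are
histogrammed at 0.001 Da (ten times finer than the 0.01-Da noise floor;
configurable) and an amplitude/mean/SD Gaussian is least-squares fitted to
the bin counts. R² = 1 − SS_res/SS_tot over bins, clipped to [0, 1]. The
fitted mean is the reported clustered delta mass.

## Numerical choices

* Window intervals are half-open [n − ½, n + ½) so the 1-Da windows tile
  without double counting boundary values.
* Rounding to 4 decimals is half-away-from-zero, fixed across platforms.
* The |Δm| > 0.01 Da cutoff is applied to the absolute value by default:
  the window range extends to −200 Da, so negative deltas are in scope. A
  `signed_cutoff` switch restores the one-sided reading.
* Mixture fitting uses 10 k-means++-initialized EM restarts per k with a
  fixed seed (best likelihood kept), variance floor (10⁻⁵ Da)² against
  singular components on duplicate-valued deltas, EM tolerance 10⁻³ on the
  per-sample lower bound. Component count ranges over
  k = 1…min(max_k, ⌊n/20⌋), clamped to at least 1.
* Degenerate regressions (fewer than 3 occupied bins, or non-convergence)
  fall back to the sample mean with floored SD and R² = 0, which fails the
  significance gate by construction.
* Annotation tolerance defaults to 0.005 Da — half the noise floor; no
  tolerance is prescribed by the procedure itself. When a peak matches
  both a PTM and a substitution (e.g. +0.984 is both deamidation and
  Asn→Asp), all matches are reported; mass alone cannot decide, so no
  forced choice is made. Leu↔Ile substitutions have delta exactly 0 and
  are flagged indistinguishable.
* The 20 residue monoisotopic masses are literal constants in
  `annotate.py` (precision ~10⁻⁵ Da), so the substitution matrix and
  peptide masses are self-contained and externally cross-checkable.

## Differential testing

Abundance is the normalized spectral count: member observations per 10⁴
filtered PSMs per technical replicate, averaged over the three technical
replicates of each biological sample. The pipeline has no intensity data,
so spectral counting is the only quantification mode. Ratios are
(mean_ischemia + c)/(mean_control + c) with pseudocount c = 0.5 normalized
units guarding empty denominators; the label-swap antisymmetry r → 1/r is
exact under this form. The p-value is a two-tailed Student *t*-test
(pooled variance) across the 3 + 3 biological samples; a Welch variant is
available by configuration. The pooled test is the default because, at
this design size and with a strict additional >2-fold gate, it retains
adequate power (≥ 90% for 2.5-fold changes at ≤ 15% within-group CV) where
the Welch correction does not, and because with n = 3 per group the pooled
test is the field's standard reading of a "Student's t-test". Zero-variance
identical groups return p = 1 by convention; both-groups-all-zero keys are
flagged uninformative. No multiple-testing correction is applied by default
(significance is defined on raw p < 0.05); Benjamini–Hochberg is available
but off.

Significance requires all three of: R² > 0.5, ratio > 2 or < ½, p < 0.05.
Direction is up if ratio > 1. Reports are emitted at cluster level, at
residue level (one point per unique protein/position/cluster with
position, residue, delta mass, ratio, direction), and as a per-protein
table of unique-ncAA frequencies split by direction (a protein may appear
in both directions).

## The synthetic generator

`simdata` emulates the statistical structure the pipeline assumes, not the
physics upstream of it: a random proteome is digested in silico (full
tryptic cleavage, cut after K/R not before P, peptides of 6–30 residues —
the observable range of a typical run), and PSM rows are drawn per
group × biological × technical replicate. A configurable
`background_unmodified_fraction` of rows samples peptides carrying no
planted site (delta 0); the rest sample planted-site peptides, carrying
the site's delta with the group-specific rate, perturbed by Gaussian ppm
error scaled to the peptide mass. Score columns are drawn from a passing
distribution, with a `decoy_fraction` of rows drawn from a failing one so
the filters have work to do. Child seeds are spawned per replicate from
the global seed with fixed keys, so adding replicates never perturbs
earlier ones.

Reference conditions (defaults, chosen once): 12 proteins of 40–60
residues, 3 vs 3 biological × 3 technical replicates, 3000 PSMs per
technical replicate, 5 ppm mass-error SD, background fraction 0.6, decoy
fraction 0.05, and five planted modifications — oxidation +15.9949 (M,
rates 0.15→0.40), acetylation +42.0106 (K, 0.40→0.15), phosphorylation
+79.9663 (S, 0.15→0.45), deamidation +0.9840 (N, 0.25→0.25, a null site),
dehydration −18.0106 (T, 0.15→0.38). This depth gives each planted site
roughly a thousand observations, so the fitted peak's standard error
(~5·10⁻⁶·M/√n Da) sits well below a milli-dalton even for 3-kDa peptides.

What the generator does **not** emulate: spectrum-level data (no peak
lists, no chimeric spectra), search-engine scoring behaviour (scores are
quality metadata, not recomputed), missed cleavages, co-occurring
modifications on one peptide, retention-time structure, or decoy-based FDR
estimation. Passing tests therefore demonstrate that the statistical
machinery — windowing, mixture resolution, constraint semantics,
annotation and differential calling — behaves correctly under the stated
error model; they do not certify performance against search-engine
idiosyncrasies on real acquisitions.

## Problem sizes

The validation suite runs the full pipeline over 20 seeded replicates of
the reference scenario for recovery, 100 seeded windows per mixture-order
case, 500 null clusters for calibration, and 100 replicates for power;
`scripts/acceptance.py` uses 5 scenario replicates and 50 windows per BIC
case. These sizes make the binomial uncertainty of each reported rate
small relative to its acceptance margin while keeping a complete run in
the low tens of seconds.

## Known limitations

* Rows with multiple wildcard sites are rejected at parse time; the input
  contract is one localized site per PSM.
* Cluster membership, not intensity, drives quantification; strongly
  ionizing peptides weigh the same as weak ones.
* The bundled PTM table is a small curated snapshot (~60 entries chosen
  for reproducibility); real annotation practice would consult live
  UniMod/RESID/ExPASy/ABRF dumps and isotope-error hypotheses.
* With n = 3 per group, the t-test's normality assumption is unverifiable
  per cluster; the calibration property is established on synthetic
  binomial counts only.
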