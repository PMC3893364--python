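# Methods

`sftdx` implements two linked analyses around one diagnostic question: does
ALDH1A1 over-expression distinguish meningeal solitary fibrous tumours (SFT)
and haemangiopericytomas (HPC) from their mimics — meningiomas and synovial
sarcomas?  The first arm integrates log2 expression matrices produced by
different laboratories and array platforms so a single gene can be compared
across all of them; the second arm quantifies the diagnostic accuracy of
ALDH1 and CD34 immunostaining from percent-stained-cell scores.

## Cross-platform integration

**Pipeline order.**  `ensure_log2` → per-set `quantile_normalize` →
`collapse_probes` → `intersect_gene_universe` → housekeeping stability
selection → sequential DWD merging → PCA mixing check → group comparisons.
Quantile normalization is applied uniformly within each set; it equalizes
sample distributions inside a study but deliberately leaves between-study
offsets for the DWD stage.  Probe variance for the collapsing rule is
computed on the normalized matrix.  Raw-array summarization (e.g. RMA of CEL
files) is out of scope: the pipeline ingests already-summarized matrices.

**Probe collapsing.**  Probes map to EntrezGene ids; redundancy is resolved
extension-class-first on Affymetrix platforms (`_at` ≻ `s_at` ≻ everything
else — `_at` probe sets are the most transcript-specific), then by highest
unbiased sample variance within the set, with exact ties broken
lexicographically by probe id so the result is deterministic.  The two rules
are not explicitly sequenced in the source protocol; class-first makes the
variance rule well defined within a class and matches Affymetrix annotation
practice.  Probes mapping to several genes are rejected at annotation load.

**Housekeeping anchors.**  For each candidate gene the stability statistic is
the *inter-set variance of intra-set variances*: the unbiased variance of the
gene's log2 values within each set, then the variance of those values across
sets.  The lowest-scoring `floor(fraction × n)` candidates are retained;
the default fraction 354/451 mirrors the published funnel in which 354 of
451 mapped housekeeping candidates survived.  The underlying cut-off rule
("defined by the distribution of variability measurements") is not a
formula, so the fraction is a configuration knob and a median + 1 MAD
alternative (`select_housekeeping_mad`) is provided.  Ranking is by
inter-set variance alone; mean intra-set variance and gene id only break
ties.  Note the statistic is an estimate: a noisy gene whose per-set sample
variances happen to coincide can out-rank a designed low-noise gene, which
is why exact-recovery guarantees hold only for zero-noise designed genes.
The candidate list is an input file (the generator supplies its own); the
published 575-gene catalogue is not shipped.  The anchor set is the selected
housekeeping genes plus the target gene, which rides along so its values are
adjusted consistently but is excluded from stability reporting.

**Distance Weighted Discrimination.**  DWD finds the direction between two
batches by minimizing Σᵢ 1/rᵢ + C·Σᵢ ξᵢ subject to
rᵢ = yᵢ(wᵀxᵢ + b) + ξᵢ, ξᵢ ≥ 0, ‖w‖₂ ≤ 1.  Unlike the SVM it lets every
sample pull on the direction, which is what makes it stable in the
high-dimension/low-sample-size regime of microarray batches.  The slack
variables have a closed-form optimum, collapsing the program to the smooth
convex loss V(u) = 1/u for u ≥ 1/√C, else 2√C − C·u, minimized under
‖w‖ ≤ 1 by SLSQP with analytic gradients plus a projected-gradient polish
(Armijo backtracking, projection onto the unit ball).  The polish is
globally convergent for this convex program and rescues the rare instances
where SLSQP stalls; with heavily overlapping batches the optimum can lie
strictly inside the ball, so activity of the norm constraint is never
assumed.  The exposed direction is the unit vector w/‖w‖ with the intercept
rescaled to match; the reported objective is that of the raw optimum.
Default penalty C = 100/d̃² with d̃ the median pairwise between-class
distance.  Convergence tolerance is 1e-13 on relative objective decrease; a
`converged` flag and diagnostics are exposed rather than failing silently.

**Batch adjustment.**  Each merge step translates *both* batches along the
fitted direction so their mean projections meet at the pooled midpoint —
a symmetric convention that privileges neither batch (the common alternative
shifts the incoming batch onto the reference); every shift is recorded in an
adjustment log so the convention can be audited.  Multi-set merging is
sequential in descending sample-size order (deterministic, keeps the
reference stable); an explicit order override exists.  Only mean shifts
along one direction per pair are removed — no variance scaling and no
empirical-Bayes shrinkage.

**Mixing check.**  Samples are projected onto the top two principal
components and batch structure is scored as the mean silhouette of the
set-id labels: near 1 when batches cluster apart, near or below 0 when they
interleave.  The default "mixed" threshold is 0.25.

**Group comparisons.**  Welch's t-test by default (pooled-variance Student
selectable), two-sided Mann–Whitney U (exact when both groups are small and
tie-free, otherwise normal approximation with tie correction), and fold
change 2^(Δ mean log2) — the ratio of geometric means, the natural dialect
for log2 data.  The meningeal-only stratum restricts meningeal tumour groups
(SFT/HPC, meningiomas) but compares them against all synovial sarcomas,
which are extrameningeal by nature.

## IHC diagnostic accuracy

A marker is positive at ≥5% stained cells; positives are banded low (5–10%),
intermediate (11–50%), high (>50%).  Contingency tables oppose a disease
group (meningeal SFT, or meningeal HPC) to a reference group — meningiomas
only by default, because that is the clinically relevant differential; a
pooled reference is a config switch.  SE, SP, PPV and NPV carry 95% Wilson
intervals by default (Clopper–Pearson selectable); the source's printed
intervals match neither method exactly, so interval bounds are reported but
never asserted.  Combined rules: AND positive iff all markers positive, OR
iff any; combined bands (min for AND, max for OR) are informational.
Paired marker sensitivities are compared with the exact McNemar test
(two-sided binomial on discordant pairs; p = 1 with a note when there is no
discordance).  Display rounding is one decimal.

## Synthetic data

The generator is the test bed standing in for the real compendium (which
requires external downloads) and defines the conditions all recovery claims
are evaluated under.

*Expression*: each set's matrix is gene baseline + histotype effect (target
gene only, optionally boosted in meningeal samples) + additive per-set batch
offset on all genes + i.i.d. Gaussian noise.  Baselines are drawn once from
the truth seed (N(8, 1.5²) for housekeeping, N(8, 2²) for background genes,
log2 scale) so all sets share them.  Housekeeping genes carry no histotype
effect and default to half the background noise sd — stability is their
defining property.  Affymetrix-style platforms emit redundant `s_at`/`x_at`
probes and the cDNA platform duplicate clones, with probe-level extra noise
proportional to the gene's own noise, so collapsing tie-breaks are exercised.
The study-shaped default (`study_layouts`) mirrors the pooled compendium: 8
sets, 52 SFT/HPC, 161 meningiomas, 30 synovial sarcomas, offsets up to 4
log2 units.  The scaled benchmark (`integration_benchmark`) used by the
recovery tests keeps the stated conditions — noise sd 0.3, batch offsets
spanning 4 log2 units, ≈20 samples per histotype group — across four sets on
four platforms, with 60 housekeeping + 140 background genes so the whole arm
runs in well under a second per replicate.

*IHC*: stochastic mode draws per-sample positivity (Bernoulli) and staining
bands (categorical), with integer percents uniform within the band — the
within-band distribution is a modeling choice, as only banded percentages
are recorded in practice.  Quota mode reproduces exact joint
ALDH1×CD34 counts per histotype group; `STUDY_QUOTA` encodes the published
cohort (25 meningeal SFT, 24+31 HPC by grade, 163 meningiomas, 98 synovial
sarcomas) including the published ALDH1 band composition, which is how the
published accuracy table is reproduced deterministically.

*What the generator does not emulate*: probe-level sequence effects,
intensity-dependent (nonlinear) batch distortions, correlated gene modules,
missing values, and platform-specific dynamic ranges.  Passing recovery
tests therefore show the pipeline is correct under additive offsets and
independent noise — the model class DWD mean-shift correction addresses —
not that it removes arbitrary real-world batch effects.

## Numerical choices and limitations

- Quantile normalization maps ties to the mean of the reference values over
  the tied rank span ("ties = average").
- Stability selection, probe collapsing and merging order are all
  deterministic given inputs; every pipeline artifact embeds the config hash
  and seed, making reruns bitwise identical.
- Fold-change recovery is assessed as the median estimate across replicate
  seeds: at noise sd 0.3 with ~20 samples per group, a single replicate's
  log2 mean difference has sampling sd ≈ 0.095, so individual replicates
  can exceed 15% relative error by sampling alone.
- The DWD adjustment assumes the batch difference is a mean shift on the
  anchor-gene space; histotype imbalance between batches can leak biology
  into the fitted direction.  The anchor trick mitigates this (only the
  target gene carries histotype signal among the anchors), which is why
  integration is anchored rather than run on all genes.
- Published mRNA contrasts (fold changes 9.5/3/20.2/6.4 and their p-values)
  depend on the real pooled data sets and are not reproduced numerically;
  the synthetic benchmark instead checks that configured effects in the same
  regime are recovered and that batch structure disappears after adjustment.
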