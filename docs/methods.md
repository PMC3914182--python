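# Methods

This note documents the models and procedures mirkit implements, the
defaults it ships, and the choices made where the design was genuinely open.

## Coordinates and alphabets

All external coordinates are 1-based and inclusive on the given (sense)
strand, matching the field's "nucleotides 2–7" convention for seed spans.
Sequences are uppercase over {A,C,G,T/U,N}; lowercase (soft-masked) input is
uppercased with a warning because masking carries no information for seed
matching or alignment at these scales.  N is accepted everywhere but never
satisfies a seed match — a deliberately conservative call, since an
ambiguous base cannot be asserted complementary.

## Pre-miRNA conservation

Hairpin orthologs are 70–90 nt and families number at most a few dozen
sequences, so the aligner is a small exact one rather than a wrapper around
an external tool: global Needleman–Wunsch (match +1, mismatch −1, linear gap
−2 by default, all configurable) with a fixed traceback preference
(diagonal, then up, then left) for determinism, wrapped in a center-star
progressive strategy.  The center is the sequence minimising the summed
3-mer distance to the rest; every other sequence is aligned to it pairwise
and merged under "once a gap, always a gap".  For substitution-dominated
hairpin families this recovers the alignment a general-purpose progressive
aligner would produce, and it keeps the whole stage dependency-free and
unit-testable against a brute-force dynamic-programming oracle.

Column conservation is the modal-residue fraction among non-gap residues —
chosen over entropy because it maps directly onto a conserved/not-conserved
presentation; an entropy-based score (1 − H/2 bits) is available via
`metric="entropy"`.  Columns that are all gaps are undefined (NaN) and
excluded from region means; columns with gap fraction > 0.5 are flagged.
Region spans (mature/star/loop) are declared on one reference sequence and
projected through its aligned row, because hairpin annotations are defined
on the reference molecule, not per species.

## Target prediction

A UTR is a target iff it contains ≥ 1 perfect seed match; site counts are
reported but do not affect target status.  The canonical and default site
class is the 6mer (reverse complement of mature positions 2–7 on the UTR
sense strand); 7mer-m8 extends pairing to position 8, and 7mer-A1/8mer
append an A opposite position 1 at the site's 3′ end.  Scanning is on the
given strand only — a 3′UTR is single-stranded transcript sequence.  All
overlapping occurrences are reported.  No thermodynamic or context scoring
is attempted.

The conserved-target fraction is 100·overlap/denominator with half-up
rounding.  When 9 reference-conserved genes are scored against the
83-target prediction the fraction is 10.84 → 11%.  The denominator is the
number of predicted target UTRs (83-style bookkeeping) rather than the
number of successfully mapped homologs (76); with only 76 of 83 targets
mappable the two conventions differ (10.8% vs 11.8%), and the predicted-set
denominator is the more conservative, self-contained choice.  It is
overridable via the `denominator` argument.

The working mature miR-122 sequence bundled in `mirkit.data` is the
validated mature-form qPCR forward primer expressed as RNA.  It is a proxy:
the primer may carry bases beyond the exact mature 3′ end, which is why the
seed span, not the full length, drives every downstream decision.

## Sub-network enrichment

Each gene set is intersected with the scored universe (ids matched
case-insensitively after trimming) and compared to the background with a
two-sided Mann–Whitney U test.  The background is the universe minus the
set's members — the standard competitive construction; commercial
implementations do not document their exact choice, so the disjoint form is
used and stated.  The p-value is exact by enumeration when n₁+n₂ ≤ 12 with
no ties, and otherwise a tie-corrected normal approximation with continuity
correction; on a 5000-gene universe with sets of 10–30 the approximation's
null rejection rate at α = 0.05 sits within Monte-Carlo error of 0.05
(verified over 2000 simulated null sets).  Sidedness is two-sided by
default since an a-priori direction is not generally available.  For binary
(membership) universes a hypergeometric upper-tail p-value is computed
alongside.  Significance flags use the raw p < α (the customary sub-network
filter); Benjamini–Hochberg q-values are always reported so users can
filter on FDR instead.

## Inhibitor design

IsomiRs share the 5′ core and vary 3′, so the inhibitor is the DNA reverse
complement of mature positions [anchor, anchor+length−1] with the anchor at
position 2 — inside the shared core, covering the seed, indifferent to 3′
ends.  With the bundled mature sequence, length 13 and anchor 2 this yields
ATTGTCACACTCC.  Verification is an exhaustive search over all contiguous
mature substrings for the longest one whose reverse complement occurs
contiguously in the oligo (ties broken toward the 5′-most start), so it
serves as its own specification; matching is pure Watson–Crick on the DNA
representation with no wobble pairs and no LNA chemistry modelling, because
the design rule is purely sequence-complementarity.  The off-target screen
flags any panel miRNA whose seed reverse complement appears in the oligo.

## qPCR quantification and group statistics

Because per-gene amplification factors E are measured quantities
(typically 1.8–2.2, i.e. 90–110% under the E/2 percent convention; the
100·(E−1) convention is also supported for display), the efficiency-
corrected ratio is the default:

    ratio_s = E_t^(C̄t_cal,t − Ct_s,t) / E_ref^(C̄t_cal,ref − Ct_s,ref)

with the calibrator C̄t the arithmetic mean Ct of the control group, which
fixes the control group's geometric-mean ratio at exactly 1.  Technical
replicates are averaged at the Ct level first (standard practice).  A ddCt
mode forcing E = 2 is provided.

Assumption checks are Shapiro–Wilk on pooled within-group residuals and
Levene's test; if either fails at α the module recommends a log₁₀ transform
and re-checks, reporting both rounds rather than silently transforming —
which transformations a given study actually applied per endpoint is rarely
recorded, so the module logs the trigger instead of guessing.

One-way ANOVA is the classical between/within decomposition (the identity
SS_total = SS_between + SS_within is asserted to 10⁻¹⁰ relative error in
tests; F on two groups equals the pooled t squared).  The SNK post-hoc
orders group means descending and steps down from the widest range: a range
of r means is rejected when q = Δmean/√(MS_within/n_h) exceeds the
studentized-range quantile at (r, df_within), with n_h the harmonic mean of
the two group sizes; an accepted range protects all its sub-ranges.  This
protection makes the non-rejection relation interval-shaped over the
ordering, so the compact letter display is the set of maximal non-rejected
intervals, and "different letters" is exactly the pairwise rejection
relation.  Because SNK's critical values shrink with the range while
Tukey's HSD uses the widest-range value throughout, SNK's rejection set
contains Tukey's (asserted on simulations).

## Simulators

Simulators are pure functions of (config, seed) — numpy `default_rng` —
and every output carries a truth record with the seed and a config hash.

**UTR pools.** Lengths uniform on [200, 1500] nt, uniform base composition.
Defaults are the study scale: 1059 UTRs with planted-target fraction
83/1059, one site per target.  In the default "clean" mode, non-target UTRs
(and target backbones before insertion) are rejection-sampled to be
site-free so recall and precision are exact rather than probabilistic; a
"natural" mode skips rejection for analytic background-rate properties
(uniform 1000-nt UTRs carry (1000−5)/4⁶ ≈ 0.243 expected 6mer sites each).
Planting can create incidental extra occurrences at insertion junctions,
which is why recall is asserted as a superset on positions and exact on
target membership.

**Hairpin families.** A star phylogeny: one random 80-nt ancestor,
per-species i.i.d. substitutions at region rates (mature 0, star 0.05, loop
0.30 by default; replacement uniform over the other three bases), no
indels, 15 species.  This emulates the conservation gradient of a real
hairpin but not phylogenetic correlation structure, rate heterogeneity
(GTR-style), or indels — so passing tests show the profiling machinery
ranks regions correctly under the intended signal, not that the aligner
handles indel-rich families.

**Gene-set universes.** Continuous scores N(0,1) with planted sets' members
shifted by (factor − 1); binary mode elevates membership probability
(baseline 0.05) by the factor.  Factor 1 is the null.

**Assays.** Three groups (saline, low-dose, high-dose), n = 6 per group.
Planted fold change f maps to a Ct shift of −log_E(f); biological noise is
normal on the Ct scale (sd 0.25 cycles), technical duplicates add sd 0.10,
reference genes (u6, ef1α) are effect-free by construction.  Default gene
effects encode the study system's directions: the three miR-122 isomiRs
down ~3-fold at both doses, three non-targeted miRNAs flat, three
de-repressed targets up 2-fold (fold magnitudes are representative choices;
in vivo reports of this system give directions and significance groupings
rather than exact fold values).
Metabolites are lognormal with CV 10% (plausible for plasma assays) around
group means baseline·(1+effect/100), with lognormal μ chosen so the
arithmetic mean equals the target; default percent effects are glucose
+62/+67%, triglycerides −10/−36%, free fatty acids −15/−46%, cholesterol
−20/−20% (low/high dose; the low-dose lipid values are chosen smaller than
the reported high-dose effects, which were the significant ones).
Baseline concentrations (glucose 5, triglycerides 2, free fatty acids 0.3,
cholesterol 9 mmol/L) are plausible postprandial trout plasma values.

At n = 6 and CV 10%, the sampling standard error of a +62% recovered effect
is ≈ 9 percentage points, so single-seed small-n recovery is only loosely
constrained; the suite therefore checks calibration properties at n = 6
(null ANOVA rejection ≈ α across 1000 seeds) and tight recovery (±1 point)
at n = 600 per group, where the estimator's noise is below a point.

## Problem sizes in the test suite

The suite runs on desk-scale problems chosen to keep oracles exact and
calibration bands tight: 500-UTR brute-force scanner comparisons, 10⁴ UTRs
for the background-rate check, 2000 null gene sets for MWU calibration,
1000 simulated assays for ANOVA calibration, 20 replicate families for the
conservation gradient.

## Known limitations

* The aligner has linear (not affine) gap costs and no guide tree beyond
  center-star; it is not meant for indel-rich or divergent families.
* The MWU exact path requires tie-free data; heavily tied small samples
  fall back to the tie-corrected approximation.
* The compact letter display relies on SNK's interval structure; for
  pathological unequal-n layouts where non-rejection is not interval-shaped
  the letters follow the ordered intervals.
* Enrichment consumes user-supplied GMT gene sets; building sub-networks
  from relationship databases is out of scope.
* No RNA secondary-structure prediction, thermodynamic site scoring, or
  LNA chemistry modelling.
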