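# Methods

## The system and the analysis

*Osedax* bone worms acquire Oceanospirillales endosymbionts from the
environment after larval settlement, so the strain composition within and
among hosts reflects local bacterial dynamics rather than vertical
inheritance.  The analysis operates on 672-bp 16S amplicons obtained with
the Oceanospirillales-specific degenerate primer pair
435F `CAGCWGTGAGGAAAGGTT` / 1213R `TGTGTAGCCCAACTCG` (W = A or T; the
reverse primer is given 5'→3' on the opposite strand).  A *ribotype* is a
strain distinguished by a unique 16S sequence; a *ribospecies* is a cluster
of ribotypes sharing ≥97% identity, the OTU-like unit used for all
contingency analyses.  Coordinates are 1-based within the trimmed amplicon.

## Trace calling and the detection limit

Direct Sanger sequencing of a mixed template superimposes the constituent
strains' peaks.  Calling uses the half-height rule: with primary peak
height h₁ and secondary h₂ at a column, the call is the primary base if
h₂ < r·h₁ and the two-fold IUPAC code for the top two bases otherwise,
with r = 0.5 by default.  "At least half" is inclusive (h₂ = 0.5·h₁ calls
an ambiguity), and tertiary peaks are never considered: in real
chromatograms they are confounded with background, so only two-strain
resolution per column is attempted.  Calls are scale-invariant in the
heights.  Ties in peak height are broken in A<C<G<T order; a 50:50 column
is ambiguous under any tie order.

Under the proportional-peak model a minority strain at fraction f yields
h₂/h₁ = f/(1−f), so it is detected iff f ≥ r/(1+r) — exactly 1/3 at
r = 0.5.  On a 10%-grid dilution series with no noise this gives detection
at 40:60, 50:50 and 60:40 only, independent of SNP position.  The
position-dependent onsets seen in the shipped empirical series (detection
at 30:70, in one mixture at 20:80) require amplification noise: the
forward model draws one multiplicative efficiency exp(N(0, σ)) per strain
per trace (not per position — the simplest model consistent with
primer-binding bias), which makes detection near the 1/3 limit
probabilistic and monotone in the minority fraction.  Calibrating σ to
reproduce the empirical onsets is illustrative only (the physical mechanism
is unidentified) and lives in `analysis/02_call_mixed_infections.py`, not
in any tested contract.

`detection_probability` integrates the detection rule over a distribution
of minority fractions on [0, ½] and reports the implied underestimation
factor for multiple-infection frequency; for fractions uniform on (0, ½)
the detection probability is exactly 1/3.

## Phase resolution

A consensus with exactly one ambiguity code is decomposed manually into its
two forced ribotypes.  Multi-site mixtures are resolved against clone
libraries: haplotypes seen once are discarded as cloning artifacts;
retained haplotypes must carry, at every ambiguous consensus position, a
base within that code's expansion (violators are flagged inconsistent);
ambiguous positions at which the consistent retained clones do not exhibit
two distinct bases remain unresolved and are masked with N, and masked
sites are subsequently excluded by pairwise deletion in all distance
computations.  The resolver deliberately does not invent an unobserved
complementary phase from a lone clone haplotype — mutation phases are not
identifiable from one observation — but a strict-two-strain complement
inference is available behind an off-by-default flag.  Ribotypes observed
only once in a survey are flagged for confirmation by re-amplification.

## Distances, diversity, clustering

All distances are uncorrected p-distances with pairwise deletion: sites
where either sequence carries a gap, N, or an ambiguity code are excluded
from that pair.  Model-corrected distances are out of scope; at ≤3%
divergence the correction is smaller than the rounding of the published
values.  S counts columns with ≥2 distinct unambiguous bases; π averages
pairwise p-distance over all n(n−1)/2 pairs; k averages raw difference
counts (π·L = k exactly on clean alignments); θ_S = S/(a·L) with
a = Σ 1/i.  The effective length L for θ_S defaults to the number of
columns free of gaps/N/ambiguities in every sequence and is always reported
alongside θ_S, because a published θ_S is not reproducible without knowing
the site-exclusion convention behind it (the value depends on L directly).

Ribospecies clustering is agglomerative with average linkage (mean
p-distance over all cross-cluster pairs, maintained exactly by the
Lance–Williams update), merging while the smallest between-cluster distance
is ≤ the 3% threshold.  Linkage choice is substantive, not cosmetic: the
two dominant ribospecies differ minimally by 13 substitutions (≈1.9%) but
by 3.5% on average, so single linkage collapses them while average linkage
keeps them apart.  Ties are broken by merging the pair whose sorted
(smallest-member-id, partner-id) key is lexicographically least, making the
partition invariant to input order.  Within-group divergence is undefined
for singleton groups and reported as not-computable (NaN), matching the
"n/c" convention of published divergence tables.

## Parsimony networks

Networks are built minimum-spanning-network style: distance levels are
processed in increasing order; at level d, every pair of haplotypes lying
in different components (membership frozen at the start of the level) is
connected, so equally parsimonious alternative connections all enter
(reticulation allowed).  A d-step connection is expanded into a path of
d−1 inferred intermediate nodes, each edge representing one mutation;
intermediate sequences are left abstract because mutation order along the
path is unidentifiable.  Pairs beyond the connection limit (default 20
steps) stay in separate subnetworks.  The TCS 95% statistical-parsimony
connection limit is not reproduced; the limit is an explicit parameter
instead, and networks are naturally built per ribospecies.  Overlays
attach per-node category proportions (sampling period, host species) from
labeled observations; unlabeled observations are excluded, and inferred
nodes carry no overlay.

## Contingency analysis

Expected counts are E = R·C/N; the G statistic is 2 Σ O ln(O/E) with
0·ln 0 = 0, natural logarithm, df = (r−1)(c−1), and the p-value from the
chi-square upper tail.  Zero cells are fine; zero margins are rejected
with advice to lump.  No Yates or Williams correction is applied by
default — the published statistics are uncorrected — but both are
available behind flags.  `lump_rare` collapses rare categories into
"other", the standard guard against sampling-zero artifacts, and
`subset_test` recomputes margins from a row/column selection before
testing.  One published quirk is preserved in the fixtures and surfaced in
their metadata: the date×ribospecies table prints df = 5 for a 5×2 layout
(true df = 4; the G value itself reproduces), and the host×ribospecies
table's row labels are swapped relative to the date table's totals.

## Compartmentalization

Dissection cells use a small dialect: "-" not dissected, "na" dissected
without amplification, commas separate independently examined ovisac
lobes, and "+" joins ribotypes co-occurring within one lobe.  Repeated
identical labels collapse.  Success rates are reported under two
denominators (dissected tissues, or all worms), because the published
per-tissue percentages mix conventions; both are always printed with their
numerator and denominator.  The published root-tissue figure (38.09%)
numerically equals the basal-trunk column over all 21 worms, not the
posterior ovisac/root column; the package reports both columns under their
own names.  The published inner-ovisac figure (78.95% = 15/19) is not
reproducible from the dissection table under any single counting
convention tried (dissected = 17, successes = 14) and is therefore not a
target.

Compartmentalization — different strains segregated between tissues — is
assessed by default between the outer ovisac sheath and the inner ovisac,
the adjacent layers where segregation is observable in this design: a worm
is flagged when both amplified with different ribotype sets.  This is the
package's own reading of an under-specified published criterion; a literal
any-pair-disjoint mode is available, but it both misses a worm whose
inner-ovisac set strictly contains the sheath set and catches a worm whose
trunk mixture places its two strains in different single-tissue calls —
i.e. it conflates within-tissue mixture with between-tissue segregation.
Within-tissue mixtures are reported separately.  Worms with fewer than two
amplified tissues are not assessable.

## Synthetic data

The generators define the study conditions for every simulation-based
check.  Defaults: 672-bp sequences; two ribospecies of 29 and 3 ribotypes
(the directly sequenced survey composition); within-group p-distance
≤ 0.03 and between-group mean ≥ 0.035; 1–9 strains per worm (clone
libraries showed 2–9, but single-strain calls must be generable);
strain fractions Dirichlet(1) — no within-host fraction distribution is
published, so the flat simplex is the declared modeling choice, exposed in
the config; per-strain log-efficiency σ = 0.2, a modest amplification bias
consistent with occasional detection-onset shifts of one grid step; survey
design cloned from the published marginals (dates with 32/19/35/34/33
worms, N = 153; per-date ribospecies quotas; pooled host and bone
probabilities).  Divergence guarantees hold by construction: each species
carries a disjoint block of ⌈0.035·L/2⌉ private substitutions from a root
sequence and each ribotype 1…⌊0.03·L/2⌋ private substitutions from its
centroid, so every within-pair distance is ≤ the cap and every
between-pair ≥ the floor exactly.  Mutations are substitutions only and
alignments are gap-free, matching the trimmed equal-length segments the
analysis assumes.  Every generator is a pure function of (config, seed).

What the generator does not emulate: sequencing error, chimeras,
position-dependent amplification bias, indels, and phylogenetic
(coalescent) structure within ribospecies.  Passing tests therefore show
that the pipeline's logic and statistics behave correctly under the stated
forward model, not that real chromatograms meet that model.

## Statistical calibration choices

The type-I-error check runs G-tests on surveys in which host species and
ribospecies are drawn independently.  It uses a design under which the
chi-square approximation is valid — hosts lumped to the two dominant
species plus "other" at study proportions and a balanced two-ribospecies
null, giving every expected cell ≥ 17 — because at the raw pooled survey
margins the smallest expected cell is ≈1.9 and the asymptotic G-test is
intrinsically anticonservative (≈6.7% rejections at α = 0.05 by direct
simulation).  That inflation is a property of the approximation, and the
very reason the lumping step exists; measuring it would say nothing about
the implementation.  Power is checked end to end (simulate → trace → call
→ cluster → G-test) against the published survey's own date×ribospecies
quotas, a very large effect (G ≈ 57 on 4 df), over 40 replicate surveys;
the calibration run uses 1000 null replicates.  These problem sizes keep
the full suite around half a minute while leaving the binomial noise small
relative to the margins being asserted.

## Known limitations

* The deposited 48-accession diversity check needs the sequences fetched
  from GenBank; they are not redistributed with the package.
* Published θ_S is reported but not targeted (effective-length convention
  unknown; see above).
* The survey totals (N = 153) are smaller than the 162 worms examined in
  the source survey; the exclusion rule for the difference is unpublished,
  so the fixtures carry the printed totals as-is.
* Inferred network intermediates are anonymous; figure-level node
  placement is not reproduced, only counts, topology and overlays.
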