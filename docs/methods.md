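# Methods

This note documents the models and procedures implemented in `beemito`,
the defaults they use, and what the synthetic-data generator does and
does not emulate.

## The COI-COII marker and lineage assignment

The mtDNA region between the tRNA-leu and COII genes of *Apis mellifera*
contains a cassette of non-coding tandem elements whose composition
separates the major maternal lineages: a single Q element and no P-type
element is characteristic of the Southeast-European C-lineage; one
P-type element followed by one to three Q copies marks the African
A-lineage (long variant, written P0) or the West/North-European
M-lineage (shortened variant, P).

`repeat_typing.detect_elements` finds elements by semi-global alignment
of each consensus (P, P0, Q) against the sample sequence: the consensus
must align end-to-end, unaligned sample flanks are free. Scoring is
match +1, mismatch −1, gap −2; identity is matches divided by alignment
columns over the consensus-spanning region. Detection is greedy: the
best-scoring hit at or above `min_identity` (default 0.8) is accepted,
its span is removed from the search space, and the search repeats.
Because P and P0 compete for the same locus, the higher-identity variant
wins; the default consensi are ~69% cross-identical, far enough apart
that a 2% mutation load cannot flip a call. Hits are reported with
0-based half-open coordinates. The structure string concatenates hit
names in genomic order; `assign_lineage` maps `Q` → C, `P0 Q{1..3}` → A,
`P Q{1..3}` → M, anything else → `unknown` (the string itself is never
altered, so out-of-grammar detections remain visible).

The element consensi shipped in `beemito/data/elements.fasta` are
synthetic AT-rich sequences of realistic lengths (Q 196 bp, P0 67 bp,
P 52 bp, flanks 45/60 bp); P is derived from P0 by a 15-bp deletion and
a handful of substitutions, mirroring the biological relationship
between the two variants. They are configuration, not truth: any FASTA
with records named P, P0, Q (and optionally TRNA_LEU/COII) can replace
them, so the pipeline can be pointed at curated consensi without code
changes.

`in_silico_dra1` reproduces the classic DraI PCR-RFLP readout: the
recognition site TTTAAA is cut between the third and fourth base,
scanning left to right so that a site destroyed by an earlier cut is not
used; fragment lengths always sum to the input length.

## Kin deduplication

Workers foraging near each other may be daughters of one queen, so
close samples are not independent. All pairs closer than `max_dist_km`
(default 5 km, haversine on WGS84 decimal degrees) are examined in
ascending distance order. A pair is collapsed only when (i) both members
carry the same mitotype (exact sequence identity) and (ii) their
Queller–Goodnight relatedness significantly exceeds zero — the lower
percentile-bootstrap bound (loci resampled with replacement, default
1000 replicates, 95% level) is above 0. The lexicographically later
sample id is dropped; already-dropped samples are skipped in later
pairs. The greedy order and drop rule are arbitrary but deterministic,
which we prioritised because the original field protocol does not state
which member of a pair was removed.

The estimator is the moment-based Queller–Goodnight coefficient for a
focal x = (a,b) against partner y = (c,d): per locus the numerator is
0.5·(S_ac+S_ad+S_bc+S_bd) − p_a − p_b and the denominator
1 + S_ab − p_a − p_b, with S an identity-in-state indicator and p the
population allele frequency. Loci are combined as a ratio of sums
(numerators summed over loci divided by summed denominators), which
stabilises loci with rare alleles; zero-denominator loci are skipped
direction-wise; the reported r is the mean of the two directed
estimates, making it symmetric by construction. A self-comparison gives
r = 1 exactly at any frequencies. Reference frequencies are computed
from the full sample including the focal dyad — the simplest
deterministic choice; note that with only the dyad itself genotyped the
denominators vanish and r is undefined (the pair is then kept). Under
honeybee haplodiploidy, super-sisters (same queen, same haploid drone
father) have expected r = 0.75; the simulation suite verifies the
estimator is unbiased within ±0.03 for super-sisters and ±0.02 for
unrelated dyads, and that ≥80% of super-sister pairs at 13 loci are
flagged significant.

## Statistical-parsimony haplotype network

Aligned unique mitotypes are collapsed by exact identity
(`call_haplotypes`, ids H1..Hk by decreasing count, ties by first
appearance). Gaps are handled by simple indel coding: each distinct
contiguous gap run (unique start and end) becomes one binary
presence/absence character; a haplotype whose own gap strictly contains
(or partially overlaps) another run is scored missing for that
character; characters without both a present and an absent carrier are
dropped. Pairwise distance is substitution differences at columns where
neither sequence is gapped (ambiguity codes never count) plus one step
per determinate indel-character difference.

The network is built agglomeratively, TCS-style: haplotype pairs are
visited in ascending distance (ties by lexicographic id pair) and
connected only if no path of at most that many steps already exists; a
d-step connection inserts d−1 unsampled median nodes; pairs beyond the
connection limit are never joined, so the result may have several
components. Node degrees and component membership are invariant to
input order whenever haplotype counts are distinct (id numbering is the
only order-dependent quantity).

The connection limit is the largest number of observed differences j
for which the parsimonious interpretation — exactly j mutations, no
superimposed hits — still has probability at least `conf` (default
0.95). We model the unknown true number of mutations between two
sequences as Poisson, spread uniformly over the m aligned sites, with
the Poisson mean moment-matched so that the expected number of hit
sites equals j (λ = −m·ln(1 − j/m)), and compute
P(M = j | J = j) by conditioning through the classical occupancy
distribution (Stirling numbers of the second kind, evaluated in log
space). The probability is monotone decreasing in j and the limit is
monotone in alignment length and in confidence. A seeded Monte-Carlo
oracle — simulate Poisson mutation placement, condition on the observed
number of differing sites — agrees with the closed-form computation
within one step at m = 100 and within estimation noise elsewhere.
`--fixed-limit` overrides the computation for users who want a specific
limit. For a ~1000-site alignment at 95% the limit is 10 steps; it
collapses to ≤3 for toy alignments under ~150 sites, which is expected
behaviour, not a defect.

## Frequencies and clines

Structure and lineage frequencies are binomial proportions k/n with
exact (Clopper–Pearson) intervals from Beta quantiles: lower
Beta⁻¹(α/2; k, n−k+1) (0 when k = 0), upper Beta⁻¹(1−α/2; k+1, n−k)
(1 when k = n). The exact method is conservative: simulated coverage at
n = 427, p = 0.0164 exceeds the nominal 95%. Reports round half-up,
proportions to 3 decimals and percentages to 2, which reproduces the
printed survey values digit for digit: with counts {Q 376, PQ 1,
PQQ 36, PQQQ 7, P0Q 2, P0QQ 5} out of 427, the A-lineage is 1.64%
(0.66–3.35%), C 88.06% (84.60–90.98%), M 10.30% (7.59–13.59%).

The geographic model is a binomial GLM with logit link:
presence ~ intercept + latitude (per degree) + transect, where transect
is a two-level factor splitting samples west/east of 20° E with
*eastern* as the reference level (so the reported coefficient is
western relative to eastern). Fitting is IRLS via statsmodels; the fit
reports Wald z tests, the model χ² (null deviance minus residual
deviance, df = number of fitted slopes) and McFadden's pseudo-R²
(1 − ℓ_model/ℓ_null). Quasi-perfect separation is flagged, not raised;
a one-class response is returned as non-estimable. If every sample lies
on one side of the demarcation meridian the factor is dropped from the
design rather than fitted unidentifiably. The fit agrees with a
brute-force gradient maximiser of the Bernoulli log-likelihood to six
decimals on small instances.

## The synthetic-data generator

The generator provides every input with known truth. Its defaults are
the study conditions: 444 bees of which 17 are planted kin duplicates
(leaving 427 independent samples), structure mixture weights
{Q 376, PQ 1, PQQ 36, PQQQ 7, P0Q 2, P0QQ 5}, 13 microsatellite loci
with 10 equifrequent alleles (heterozygosity 0.9, typical of honeybee
marker panels), substitution rate 1.5·10⁻⁴ per site per individual and
indel rate 10⁻⁵ (lengths 1–3) — rates chosen so a 427-bee survey yields
on the order of 45 unique mitotypes — and two ~900 km meridional
transects near 17.5° E and 23° E spanning latitudes 46.5–54.5° N.

Structure counts are apportioned deterministically (largest remainder)
rather than drawn multinomially, so the default weights at n = 427
yield exactly the canonical counts; which *sites* receive the A- and
M-lineage quotas is decided by weighted sampling without replacement
(Gumbel-top-k) with weights from per-lineage logistic clines, so exact
counts coexist with realistic spatial trends. The standalone
`simulate_geography` instead draws presence i.i.d. from the logistic
model (default M-lineage coefficients: intercept −29.638, latitude
0.535, west transect −0.615), which is the right generating process for
coefficient-recovery experiments.

Sampling sites are placed by sequential rejection with a 7 km minimum
separation, reflecting a design in which each site is a distinct apiary
and distinct apiaries are independent data points; each kin duplicate
is placed 0.5–2 km from its focal sample and carries its focal's exact
mtDNA sequence (same mother). A consequence worth stating: only planted
pairs ever fall inside the 5 km deduplication radius, so the filter's
false-positive behaviour on unrelated neighbours is exercised by the
dedicated statistical tests, not by the end-to-end run. Pedigrees are
haplodiploid: super-sisters share the drone's allele at every locus and
the same maternal allele with probability 1/2.

What the generator does not emulate: coalescent structure (mutations
are i.i.d. per individual, so shared derived polymorphism between
unrelated bees is rare), sequencing artefacts and chromatogram noise,
heteroplasmy, within-colony drift, and real-world clustering of
apiaries. Passing the end-to-end tests therefore demonstrates that the
pipeline's logic is correct under its stated assumptions, not that the
element consensi or rates match any particular wild population.

## Problem sizes and numerical choices

The test suite runs the full study at its natural size (444 bees,
427 after deduplication), 200 cline replicates at n = 427, 10⁵
Monte-Carlo replicates per step count for the connection-limit oracle,
10⁴ binomial draws for CI coverage, and 1000 unrelated plus 100
super-sister dyads for estimator calibration; the whole suite completes
in well under a minute on one core. Bootstrap and simulation seeds are
fixed in tests and flow from a single `--seed` in the CLI and the
acceptance script. Degenerate inputs are handled explicitly: empty
annotation for sequences shorter than every consensus, undefined r for
dyads without two usable loci, non-estimable logistic fits for
one-class responses, and header-only network files for empty graphs.

## Known limitations

* Named haplotype nomenclature within lineages (A1e, A4, A4s, C2
  variants) is out of scope; the pipeline reports structure strings and
  lineage calls only.
* Multiple-sequence alignment is out of scope; `call_haplotypes` and
  the network module expect pre-aligned input (align externally, e.g.
  with MAFFT).
* The connection-limit model assumes mutations land uniformly and
  independently across sites; rate heterogeneity would lower the true
  parsimony probability at a given j.
* Relatedness reference frequencies include the focal dyad; with very
  small genotype tables this biases denominators toward zero (a config
  switch to exclude the dyad would be a straightforward extension).
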