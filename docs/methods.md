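# Methods

## Scope and data model

The pipeline operates on site-level label-free phosphoproteomics
quantifications: one record per phosphosite × peptide-multiplicity state,
carrying the protein accession, gene symbol, 1-based residue position,
residue (S/T/Y), MaxQuant localization probability and delta score, and
one intensity per sample. Intensities of 0 and empty cells are read as
missing — MaxQuant's convention for unquantified cells — which is a
precondition for meaningful valid-value filtering. Gene symbols are
uppercased at the I/O boundary and are the join key to gene sets and
interaction edges.

The study design is four groups (C control, H disease, S and E
treatments) × three replicates, with ordered contrasts defaulting to H/C,
S/H, E/H; E/C and S/E can be declared. Every table written to disk carries
a provenance header (pipeline version, config hash) and floats at 12
significant digits so a re-read round-trips values.

## Site processing

Stages, in the default order:

1. **Class-I filter**: keep sites with localization probability ≥ 0.75
   and delta score ≥ 8. Both thresholds are inclusive, exactly as
   conventionally stated.
2. **Valid-value filter**: keep sites quantified in ≥ 50% of the samples
   of at least one group. With 3 replicates this means 2 of 3 (the
   fraction is compared, not a rounded count: 1/3 fails, 2/3 passes).
3. **log2 transform** (missing preserved; zeros are already missing).
4. **Median normalization**: each sample's median over observed values is
   subtracted and the grand median of the pre-normalization sample medians
   added back, so all sample medians coincide and the overall location is
   preserved. One pass is exact; a second pass is the identity.
5. **Group-mean imputation**: a missing cell is filled with the
   arithmetic mean of its own group's observed values when that group is
   ≥ 50% observed for the site (missingness ≤ 50%); groups below the
   threshold stay missing, observed cells are never touched.

Imputation runs last, on the normalized log2 scale, because a raw-scale
arithmetic mean is dominated by the highest intensities; `stage_order`
permits any permutation, including imputing on the raw scale before
filtering, for users who want the literal published ordering. Whether the
original analysis imputed on the raw or log2 scale, and whether the
confidence filter preceded the valid-value filter, is not stated there;
both orders run here and neither is asserted as the original.

A caveat stated here because it matters for inference: group-mean
imputation shrinks within-group variance (imputed cells sit exactly at
the group mean), which inflates downstream t-statistics. On null data the
measured p < 0.05 fraction rises from the nominal range to ≈ 0.063 after
imputation. This is a property of the published imputation scheme, not of
this implementation; calibration checks therefore run pre-imputation, and
users needing calibrated p-values should consider `impute: none`.

## Differential sites

For contrast N/D, per site: log2FC = mean(N) − mean(D) over observed log2
values, and a two-sided two-sample t-test. Welch (unequal variance) is
the default; Student's pooled-variance test is available. Sites with
fewer than two observed values in either group are reported with p = NA
and call = ns rather than dropped. Calls: *up* iff log2FC ≥ log2(1.5) and
p < 0.05 (raw p by default, Benjamini–Hochberg optional), *down*
symmetrically. The thresholds are field-standard defaults, configurable;
the original study prints no cutoffs, so its significant-site counts
(844 / 1,084 / 1,552) are not reproduction targets — the package's
acceptance checks only verify that the printed up/down splits sum to the
printed totals.

Small-sample caveat: with n = 3 per group the Welch–Satterthwaite degrees
of freedom estimate makes the Welch test conservative (measured type-I
≈ 0.028 at α = 0.05 on null normal data; ≈ 0.032 under MNAR missingness,
where the observed values are additionally non-normal by selection).
Student's t is exact under the generator's normal equal-variance noise and
is what the calibration check runs; Welch is kept as the robust default
for real data, where equal variances cannot be assumed.

## Enrichment

One-sided over-representation per gene set: p = P(X ≥ k) for
X ~ Hypergeom(N, K, n), with n the foreground (proteins carrying ≥ 1
significant site in the contrast; a protein with both up and down sites
counts once), N the background (all quantified proteins post-processing
by default — standard practice; a supplied universe is accepted), K the
set's background members, k the overlap. This equals the one-sided
Fisher's exact test on the 2×2 table. The enrichment score is
(k/n)/(K/N). Ranking is by (p ascending, score descending, set id), a
total order, so the top-20 selection is deterministic. No GO-graph
propagation is performed; annotations are flat sets as provided. No
multiple-testing correction by default (the original work reports
uncorrected Fisher p-values); BH is available.

## Reversal screen

A protein is a reversal hit for treatment T when it has a significant
site in one direction in H/C and a significant site in the opposite
direction in T/H. Matching is protein-level by default — the two sites
need not coincide, since published examples reverse at different residues
of the same protein (e.g. Down at Ser802 in disease, Up at Ser869 under
treatment) — with a stricter same-site mode available. Classes: *down_up*
(only Down→Up site pairs), *up_down*, *mixed* (both patterns on distinct
pairs; a single pair can never be mixed). Hits are then restricted to
proteins in the top-20 enriched KEGG pathways; which contrast's top-20 is
used (disease, treatment, or their union) is configurable, union by
default. Both differential tables must descend from the same processed
site table, enforced by a provenance hash.

## PPI subnetworks

Edges are canonical undirected pairs with a confidence in [0, 1]
(STRING flat-file milli-scores are divided by 1000 at read time; the
combined score is assumed). The filter keeps confidence ≥ 0.7, inclusive.
The subnetwork is induced on exactly the reversal-hit proteins; isolated
hits are retained and flagged, components are ordered largest-first and
hubs are top-k by degree with lexicographic tie-break.

## Synthetic studies and what they do (and do not) show

The generator emulates the study at the quantified-site level (no
spectra, identification or retention-time simulation). On the log2 scale:

x[site, sample] = base + protein effect + site offset + group effect + noise

with defaults: base 23, protein effect ~ N(0, 2²), site offset ~ N(0, 1²),
replicate noise ~ N(0, 0.3²), 21,239 sites on 4,290 proteins (every
protein ≥ 1 site), S/T/Y drawn at 82.76/16.12/1.12%, multiplicity classes
1/2/3/3+ at 17,003:2,824:571:95, localization probability ~ Beta(6, 1)
(≈ 18% below 0.75, so the class-I filter has work to do), delta score ~
Gamma(2, 15) (≈ 10% below 8). Intensities are 2^x (log-normal, the
standard LFQ assumption).

**Effects.** 5% of sites, assigned protein-wise, receive a ±1.5 log2
group effect in H vs C. 30% of the differential proteins are "reversed"
by each treatment: their sites' treatment group returns to the control
level, so the T/H contrast carries the opposite-signed effect;
non-reversed differential effects persist under treatment. 10% of
reversed proteins get discordant site directions ("mixed"). Effect size
and variance components are calibration choices — the original study
reports none — chosen to put per-site power in a realistic regime (Welch
t ≈ 6 at n = 3).

**Missingness.** Cells are masked with probability
`missing_rate · exp(−w·z) / E[exp(−w·z)]` (z the standardized log2 value,
w the MNAR weight, default 1), clipped at 0.95: low-abundance cells are
preferentially missing, on top of a uniform floor, matching LFQ behavior.
Consequence: observed-value means exceed all-value means, and sites whose
disease effect lowers abundance can lose testability in group H entirely.
On the default spiked simulation this caps reversed-protein recovery at
the measurability ceiling (≈ 91% of planted reversed proteins have ≥ 1
site testable in both contrasts at seed 1); recovery conditional on
measurability is 95–100% across seeds, and 98% with missingness disabled.
Passing recovery tests therefore demonstrate the screen's correctness and
power on measurable signal — they do not show that MNAR-lost biology can
be recovered, because it cannot be.

**Annotations.** 50 gene sets (sizes 10–80); three "target" sets draw
half their members from reversed proteins, the rest uniformly. PPI edges
are background Erdős–Rényi (density 10⁻³) plus denser wiring (0.2) within
target sets; confidences ~ Beta(6, 2), straddling the 0.7 threshold.

The generator does not emulate: peptide-level co-quantification of sites
(multiplicity states are drawn independently), shared-peptide ambiguity,
batch effects, or heavy-tailed intensity noise. Conclusions about those
phenomena cannot be drawn from these simulations.

## Numerical and testing choices

- All randomness flows through one `numpy` Generator per run; a fixed
  seed gives byte-identical outputs.
- Vectorized t-statistics are checked against `scipy.stats.ttest_ind`
  and against explicit textbook formulas to 1e-10; Fisher p-values are
  checked against exhaustive exact-fraction enumeration for every
  configuration with N ≤ 50 (agreement ≤ 4·10⁻¹⁶).
- Type-I calibration uses 10,000 null sites without missingness and the
  Student option (exact under the generator's noise); measured fraction
  0.0446 with a 3-binomial-SE band around 0.05.
- Ties in enrichment ranking break by (p, −score, set id); components
  order by (−size, first node); hubs by (−degree, protein) — every
  reported ordering is deterministic.
- Degenerate inputs: empty tables round-trip; a sample with no observed
  values fails median normalization with the sample named; zero-member
  gene sets are dropped with a warning; self-loop edges are dropped with
  a warning; an empty node set yields a valid empty subnetwork.
- Test problem sizes: property tests run at ≤ 200 sites / ≤ 50 nodes with
  brute-force oracles; calibration and recovery checks run at the study's
  full simulated scale (10,000–21,239 sites), each in ~1–3 s.

## Known limitations

- Imputation-induced anticonservatism (above) is inherited from the
  published scheme; no MinProb/kNN alternatives in this version.
- The headline counts of the original study (844/1,084/1,552 significant
  sites, 11,681 class-I loci) depend on its unreleased raw data and
  unstated cutoffs and are not reproducible here by design.
- Site/peptide distinction: summary statistics count one record per
  site × multiplicity state; real MaxQuant tables can map several sites
  to one peptide, so "peptides by multiplicity" is an approximation in
  simulated summaries (the published arithmetic is verified on the
  printed counts directly).
- The reversal screen is a set operation on direction calls; it makes no
  causal-pharmacology claim.
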