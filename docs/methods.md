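# Methods

## Selection rates from bulk competitions

Fitness is the selection rate, the difference of Malthusian parameters of a
genotype X and the reference Y over one competition assay:

    s = [ln(X_T/X_0) − ln(Y_T/Y_0)] / T,

reported per assay period (T = 4 h by default, so the division by T is
omitted in the stored values). Because both competitors are read from the
same sequencing sample, all common normalizations cancel: counts,
frequencies, and absolute densities give identical s. The reference is the
library's own wild-type genotype (bitstring `0…0`); the 1:9 ancestral spike
used to keep the mean fitness of the flask constant is engineered to be
non-amplifiable, so it never appears in count tables and is not modeled as a
sequencing category.

Per replicate, watermark variants are summed into focal genotypes, counts
are averaged across the PCR barcodes present, and a genotype enters the
estimator only if its mean count reaches `min_count` (default 1.0) at both
timepoints — genotypes below detection are excluded from that replicate, not
pseudocounted, and genotypes with no usable replicate are absent from the
landscape. The landscape stores the per-replicate rates and their mean; the
mean is recomputed and checked on every load.

## Watermark-conditioned genotype calling

Amplicon reads are fixed-layout, so calling is exact positional lookup with
no alignment or indel tolerance. A focal locus is scored mutant only when
its mutant base co-occurs with one of its two synonymous watermark bases; a
focal mutant base with no watermark is attributed to sequencing error and
scored wild type. Reads with more than one mismatch outside the
focal-and-watermark whitelist are rejected (`excess_mismatches`); this
filter is the quality control, and Phred scores are not used. Focal and
watermark positions are whitelisted as positions, so any base there never
counts toward the extraneous-mismatch budget. Accepted + rejected reads
always sum to the input.

## The synthetic experiment generator

The generator draws a ground-truth landscape pair from the same linear model
the regression later fits (main effects, pairwise epistasis, and their host
interactions, each group with its own effect-size s.d.), so the analysis can
be validated against known coefficients. Default scales — 0.5 for mains,
0.15 for pairs, and the same for their host interactions, in per-assay
selection-rate units — produce landscapes whose fitness range and
host-dependent reshaping resemble the measured ones; the host main effect
defaults to 0 because rates are defined relative to the same-host wild type
(making the E coefficient structurally zero in truth). Library composition
is log-normal (σ = 1.5) over genotypes with a constructed fraction of
1 − 0.345 (matching 671 of 1024 genotypes engineered); each genome carries
one of the two watermark options at every mutant locus, split 50/50 per
genotype. Growth over the assay is deterministic exponential at
s + per-replicate Gaussian noise; sequencing is a multinomial draw per
barcode at the configured depth (default 10⁵ reads, error 10⁻³ per base,
substitutions only, i.i.d.). Features of real data *not* emulated: PCR
chimeras and amplification bias, indels, quality-score structure,
within-assay ecological feedback, and cycle-by-cycle MAGE editing
efficiency. Passing recovery tests therefore demonstrates correctness of the
estimators under the model's own assumptions, not robustness to those
artifacts.

## Epistasis regression

Indicator (0/1) coding is used for mutations and host, as in the field's
standard formulation. Single-host designs have L + C(L,2) = 55 predictors at
L = 10; the combined design adds E, G×E, and G×G×E for 111. Observations are
genotype means. Inference is OLS with per-term t tests; the
Benjamini–Hochberg step-up rule at q = 0.05 (configurable) controls the FDR
within each model's coefficient family. Rank-deficient designs (duplicated
or unobserved term patterns, common in the sparse malT⁻ landscape) have the
redundant columns flagged inestimable and excluded from inference with a
warning, never silently dropped.

AIC selection is bidirectional greedy search from the full model, minimizing
n·ln(RSS/n) + 2k and respecting marginality (a term is only removable when
no retained higher-order term contains it; only addable when all its
lower-order components are present). Ties break to the first-listed
candidate, making the trace deterministic. Note that AIC stepwise is not
selection-consistent — a pure-noise term survives with probability
≈ P(χ²₁ > 2) ≈ 0.16 — so tests assert recovery behavior, not certainty.

Variance partitioning uses sequential (type-I) sums of squares with groups
entered mains → pairwise → host → host×main → host×pair (order
configurable), each group's incremental SS divided by the total SS. With
indicator coding the groups are *not* orthogonal even on a complete balanced
factorial (that property belongs to ±1 coding), so the partition is
order-dependent by construction; the default order reflects the scientific
hierarchy of the question being asked.

## Landscape completion

Each simulation trial receives its own completed landscape. Measured
genotypes get a replicate bootstrap: n resamples-with-replacement of their n
replicate rates, averaged — so single-replicate genotypes are constant
across trials while well-replicated ones fluctuate with their measurement
error. Missing genotypes are filled by random-order nearest-neighbor means:
repeatedly pick, uniformly, a missing genotype with at least one non-missing
one-mutation neighbor and assign the mean of its current non-missing
neighbors. Restricting candidates to those with a known neighbor keeps the
update well defined; the hypercube's connectivity guarantees completion in
at most 2^L assignments. The fill order varies between trials and is an
intentional extra variance source capturing imputation uncertainty. Imputed
values cannot escape the hull [min, max] of the measured values.

## Wright–Fisher evolution on shifting landscapes

Each generation draws offspring counts k ~ Multinomial(N, p) with
pᵢ ∝ nᵢwᵢ and wᵢ = exp(sᵢ) from the active landscape. Mutation then acts on
the increments: for genotypes with zᵢ = kᵢ − nᵢ > 0, each of the zᵢ new
individuals keeps its genotype with probability e^(−μ) and otherwise moves
to a uniformly chosen one-mutation neighbor (reversions included; multiple
simultaneous mutations ignored). μ sums the per-base rate over the L focal
sites (default 10 × 7.7×10⁻⁸), since only focal-site changes alter state in
this genotype space.

**A provable consequence of the increment-only rule**: a monomorphic
population is an absorbing state — the multinomial with a degenerate p
returns k = n exactly, so z ≡ 0 and no mutant can ever arise. A simulation
started from the unmutated ancestor (the intended initial condition)
therefore never evolves under the literal rule. The configuration switch
`mutate_all_offspring` exposes all kᵢ offspring to mutation instead and is
the setting used for simulations from a monomorphic start; the default
leaves the literal rule in place for step-level analysis.

Host switching evolves the population on the ancestral-host landscape for a
fraction f of the generations (switch generation = round(f·G)), then
continues on the malT⁻ landscape with counts carried over. The treatment
schedule is the two single-host baselines plus nine switch fractions
0.1–0.9. A run is scored OmpF⁺, with a latching flag, as soon as any
genotype satisfying the 3+1 rule reaches the detection threshold (default
5000 particles, the plating detection limit analog); detection is checked at
initialization and after every generation. Default scale is N = 6.3×10⁹ and
960 generations with 300 trials per treatment in batches of 30; batch OmpF⁺
frequencies give a Student-t 95% CI, and treatments are compared by one-way
ANOVA on batch frequencies with Tukey HSD. Seeding: one master seed spawns a
substream per (treatment, trial); bootstrap, imputation, and WF randomness
draw from that substream in fixed order, so runs are bit-reproducible.

### Scaled-down test conditions

The test suite and acceptance script run the shifting-landscape design at
N = 10⁶ and 200 generations with 50–100 trials per treatment, on a stylized
"funnel" landscape pair in which non-trio mutations are beneficial only on
host 1 (+0.25 each, trio −0.7 each) and the trio is beneficial only on
host 2 (+1.0 each, non-trio −0.5 each) — a sharpened version of the
host-switch-dependent accessibility the experiment probes. The per-individual
mutation probability is scaled to preserve the mutation supply N·μ of the
full-scale setting (≈4.9×10³ mutants per generation, giving μ ≈ 4.85×10⁻³ at
N = 10⁶), the population-genetic quantity controlling how often new genotypes
are seeded. `mutate_all_offspring` is enabled for the reason above.

### Replay power

`replicate_null_probability(p, n, k)` is the exact binomial point mass
C(n,k)·pᵏ(1−p)ⁿ⁻ᵏ; with the historical OmpF⁺ success rate p = 0.25 and 12
replicates, observing zero successes has probability 0.75¹² ≈ 0.0317, the
power calculation behind the replay-experiment design.

## Numerical and interface choices

- Genotypes are integer bitmasks (locus 0 = least significant bit);
  canonical order is binary counting; the string form writes locus 0
  leftmost. All CSVs carry the bitstring form.
- Timepoints are encoded "t0"/"tT" in count tables; T is configuration.
- Multinomial sampling is performed at category level, distributionally
  identical to individual-level sampling; population size is asserted
  conserved every generation.
- Floating-point output uses a fixed `%.10g` format so identical
  config + seed reproduce byte-identical artifacts.
- The default catalog is synthetic apart from the trio's real coordinates
  and base changes; synonymy of watermarks is declared metadata (all default
  watermarks sit on wobble positions of the declared frame), not validated
  against a codon table.

## Known limitations

- No host population dynamics: host change is an exogenous schedule, not a
  feedback loop.
- No phage life-cycle mechanics (adsorption, burst size, lysis timing);
  growth is summarized by per-assay Malthusian rates.
- The watermark design assumes two clean sub-libraries; mosaics of watermark
  options within one genome are called faithfully but are not generated.
- Epistasis is modeled at most pairwise within a host; third-order G×G×G
  terms are out of scope.
- The neighbor-mean imputation is the only completion scheme offered — by
  design, since the simulation results depend on reproducing exactly that
  scheme's variance contribution.
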