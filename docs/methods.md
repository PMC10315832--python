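# Methods

This note documents the statistical model behind `pqtlmr`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Data model and harmonization

Summary statistics are per-variant marginal associations (β, se, p, N,
effect/other allele, effect-allele frequency). Protein βs are treated as per
SD of protein level; disease βs as log-odds. Positions are 1-based; both
sides of an analysis must declare the same genome-build label and a mismatch
is a hard error (silent build mixing is the dominant harmonization failure
mode, and no liftover is attempted).

Harmonization aligns the outcome to the exposure's effect allele: identical
alleles pass through, swapped alleles negate the outcome β and reflect its
frequency, strand complements are resolved by (base-wise) complementing.
Palindromic variants (A/T, C/G) are their own complement, so orientation is
inferred from allele frequency — and dropped when either frequency lies
within 0.08 of 0.5 (the conventional two-sample-MR window) or is missing.
Indel alleles are allowed but never treated as palindromic. Unknown extra
columns in input files are ignored; column-name synonyms (SE /
standard_error / StdErr, SNP / rsid, ...) are resolved case-insensitively
via `pqtlmr.gwas_io.COLUMN_SYNONYMS`.

## Instrument selection

Filters run in a fixed order — cis window → significance → strength →
clumping — so the per-stage counts in the screen report are reproducible.

* **cis window**: ±1 Mb around the gene's TSS, the prevailing pQTL
  convention (configurable). Restricting to cis-pQTLs is itself a pleiotropy
  defense: a variant near the encoding gene most plausibly affects the
  disease through that protein.
* **Significance / strength**: P < 5×10⁻⁸ and F > 10, with
  PVE = β²/(β²+N·se²) and the single-instrument approximation
  F = PVE·(N−k−1)/(k·(1−PVE)), k = 1. (Algebraically, F > 10 at k = 1 is
  PVE > 10/(N+8).)
* **Clumping**: greedy — keep the most significant remaining variant, drop
  everything with r² ≥ 0.001 against it, repeat. The retained set is the
  lexicographically-first (by p-rank) maximal independent set; tests verify
  this against full subset enumeration. Ranking ties in p are broken by |z|
  first — two-sided normal p-values underflow double precision around
  |z| ≈ 38, where |z| still orders candidates correctly — then by genomic
  coordinate for determinism.

The pleiotropy scan is a lookup in a user-supplied SNP→trait catalog (a
local stand-in for a phenome-scanner query); any genome-wide-significant
(P < 5×10⁻⁸) catalog trait flags the instrument. The verdict is advisory:
it demotes a protein from the final validated tier but nothing is dropped,
so users can apply their own judgment about which co-associations matter.

## Causal estimation

Single instrument: Wald ratio β_out/β_exp with the first-order delta-method
standard error se_out/|β_exp| (the term in se_exp is second-order for strong
instruments). Two or more: fixed-effect IVW over the per-instrument ratios,
β = Σwᵢβᵢ/Σwᵢ, se = (Σwᵢ)^(−1/2), wᵢ = 1/sᵢ². Fixed-effect is the minimal
reading of "inverse-variance weighted"; a multiplicative random-effects
toggle (se inflated by √max(1, Q/(k−1))) is exposed but off by default.
Cochran's Q is computed and reported for k ≥ 2, never filtered on.
P-values are two-sided normal (summary-statistic MR convention, not t) and
floored at 1e-300 to stay in (0, 1]; 95% CIs use Φ⁻¹(0.975) = 1.959964.
Screen-level prioritization is Bonferroni: α/n_tests, by default the number
of proteins screened.

## Directionality

**Steiger**: per-trait PVE is summed over the clumped (≈independent)
instruments, converted to r = √PVE, Fisher z-transformed, and compared with
z = (z_exp − z_out)/√(1/(n_exp−3) + 1/(n_out−3)); the test passes when the
direction is correct (PVE_exp > PVE_out) and p < 0.05. For the binary
outcome the same observed-scale PVE formula is used with total N — an
approximation (no liability-scale conversion), conservative here because it
mirrors how the forward analysis treats the outcome. Sample sizes per trait
are taken as the minimum across instruments when they differ.

**Bidirectional MR**: instruments are selected from the disease GWAS with
the same significance/strength/clumping criteria (no cis restriction — the
notion does not apply to a disease), and the disease→protein effect is
estimated with the same Wald/IVW machinery. The pipeline excludes disease
instruments inside the protein's cis window first: such a variant can act on
the protein directly rather than through the disease, so including it feeds
the forward (mediated) pathway into the reverse test and manufactures false
reverse-causation signals. A disease with no surviving instruments yields an
explicit not-testable result, which counts as non-significant.

**Combined verdict**: reverse causation is confirmed iff the reverse MR is
significant (p < 0.05) or Steiger failed.

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor,
log ABF = ½[log(V/(V+W)) + z²·W/(V+W)] with V = se² and W the effect-size
prior variance (prior sd 0.15 for the quantitative protein, 0.2 for the
binary outcome — the canonical defaults, configurable). The five-hypothesis
single-causal-variant enumeration uses per-variant priors p1 = p2 = 1e-4,
p12 = 1e-5, with H3's mass computed as L1·L2 − L12_same. All sums run in
log space (log ABF can exceed 700); the H3 difference uses a guarded
log-diff-exp that returns −∞ when the same-variant mass saturates the
product (and exactly for a one-variant region, where H3 is impossible).
Posteriors are clamped to [0, 1] after normalization. A region colocalizes
when PPH4 > 0.8 (strict). The region is all harmonized variants within the
same ±1 Mb cis window used for instrument selection.

## PheW-MR

Prioritized proteins keep their primary-analysis instruments and are
screened against a battery of disease GWASs. Per-SD estimates are rescaled
by ln(0.90)/β̂ — the signed SD change of protein whose predicted effect on
the index disease equals a 10% risk reduction — so that effects across
diseases are comparable as "per plausible therapeutic dose". A protective
protein gets a positive factor, a harmful one a negative factor (the
intervention lowers it); CI bounds swap under a negative factor so
lower < upper always. Multiplicity across the battery is controlled per
protein by Benjamini–Hochberg FDR (the paperless default for an agnostic
battery); a Bonferroni toggle is available. Diseases where harmonization
leaves no instrument are reported as untested, never silently passed.

## Replication and final status

Replication re-runs instrument selection and MR in an alternative pQTL
source; a protein replicates when p < 0.05 **and** the direction matches the
primary estimate. The direction requirement goes beyond the bare p < 0.05
rule — a significant opposite-direction effect is not a replication — and
can be toggled off. A protein absent from the replication source is
`not_replicable`.

Final per-protein status: `not_instrumentable` → `not_significant` →
`prioritized` → `validated_target`, where validation requires no
reverse-causality evidence, no pleiotropy flag, colocalization, and
replication. Stages that cannot run (no catalog, no replication source)
never silently pass: the protein stays `prioritized`.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
directly on the summary scale (no individual-level genotypes — the pipeline
never sees them, and direct generation controls the truth exactly):

* a cis block of m variants (default 200) with AR-1 signed LD
  r_ij = ρ^|i−j| (ρ = 0.95), MAF ~ U(0.05, 0.5);
* an unlinked disease background block (chromosome 2) carrying the
  disease's own loci — the polygenic signal a real disease GWAS has outside
  any one protein's locus, which is what bidirectional MR instruments;
* true marginal effects are the LD convolution of the placed direct
  effects; observed β = truth + noise, with the GWAS-scale standard error
  se = 1/√(2·maf·(1−maf)·N) and noise drawn LD-correlated (AR-1, matching
  the correlation of real GWAS z-statistics; without it the two traits' ABF
  maxima drift to different neighboring variants and shared-causal regions
  stop colocalizing);
* pathways: θ (protein→disease), horizontal pleiotropy (direct disease
  effects in the cis block), and reverse causation (the protein inherits
  `reverse_effect` × the disease's genetic signal).

Default sample sizes mirror the screen's study conditions: n = 7,213 for
the discovery pGWAS, 35,559 for the replication cohort, 459,702 (22,037
cases) for the disease GWAS. The default cis-pQTL effect is 0.3 SD per
allele — a strong cis signal, as top pQTLs typically are. Scenario presets:
`null`, `causal` (three independent cis-pQTLs at indices 20/100/180, θ =
−0.2), `shared_coloc` (one causal variant driving both traits),
`distinct_coloc` (separate causal variants, r² ≈ 0.002), and `reverse`
(disease→protein 0.3 SD per log-odds at n_out = 100,000, the disease's own
locus carrying 0.5 log-odds per allele so the backdoor protein signal is
resolvable at n = 7,213 across the MAF range). Per-protein seeds in
`simulate_screen` are `master_seed + index`, so any protein regenerates in
isolation; identical configs are bit-identical.

What the generator does **not** emulate: real human LD (block structure,
long-range LD), binary-trait se on the liability scale (the quantitative
formula is used on the log-odds scale; case counts are metadata only),
allele-frequency mismatch between cohorts, strand errors, or sample overlap
between exposure and outcome GWAS. Passing tests therefore demonstrate the
estimators and decision rules behave correctly under the assumed model, not
robustness to those real-data pathologies.

Monte-Carlo fixtures used by the validation suite: parameter recovery runs
200 proteins with deliberately strong instruments (effect 0.5 SD per allele
at n = 35,559, F ≈ 3,700) so the check isolates estimator consistency —
first-order weak-instrument bias scales as θ/F and would otherwise be of
the same order as the Monte-Carlo resolution; type-I calibration uses 2,000
null screens; coloc fidelity 50 regions per scenario; orientation 200
replicates per direction; oracle agreement 100 colocalization regions
(≤10 variants, full linear-space enumeration) and 500 clumping instances
(≤15 variants, full bitmask enumeration).

## Known limitations

* Steiger PVE on the observed binary scale, as above.
* Fixed-effect IVW default; with heterogeneous instruments the reported se
  is anti-conservative (Q is reported; the random-effects toggle exists).
* Single-causal-variant colocalization: a cis region with several
  independent pQTLs violates H4's assumption and PPH4 becomes
  unstable — use the one-signal region around the lead pQTL, or interpret
  with care.
* The pleiotropy catalog is only as complete as the user supplies; an empty
  catalog scans clean.
* Applying the screen to real cohorts (ARIC/deCODE pGWAS, UK Biobank +
  FinnGen outcome) needs externally prepared summary statistics and LD
  matrices; no genome build conversion or allele-frequency imputation is
  performed.
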