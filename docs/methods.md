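# Methods

This note documents the statistical models behind each analysis stage, the
defaults and why they were chosen, the numerical decisions that a user might
otherwise have to reverse-engineer from the code, and what the synthetic
cohorts do and do not establish about behaviour on real data.

## Coordinate and annotation conventions

BED intervals are 0-based half-open; mutation tables are serialized 1-based
(the human-readable convention) and converted internally. All coding
sequences are supplied in coding orientation — the pipeline never flips
strands except when collapsing substitutions into the pyrimidine-centred
spectrum channels. Consequence calls come from the standard genetic code on
the mutated codon: a substitution creating a stop is nonsense; stop-loss is
treated as missense, since downstream analyses only distinguish
synonymous / missense / truncating; mutations inside a terminal stop codon
are allowed. An unknown (`N`) flanking base does not discard the mutation:
its context weight is spread uniformly over the four possible flanks, which
makes spectrum counts fractional at sequence ends but conserves total mass
(`sum(counts) == n − skips` is asserted in tests).

## Copy-number classification

rel = log₂(total_cn / ploidy), with total_cn = 0 mapped to −∞. Deleted ⇔
total_cn = 0 or rel < −1; amplified ⇔ rel > 1; both inequalities strict, so
rel = ±1 exactly is neutral, and the exact-zero rule takes precedence. The
classification is scale-invariant in (total_cn, ploidy) except for the
exact-zero rule, and this invariance is property-tested. One value per
(sample, gene) is assumed; sub-gene events must be summarized upstream.

## Spectrum and signature refit

Channels follow the COSMIC order (substitution class major: C>A, C>G, C>T,
T>A, T>C, T>G; flanks minor, A/C/G/T × A/C/G/T). Without a reference
catalog, the refit is the spectrum plus a pseudocount of α = 0.5 per
channel, normalized; the pseudocount prevents an empty channel from zeroing
every site rate that maps to it, while perturbing well-populated channels
by < 1% at a few hundred observations. With a 96 × K reference, exposures
are fit by non-negative least squares and renormalized — a deterministic,
closed-form substitute for iterative forward-selection refitters, adequate
when K is small and the columns are not nearly collinear. With an identity
reference the NNLS reconstruction equals the unsmoothed empirical spectrum
(smoothing applies only to the reference-free path).

## Site rates, expected profiles, window track

Every possible substitution (position × 3 alternates) gets the signature
probability of its collapsed channel as a relative rate, together with its
consequence class. The expected per-residue profile for a class is the
class rate mass per codon, normalized over the gene and scaled by the
observed class total — so it sums to the observed total by construction
(tolerance 1e-9, tested).

The observed/expected track uses windows of 50 bases (default), stride 1,
fully inside the CDS, and reports the **ratio of windowed sums** rather
than the mean of per-base ratios: per-base ratios are undefined wherever
the expected rate is zero (e.g. four-fold degenerate third positions under
a missense track), while the sum ratio is stable and identical in the
continuum limit. Expected mass is rescaled so gene-wide totals agree; when
nothing is observed the relative expectation is kept so empty windows read
0 rather than 0/0. Windows with zero expected mass are flagged undefined
(NaN in output). Window centres are also reported as residue indices
(floor(center/3)+1) for plotting alongside protein-level clusters. Note
that around a strong hotspot the off-hotspot track sits somewhat below 1,
because rescaling to the observed total spreads the hotspot's excess over
the whole gene; this is a property of the normalization, not a bug.

## 1D clustering (NMC)

Mutated residue positions are modelled as m iid draws from the discrete
uniform distribution on {1..N}; recurrent hits are separate draws, so ties
are legitimate and common. For order statistics k < l, the continuous span
X₍l₎ − X₍k₎ is Beta(l−k, m−l+k+1); the discrete analogue is evaluated
exactly by a trinomial sum over placements below / inside / above the
window, at O(m²N) per pair.

Back-end choice: `pair_pvalue` defaults to the exact discrete computation —
the continuous CDF at span/N is biased low at small N and degenerates to
p = 0 at span 0 (tied positions), which would fabricate infinitely
significant "clusters" out of any recurrent site. Scans over all m(m−1)/2
pairs switch to the continuous form above a cost budget, but evaluate the
CDF at (span+1)/N: since a discrete gap ≤ s forces the continuous gap below
(s+1)/N, this is a guaranteed upper bound on the exact p — conservative,
never anti-conservative, and it handles ties sanely. Calibration
simulations (2,000 uniform scans at m = 20, N = 500) put the family-wise
rate of any q < 0.05 call at ~2–3%, and a planted 5-residue cluster holding
a third of the mutations is detected essentially always.

Multiple testing across pairs uses Benjamini–Hochberg by default
(Bonferroni by flag). Significant pairs can optionally be collapsed to
maximal spans; note that when most mutations sit in one run, pairs
stretching to outlying positions can be individually significant, so
collapsed spans may legitimately exceed the visual hotspot.

## 3D clustering

The score is weighted average proximity, WAP = Σ_{i<j} nᵢnⱼ exp(−d²ᵢⱼ/2t²),
over distinct mutated residues with Cα–Cα distances; t = 6 Å spans roughly
one helical turn and is recorded in all outputs. The permutation null
redraws the residue set uniformly without replacement among residues with
coordinates and reassigns the observed count multiset; p uses the add-one
estimator, so p ≥ 1/(n_permutations+1) and the test is exactly valid. The
structure reader keeps one Cα per residue (first altloc encountered),
warns on Cα-less residues, and analyses a single chain by default —
multimeric analyses must merge chains explicitly to avoid silent
inter-subunit distances. The statistic itself is a standard spatial-
clustering choice made by this package; alternative kernels can be
emulated by rescaling t.

## Selection (dN/dS)

e_N and e_S are the signature-weighted rate masses of nonsynonymous
(default: missense + nonsense, configurable) and synonymous sites.
Conditioning on the observed informative total n + s removes the unknown
per-gene mutation rate; under neutrality n ~ Binomial(n+s, e_N/(e_N+e_S)),
tested two-sided and exactly. ω = (n/e_N)/(s/e_S) is reported with ∞/NaN
sentinels at empty cells plus a Haldane-corrected (+0.5) version for
plotting. This conditional binomial construction is deliberately simpler
than covariate-rich regression models of selection: exact at any count,
assumption-light, and auditable — at the price of ignoring gene-level
covariates (expression, replication timing) that matter for whole-exome
scans but not for a handful of pre-specified genes. Neutral simulation
(genes mutated from their own site rates, 100 mutations per gene) gives
mean ω ≈ 1.03–1.08 (the small upward bias is the Jensen bias of the ratio
estimator at finite synonymous counts) and type-I error below nominal; a
5× enrichment is flagged in ≳95% of runs.

## Mutual exclusivity / co-occurrence

The null preserves both margins of the binary patients × genes matrix
exactly, implementing the same exchangeability intent as analytic
Poisson-binomial methods but from first principles: curveball trades
(shuffling the symmetric difference of two random patients' gene sets)
walk uniformly over the set of margin-fixed matrices. Burn-in is 20·n_rows
trades and successive samples are 5·n_rows trades apart; margins are
asserted on every sample. Overlap tails use add-one estimators (hence
p_mutex + p_cooc ≥ 1), BH runs separately per direction, and genes altered
in no or all samples are skipped — their overlap is fixed by the margins.
On 4×3 matrices the permutation tails agree with exhaustive enumeration of
all margin-preserving states within Monte-Carlo error (tested).

## Synthetic cohorts: what they emulate, and what they do not

The generator produces every input format the pipeline reads, with truth
attached: CDS at a target GC (stop codons rejected codon-wise), mutation
catalogs drawn from the gene's own signature-driven site rates with
multiplicative hotspot and ω enrichments applied before renormalization
(so enriched catalogs remain proper distributions), copy-number tables
whose planted states are recoverable exactly by the classification rule,
Bernoulli alteration matrices with planted XOR pairs, and an ideal α-helix
(100°/residue, 2.3 Å radius, 1.5 Å rise; consecutive Cα ≈ 3.8 Å apart).
Every generator is a pure function of `SimConfig` with per-generator seed
substreams.

Defaults emulate a mid-sized untargeted cohort: one ~500-codon gene, ~200
SNVs over 100 patients, near-diploid ploidy (mean 2.0, sd 0.15), 20%
background alteration rate. What the synthetic data deliberately lacks:
sequencing artefacts and calling errors, subclonal structure and purity
noise, inter-patient rate heterogeneity, genes with shared paralogy, and
real signature catalogs (presets are uniform and a crude CpG-heavy
deamination proxy). Passing tests therefore demonstrate calibration and
power of the statistics under their own model assumptions — not robustness
to the messiness of real cohorts, where signature misestimation and
transcript choice dominate the error budget.

## Problem sizes and tolerances

The test and acceptance simulations use sizes chosen to give comfortable
statistical resolution on a single CPU: 1,000–2,000 null scans for NMC
calibration, 200 genes × 100 mutations for neutral dN/dS, 200–500 null
datasets (199–999 permutations each) for the spatial test, 2,000–4,000
curveball samples for exclusivity, 10⁶ draws for discrete-null oracles.
Monte-Carlo comparisons use 3–4 standard-error tolerances plus the add-one
lattice width; exact identities (profile mass, margin preservation, WAP
brute force) are asserted to 1e-9 or bitwise.

## Known limitations

- One transcript per gene, taken as authoritative; no liftover from genome
  coordinates, no indels.
- The gene-level selection test does not model regional covariates and
  should not be read as a whole-exome driver scan.
- The 3D test's score and permutation scheme are this package's documented
  choices; other WAP-family statistics exist and can rank borderline cases
  differently.
- Sliding-window ratios are descriptive; significance assessment of
  hotspots belongs to the clustering tests, not the track.
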