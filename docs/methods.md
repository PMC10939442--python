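# Methods

## The incorporation model

Translation is modelled at steady state as a two-stage competition at the
ribosomal A-site.

**Arrival.** tRNAs move by diffusion only. The cell is discretised into
n = V/l³ sites (V cell volume, l = 1.58×10⁻⁸ m the effective tRNA
length); a tRNA transitions between sites in τ = l²/(6D) seconds with
D = 8.42×10⁻¹¹ m²/s. A species with copy number [tRNAᵢ] occupies a given
site with probability [tRNAᵢ]/n and arrives at rate λᵢ = ([tRNAᵢ]/n)/τ.
Waiting times are exponential, so P(i before j) = λᵢ/(λᵢ+λⱼ), sets of
competitors sum their rates, and competitor k is expected to make λₖ/λᵢ
binding attempts before the focal species arrives (used as a continuous
exponent). Shipped geometry presets: V = 0.6×10⁻¹⁸ m³ (E. coli) and
4.2×10⁻¹⁷ m³ (S. cerevisiae), shared l and D. D is interpreted as a
diffusion coefficient in m²/s — the dimensionally necessary reading for
τ to be a time.

**Binding.** The effective affinity of codon i against anticodon j is
positionally additive, ΔA_ij = Σₖ a[cₖ,acₖ]·sₖ with s₃ ≡ 1, over a 4×5
nucleotide-pair matrix (anticodon side includes lysidine L, restricted to
the anticodon wobble slot). Codon and anticodon are both stored 5'→3' and
aligned antiparallel: codon position k pairs with anticodon position 4−k,
wobble = codon 3 × anticodon 1. "Effective" means the parameter absorbs
proofreading and conformational discrimination, not just hybridisation
energy; it is unit-less, lower = stronger. Binding probabilities are the
Boltzmann weights Pb_ij = e^(−ΔA_ij)/Σₖe^(−ΔA_ik) over all species
present (species sharing an anticodon split the weight equally; species
with zero abundance are excluded — they never arrive). The incorporation
probability combines the arrived-first branch (PI|first = Pb) with the
all-earlier-arrivals-rejected branch, and the resulting PIs are
renormalised per codon into a probability simplex, which the multinomial
count likelihood requires. Aggregating normalised PIs by the amino acid
each species carries gives the 61×19 error landscape (I/L merged; an
unmerged 61×20 variant serves the fitness layer, where variant-effect
scores do distinguish Ile from Leu).

## Identifiability and gauge fixing

The likelihood sees affinities only through per-codon softmaxes. Because
every alignment consumes exactly one matrix entry per position, adding a
constant to one *row* of the matrix (one codon nucleotide) shifts ΔA
identically for every anticodon at every affected codon and cancels in
the softmax: each of the four rows carries one unobservable additive
degree of freedom. We therefore anchor the column-U entry of every row to
zero (a[A][U] = a[C][U] = a[G][U] = a[U][U] = 0) and report
gauge-invariant quantities (Pb, PI, within-row ΔA contrasts) everywhere.
A consequence worth remembering when reading fitted matrices: comparing
entries *across* rows is not gauge-meaningful; Watson-Crick-vs-mismatch
statements are made within rows.

## MCMC fitting

Misincorporation counts per codon are one multinomial draw over
{correct} ∪ {destination categories} with probabilities from the forward
model; the log-likelihood includes the multinomial coefficient, so an
empty dataset scores exactly 0. Destinations indistinguishable from PTMs
can be masked per codon; masking removes those categories and
renormalises the rest at likelihood time only — the forward landscape is
never altered. Observations from several datasets are pooled by summation
before fitting.

Sampling is Metropolis-within-Gibbs: one Gaussian random-walk update per
scalar parameter per sweep, plus one joint shift proposal per matrix row.
The row moves matter: within-row contrasts are sharply informed while a
row's offset against its anchored entry is only weakly informed, and
scalar updates crawl along that ridge (2,000-sweep chains stall mid-ridge
where 20,000-sweep chains converge; with row moves the short chains match
the long-chain posteriors). Proposal scales adapt toward 30% acceptance
during burn-in only; a mean acceptance rate outside [0.1, 0.6] triggers a
diagnostic warning, not a failure. Priors are flat on a wide box
(|a| ≤ 50, s₁, s₂ ∈ [0, 50]); posteriors on identifiable parameters sit
far from the bounds. Initialisation is all-zero affinities with
s₁ = s₂ = 1, with seed-jittered restarts if the likelihood is non-finite.
Only parameters that occur in the pool's codon/anticodon alignments are
sampled; unused entries stay at zero. Defaults: 10,000 sweeps including
5,000 burn-in, every 10th post-burn-in sweep recorded, last 500 records
retained. Chains are bit-reproducible given a seed.

## eTEL detection

Filters run in a fixed order, and every dropped PSM is attributed to
exactly one filter: multi-protein peptides; the ±5 mDa unmodified band
(these PSMs build the coverage map); missing unmodified coverage of the
modified position in the same dataset (and raw file, when given);
ambiguous or absent localisation; no residue-mass match within the
tolerance; collision with a PTM on the localised residue. The ±5 mDa
tolerance is reused for substitution matching and PTM exclusion (one
coherent mass tolerance, adjustable by flag). The shipped PTM list
(`mtel/data/ptm_list.tsv`) covers Unimod-common modifications; exactly
reproducing any particular study requires that study's own exclusion
list. When a shift matches several destinations the closest is taken and
a warning issued; I and L are merged into one destination label.
Coordinates are 1-based and inclusive; codon index = protein position.
Dataset curation keeps datasets with ≥ 10 substitution PSMs and ≤ 10%
label-like shifts (SILAC-style shift list configurable). Error detection
rates are substitution PSMs over total covering PSMs, per codon and per
protein; a codon never covered is reported missing, not zero. RSCU
follows the standard definition, computed on the top-5% expressed
sequences when expression weights are supplied.

## Fitness layer

ΔE score tables are consumed, never computed; the encoded residue is
defined to score 0, so the site cost Δx_s = Σₐ P_{s,a}ΔE(a) effectively
sums over misincorporations. With a merged landscape the I/L category
uses the mean of the I and L scores; the unmerged landscape avoids the
approximation and is preferred. Missing scores either raise or drop-and-
renormalise, per flag. Θ(Δx) = 2S/(1−e^(−2S)), S = q·Ne·Δx with
q = 4.19×10⁻⁷ and presets Ne = 10⁸ (E. coli) and 8.6×10⁶
(S. cerevisiae), is computed via expm1 (exact limit Θ(0) = 1) and
switches to the asymptotic form −2S·e^(2S) below S = −350 to avoid
overflow; it satisfies Θ(S)/Θ(−S) = e^(2S) to floating-point accuracy.
Site classification uses the nearly-neutral band |Θ−1| ≤ 0.05, with the
band edges belonging to the neutral class so the three classes partition
[0, ∞) exactly; classification is unweighted by default with optional
per-site weights. Synonymous-codon cost comparisons use Wilcoxon's
rank-sum test on every within-family codon pair, reporting raw p-values
and Benjamini–Hochberg q-values across all pairs, with RSCU > 1 marking
preferred codons.

## Synthetic data: what it emulates, and what it does not

The generators make every stage testable without downloads. All
randomness in one call flows through a single seeded generator; the same
seed is bit-reproducible.

*Pools* contain a wobble-aware covering repertoire — 32 anticodons
reading every sense codon through Watson-Crick or G:U/lysidine wobble
pairing, the strategy real decoding repertoires use — plus random extra
perfect anticodons up to `n_species` (default 42), with log-uniform
abundances over 10³–10⁵ molecules/cell. *True models* give WC pairs
affinity −wc_strength (default 4) with jitter, wobble-capable G:U pairs
half that, lysidine mildly favorable against all codon nucleotides, plain
mismatches uniform in [0.5, 2.5], and s₁, s₂ uniform in [0.5, 3], all
returned gauge-anchored. Under these conditions mean per-codon error
probabilities are ~0.1 — far above the ~10⁻⁴–10⁻³ measured biologically.
That is deliberate: at simulation depths of 10⁴ observations per codon,
every affinity parameter then receives informative error counts, which is
what a parameter-recovery calibration needs. Passing recovery therefore
demonstrates that the inference machinery is correct and calibrated, not
that real proteomics data would constrain all parameters equally well; on
real data, mismatch parameters at rarely erring positions would carry
wide posteriors.

*PSM fixtures* inject true substitutions (each backed by unmodified
coverage), PTM decoys whose masses also match substitutions, multi-
protein decoys, unlocalised shifts, label-like shifts, and sub-5 mDa
Gaussian mass jitter (sd 1 mDa, truncated at 4 mDa so classes never leak
across the band). Injected substitutions avoid destinations whose delta
collides with a shipped PTM mass for the original residue, making every
injected call recoverable by construction. The fixtures do not model
spectra, retention times, intensities, missed cleavages or real FDR
behaviour. *Score tables* draw ΔE from a two-component DFE-like mixture
(70% N(0, 0.05), 30% −Exp(2)); they mimic the shape, not the values, of
predictor outputs.

The parameter-recovery experiment runs lysidine-free (the 16-parameter
configuration): the lysidine column's pairings with pyrimidine-ending
codons only reshuffle probability *within* the merged I/L category —
the lysidine tRNA is synonymous at those codons — and are structurally
unidentifiable from count data, so their flat posteriors would wander the
prior box and contaminate recovery metrics for reasons unrelated to
inference quality. Recovery at seeds 1–5 (depth 10⁴/codon, 2,000-sweep
chains) achieves Pearson r ≥ 0.999 between true and posterior-mean
affinities and ~0.90 pooled 95%-CI coverage; residual misses come in
correlated within-row clusters when a data realization lands ~2 posterior
standard deviations from truth, which short and long chains agree on.

## Numerical choices

Softmaxes subtract the row maximum. log(1−Pb) clips Pb at 1−10⁻¹⁵; the
clip only engages when a competitor binds with certainty, where the exact
product is 0 anyway. Unproducible observed destinations (no pool tRNA
mismatch can generate them) are a hard error by default, droppable by
flag. Problem sizes in the shipped tests and the acceptance script —
10⁴ observations/codon, 2,000-sweep recovery chains, 600-PSM fixtures,
10⁴-replicate Monte-Carlo checks, 10⁵-draw arrival races — were chosen to
keep every parameter well-informed while the full suite completes in a
couple of minutes on one CPU.

## Known limitations

The model ignores mischarging, ribosome stalling, frameshifts, premature
termination, tRNA channeling and spatial heterogeneity; abundances stand
in for charged-tRNA availability. The affinity model is positionally
additive with no stacking or neighbour effects, so any physical
interaction that couples positions is absorbed into the effective
parameters. Error detection from proteomics observes proteins *after*
cellular quality control, so empirical rates are post-selection. Site
independence underlies the error-free translation probability; correlated
errors (e.g. from a stalled ribosome) would violate it.
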