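# Methods

`emkmer` detects DNA-methylation motifs in bacteria from SMRT-sequencing
kinetics by treating motif inference as a kmer comparison problem, and
extends the detector to metagenomes by clustering contigs on their
epigenetic profiles. This note records the model, its assumptions, the
tunable parameters, the synthetic-data generator, and the design choices
made where the design was genuinely open.

## Signal model

A base modification (m6A, m4C) slows the polymerase as it traverses the
template, lengthening the inter-pulse durations (IPDs) observed at the
modified base in native DNA. Whole-genome-amplified (WGA) DNA carries no
modifications and serves as the matched control. Per-read IPDs are
heavy-tailed, so the pipeline first collapses them to the **median IPD per
(contig, strand, position)**; the median is robust to outlier pulses and
weights every occurrence of a motif equally regardless of local coverage.
Coordinates are strand-specific (a reverse-strand position counts from the
reverse-complement 5' end) because SMRT kinetics are a property of the
template strand actually read.

## Motif space and observations

A candidate motif is a pair (kmer, offset): the sequence plus the position
of its putatively modified base — G(m6A)TC is ("GATC", 1). With lengths
4 ≤ k ≤ 7 the table holds Σ k·4^k = 145,408 keys. For each key, every exact
occurrence on either strand contributes the native and WGA median IPD at
the modified base (each side independently; missing values are skipped).
The batch scanner accumulates per-motif sufficient statistics (count, sum,
sum of squares of ln medians) in one sweep per (k, strand).

## LLR statistic

ln median IPDs are modelled as normal with a common (pooled) spread:

    llr = Σ_i [ ln φ(y_i; μ̂_y, s_p) − ln φ(y_i; μ̂_z, s_p) ]
        = n_y (μ̂_y − μ̂_z)² / (2 s_p²),

where y are the motif's ln native medians, z the ln WGA medians, μ̂ the MLE
means and s_p² = (n_y·var_y + n_z·var_z)/(n_y + n_z) the pooled MLE
variance, floored at 10⁻³ ln-units against degenerate (tied) sets. Pooling
the spread makes the statistic a mean-shift test whose null is approximately
χ²₁ — comfortably inside the gamma family used for calibration — and
deliberately does **not** reward variance inflation. That matters for
nested motif families: a motif whose native set is a mixture of modified
and unmodified contexts (e.g. GATC in a genome that methylates only GGATC)
gains nothing from the mixture's inflated spread, so the pure sub-motif
out-scores its diluted parent and the family resolves in the right order.
An unequal-variance variant (null spread from the WGA set alone) was
evaluated and rejected: it let variance-ratio sampling flukes through under
the null, scored diluted partial-overlap motifs in the hundreds, and made
occurrence count beat signal purity ~4:1 per nesting level, inverting the
order in which nested families must be discovered.

Motifs whose WGA mean exceeds the native mean cannot be modification-driven
and are labelled noise; they are retained in the output with survival
probability 1.

## Gamma null and correction

Motifs of one length share occurrences, so significance is calibrated
empirically and separately per k. The fit set for the per-k gamma null is
every LLR strictly below max(largest noise-direction LLR, 99th percentile
of the class); this keeps genuine outliers out of the null while tolerating
classes where many motifs are perturbed by a shared strong signal.
Positive LLRs only (the gamma log-likelihood is undefined at 0); maximum
likelihood with location fixed at 0; method-of-moments fallback on
non-convergence. Each motif then gets p = gamma survival at its LLR and a
Bonferroni-style corrected value corr = p · k·4^k, compared against
t_gamma = 10⁻⁶.

## Two-phase detection

**Phase 1** walks candidates in decreasing LLR order (ties broken
lexicographically). The walk terminates as soon as the current candidate
fails corr < t_gamma. A surviving candidate is accepted iff its LLR exceeds
that of every scorable parent (the length-(k−1) substrings preserving the
modified base); on acceptance its *co-observation family* is removed from
the pool: all motifs of any length whose windows can align over the
accepted motif's modified base, agree on the overlap, and leave at most 2
of its bases uncovered (expected signal inheritance ≥ 4⁻² of the accepted
motif's). This family generalises parents/children/one-step shifts and is
what keeps partial-overlap relatives — which genuinely carry 6–25 % of a
strong motif's modified positions — from flooding the output.

**Phase 2** revisits the suppressed neighborhood of each accepted motif,
split into structural comparison classes: parents, children, and shift
families at each alignment distance |d| (expected dilution is a function of
the relation, so only same-relation members are exchangeable). Each
member's LLR is standardised against its class using the **median and
1.4826·MAD**. Robust location/scale is essential here: a class can contain
several truly modified motifs (GGATC and GATCC are both children of GATC),
and a mean/SD standardisation is masked by them — with n ≤ 8 members the
mean/SD z is in fact bounded by (n−1)/√n < 2.5, which would make any
z-threshold of 10 unreachable. With median/MAD, up to half the class can
stand out; a neighbor passes when z ≥ t_n (default 10) **and** clears the
gamma cutoff in its own right. Classes with fewer than 3 scorable members
or no spread are unscored; a zero MAD with a genuinely deviating member
yields z = ∞. A probability-threshold gate and the mean/SD mode remain
available as configuration options.

Known limitation: when half or more of a class is truly modified (the
four RGATCY 6-mers among the children of GATC), the MAD breaks down too and
Phase 2 cannot rescue them from a pooled sample; per-cluster re-detection
(below) is then the mechanism that recovers them.

## Metagenomic clustering

Pooled detection only finds motifs whose signal survives averaging over the
mixture. Each contig of length ≥ 10 kb is therefore summarised by a vector
over the pooled significant motif set: entry j is the ratio of the contig's
mean native median IPD to its mean WGA median IPD across motif j's
occurrences (~1 unmodified, ≈ e^effect modified). Averaging each side
before dividing keeps entries stable at low per-genome coverage; dividing
per occurrence first was measured to be dominated by the sampling noise of
WGA medians built from ~3 reads. Missing entries are imputed with 1 (the
no-modification ratio); contigs are clustered with seeded k-means++
(Euclidean, K = 3 by default, 10 restarts), and the full scoring + detection
pipeline is rerun inside each cluster. One refinement round is the default;
`iterate` reuses the refined motif union as features for further rounds.
First-two-component PCA coordinates are provided for diagnostics only.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| t_gamma | 1e-6 | corrected gamma-probability cutoff |
| t_n | 10 | Phase-2 deviation gate, in robust-scale units |
| kmin..kmax | 4..7 | motif length range (table size Σ k·4^k) |
| min_depth | 1 | reads required for a per-position median; 1 keeps the low-coverage use case alive |
| min_obs | 25 | observations per side before a motif is scorable; with fewer, the Studentized null tail across ~10⁵ motifs is heavy enough that extreme flukes clear t_gamma, which no gamma fit extrapolation can absorb (chi-square/t tail bound) |
| min_fit_points | 20 | LLRs needed to fit a per-k gamma null |
| min_contig_len | 10,000 bp | contigs shorter than this carry too few occurrences per motif to vectorise |
| K | 3 | number of contig clusters |

## Synthetic kinetics generator

The generator emulates exactly the structure the detector assumes: reads of
fixed length (default 1 kb) placed uniformly per contig, each on a random
strand; one IPD per covered base, LogNormal(μ, σ) in ln space with
σ = 0.8 (heavy-tailed per-read IPDs); planted motifs add effect_size = 1.5
ln-units (a native/control IPD ratio of ~4.5×, typical of m6A) at the
modified base of each occurrence selected by fraction_modified (default 1;
the decision is made once per occurrence — methylation is a property of the
template site). WGA reads never carry the shift. Contamination replaces a
fraction of native reads with reads from an independent modification-free
pool; contigs come from fragmenting each genome, standing in for a
metagenomic assembly.

What the generator does **not** emulate: sequence-context kinetic effects
beyond the modified base (real IPDs have a context footprint several bases
wide), mapping errors, partial or chimeric reads, per-ZMW rate variation,
and position-correlated IPDs within a read. Passing tests therefore show
that the statistical machinery behaves correctly under its own model
assumptions at desk scale, not that real-genome accuracy is reproduced.

## Study conditions used by the acceptance checks

Desk-scale genomes stand in for real megabase-scale bacterial
chromosomes; sizes were chosen as the smallest giving adequate per-motif
observation counts for each scenario:

- **Null specificity**: 20 runs, 100 kb genome, 10X native / 10X WGA, no
  plants — at most one run in twenty may report anything.
- **Single-genome recovery**: 100 kb, 10X, the E. coli-like trio
  (GATC, ACCACC, CTGCAG) — all three recovered, nothing outside the planted
  keys and their ancestors reported.
- **Contamination**: 250 kb (≈ 3,800 GATC observations — the residual
  median-of-5 signal at 90 % contamination needs that many), GATC recovered
  at 10X / 90 % WGA reads and at 1X / 75 %.
- **Metagenome**: three 200 kb genomes, 4 contigs each, 20X total.
  Genome A carries the trio above, genome B the GGATC/GATCC/TCCAGG trio,
  genome C the four RGATCY 6-mers. Post-clustering recall strictly exceeds
  pooled recall at skewed depths (10/5/5)X, and contigs cluster by genome
  (majority agreement ≥ 0.9) at balanced depths.

## Numerical choices

- Even-count medians: mean of the two middle order statistics.
- Median aggregation is exact (lexsort + segment order statistics) and
  permutation-invariant.
- IPDs must be strictly positive; loaders reject non-positive values rather
  than adding pseudocounts (the ln transform requires positivity).
- Gamma survival values above 1/k·4^k correction are left as-is (values > 1
  simply fail every cutoff).
- K-means and PCA use scikit-learn with fixed seeds; all simulator
  randomness flows from a single SeedSequence.
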