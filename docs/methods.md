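# Methods

`tetrapop` re-implements, as a tested pipeline on synthetic data, the
population-genomic analysis of an outcrossing autotetraploid plant sampled as
12 individuals (48 chromosomes) resequenced at ~25x and aligned against two
diploid relatives (a close sister species used as mapping reference, and a
more distant outgroup).  This note records the models, the parameter choices,
and the places where the design was genuinely open, together with what the
synthetic experiments do and do not demonstrate.

## Tetraploid genotype likelihood model

At a biallelic site with alleles A1/A2, a tetraploid individual has five
genotypes, indexed by the A1 dosage i in {0..4}.  Given the pileup D of read
bases b,

    P(D | G) = prod_b P(b | G)
    P(b | G) = (i/4) P(b | A1) + (j/4) P(b | A2),    i + j = 4
    P(b | a) = 1 - e  if b = a,  else e/3

with e the individual's combined sequencing + mapping error rate.  The e/3
split of the error mass over the three wrong bases is the simplest completion
consistent with a single scalar e; it makes sum_b P(b|G) = 1 exactly for
every genotype (a property test).  The most probable genotype is accepted
when its log10-odds over the runner-up reaches 2; sites are attempted only
when every individual has coverage strictly greater than 4x and at most two
variant bases are present sample-wide (a base counts as a variant when its
pooled count is >= 2 and inconsistent with pure error at level 1e-3 under
Binomial(depth, e/3)).  Sites with any unaccepted individual are excluded
from frequency-based analyses, keeping the allele-frequency denominator fixed
at 48.

Two numerical floors: an error estimate of exactly 0 would make the
likelihood degenerate (a single mismatching read would veto a homozygote with
infinite weight), so estimates are floored at 1e-5 inside the likelihood; and
log-odds are computed in base 10 throughout, the convention the acceptance
threshold of 2 refers to.

**Consequence of the base-10 threshold at 25x.** The expected log10-odds
separating adjacent heterozygous dosages at depth 25 is ~1.4-1.5, below the
threshold, and one error read already drops a depth-25 homozygote to ~0.4.
With the all-individuals-called rule, only ~4% of simulated SNP sites survive
genotyping at the default depth, strongly ascertained toward sites where all
12 individuals are homozygous.  The genotyper is precise (accuracy > 99% at
depth 100; recovered allele frequencies at surviving sites correlate > 0.99
with truth at depth 25) but not sensitive at study depth.  Every downstream
stage that consumes called genotypes inherits this ascertainment; see
"Pipeline behaviour" below.

## Error-rate estimation

For each individual, the read consensus, the reference (sister) sequence and
the outgroup sequence are compared over the same gap-free alignment columns.
Reads and reference sit at (approximately) the same evolutionary distance
from the outgroup, so

    e_hat = mismatch(reads, outgroup) - mismatch(reference, outgroup)

estimates the combined error rate.  Negative excess is clamped to 0 with a
warning flag; fewer than 1,000 aligned columns is an error.  On synthetic
equal-divergence triples the estimator recovers an injected flip rate of
0.15% within 20% relative error at 1e6 columns and is unbiased in the mean.

## Diversity statistics

* Watterson's theta per site: `theta_W = S / (a_{n-1} L)` with
  `a_47 ~ 4.438` for n = 48.
* Nucleotide diversity pi is expected gametic heterozygosity: per site
  `(n/(n-1)) (1 - sum_a p_a^2)`, i.e. the probability two chromosomes drawn
  without replacement differ, summed over sites and divided by aligned
  length.  The n/(n-1) correction makes the estimator match the mean
  pairwise Hamming distance over all 48*47/2 chromosome pairs exactly (a
  brute-force oracle test).
* Site classification is by codon context: a CDS SNP is synonymous iff
  swapping the two alleles inside the reference codon (spliced across exon
  junctions, using the feature frame) preserves the amino acid.  Class-
  stratified per-gene lengths use the positional approximation (third codon
  position ~ synonymous) that also drives the generator's rates.
* Polarization: the ancestral state is the base on which the two outgroup
  sequences agree; disagreement, or a shared base absent from the sample's
  two alleles, leaves the site unpolarized — excluded from the unfolded SFS
  and the sweep scan, retained in the folded SFS.
* F_ST is the Weir & Cockerham variance-components estimator with each
  tetraploid individual contributing four independent gametes and no
  within-individual correlation term — the "gametic heterozygosity"
  treatment justified by tetrasomic inheritance.  Genome averages are
  ratios of summed components, not means of ratios.
* Gene alignments with any pairwise identity below 80% over non-gap columns
  are excluded; the threshold is inclusive (exactly 80% passes).

## Coalescent simulation of inheritance modes

Time is measured in units of 4N generations, theta is the ms-style locus
rate (E[S] = theta a_{n-1}); the internal simulator draws exponential
coalescence waiting times (pair rate 2 per unit, divided by a chromosome-
pool scale factor) and Poisson mutations on branches under infinite sites.
It is validated against closed-form expectations and against msprime as an
independent oracle (two-deme split model, mean total branch length to 5%).
There is no within-gene recombination; the parameter is exposed but
unimplemented, and its absence matters (see the sweep scan discussion).

Tetrasomic inheritance: one panmictic pool of 48 chromosomes; individuals
are a random partition into 12 groups of 4.  Disomic inheritance: two
isolated sub-pools of 24 merging t_d (in 4N units) in the past; each
individual receives two chromosomes per sub-pool.  The merge is implemented
as a clean deme join at t_d.  The default t_d grid is
{0.2, 0.4, 0.6, 0.8, 1.0}.  Expected tetrasomic genotype frequencies are
Binomial(4, p) (bivalent pairing, no double reduction); conditional on a
site's allele count k the simulated dosages follow Hypergeometric(48, k, 4),
which the tests check directly.  Long-diploidized pools show the two
diagnostic footprints: folded-SFS mass piling at minor count 24 (homeologous
fixed differences force every individual duplex) and a duplex genotype
excess.

**SNP pooling and rank tests.** SNPs pooled across runs share genealogies
within a run and are strongly correlated; a Mann-Whitney U test on such
pooled per-SNP classes rejects a true null far above its nominal level
(measured ~65% at alpha = 0.05).  `sample_snp_classes` therefore draws one
random segregating site per run, giving independent class draws; the
calibration and power properties (null rejection at the nominal rate; one
tetrasomic pool of >= 4,000 SNPs rejecting disomic pools at p << 0.01) hold
under that sampling and are tested there.  The SFS comparison itself is a
two-sided Mann-Whitney U with tie correction (classes are heavily tied);
genotype-class comparisons use a chi-square divergence plus a one-sided
binomial flag for duplex excess.

## Sweep scan

Polarized SNPs of each gene are cut into consecutive 100-SNP windows (a
trailing short block is scored but flagged partial; an option excludes
partial blocks).  The window score is a composite likelihood ratio against
the genome-wide unfolded background spectrum q (pseudo-count 0.5 on empty
classes).  The alternative is the background exponentially tilted toward
high derived classes,

    p_c(lam) = q_c e^(lam c) / Z(lam),  lam >= 0
    CLR = 2 max_lam sum_c m_c ln(p_c(lam) / q_c)

maximised exactly by a bounded concave scalar optimisation (the exponential-
family log-likelihood is concave in lam; lam is capped at 40, far beyond any
finite optimum that matters).  CLR is 0 for windows at or below the
background mean frequency and grows as mass moves into rare high-frequency-
derived classes; a window of 100 SNPs all in the top class against a uniform
47-class background scores 2*100*ln(47) ~ 770.

The constrained directional alternative is essential, not cosmetic.  An
unconstrained multinomial ratio (G statistic) measures *any* deviation from
the background, and in a non-recombining gene all ~100 window SNPs share one
genealogy, so every neutral window deviates wildly: measured neutral window
G values (~170-530) overlap injected-sweep values (~230-465) almost
completely and the scan recovers only ~20-30% of strong synthetic sweeps.
Restricting the alternative to a one-parameter high-frequency tilt — the
same logic by which the original SFS scan statistic constrains its sweep
model — recovers 80% of genes swept at carrier fraction 0.9 with no false
flags among neutral genes at the 5%/5% tails (400-gene experiment, 20 swept).
With recombination the distinction would shrink, since neutral windows would
mix genealogies and sit closer to the background.

Candidates are genes with at least one window at or above the genome-wide
95th-percentile window CLR *and* gene pi/bp at or below the 5th percentile;
quantiles are empirical order statistics with ties included, and a fully
degenerate input (every gene passing both tails) is reported as "no scan
possible" rather than flagging everything.  Gene-set enrichment among
candidates is a one-sided Fisher exact test on the 2x2 membership table
(identical to the hypergeometric tail, which a test asserts); fold
enrichment is the in-set candidate fraction over the universe candidate
fraction.

## Synthetic data generator

The generator emulates the study conditions: 12 tetraploid individuals,
theta = 0.043 per silent site (synonymous and intronic; 0.017 at
non-synonymous sites), focal/sister divergences 8.7e-4 / 2.7e-4 / 9.6e-4 at
synonymous / non-synonymous / intronic positions (split half-and-half over
the two branches from their common ancestor), an outgroup 20x more diverged,
mean depth 25 (Poisson per individual per site), and error rate 0.0015
(uniform flips to the three other bases), with 200 genes of three ~400-bp
exons and two ~150-bp introns by default.  Sweeps are emulated by star-like
replacement: ceil(f*48) chromosomes, always including the donor, become
copies of the sampled haplotype carrying the most derived alleles — reduced
pi and excess high-frequency-derived mass without modelling the sweep
forward.  Features of real data deliberately not emulated: indels and gaps,
multi-allelic sites, read-level qualities, mapping artefacts, recombination,
linkage between genes, and GC or codon-usage structure.  Passing tests
therefore demonstrate the statistical machinery, not robustness to
alignment or mapping pathologies.

## Pipeline behaviour at the default settings

The run-all pipeline (simulate -> genotype -> stats -> inherit -> scan) is
deterministic under a master seed (per-stage seeds are spawned from it;
manifests record sha256 checksums, and a same-seed rerun is bit-identical).
Because of the genotyping ascertainment described above, the pipeline's
genotype-based analyses are demonstrative rather than powerful at the
default 25x depth: of ~5,800 simulated SNPs in a 200-gene run about 1,500
survive complete calling, almost all at extreme frequencies.  The inherit
stage therefore pushes every simulated model pool through the same
pileup -> call -> filter chain before the Mann-Whitney comparison (matched
ascertainment, one surviving SNP per run).  Under that matching the
generating tetrasomic model is accepted while sharply diploidized pools can
still be rejected, but most of the model-separating signal — intermediate-
frequency duplex sites — lies exactly in the genotypes the stringent
threshold refuses to call, so several disomic grid points remain
indistinguishable end-to-end, and the end-to-end sweep scan recovers little.
The module-level experiments on true population samples (where the spec-level
discrimination and recovery properties are established) quantify what the
statistics themselves can do; the pipeline quantifies what survives the
full short-read calling chain at these settings.

## Problem sizes

Module tests and the acceptance script use scaled-down simulation sizes
chosen to keep the whole suite in the low minutes on one core while leaving
every comparison's Monte-Carlo error far inside its assertion margin:
300-1,500 coalescent replicates for moment checks, 3,000-4,000-SNP pools for
rank tests (the paper-scale analogue used 500,000 runs), 400 genes for the
sweep-recovery experiment, and 200 genes / 2,000 runs for the default
pipeline.  All are parameters, not constants.
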