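# tetrapop

Population-genomic analysis of autotetraploid resequencing data: tetraploid
genotype calling from read pileups, tetraploid diversity statistics,
coalescent discrimination of tetrasomic vs. disomic inheritance, and a
selective-sweep scan — together with a synthetic-data generator so the whole
pipeline runs and is testable without external sequencing data.

The package is aimed at population geneticists working with established
autopolyploids (the motivating system is a tetraploid *Arabidopsis* relative
sampled as 12 individuals, i.e. 48 chromosomes, at ~25x coverage against two
diploid outgroup genomes), and at anyone who needs tetraploid-aware versions
of standard genome-scan machinery.

## What it computes

**Genotypes.** A tetraploid has five biallelic genotypes per site (A1 dosage
i = 0..4).  From the base pileup D of one individual,

    P(D|G) = ∏_b P(b|G),   P(b|G) = (i/4)·P(b|A1) + (j/4)·P(b|A2),  i+j = 4,
    P(b|a) = 1−e (match) or e/3 (mismatch),

where e is that individual's sequencing+mapping error rate, estimated from
three-way alignments as the excess divergence of reads over the reference
relative to an outgroup.  The best genotype is accepted at log10-odds ≥ 2;
sites require >4x coverage in every individual and ≤2 variants sample-wide.

**Diversity.**  Watterson's θ_W = S/(a₄₇·L); π as expected gametic
heterozygosity, Σ (n/(n−1))(1−Σp²)/L over sites; unfolded/folded site
frequency spectra with outgroup polarization; Weir & Cockerham F_ST treating
each tetraploid as four gametes.

**Inheritance mode.**  Neutral coalescent simulation of a sample of 48
chromosomes under tetrasomic inheritance (one pool) or disomic inheritance
(two isolated 24-chromosome homeolog pools merging t_d·4N generations ago),
assembly into 12 tetraploid individuals, and Mann-Whitney comparison of
observed vs. simulated folded SFS plus genotype-class (nulliplex..quadruplex)
divergence.  Long-diploidized pools are diagnosed by SNPs piling near 50%
frequency and an excess of duplex (AAaa) genotypes.

**Sweeps.**  Per gene, consecutive 100-SNP windows are scored with a
composite likelihood ratio of the window's derived-class spectrum against
the genome-wide background, with the alternative constrained to an
exponential tilt toward high derived frequencies — the directional signal a
sweep leaves.  Candidates are genes in both the top 5% of window CLR and the
bottom 5% of π/bp; gene-set enrichment among candidates uses a one-sided
Fisher exact test.

## Worked example

Run the full synthetic pipeline (simulate → genotype → stats → inherit →
scan) with one master seed:

```
$ tetrapop run-all --seed 42 --outdir demo -v
INFO tetrapop: simulate: 200 genes, 36982 SNPs, 0 swept
INFO tetrapop: genotype: 36592 sites written, mean e=0.00151
INFO tetrapop: stats: 1467 SNPs (1448 polarized), 200 genes kept
INFO tetrapop: inherit: consistent models ['tetrasomic', ...]
INFO tetrapop: scan: 0 candidates of 200 genes
{"outdir": "demo", "n_outputs": 20}
```

What the numbers mean: the generator simulated 200 genes carrying 36,982
SNPs among 48 chromosomes and emitted error-bearing 25x pileups; the
genotyper estimated each individual's error rate from the calibration
alignments (true value 0.0015; estimates ranged 0.00132–0.00164) and wrote
36,592 candidate sites, of which 1,467 SNPs had confident tetraploid calls
for all 12 individuals — the stringent base-10 log-odds rule refuses most
heterozygous dosages at 25x, an ascertainment documented in
`docs/methods.md`.  The inherit stage pushed each simulated inheritance
model through the same pileup→call→filter chain and accepted the generating
tetrasomic model (Mann-Whitney p = 0.96) while rejecting the sharpest
recently-diploidized pool (t_d = 0.2, p = 0.008); the scan stage flagged no
sweep candidates, as expected for a run with no injected sweeps
(`sim.sweep_fraction = 0`).

Every output is plain text under `demo/` (BED gene models, FASTA triples,
pileup TSV, a tetraploid VCF with GT fields like `0/0/0/1`, per-gene
summary TSVs, JSON reports) and `demo/manifest.json` records sha256
checksums — rerunning with the same seed is bit-identical.

The same machinery is exposed as a library:

```python
import numpy as np
from tetrapop import inheritance_sim as isim, popgen_stats as pg

rng = np.random.default_rng(1)
haps = isim.coalescent_sample(48, theta=0.043 * 1000, rng=rng)
print(pg.watterson_theta(haps.shape[1], n=48, L=1000))  # ~0.043
```

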