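"""Synthetic data generator for the autotetraploid resequencing analysis.

Emulates the statistical structure the downstream pipeline assumes, so every
stage (genotyping, diversity statistics, inheritance-mode testing, sweep
scanning) is testable without raw sequencing data:

* gene models with CDS/intron features (BED-style, 0-based half-open);
* three-species alignments per gene (focal consensus, reference sister
  species, outgroup) with class-specific divergence — defaults follow the
  focal/sister per-site divergences 8.7e-4 (synonymous), 2.7e-4
  (non-synonymous) and 9.6e-4 (intronic);
* population samples of 48 chromosomes (12 tetraploid individuals) from the
  neutral coalescent, silent theta 0.043 per site;
* optional injected selective sweeps (star-like haplotype replacement) that
  lower diversity and push derived alleles to high frequency;
* per-individual, per-site base pileups at ~25x Poisson depth with a uniform
  base-flip error rate (default 0.15%).

All randomness flows through a seeded :class:`numpy.random.Generator`; with a
fixed seed, outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inheritance_sim import InheritanceModel, assemble_individuals, coalescent_sample

__all__ = [
    "GeneFeature",
    "GeneModel",
    "SpeciesTriple",
    "PopulationSample",
    "SimConfig",
    "make_gene_models",
    "simulate_triple",
    "simulate_population",
    "inject_sweep",
    "simulate_pileups",
    "write_gene_models_bed",
    "read_gene_models_bed",
    "write_triples_fasta",
    "read_triples_fasta",
    "write_pileups_tsv",
    "read_pileups_tsv",
]

BASES = np.array(["A", "C", "G", "T"])
N_INDIVIDUALS = 12
N_CHROM = 48  # 12 tetraploid individuals x 4 chromosomes


@dataclass(frozen=True)
class GeneFeature:
    start: int  # 0-based, inclusive
    end: int  # exclusive
    kind: str  # "CDS" or "intron"
    frame: int | None = None  # codon offset of `start`, CDS only


@dataclass
class GeneModel:
    """A protein-coding gene: ordered, non-overlapping CDS and intron features."""

    gene_id: str
    length: int
    features: list[GeneFeature]
    chrom: str = "scaffold_1"
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.gene_id}: length must be positive")
        prev_end = 0
        cds_len = 0
        for f in sorted(self.features, key=lambda f: f.start):
            if f.start < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping features")
            if not (0 <= f.start < f.end <= self.length):
                raise ValueError(f"{self.gene_id}: feature outside gene")
            if f.kind not in ("CDS", "intron"):
                raise ValueError(f"{self.gene_id}: unknown feature kind {f.kind}")
            if f.kind == "CDS":
                cds_len += f.end - f.start
            prev_end = f.end
        if cds_len % 3:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        self.features = sorted(self.features, key=lambda f: f.start)

    def site_classes(self) -> np.ndarray:
        """Nominal site class per position: S/N/I/O codes.

        Inside CDS, third codon positions are labelled synonymous ("S") and
        first/second positions non-synonymous ("N") — the standard
        approximation used when *generating* class-specific rates.  Exact
        codon-context classification of observed SNPs lives in
        :func:`tetrapop.popgen_stats.classify_site`.
        """
        classes = np.full(self.length, "O", dtype="U1")
        cds_offset = 0
        for f in self.features:
            if f.kind == "intron":
                classes[f.start : f.end] = "I"
            else:
                frame = f.frame or 0
                pos_in_codon = (np.arange(f.end - f.start) + frame) % 3
                cls = np.where(pos_in_codon == 2, "S", "N")
                classes[f.start : f.end] = cls
                cds_offset += f.end - f.start
        return classes

    def cds_positions(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(f.start, f.end) for f in self.features if f.kind == "CDS"]
        )


@dataclass
class SpeciesTriple:
    """Aligned gene sequences: focal consensus, reference sister, outgroup.

    Columns are annotated with the generator's nominal site class
    (S/N/I/O).  Alphabet {A,C,G,T,-}; the generator itself emits no gaps
    (no indels) but the type and its consumers are gap-aware.
    """

    gene_id: str
    focal: str
    sister: str
    outgroup: str
    site_class: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.focal) == len(self.sister) == len(self.outgroup)):
            raise ValueError(f"{self.gene_id}: unequal aligned lengths")
        if len(self.site_class) != len(self.focal):
            raise ValueError(f"{self.gene_id}: site_class length mismatch")
        alphabet = set("ACGT-")
        for seq in (self.focal, self.sister, self.outgroup):
            if not set(seq) <= alphabet:
                raise ValueError(f"{self.gene_id}: invalid characters in alignment")


@dataclass
class PopulationSample:
    """48 sampled chromosomes of one gene over its segregating sites.

    ``haplotypes[h, s]`` is 1 when chromosome ``h`` carries the derived allele
    at segregating site ``s``.  ``genotypes[i, s]`` is individual ``i``'s true
    derived-allele dosage (0..4), fixed by ``assignment`` (chromosome ->
    individual).  ``ancestral``/``derived`` give the actual bases.
    """

    gene_id: str
    length: int
    positions: np.ndarray  # (S,) int, sorted, unique
    ancestral: np.ndarray  # (S,) U1
    derived: np.ndarray  # (S,) U1
    haplotypes: np.ndarray  # (48, S) uint8
    site_class: np.ndarray  # (S,) U1 in {S,N,I,O}
    assignment: np.ndarray  # (48,) chromosome -> individual index

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] != N_CHROM:
            raise ValueError("expected exactly 48 haplotypes")
        k = self.haplotypes.sum(axis=0)
        if np.any((k == 0) | (k == N_CHROM)):
            raise ValueError("monomorphic column in segregating-site matrix")

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def genotypes(self) -> np.ndarray:
        """True per-individual derived dosages, (12, S) uint8."""
        dos = np.zeros((N_INDIVIDUALS, self.n_sites), dtype=np.int64)
        np.add.at(dos, self.assignment, self.haplotypes.astype(np.int64))
        return dos.astype(np.uint8)

    def derived_counts(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(int)


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults reproduce the resequencing design being emulated: 12 tetraploid
    individuals (48 chromosomes) at ~25x mean coverage with a combined
    sequencing+mapping error of 0.15% (middle of the 0.1-0.2% range), silent
    per-site theta 0.043, and focal/sister per-site divergences of 8.7e-4 /
    2.7e-4 / 9.6e-4 at synonymous / non-synonymous / intronic sites.
    """

    seed: int  # mandatory for reproducibility
    n_genes: int = 200
    n_exons: int = 3
    exon_length: int = 402
    intron_length: int = 150
    theta_silent: float = 0.043
    theta_nonsyn: float = 0.017
    d_syn: float = 8.7e-4
    d_nonsyn: float = 2.7e-4
    d_intron: float = 9.6e-4
    outgroup_scale: float = 20.0  # outgroup-branch divergence multiplier
    mean_depth: float = 25.0
    error_rate: float = 0.0015
    sweep_fraction: float = 0.0  # fraction of genes carrying a sweep
    sweep_carrier_fraction: float = 0.9
    recombination_rate: float = 0.0  # within-gene rho; 0 = no recombination

    def __post_init__(self) -> None:
        for name in ("theta_silent", "theta_nonsyn", "d_syn", "d_nonsyn",
                     "d_intron", "error_rate", "sweep_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 < self.sweep_carrier_fraction <= 1.0:
            raise ValueError("sweep_carrier_fraction must be in (0, 1]")
        if self.recombination_rate != 0.0:
            raise NotImplementedError(
                "within-gene recombination is exposed but not implemented; "
                "the coalescent assumes a non-recombining gene"
            )

    def class_rate(self, which: str) -> dict[str, float]:
        if which == "theta":
            return {"S": self.theta_silent, "N": self.theta_nonsyn,
                    "I": self.theta_silent, "O": self.theta_silent}
        if which == "divergence":
            return {"S": self.d_syn, "N": self.d_nonsyn,
                    "I": self.d_intron, "O": self.d_intron}
        raise ValueError(which)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))


def make_gene_models(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Build ``cfg.n_genes`` exon/intron gene models with mild length jitter."""
    genes = []
    for g in range(cfg.n_genes):
        features = []
        pos = 0
        cds_offset = 0
        for e in range(cfg.n_exons):
            elen = cfg.exon_length + 3 * int(rng.integers(-20, 21))
            elen = max(elen, 30)
            features.append(GeneFeature(pos, pos + elen, "CDS", cds_offset % 3))
            cds_offset += elen
            pos += elen
            if e < cfg.n_exons - 1:
                ilen = cfg.intron_length + int(rng.integers(-40, 41))
                ilen = max(ilen, 20)
                features.append(GeneFeature(pos, pos + ilen, "intron"))
                pos += ilen
        genes.append(GeneModel(gene_id=f"gene{g:05d}", length=pos, features=features))
    return genes


def _mutate(seq: np.ndarray, rate_per_pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flip each position independently with its own rate, to a random other base."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate_per_pos)[0]
    for i in hits:
        choices = BASES[BASES != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def simulate_triple(gene: GeneModel, cfg: SimConfig, rng: np.random.Generator) -> SpeciesTriple:
    """Simulate a three-species alignment for one gene.

    An ancestral sequence is drawn uniformly; focal and sister each accumulate
    half the class-specific focal/sister divergence on their own branches
    (so their pairwise difference rate matches d_class), and the outgroup
    accumulates ``outgroup_scale`` times that divergence independently.
    """
    if gene.length <= 0:
        raise ValueError("zero-length gene")
    classes = gene.site_classes()
    rates = cfg.class_rate("divergence")
    d = np.array([rates[c] for c in classes])
    anc = BASES[rng.integers(4, size=gene.length)]
    focal = _mutate(anc, d / 2, rng)
    sister = _mutate(anc, d / 2, rng)
    outgroup = _mutate(anc, np.minimum(cfg.outgroup_scale * d, 0.75), rng)
    return SpeciesTriple(
        gene_id=gene.gene_id,
        focal="".join(focal),
        sister="".join(sister),
        outgroup="".join(outgroup),
        site_class=classes,
    )


def simulate_population(
    gene: GeneModel,
    cfg: SimConfig,
    model: InheritanceModel,
    rng: np.random.Generator,
    *,
    triple: SpeciesTriple | None = None,
) -> PopulationSample:
    """Simulate 48 chromosomes of one gene under an inheritance model.

    Haplotype generation delegates to the coalescent
    (:func:`tetrapop.inheritance_sim.coalescent_sample`); the locus theta is
    the sum of per-position class rates, and each resulting segregating site
    is placed at a distinct position drawn proportionally to its class rate.
    When ``triple`` is supplied the ancestral base at each SNP is read from
    the focal consensus sequence, keeping pileups, alignments and
    polarization mutually consistent.
    """
    classes = gene.site_classes()
    rates = cfg.class_rate("theta")
    per_pos = np.array([rates[c] for c in classes])
    theta_locus = per_pos.sum()
    demes = 1 if model.kind == "tetrasomic" else 2
    t_merge = None if model.kind == "tetrasomic" else model.t_d
    haps = coalescent_sample(N_CHROM, theta_locus, demes=demes, t_merge=t_merge, rng=rng)
    S = haps.shape[1]
    S = min(S, gene.length)  # infinite-sites on a finite gene
    haps = haps[:, :S]
    if S:
        weights = per_pos / per_pos.sum() if per_pos.sum() > 0 else None
        positions = rng.choice(gene.length, size=S, replace=False, p=weights)
    else:
        positions = np.empty(0, dtype=int)
    order = np.argsort(positions)
    positions = positions[order]
    haps = haps[:, order]

    if triple is not None:
        anc_seq = np.array(list(triple.focal))
        ancestral = anc_seq[positions]
    else:
        ancestral = BASES[rng.integers(4, size=S)]
    derived = np.empty(S, dtype="U1")
    for s in range(S):
        choices = BASES[BASES != ancestral[s]]
        derived[s] = choices[rng.integers(3)]

    _, assignment = assemble_individuals(haps, model, rng=rng)
    return PopulationSample(
        gene_id=gene.gene_id,
        length=gene.length,
        positions=positions,
        ancestral=ancestral,
        derived=derived,
        haplotypes=haps,
        site_class=classes[positions],
        assignment=assignment,
    )


def inject_sweep(
    sample: PopulationSample,
    carrier_fraction: float,
    rng: np.random.Generator,
) -> PopulationSample:
    """Emulate a recent selective sweep by star-like haplotype replacement.

    The sampled haplotype carrying the most derived alleles is designated the
    sweep haplotype; ``ceil(carrier_fraction * 48)`` chromosomes — always
    including the sweep haplotype itself, so a vanishing fraction leaves the
    sample unchanged — are replaced by copies of it.  This lowers pi and
    shifts SFS mass toward high-frequency derived classes, the two signals
    the sweep scan keys on, without modelling the sweep's coalescent history.
    Sites driven monomorphic by the replacement are dropped.
    """
    if not 0.0 < carrier_fraction <= 1.0:
        raise ValueError("carrier_fraction must be in (0, 1]")
    n_carriers = math.ceil(carrier_fraction * N_CHROM)
    haps = sample.haplotypes.copy()
    if sample.n_sites == 0 or n_carriers <= 1:
        replaced = haps
    else:
        sweep_idx = int(haps.sum(axis=1).argmax())
        others = np.delete(np.arange(N_CHROM), sweep_idx)
        extra = rng.choice(others, size=n_carriers - 1, replace=False)
        replaced = haps
        replaced[extra] = haps[sweep_idx]
    k = replaced.sum(axis=0)
    keep = (k > 0) & (k < N_CHROM)
    return PopulationSample(
        gene_id=sample.gene_id,
        length=sample.length,
        positions=sample.positions[keep],
        ancestral=sample.ancestral[keep],
        derived=sample.derived[keep],
        haplotypes=replaced[:, keep],
        site_class=sample.site_class[keep],
        assignment=sample.assignment.copy(),
    )


def simulate_pileups(
    sample: PopulationSample,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate per-individual base pileups at the sample's segregating sites.

    Depth is Poisson(``mean_depth``) per individual per site.  Each read draws
    one of the individual's four chromosomes uniformly and reports its base,
    flipped with probability ``error_rate`` to a uniformly chosen different
    base.  Returns a tidy frame: gene_id, pos, individual, count_A..count_T.
    """
    S = sample.n_sites
    e = cfg.error_rate
    dosage = sample.genotypes.astype(float)  # (12, S)
    anc_idx = np.searchsorted(BASES, sample.ancestral)
    der_idx = np.searchsorted(BASES, sample.derived)

    # per (individual, site) base-emission probabilities marginalised over reads
    p = np.full((N_INDIVIDUALS, S, 4), 0.0)
    eye = np.eye(4)
    emit = eye * (1 - e) + (1 - eye) * (e / 3)  # emit[true, observed]
    frac_der = dosage / 4.0
    for b in range(4):
        p[:, :, b] = frac_der * emit[der_idx, b] + (1 - frac_der) * emit[anc_idx, b]

    depth = rng.poisson(cfg.mean_depth, size=(N_INDIVIDUALS, S))
    counts = rng.multinomial(depth, p)  # (12, S, 4)

    ind, pos = np.meshgrid(np.arange(N_INDIVIDUALS), np.arange(S), indexing="ij")
    return pd.DataFrame(
        {
            "gene_id": sample.gene_id,
            "pos": sample.positions[pos.ravel()],
            "individual": ind.ravel(),
            "count_A": counts[:, :, 0].ravel(),
            "count_C": counts[:, :, 1].ravel(),
            "count_G": counts[:, :, 2].ravel(),
            "count_T": counts[:, :, 3].ravel(),
        }
    )


# ---------------------------------------------------------------------------
# File interfaces (plain text; every file carries the seed in a header comment)
# ---------------------------------------------------------------------------

def write_gene_models_bed(genes: list[GeneModel], path: Path | str, seed: int) -> None:
    """BED-like (0-based, half-open): chrom, start, end, gene_id:kind:frame, ., strand."""
    with open(path, "w") as fh:
        fh.write(f"# tetrapop gene models; seed={seed}\n")
        for g in genes:
            for f in g.features:
                frame = "." if f.frame is None else str(f.frame)
                fh.write(
                    f"{g.chrom}\t{f.start}\t{f.end}\t{g.gene_id}:{f.kind}:{frame}\t.\t{g.strand}\n"
                )


def read_gene_models_bed(path: Path | str) -> list[GeneModel]:
    feats: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, _, strand = line.rstrip("\n").split("\t")
            gene_id, kind, frame = name.split(":")
            feats.setdefault(gene_id, []).append(
                GeneFeature(int(start), int(end), kind, None if frame == "." else int(frame))
            )
            meta[gene_id] = (chrom, strand)
    genes = []
    for gene_id, fs in feats.items():
        chrom, strand = meta[gene_id]
        length = max(f.end for f in fs)
        genes.append(GeneModel(gene_id, length, fs, chrom=chrom, strand=strand))
    return genes


def write_triples_fasta(triples: list[SpeciesTriple], path: Path | str, seed: int) -> None:
    """Three records per gene: <gene>|focal, <gene>|sister, <gene>|outgroup."""
    with open(path, "w") as fh:
        fh.write(f"; tetrapop species triples; seed={seed}\n")
        for t in triples:
            for tag, seq in (("focal", t.focal), ("sister", t.sister), ("outgroup", t.outgroup)):
                fh.write(f">{t.gene_id}|{tag}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def read_triples_fasta(path: Path | str, genes: list[GeneModel]) -> list[SpeciesTriple]:
    from Bio import SeqIO

    by_gene: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta-pearson"):
        gene_id, tag = rec.id.split("|")
        by_gene.setdefault(gene_id, {})[tag] = str(rec.seq)
    gene_map = {g.gene_id: g for g in genes}
    triples = []
    for gene_id, seqs in by_gene.items():
        triples.append(
            SpeciesTriple(
                gene_id=gene_id,
                focal=seqs["focal"],
                sister=seqs["sister"],
                outgroup=seqs["outgroup"],
                site_class=gene_map[gene_id].site_classes(),
            )
        )
    return triples


def write_pileups_tsv(pileups: pd.DataFrame, path: Path | str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tetrapop pileups; seed={seed}\n")
        pileups.to_csv(fh, sep="\t", index=False)


def read_pileups_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
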