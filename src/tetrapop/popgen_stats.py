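"""Diversity statistics for tetraploid population samples.

Sites are polarized against two outgroup sequences (a position's ancestral
state is the base the two outgroups share), classified as synonymous /
non-synonymous / intronic by codon context, and summarised as:

* the site frequency spectrum (folded by minor-allele count, or unfolded by
  outgroup-polarized derived count out of n = 48 chromosomes);
* Watterson's theta, theta_W = S / (a_{n-1} L);
* nucleotide diversity pi as expected gametic heterozygosity — the average
  number of differences between two sampled chromosomes — with the sample
  correction n/(n-1);
* counts of fixed differences of the sample consensus against both outgroups;
* pairwise Weir & Cockerham F_ST, treating each tetraploid individual as four
  independent gametes (consistent with tetrasomic inheritance).

Alignments with < 80% pairwise identity among the three species are excluded
upstream by :func:`identity_filter`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import GeneModel, SpeciesTriple

__all__ = [
    "SiteRecord",
    "SFS",
    "GeneSummary",
    "polarize",
    "classify_site",
    "build_sfs",
    "fold_sfs",
    "harmonic",
    "watterson_theta",
    "pi",
    "pi_per_site",
    "count_fixed_differences",
    "pairwise_fst",
    "identity_filter",
]

DEFAULT_N = 48

_CODON_TABLE = None


def _translate(codon: str) -> str:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE[codon]


@dataclass
class SiteRecord:
    """One polarized, classified SNP in the 48-chromosome sample."""

    gene_id: str
    position: int
    alleles: tuple[str, str]
    ancestral: str  # base, or "unpolarized"
    derived_count: int  # k out of n; -1 when unpolarized
    minor_count: int  # folded class, min(k, n - k)
    site_class: str  # synonymous | nonsynonymous | intron | other
    n: int = DEFAULT_N

    def __post_init__(self) -> None:
        if self.derived_count > self.n:
            raise ValueError("derived count exceeds sample size")
        if self.derived_count >= 0:
            expected = min(self.derived_count, self.n - self.derived_count)
            if self.minor_count != expected:
                raise ValueError("inconsistent folded count")


@dataclass
class SFS:
    """Site frequency spectrum for a sample of ``n`` chromosomes.

    ``counts[i]`` is the number of SNPs in frequency class ``i``; class 0 is
    unused (kept for direct indexing).  Folded: classes 1..n/2; unfolded:
    classes 1..n-1.
    """

    n: int
    flavor: str  # "folded" | "unfolded"
    counts: np.ndarray

    def __post_init__(self) -> None:
        expect = self.n // 2 + 1 if self.flavor == "folded" else self.n
        if self.flavor not in ("folded", "unfolded"):
            raise ValueError(f"unknown SFS flavor {self.flavor}")
        if len(self.counts) != expect:
            raise ValueError(f"{self.flavor} SFS for n={self.n} needs {expect} slots")
        if np.any(self.counts < 0) or self.counts[0] != 0:
            raise ValueError("invalid SFS counts")

    @property
    def n_snps(self) -> int:
        return int(self.counts.sum())

    def classes(self) -> np.ndarray:
        """Per-SNP class values (multiset expansion of the histogram)."""
        return np.repeat(np.arange(len(self.counts)), self.counts)

    def proportions(self) -> np.ndarray:
        return self.counts / max(self.n_snps, 1)


@dataclass
class GeneSummary:
    """Per-gene diversity summary, overall and stratified by site class."""

    gene_id: str
    length: int
    n_sites: dict[str, int]  # aligned length per class (+ "all")
    S: dict[str, int]
    theta_w: dict[str, float]
    pi: dict[str, float]
    max_clr: float | None = None
    candidate: bool = False


def polarize(
    alleles: tuple[str, str], reference_base: str, outgroup_base: str
) -> str | None:
    """Ancestral-state assignment from two outgroup sequences.

    The ancestral state is the base shared by both outgroups; if they
    disagree, or the shared base is not one of the two sample alleles, the
    site is left unpolarized (returns None) and contributes only to the
    folded spectrum.
    """
    if reference_base != outgroup_base:
        return None
    if reference_base not in alleles:
        return None
    return reference_base


def classify_site(
    gene: GeneModel, ref_seq: str, position: int, alleles: tuple[str, str]
) -> str:
    """Classify a SNP by codon context: synonymous/nonsynonymous/intron/other.

    A CDS site is synonymous iff exchanging the two alleles within the
    reference codon context leaves the amino acid unchanged.  ``ref_seq``
    supplies the codon context (the aligned focal/reference sequence).
    """
    for f in gene.features:
        if f.start <= position < f.end:
            if f.kind == "intron":
                return "intron"
            break
    else:
        return "other"

    # locate the position along the spliced CDS; the feature frame gives the
    # codon phase at the feature start
    cds_pos = None
    within = None
    offset = 0
    for f in gene.features:
        if f.kind != "CDS":
            continue
        if f.start <= position < f.end:
            cds_pos = offset + (position - f.start)
            within = (position - f.start + (f.frame or 0)) % 3
            break
        offset += f.end - f.start
    if cds_pos is None:  # pragma: no cover - guarded above
        return "other"
    if gene.strand == "-":
        raise NotImplementedError("minus-strand gene models are not produced here")

    codon_start_cds = cds_pos - within
    cds_seq = "".join(ref_seq[f.start : f.end] for f in gene.features if f.kind == "CDS")
    codon = cds_seq[codon_start_cds : codon_start_cds + 3]
    if codon_start_cds < 0:
        raise ValueError("reading frame violation: codon starts before the CDS")
    if len(codon) < 3:
        raise ValueError("reading frame violation: truncated codon")
    a, b = alleles
    cod_a = codon[:within] + a + codon[within + 1 :]
    cod_b = codon[:within] + b + codon[within + 1 :]
    return "synonymous" if _translate(cod_a) == _translate(cod_b) else "nonsynonymous"


def build_sfs(sites: list[SiteRecord] | np.ndarray, flavor: str, n: int = DEFAULT_N) -> SFS:
    """Histogram SNPs into an SFS.

    ``sites`` may be SiteRecords or a bare array of class values (derived
    counts for unfolded, minor counts for folded).  Unpolarized sites are
    skipped in the unfolded flavor.  Monomorphic input (class 0 or n) is an
    error.
    """
    if flavor == "unfolded":
        size = n
        if isinstance(sites, np.ndarray) or (sites and isinstance(sites[0], (int, np.integer))):
            vals = np.asarray(sites, dtype=int)
        else:
            vals = np.array(
                [s.derived_count for s in sites if s.ancestral != "unpolarized"], dtype=int
            )
        if np.any((vals <= 0) | (vals >= n)):
            raise ValueError("monomorphic site in SFS input")
    elif flavor == "folded":
        size = n // 2 + 1
        if isinstance(sites, np.ndarray) or (sites and isinstance(sites[0], (int, np.integer))):
            vals = np.asarray(sites, dtype=int)
        else:
            vals = np.array([s.minor_count for s in sites], dtype=int)
        if np.any((vals <= 0) | (vals > n // 2)):
            raise ValueError("folded class out of range")
    else:
        raise ValueError(f"unknown SFS flavor {flavor}")
    counts = np.bincount(vals, minlength=size)
    return SFS(n=n, flavor=flavor, counts=counts)


def fold_sfs(sfs: SFS) -> SFS:
    """Fold an unfolded SFS: class i and n-i collapse onto min(i, n-i)."""
    if sfs.flavor != "unfolded":
        raise ValueError("can only fold an unfolded SFS")
    n = sfs.n
    folded = np.zeros(n // 2 + 1, dtype=sfs.counts.dtype)
    for i in range(1, n):
        folded[min(i, n - i)] += sfs.counts[i]
    return SFS(n=n, flavor="folded", counts=folded)


def harmonic(m: int) -> float:
    """a_m = sum_{i=1}^{m} 1/i (Watterson's denominator uses a_{n-1})."""
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def watterson_theta(S: int, n: int = DEFAULT_N, L: float = 1.0) -> float:
    """Watterson's estimator per site: theta_W = S / (a_{n-1} L)."""
    if L <= 0:
        raise ValueError("L must be > 0")
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / (harmonic(n - 1) * L)


def pi_per_site(k: np.ndarray, n: int = DEFAULT_N) -> np.ndarray:
    """Per-site gametic heterozygosity with the n/(n-1) sample correction.

    For a biallelic site with allele count k out of n this equals
    2 k (n-k) / (n (n-1)), the probability that two chromosomes drawn without
    replacement differ — i.e. the expected number of differences between two
    random gametes at that site.
    """
    k = np.asarray(k, dtype=float)
    p = k / n
    return (n / (n - 1)) * (1.0 - p**2 - (1.0 - p) ** 2)


def pi(k: np.ndarray, n: int = DEFAULT_N, L: float = 1.0) -> float:
    """Nucleotide diversity per base pair over a gene of aligned length L."""
    if L <= 0:
        raise ValueError("L must be > 0")
    return float(pi_per_site(k, n).sum() / L)


def count_fixed_differences(
    sample_alleles: dict[int, tuple[str, int]],
    triple: SpeciesTriple,
    n: int = DEFAULT_N,
) -> int:
    """Count sites where the sample is fixed for an allele absent from both outgroups.

    ``sample_alleles`` maps positions carrying non-reference variation to
    (derived base, derived count).  A position is a fixed difference when the
    two outgroup sequences agree (non-gap) and the sample is monomorphic
    (k = n at a recorded site, or no variation and the focal consensus
    differs) for a different base.
    """
    sister = np.array(list(triple.sister))
    out = np.array(list(triple.outgroup))
    focal = np.array(list(triple.focal))
    agree = (sister == out) & (sister != "-") & (focal != "-")
    fixed = 0
    polymorphic = {p for p, (_, k) in sample_alleles.items() if 0 < k < n}
    for pos in np.nonzero(agree & (focal != sister))[0]:
        if int(pos) not in polymorphic:
            fixed += 1
    for pos, (base, k) in sample_alleles.items():
        if k == n and agree[pos] and base != sister[pos] and focal[pos] == sister[pos]:
            fixed += 1  # fixed derived allele not reflected in the consensus
    return fixed


def pairwise_fst(
    counts1: np.ndarray,
    counts2: np.ndarray,
    n1: int,
    n2: int,
) -> tuple[np.ndarray, float]:
    """Weir & Cockerham F_ST between two populations of gametes.

    ``counts1``/``counts2`` are per-site allele counts; ``n1``/``n2`` the
    per-population gamete sample sizes (each tetraploid individual
    contributes four independent gametes, with no within-individual
    correlation term, per tetrasomic inheritance).  Uses the two-population
    haploid variance-components estimator; the genome-wide average is the
    ratio of summed components across sites (standard W&C practice), NaN when
    both populations are monomorphic and identical everywhere.

    Returns (per-site theta, ratio-of-sums average).
    """
    p1 = np.asarray(counts1, dtype=float) / n1
    p2 = np.asarray(counts2, dtype=float) / n2
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_within = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 - 1 + n2 - 1)
    # haploid W&C: a = between-population variance component, b = within
    a = (n_bar / n_c) * (s2 - h_within / n_bar)
    b = h_within
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(denom > 0, a / denom, np.nan)
    total = denom.sum()
    avg = float(a.sum() / total) if total > 0 else float("nan")
    return per_site, avg


def identity_filter(triple: SpeciesTriple, threshold: float = 0.8) -> bool:
    """Keep a gene iff all three pairwise identities (non-gap columns) >= threshold.

    The threshold is inclusive: exactly 80% identity passes.
    """
    seqs = [np.array(list(s)) for s in (triple.focal, triple.sister, triple.outgroup)]
    any_valid = False
    for i in range(3):
        for j in range(i + 1, 3):
            ok = (seqs[i] != "-") & (seqs[j] != "-")
            if not ok.any():
                continue
            any_valid = True
            ident = float((seqs[i][ok] == seqs[j][ok]).mean())
            if ident < threshold:
                return False
    if not any_valid:
        raise ValueError(f"{triple.gene_id}: all-gap alignment")
    return True
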