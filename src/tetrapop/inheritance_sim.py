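"""Coalescent simulation of tetrasomic vs. disomic inheritance in an autotetraploid.

An autotetraploid with tetrasomic inheritance segregates all four homologous
chromosome copies in a single pool, so a sample of 12 tetraploid individuals is
a sample of 48 exchangeable chromosomes.  If pairing preferences evolve
(genetic diploidization), the four copies split into two isolated homeologous
pools and each locus behaves as a pair of duplicated diploid loci: disomic
inheritance.  The two modes leave different footprints in the site frequency
spectrum (SFS) and in tetraploid genotype-class frequencies, which is what the
functions here simulate:

* ``tetrasomic`` — a single panmictic pool of 48 chromosomes.
* ``disomic``   — two isolated sub-pools of 24 chromosomes that merge into one
  ancestral pool ``t_d`` time units (4N generations) in the past, the time
  since disomic inheritance evolved.  Each simulated individual receives two
  chromosomes from each sub-pool (its two homeologous pairs).

Mutation follows the infinite-sites model.  Time is measured in units of 4N
generations and the population mutation rate ``theta`` is the ms-style locus
rate 4Nu, so for a sample of n chromosomes E[S] = theta * a_{n-1} with
a_{n-1} = sum_{i<n} 1/i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InheritanceModel",
    "SimulatedPool",
    "coalescent_sample",
    "assemble_individuals",
    "simulate_model",
    "sample_snp_classes",
    "expected_tetrasomic_genotype_freqs",
    "DOSAGE_LABELS",
]

DOSAGE_LABELS = ("nulliplex", "simplex", "duplex", "triplex", "quadruplex")

#: default grid of diploidization times (units of 4N generations)
TD_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class InheritanceModel:
    """Inheritance mode of a simulated tetraploid population.

    Parameters
    ----------
    kind:
        ``"tetrasomic"`` or ``"disomic"``.
    t_d:
        Time since the evolution of disomic inheritance, in units of 4N
        generations.  Required (and > 0) for disomic models; ignored for
        tetrasomic ones.
    """

    kind: str
    t_d: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("tetrasomic", "disomic"):
            raise ValueError(f"unknown inheritance kind {self.kind!r}")
        if self.kind == "disomic":
            if self.t_d is None or not self.t_d > 0:
                raise ValueError("disomic model requires t_d > 0")

    @property
    def label(self) -> str:
        if self.kind == "tetrasomic":
            return "tetrasomic"
        return f"disomic_td{self.t_d:g}"


@dataclass
class SimulatedPool:
    """SNPs pooled across coalescent runs under one inheritance model.

    ``folded_counts[i]`` is the number of pooled SNPs with minor-allele count
    ``i`` (i = 1..n/2); ``unfolded_counts[i]`` the number with derived count
    ``i`` (i = 1..n-1).  ``genotype_class_counts`` holds pooled counts of
    individual dosage classes (nulliplex..quadruplex) over all segregating
    sites and individuals.
    """

    model: InheritanceModel
    n: int
    n_runs: int
    folded_counts: np.ndarray
    unfolded_counts: np.ndarray
    genotype_class_counts: np.ndarray

    @property
    def n_snps(self) -> int:
        return int(self.unfolded_counts.sum())

    def folded_classes(self) -> np.ndarray:
        """Per-SNP folded minor-allele classes, reconstructed from the histogram."""
        return np.repeat(np.arange(1, self.n // 2 + 1), self.folded_counts[1:])


def _simulate_branches(
    n: int,
    demes: int,
    t_merge: float | None,
    pool_scale: float,
    rng: np.random.Generator,
) -> list[tuple[float, list[int]]]:
    """Run one coalescent genealogy; return (branch length, descendant leaves) pairs.

    Pair-coalescence rate is 2/pool_scale per unit of 4N generations, so the
    expected total tree length is ``pool_scale * a_{n-1}``.  With two demes
    there is no migration: lineages coalesce only within a deme until
    ``t_merge``, when the demes join into the single ancestral pool.
    """
    if demes == 2:
        if n % 2:
            raise ValueError("two-deme sample size must be even")
        deme_of = [0] * (n // 2) + [1] * (n // 2)
    else:
        deme_of = [0] * n

    leaves: list[list[int]] = [[i] for i in range(n)]
    lengths = [0.0] * n
    demes_of = list(deme_of)
    merged = demes == 1
    t = 0.0
    branches: list[tuple[float, list[int]]] = []

    while len(leaves) > 1:
        ks = [demes_of.count(d) for d in (0, 1)]
        rate = sum(k * (k - 1) for k in ks) / pool_scale
        if rate > 0:
            dt = rng.exponential(1.0 / rate)
        else:
            dt = np.inf
        if not merged and t + dt >= t_merge:
            dt = t_merge - t
            for i in range(len(lengths)):
                lengths[i] += dt
            t = t_merge
            demes_of = [0] * len(demes_of)
            merged = True
            continue
        for i in range(len(lengths)):
            lengths[i] += dt
        t += dt
        # pick deme proportional to its coalescence rate, then a random pair
        if merged or ks[1] == 0:
            d = 0
        else:
            w0 = ks[0] * (ks[0] - 1)
            w1 = ks[1] * (ks[1] - 1)
            d = 0 if rng.random() < w0 / (w0 + w1) else 1
        idx = [i for i, dd in enumerate(demes_of) if dd == d]
        i, j = rng.choice(len(idx), size=2, replace=False)
        a, b = sorted((idx[i], idx[j]), reverse=True)
        branches.append((lengths[a], leaves[a]))
        branches.append((lengths[b], leaves[b]))
        new_leaves = leaves[a] + leaves[b]
        for k in (a, b):
            leaves.pop(k)
            lengths.pop(k)
            demes_of.pop(k)
        leaves.append(new_leaves)
        lengths.append(0.0)
        demes_of.append(d)
    return branches


def coalescent_sample(
    n: int,
    theta: float,
    *,
    demes: int = 1,
    t_merge: float | None = None,
    pool_scale: float = 1.0,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one sample of ``n`` haplotypes under the neutral coalescent.

    Parameters
    ----------
    n:
        Number of sampled chromosomes (48 for 12 tetraploid individuals).
    theta:
        Locus-wide population mutation rate 4Nu (ms ``-t``).
    demes:
        1 (panmictic) or 2 (isolated homeologous sub-pools of n/2 each).
    t_merge:
        With ``demes=2``, the time (4N-generation units) at which the two
        sub-pools join the ancestral pool, i.e. the diploidization time t_d.
    pool_scale:
        Multiplier on the chromosome-pool (effective) size: coalescence is
        slowed by this factor, so expected diversity scales linearly with it.
        A tetraploid pool of 4N chromosomes relative to a diploid pool of 2N
        corresponds to ``pool_scale=2``.
    rng:
        numpy random generator (mandatory; all randomness flows through it).

    Returns
    -------
    ndarray of shape (n, S), dtype uint8
        0/1 haplotypes at the S segregating sites (0 = ancestral), in no
        particular positional order (infinite sites: every site biallelic).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if demes not in (1, 2):
        raise ValueError("demes must be 1 or 2")
    if demes == 2 and (t_merge is None or t_merge <= 0):
        raise ValueError("demes=2 requires t_merge > 0")
    if pool_scale <= 0:
        raise ValueError("pool_scale must be > 0")

    branches = _simulate_branches(n, demes, t_merge, pool_scale, rng)
    lengths = np.array([b[0] for b in branches])
    n_mut = rng.poisson(theta * lengths)
    total = int(n_mut.sum())
    haps = np.zeros((n, total), dtype=np.uint8)
    col = 0
    for (_, desc), m in zip(branches, n_mut):
        for _ in range(m):
            haps[desc, col] = 1
            col += 1
    return haps


def assemble_individuals(
    haplotypes: np.ndarray,
    model: InheritanceModel,
    *,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Group 48 chromosomes into 12 simulated tetraploid individuals.

    Tetrasomic: a random partition of all 48 into 12 groups of four.
    Disomic: each individual receives two chromosomes from each sub-pool
    (haplotypes 0..23 are sub-pool one, 24..47 sub-pool two), representing its
    two homeologous chromosome pairs.

    Returns
    -------
    (dosages, assignment):
        ``dosages`` is a (12, S) array of per-individual derived-allele
        dosages (0..4); ``assignment`` maps each haplotype index to its
        individual (length 48).
    """
    n = haplotypes.shape[0]
    if n != 48:
        raise ValueError(f"expected 48 haplotypes, got {n}")
    if model.kind == "tetrasomic":
        perm = rng.permutation(48)
    else:
        a = rng.permutation(24)
        b = rng.permutation(24) + 24
        # individual i gets a[2i], a[2i+1], b[2i], b[2i+1]
        perm = np.empty(48, dtype=np.intp)
        perm[0::4] = a[0::2]
        perm[1::4] = a[1::2]
        perm[2::4] = b[0::2]
        perm[3::4] = b[1::2]
    assignment = np.empty(48, dtype=np.intp)
    assignment[perm] = np.repeat(np.arange(12), 4)
    dosages = haplotypes[perm].reshape(12, 4, -1).sum(axis=1).astype(np.uint8)
    return dosages, assignment


def simulate_model(
    model: InheritanceModel,
    theta_source: np.ndarray,
    runs: int,
    *,
    n: int = 48,
    rng: np.random.Generator,
) -> SimulatedPool:
    """Pool SNP frequencies and genotype classes over many coalescent runs.

    Each run draws its locus theta with replacement from ``theta_source``
    (empirical per-gene silent theta values), simulates a genealogy under
    ``model``, assembles 12 individuals, and accumulates every segregating
    site's derived count plus each individual's dosage class at that site.
    """
    theta_source = np.asarray(theta_source, dtype=float)
    if theta_source.size == 0:
        raise ValueError("theta_source must be non-empty")
    if runs < 1:
        raise ValueError("runs must be >= 1")

    folded = np.zeros(n // 2 + 1, dtype=np.int64)
    unfolded = np.zeros(n, dtype=np.int64)
    classes = np.zeros(5, dtype=np.int64)
    demes = 1 if model.kind == "tetrasomic" else 2
    t_merge = None if model.kind == "tetrasomic" else model.t_d

    for _ in range(runs):
        theta = theta_source[rng.integers(theta_source.size)]
        haps = coalescent_sample(
            n, theta, demes=demes, t_merge=t_merge, rng=rng
        )
        if haps.shape[1] == 0:
            continue
        k = haps.sum(axis=0)
        np.add.at(unfolded, k, 1)
        np.add.at(folded, np.minimum(k, n - k), 1)
        dosages, _ = assemble_individuals(haps, model, rng=rng)
        classes += np.bincount(dosages.ravel(), minlength=5)
    return SimulatedPool(
        model=model,
        n=n,
        n_runs=runs,
        folded_counts=folded,
        unfolded_counts=unfolded,
        genotype_class_counts=classes,
    )


def sample_snp_classes(
    model: InheritanceModel,
    theta_source: np.ndarray,
    n_snps: int,
    *,
    n: int = 48,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n_snps`` independent folded SNP classes, one per coalescent run.

    SNPs within one run share a genealogy and are therefore strongly
    correlated; rank tests that assume independent observations (the
    Mann-Whitney SFS comparison) are anti-conservative on run-pooled SNPs.
    Taking a single random segregating site per run yields independent
    draws from the model's SNP class distribution, suitable as calibrated
    pseudo-observed data.
    """
    theta_source = np.asarray(theta_source, dtype=float)
    if theta_source.size == 0:
        raise ValueError("theta_source must be non-empty")
    demes = 1 if model.kind == "tetrasomic" else 2
    t_merge = None if model.kind == "tetrasomic" else model.t_d
    out = np.empty(n_snps, dtype=int)
    got = 0
    while got < n_snps:
        theta = theta_source[rng.integers(theta_source.size)]
        haps = coalescent_sample(n, theta, demes=demes, t_merge=t_merge, rng=rng)
        if haps.shape[1] == 0:
            continue
        k = int(haps[:, rng.integers(haps.shape[1])].sum())
        out[got] = min(k, n - k)
        got += 1
    return out


def expected_tetrasomic_genotype_freqs(p: float) -> np.ndarray:
    """Expected tetraploid genotype-class frequencies under tetrasomic inheritance.

    With bivalent pairing and random four-allele segregation (no double
    reduction), an individual's derived dosage at a site with derived allele
    frequency ``p`` is Binomial(4, p):
    freq(dosage g) = C(4, g) p^g (1-p)^(4-g) for g = 0..4.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    g = np.arange(5)
    from scipy.stats import binom

    return binom.pmf(g, 4, p)
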