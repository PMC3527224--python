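"""Maximum-likelihood tetraploid genotype calling from base pileups.

A tetraploid individual has five possible biallelic genotypes at a site:
the homozygotes A1A1A1A1 / A2A2A2A2 and three heterozygous dosage states
(A1A1A1A2, A1A1A2A2, A1A2A2A2).  Given the pileup D of mapped read bases at a
position, the likelihood of genotype G with ``i`` copies of allele A1
(i + j = 4) is

    P(D | G) = prod_b P(b | G),
    P(b | G) = (i/4) P(b | A1) + (j/4) P(b | A2),
    P(b | a) = 1 - e   if b == a,   e / 3 otherwise,

where ``e`` is the individual's combined sequencing + mapping error rate.
The most probable genotype is accepted when its log10-odds over the runner-up
is >= 2.  Sites are only genotyped when every individual has coverage
strictly greater than 4x and no more than two variant bases are present
across the whole sample.

``e`` itself is estimated from three-way alignments (reads, reference sister
species, outgroup): both the reads and the sister sequence are separated from
the outgroup by the same evolutionary divergence, so the excess mismatch rate
of reads over the sister sequence estimates the error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "PileupColumn",
    "GenotypeCall",
    "ErrorRateEstimate",
    "genotype_likelihoods",
    "genotype_likelihood_matrix",
    "call_genotype",
    "call_genotypes",
    "detect_variants",
    "site_filter",
    "estimate_error_rate",
    "allele_frequencies",
]

BASES = ("A", "C", "G", "T")
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

#: genotype dosage order used throughout: index g = copies of allele A1 (0..4)
DOSAGES = np.arange(5)


@dataclass(frozen=True)
class PileupColumn:
    """Base counts for one individual at one site."""

    gene_id: str
    position: int
    individual: int
    counts: tuple[int, int, int, int]  # n_A, n_C, n_G, n_T

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("negative base count")

    @property
    def depth(self) -> int:
        return sum(self.counts)


@dataclass
class GenotypeCall:
    """A biallelic tetraploid genotype call.

    ``dosage`` counts copies of ``a1`` (i; the remaining 4 - i copies are
    ``a2``).  ``log10_likelihoods[g]`` is log10 P(D | dosage g).  ``status``
    is "called", "no_call" (log-odds below threshold) or "filtered".
    """

    a1: str
    a2: str | None
    dosage: int
    log10_likelihoods: np.ndarray
    log_odds: float
    status: str

    def __post_init__(self) -> None:
        if not 0 <= self.dosage <= 4:
            raise ValueError("dosage must be 0..4")
        if self.log_odds < 0:
            raise ValueError("log-odds must be >= 0")


@dataclass
class ErrorRateEstimate:
    individual: int
    e: float
    n_columns: int
    mismatches_reads_outgroup: int
    mismatches_reference_outgroup: int
    clamped: bool = False


def genotype_likelihood_matrix(
    counts: np.ndarray, a1_idx: np.ndarray, a2_idx: np.ndarray, e: float
) -> np.ndarray:
    """Vectorised log10 genotype likelihoods.

    Parameters
    ----------
    counts: (..., 4) base counts; a1_idx, a2_idx: allele indices broadcastable
    to ``counts.shape[:-1]``; e: error rate in (0, 1).

    Returns (..., 5): log10 P(D | dosage g) for g = 0..4 copies of A1.
    """
    if not 0.0 < e < 1.0:
        raise ValueError("error rate must be in (0, 1)")
    counts = np.asarray(counts, dtype=float)
    a1_idx = np.asarray(a1_idx)
    a2_idx = np.asarray(a2_idx)
    eye = np.eye(4)
    emit = eye * (1.0 - e) + (1.0 - eye) * (e / 3.0)  # emit[allele, base]
    p1 = emit[a1_idx]  # (..., 4)
    p2 = emit[a2_idx]
    g = DOSAGES.reshape((5,) + (1,) * counts.ndim)  # (5, ..., 1)
    pb = (g / 4.0) * p1[None] + (1.0 - g / 4.0) * p2[None]  # (5, ..., 4)
    ll = (counts[None] * np.log10(pb)).sum(axis=-1)  # (5, ...)
    return np.moveaxis(ll, 0, -1)


def genotype_likelihoods(
    col: PileupColumn, alleles: tuple[str, str], e: float
) -> np.ndarray:
    """log10 P(D | G) for the five tetraploid genotypes of one pileup column.

    Returned in dosage order g = 0..4 copies of ``alleles[0]``.
    """
    a1, a2 = alleles
    if a1 == a2:
        raise ValueError("alleles must differ")
    if col.depth == 0:
        raise ValueError("zero-depth pileup")
    return genotype_likelihood_matrix(
        np.array(col.counts), _BASE_IDX[a1], _BASE_IDX[a2], e
    )


def call_genotype(
    col: PileupColumn,
    alleles: tuple[str, str],
    e: float,
    lod_min: float = 2.0,
) -> GenotypeCall:
    """Call the most probable genotype; accept when log10-odds >= ``lod_min``."""
    ll = genotype_likelihoods(col, alleles, e)
    order = np.argsort(ll)
    best, second = order[-1], order[-2]
    lod = float(ll[best] - ll[second])
    return GenotypeCall(
        a1=alleles[0],
        a2=alleles[1],
        dosage=int(best),
        log10_likelihoods=ll,
        log_odds=lod,
        status="called" if lod >= lod_min else "no_call",
    )


def call_genotypes(
    counts: np.ndarray,
    a1_idx: np.ndarray,
    a2_idx: np.ndarray,
    e: float | np.ndarray,
    lod_min: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised calling over many (individual, site) pileups.

    ``counts`` is (n_ind, n_sites, 4); allele indices are per-site.  ``e`` may
    be a scalar or per-individual array (each individual's own estimate is
    used inside its likelihood).  Returns (dosage, log_odds, called) arrays of
    shape (n_ind, n_sites); dosage counts copies of A1.
    """
    e_arr = np.atleast_1d(np.asarray(e, dtype=float))
    n_ind = counts.shape[0]
    if e_arr.size == 1:
        e_arr = np.full(n_ind, float(e_arr[0]))
    dosage = np.empty(counts.shape[:2], dtype=np.int8)
    lod = np.empty(counts.shape[:2])
    for i in range(n_ind):
        ll = genotype_likelihood_matrix(counts[i], a1_idx, a2_idx, e_arr[i])
        srt = np.sort(ll, axis=-1)
        dosage[i] = np.argmax(ll, axis=-1)
        lod[i] = srt[..., -1] - srt[..., -2]
    return dosage, lod, lod >= lod_min


@lru_cache(maxsize=100_000)
def _variant_cutoff(depth: int, e: float, alpha: float) -> int:
    """Smallest count c (>= 2) with P(Binom(depth, e/3) >= c) < alpha."""
    c = int(binom.ppf(1.0 - alpha, depth, e / 3.0))
    while binom.sf(c - 1, depth, e / 3.0) >= alpha:
        c += 1
    return max(c, 2)


def detect_variants(
    pooled_counts: np.ndarray, e: float, alpha: float = 1e-3
) -> list[int]:
    """Bases present above error-consistent counts in the pooled pileup.

    A base with count c out of total depth D is a variant when c >= 2 and the
    chance of seeing >= c error reads — each read errs toward a specific base
    with probability e/3 — is below ``alpha``.  Returned sorted by count,
    descending.
    """
    pooled = np.asarray(pooled_counts)
    depth = int(pooled.sum())
    if depth == 0:
        return []
    cutoff = _variant_cutoff(depth, e, alpha)
    variants = [b for b in range(4) if pooled[b] >= cutoff]
    return sorted(variants, key=lambda b: -pooled[b])


def site_filter(
    depths: np.ndarray,
    pooled_counts: np.ndarray,
    e: float,
    min_depth: int = 4,
    max_variants: int = 2,
) -> tuple[bool, str]:
    """Decide whether a site is eligible for genotyping.

    Keep iff every individual's coverage is strictly greater than
    ``min_depth`` and at most ``max_variants`` variant bases are present
    across all individuals.  Returns (keep, reason).
    """
    depths = np.asarray(depths)
    if depths.size != 12:
        raise ValueError("expected depths for all 12 individuals")
    if np.any(depths <= min_depth):
        return False, "low_coverage"
    if len(detect_variants(pooled_counts, e)) > max_variants:
        return False, "too_many_variants"
    return True, "pass"


def estimate_error_rate(
    reads: str,
    reference: str,
    outgroup: str,
    individual: int = 0,
    min_columns: int = 1000,
) -> ErrorRateEstimate:
    """Estimate the combined sequencing + mapping error rate of one individual.

    Over alignment columns where none of the three sequences is a gap, the
    observed reads-vs-outgroup mismatch rate contains both evolutionary
    divergence and error, while the reference(sister)-vs-outgroup rate
    contains divergence only; their difference estimates e.  A negative
    excess is clamped to zero with a warning flag.
    """
    if not (len(reads) == len(reference) == len(outgroup)):
        raise ValueError("sequences must be aligned to equal length")
    r = np.array(list(reads))
    s = np.array(list(reference))
    o = np.array(list(outgroup))
    ok = (r != "-") & (s != "-") & (o != "-")
    n = int(ok.sum())
    if n < min_columns:
        raise ValueError(f"only {n} aligned columns; need >= {min_columns}")
    mm_r = int((r[ok] != o[ok]).sum())
    mm_s = int((s[ok] != o[ok]).sum())
    e = (mm_r - mm_s) / n
    clamped = e < 0
    if clamped:
        warnings.warn(
            f"individual {individual}: reference more diverged than reads; "
            "error estimate clamped to 0",
            stacklevel=2,
        )
        e = 0.0
    return ErrorRateEstimate(
        individual=individual,
        e=e,
        n_columns=n,
        mismatches_reads_outgroup=mm_r,
        mismatches_reference_outgroup=mm_s,
        clamped=clamped,
    )


def allele_frequencies(
    dosage: np.ndarray, called: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site A1 allele counts from per-individual genotype calls.

    ``dosage``/``called`` are (n_ind, n_sites).  Sites where any individual is
    uncalled are excluded (masked) so the sample size stays fixed at
    4 * n_ind chromosomes.  Returns (counts, complete) where ``counts[s]`` is
    the summed dosage at site s (only valid where ``complete[s]``).
    """
    complete = called.all(axis=0)
    counts = dosage.astype(int).sum(axis=0)
    return np.where(complete, counts, -1), complete
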