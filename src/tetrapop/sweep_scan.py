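"""Selective-sweep scan: windowed SFS skew plus diversity outliers.

A recent sweep leaves two linked footprints: the local unfolded SFS is skewed
toward high-frequency derived alleles, and nucleotide diversity is reduced.
The scan scores both:

* each gene's polarized SNPs are cut into consecutive 100-SNP windows and
  every window receives a composite likelihood ratio (CLR) contrasting its
  own derived-class spectrum with the genome-wide background spectrum.  The
  alternative is the one-parameter exponential tilting of the background
  toward high derived frequencies, p_c(lam) = q_c e^(lam c) / Z(lam) with
  lam >= 0, so

      CLR = 2 * max_{lam >= 0} sum_c m_c * ln( p_c(lam) / q_c ),

  where m_c is the window's count in derived class c and q_c the background
  class proportion.  CLR = 0 when the window matches the background (or is
  shifted toward low frequencies) and CLR >= 0 always; constraining the
  alternative to a directional frequency shift makes the score specific to
  the high-frequency-derived excess a sweep leaves, rather than to any
  deviation from the background (an unconstrained multinomial ratio is
  dominated by the genealogical clustering of linked SNPs and barely ranks
  true sweeps above neutral windows);
* per-gene pi/bp is computed from the same call set.

Candidate sweep genes fall simultaneously in the top 5% of the genome-wide
CLR distribution (any window) and the bottom 5% of pi/bp.  Enrichment of a
gene set (e.g. annotated meiosis genes) among candidates is tested with a
one-sided Fisher's exact test on the 2x2 membership table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .popgen_stats import SFS

__all__ = [
    "Window",
    "CandidateList",
    "EnrichmentResult",
    "make_windows",
    "background_proportions",
    "clr_score",
    "select_candidates",
    "check_independence",
    "enrichment_test",
    "enrichment_from_counts",
]

WINDOW_SNPS = 100
PSEUDOCOUNT = 0.5


@dataclass
class Window:
    """A block of up to ``window_snps`` consecutive polarized SNPs of one gene."""

    gene_id: str
    index: int
    derived_counts: np.ndarray  # per-SNP derived classes (1..n-1)
    partial: bool

    @property
    def n_snps(self) -> int:
        return len(self.derived_counts)


@dataclass
class EnrichmentResult:
    """2x2 Fisher test of gene-set membership vs. sweep candidacy."""

    in_set_candidate: int
    in_set_other: int
    out_set_candidate: int
    out_set_other: int
    odds_ratio: float
    fold_enrichment: float
    p_value: float

    @property
    def universe_size(self) -> int:
        return (
            self.in_set_candidate
            + self.in_set_other
            + self.out_set_candidate
            + self.out_set_other
        )

    @property
    def in_set_candidate_fraction(self) -> float:
        return self.in_set_candidate / (self.in_set_candidate + self.in_set_other)


@dataclass
class CandidateList:
    """Per-gene scan results with tail thresholds and candidate flags."""

    table: pd.DataFrame  # gene_id, max_clr, pi_bp, candidate
    clr_threshold: float
    pi_threshold: float
    degenerate: bool = False

    @property
    def candidates(self) -> set[str]:
        return set(self.table.loc[self.table["candidate"], "gene_id"])


def make_windows(
    gene_id: str,
    derived_counts: np.ndarray,
    positions: np.ndarray | None = None,
    window_snps: int = WINDOW_SNPS,
) -> list[Window]:
    """Cut a gene's polarized SNPs into consecutive non-overlapping windows.

    SNPs must be supplied (or sortable via ``positions``) in positional
    order.  The final short block — or a gene with fewer than ``window_snps``
    SNPs altogether — forms a single window flagged partial.  A gene with no
    polarized SNPs yields no windows.
    """
    counts = np.asarray(derived_counts, dtype=int)
    if positions is not None:
        counts = counts[np.argsort(np.asarray(positions), kind="stable")]
    if counts.size == 0:
        return []
    windows = []
    for i, start in enumerate(range(0, counts.size, window_snps)):
        block = counts[start : start + window_snps]
        windows.append(
            Window(
                gene_id=gene_id,
                index=i,
                derived_counts=block,
                partial=block.size < window_snps,
            )
        )
    return windows


def background_proportions(background: SFS | np.ndarray, n: int = 48) -> np.ndarray:
    """Background derived-class proportions q_c (classes 1..n-1).

    Classes with zero genome-wide mass receive a 0.5 pseudo-count before
    normalisation so any window occupancy stays scoreable.
    """
    if isinstance(background, SFS):
        if background.flavor != "unfolded":
            raise ValueError("background must be an unfolded SFS")
        counts = background.counts[1:].astype(float)
    else:
        counts = np.asarray(background, dtype=float)
        if counts.size == n:  # histogram including the unused 0 slot
            counts = counts[1:]
    counts = counts.copy()
    counts[counts == 0] = PSEUDOCOUNT
    return counts / counts.sum()


LAMBDA_MAX = 40.0


def _tilted_loglik(lam: float, m_c: np.ndarray, log_q: np.ndarray, cls: np.ndarray) -> float:
    """Window log-likelihood under the background tilted by e^(lam * class)."""
    x = log_q + lam * cls
    x -= x.max()  # log-sum-exp stabilisation
    log_p = x - np.log(np.exp(x).sum())
    return float((m_c * log_p).sum())


def clr_score(window: Window, q: np.ndarray) -> float:
    """Composite likelihood ratio of the window spectrum vs. the background.

    ``q`` are background class proportions from
    :func:`background_proportions` (classes 1..n-1).  The alternative tilts
    the background exponentially toward high derived classes (lam >= 0); the
    log-likelihood is concave in lam, so a bounded scalar maximisation is
    exact.  A window whose mean derived class does not exceed the
    background's scores 0.
    """
    m = window.n_snps
    if m == 0:
        raise ValueError("empty window")
    m_c = np.bincount(window.derived_counts, minlength=q.size + 1)[1:].astype(float)
    if m_c.sum() != m:
        raise ValueError("window contains classes outside the background support")
    cls = np.arange(1, q.size + 1, dtype=float)
    cls_centred = cls - float((cls * q).sum())
    # gradient at lam=0 is m * (window mean class - background mean class)
    if float((m_c * cls_centred).sum()) <= 0:
        return 0.0
    log_q = np.log(q)
    ll0 = _tilted_loglik(0.0, m_c, log_q, cls_centred)
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda lam: -_tilted_loglik(lam, m_c, log_q, cls_centred),
        bounds=(0.0, LAMBDA_MAX),
        method="bounded",
        options={"xatol": 1e-8},
    )
    best = max(-res.fun, _tilted_loglik(LAMBDA_MAX, m_c, log_q, cls_centred))
    return max(2.0 * (best - ll0), 0.0)


def select_candidates(
    genes: pd.DataFrame,
    window_clrs: pd.DataFrame,
    clr_tail: float = 0.05,
    pi_tail: float = 0.05,
) -> CandidateList:
    """Intersect the CLR upper tail with the pi/bp lower tail.

    ``genes`` needs columns gene_id and pi_bp; ``window_clrs`` columns
    gene_id and clr (one row per scored window).  A gene is a candidate iff
    at least one of its windows reaches the genome-wide (1 - clr_tail)
    empirical quantile of window CLRs AND its pi/bp is at or below the
    pi_tail quantile.  Thresholds are order statistics, ties included.  Fully
    degenerate inputs (every gene passing both tails) mean no scan is
    possible; the list is returned empty and flagged.
    """
    if len(genes) < 20:
        raise ValueError("need at least 20 genes for meaningful tail quantiles")
    clr_vals = window_clrs["clr"].to_numpy(dtype=float)
    pi_vals = genes["pi_bp"].to_numpy(dtype=float)
    clr_thr = float(np.quantile(clr_vals, 1.0 - clr_tail, method="higher")) if clr_tail > 0 else np.inf
    pi_thr = float(np.quantile(pi_vals, pi_tail, method="lower")) if pi_tail > 0 else -np.inf

    max_clr = window_clrs.groupby("gene_id")["clr"].max()
    table = genes[["gene_id", "pi_bp"]].copy()
    table["max_clr"] = table["gene_id"].map(max_clr)
    table["candidate"] = (table["max_clr"] >= clr_thr) & (table["pi_bp"] <= pi_thr)
    table.loc[table["max_clr"].isna(), "candidate"] = False

    degenerate = bool(table["candidate"].all() and len(table) > 0 and clr_tail < 1)
    if degenerate:
        table["candidate"] = False
    return CandidateList(
        table=table,
        clr_threshold=clr_thr,
        pi_threshold=pi_thr,
        degenerate=degenerate,
    )


def check_independence(clr: np.ndarray, pi: np.ndarray) -> float:
    """Squared Pearson correlation of per-gene CLR and pi values (sign-blind)."""
    clr = np.asarray(clr, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if clr.std() == 0 or pi.std() == 0:
        return float("nan")
    r = np.corrcoef(clr, pi)[0, 1]
    return float(r**2)


def enrichment_test(
    candidates: set[str], gene_set: set[str], universe: set[str]
) -> EnrichmentResult:
    """One-sided Fisher's exact test for gene-set enrichment among candidates.

    Fold enrichment is the candidate fraction inside the set divided by the
    candidate fraction over the whole universe.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= universe or not candidates <= universe:
        raise ValueError("gene set and candidates must lie within the universe")
    a = len(gene_set & candidates)
    b = len(gene_set - candidates)
    c = len(candidates - gene_set)
    d = len(universe) - a - b - c
    return enrichment_from_counts(a, b, c, d)


def enrichment_from_counts(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Build an :class:`EnrichmentResult` from the 2x2 table directly.

    Table layout: a = in-set candidates, b = in-set non-candidates,
    c = out-of-set candidates, d = out-of-set non-candidates.
    """
    odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    n = a + b + c + d
    set_frac = a / (a + b) if a + b else float("nan")
    uni_frac = (a + c) / n if n else float("nan")
    fold = set_frac / uni_frac if uni_frac else float("nan")
    return EnrichmentResult(
        in_set_candidate=a,
        in_set_other=b,
        out_set_candidate=c,
        out_set_other=d,
        odds_ratio=float(odds),
        fold_enrichment=float(fold),
        p_value=float(p),
    )
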