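"""Statistical discrimination of tetrasomic vs. disomic inheritance.

An observed SNP pool is compared against coalescent pools simulated under
each candidate inheritance model (:mod:`tetrapop.inheritance_sim`):

* the folded site-frequency distributions are compared with a two-sided,
  tie-corrected Mann-Whitney U test (frequency classes are heavily tied);
* inferred tetraploid genotype-class proportions (nulliplex..quadruplex) are
  compared with a chi-square divergence, flagging the duplex (AAaa) excess
  that long-standing disomic inheritance forces (homeologous fixed
  differences make every individual duplex, piling SNPs near frequency 50%).

A model is rejected when its SFS comparison yields p < alpha (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chisquare, mannwhitneyu, binomtest

from .inheritance_sim import DOSAGE_LABELS, SimulatedPool

__all__ = ["ModelComparison", "compare_sfs", "compare_genotype_classes", "classify_inheritance"]


@dataclass
class ModelComparison:
    """Outcome of testing one inheritance model against observed data."""

    model_label: str
    u_statistic: float
    p_value: float
    verdict: str  # "consistent" | "rejected"
    alpha: float
    genotype_divergence: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _as_classes(x) -> np.ndarray:
    if isinstance(x, SimulatedPool):
        return x.folded_classes()
    return np.asarray(x, dtype=int)


def compare_sfs(observed, simulated) -> tuple[float, float]:
    """Mann-Whitney U of observed vs. simulated folded SNP frequency classes.

    Arguments may be per-SNP folded minor-count arrays or
    :class:`SimulatedPool` objects.  Two-sided, with tie correction.
    Returns (U, p).
    """
    obs = _as_classes(observed)
    sim = _as_classes(simulated)
    if obs.size == 0 or sim.size == 0:
        raise ValueError("empty SNP pool")
    res = mannwhitneyu(obs, sim, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_genotype_classes(
    observed_counts: np.ndarray,
    expected_counts: np.ndarray,
    alpha: float = 0.01,
) -> dict:
    """Chi-square divergence of observed vs. expected genotype-class counts.

    ``expected_counts`` (e.g. a simulated pool's pooled dosage classes) is
    rescaled to the observed total.  Flags a duplex excess when the observed
    duplex proportion significantly exceeds the expected one (one-sided
    binomial test at ``alpha``).
    """
    obs = np.asarray(observed_counts, dtype=float)
    exp = np.asarray(expected_counts, dtype=float)
    if obs.shape != (5,) or exp.shape != (5,):
        raise ValueError("genotype-class vectors must have 5 dosage categories")
    if obs.sum() == 0 or exp.sum() == 0:
        raise ValueError("no segregating genotypes to compare")
    exp_prop = exp / exp.sum()
    keep = exp_prop > 0
    stat, p = chisquare(
        obs[keep], exp_prop[keep] / exp_prop[keep].sum() * obs[keep].sum()
    )
    duplex_obs = obs[2] / obs.sum()
    duplex_exp = float(exp_prop[2])
    duplex_p = binomtest(
        int(obs[2]), int(obs.sum()), duplex_exp, alternative="greater"
    ).pvalue
    return {
        "chi2": float(stat),
        "p": float(p),
        "classes": dict(zip(DOSAGE_LABELS, (obs / obs.sum()).round(6))),
        "expected": dict(zip(DOSAGE_LABELS, exp_prop.round(6))),
        "duplex_excess": bool(duplex_obs > duplex_exp and duplex_p < alpha),
        "duplex_p": float(duplex_p),
    }


def classify_inheritance(
    observed,
    pools: list,
    alpha: float = 0.01,
    observed_genotype_counts: np.ndarray | None = None,
) -> dict:
    """Test the observed data against every simulated inheritance model.

    ``pools`` entries are :class:`SimulatedPool` objects or ``(label,
    classes)`` pairs of independently drawn per-SNP folded classes (see
    :func:`tetrapop.inheritance_sim.sample_snp_classes` for why independence
    matters).  Returns a report dict with one :class:`ModelComparison` per
    model and the names of the non-rejected (consistent) models.
    """
    if len(pools) < 2:
        raise ValueError("need at least two candidate models")
    comparisons = []
    for pool in pools:
        if isinstance(pool, SimulatedPool):
            label, classes = pool.model.label, pool
            gcounts = pool.genotype_class_counts
        else:
            label, classes = pool
            gcounts = None
        u, p = compare_sfs(observed, classes)
        gdiv = None
        if (
            observed_genotype_counts is not None
            and gcounts is not None
            and gcounts.sum() > 0
        ):
            gdiv = compare_genotype_classes(observed_genotype_counts, gcounts, alpha)
        comparisons.append(
            ModelComparison(
                model_label=label,
                u_statistic=u,
                p_value=p,
                verdict="rejected" if p < alpha else "consistent",
                alpha=alpha,
                genotype_divergence=gdiv,
            )
        )
    consistent = [c.model_label for c in comparisons if c.verdict == "consistent"]
    return {
        "alpha": alpha,
        "comparisons": comparisons,
        "consistent_models": consistent,
    }
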