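"""Exact binomial tests of allelic read-count imbalance.

At a heterozygous site the reference-allele read count k out of total
depth n is compared against a null proportion p0 derived from the local
genotype: 0.5 for a balanced diploid or tetraploid heterozygote, 1/3 or
2/3 for the two triploid heterozygous configurations.  The default
two-sided p-value is the "minlike" convention — the sum of binomial point
probabilities no larger than that of the observed count — computed in log
space so extreme imbalances (p ~ 1e-45) stay representable; doubling the
smaller tail is offered as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from allelescan.types import AllelicCounts, ValidationError

logger = logging.getLogger(__name__)

#: relative slack when comparing point probabilities, to avoid
#: floating-point inclusion/exclusion flips at ties
MINLIKE_REL_SLACK = 1e-7


@dataclass(frozen=True)
class ImbalanceTest:
    """Result of one exact binomial imbalance test."""

    counts: AllelicCounts
    null_p: float
    pvalue: float
    direction: str  # 'ref-biased', 'alt-biased' or 'none'
    method: str = "minlike"

    @property
    def k(self) -> int:
        return self.counts.ref_count

    @property
    def n(self) -> int:
        return self.counts.depth

    @property
    def fraction(self) -> float:
        return self.counts.ref_fraction


def binom_two_sided(
    k: int, n: int, null_p: float, method: str = "minlike"
) -> float:
    """Exact two-sided binomial p-value for k successes out of n.

    minlike sums P(X = j) over all j whose point probability does not
    exceed that of k (within a small relative slack); doubled returns
    2 * min(P(X <= k), P(X >= k)) capped at 1.  Both run in log space.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValidationError(f"k={k} outside [0, {n}]")
    if not 0.0 < null_p < 1.0:
        raise ValidationError(f"null_p={null_p} outside (0, 1)")
    if method not in ("minlike", "doubled"):
        raise ValueError(f"unknown method {method!r}")

    j = np.arange(n + 1)
    logpmf = binom.logpmf(j, n, null_p)
    if method == "doubled":
        log_lower = logsumexp(logpmf[: k + 1])
        log_upper = logsumexp(logpmf[k:])
        p = 2.0 * float(np.exp(min(log_lower, log_upper)))
        return min(p, 1.0)
    cutoff = logpmf[k] + np.log1p(MINLIKE_REL_SLACK)
    included = logpmf <= cutoff
    p = float(np.exp(logsumexp(logpmf[included])))
    return min(p, 1.0)


def ploidy_null(total_copies: int, ref_copies: int) -> float:
    """Expected reference-read fraction for a heterozygous copy-number state.

    E.g. (2, 1) -> 0.5; (3, 1) -> 1/3 and (3, 2) -> 2/3 for the two
    triploid heterozygotes; (4, 2) -> 0.5 for a balanced tetraploid.
    """
    if total_copies < 2:
        raise ValidationError(f"total_copies must be >= 2, got {total_copies}")
    if not 1 <= ref_copies <= total_copies - 1:
        raise ValidationError(
            f"homozygous configuration ({ref_copies}/{total_copies}): "
            "no imbalance test is defined"
        )
    return float(Fraction(ref_copies, total_copies))


def _direction(k: int, n: int, null_p: float) -> str:
    frac = k / n
    if frac > null_p:
        return "ref-biased"
    if frac < null_p:
        return "alt-biased"
    return "none"


def _test_one(counts: AllelicCounts, null_p: float, method: str) -> ImbalanceTest:
    k, n = counts.ref_count, counts.depth
    return ImbalanceTest(
        counts=counts,
        null_p=null_p,
        pvalue=binom_two_sided(k, n, null_p, method=method),
        direction=_direction(k, n, null_p),
        method=method,
    )


def test_samples(
    samples: list[AllelicCounts], null_p: float, method: str = "minlike"
) -> tuple[list[ImbalanceTest], ImbalanceTest]:
    """Per-sample imbalance tests plus one pooled test on summed counts.

    Zero-depth samples are dropped with a warning and contribute no
    evidence; an all-zero input is an error.  The pooled test treats the
    summed reference count over all informative samples as one binomial
    draw at the same null.
    """
    if not samples:
        raise ValidationError("no samples provided")
    informative = []
    for s in samples:
        if s.depth == 0:
            logger.warning("dropping zero-depth sample %s", s.sample_id)
        else:
            informative.append(s)
    if not informative:
        raise ValidationError("all samples have zero depth")
    per_sample = [_test_one(s, null_p, method) for s in informative]
    pooled_counts = AllelicCounts(
        sample_id="pooled",
        ref_count=sum(s.ref_count for s in informative),
        alt_count=sum(s.alt_count for s in informative),
    )
    pooled = _test_one(pooled_counts, null_p, method)
    return per_sample, pooled


test_samples.__test__ = False  # not a pytest case despite the name


def heterogeneity(samples: list[AllelicCounts]) -> float:
    """Max pairwise difference in per-sample reference fractions (reported,
    not tested)."""
    fracs = [s.ref_fraction for s in samples if s.depth > 0]
    if len(fracs) < 2:
        return 0.0
    return max(fracs) - min(fracs)


def null_sensitivity(
    counts: AllelicCounts, null_ps: list[float], method: str = "minlike"
) -> list[ImbalanceTest]:
    """Re-test the same counts under several null proportions.

    Mirrors the robustness check of testing one imbalance against the
    balanced null and both triploid heterozygous nulls {0.5, 1/3, 2/3}.
    """
    return [_test_one(counts, p0, method) for p0 in null_ps]
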