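"""Recessive-model inference and the per-allele / recessive OR mapping.

Four statistics built on the per-genotype log-OR framework:

* the recessive-model difference test d = beta_AA - beta_AG (one-sided,
  H_a: d > 0), with the shared-baseline covariance between the two log-ORs
  when counts are available;
* a combined-evidence z test that the inverse-variance weighted mean of
  homozygote effects across diseases is zero;
* a genotype-class coefficient of determination quantifying how much of the
  variation among a set of per-genotype ORs is explained by genotype class
  (between-class SS over total SS on the OR scale, baseline excluded) —
  an eta-squared under a one-way variance decomposition;
* the linear attenuation of a purely recessive effect into a per-allele
  (additive) OR: or_N = f_N * (or_NN - 1) + 1, and its inverse.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .association import EffectEstimate
from .counts import GenotypeCountTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecessiveTestResult:
    """One-sided test of d = beta_AA - beta_AG > 0 (risk confined to homozygotes)."""

    d: float
    se_d: float
    z: float
    p_one_sided: float
    cov: float
    cov_source: str  # "counts" | "supplied" | "default_zero"


@dataclass(frozen=True)
class CombinedEvidenceResult:
    """Inverse-variance weighted mean effect across diseases and its z test."""

    beta_bar: float
    se_bar: float
    z: float
    p: float
    weights: tuple[float, ...]
    sidedness: str = "two-sided"


@dataclass(frozen=True)
class ConcordanceResult:
    """Genotype-class eta-squared over a set of per-genotype odds ratios."""

    r2: float
    ss_between: float
    ss_total: float
    n_points: int
    degenerate: bool = False


@dataclass(frozen=True)
class DominanceMapping:
    """A recessive effect (or_NN at frequency f_N) and its per-allele shadow or_N."""

    f_N: float
    or_NN: float
    or_N: float
    or_NX: float = 1.0


def shared_baseline_cov(table: GenotypeCountTable) -> float:
    """Covariance of the two Woolf log-ORs sharing the GG baseline cells."""
    if table.case_counts[0] == 0 or table.control_counts[0] == 0:
        raise ValueError("shared-baseline covariance undefined with empty GG cells")
    return 1 / table.case_counts[0] + 1 / table.control_counts[0]


def recessive_test(
    est_ag: EffectEstimate,
    est_aa: EffectEstimate,
    cov: float | None = None,
    table: GenotypeCountTable | None = None,
) -> RecessiveTestResult:
    """Test whether the homozygote effect exceeds the heterozygote effect.

    var(d) = se_AA^2 + se_AG^2 - 2*cov.  With a count table the covariance is
    the shared-baseline 1/case_GG + 1/control_GG; for summary-only inputs it
    defaults to 0 with a logged warning (conservative when the true
    correlation is positive).
    """
    if table is not None:
        if cov is not None:
            raise ValueError("pass either cov or table, not both")
        cov = shared_baseline_cov(table)
        source = "counts"
    elif cov is not None:
        source = "supplied"
    else:
        cov = 0.0
        source = "default_zero"
        logger.warning(
            "recessive_test: no covariance available for summary-only input; "
            "defaulting cov=0 (conservative for positively correlated log-ORs)"
        )
    d = est_aa.beta - est_ag.beta
    var_d = est_aa.se**2 + est_ag.se**2 - 2 * cov
    if var_d <= 0:
        raise ValueError(f"inconsistent covariance: var(d) = {var_d} <= 0")
    se_d = math.sqrt(var_d)
    z = d / se_d
    return RecessiveTestResult(
        d=d, se_d=se_d, z=z, p_one_sided=float(stats.norm.sf(z)), cov=cov, cov_source=source
    )


def combined_evidence_test(
    estimates: Sequence[EffectEstimate], sidedness: str = "two-sided"
) -> CombinedEvidenceResult:
    """z test that the inverse-variance weighted mean of the effects is zero."""
    if not estimates:
        raise ValueError("need at least one estimate")
    weights = tuple(1.0 / e.se**2 for e in estimates)
    w_sum = sum(weights)
    beta_bar = sum(w * e.beta for w, e in zip(weights, estimates)) / w_sum
    se_bar = 1.0 / math.sqrt(w_sum)
    z = beta_bar / se_bar
    if sidedness == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    elif sidedness == "one-sided":
        p = float(stats.norm.sf(z))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return CombinedEvidenceResult(
        beta_bar=beta_bar, se_bar=se_bar, z=z, p=p, weights=weights, sidedness=sidedness
    )


def genotype_class_r2(
    or_values: Mapping[str, tuple[float, float]]
) -> ConcordanceResult:
    """Fraction of OR variation explained by genotype class, across diseases.

    ``or_values`` maps each disease to its (OR_AG, OR_AA) pair; the baseline
    genotype (OR fixed at 1) is excluded.  The ORs are treated on the OR
    scale as observations grouped by genotype class and R^2 is the
    between-class sum of squares over the total sum of squares about the
    grand mean (a one-way eta-squared).  This convention reproduces the
    headline concordance values computed from published per-genotype ORs.
    """
    if len(or_values) < 2:
        raise ValueError("need at least two diseases")
    ag = [v[0] for v in or_values.values()]
    aa = [v[1] for v in or_values.values()]
    values = ag + aa
    n = len(values)
    grand = sum(values) / n
    ss_total = sum((v - grand) ** 2 for v in values)
    ss_between = 0.0
    for group in (ag, aa):
        mean = sum(group) / len(group)
        ss_between += len(group) * (mean - grand) ** 2
    if ss_total <= 0:
        return ConcordanceResult(r2=1.0, ss_between=0.0, ss_total=0.0, n_points=n, degenerate=True)
    ss_between = min(ss_between, ss_total)  # guard fp overshoot
    return ConcordanceResult(r2=ss_between / ss_total, ss_between=ss_between, ss_total=ss_total, n_points=n)


def per_allele_or(f_N: float, or_NN: float) -> DominanceMapping:
    """Per-allele OR perceived for a purely recessive effect: f_N*(or_NN - 1) + 1.

    Heterozygotes sit at baseline (or_NX = 1); the additive test then sees an
    effect that shrinks linearly as the risk allele gets rarer.
    """
    if not 0 <= f_N <= 1:
        raise ValueError("f_N must lie in [0, 1]")
    if or_NN <= 0:
        raise ValueError("or_NN must be positive")
    return DominanceMapping(f_N=f_N, or_NN=or_NN, or_N=f_N * (or_NN - 1.0) + 1.0)


def recessive_or_from_per_allele(f_N: float, or_N: float) -> float:
    """Invert the per-allele line: or_NN = (or_N - 1)/f_N + 1."""
    if not 0 < f_N <= 1:
        raise ValueError("f_N must lie in (0, 1]")
    or_NN = (or_N - 1.0) / f_N + 1.0
    if or_NN <= 0:
        raise ValueError(f"implied recessive OR {or_NN} is outside the model domain")
    return or_NN
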