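"""Pooling genotype-contrast effects across studies.

Three poolers on the log-OR scale:

* ``iv_fixed`` — inverse-variance fixed effect from summary estimates; the
  package's headline pooling path because every input it needs (OR plus a CI
  or p-value per study) is available from published reports.
* ``mh_fixed`` — Mantel-Haenszel fixed effect straight from per-study 2x2
  counts with the Robins-Breslow-Greenland variance; for count-complete
  collections.
* ``dl_random`` — DerSimonian-Laird random effects (method-of-moments tau^2
  truncated at zero) on summary estimates.

All return heterogeneity statistics (Cochran Q, tau^2, I^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .association import CONTRASTS, EffectEstimate, genotype_odds_ratios
from .counts import GenotypeCountTable

logger = logging.getLogger(__name__)

_CONTRAST_INDEX = {"AG_vs_GG": 1, "AA_vs_GG": 2}


@dataclass(frozen=True)
class StudySummary:
    """A study's per-contrast effect estimates, with its count table if known.

    When counts are present they are authoritative: estimates are recomputed
    from them and any supplied summary disagreeing by more than 1e-6 on beta
    is logged as a warning.
    """

    study_id: str
    estimates: dict[str, EffectEstimate]
    counts: GenotypeCountTable | None = None

    @classmethod
    def from_counts(cls, table: GenotypeCountTable, zero_cell: str = "haldane") -> "StudySummary":
        ag, aa = genotype_odds_ratios(table, zero_cell=zero_cell)
        return cls(study_id=table.study_id, estimates={ag.contrast: ag, aa.contrast: aa}, counts=table)

    @classmethod
    def reconcile(
        cls,
        study_id: str,
        summaries: dict[str, EffectEstimate] | None = None,
        counts: GenotypeCountTable | None = None,
    ) -> "StudySummary":
        """Combine summary rows and counts for one study; counts win."""
        if counts is None:
            if not summaries:
                raise ValueError(f"study {study_id!r}: no summaries and no counts")
            return cls(study_id=study_id, estimates=dict(summaries))
        from_counts = cls.from_counts(counts)
        if summaries:
            for contrast, est in summaries.items():
                ref = from_counts.estimates.get(contrast)
                if ref is not None and abs(ref.beta - est.beta) > 1e-6:
                    logger.warning(
                        "study %s %s: summary beta %.6f disagrees with counts beta %.6f; using counts",
                        study_id, contrast, est.beta, ref.beta,
                    )
        return from_counts


@dataclass(frozen=True)
class MetaResult:
    method: str  # "mh_fixed" | "iv_fixed" | "dl_random"
    pooled: EffectEstimate
    q: float
    df: int
    tau2: float
    i2: float
    p_heterogeneity: float
    per_study_weights: tuple[float, ...]


def _heterogeneity(betas: Sequence[float], weights: Sequence[float], pooled_beta: float):
    q = sum(w * (b - pooled_beta) ** 2 for b, w in zip(betas, weights))
    df = len(betas) - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    p_het = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return q, df, i2, p_het


def iv_fixed(studies: Sequence[EffectEstimate], alpha: float = 0.05) -> MetaResult:
    """Inverse-variance fixed-effect pooled log OR with Q and I^2."""
    if not studies:
        raise ValueError("need at least one estimate")
    contrast = studies[0].contrast
    weights = [1.0 / e.se**2 for e in studies]
    w_sum = sum(weights)
    beta = sum(w * e.beta for w, e in zip(weights, studies)) / w_sum
    se = 1.0 / math.sqrt(w_sum)
    q, df, i2, p_het = _heterogeneity([e.beta for e in studies], weights, beta)
    return MetaResult(
        method="iv_fixed",
        pooled=EffectEstimate.from_beta_se(contrast, beta, se, alpha=alpha),
        q=q, df=df, tau2=0.0, i2=i2, p_heterogeneity=p_het,
        per_study_weights=tuple(weights),
    )


def dl_random(studies: Sequence[EffectEstimate], alpha: float = 0.05) -> MetaResult:
    """DerSimonian-Laird random-effects pooled log OR.

    tau^2 = max(0, (Q - df)/C) with C = sum(w) - sum(w^2)/sum(w) on the
    fixed-effect weights; with tau^2 = 0 the result coincides with iv_fixed.
    """
    if len(studies) < 2:
        raise ValueError("random-effects pooling needs at least two estimates")
    contrast = studies[0].contrast
    w_fixed = [1.0 / e.se**2 for e in studies]
    w_sum = sum(w_fixed)
    beta_fixed = sum(w * e.beta for w, e in zip(w_fixed, studies)) / w_sum
    q, df, _, p_het = _heterogeneity([e.beta for e in studies], w_fixed, beta_fixed)
    c = w_sum - sum(w * w for w in w_fixed) / w_sum
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = [1.0 / (e.se**2 + tau2) for e in studies]
    ws_sum = sum(w_star)
    beta = sum(w * e.beta for w, e in zip(w_star, studies)) / ws_sum
    se = 1.0 / math.sqrt(ws_sum)
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return MetaResult(
        method="dl_random",
        pooled=EffectEstimate.from_beta_se(contrast, beta, se, alpha=alpha),
        q=q, df=df, tau2=tau2, i2=i2, p_heterogeneity=p_het,
        per_study_weights=tuple(w_star),
    )


def mh_fixed(
    studies: Sequence[GenotypeCountTable], contrast: str, alpha: float = 0.05
) -> MetaResult:
    """Mantel-Haenszel pooled OR over per-study 2x2 (risk genotype vs baseline).

    The CI uses the Robins-Breslow-Greenland variance of the pooled log OR.
    Heterogeneity is reported from the per-study Woolf log-ORs (Haldane
    correction on zero cells) weighted inverse-variance about the MH estimate.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    if not studies:
        raise ValueError("need at least one count table")
    g = _CONTRAST_INDEX[contrast]
    r_sum = s_sum = 0.0
    p_r = q_s = pq_rs = 0.0  # RBG accumulators: sum(PR), sum(QS), sum(PS+QR)
    for t in studies:
        a = t.case_counts[g]      # case, risk genotype
        b = t.case_counts[0]      # case, baseline
        c = t.control_counts[g]   # control, risk genotype
        d = t.control_counts[0]   # control, baseline
        n = a + b + c + d
        if n == 0:
            continue
        r = a * d / n
        s = b * c / n
        p = (a + d) / n
        q = (b + c) / n
        r_sum += r
        s_sum += s
        p_r += p * r
        q_s += q * s
        pq_rs += p * s + q * r
    if r_sum == 0 or s_sum == 0:
        raise ValueError("Mantel-Haenszel sums are degenerate (no informative strata)")
    beta = math.log(r_sum / s_sum)
    var = p_r / (2 * r_sum**2) + pq_rs / (2 * r_sum * s_sum) + q_s / (2 * s_sum**2)
    se = math.sqrt(var)
    per_betas = []
    per_weights = []
    for t in studies:
        ag, aa = genotype_odds_ratios(t, zero_cell="haldane")
        est = aa if g == 2 else ag
        per_betas.append(est.beta)
        per_weights.append(1.0 / est.se**2)
    q_stat, df, i2, p_het = _heterogeneity(per_betas, per_weights, beta)
    return MetaResult(
        method="mh_fixed",
        pooled=EffectEstimate.from_beta_se(contrast, beta, se, alpha=alpha),
        q=q_stat, df=df, tau2=0.0, i2=i2, p_heterogeneity=p_het,
        per_study_weights=tuple(per_weights),
    )


def forest_table(studies: Sequence[tuple[str, EffectEstimate]], result: MetaResult):
    """Per-study OR/CI/weight rows plus the pooled row, as a DataFrame (forest-plot data)."""
    import pandas as pd

    w_total = sum(result.per_study_weights)
    rows = []
    for (study_id, est), w in zip(studies, result.per_study_weights):
        rows.append(
            {
                "study_id": study_id,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "weight_pct": 100.0 * w / w_total,
            }
        )
    pooled = result.pooled
    rows.append(
        {
            "study_id": f"pooled ({result.method})",
            "or": pooled.or_,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame.from_records(rows)
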