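"""Per-genotype odds ratios, the exact 2x3 association test, and SE recovery.

Each genotype contrast (AG vs GG, AA vs GG) is a 2x2 subtable against the
baseline homozygote.  Effects are carried on the log-odds-ratio scale with
Woolf standard errors; printed summary statistics (OR with CI, or OR with a
p-value) can be converted back to log-scale estimates so that studies whose
raw counts were never published remain usable as meta-analysis inputs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .counts import GenotypeCountTable

Z975 = 1.959964  # Phi^-1(0.975), fixed so printed CIs round reproducibly

CONTRASTS = ("AG_vs_GG", "AA_vs_GG")
_CONTRAST_INDEX = {"AG_vs_GG": 1, "AA_vs_GG": 2}


@dataclass(frozen=True)
class EffectEstimate:
    """A log odds ratio with its Woolf-scale standard error, CI and Wald p."""

    contrast: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    p_sidedness: str = "two-sided"

    @classmethod
    def from_beta_se(cls, contrast: str, beta: float, se: float, alpha: float = 0.05) -> "EffectEstimate":
        if se <= 0 or not math.isfinite(se):
            raise ValueError(f"standard error must be finite and > 0, got {se}")
        z_crit = float(stats.norm.ppf(1 - alpha / 2)) if alpha != 0.05 else Z975
        z = beta / se

        def _exp(x: float) -> float:
            try:
                return math.exp(x)
            except OverflowError:
                return math.inf

        return cls(
            contrast=contrast,
            beta=beta,
            se=se,
            or_=_exp(beta),
            ci_low=_exp(beta - z_crit * se),
            ci_high=_exp(beta + z_crit * se),
            p=float(2 * stats.norm.sf(abs(z))),
        )


def _contrast_cells(table: GenotypeCountTable, contrast: str) -> tuple[int, int, int, int]:
    g = _CONTRAST_INDEX[contrast]
    return (table.case_counts[g], table.control_counts[g], table.case_counts[0], table.control_counts[0])


def genotype_odds_ratios(
    table: GenotypeCountTable,
    zero_cell: str = "haldane",
    alpha: float = 0.05,
) -> tuple[EffectEstimate, EffectEstimate]:
    """Odds ratios for AG vs GG and AA vs GG with Woolf SEs and Wald p-values.

    For contrast g: beta = ln[(case_g * control_GG) / (control_g * case_GG)],
    se = sqrt(sum of reciprocal cells).  ``zero_cell="haldane"`` adds 0.5 to
    all four cells of a contrast whose 2x2 contains a zero (Haldane-Anscombe);
    ``"none"`` raises instead.
    """
    if zero_cell not in ("haldane", "none"):
        raise ValueError(f"unknown zero-cell policy {zero_cell!r}")
    out = []
    for contrast in CONTRASTS:
        cells = _contrast_cells(table, contrast)
        a, b, c, d = (float(x) for x in cells)
        if min(cells) == 0:
            if zero_cell == "none":
                raise ValueError(
                    f"{table.study_id}: zero cell in {contrast} 2x2 with zero-cell policy 'none'"
                )
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        beta = math.log(a * d) - math.log(b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        out.append(EffectEstimate.from_beta_se(contrast, beta, se, alpha=alpha))
    return out[0], out[1]


def fisher_exact_2x3(
    table: GenotypeCountTable,
    max_cells: int = 20_000_000,
    tie_rel_tol: float = 1e-7,
    monte_carlo: bool = False,
    n_mc: int = 200_000,
    seed: int | None = None,
) -> float:
    """Two-sided Fisher exact p for the 2x3 case-control genotype table.

    Enumerates the 2-df lattice of tables sharing the observed margins; the
    p-value sums the multivariate-hypergeometric probabilities of all tables
    no more probable than the observed one (ties within ``tie_rel_tol``
    relative).  When the margin lattice exceeds ``max_cells`` an error is
    raised advising the ``monte_carlo`` fallback, which estimates the same
    tail by sampling tables from the null.
    """
    case = table.case_counts
    cols = tuple(c + d for c, d in zip(case, table.control_counts))
    n1 = sum(case)
    n = n1 + sum(table.control_counts)
    if n == 0 or n1 == 0 or n1 == n or min(cols) < 0 or any(c == 0 for c in (n1, n - n1)):
        raise ValueError("all margins must be positive")

    lgam = math.lgamma

    def log_choose(m: int, k: int) -> float:
        return lgam(m + 1) - lgam(k + 1) - lgam(m - k + 1)

    denom = log_choose(n, n1)

    def log_prob(a0: int, a1: int, a2: int) -> float:
        return log_choose(cols[0], a0) + log_choose(cols[1], a1) + log_choose(cols[2], a2) - denom

    lp_obs = log_prob(*case)

    if monte_carlo:
        rng = np.random.default_rng(seed)
        # sample case rows from the null: draw n1 individuals without
        # replacement from the genotype margins
        draws = rng.multivariate_hypergeometric(cols, n1, size=n_mc)
        lp = np.array([log_prob(*d) for d in draws])
        return float(np.mean(lp <= lp_obs + math.log1p(tie_rel_tol)))

    a1_max = min(cols[1], n1)
    a2_max = min(cols[2], n1)
    if (a1_max + 1) * (a2_max + 1) > max_cells:
        raise ValueError(
            "margin lattice too large for full enumeration; pass monte_carlo=True"
        )
    thresh = lp_obs + math.log1p(tie_rel_tol)
    total = 0.0
    for a1 in range(a1_max + 1):
        rem = n1 - a1
        lo = max(0, rem - cols[0])
        hi = min(a2_max, rem)
        for a2 in range(lo, hi + 1):
            lp = log_prob(n1 - a1 - a2, a1, a2)
            if lp <= thresh:
                total += math.exp(lp)
    return min(1.0, total)


def se_from_ci(or_: float, ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Recover the log-OR standard error from a symmetric-on-log-scale CI."""
    if min(or_, ci_low, ci_high) <= 0:
        raise ValueError("odds ratio and CI bounds must be positive")
    if not ci_low < ci_high:
        raise ValueError("ci_low must be below ci_high")
    z = float(stats.norm.ppf(0.5 + level / 2)) if level != 0.95 else Z975
    return (math.log(ci_high) - math.log(ci_low)) / (2 * z)


def se_from_pvalue(or_: float, p: float, sidedness: str = "two-sided") -> float:
    """Recover the log-OR standard error from a printed OR and Wald p-value."""
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    if or_ == 1.0:
        raise ValueError("cannot recover an SE from OR = 1 (z = 0)")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    if sidedness == "two-sided":
        z = float(stats.norm.isf(p / 2))
    elif sidedness == "one-sided":
        z = float(stats.norm.isf(p))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if z <= 0:
        raise ValueError(f"p = {p} gives a non-positive z quantile")
    return abs(math.log(or_)) / z


_SUMMARY_HEADER = ["study_id", "contrast", "or", "ci_low", "ci_high", "p"]


def read_summary_studies(path: str | Path) -> dict[str, dict[str, EffectEstimate]]:
    """Read a summary-study TSV into {study_id: {contrast: EffectEstimate}}.

    Each row gives an OR with a CI and/or a p-value; the SE is recovered from
    the CI when present, else from the p-value.
    """
    path = Path(path)
    out: dict[str, dict[str, EffectEstimate]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header] != _SUMMARY_HEADER:
            raise ValueError(f"{path}: bad header, expected {_SUMMARY_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            study_id, contrast = row[0].strip(), row[1].strip()
            if contrast not in CONTRASTS:
                raise ValueError(f"{path}:{lineno}: unknown contrast {contrast!r}")
            or_ = float(row[2])
            ci_low = float(row[3]) if row[3].strip() else None
            ci_high = float(row[4]) if row[4].strip() else None
            p = float(row[5]) if len(row) > 5 and row[5].strip() else None
            if ci_low is not None and ci_high is not None:
                se = se_from_ci(or_, ci_low, ci_high)
            elif p is not None:
                se = se_from_pvalue(or_, p)
            else:
                raise ValueError(f"{path}:{lineno}: need a CI or a p-value")
            out.setdefault(study_id, {})[contrast] = EffectEstimate.from_beta_se(
                contrast, math.log(or_), se
            )
    return out
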