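"""Genotype count tables: data model, TSV I/O and descriptive statistics.

The unit of data throughout the package is the aggregated 2 x 3 case-control
genotype count table for a biallelic autosomal SNP.  Genotype order is fixed
everywhere as (GG, AG, AA) = (baseline homozygote, heterozygote, risk
homozygote); files and APIs all use this order, which removes any
strand/allele-order ambiguity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

GENOTYPE_ORDER = ("GG", "AG", "AA")
_COUNTS_HEADER = ["study_id", "group", "gg", "ag", "aa"]


@dataclass(frozen=True)
class GenotypeCountTable:
    """One study's case/control genotype counts, ordered (GG, AG, AA)."""

    study_id: str
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]
    risk_allele: str = "A"
    baseline_genotype: str = "GG"

    def __post_init__(self) -> None:
        for name in ("case_counts", "control_counts"):
            counts = getattr(self, name)
            if len(counts) != 3:
                raise ValueError(f"{name} must have exactly 3 entries (GG, AG, AA)")
            for c in counts:
                if not isinstance(c, (int,)) or isinstance(c, bool):
                    raise TypeError(f"{name} must be integers, got {c!r}")
                if c < 0:
                    raise ValueError(f"{name} must be nonnegative, got {c}")
            object.__setattr__(self, name, tuple(int(c) for c in counts))
        if self.baseline_genotype != "GG":
            raise ValueError("baseline genotype is fixed at GG")

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)

    def with_study_id(self, study_id: str) -> "GenotypeCountTable":
        return replace(self, study_id=study_id)


@dataclass(frozen=True)
class HweResult:
    """Pearson goodness-of-fit of genotype counts to Hardy-Weinberg proportions."""

    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p: float
    method: str = "chi2"


def allele_frequency(counts: Sequence[int]) -> float:
    """Risk-allele frequency (2*n_AA + n_AG) / (2*N) for counts (GG, AG, AA)."""
    n = sum(counts)
    if n <= 0:
        raise ValueError("allele frequency undefined for all-zero counts")
    return (2 * counts[2] + counts[1]) / (2 * n)


def genotype_proportions(counts: Sequence[int]) -> tuple[float, float, float]:
    """Genotype proportions (GG, AG, AA), counts normalised by their sum."""
    n = sum(counts)
    if n <= 0:
        raise ValueError("genotype proportions undefined for all-zero counts")
    return tuple(c / n for c in counts)  # type: ignore[return-value]


def hwe_test(counts: Sequence[int], method: str = "chi2") -> HweResult:
    """Test genotype counts (GG, AG, AA) against Hardy-Weinberg proportions.

    ``method="chi2"`` (default) is the 1-df Pearson chi-square against
    expected counts N*(1-f)^2, N*2f(1-f), N*f^2 at the observed allele
    frequency f, with no continuity correction.  ``method="midp"`` keeps the
    Pearson statistic but replaces the p-value with the exact mid-p obtained
    by enumerating heterozygote counts conditional on the observed allele
    counts (Wigginton-style); the exact test is preferable for sparse tables.
    """
    obs = tuple(int(c) for c in counts)
    n = sum(obs)
    f = allele_frequency(obs)
    expected = (n * (1 - f) ** 2, n * 2 * f * (1 - f), n * f * f)
    chi2 = 0.0
    for o, e in zip(obs, expected):
        if e < 1e-12:
            if o:
                raise ValueError("degenerate allele frequency: expected cell ~0 with nonzero observed")
            continue
        chi2 += (o - e) ** 2 / e
    if method == "chi2":
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "midp":
        p = _hwe_exact_midp(obs)
    else:
        raise ValueError(f"unknown HWE method {method!r}")
    return HweResult(observed=obs, expected=expected, chi2=chi2, df=1, p=p, method=method)


def _hwe_exact_midp(obs: tuple[int, int, int]) -> float:
    """Exact HWE mid-p by enumeration over heterozygote counts.

    Conditions on the observed minor-allele count; the null probability of
    n_het heterozygotes is the standard conditional HWE distribution.  Mid-p
    sums probabilities strictly below that of the observed table plus half
    the tied probability.
    """
    import math

    n = sum(obs)
    n_a = 2 * obs[2] + obs[1]  # risk-allele count
    n_minor = min(n_a, 2 * n - n_a)
    het_obs = obs[1]
    hets = range(n_minor % 2, n_minor + 1, 2)
    logps = {}
    for h in hets:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        logps[h] = (
            h * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(hom_major + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_minor + 1)
        )
    mx = max(logps.values())
    total = sum(math.exp(v - mx) for v in logps.values())
    probs = {h: math.exp(v - mx) / total for h, v in logps.items()}
    p_obs = probs[het_obs]
    p = sum(q for q in probs.values() if q < p_obs * (1 - 1e-12)) + 0.5 * sum(
        q for q in probs.values() if abs(q - p_obs) <= p_obs * 1e-12
    )
    return min(1.0, p)


def read_count_tables(path: str | Path) -> list[GenotypeCountTable]:
    """Read a counts TSV (study_id, group, gg, ag, aa) into one table per study.

    Each study needs exactly one ``case`` and one ``control`` row; rows may
    appear in any order.  Studies are returned in first-appearance order.
    """
    path = Path(path)
    rows: dict[str, dict[str, tuple[int, int, int]]] = {}
    order: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header {_COUNTS_HEADER}")
        if [h.strip().lower() for h in header] != _COUNTS_HEADER:
            raise ValueError(f"{path}: bad header {header!r}, expected {_COUNTS_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            study_id, group = row[0].strip(), row[1].strip().lower()
            if group not in ("case", "control"):
                raise ValueError(f"{path}:{lineno}: group must be case/control, got {group!r}")
            try:
                counts = tuple(int(c) for c in row[2:5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count ({exc})") from None
            if any(c < 0 for c in counts):
                raise ValueError(f"{path}:{lineno}: negative count")
            if study_id not in rows:
                rows[study_id] = {}
                order.append(study_id)
            if group in rows[study_id]:
                raise ValueError(f"{path}: duplicate {group} row for study {study_id!r}")
            rows[study_id][group] = counts  # type: ignore[assignment]
    tables = []
    for study_id in order:
        groups = rows[study_id]
        for need in ("case", "control"):
            if need not in groups:
                raise ValueError(f"{path}: study {study_id!r} is missing its {need} row")
        tables.append(
            GenotypeCountTable(
                study_id=study_id,
                case_counts=groups["case"],
                control_counts=groups["control"],
            )
        )
    return tables


def write_count_tables(tables: Iterable[GenotypeCountTable], path: str | Path) -> None:
    """Write tables in the same TSV dialect that :func:`read_count_tables` reads."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COUNTS_HEADER)
        for t in tables:
            writer.writerow([t.study_id, "case", *t.case_counts])
            writer.writerow([t.study_id, "control", *t.control_counts])


def describe_tables(tables: Iterable[GenotypeCountTable], hwe_method: str = "chi2"):
    """Descriptive statistics per study and group as a pandas DataFrame.

    Columns: study_id, group, n, freq_risk_allele, prop_gg, prop_ag, prop_aa,
    hwe_chi2, hwe_p.
    """
    import pandas as pd

    records = []
    for t in tables:
        for group, counts in (("case", t.case_counts), ("control", t.control_counts)):
            props = genotype_proportions(counts)
            hwe = hwe_test(counts, method=hwe_method)
            records.append(
                {
                    "study_id": t.study_id,
                    "group": group,
                    "n": sum(counts),
                    "freq_risk_allele": allele_frequency(counts),
                    "prop_gg": props[0],
                    "prop_ag": props[1],
                    "prop_aa": props[2],
                    "hwe_chi2": hwe.chi2,
                    "hwe_p": hwe.p,
                }
            )
    return pd.DataFrame.from_records(records)
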