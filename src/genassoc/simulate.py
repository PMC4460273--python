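"""Synthetic case-control genotype data with the structure the analysis assumes.

Controls are drawn from a reference genotype distribution — either
Hardy-Weinberg proportions at a given risk-allele frequency, or the observed
proportions of a real control sample.  Case genotype probabilities are the
control probabilities tilted by specified per-genotype odds ratios and
renormalised:

    case_probs  propto  (p_GG, p_AG * OR_AG, p_AA * OR_AA)

which is the exact case genotype distribution implied by those ORs against
the GG baseline.  Sampling a study of n cases and m controls is a pair of
independent trinomial draws — distributionally identical to allocating a
genotype to each simulated individual, but vectorizable.

Reproducibility: every sampler takes a seed (or a numpy Generator); study
collections derive child seeds from the master seed via numpy's
SeedSequence spawning, so results are independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .counts import GenotypeCountTable, genotype_proportions


@dataclass(frozen=True)
class PopulationModel:
    """Control genotype distribution plus alternative-hypothesis ORs."""

    control_probs: tuple[float, float, float]
    or_ag: float
    or_aa: float
    label: str = ""

    def __post_init__(self) -> None:
        p = self.control_probs
        if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("control_probs must be 3 nonnegative reals summing to 1")
        if self.or_ag <= 0 or self.or_aa <= 0:
            raise ValueError("odds ratios must be positive")
        object.__setattr__(self, "control_probs", tuple(float(x) for x in p))

    @property
    def case_probs(self) -> tuple[float, float, float]:
        p = self.control_probs
        raw = (p[0], p[1] * self.or_ag, p[2] * self.or_aa)
        total = sum(raw)
        return tuple(x / total for x in raw)  # type: ignore[return-value]


def model_from_frequency(f: float, or_ag: float, or_aa: float, label: str = "") -> PopulationModel:
    """Population model with HWE controls at risk-allele frequency f."""
    if not 0 < f < 1:
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    probs = ((1 - f) ** 2, 2 * f * (1 - f), f * f)
    return PopulationModel(control_probs=probs, or_ag=or_ag, or_aa=or_aa, label=label)


def model_from_control_table(
    table: GenotypeCountTable, or_ag: float, or_aa: float, label: str | None = None
) -> PopulationModel:
    """Population model using a study's observed control proportions (no HWE smoothing)."""
    probs = genotype_proportions(table.control_counts)
    return PopulationModel(
        control_probs=probs,
        or_ag=or_ag,
        or_aa=or_aa,
        label=label if label is not None else table.study_id,
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_study(
    model: PopulationModel,
    n_cases: int,
    n_controls: int,
    seed,
    study_id: str = "sim",
) -> GenotypeCountTable:
    """Draw one synthetic study: independent trinomials for cases and controls."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("sample sizes must be positive")
    rng = _as_rng(seed)
    case = rng.multinomial(n_cases, model.case_probs)
    control = rng.multinomial(n_controls, model.control_probs)
    return GenotypeCountTable(
        study_id=study_id,
        case_counts=tuple(int(x) for x in case),
        control_counts=tuple(int(x) for x in control),
    )


def generate_study_collection(
    model: PopulationModel,
    k: int,
    sizes: Sequence[tuple[int, int]],
    seed: int,
) -> list[GenotypeCountTable]:
    """k independent studies from one model, with per-study child seeds.

    Child generators are spawned from ``SeedSequence(seed)`` so each study's
    stream is fixed by (seed, index) alone.
    """
    if k != len(sizes):
        raise ValueError(f"k = {k} but {len(sizes)} size pairs supplied")
    if k == 0:
        return []
    children = np.random.SeedSequence(seed).spawn(k)
    return [
        sample_study(
            model,
            n_cases,
            n_controls,
            np.random.default_rng(child),
            study_id=f"sim_{i:03d}",
        )
        for i, ((n_cases, n_controls), child) in enumerate(zip(sizes, children))
    ]
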