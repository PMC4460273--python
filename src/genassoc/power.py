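"""Monte-Carlo power for the recessive (AA vs GG) case-control z test.

Each iteration draws a synthetic study from a :class:`PopulationModel`,
computes the log OR of AA vs GG with its Woolf standard error (Haldane
correction when any of the four cells is zero — discarding such iterations
would bias power upward at small sample sizes), and declares success when
|log OR| / SE exceeds the two-tailed normal critical value.  Power is the
success fraction; a closed-form normal approximation at the expected cell
counts serves as an independent analytic oracle and seeds the sample-size
search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .simulate import PopulationModel, _as_rng


@dataclass(frozen=True)
class PowerSpec:
    """A single power-simulation design."""

    model: PopulationModel
    n_cases: int
    n_controls: int
    alpha: float = 0.05
    reps: int = 10_000
    seed: int = 0
    test: str = "z_logor_aa"

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.test != "z_logor_aa":
            raise ValueError(f"unknown test {self.test!r}")


@dataclass(frozen=True)
class PowerResult:
    power: float
    mc_se: float
    reps_used: int
    n_degenerate: int

    @classmethod
    def from_successes(cls, successes: int, reps: int, n_degenerate: int) -> "PowerResult":
        power = successes / reps
        return cls(
            power=power,
            mc_se=math.sqrt(power * (1 - power) / reps),
            reps_used=reps,
            n_degenerate=n_degenerate,
        )


def _simulated_beta_se(
    model: PopulationModel, n_cases: int, n_controls: int, reps: int, rng: np.random.Generator
):
    """Vectorized per-iteration (beta_AA, se_AA, any-zero-cell) over reps draws."""
    case = rng.multinomial(n_cases, model.case_probs, size=reps).astype(float)
    ctrl = rng.multinomial(n_controls, model.control_probs, size=reps).astype(float)
    cells = np.stack([case[:, 2], ctrl[:, 2], case[:, 0], ctrl[:, 0]], axis=1)
    degenerate = (cells == 0).any(axis=1)
    cells[degenerate] += 0.5  # Haldane-Anscombe on the affected 2x2
    a, b, c, d = cells.T
    beta = np.log(a * d) - np.log(b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return beta, se, degenerate


def _check_model(model: PopulationModel) -> None:
    if model.case_probs[2] == 0 and model.control_probs[2] == 0:
        raise ValueError("AA probability is zero in both groups; the AA-vs-GG test is undefined")


def power_single(spec: PowerSpec) -> PowerResult:
    """Monte-Carlo power of one study for the two-tailed z test on log OR_AA."""
    _check_model(spec.model)
    rng = _as_rng(spec.seed)
    z_crit = stats.norm.isf(spec.alpha / 2)
    beta, se, degenerate = _simulated_beta_se(
        spec.model, spec.n_cases, spec.n_controls, spec.reps, rng
    )
    successes = int(np.count_nonzero(np.abs(beta / se) > z_crit))
    return PowerResult.from_successes(successes, spec.reps, int(degenerate.sum()))


def power_meta(spec_a: PowerSpec, spec_b: PowerSpec) -> PowerResult:
    """Power of a two-study fixed-effect meta-analysis, both studies simulated per iteration.

    The per-iteration pooled statistic is the inverse-variance weighted mean
    of the two log ORs divided by its standard error — the z test on the
    weighted normal, equivalent to a fixed-effect meta-analysis.
    """
    if spec_a.model is not spec_b.model and spec_a.model != spec_b.model:
        raise ValueError("both specs must share one population model")
    if spec_a.alpha != spec_b.alpha or spec_a.reps != spec_b.reps:
        raise ValueError("both specs must share alpha and reps")
    _check_model(spec_a.model)
    rng = _as_rng(spec_a.seed)
    z_crit = stats.norm.isf(spec_a.alpha / 2)
    beta1, se1, deg1 = _simulated_beta_se(
        spec_a.model, spec_a.n_cases, spec_a.n_controls, spec_a.reps, rng
    )
    beta2, se2, deg2 = _simulated_beta_se(
        spec_b.model, spec_b.n_cases, spec_b.n_controls, spec_b.reps, rng
    )
    w1, w2 = 1 / se1**2, 1 / se2**2
    pooled = (w1 * beta1 + w2 * beta2) / (w1 + w2)
    pooled_se = 1 / np.sqrt(w1 + w2)
    successes = int(np.count_nonzero(np.abs(pooled / pooled_se) > z_crit))
    return PowerResult.from_successes(successes, spec_a.reps, int((deg1 | deg2).sum()))


def power_analytic(spec: PowerSpec) -> float:
    """Closed-form normal approximation to the simulated power.

    Power ~ Phi(|beta| / se_exp - z_crit) with beta = ln(OR_AA) and se_exp
    the Woolf SE evaluated at the expected cell counts.  The opposite tail is
    ignored, so at OR_AA = 1 this returns alpha/2, not alpha.
    """
    model = spec.model
    cells = (
        spec.n_cases * model.case_probs[2],
        spec.n_controls * model.control_probs[2],
        spec.n_cases * model.case_probs[0],
        spec.n_controls * model.control_probs[0],
    )
    if min(cells) < 1:
        raise ValueError("expected AA and GG cells must be >= 1 in both groups")
    beta = abs(math.log(model.or_aa))
    se = math.sqrt(sum(1 / c for c in cells))
    z_crit = float(stats.norm.isf(spec.alpha / 2))
    return float(stats.norm.cdf(beta / se - z_crit))


def _analytic_required_cases(
    model: PopulationModel, n_controls: int, target_power: float, alpha: float
) -> float:
    """Invert the analytic power formula for n_cases (real-valued)."""
    beta = abs(math.log(model.or_aa))
    if beta == 0:
        raise ValueError("no effect under the alternative; target power unattainable")
    z_crit = float(stats.norm.isf(alpha / 2))
    z_pow = float(stats.norm.ppf(target_power))
    if z_crit + z_pow <= 0:
        return 1.0  # target below the test's one-tail size: any n suffices
    se_needed = beta / (z_crit + z_pow)
    control_var = (1 / model.control_probs[2] + 1 / model.control_probs[0]) / n_controls
    case_var = se_needed**2 - control_var
    if case_var <= 0:
        raise ValueError(
            "target power unattainable with this control sample: the control-side "
            f"variance floor caps power below {target_power}"
        )
    return (1 / model.case_probs[2] + 1 / model.case_probs[0]) / case_var


def required_cases(
    model: PopulationModel,
    n_controls: int,
    target_power: float,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int = 0,
) -> int:
    """Smallest n_cases whose simulated power reaches the target.

    The analytic inversion provides an initial bracket; bisection then runs
    on the Monte-Carlo power curve evaluated with common random numbers (the
    same seed at every candidate n, so the curve is monotone up to the shared
    noise).  Deterministic given the seed.
    """
    _check_model(model)
    if not 0 < target_power < 1:
        raise ValueError("target power must lie in (0, 1)")

    def mc_power(n_cases: int) -> float:
        spec = PowerSpec(
            model=model, n_cases=n_cases, n_controls=n_controls,
            alpha=alpha, reps=reps, seed=seed,
        )
        return power_single(spec).power

    n0 = _analytic_required_cases(model, n_controls, target_power, alpha)
    hi = max(2, int(math.ceil(n0 * 1.5)))
    # grow the upper bracket until the simulated power clears the target
    while mc_power(hi) < target_power:
        hi *= 2
        if hi > 10_000_000:
            raise ValueError("target power not reached at 10M cases; check the model")
    # shrink the lower bracket until the simulated power falls below it
    lo = min(hi - 1, max(1, int(n0 / 2)))
    while lo >= 1 and mc_power(lo) >= target_power:
        hi = lo
        lo //= 2
    if lo == 0:
        return 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if mc_power(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def null_spec(spec: PowerSpec) -> PowerSpec:
    """The same design with both ORs set to 1 (type-I-error configuration)."""
    null_model = replace(spec.model, or_ag=1.0, or_aa=1.0)
    return replace(spec, model=null_model)
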