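"""Monte-Carlo power analysis for fragment × section sampling designs.

Given the fitted variance components (fragment 0.116, section 0.993 on the
log10 scale by default), the engine answers the design question: how many
cortical fragments per treatment group, and how many analyzed sections per
fragment, are needed to detect a p% change in follicular density?  Each
replicate simulates a balanced two-group experiment from the hierarchical
model, tests the treatment effect at level alpha, and the power is the
rejection fraction over ``n_sims`` replicates, with a binomial confidence
interval.

For the default balanced design with no ewe/ovary covariates the REML
mixed-model F-test of treatment (containment df) is algebraically identical
to the two-sample t-test on fragment means, so the engine uses that exact
reduction per replicate (``analysis="exact"``); ``analysis="reml"`` refits
the full mixed model each time.  A closed-form noncentral-t oracle
(:func:`analytic_power`) gives the exact power of the same test; the
normal-theory approximation is available as ``method="normal"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ParameterError, PowerRunError
from .mixedmodel import ModelSpec, fit_mixed_model, test_fixed_effect
from .simulate import HierarchyParams, generate_density_table

__all__ = [
    "DesignSpec",
    "PowerResult",
    "effect_delta",
    "simulate_experiment",
    "run_power",
    "analytic_power",
    "power_grid",
    "reference_grid",
    "recommend_design",
]

PARAMETERIZATIONS = ("multiplicative_log10", "absolute_shift")


def effect_delta(effect_pct: float, parameterization: str = "multiplicative_log10") -> float:
    """Map a percent density modification to a shift on the log10 scale.

    ``multiplicative_log10``: a p% change multiplies density by (1 + p/100),
    i.e. an additive log10(1 + p/100) shift of the transformed response.
    ``absolute_shift``: p/100 is taken directly as the shift in log10 units.
    """
    if parameterization not in PARAMETERIZATIONS:
        raise ParameterError(f"unknown parameterization '{parameterization}'")
    if effect_pct <= -100.0:
        raise ParameterError("effect_pct must exceed -100")
    if parameterization == "multiplicative_log10":
        return math.log10(1.0 + effect_pct / 100.0)
    return effect_pct / 100.0


@dataclass(frozen=True)
class DesignSpec:
    """One experimental design point for the power analysis."""

    n_fragments: int = 10
    n_sections: int = 20
    effect_pct: float = 25.0
    n_groups: int = 2
    effect_parameterization: str = "multiplicative_log10"
    raw_delta: float | None = None  # direct log10 shift, overrides effect_pct
    alpha: float = 0.05
    n_sims: int = 2000
    seed: int = 0
    sigma2_fragment: float = 0.116
    sigma2_section: float = 0.993
    mu: float = 0.56

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ParameterError("n_groups must be >= 2")
        if self.n_fragments < 2:
            raise ParameterError("n_fragments must be >= 2 per group")
        if self.n_sections < 1:
            raise ParameterError("n_sections must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0, 1)")
        if self.n_sims < 1:
            raise ParameterError("n_sims must be >= 1")
        if self.sigma2_fragment < 0 or self.sigma2_section < 0:
            raise ParameterError("variance components must be >= 0")
        if self.raw_delta is None:
            effect_delta(self.effect_pct, self.effect_parameterization)  # validate

    @property
    def delta(self) -> float:
        """Treatment shift on the log10 scale."""
        if self.raw_delta is not None:
            return self.raw_delta
        return effect_delta(self.effect_pct, self.effect_parameterization)


@dataclass(frozen=True)
class PowerResult:
    """Estimated detection probability for one design."""

    design: DesignSpec
    power: float
    ci_low: float
    ci_high: float
    n_sims_completed: int
    n_failures: int = 0
    analysis: str = "exact"

    def __post_init__(self) -> None:
        assert 0.0 <= self.ci_low <= self.power <= self.ci_high <= 1.0

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error sqrt(p(1-p)/n)."""
        n = max(self.n_sims_completed, 1)
        return math.sqrt(self.power * (1.0 - self.power) / n)


def _rep_seed(master_seed: int, rep_index: int) -> int:
    """Counter-based replicate seed: SeedSequence over (master, index)."""
    return int(np.random.SeedSequence((master_seed, rep_index)).generate_state(1)[0])


def simulate_experiment(design: DesignSpec, rep_seed: int) -> pd.DataFrame:
    """One simulated experiment table: n_groups × n_fragments × n_sections rows."""
    params = HierarchyParams(
        n_ewes=1,
        ovaries_per_ewe=1,
        fragments_per_ovary=design.n_groups * design.n_fragments,
        sections_per_fragment=design.n_sections,
        mu=design.mu,
        sigma2_fragment=design.sigma2_fragment,
        sigma2_section=design.sigma2_section,
        seed=rep_seed,
    )
    labels = tuple(
        ["control"] + [f"treated{i}" if i > 1 else "treated" for i in range(1, design.n_groups)]
    )
    return generate_density_table(
        params, treatment_delta=design.delta, n_groups=design.n_groups, group_labels=labels
    )


def _treatment_pvalue_exact(table: pd.DataFrame) -> float:
    """Exact between-fragment test of treatment on a balanced table.

    Fragment means are iid N(group mean, s2f + s2s/S) within each group, so
    the treatment test reduces to a two-sample t (or one-way F) on the
    fragment means — the balanced-case mixed-model F-test in closed form.
    """
    means = table.groupby(["group", "fragment_id"], sort=False)["y"].mean()
    groups = [means.xs(g).to_numpy() for g in means.index.get_level_values(0).unique()]
    if len(groups) == 2:
        return float(stats.ttest_ind(groups[0], groups[1], equal_var=True).pvalue)
    return float(stats.f_oneway(*groups).pvalue)


def _treatment_pvalue_reml(table: pd.DataFrame) -> float:
    spec = ModelSpec(fixed_factors=("group",), nesting={"fragment_id": ("group",)})
    fit = fit_mixed_model(table, spec)
    return test_fixed_effect(fit, "group")


def run_power(design: DesignSpec, analysis: str = "exact") -> PowerResult:
    """Monte-Carlo power of the treatment test for one design.

    Each replicate simulates an experiment and tests the treatment effect at
    ``design.alpha``; replicates whose analysis fails are excluded and
    counted, and more than 10% failures aborts the run.
    """
    if analysis not in ("exact", "reml"):
        raise ParameterError(f"unknown analysis '{analysis}'")
    pfun = _treatment_pvalue_exact if analysis == "exact" else _treatment_pvalue_reml
    rejections = 0
    failures = 0
    for rep in range(design.n_sims):
        table = simulate_experiment(design, _rep_seed(design.seed, rep))
        try:
            p = pfun(table)
        except Exception:
            p = float("nan")
        if not np.isfinite(p):
            failures += 1
            continue
        if p < design.alpha:
            rejections += 1
    completed = design.n_sims - failures
    if failures > 0.1 * design.n_sims or completed == 0:
        raise PowerRunError(
            f"{failures}/{design.n_sims} replicate analyses failed; "
            "design numerically unstable"
        )
    power = rejections / completed
    lo, hi = proportion_confint(rejections, completed, alpha=0.05, method="wilson")
    return PowerResult(
        design=design,
        power=power,
        ci_low=min(float(lo), power),
        ci_high=max(float(hi), power),
        n_sims_completed=completed,
        n_failures=failures,
        analysis=analysis,
    )


def analytic_power(design: DesignSpec, method: str = "exact") -> float:
    """Closed-form power of the two-group treatment test.

    The group-mean contrast has variance 2V with
    V = s2f/F + s2s/(F·S).  ``method="exact"`` uses the noncentral-t
    distribution of the between-fragment t statistic with 2(F−1) degrees of
    freedom (the distribution the Monte-Carlo engine's test actually has);
    ``method="normal"`` uses the normal-theory approximation
    power = Phi(z − z_{1−a/2}) + Phi(−z − z_{1−a/2}) with z = |delta|/sqrt(2V).
    """
    if design.n_groups != 2:
        raise ParameterError("analytic power implemented for two groups")
    if method not in ("exact", "normal"):
        raise ParameterError(f"unknown method '{method}'")
    delta = abs(design.delta)
    V = design.sigma2_fragment / design.n_fragments + design.sigma2_section / (
        design.n_fragments * design.n_sections
    )
    if V == 0.0:
        if delta == 0.0:
            raise ParameterError("zero variance and zero effect: power undefined")
        return 1.0
    z = delta / math.sqrt(2.0 * V)
    if method == "normal":
        zcrit = stats.norm.ppf(1.0 - design.alpha / 2.0)
        return float(stats.norm.cdf(z - zcrit) + stats.norm.cdf(-z - zcrit))
    df = 2 * (design.n_fragments - 1)
    tcrit = stats.t.ppf(1.0 - design.alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, z) + stats.nct.cdf(-tcrit, df, z))


def _derived_seed(master_seed: int, design: DesignSpec) -> int:
    key = (master_seed, int(round(100 * design.effect_pct)), design.n_fragments, design.n_sections)
    return int(np.random.SeedSequence(key).generate_state(1)[0])


def power_grid(
    designs: Iterable[DesignSpec],
    master_seed: int | None = None,
    analysis: str = "exact",
) -> list[PowerResult]:
    """Power for a list of designs, sorted Table-3 style.

    Rows are ordered by (effect desc, fragments desc, sections desc).  With
    ``master_seed`` each design gets an independent seed derived from
    (master, effect, fragments, sections), so any row can be reproduced in
    isolation regardless of grid composition.
    """
    designs = list(designs)
    if not designs:
        raise ParameterError("empty design grid")
    if master_seed is not None:
        designs = [replace(d, seed=_derived_seed(master_seed, d)) for d in designs]
    designs.sort(key=lambda d: (-d.effect_pct, -d.n_fragments, -d.n_sections))
    return [run_power(d, analysis=analysis) for d in designs]


def grid_frame(results: Sequence[PowerResult]) -> pd.DataFrame:
    """Tabulate PowerResults with powers and CIs in percent."""
    return pd.DataFrame(
        {
            "effect_pct": [r.design.effect_pct for r in results],
            "n_fragments": [r.design.n_fragments for r in results],
            "n_sections": [r.design.n_sections for r in results],
            "power_pct": [100.0 * r.power for r in results],
            "ci_low_pct": [100.0 * r.ci_low for r in results],
            "ci_high_pct": [100.0 * r.ci_high for r in results],
            "n_sims": [r.n_sims_completed for r in results],
        }
    )


def reference_grid(
    effects: Sequence[float] = (50.0, 25.0, 10.0),
    fragments: Sequence[int] = (20, 10, 5),
    sections: Sequence[int] = (40, 20, 10),
    n_sims: int = 2000,
    **kwargs,
) -> list[DesignSpec]:
    """The study's 3 × 3 × 3 design grid (effects × fragments × sections)."""
    return [
        DesignSpec(n_fragments=f, n_sections=s, effect_pct=e, n_sims=n_sims, **kwargs)
        for e in effects
        for f in fragments
        for s in sections
    ]


def recommend_design(
    target_power: float,
    effect_pct: float,
    candidates: Iterable[tuple[int, int] | DesignSpec],
    use: str = "analytic",
    **design_kwargs,
) -> DesignSpec | None:
    """Smallest design meeting a target power for a given effect.

    Candidates are (n_fragments, n_sections) pairs or DesignSpecs; among
    those with power >= target the one minimizing total sections per group
    (fragments × sections) wins, ties broken by fewer fragments.  Returns
    None when no candidate qualifies.
    """
    if not 0.0 < target_power < 1.0:
        raise ParameterError("target_power must be in (0, 1)")
    if use not in ("analytic", "monte_carlo"):
        raise ParameterError(f"unknown power source '{use}'")
    specs: list[DesignSpec] = []
    for cand in candidates:
        if isinstance(cand, DesignSpec):
            specs.append(replace(cand, effect_pct=effect_pct))
        else:
            f, s = cand
            specs.append(
                DesignSpec(n_fragments=f, n_sections=s, effect_pct=effect_pct, **design_kwargs)
            )
    if not specs:
        raise ParameterError("empty candidate grid")
    qualifying = []
    for d in specs:
        p = analytic_power(d) if use == "analytic" else run_power(d).power
        if p >= target_power:
            qualifying.append(d)
    if not qualifying:
        return None
    return min(qualifying, key=lambda d: (d.n_fragments * d.n_sections, d.n_fragments))
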