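"""Predictor roster: declared categorical variables with marginals and true effects.

A roster entry fully describes one categorical predictor: its ordered category
labels, the population marginal probabilities used by the synthetic generator,
the true log-time coefficients of the outcome process (reference level carries
0), and metadata consumed by the imputation engine (variable kind, whether the
variable is a low-prevalence condition indicator with a designated
"absent" level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "CategoricalSpec",
    "beta_from_hr",
    "default_female_roster",
    "default_male_roster",
]


def beta_from_hr(hr: float, sigma: float) -> float:
    """Log-time coefficient implied by a Weibull AFT hazard ratio: beta = -sigma*log(HR)."""
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return -sigma * math.log(hr)


@dataclass(frozen=True)
class CategoricalSpec:
    """One categorical predictor: labels, marginals, true effects, metadata."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    betas: Mapping[str, float] = field(default_factory=dict)
    ref_level: str | None = None
    kind: str = "nominal"  # binary | nominal | ordinal
    is_condition: bool = False
    absent_level: str | None = None

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"{self.name}: needs >= 2 categories")
        if len(self.levels) != len(self.probs):
            raise ValueError(f"{self.name}: levels/probs length mismatch")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"{self.name}: duplicate level labels")
        if any(p < 0 for p in self.probs):
            raise ValueError(f"{self.name}: negative marginal probability")
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: marginal probabilities must sum to 1")
        if self.kind not in ("binary", "nominal", "ordinal"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.ref_level is None:
            object.__setattr__(self, "ref_level", self.levels[0])
        if self.ref_level not in self.levels:
            raise ValueError(f"{self.name}: ref_level {self.ref_level!r} not a level")
        for lvl in self.betas:
            if lvl not in self.levels:
                raise ValueError(f"{self.name}: beta for unknown level {lvl!r}")
        if abs(self.betas.get(self.ref_level, 0.0)) > 1e-12:
            raise ValueError(f"{self.name}: reference level must carry coefficient 0")
        if self.is_condition and self.absent_level is None:
            object.__setattr__(self, "absent_level", self.levels[0])
        if self.absent_level is not None and self.absent_level not in self.levels:
            raise ValueError(f"{self.name}: absent_level not a level")

    @property
    def non_ref_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.ref_level)

    def beta(self, level: str) -> float:
        return float(self.betas.get(level, 0.0))

    def beta_vector(self) -> dict[str, float]:
        """Coefficients keyed by dummy-column name for every non-reference level."""
        return {f"{self.name}[{l}]": self.beta(l) for l in self.non_ref_levels}


def _norm(p: Sequence[float]) -> tuple[float, ...]:
    s = float(sum(p))
    return tuple(x / s for x in p)


def _hr_betas(sigma: float, hrs: Mapping[str, float]) -> dict[str, float]:
    return {lvl: beta_from_hr(hr, sigma) for lvl, hr in hrs.items()}


def _condition(name: str, prev: float, hr: float, sigma: float) -> CategoricalSpec:
    return CategoricalSpec(
        name=name,
        levels=("No", "Yes"),
        probs=_norm([1 - prev, prev]),
        betas={"Yes": beta_from_hr(hr, sigma)},
        ref_level="No",
        kind="binary",
        is_condition=True,
        absent_level="No",
    )


def default_female_roster(sigma: float = 0.82) -> list[CategoricalSpec]:
    """Default female-like roster: marginals and effect sizes typical of a
    national health-survey cohort of adult women (12 predictors)."""
    return [
        CategoricalSpec(
            name="income",
            levels=("Q1", "Q2", "Q3", "Q4", "Q5"),
            probs=_norm([0.211, 0.145, 0.185, 0.256, 0.203]),
            betas=_hr_betas(sigma, {"Q1": 1.24, "Q2": 1.09, "Q3": 1.09, "Q4": 1.13}),
            ref_level="Q5",
            kind="ordinal",
        ),
        CategoricalSpec(
            name="education",
            levels=("LessThanSecondary", "Secondary", "PostSecondary"),
            probs=_norm([0.071, 0.105, 0.824]),
            betas=_hr_betas(sigma, {"LessThanSecondary": 1.13, "Secondary": 1.03}),
            ref_level="PostSecondary",
            kind="ordinal",
        ),
        CategoricalSpec(
            name="bmi",
            levels=("Underweight", "Normal", "Overweight", "ObeseI", "ObeseII", "ObeseIII"),
            probs=_norm([0.039, 0.545, 0.258, 0.105, 0.035, 0.018]),
            betas=_hr_betas(
                sigma,
                {
                    "Underweight": 1.55,
                    "Overweight": 0.74,
                    "ObeseI": 0.65,
                    "ObeseII": 0.67,
                    "ObeseIII": 0.91,
                },
            ),
            ref_level="Normal",
            kind="ordinal",
        ),
        CategoricalSpec(
            name="health",
            levels=("Poor", "Fair", "Good", "VeryGood", "Excellent"),
            probs=_norm([0.027, 0.086, 0.283, 0.381, 0.224]),
            betas=_hr_betas(
                sigma, {"Poor": 6.20, "Fair": 2.83, "Good": 1.71, "VeryGood": 1.20}
            ),
            ref_level="Excellent",
            kind="ordinal",
        ),
        CategoricalSpec(
            name="smoking",
            levels=(
                "Never",
                "FormerLight",
                "FormerHeavy",
                "CurrentLight",
                "CurrentHeavy",
            ),
            probs=_norm([0.571, 0.166, 0.050, 0.184, 0.029]),
            betas=_hr_betas(
                sigma,
                {
                    "FormerLight": 1.59,
                    "FormerHeavy": 1.93,
                    "CurrentLight": 2.34,
                    "CurrentHeavy": 2.76,
                },
            ),
            ref_level="Never",
            kind="nominal",
        ),
        CategoricalSpec(
            name="phys_act",
            levels=("Active", "Moderate", "Inactive"),
            probs=_norm([0.224, 0.254, 0.522]),
            betas=_hr_betas(sigma, {"Moderate": 1.09, "Inactive": 1.40}),
            ref_level="Active",
            kind="ordinal",
        ),
        _condition("copd", 0.017, 1.23, sigma),
        _condition("heart_disease", 0.033, 1.22, sigma),
        _condition("diabetes", 0.047, 1.30, sigma),
        _condition("cancer", 0.018, 5.31, sigma),
        _condition("stroke", 0.008, 1.37, sigma),
    ]


def default_male_roster(sigma: float = 0.82) -> list[CategoricalSpec]:
    """Default male-like roster (13 predictors; marital status replaces
    BMI/physical activity, with two extra condition indicators)."""
    return [
        CategoricalSpec(
            name="income",
            levels=("Q1", "Q2", "Q3", "Q4", "Q5"),
            probs=_norm([0.106, 0.124, 0.178, 0.272, 0.319]),
            betas=_hr_betas(sigma, {"Q1": 1.38, "Q2": 1.46, "Q3": 1.23, "Q4": 1.14}),
            ref_level="Q5",
            kind="ordinal",
        ),
        CategoricalSpec(
            name="marital",
            levels=("SingleNeverMarried", "DomesticPartner", "WidowedSeparatedDivorced"),
            probs=_norm([0.268, 0.658, 0.074]),
            betas=_hr_betas(
                sigma, {"DomesticPartner": 0.56, "WidowedSeparatedDivorced": 0.90}
            ),
            ref_level="SingleNeverMarried",
            kind="nominal",
        ),
        CategoricalSpec(
            name="education",
            levels=("LessThanSecondary", "Secondary", "PostSecondary"),
            probs=_norm([0.062, 0.103, 0.835]),
            betas=_hr_betas(sigma, {"LessThanSecondary": 1.10, "Secondary": 1.07}),
            ref_level="PostSecondary",
            kind="ordinal",
        ),
        CategoricalSpec(
            name="health",
            levels=("Poor", "Fair", "Good", "VeryGood", "Excellent"),
            probs=_norm([0.024, 0.078, 0.284, 0.379, 0.234]),
            betas=_hr_betas(
                sigma, {"Poor": 5.48, "Fair": 2.49, "Good": 1.59, "VeryGood": 1.13}
            ),
            ref_level="Excellent",
            kind="ordinal",
        ),
        CategoricalSpec(
            name="smoking",
            levels=(
                "Never",
                "FormerLight",
                "FormerHeavy",
                "CurrentLight",
                "CurrentHeavy",
            ),
            probs=_norm([0.479, 0.167, 0.094, 0.203, 0.057]),
            betas=_hr_betas(
                sigma,
                {
                    "FormerLight": 1.17,
                    "FormerHeavy": 1.56,
                    "CurrentLight": 2.08,
                    "CurrentHeavy": 2.87,
                },
            ),
            ref_level="Never",
            kind="nominal",
        ),
        _condition("copd", 0.015, 1.23, sigma),
        _condition("heart_disease", 0.048, 1.25, sigma),
        _condition("diabetes", 0.058, 1.33, sigma),
        _condition("cancer", 0.015, 3.49, sigma),
        _condition("stroke", 0.009, 1.27, sigma),
        _condition("alzheimers", 0.002, 2.02, sigma),
        _condition("arthritis", 0.117, 0.76, sigma),
    ]
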