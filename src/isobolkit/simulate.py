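"""Synthetic quantal-assay experiments with known ground truth.

The per-animal data behind published ED50 tables are almost never
released, so the generator here emulates the experiment the analysis
assumes: Bernoulli protection outcomes under a probit model on log10
dose, small groups (8 animals) at 2-3 dose levels, fixed-dose
combination assays under Loewe dose-equivalence with a tunable
interaction index, and normally distributed brain-concentration samples.

The combination generative rule uses the Loewe sum
``L = d_varied / ED50_V + d_adjunct / ED50_A`` and an interaction index
``gamma``:

    P(protection) = Phi(slope_V * log10(L / gamma))

``gamma = 1`` reproduces the additive isobole exactly in expectation
(protection crosses 50% where L = 1); ``gamma < 1`` is supra-additive
(synergy: less total drug needed), ``gamma > 1`` sub-additive.  The
mixture inherits the varied drug's slope — the parallelism assumption
that also underlies the additive prediction.

All randomness flows through a single ``numpy.random.Generator``; equal
seeds give bit-identical experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .quantal import DoseGroup, QuantalAssay

__all__ = [
    "DrugModel",
    "CombinationModel",
    "ExperimentDesign",
    "default_doses",
    "simulate_assay",
    "simulate_combination_assay",
    "simulate_brain_concentrations",
]


@dataclass(frozen=True)
class DrugModel:
    """Generative truth for one drug: ED50 and probit slope.

    ``slope_true`` is in probits per log10(mg/kg).  The default of 3
    probits per decade places the outer groups of the standard
    spacing-2 design at ~18%/82% expected response — inside the 4th-6th
    probit window, so simulated determinations carry the 16-24
    in-window animals that real screening tables report.
    """

    label: str
    ed50_true: float
    slope_true: float = 3.0

    def __post_init__(self) -> None:
        if not self.ed50_true > 0:
            raise ValueError(f"ed50_true must be > 0, got {self.ed50_true}")
        if not self.slope_true > 0:
            raise ValueError(f"slope_true must be > 0, got {self.slope_true}")

    def protection_probability(self, dose: np.ndarray | float) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        # same expression as the combination rule at f=0, gamma=1, so the
        # degenerate-adjunct reduction is bit-exact
        return norm.cdf(self.slope_true * np.log10(d / self.ed50_true))


@dataclass(frozen=True)
class CombinationModel:
    """Two drugs under Loewe dose-equivalence with interaction index gamma."""

    varied: DrugModel
    adjunct: DrugModel
    interaction_index: float = 1.0

    def __post_init__(self) -> None:
        if not self.interaction_index > 0:
            raise ValueError(
                f"interaction_index must be > 0, got {self.interaction_index}"
            )


@dataclass(frozen=True)
class ExperimentDesign:
    """The standard screening design: 2-3 dose levels of 8 animals.

    ``dose_spacing`` is the multiplicative factor between adjacent dose
    levels (geometric grid, centered on the relevant true ED50 unless
    explicit doses are supplied to the simulators).
    """

    dose_levels: int = 3
    animals_per_group: int = 8
    dose_spacing: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dose_levels < 2:
            raise ValueError(f"dose_levels must be >= 2, got {self.dose_levels}")
        if self.animals_per_group < 1:
            raise ValueError("animals_per_group must be >= 1")
        if not self.dose_spacing > 1:
            raise ValueError(f"dose_spacing must be > 1, got {self.dose_spacing}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_doses(center: float, design: ExperimentDesign) -> np.ndarray:
    """Geometric dose grid centered on ``center`` with the design spacing."""
    k = design.dose_levels
    exponents = np.arange(k, dtype=float) - (k - 1) / 2.0
    return center * design.dose_spacing**exponents


def _draw_assay(
    label: str,
    probabilities: np.ndarray,
    doses: np.ndarray,
    design: ExperimentDesign,
    rng: np.random.Generator,
    adjunct_label: str | None = None,
    adjunct_dose: float | None = None,
) -> QuantalAssay:
    protected = rng.binomial(design.animals_per_group, probabilities)
    groups = tuple(
        DoseGroup(dose=float(d), n_protected=int(r), n_total=design.animals_per_group)
        for d, r in zip(doses, protected)
    )
    return QuantalAssay(
        drug_label=label,
        groups=groups,
        adjunct_label=adjunct_label,
        adjunct_dose=adjunct_dose,
    )


def simulate_assay(
    model: DrugModel,
    design: ExperimentDesign,
    rng: np.random.Generator | None = None,
    doses: Sequence[float] | None = None,
) -> QuantalAssay:
    """Simulate a single-drug quantal assay.

    Each animal at dose ``d`` is protected independently with
    probability ``Phi(slope * (log10 d - log10 ED50))``.  Doses default
    to a geometric grid centered on the true ED50.  Passing ``rng``
    overrides the design's seed (useful for replicate streams).
    """
    if rng is None:
        rng = design.rng()
    d = np.asarray(doses, dtype=float) if doses is not None else default_doses(
        model.ed50_true, design
    )
    return _draw_assay(model.label, model.protection_probability(d), d, design, rng)


def simulate_combination_assay(
    model: CombinationModel,
    adjunct_dose: float,
    design: ExperimentDesign,
    rng: np.random.Generator | None = None,
    doses: Sequence[float] | None = None,
) -> QuantalAssay:
    """Simulate a fixed-dose combination assay under Loewe equivalence.

    Protection probability is ``Phi(slope_V * log10(L / gamma))`` with
    ``L`` the Loewe sum of the two dose fractions.  With ``gamma = 1``
    and ``adjunct_dose = 0`` this reduces exactly to
    :func:`simulate_assay` for the varied drug.

    Default doses are centered on the true combination ED50 of the
    varied drug, ``ED50_V * (gamma - f)`` with ``f`` the adjunct dose
    fraction — mirroring the adaptive dose-ranging of a real
    determination.  Requires ``gamma > f`` (otherwise the adjunct alone
    already exceeds combination equipotence).
    """
    if rng is None:
        rng = design.rng()
    if adjunct_dose < 0:
        raise ValueError(f"adjunct_dose must be >= 0, got {adjunct_dose}")
    gamma = model.interaction_index
    f = adjunct_dose / model.adjunct.ed50_true
    if doses is None:
        center = model.varied.ed50_true * (gamma - f)
        if center <= 0:
            raise ValueError(
                f"adjunct fraction {f:.3g} >= interaction index {gamma:.3g}: "
                "no varied-drug dose needed; supply doses explicitly"
            )
        d = default_doses(center, design)
    else:
        d = np.asarray(doses, dtype=float)
    loewe_sum = d / model.varied.ed50_true + f
    prob = norm.cdf(model.varied.slope_true * np.log10(loewe_sum / gamma))
    adjunct_label = model.adjunct.label if adjunct_dose > 0 else None
    return _draw_assay(
        model.varied.label,
        prob,
        d,
        design,
        rng,
        adjunct_label=adjunct_label,
        adjunct_dose=adjunct_dose if adjunct_dose > 0 else None,
    )


def simulate_brain_concentrations(
    mean_true: float,
    sd_true: float,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """n independent normal draws emulating per-animal brain levels (ug/ml).

    Draws are not truncated at zero: at the coefficients of variation
    typical of brain-concentration tables negative values are
    negligible, and truncation would bias t-test calibration checks.
    """
    if sd_true < 0:
        raise ValueError(f"sd_true must be >= 0, got {sd_true}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return mean_true + sd_true * rng.standard_normal(n)
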