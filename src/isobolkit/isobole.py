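"""Isobolographic transformation for fixed-dose drug combinations.

Under Loewe additivity two drugs behave as dilutions of one another:
every dose pair ``(d_A, d_B)`` with

    d_A / ED50_A + d_B / ED50_B = 1

is equipotent to either drug's ED50.  In the (adjunct dose, varied dose)
plane this is the straight "additivity isobole" joining ``(0, ED50_V)``
and ``(ED50_A, 0)``.

A fixed-dose (subthreshold) combination design holds the adjunct at a
constant dose ``d`` and titrates the varied drug.  Reading the isobole
at ``x = d`` gives the theoretical additive ED50 of the varied drug,

    ED50_add = ED50_V * (1 - d / ED50_A),

with a first-order (delta-method) standard error propagated from the
SEMs of the two single-drug ED50s under independence.  Comparing the
experimentally fitted combination ED50 (``ED50_mix``) against
``ED50_add`` with Welch's t-test classifies the interaction:

* no significant difference  -> additive,
* ED50_mix significantly below ED50_add -> supra-additive (synergy),
* ED50_mix significantly above ED50_add -> sub-additive (antagonism).

The derivation of the additive line assumes constant relative potency,
i.e. parallel log-probit dose-response curves for the two drugs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .quantal import ED50Estimate
from .summaries import TTestResult, welch_t

__all__ = [
    "FixedDoseDesign",
    "AdditivePrediction",
    "InteractionResult",
    "IsobolePoint",
    "IsobologramCoordinates",
    "fraction_of_ed50",
    "additive_ed50",
    "classify_interaction",
    "isobologram_coordinates",
]

CLASSIFICATIONS = ("additive", "supra-additive", "sub-additive")


@dataclass(frozen=True)
class FixedDoseDesign:
    """A fixed-dose combination: varied drug + constant-dose adjunct.

    ``varied`` is the ED50 estimate of the titrated drug alone;
    ``adjunct`` the ED50 estimate of the constant-dose partner alone;
    ``adjunct_dose`` the constant dose (mg/kg) used in the mixture.
    A meaningful additive prediction requires
    ``0 <= adjunct_dose < adjunct.ed50``.
    """

    varied: ED50Estimate
    adjunct: ED50Estimate
    adjunct_dose: float
    varied_label: str = ""
    adjunct_label: str = ""

    def __post_init__(self) -> None:
        if self.adjunct_dose < 0:
            raise ValueError(f"adjunct_dose must be >= 0, got {self.adjunct_dose}")
        if self.adjunct_dose >= self.adjunct.ed50:
            raise ValueError(
                f"adjunct_dose {self.adjunct_dose} >= adjunct ED50 "
                f"{self.adjunct.ed50}: additive prediction non-positive"
            )


@dataclass(frozen=True)
class AdditivePrediction:
    """Theoretical additive ED50 of the varied drug at a fixed adjunct dose."""

    ed50_add: float
    sem_add: float
    df: float
    adjunct_dose: float = float("nan")


@dataclass(frozen=True)
class InteractionResult:
    ed50_mix: ED50Estimate
    prediction: AdditivePrediction
    test: TTestResult
    classification: str
    varied_label: str = ""
    adjunct_label: str = ""

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")


@dataclass(frozen=True)
class IsobolePoint:
    """A plotted point with SEM bars on both axes (x = adjunct, y = varied)."""

    x: float
    y: float
    x_sem: float = 0.0
    y_sem: float = 0.0


@dataclass(frozen=True)
class IsobologramCoordinates:
    """Exact plotting coordinates for one isobologram panel.

    ``additivity_line`` joins ``(0, ED50_varied)`` and
    ``(ED50_adjunct, 0)``; ``vertical_lines`` are the constant adjunct
    doses; ``a_points`` lie on the line (theoretical additive values)
    and ``e_points`` carry the experimental mixture ED50s.
    """

    additivity_line: tuple[IsobolePoint, IsobolePoint]
    vertical_lines: tuple[float, ...]
    a_points: tuple[IsobolePoint, ...]
    e_points: tuple[IsobolePoint, ...]
    varied_label: str = ""
    adjunct_label: str = ""

    def to_dict(self) -> dict:
        as_xy = lambda p: {"x": p.x, "y": p.y, "x_sem": p.x_sem, "y_sem": p.y_sem}
        return {
            "varied_label": self.varied_label,
            "adjunct_label": self.adjunct_label,
            "additivity_line": [as_xy(p) for p in self.additivity_line],
            "vertical_lines": list(self.vertical_lines),
            "a_points": [as_xy(p) for p in self.a_points],
            "e_points": [as_xy(p) for p in self.e_points],
        }


def fraction_of_ed50(dose: float, reference: ED50Estimate) -> float:
    """Express a dose as a fraction of a reference ED50 (dimensionless)."""
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    return dose / reference.ed50


def additive_ed50(design: FixedDoseDesign) -> AdditivePrediction:
    """Theoretical additive ED50 with delta-method SEM.

    With ``f = adjunct_dose / ED50_A``:

        ED50_add = ED50_V * (1 - f)
        Var(ED50_add) = (1-f)^2 * SEM_V^2
                        + (ED50_V * d / ED50_A^2)^2 * SEM_A^2

    assuming independent errors on the two single-drug ED50s.  Degrees
    of freedom combine the two variance components by
    Welch-Satterthwaite, using each estimate's own df.
    """
    v, a, d = design.varied, design.adjunct, design.adjunct_dose
    f = fraction_of_ed50(d, a)
    ed50_add = v.ed50 * (1.0 - f)
    var_v = (1.0 - f) ** 2 * v.sem**2
    var_a = (v.ed50 * d / a.ed50**2) ** 2 * a.sem**2
    sem_add = float(np.sqrt(var_v + var_a))
    df_v = v.df if v.df is not None else float("inf")
    df_a = a.df if a.df is not None else float("inf")
    if var_a == 0.0:
        df = df_v
    else:
        df = (var_v + var_a) ** 2 / (var_v**2 / df_v + var_a**2 / df_a)
    return AdditivePrediction(
        ed50_add=float(ed50_add), sem_add=sem_add, df=float(df), adjunct_dose=d
    )


def classify_interaction(
    ed50_mix: ED50Estimate,
    prediction: AdditivePrediction,
    alpha: float = 0.05,
    *,
    varied_label: str = "",
    adjunct_label: str = "",
) -> InteractionResult:
    """Classify a combination by Welch's t-test of ED50_mix vs ED50_add.

    ``additive`` when p >= alpha; otherwise ``supra-additive`` if the
    experimental mixture ED50 is below the additive prediction
    (synergy), ``sub-additive`` if above (antagonism).
    """
    if not 0 < alpha <= 0.5:
        raise ValueError(f"alpha must lie in (0, 0.5], got {alpha}")
    df_mix = ed50_mix.df if ed50_mix.df is not None else float("inf")
    test = welch_t(
        ed50_mix.ed50, ed50_mix.sem, df_mix,
        prediction.ed50_add, prediction.sem_add, prediction.df,
    )
    if test.p_value >= alpha:
        classification = "additive"
    elif ed50_mix.ed50 < prediction.ed50_add:
        classification = "supra-additive"
    else:
        classification = "sub-additive"
    return InteractionResult(
        ed50_mix=ed50_mix,
        prediction=prediction,
        test=test,
        classification=classification,
        varied_label=varied_label,
        adjunct_label=adjunct_label,
    )


def isobologram_coordinates(
    varied: ED50Estimate,
    adjunct: ED50Estimate,
    results: Sequence[InteractionResult],
    *,
    varied_label: str = "",
    adjunct_label: str = "",
) -> IsobologramCoordinates:
    """Coordinates of one isobologram panel (adjunct on X, varied on Y).

    Each interaction result contributes one vertical line at its
    adjunct dose, one A point on the additivity line at that dose (SEM
    bar from the additive prediction) and one E point at the
    experimental mixture ED50 (SEM bar from its estimate).
    """
    line = (
        IsobolePoint(x=0.0, y=varied.ed50, y_sem=varied.sem),
        IsobolePoint(x=adjunct.ed50, y=0.0, x_sem=adjunct.sem),
    )
    ordered = sorted(results, key=lambda r: r.prediction.adjunct_dose)
    verticals = tuple(r.prediction.adjunct_dose for r in ordered)
    a_points = tuple(
        IsobolePoint(
            x=r.prediction.adjunct_dose,
            y=varied.ed50 * (1.0 - r.prediction.adjunct_dose / adjunct.ed50),
            y_sem=r.prediction.sem_add,
        )
        for r in ordered
    )
    e_points = tuple(
        IsobolePoint(
            x=r.prediction.adjunct_dose,
            y=r.ed50_mix.ed50,
            y_sem=r.ed50_mix.sem,
        )
        for r in ordered
    )
    return IsobologramCoordinates(
        additivity_line=line,
        vertical_lines=verticals,
        a_points=a_points,
        e_points=e_points,
        varied_label=varied_label,
        adjunct_label=adjunct_label,
    )
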