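"""Shared fixtures and independent oracles for the isobolkit suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.stats import binom, norm

from isobolkit.datasets import load_brain_concentrations, load_mes_ed50_summary
from isobolkit.pipeline import group_label
from isobolkit.quantal import DoseGroup, QuantalAssay
from isobolkit.summaries import SummaryGroup

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Printed reference statistics for the bundled study tables.
PRINTED_F = {"LCM": 5.981, "OXC": 6.477, "PGB": 5.877, "TPM": 4.979}
PRINTED_T = {"LCM": 0.608, "OXC": 0.565, "PGB": 0.250, "TPM": 0.661}


@pytest.fixture(scope="session")
def ed50_table():
    return load_mes_ed50_summary()


@pytest.fixture(scope="session")
def conc_table():
    return load_brain_concentrations()


def ed50_summary_groups(ed50_table, drug: str) -> list[SummaryGroup]:
    """SummaryGroups (SEM-tagged, df = n - 2) for one drug's table block."""
    block = ed50_table[ed50_table.drug == drug]
    return [
        SummaryGroup(
            label=group_label(str(r.adjunct), float(r.adjunct_dose)),
            mean=float(r.ed50),
            dispersion=float(r.sem),
            dispersion_kind="SEM",
            n=int(r.n),
            df=float(int(r.n) - 2),
        )
        for r in block.itertuples()
    ]


def grid_search_probit(
    doses: np.ndarray,
    protected: np.ndarray,
    total: np.ndarray,
    b0_range: tuple[float, float] = (-20.0, 20.0),
    b1_range: tuple[float, float] = (0.05, 20.0),
    points: int = 201,
    refinements: int = 2,
) -> tuple[float, float]:
    """Brute-force maximizer of the binomial probit log-likelihood.

    Dense 2-D grid over (intercept, slope) with iterative refinement
    around the incumbent; entirely independent of the package's
    Newton-Raphson fit (likelihood evaluated through
    ``scipy.stats.binom.logpmf``).  Final grid resolution is below 1e-3
    in both coordinates.
    """
    x = np.log10(np.asarray(doses, dtype=float))
    r = np.asarray(protected, dtype=float)
    n = np.asarray(total, dtype=float)

    def loglik_grid(b0s: np.ndarray, b1s: np.ndarray) -> np.ndarray:
        eta = b0s[:, None, None] + b1s[None, :, None] * x[None, None, :]
        p = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
        return binom.logpmf(r, n, p).sum(axis=-1)

    lo0, hi0 = b0_range
    lo1, hi1 = b1_range
    best = (np.nan, np.nan)
    for _ in range(1 + refinements):
        b0s = np.linspace(lo0, hi0, points)
        b1s = np.linspace(lo1, hi1, points)
        ll = loglik_grid(b0s, b1s)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (float(b0s[i]), float(b1s[j]))
        step0 = (hi0 - lo0) / (points - 1)
        step1 = (hi1 - lo1) / (points - 1)
        lo0, hi0 = best[0] - 2 * step0, best[0] + 2 * step0
        lo1, hi1 = max(best[1] - 2 * step1, 1e-6), best[1] + 2 * step1
    return best


def random_informative_assay(rng: np.random.Generator) -> QuantalAssay:
    """A small random assay with a well-identified maximum.

    At least two dose groups must show interior responses: with a
    single interior group the likelihood has a flat ridge (slope
    unbounded) and no meaningful maximizer to compare against.
    """
    while True:
        ed50 = float(rng.uniform(2.0, 50.0))
        slope = float(rng.uniform(1.5, 5.0))
        k = int(rng.integers(3, 5))
        doses = ed50 * 2.0 ** (np.arange(k) - (k - 1) / 2)
        p = norm.cdf(slope * np.log10(doses / ed50))
        protected = rng.binomial(8, p)
        if np.sum((protected > 0) & (protected < 8)) >= 2:
            groups = tuple(
                DoseGroup(float(d), int(r), 8) for d, r in zip(doses, protected)
            )
            return QuantalAssay("random", groups)
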