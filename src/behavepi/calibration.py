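"""Contact-survey calibration of the endogenous distancing law.

Weekly contact surveys (such as the UK Flusurvey) record, per week, the
incidence of influenza-like illness (ILI) among participants and the median
number of contacts reported by healthy and by symptomatic participants.
Regressing median contacts on incidence gives a (negative) slope per health
status; extrapolating that linear reduction to the incidence at which
contacts have fallen ``fold``-fold yields the scale of the exponential
endogenous contact law ``q = fold**(-rho/scale)`` used by the simulator.

The real survey microdata is not redistributable, so this module ships a
synthetic generator whose defaults mirror the published summary numbers
(baseline of about 13 contacts per week, slopes of roughly -70 for healthy
and -110 for ill participants, weekly incidence between 3 and 8%).  All
contracts and tests are defined on the synthetic tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SlopeFit",
    "generate_survey",
    "fit_slope",
    "contacts_correlation",
    "slope_to_decay",
]

#: Columns of a survey table (one row per survey week).
SURVEY_COLUMNS = (
    "week",
    "incidence",
    "contacts_healthy",
    "contacts_ill",
    "n_participants",
)


@dataclass(frozen=True)
class SlopeFit:
    """An OLS slope with its 95% confidence interval and p-value."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    p_value: float
    stderr: float

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def generate_survey(
    weeks: int = 30,
    baseline_contacts: float = 13.0,
    slope_healthy: float = -70.0,
    slope_ill: float = -110.0,
    incidence_range: tuple[float, float] = (0.03, 0.08),
    noise_sd: float = 2.0,
    seed: int | None = None,
    n_participants: int = 1000,
) -> pd.DataFrame:
    """Synthetic weekly survey table.

    Weekly ILI incidence is drawn uniformly on ``incidence_range``; median
    contacts per status are ``baseline + slope * incidence`` plus Gaussian
    noise, truncated at zero.  Defaults emulate two UK influenza seasons:
    ~13 contacts per week off-season, incidence between 3 and 8%, and the
    published healthy/ill contact slopes.
    """
    if weeks < 6:
        raise ValueError("weeks must be >= 6")
    lo, hi = incidence_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("incidence_range must satisfy 0 <= lo <= hi <= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if lo == hi and weeks > 1:
        warnings.warn(
            "degenerate incidence range: design is collinear, slopes unidentifiable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    incidence = rng.uniform(lo, hi, weeks)
    healthy = baseline_contacts + slope_healthy * incidence
    ill = baseline_contacts + slope_ill * incidence
    if noise_sd > 0:
        healthy = healthy + rng.normal(0.0, noise_sd, weeks)
        ill = ill + rng.normal(0.0, noise_sd, weeks)
    return pd.DataFrame(
        {
            "week": np.arange(weeks),
            "incidence": incidence,
            "contacts_healthy": np.maximum(healthy, 0.0),
            "contacts_ill": np.maximum(ill, 0.0),
            "n_participants": n_participants,
        }
    )


def _ols_fit(x: np.ndarray, y: np.ndarray) -> SlopeFit:
    if len(x) < 3:
        raise ValueError("need at least 3 rows to fit a slope")
    if np.ptp(x) < 1e-15:
        raise ValueError("singular design: predictor is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return SlopeFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=float(res.pvalues[1]),
        stderr=float(res.bse[1]),
    )


def fit_slope(table: pd.DataFrame, status: Literal["healthy", "ill"]) -> SlopeFit:
    """OLS of median contacts on weekly incidence for one health status."""
    if status not in ("healthy", "ill"):
        raise ValueError(f"unknown status {status!r}")
    return _ols_fit(
        table["incidence"].to_numpy(), table[f"contacts_{status}"].to_numpy()
    )


def contacts_correlation(table: pd.DataFrame) -> SlopeFit:
    """OLS of ill contacts on healthy contacts across weeks.

    The game model predicts opposite contact adjustments of the two health
    types (a negative association); a common incidence driver instead
    induces a positive one, which is what the published survey analysis
    found.  This regression reproduces that check on synthetic tables.
    """
    return _ols_fit(
        table["contacts_healthy"].to_numpy(), table["contacts_ill"].to_numpy()
    )


def slope_to_decay(slope: float, baseline_contacts: float, fold: float = 3.0) -> float:
    """Incidence scale of the endogenous law from a fitted contact slope.

    Solves ``baseline + slope * rho = baseline / fold`` for the incidence
    ``rho*`` at which linear contact reduction reaches a ``fold``-fold
    decrease: ``rho* = baseline * (1 - 1/fold) / (-slope)``.  Using
    ``rho*`` as the ``incidence_scale`` of :func:`behavepi.seir.endogenous_q`
    makes ``q(rho*) = 1/fold`` by construction.
    """
    if slope >= 0:
        raise ValueError("slope must be negative (contacts fall with incidence)")
    if baseline_contacts <= 0:
        raise ValueError("baseline_contacts must be positive")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    return baseline_contacts * (1.0 - 1.0 / fold) / (-slope)
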