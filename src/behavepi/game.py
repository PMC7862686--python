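"""Social distancing game: utilities, best responses, symmetric Nash equilibrium.

A population of ``n`` individuals is split into healthy (``H``) and sick
(``S = N \\ H``) types.  Each individual chooses a contact rate
``beta in [0, 1]``.  Absent disease, utility is a single-peaked "base
utility" maximised at an interior rate ``beta_star``.  With disease present,
a healthy individual discounts utility by the risk of meeting at least one
mobile sick individual (weighted by a fear parameter ``f``), and a sick
individual discounts a sickness-reduced utility by the risk of meeting at
least one mobile healthy individual (weighted by a pro-social concern
parameter ``c``).  Both risks rise with one's own mobility, so in any
interior equilibrium both types choose rates strictly below ``beta_star`` —
they socially distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

Role = Literal["healthy", "sick"]

__all__ = [
    "GameParams",
    "ContactProfile",
    "ComparativeStaticsReport",
    "ConvergenceError",
    "base_utility",
    "base_utility_prime",
    "healthy_utility",
    "sick_utility",
    "foc_residual",
    "best_response",
    "solve_symmetric_equilibrium",
    "comparative_statics",
    "simplified_game_table",
    "TABLE_SIGNS",
]


class ConvergenceError(RuntimeError):
    """Raised when the equilibrium iteration fails to converge.

    Carries the last iterate and the first-order-condition residuals so a
    caller can inspect how close the solver got.
    """

    def __init__(self, msg: str, last_iterate=None, residuals=None):
        super().__init__(msg)
        self.last_iterate = last_iterate
        self.residuals = residuals


@dataclass(frozen=True)
class GameParams:
    """Parameters of the social distancing game.

    Parameters
    ----------
    n : int
        Population size (>= 2).
    n_healthy : int
        Number of healthy individuals ``|H|`` (the rest are sick).
    f : float
        Fear of infection of the healthy, in [0, 1].
    c : float
        Pro-social concern of the sick, in [0, 1].
    delta : float
        Proportional disutility of being sick, in [0, 1]; sick base utility
        is ``delta * u(beta)``.
    utility_shape : (float, float)
        Pair ``(a, b)`` of the base-utility family
        ``u(beta) = K * beta**a * (1-beta)**b`` (``a, b >= 1``), normalised
        so the interior maximum ``u(beta_star) = 1`` at
        ``beta_star = a / (a + b)``.
    """

    n: int
    n_healthy: int
    f: float
    c: float
    delta: float
    utility_shape: tuple[float, float] = (2.0, 2.0)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not 0 <= self.n_healthy <= self.n:
            raise ValueError(f"n_healthy must lie in [0, n], got {self.n_healthy}")
        for name in ("f", "c", "delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        a, b = self.utility_shape
        if a < 1 or b < 1:
            # a, b >= 1 guarantees strict concavity of u on (0, 1)
            raise ValueError(f"utility_shape entries must be >= 1, got {(a, b)}")

    @property
    def n_sick(self) -> int:
        return self.n - self.n_healthy

    @property
    def beta_star(self) -> float:
        """No-disease optimal contact rate, the peak of the base utility."""
        a, b = self.utility_shape
        return a / (a + b)


@dataclass(frozen=True)
class ContactProfile:
    """A symmetric contact-rate profile (one rate per health type)."""

    beta_H: float
    beta_S: float
    beta_star: float

    def __post_init__(self):
        for name in ("beta_H", "beta_S", "beta_star"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.beta_star < 1.0:
            raise ValueError("beta_star must be strictly interior")


def _shape_norm(shape: tuple[float, float]) -> float:
    a, b = shape
    bstar = a / (a + b)
    return 1.0 / (bstar**a * (1.0 - bstar) ** b)


def base_utility(beta, shape: tuple[float, float] = (2.0, 2.0)):
    """Base utility ``u(beta) = K beta^a (1-beta)^b``, normalised to max 1.

    Vanishes at both full isolation (``beta = 0``) and full mobility
    (``beta = 1``), is positive in between, and peaks at
    ``beta_star = a/(a+b)``.  Accepts scalars or arrays.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0) or np.any(beta > 1):
        raise ValueError("beta must lie in [0, 1]")
    a, b = shape
    u = _shape_norm(shape) * beta**a * (1.0 - beta) ** b
    return u if u.ndim else float(u)


def base_utility_prime(beta, shape: tuple[float, float] = (2.0, 2.0)):
    """Derivative ``u'(beta)`` of the base utility."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0) or np.any(beta > 1):
        raise ValueError("beta must lie in [0, 1]")
    a, b = shape
    k = _shape_norm(shape)
    du = k * (
        a * beta ** (a - 1.0) * (1.0 - beta) ** b
        - b * beta**a * (1.0 - beta) ** (b - 1.0)
    )
    return du if du.ndim else float(du)


def _encounter_risk(beta_i, beta_other, count: int):
    """Probability of exposing oneself to >=1 mobile counterpart.

    Equals ``1 - [(1 - beta_other)^count * beta_i + 1 - beta_i]``, i.e.
    ``beta_i * (1 - (1 - beta_other)^count)``: one must go out (``beta_i``)
    and at least one of ``count`` counterparts, each mobile with rate
    ``beta_other``, must do the same.
    """
    return beta_i * (1.0 - (1.0 - beta_other) ** count)


def healthy_utility(beta_i, beta_S: float, params: GameParams):
    """Utility of a healthy individual at own rate ``beta_i``.

    The base utility is scaled down by the fear-weighted risk of meeting at
    least one of the ``n - |H|`` sick individuals, each mobile at rate
    ``beta_S``.  Accepts scalar or array ``beta_i``.
    """
    beta_i = np.asarray(beta_i, dtype=float)
    if not 0.0 <= beta_S <= 1.0:
        raise ValueError("beta_S must lie in [0, 1]")
    risk = _encounter_risk(beta_i, beta_S, params.n_sick)
    out = (1.0 - params.f * risk) * base_utility(beta_i, params.utility_shape)
    return out if out.ndim else float(out)


def sick_utility(beta_i, beta_H: float, params: GameParams):
    """Utility of a sick individual at own rate ``beta_i``.

    The sickness-reduced base utility ``delta * u`` is scaled down by the
    concern-weighted risk of meeting at least one of the ``|H|`` healthy
    individuals, each mobile at rate ``beta_H``.
    """
    beta_i = np.asarray(beta_i, dtype=float)
    if not 0.0 <= beta_H <= 1.0:
        raise ValueError("beta_H must lie in [0, 1]")
    risk = _encounter_risk(beta_i, beta_H, params.n_healthy)
    out = (
        (1.0 - params.c * risk)
        * params.delta
        * base_utility(beta_i, params.utility_shape)
    )
    return out if out.ndim else float(out)


def foc_residual(beta_i: float, beta_other: float, role: Role, params: GameParams) -> float:
    """First-order-condition residual (marginal utility minus marginal risk).

    For the healthy:
    ``(1 - f*beta_i*P) u'(beta_i) - f*P*u(beta_i)`` with
    ``P = 1 - (1-beta_S)^(n-|H|)``; analogously for the sick with ``c`` and
    ``P = 1 - (1-beta_H)^|H|`` (the sickness factor ``delta`` cancels).
    A root where the second-order condition holds is a best response.
    """
    if not 0.0 < beta_i < 1.0:
        raise ValueError("beta_i must lie in (0, 1)")
    if not 0.0 <= beta_other <= 1.0:
        raise ValueError("beta_other must lie in [0, 1]")
    if role == "healthy":
        weight, count = params.f, params.n_sick
    elif role == "sick":
        weight, count = params.c, params.n_healthy
    else:
        raise ValueError(f"unknown role {role!r}")
    p = 1.0 - (1.0 - beta_other) ** count
    u = base_utility(beta_i, params.utility_shape)
    du = base_utility_prime(beta_i, params.utility_shape)
    return (1.0 - weight * beta_i * p) * du - weight * p * u


def _role_utility(beta_i, beta_other: float, role: Role, params: GameParams):
    if role == "healthy":
        return healthy_utility(beta_i, beta_other, params)
    if role == "sick":
        return sick_utility(beta_i, beta_other, params)
    raise ValueError(f"unknown role {role!r}")


def best_response(
    beta_other: float, role: Role, params: GameParams, grid_size: int = 2001
) -> float:
    """Global maximiser of the role's utility over its own rate in [0, 1].

    A dense grid locates the basin of the global maximum, then a bounded
    scalar optimisation polishes it.  When the utility is identically zero
    (e.g. ``delta = 0`` for the sick), the tie is broken towards staying
    home (rate 0).
    """
    if not 0.0 <= beta_other <= 1.0:
        raise ValueError("beta_other must lie in [0, 1]")
    grid = np.linspace(0.0, 1.0, grid_size)
    vals = _role_utility(grid, beta_other, role, params)
    k = int(np.argmax(vals))
    if vals[k] <= 0.0:
        return 0.0  # flat-zero utility: staying home is weakly dominant
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_size - 1)]
    res = minimize_scalar(
        lambda b: -_role_utility(b, beta_other, role, params),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    # keep whichever of the grid point and the polished point is better
    if -res.fun >= vals[k]:
        return float(res.x)
    return float(grid[k])


def solve_symmetric_equilibrium(
    params: GameParams,
    tol: float = 1e-8,
    max_iter: int = 500,
    damping: float = 0.5,
) -> ContactProfile:
    """Symmetric Nash equilibrium ``(beta_H, beta_S)`` by damped best response.

    All healthy individuals play ``beta_H`` and all sick play ``beta_S``,
    each a best response to the other type's rate.  Iteration starts at
    ``(beta_star, beta_star)`` and stops when successive iterates move less
    than ``tol``.  If one type is absent, the remaining type faces no risk
    term and plays ``beta_star`` (the no-disease optimum is reported for the
    absent type as well).
    """
    bstar = params.beta_star
    if params.n_sick == 0 or params.n_healthy == 0:
        return ContactProfile(beta_H=bstar, beta_S=bstar, beta_star=bstar)
    b_h, b_s = bstar, bstar
    for _ in range(max_iter):
        new_h = (1 - damping) * b_h + damping * best_response(b_s, "healthy", params)
        new_s = (1 - damping) * b_s + damping * best_response(b_h, "sick", params)
        move = max(abs(new_h - b_h), abs(new_s - b_s))
        b_h, b_s = new_h, new_s
        if move < tol:
            return ContactProfile(beta_H=b_h, beta_S=b_s, beta_star=bstar)
    residuals = (
        foc_residual(min(max(b_h, 1e-9), 1 - 1e-9), b_s, "healthy", params),
        foc_residual(min(max(b_s, 1e-9), 1 - 1e-9), b_h, "sick", params),
    )
    raise ConvergenceError(
        f"equilibrium iteration did not converge in {max_iter} iterations",
        last_iterate=(b_h, b_s),
        residuals=residuals,
    )


#: Predicted equilibrium responses: (perturbed quantity, affected rate) -> sign
#: of the derivative of the affected rate w.r.t. the quantity.  A negative
#: sign on a rate means "more social distancing".
TABLE_SIGNS: dict[tuple[str, str], int] = {
    ("beta_H", "beta_S"): -1,  # more distancing of healthy -> less of sick
    ("beta_S", "beta_H"): -1,  # more distancing of sick -> less of healthy
    ("n_healthy", "beta_S"): -1,  # larger healthy population -> more distancing of sick
    ("n_sick", "beta_H"): -1,  # larger sick population -> more distancing of healthy
    ("c", "beta_S"): -1,  # more concern -> more distancing of sick
    ("f", "beta_H"): -1,  # more fear -> more distancing of healthy
}


@dataclass
class StaticsEntry:
    sign: int
    derivative: float
    step: float


@dataclass
class ComparativeStaticsReport:
    """Finite-difference equilibrium responses to parameter perturbations."""

    params: GameParams
    entries: dict[tuple[str, str], StaticsEntry] = field(default_factory=dict)

    def signs(self) -> dict[tuple[str, str], int]:
        return {k: e.sign for k, e in self.entries.items()}

    def matches_predictions(self) -> bool:
        """True when every computed sign equals the model's prediction."""
        return all(self.entries[k].sign == s for k, s in TABLE_SIGNS.items())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "perturbed": k[0],
                "affected": k[1],
                "sign": e.sign,
                "derivative": e.derivative,
                "step": e.step,
                "predicted_sign": TABLE_SIGNS.get(k, 0),
            }
            for k, e in self.entries.items()
        ]
        return pd.DataFrame(rows)


def _with(params: GameParams, **kw) -> GameParams:
    d = {
        "n": params.n,
        "n_healthy": params.n_healthy,
        "f": params.f,
        "c": params.c,
        "delta": params.delta,
        "utility_shape": params.utility_shape,
    }
    d.update(kw)
    return GameParams(**d)


def comparative_statics(
    params: GameParams,
    step: float = 1e-3,
    tol: float = 1e-8,
    sign_tol: float | None = None,
) -> ComparativeStaticsReport:
    """Numerical comparative statics of the symmetric equilibrium.

    Central finite differences of the equilibrium rates with respect to the
    opposite type's rate (best-response slope), the two population sizes
    (unit increments, total ``n`` adjusting so the other subpopulation is
    held fixed), and the behavioural weights ``c`` and ``f``.  A sign of 0
    is reported when the difference magnitude does not exceed ``sign_tol``
    (default ``10 * tol``).
    """
    if sign_tol is None:
        sign_tol = 10.0 * tol
    report = ComparativeStaticsReport(params=params)
    eq = solve_symmetric_equilibrium(params, tol=tol)

    def classify(deriv: float, h: float) -> StaticsEntry:
        if abs(deriv) * h <= sign_tol:
            return StaticsEntry(0, deriv, h)
        return StaticsEntry(1 if deriv > 0 else -1, deriv, h)

    # best-response slopes: perturb the opposite type's rate exogenously
    for src, role, at in (
        ("beta_H", "sick", eq.beta_H),
        ("beta_S", "healthy", eq.beta_S),
    ):
        h = step * max(at, step)
        lo, hi = max(at - h, 0.0), min(at + h, 1.0)
        d = (best_response(hi, role, params) - best_response(lo, role, params)) / (hi - lo)
        dst = "beta_S" if src == "beta_H" else "beta_H"
        report.entries[(src, dst)] = classify(d, hi - lo)

    # population sizes: unit increments, holding the other subpopulation fixed
    eq_h_up = solve_symmetric_equilibrium(
        _with(params, n=params.n + 1, n_healthy=params.n_healthy + 1), tol=tol
    )
    eq_h_dn = solve_symmetric_equilibrium(
        _with(params, n=params.n - 1, n_healthy=params.n_healthy - 1), tol=tol
    )
    report.entries[("n_healthy", "beta_S")] = classify(
        (eq_h_up.beta_S - eq_h_dn.beta_S) / 2.0, 2.0
    )
    eq_s_up = solve_symmetric_equilibrium(_with(params, n=params.n + 1), tol=tol)
    eq_s_dn = solve_symmetric_equilibrium(_with(params, n=params.n - 1), tol=tol)
    report.entries[("n_sick", "beta_H")] = classify(
        (eq_s_up.beta_H - eq_s_dn.beta_H) / 2.0, 2.0
    )

    # behavioural weights
    for name, dst in (("c", "beta_S"), ("f", "beta_H")):
        v = getattr(params, name)
        h = step * max(v, step)
        lo, hi = max(v - h, 0.0), min(v + h, 1.0)
        eq_up = solve_symmetric_equilibrium(_with(params, **{name: hi}), tol=tol)
        eq_dn = solve_symmetric_equilibrium(_with(params, **{name: lo}), tol=tol)
        d = (getattr(eq_up, dst) - getattr(eq_dn, dst)) / (hi - lo)
        report.entries[(name, dst)] = classify(d, hi - lo)

    return report


def simplified_game_table(params: GameParams) -> pd.DataFrame:
    """2x2 payoff table of the simplified home/mobile interaction.

    Each type either stays home (rate 0) or goes out at the no-disease
    optimum ``beta_star``.  Cells hold ``(healthy payoff, sick payoff)``;
    rows index the healthy strategy, columns the sick strategy.
    """
    bstar = params.beta_star
    strategies = {"home": 0.0, "mobile": bstar}
    table = pd.DataFrame(index=list(strategies), columns=list(strategies), dtype=object)
    for h_name, bh in strategies.items():
        for s_name, bs in strategies.items():
            table.loc[h_name, s_name] = (
                float(healthy_utility(bh, bs, params)),
                float(sick_utility(bs, bh, params)),
            )
    table.index.name = "healthy"
    table.columns.name = "sick"
    return table
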