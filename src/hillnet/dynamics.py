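"""Normalized-Hill logic dynamics: fluxes, ODE right-hand side, integration.

The model class is a logic-based differential equation (LDE) system.
Each species i obeys

    dy_i/dt = ( phi_i(y) * y_max_i - y_i ) / tau_i

where phi_i in [0, 1] is the fuzzy-logic drive onto species i.  A single
activating edge contributes the *normalized Hill* activation

    f_act(x) = beta * x^n / (k^n + x^n)

with (beta, k) chosen so that f_act(0) = 0, f_act(ec50) = 1/2 and
f_act(1) = 1; an inhibiting edge contributes 1 - f_act(x).  Terms ANDed
inside one rule multiply; reactions converging on one target combine by
the probabilistic OR a + b - a*b, which is associative, commutative and
smooth.  The flow never leaves the box [0, y_max] componentwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import NetworkModel, Reaction

__all__ = [
    "HillShape",
    "TimeCourse",
    "HillParameterizationError",
    "hill_shape",
    "act",
    "inhib",
    "reaction_flux",
    "node_drive",
    "rhs",
    "simulate_segment",
    "steady_state",
]

RTOL = 1e-6
ATOL = 1e-8


class HillParameterizationError(ValueError):
    """The (n, ec50) pair admits no normalized-Hill parameterization."""


@dataclass(frozen=True)
class HillShape:
    """Normalized Hill curve parameters.

    beta (gain) and k (half-saturation) are derived from (n, ec50) by
    the unique solution of f(1) = 1 and f(ec50) = 1/2:

        k^n  = ec50^n / (1 - 2 * ec50^n)
        beta = 1 + k^n = (ec50^n - 1) / (2 * ec50^n - 1)

    which exists iff 0 < ec50 < 1 and ec50^n < 1/2.
    """

    n: float
    ec50: float
    beta: float
    k: float


def hill_shape(n: float, ec50: float) -> HillShape:
    """Parameterize the normalized Hill curve for a given (n, ec50)."""
    if not n > 0:
        raise HillParameterizationError(f"Hill coefficient must be > 0, got {n}")
    if not 0.0 < ec50 < 1.0:
        raise HillParameterizationError(f"ec50 must be in (0, 1), got {ec50}")
    e = ec50 ** n
    if not e < 0.5:
        raise HillParameterizationError(
            f"ec50**n = {e:.6g} >= 1/2: no normalized Hill curve passes "
            "through (0,0), (ec50,1/2) and (1,1) with these parameters"
        )
    beta = (e - 1.0) / (2.0 * e - 1.0)
    k = (beta - 1.0) ** (1.0 / n)
    return HillShape(n=float(n), ec50=float(ec50), beta=beta, k=k)


def act(x, shape: HillShape):
    """Normalized Hill activation, clamped to [0, 1]; monotone in x.

    Accepts scalars or arrays; x must be nonnegative (activities are).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("activity input to act() must be nonnegative")
    xn = x ** shape.n
    f = shape.beta * xn / (shape.k ** shape.n + xn)
    out = np.clip(f, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def inhib(x, shape: HillShape):
    """Normalized Hill inhibition: 1 - act(x)."""
    return 1.0 - act(x, shape)


def reaction_flux(r: Reaction, y: np.ndarray, model: NetworkModel) -> float:
    """Flux of one reaction given the current activity vector.

    Input reactions yield their weight; otherwise w times the product of
    act/inhib over the rule's terms (AND as fuzzy product).  Result lies
    in [0, w].
    """
    if r.is_input:
        return r.w
    shape = hill_shape(r.n, r.ec50)
    flux = r.w
    for t in r.terms:
        x = max(y[model.species_index(t.species_id)], 0.0)
        flux *= act(x, shape) if t.sign > 0 else inhib(x, shape)
    return flux


def _or_fold(fluxes) -> float:
    """Probabilistic OR a + b - a*b, folded associatively; 0 if empty."""
    phi = 0.0
    for f in fluxes:
        phi = phi + f - phi * f
    return min(max(phi, 0.0), 1.0)


def node_drive(species_id: str, y: np.ndarray, model: NetworkModel) -> float:
    """Total fuzzy-OR drive onto one species, in [0, 1].

    Species with no incoming reactions get drive 0 and decay to zero; a
    species regulated only by inhibitors gets full drive while its
    repressors are off (the product of inhib terms inside the reaction).
    """
    incoming = model.incoming_index.get(species_id, ())
    return _or_fold(reaction_flux(r, y, model) for r in incoming)


# ---------------------------------------------------------------------
# compiled right-hand side
# ---------------------------------------------------------------------

class _Compiled:
    """Index-resolved model for fast repeated rhs evaluation."""

    def __init__(self, model: NetworkModel):
        self.model = model
        self.y_max = np.array([s.y_max for s in model.species])
        self.tau = np.array([s.tau for s in model.species])
        self.y_init = np.array([s.y_init for s in model.species])
        ids = {s.id: i for i, s in enumerate(model.species)}
        # per target: list of (w, [(src_index, sign, shape), ...])
        self.incoming: list[list[tuple[float, list[tuple[int, int, HillShape]]]]] = [
            [] for _ in model.species
        ]
        for r in model.reactions:
            terms = [
                (ids[t.species_id], t.sign, hill_shape(r.n, r.ec50)) for t in r.terms
            ]
            self.incoming[ids[r.target_id]].append((r.w, terms))

    def drives(self, y: np.ndarray) -> np.ndarray:
        phi = np.zeros_like(self.y_max)
        for i, reactions in enumerate(self.incoming):
            acc = 0.0
            for w, terms in reactions:
                flux = w
                for j, sign, shape in terms:
                    a = act(max(y[j], 0.0), shape)
                    flux *= a if sign > 0 else 1.0 - a
                acc = acc + flux - acc * flux
            phi[i] = min(max(acc, 0.0), 1.0)
        return phi

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            raise ValueError(f"non-finite state at t={t}: {y}")
        return (self.drives(y) * self.y_max - y) / self.tau


def rhs(t: float, y: np.ndarray, model: NetworkModel) -> np.ndarray:
    """LDE right-hand side dy_i/dt = (phi_i(y) * y_max_i - y_i) / tau_i."""
    return _Compiled(model).rhs(t, np.asarray(y, dtype=float))


# ---------------------------------------------------------------------
# time courses and integration
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class TimeCourse:
    """A simulated trajectory: time grid by species activity matrix."""

    times: np.ndarray  # strictly increasing, shape (T,)
    activities: np.ndarray  # shape (T, S)
    species_ids: tuple[str, ...]
    segment_boundaries: tuple[float, ...] = ()

    @property
    def final_state(self) -> np.ndarray:
        return self.activities[-1].copy()

    def activity(self, species_id: str) -> np.ndarray:
        """Trajectory of a single species by id."""
        return self.activities[:, self.species_ids.index(species_id)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.activities, columns=list(self.species_ids))
        df.insert(0, "time", self.times)
        return df


def simulate_segment(
    model: NetworkModel,
    y0: np.ndarray | None = None,
    duration: float = 10.0,
    n_out: int = 101,
    t0: float = 0.0,
) -> TimeCourse:
    """Integrate the model for one segment of constant parameters.

    Uses an adaptive explicit Runge-Kutta method (rtol 1e-6, atol 1e-8);
    the dynamics are smooth, bounded and non-stiff.  Output is reported
    on an evenly spaced grid of ``n_out`` points including both
    endpoints; the first row is exactly ``y0`` (default: the model's
    y_init vector).
    """
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if n_out < 2:
        raise ValueError(f"n_out must be >= 2, got {n_out}")
    compiled = _Compiled(model)
    y0 = compiled.y_init.copy() if y0 is None else np.asarray(y0, dtype=float).copy()
    if y0.shape != compiled.y_init.shape:
        raise ValueError(
            f"y0 has {y0.size} entries, model has {len(model.species)} species"
        )
    t_eval = np.linspace(t0, t0 + duration, n_out)
    sol = solve_ivp(
        compiled.rhs,
        (t0, t0 + duration),
        y0,
        method="RK45",
        t_eval=t_eval,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:  # pragma: no cover - bounded smooth dynamics
        raise RuntimeError(f"integration failed at t={sol.t[-1]}: {sol.message}")
    activities = sol.y.T.copy()
    activities[0] = y0
    return TimeCourse(
        times=sol.t.copy(), activities=activities, species_ids=model.species_ids
    )


def steady_state(
    model: NetworkModel,
    y0: np.ndarray | None = None,
    tol: float = 1e-6,
    t_cap: float | None = None,
) -> tuple[np.ndarray, bool]:
    """Integrate until the flow stalls; returns (state, converged).

    Convergence criterion: max_i |dy_i/dt| * tau_i < tol, i.e. every
    species is within tol of its own drive target.  Integration is
    capped at ``t_cap`` (default 500 * max tau); oscillatory networks
    simply come back unconverged, never raise.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    compiled = _Compiled(model)
    y = compiled.y_init.copy() if y0 is None else np.asarray(y0, dtype=float).copy()
    max_tau = float(np.max(compiled.tau)) if len(model.species) else 1.0
    if t_cap is None:
        t_cap = 500.0 * max_tau

    def settled(y: np.ndarray) -> bool:
        return float(np.max(np.abs(compiled.rhs(0.0, y)) * compiled.tau, initial=0.0)) < tol

    if settled(y):
        return y, True
    t = 0.0
    chunk = 10.0 * max_tau
    while t < t_cap:
        dt = min(chunk, t_cap - t)
        sol = solve_ivp(compiled.rhs, (t, t + dt), y, method="RK45", rtol=RTOL, atol=ATOL)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"integration failed at t={sol.t[-1]}: {sol.message}")
        y = sol.y[:, -1]
        t += dt
        if settled(y):
            return y, True
    return y, False
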