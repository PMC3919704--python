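"""Integration of the NHEJ rate equations and fluorescence observables.

The measured quantities are the levels of Ku80-EGFP (``K``) and
DNA-PKcs-YFP (``D``) recruited at damage sites.  Each DSB end carries one
tagged molecule (synapses therefore carry two), so the observables are
weighted sums of the protein-bound species; species past the release step of
the tagged protein contribute nothing.  Measured curves are normalized to
their maximum, so ``K_hat``/``D_hat`` divide by the maximum over the dense
simulation grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import DoseSchedule, ReactionNetwork

__all__ = [
    "Trajectory",
    "integrate",
    "ku_signal",
    "dnapkcs_signal",
    "ku_weights",
    "dnapkcs_weights",
    "normalize",
    "default_grid",
]

# observable weights: species -> tagged-molecule count, per variant family.
_KU = {
    "SF1": {"S1": 1, "S2": 2, "C1": 1, "C2": 2, "C3": 2, "C4": 2},
    "SF2": {"S1": 1, "S2": 2, "C1": 1, "C1p": 1, "C3": 2, "C4": 2},
    "SF3": {"S1": 1, "S2": 2, "C1": 1, "C3": 2, "C4": 2},
    "BF": {"SKu": 1, "S2": 1, "CKu": 1, "C2": 1, "C3": 1, "C4": 1},
}
_DNAPK = {
    "SF1": {"C1": 1, "C2": 2, "C3": 2, "C4": 2},
    "SF2": {"C1": 1, "C1p": 1, "C3": 2, "C4": 2},
    "SF3": {"C1": 1, "C3": 2, "C4": 2},
    "BF": {"C2": 1, "C3": 1, "C4": 1},
}


def ku_weights(variant: str, species: list[str]) -> np.ndarray:
    """Per-species Ku80-EGFP weights (K = w @ X)."""
    w = _KU[variant]
    return np.array([float(w.get(s, 0)) for s in species])


def dnapkcs_weights(variant: str, species: list[str]) -> np.ndarray:
    """Per-species DNA-PKcs-YFP weights (D = w @ X); zero on the simple chain."""
    w = _DNAPK[variant]
    return np.array([float(w.get(s, 0)) for s in species])


def ku_signal(state: np.ndarray, net: ReactionNetwork) -> float:
    """Recruited Ku level of one state (clipped at 0 for solver round-off)."""
    return float(ku_weights(net.variant, net.species) @ np.clip(state, 0.0, None))


def dnapkcs_signal(state: np.ndarray, net: ReactionNetwork) -> float:
    """Recruited DNA-PKcs level of one state."""
    return float(dnapkcs_weights(net.variant, net.species) @ np.clip(state, 0.0, None))


def normalize(series: np.ndarray) -> np.ndarray:
    """Divide a series by its maximum; rejects identically-zero input."""
    series = np.asarray(series, dtype=float)
    m = series.max(initial=-np.inf)
    if not np.isfinite(m) or m <= 0:
        raise ValueError("cannot normalize a series without a positive maximum")
    return series / m


def default_grid(t_end: float, T_R: float = 0.5, n_coarse: int = 240) -> np.ndarray:
    """Dense output grid: fine near the dose window and peak, coarser after.

    Steps of 0.02 min up to min(5, t_end) to resolve the sub-minute
    recruitment phase, then uniform out to ``t_end``.
    """
    t_fine = np.arange(0.0, min(5.0, t_end) + 1e-12, 0.02)
    if t_end <= 5.0:
        grid = t_fine
    else:
        grid = np.concatenate([t_fine, np.linspace(5.0, t_end, n_coarse)])
    grid = np.union1d(grid, [0.0, T_R, t_end])
    return grid[grid <= t_end + 1e-12]


@dataclass
class Trajectory:
    """Solution of one variant's rate equations on a time grid.

    ``states`` is (n_times, n_species).  ``K``/``D`` are the raw observables,
    ``K_hat``/``D_hat`` their max-normalized forms (the normalizing maximum is
    taken over this grid, which is the dense simulation grid).
    """

    times: np.ndarray
    states: np.ndarray
    species: list[str]
    variant: str
    condition: str = "control"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")
        if self.states.shape != (self.times.size, len(self.species)):
            raise ValueError("states shape does not match (n_times, n_species)")
        self._clipped = np.clip(self.states, 0.0, None)

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, self.species.index(species)]

    @property
    def K(self) -> np.ndarray:
        return self._clipped @ ku_weights(self.variant, self.species)

    @property
    def D(self) -> np.ndarray:
        return self._clipped @ dnapkcs_weights(self.variant, self.species)

    @property
    def K_hat(self) -> np.ndarray:
        return normalize(self.K)

    @property
    def D_hat(self) -> np.ndarray:
        return normalize(self.D)

    def signal(self, channel: str, normalized: bool = True) -> np.ndarray:
        if channel == "Ku":
            return self.K_hat if normalized else self.K
        if channel == "DNAPKcs":
            return self.D_hat if normalized else self.D
        raise ValueError(f"unknown channel {channel!r}")

    def interp(self, channel: str, t: np.ndarray, normalized: bool = True) -> np.ndarray:
        """Linear interpolation of a channel onto times ``t`` (must lie in span)."""
        t = np.asarray(t, dtype=float)
        if t.min(initial=np.inf) < self.times[0] - 1e-9 or t.max(initial=-np.inf) > self.times[-1] + 1e-9:
            raise ValueError("requested times fall outside the trajectory span")
        return np.interp(t, self.times, self.signal(channel, normalized))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.species)
        df.insert(0, "time_min", self.times)
        df["K"] = self.K
        df["D"] = self.D
        df["K_hat"] = self.K_hat
        df["D_hat"] = self.D_hat
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries variant/parameter context."""


def integrate(
    net: ReactionNetwork,
    sched: DoseSchedule | None = None,
    t_end: float = 180.0,
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Solve dX/dt = SM @ R(X, p, t) from an all-zero initial state.

    The piecewise-constant dose forcing is handled by splitting the
    integration at every window boundary, so the solver never steps across a
    discontinuity.  ``grid`` defaults to :func:`default_grid`; extra times
    (e.g. observation times) can be unioned in by the caller.
    """
    sched = sched or net.schedule
    if grid is None:
        grid = default_grid(t_end, sched.T_R)
    grid = np.asarray(grid, dtype=float)
    if grid.min(initial=np.inf) < 0 or grid.max(initial=-np.inf) > t_end + 1e-9:
        raise ValueError("grid must lie within [0, t_end]")

    edges = [b for b in sched.boundaries if 0.0 < b < t_end]
    seg_bounds = np.array([0.0] + edges + [t_end])

    x = np.zeros(net.n_species)
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    if grid[0] == 0.0:
        times_out.append(np.array([0.0]))
        states_out.append(x[None, :].copy())

    use_jac = method in ("LSODA", "BDF", "Radau")
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        t_eval = grid[(grid > a + 1e-15) & (grid <= b + 1e-15)]
        t_eval = t_eval[t_eval <= b]
        # evaluate the forcing at the segment interior so boundary values are
        # unambiguous under the right-open window convention
        mid = 0.5 * (a + b)
        u_const = float(sched.indicator(mid))
        rhs = _frozen_rhs(net, u_const)
        sol = solve_ivp(
            rhs,
            (a, b),
            x,
            method=method,
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
            jac=(lambda t, y: net.jacobian(t, y)) if use_jac else None,
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE solver failed on [{a}, {b}] for {net!r}: {sol.message} "
                f"(parameters: {net.params.to_dict()})"
            )
        if t_eval.size:
            times_out.append(sol.t)
            states_out.append(sol.y.T)
        x = sol.y[:, -1] if sol.t.size else x
        if sol.t.size == 0 or sol.t[-1] < b - 1e-12:
            # advance to the segment end even if no grid point sits there
            sol_end = solve_ivp(
                rhs, (sol.t[-1] if sol.t.size else a, b), x,
                method=method, rtol=rtol, atol=atol,
                jac=(lambda t, y: net.jacobian(t, y)) if use_jac else None,
            )
            if not sol_end.success:
                raise IntegrationError(
                    f"ODE solver failed reaching segment end {b} for {net!r}"
                )
            x = sol_end.y[:, -1]

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    # drop duplicate time points arising from segment edges
    keep = np.concatenate([[True], np.diff(times) > 1e-15])
    return Trajectory(times[keep], states[keep], list(net.species), net.variant, net.condition)


def _frozen_rhs(net: ReactionNetwork, u_const: float):
    """RHS with the dose indicator frozen to its in-segment value."""
    rates = net._rates
    SM = net.SM
    orders = net._orders
    ridx = net._react_idx
    n = net.n_reactions

    zsel = np.array([o == "zero" for o in orders])
    fsel = np.array([o == "first" for o in orders])
    ssel = np.array([o == "second_self" for o in orders])

    def rhs(t, x):
        b = np.empty(n)
        b[zsel] = u_const
        if fsel.any():
            b[fsel] = x[ridx[fsel]]
        if ssel.any():
            b[ssel] = x[ridx[ssel]] ** 2
        return SM @ (rates * b)

    return rhs
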