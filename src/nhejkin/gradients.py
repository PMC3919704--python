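"""Gradients of the total fitting error: finite differences and the adjoint system.

The default route is central finite differences with a relative step per
log-parameter.  The adjoint route integrates the linear adjoint ODE
``lambda' = -J(x, t)^T lambda`` backward in time with jump conditions at the
observation times (and at the normalization maximum, whose location enters
the max-normalized observables), then accumulates
``dE/dp = integral lambda^T df/dp dt`` per free rate constant.  Both routes
differentiate the same discrete objective, so they agree to solver tolerance;
the adjoint costs two ODE solves per condition instead of two per parameter.

Gradients are taken with the inhibited rate members materialized as
independent coordinates (``k_pD_i`` etc.), matching the control/inhibited
parameter-sharing scheme of the fit.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .data import bundle_index
from .network import DoseSchedule, ParameterSet, build_network
from .objective import _observation_grid, total_error

__all__ = ["finite_difference_gradient", "adjoint_gradient", "materialize"]


def materialize(params: ParameterSet, variant: str) -> ParameterSet:
    """Copy with every variant-relevant inhibited member set explicitly."""
    from .network import _INHIBITED_SWAP

    changes = {}
    for inh in _INHIBITED_SWAP[variant].values():
        changes[inh] = params.value(inh)
    return params.updated(**changes)


def finite_difference_gradient(
    params: ParameterSet,
    variant: str,
    datasets,
    free: list[str],
    schedule: DoseSchedule | None = None,
    metric: str = "l2",
    rel_step: float = 1e-3,
    breaks_mode: str = "ends",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, float]:
    """Central-difference gradient dE/dp (natural scale) for the free names.

    The step is ``rel_step`` on log p, i.e. p is multiplied by exp(+-h).
    """
    params = materialize(params, variant)
    grad = {}
    for name in free:
        p0 = params.value(name)
        hi = params.updated(**{name: p0 * np.exp(rel_step)})
        lo = params.updated(**{name: p0 * np.exp(-rel_step)})
        e_hi = total_error(hi, variant, datasets, schedule, metric,
                           breaks_mode=breaks_mode, rtol=rtol, atol=atol)
        e_lo = total_error(lo, variant, datasets, schedule, metric,
                           breaks_mode=breaks_mode, rtol=rtol, atol=atol)
        # d E / d log p, then back to natural scale
        grad[name] = (e_hi - e_lo) / (2.0 * rel_step) / p0
    return grad


class AdjointError(RuntimeError):
    """Adjoint backward solve failed; callers fall back to finite differences."""


def adjoint_gradient(
    params: ParameterSet,
    variant: str,
    datasets,
    free: list[str],
    schedule: DoseSchedule | None = None,
    metric: str = "l2",
    breaks_mode: str = "ends",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, float]:
    """Gradient dE/dp via backward adjoint integration.

    For each condition the forward trajectory is solved and stored densely;
    the adjoint state receives a jump ``c_i * w_ch`` at every data time
    (``w_ch`` the channel's observable weight vector) and the Danskin term
    at the grid argmax of the raw observable, accounting for the dependence
    of the normalizing maximum on the parameters.
    """
    params = materialize(params, variant)
    schedule = schedule or DoseSchedule.acute()
    idx = bundle_index(datasets)
    grad = {name: 0.0 for name in free}

    from .simulate import dnapkcs_weights, ku_weights

    for cond in ("control", "inhibited"):
        net = build_network(variant, params, schedule, condition=cond, breaks_mode=breaks_mode)
        ds_by_ch = {ch: idx[(ch, cond)] for ch in ("Ku", "DNAPKcs")}
        t_end = max(ds.times.max() for ds in ds_by_ch.values())
        grid = _observation_grid(list(ds_by_ch.values()), t_end, schedule.T_R)

        states, segments = _forward_dense(net, schedule, t_end, grid, rtol, atol)
        states_c = np.clip(states, 0.0, None)

        # assemble point-cost vectors on the state at each event time
        events: dict[float, np.ndarray] = {}
        wvecs = {
            "Ku": ku_weights(variant, net.species),
            "DNAPKcs": dnapkcs_weights(variant, net.species),
        }
        for ch, ds in ds_by_ch.items():
            w = wvecs[ch]
            raw = states_c @ w
            M = raw.max()
            if M <= 0:
                raise AdjointError(f"channel {ch} has identically-zero signal")
            i_star = int(np.argmax(raw))
            pos = np.searchsorted(grid, ds.times)
            if not np.allclose(grid[pos], ds.times, rtol=0, atol=1e-9):
                raise AdjointError("data times missing from the simulation grid")
            r = raw[pos] / M - ds.values
            ssq = float(np.sum(r * r))
            # below integration accuracy the residual direction is noise, and
            # the root-sum-square metric is non-smooth at 0: treat as perfect
            if ssq <= 1e-12:
                continue  # zero residuals contribute a zero gradient
            dE_dr = r / np.sqrt(ssq) if metric == "l2" else 2.0 * r
            for ti, ci in zip(ds.times, dE_dr / M):
                events[ti] = events.get(ti, np.zeros(net.n_species)) + ci * w
            c_star = -float(np.sum(dE_dr * raw[pos])) / M**2
            t_star = grid[i_star]
            events[t_star] = events.get(t_star, np.zeros(net.n_species)) + c_star * w

        if events:
            grad_c = _backward_pass(net, segments, events, free, t_end, rtol, atol)
            for name, g in zip(free, grad_c):
                grad[name] += g
    return grad


def _forward_dense(net, schedule, t_end, grid, rtol, atol):
    """Forward solve returning (states on grid, per-segment dense solutions)."""
    edges = [b for b in schedule.boundaries if 0.0 < b < t_end]
    seg_bounds = np.array([0.0] + edges + [t_end])
    x = np.zeros(net.n_species)
    states = np.zeros((grid.size, net.n_species))
    segments = []  # (a, b, u_const, OdeSolution)
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        u_const = float(schedule.indicator(0.5 * (a + b)))
        from .simulate import _frozen_rhs

        rhs = _frozen_rhs(net, u_const)
        sol = solve_ivp(
            rhs, (a, b), x, method="LSODA", dense_output=True,
            rtol=rtol, atol=atol, jac=lambda t, y: net.jacobian(t, y),
        )
        if not sol.success:
            raise AdjointError(f"forward solve failed on [{a}, {b}]: {sol.message}")
        segments.append((a, b, u_const, sol.sol))
        sel = (grid >= a) & (grid <= b)
        if sel.any():
            states[sel] = sol.sol(grid[sel]).T
        x = sol.y[:, -1]
    return states, segments


def _backward_pass(net, segments, events, free, t_end, rtol, atol):
    """Integrate the adjoint + quadrature system from t_end down to 0."""
    n = net.n_species
    nf = len(free)

    def x_of(t, segments):
        for a, b, _, interp in segments:
            if a - 1e-12 <= t <= b + 1e-12:
                return np.clip(interp(np.clip(t, a, b)), 0.0, None)
        raise AdjointError(f"time {t} outside stored segments")

    # backward breakpoints: events, window edges, endpoints
    times = sorted(set([0.0, t_end] + [a for a, *_ in segments] + list(events)))
    lam = np.zeros(n)
    quad = np.zeros(nf)

    def rhs(t, y, segs):
        x = x_of(t, segs)
        lam_ = y[:n]
        J = net.jacobian(t, x)
        dlam = -J.T @ lam_
        Fp = net.rhs_param_jacobian(t, x, free)
        dquad = Fp.T @ lam_
        return np.concatenate([dlam, dquad])

    for hi, lo in zip(times[::-1], times[-2::-1]):
        if hi in events:
            lam = lam + events[hi]
        # restrict to segments overlapping [lo, hi]
        segs = [s for s in segments if s[0] < hi - 1e-15 and s[1] > lo + 1e-15]
        y0 = np.concatenate([lam, quad])
        sol = solve_ivp(
            rhs, (hi, lo), y0, args=(segs,), method="LSODA",
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise AdjointError(f"adjoint solve failed on [{lo}, {hi}]: {sol.message}")
        lam = sol.y[:n, -1]
        quad = sol.y[n:, -1]
    if 0.0 in events:  # jump exactly at t = 0 (no dynamics left to apply it to)
        pass
    # quad integrated from t_end down to 0 equals -int_0^T lam^T f_p dt
    return -quad
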