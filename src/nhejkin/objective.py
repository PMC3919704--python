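"""Error functions comparing simulated observables with measured kinetics.

Per channel the misfit is the discrete L2 norm of the residuals between the
max-normalized model curve and the data points (a plain sum-of-squares
"least-squares" variant is selectable).  The total error sums the four
channel errors: control curves are simulated with the control rates and
ATM-inhibited curves with the ``_i`` rates, all other parameters shared —
this is the parameter-sharing scheme under which ATM inhibition is fitted
by freeing only the inhibited rates.
"""

from __future__ import annotations

import numpy as np

from .data import CONDITIONS, KineticDataset, bundle_index
from .network import DoseSchedule, ParameterSet, build_network
from .simulate import Trajectory, default_grid, integrate

__all__ = ["channel_error", "total_error", "error_components", "simulate_conditions"]

METRICS = ("l2", "lsq")


def channel_error(traj: Trajectory, ds: KineticDataset, metric: str = "l2") -> float:
    """Misfit of one channel: sqrt(sum r_i^2) ("l2") or sum r_i^2 ("lsq").

    The model curve (K_hat or D_hat by ``ds.channel``) is interpolated
    linearly from the trajectory grid onto the data times, which must lie
    inside the grid span.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    model = traj.interp(ds.channel, ds.times, normalized=True)
    ssq = float(np.sum((model - ds.values) ** 2))
    return np.sqrt(ssq) if metric == "l2" else ssq


def _observation_grid(datasets, t_end: float, T_R: float) -> np.ndarray:
    grid = default_grid(t_end, T_R)
    all_times = np.concatenate([ds.times for ds in datasets])
    return np.union1d(grid, all_times)


def simulate_conditions(
    params: ParameterSet,
    variant: str,
    datasets,
    schedule: DoseSchedule | None = None,
    breaks_mode: str = "ends",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, Trajectory]:
    """Integrate the control and inhibited trajectories covering the data span.

    The output grid is the dense simulation grid unioned with every data
    time, so interpolation onto data times is exact at grid nodes.
    """
    idx = bundle_index(datasets)
    schedule = schedule or DoseSchedule.acute()
    out = {}
    for cond in CONDITIONS:
        ds_cond = [idx[(ch, cond)] for ch in ("Ku", "DNAPKcs")]
        t_end = max(ds.times.max() for ds in ds_cond)
        grid = _observation_grid(ds_cond, t_end, schedule.T_R)
        net = build_network(variant, params, schedule, condition=cond, breaks_mode=breaks_mode)
        out[cond] = integrate(net, schedule, t_end, grid, rtol=rtol, atol=atol)
    return out


def error_components(
    params: ParameterSet,
    variant: str,
    datasets,
    schedule: DoseSchedule | None = None,
    metric: str = "l2",
    weights: dict | None = None,
    breaks_mode: str = "ends",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, float]:
    """Per-quadrant errors {E_K, E_D, E_K_i, E_D_i} plus their sum ``E``.

    ``weights`` optionally rescales quadrants by (channel, condition) key;
    the default leaves the raw norms unweighted (unequal point counts are
    not compensated).
    """
    idx = bundle_index(datasets)
    trajs = simulate_conditions(params, variant, datasets, schedule, breaks_mode, rtol, atol)
    comp = {}
    for (ch, cond), ds in idx.items():
        w = 1.0 if weights is None else float(weights.get((ch, cond), 1.0))
        label = ("E_K" if ch == "Ku" else "E_D") + ("_i" if cond == "inhibited" else "")
        comp[label] = w * channel_error(trajs[cond], ds, metric)
    comp["E"] = comp["E_K"] + comp["E_D"] + comp["E_K_i"] + comp["E_D_i"]
    return comp


def total_error(
    params: ParameterSet,
    variant: str,
    datasets,
    schedule: DoseSchedule | None = None,
    metric: str = "l2",
    weights: dict | None = None,
    breaks_mode: str = "ends",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Total misfit E = E_K + E_D + E_K^i + E_D^i over a 4-quadrant bundle."""
    return error_components(
        params, variant, datasets, schedule, metric, weights, breaks_mode, rtol, atol
    )["E"]
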