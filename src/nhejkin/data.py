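"""Observed fluorescence kinetics: the dataset container and its CSV dialect.

A bundle is the four curves the fitting stage needs: {Ku80-EGFP,
DNA-PKcs-YFP} x {control, ATM-inhibited}, each a set of (time, normalized
intensity) points.  Times are stored on the model clock (experiment clock
shifted by the irradiation time T_R, because experimental time zero is
recorded immediately after irradiation ends).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["KineticDataset", "CHANNELS", "CONDITIONS", "read_bundle_csv", "write_bundle_csv", "bundle_index"]

CHANNELS = ("Ku", "DNAPKcs")
CONDITIONS = ("control", "inhibited")

#: tolerated overshoot of normalized intensity above 1 due to noise
MAX_INTENSITY_ALLOWANCE = 0.25


@dataclass
class KineticDataset:
    """One channel x condition fluorescence time series.

    ``times`` are minutes on the model clock (already includes the +T_R
    shift), strictly increasing, N >= 2.  ``values`` are max-normalized
    intensities in [0, ~1.2].  ``provenance`` records where the points came
    from (synthetic seed + generating parameters, or a source file).
    """

    channel: str
    condition: str
    times: np.ndarray
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.values.size:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("a kinetic dataset needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            bad = int(np.argmax(np.diff(self.times) <= 0)) + 1
            raise ValueError(f"times must be strictly increasing (violated at row {bad})")
        if np.any(self.values < 0):
            raise ValueError("normalized intensities must be non-negative")
        if self.values.max() > 1.0 + MAX_INTENSITY_ALLOWANCE:
            raise ValueError(
                f"normalized intensity {self.values.max():.3f} exceeds 1 + allowance "
                f"({MAX_INTENSITY_ALLOWANCE})"
            )

    @property
    def n(self) -> int:
        return self.times.size

    def key(self) -> tuple[str, str]:
        return (self.channel, self.condition)


def bundle_index(datasets) -> dict[tuple[str, str], KineticDataset]:
    """Index a bundle by (channel, condition); reject missing quadrants."""
    idx = {ds.key(): ds for ds in datasets}
    missing = [
        (ch, co) for ch in CHANNELS for co in CONDITIONS if (ch, co) not in idx
    ]
    if missing:
        raise ValueError(f"bundle is missing dataset quadrant(s): {missing}")
    return idx


def write_bundle_csv(path, datasets, T_R: float = 0.5, extra_meta: dict | None = None) -> None:
    """Write datasets to the bundle CSV dialect.

    Header comment lines (``# key: value``) carry metadata; the table has
    columns time_min, intensity, channel, condition.  Times are written on
    the model clock, declared by ``time_origin: absolute``.
    """
    frames = []
    for ds in datasets:
        frames.append(
            pd.DataFrame(
                {
                    "time_min": ds.times,
                    "intensity": ds.values,
                    "channel": ds.channel,
                    "condition": ds.condition,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    meta = {"time_origin": "absolute", "T_R": T_R}
    meta.update(extra_meta or {})
    buf = io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}: {v}\n")
    table.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_bundle_csv(path) -> list[KineticDataset]:
    """Read a bundle CSV; applies the +T_R shift for post-irradiation clocks.

    A file declaring ``time_origin: post_irradiation`` stores experimental
    times (zero at the end of irradiation); its times are shifted by the
    declared T_R onto the model clock.  ``absolute`` times are used as-is.
    """
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                k, v = line.lstrip("#").split(":", 1)
                meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    table = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    required = {"time_min", "intensity", "channel", "condition"}
    if not required.issubset(table.columns):
        raise ValueError(f"bundle CSV must have columns {sorted(required)}")

    origin = meta.get("time_origin", "absolute")
    if origin not in ("absolute", "post_irradiation"):
        raise ValueError(f"unknown time_origin {origin!r}")
    shift = float(meta.get("T_R", 0.5)) if origin == "post_irradiation" else 0.0

    datasets = []
    for (ch, co), grp in table.groupby(["channel", "condition"], sort=False):
        grp = grp.reset_index(drop=True)
        t = grp["time_min"].to_numpy(dtype=float) + shift
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(
                f"non-monotone times in channel {ch!r} condition {co!r} at row {row}"
            )
        prov = {"source": str(path), **{k: v for k, v in meta.items() if k not in ("time_origin",)}}
        datasets.append(KineticDataset(ch, co, t, grp["intensity"].to_numpy(dtype=float), prov))
    return datasets
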