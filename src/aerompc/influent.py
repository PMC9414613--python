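"""Synthetic diurnal influent generator.

Municipal inflow and pollutant loads follow a strong 24-h cycle: low at
night, peaking mid-morning.  The generator produces seeded, reproducible
time series of flow and concentrations that stay inside configured bounds
representative of a medium-size plant (design inflow 10,000-35,000 m^3/d,
COD 400-650 mg/L, total nitrogen 40-65 mg/L).

The deterministic component is a unit-amplitude diurnal shape (cosine with
an optional second harmonic for an evening peak) mapped onto each range;
truncated multiplicative Gaussian noise is added on top and the result is
clipped back into the range, so bound containment holds for every record.

Only a share of total nitrogen enters as ammonium (the rest is organic N
outside the reduced model); SNH_in = 0.7 * TN by default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import InfluentRecord

CSV_COLUMNS = ["t_days", "Qin", "XCOD_in", "SNH_in", "XBH_in"]

#: ammonium share of influent total nitrogen
SNH_FRACTION_OF_TN = 0.7


@dataclass(frozen=True)
class InfluentProfileConfig:
    duration: float = 7.0            # days
    step: float = 1.0 / 96.0         # days (15 min)
    Qin_range: tuple = (10_000.0, 35_000.0)   # m^3/day
    COD_range: tuple = (400.0, 650.0)         # g/m^3
    N_range: tuple = (40.0, 65.0)             # g/m^3 total nitrogen
    BOD_range: tuple = (175.0, 225.0)         # g/m^3, recorded but unused
    XBHin_mean: float = 30.0                  # g/m^3
    noise_sd: float = 0.05           # fractional noise amplitude
    seed: int = 0
    peak_time: float = 10.5 / 24.0   # diurnal peak (fraction of day)
    second_harmonic: float = 0.0     # evening-peak amplitude, 0 disables

    def __post_init__(self):
        for name in ("Qin_range", "COD_range", "N_range", "BOD_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy low < high")
        n = self.step and (1.0 / self.step)
        if self.step <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("step must divide one day evenly")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


class InfluentSeries:
    """Time-indexed influent records backed by a DataFrame."""

    def __init__(self, frame: pd.DataFrame):
        missing = set(CSV_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"influent table missing columns {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, k: int) -> InfluentRecord:
        row = self.frame.iloc[k]
        return InfluentRecord(t=row.t_days, Qin=row.Qin, XCOD_in=row.XCOD_in,
                              SNH_in=row.SNH_in, XBH_in=row.XBH_in)

    def at_time(self, t: float) -> InfluentRecord:
        """Record in force at time t (zero-order hold on the step grid)."""
        tt = self.frame.t_days.values
        k = int(np.clip(np.searchsorted(tt, t + 1e-12) - 1, 0, len(tt) - 1))
        return self[k]

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path,
                 cfg: InfluentProfileConfig | None = None) -> "InfluentSeries":
        frame = pd.read_csv(path)
        series = cls(frame)
        if cfg is not None:
            _check_bounds(series.frame, cfg)
        return series


def _check_bounds(frame: pd.DataFrame, cfg: InfluentProfileConfig) -> None:
    checks = [("Qin", cfg.Qin_range), ("XCOD_in", cfg.COD_range)]
    snh_lo = cfg.N_range[0] * SNH_FRACTION_OF_TN
    snh_hi = cfg.N_range[1] * SNH_FRACTION_OF_TN
    checks.append(("SNH_in", (snh_lo, snh_hi)))
    for col, (lo, hi) in checks:
        v = frame[col].values
        if v.min() < lo - 1e-9 or v.max() > hi + 1e-9:
            raise ValueError(f"influent column {col} outside [{lo}, {hi}]")


def diurnal_shape(t: np.ndarray, cfg: InfluentProfileConfig) -> np.ndarray:
    """Deterministic unit-amplitude diurnal pattern, 24-h periodic.

    Normalized to attain -1 and +1 so that range endpoints are reached
    when noise is disabled; the maximum sits at ``cfg.peak_time``.
    """
    t = np.asarray(t, dtype=float)
    base = np.cos(2 * np.pi * (t - cfg.peak_time))
    if cfg.second_harmonic:
        base = base + cfg.second_harmonic * np.cos(
            4 * np.pi * (t - cfg.peak_time - 0.375))
        grid = np.linspace(0, 1, 2001)
        ref = np.cos(2 * np.pi * (grid - cfg.peak_time)) + \
            cfg.second_harmonic * np.cos(4 * np.pi * (grid - cfg.peak_time - 0.375))
        base = -1.0 + 2.0 * (base - ref.min()) / (ref.max() - ref.min())
    return base


def generate(cfg: InfluentProfileConfig) -> InfluentSeries:
    """Generate a seeded diurnal influent series within the configured bounds."""
    n = int(round(cfg.duration / cfg.step))
    t = np.arange(n) * cfg.step
    shape = diurnal_shape(t, cfg)
    rng = np.random.default_rng(cfg.seed)

    def channel(lo: float, hi: float) -> np.ndarray:
        mid, amp = 0.5 * (lo + hi), 0.5 * (hi - lo)
        base = mid + amp * shape
        if cfg.noise_sd > 0:
            noise = np.clip(rng.standard_normal(n), -3.0, 3.0)
            base = base * (1.0 + cfg.noise_sd * noise)
        return np.clip(base, lo, hi)

    qin = channel(*cfg.Qin_range)
    cod = channel(*cfg.COD_range)
    tn = channel(*cfg.N_range)
    xbh = cfg.XBHin_mean * (1.0 + 0.2 * shape)
    if cfg.noise_sd > 0:
        xbh = xbh * (1.0 + cfg.noise_sd *
                     np.clip(rng.standard_normal(n), -3.0, 3.0))
    xbh = np.maximum(xbh, 0.0)

    frame = pd.DataFrame({
        "t_days": t,
        "Qin": qin,
        "XCOD_in": cod,
        "SNH_in": SNH_FRACTION_OF_TN * tn,
        "XBH_in": xbh,
    })
    return InfluentSeries(frame)


def config_to_dict(cfg: InfluentProfileConfig) -> dict:
    d = asdict(cfg)
    for key in ("Qin_range", "COD_range", "N_range", "BOD_range"):
        d[key] = list(d[key])
    return d


def config_from_dict(d: dict) -> InfluentProfileConfig:
    d = dict(d)
    for key in ("Qin_range", "COD_range", "N_range", "BOD_range"):
        if key in d:
            d[key] = tuple(d[key])
    return InfluentProfileConfig(**d)
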