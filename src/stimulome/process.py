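"""Fed-batch fermentation process metrics.

Implements the exponential feeding law F(t) = F0 · exp(μ_set · t), the
linear OD600 → cell-dry-weight conversion, CO2 yield per biomass formed,
the carbon fraction diverted to product, phase labelling, and an optional
detector for the batch → fed-batch switch (triggered in practice by a 50%
decline in the CO2 formation rate once glucose is exhausted).

Defaults follow a 0.25 L fed-batch cultivation of E. coli: F0 = 0.535 mL/h,
μ_set = 0.11 /h, and 0.34 g CDW per litre per OD600 unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_F0_ML_H = 0.535
DEFAULT_MU_SET_PER_H = 0.11
OD_TO_CDW_FACTOR = 0.34  # g/L CDW per OD600 unit

#: Default fermentation phase boundaries in hours of fed-batch process time:
#: I→II at the batch→fed-batch switch (0 h), II→III at 10 h, III→IV at 20 h.
DEFAULT_PHASE_BOUNDARIES_H = (0.0, 10.0, 20.0)
PHASE_LABELS = ("I", "II", "III", "IV")


@dataclass
class ProcessTimeSeries:
    """Fermentation time series: feed, biomass, off-gas and products.

    ``data`` holds at least ``time_h``; recognised columns are
    ``feed_mL_h``, ``od600``, ``cdw_g_L``, ``co2_mol_h``, and one column
    per product analyte (g/L). Time must be strictly increasing and all
    recognised columns non-negative.
    """

    data: pd.DataFrame
    volume_l: float = 0.25

    def __post_init__(self):
        if "time_h" not in self.data.columns:
            raise ValueError("ProcessTimeSeries requires a time_h column")
        t = self.data["time_h"].to_numpy(float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("time_h must be strictly increasing")
        for col in self.data.columns:
            if col == "time_h":
                continue
            if (self.data[col].to_numpy(float) < -1e-12).any():
                raise ValueError(f"negative values in column {col!r}")

    @property
    def time_h(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, volume_l: float = 0.25) -> "ProcessTimeSeries":
        return cls(pd.read_csv(path), volume_l=volume_l)


def feed_rate(t, F0: float = DEFAULT_F0_ML_H, mu_set: float = DEFAULT_MU_SET_PER_H):
    """Exponential feed rate F(t) = F0 · exp(μ_set · t), in mL/h.

    ``t`` is process time in hours (scalar or array), non-negative.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("process time must be non-negative")
    if F0 <= 0:
        raise ValueError("F0 must be positive")
    out = F0 * np.exp(mu_set * t)
    return float(out) if out.ndim == 0 else out


def od_to_cdw(od600, factor: float = OD_TO_CDW_FACTOR):
    """OD600 → cell dry weight (g/L) via a linear correlation factor."""
    od600 = np.asarray(od600, dtype=float)
    if (od600 < 0).any():
        raise ValueError("OD600 must be non-negative")
    out = od600 * factor
    return float(out) if out.ndim == 0 else out


def co2_yield_per_biomass(
    series: ProcessTimeSeries, window: tuple[float, float]
) -> float:
    """Mol CO2 produced per gram of biomass formed over a time window.

    Integrates the CO2 formation rate (trapezoid rule) over ``window``
    and divides by the biomass formed, ΔCDW · culture volume. Biomass
    must increase over the window.
    """
    t0, t1 = window
    t = series.time_h
    if t0 < t[0] or t1 > t[-1] or t1 <= t0:
        raise ValueError("window must lie within the series and be non-empty")
    mask = (t >= t0) & (t <= t1)
    tw = t[mask]
    co2 = series.data.loc[mask, "co2_mol_h"].to_numpy(float)
    cdw = series.data.loc[mask, "cdw_g_L"].to_numpy(float)
    d_biomass_g = (cdw[-1] - cdw[0]) * series.volume_l
    if d_biomass_g <= 0:
        raise ValueError("biomass must increase over the window")
    return float(np.trapezoid(co2, tw) / d_biomass_g)


def carbon_fraction_to_product(
    product_carbon_flux: float, glucose_carbon_uptake: float
) -> float:
    """Fraction of glucose carbon uptake ending up in product (mol C basis)."""
    if glucose_carbon_uptake <= 0:
        raise ValueError("glucose carbon uptake must be positive")
    if product_carbon_flux < 0:
        raise ValueError("product carbon flux must be non-negative")
    return float(product_carbon_flux / glucose_carbon_uptake)


def assign_phases(
    series: ProcessTimeSeries,
    boundaries_h: tuple[float, ...] = DEFAULT_PHASE_BOUNDARIES_H,
) -> pd.Series:
    """Label each time point with a fermentation phase (I–IV by default).

    Phase boundaries are configuration, not detected: the phase structure
    of a fed-batch run is inferred from multiple process signals and is
    supplied by the analyst.
    """
    labels = PHASE_LABELS[: len(boundaries_h) + 1]
    idx = np.searchsorted(np.asarray(boundaries_h, float), series.time_h, side="right")
    return pd.Series([labels[i] for i in idx], index=series.data.index, name="phase")


def detect_fedbatch_start(
    series: ProcessTimeSeries,
    decline_fraction: float = 0.5,
    smooth_points: int = 3,
) -> float | None:
    """Time at which the smoothed CO2 rate first drops below a fraction
    of its running maximum — the trigger used to switch from batch to
    fed-batch feeding when glucose runs out.

    Returns None if no such decline occurs. The smoothing window (in
    points of the series) is configurable because the appropriate value
    depends on the sampling interval of the off-gas analyser.
    """
    co2 = (
        series.data["co2_mol_h"]
        .rolling(smooth_points, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    running_max = np.maximum.accumulate(co2)
    below = co2 < decline_fraction * running_max
    hits = np.nonzero(below)[0]
    if len(hits) == 0:
        return None
    return float(series.time_h[hits[0]])
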