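"""Media background correction and OD-to-relative-cell-density calibration.

Blank (media-only) wells drift slightly over a long plate-reader run, in both
absorbance and fluorescence. Each channel's pooled media signal is fitted with
a squared-exponential GP — per-point noise estimated from the 10 nearest
points in time, falling back to a single learned constant noise if the
heteroscedastic fit fails to converge — and the posterior-mean baseline is
subtracted from every cell-containing well.

Absorbance is only proportional to cell density at low density. A doubling
dilution series of a dense culture (known relative densities, measured ODs)
calibrates a monotone map OD -> relative density, fitted with a
squared-exponential + linear GP; the undiluted sample defines relative
density 1.0. Sampling calibration curves from this posterior propagates the
calibration uncertainty into the final per-cell error bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CalibrationError, FitError, LayoutError, NumericalError
from .gp import (
    GPPosterior,
    Linear,
    SquaredExponential,
    empirical_noise,
    gp_fit,
    gp_predict,
    gp_sample,
)
from .plate import PlateDataset, WellTimeSeries

#: Window (points) for the nearest-neighbour noise estimate on media wells.
MEDIA_NOISE_K = 10

_CHANNELS = ("od", "f525", "f585")


@dataclass
class MediaCorrection:
    """Per-channel GP baselines fitted to the pooled media wells."""

    od_baseline: GPPosterior
    f525_baseline: GPPosterior
    f585_baseline: GPPosterior
    mode_used: dict[str, str] = field(default_factory=dict)

    def baseline(self, channel: str) -> GPPosterior:
        return getattr(self, f"{channel}_baseline")


def _fit_channel(t_pool: np.ndarray, y_pool: np.ndarray, seed: int):
    """Heteroscedastic squared-exponential fit, constant-noise fallback."""
    k = min(MEDIA_NOISE_K, len(y_pool))
    try:
        noise = empirical_noise(t_pool, y_pool, k=k)
        post = gp_fit(t_pool, y_pool, noise, SquaredExponential(), seed=seed)
        return post, "heteroscedastic"
    except (FitError, NumericalError):
        post = gp_fit(t_pool, y_pool, "learn", SquaredExponential(), seed=seed)
        return post, "constant_noise"


def fit_media(dataset: PlateDataset, seed: int = 0) -> MediaCorrection:
    """Fit GP baselines to each channel of the pooled media wells."""
    media = dataset.wells_by_role("media")
    if not media:
        raise LayoutError("no media wells in layout; cannot fit background")
    posts: dict[str, GPPosterior] = {}
    modes: dict[str, str] = {}
    for channel in _CHANNELS:
        t_pool = np.concatenate([w.times for w in media])
        y_pool = np.concatenate([getattr(w, channel) for w in media])
        order = np.argsort(t_pool, kind="stable")
        posts[channel], modes[channel] = _fit_channel(
            t_pool[order], y_pool[order], seed=seed
        )
    return MediaCorrection(
        od_baseline=posts["od"],
        f525_baseline=posts["f525"],
        f585_baseline=posts["f585"],
        mode_used=modes,
    )


def apply_media_correction(
    dataset: PlateDataset, mc: MediaCorrection
) -> tuple[PlateDataset, pd.DataFrame]:
    """Subtract the media baselines from every cell well.

    The posterior-mean baseline of each channel is evaluated on the shared
    time grid and subtracted from all non-media wells; media wells are dropped
    from the result. Corrected values may be negative (never clipped); the
    returned QC table counts negatives per well and channel.
    """
    times = dataset.times
    baselines = {ch: gp_predict(mc.baseline(ch), times)[0] for ch in _CHANNELS}
    corrected: dict[str, WellTimeSeries] = {}
    qc_rows = []
    for wid in sorted(dataset.wells):
        if dataset.layout[wid].role == "media":
            continue
        w = dataset.wells[wid]
        vals = {ch: getattr(w, ch) - baselines[ch] for ch in _CHANNELS}
        corrected[wid] = WellTimeSeries(well_id=wid, times=w.times, **vals)
        for ch in _CHANNELS:
            qc_rows.append(
                {
                    "well": wid,
                    "channel": ch,
                    "n_negative_after_correction": int(np.sum(vals[ch] < 0)),
                }
            )
    layout = {w: a for w, a in dataset.layout.items() if w in corrected}
    meta = dict(dataset.meta)
    meta["media_corrected"] = True
    out = PlateDataset(wells=corrected, layout=layout, meta=meta)
    return out, pd.DataFrame(qc_rows)


@dataclass
class ODCalibration:
    """Monotone map from measured OD to relative cell density.

    ``absolute_anchor`` optionally records (relative density, cells/mL) from an
    independent absolute count (e.g. hemocytometer); it is metadata only.
    """

    gp: Optional[GPPosterior]
    od_range: tuple[float, float]
    absolute_anchor: Optional[tuple[float, float]] = None
    identity: bool = False

    def in_range(self, od: np.ndarray) -> np.ndarray:
        lo, hi = self.od_range
        return (od >= lo) & (od <= hi)


def identity_calibration(od_range=(0.0, np.inf)) -> ODCalibration:
    """Density = OD passthrough, for runs without a dilution series."""
    return ODCalibration(gp=None, od_range=od_range, identity=True)


def fit_od_calibration(
    measured_od,
    dilution_factor,
    seed: int = 0,
    absolute_anchor: Optional[tuple[float, float]] = None,
) -> ODCalibration:
    """Fit the OD -> relative density map from a dilution series.

    Relative density is 1/dilution_factor, normalized so the most concentrated
    sample sits at 1.0. The GP kernel is squared-exponential + linear; the
    linear component keeps extrapolation sane. Noise is treated as a learned
    multiple of the relative density (dilution error is multiplicative on OD,
    and densities are known exactly, so the density-equivalent error scales
    with density). The posterior-mean map must be non-decreasing on a
    200-point grid over the calibration range.
    """
    od = np.asarray(measured_od, dtype=float)
    factor = np.asarray(dilution_factor, dtype=float)
    if len(od) != len(factor):
        raise ValueError("measured_od and dilution_factor must have equal length")
    if len(od) < 4:
        raise ValueError(f"need >= 4 dilution points, got {len(od)}")
    if np.any(factor <= 0):
        raise ValueError("dilution factors must be positive")

    density = (1.0 / factor) / np.max(1.0 / factor)
    order = np.argsort(od, kind="stable")
    od, density = od[order], density[order]

    gp = gp_fit(
        od,
        density,
        ("learn_scaled", density),
        SquaredExponential() + Linear(),
        seed=seed,
    )
    od_range = (float(od.min()), float(od.max()))
    grid = np.linspace(*od_range, 200)
    mean, _ = gp_predict(gp, grid)
    if np.any(np.diff(mean) < -1e-9 * max(1.0, np.max(np.abs(mean)))):
        raise CalibrationError(
            "calibration posterior mean is not monotone non-decreasing over the "
            "OD range; collect more dilution points or narrow the range"
        )
    return ODCalibration(gp=gp, od_range=od_range, absolute_anchor=absolute_anchor)


def correct_od(
    cal: ODCalibration, od
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map measured ODs to relative density (mean, sd, extrapolation flags)."""
    od = np.atleast_1d(np.asarray(od, dtype=float))
    extrapolated = ~cal.in_range(od)
    if cal.identity:
        return od.copy(), np.zeros_like(od), extrapolated
    mean, sd = gp_predict(cal.gp, od)
    return mean, sd, extrapolated


def sample_od_correction(cal: ODCalibration, od, n: int, seed) -> np.ndarray:
    """Joint samples of the calibration map at the given ODs; shape (n, len(od))."""
    od = np.atleast_1d(np.asarray(od, dtype=float))
    if cal.identity:
        return np.tile(od, (n, 1))
    return gp_sample(cal.gp, od, n, seed)
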