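"""Spectral unmixing of reporter fluorescence from cellular autofluorescence.

Each fluorescence reading is modelled as a linear sum of reporter signal g and
autofluorescence a. With two emission channels (525 and 585 nm, excitation
485 nm) the tagged strain gives

    f525 = g + a
    f585 = rg * g + ra * a

where rg is the reporter's spectral constant (EGFP ~ 0.114) and ra is the
autofluorescence emission ratio, which drifts with the physiological state of
the culture and is therefore modelled as a smooth function of OD, estimated
from untagged (wild-type) wells:

    ra(OD) = f585_WT / f525_WT.

Inverting the two equations gives the reporter signal

    g = (ra * f525 - f585) / (ra - rg),

which divided by relative cell density is the mean fluorescence per cell.

Two point-estimate routes live here: the direct approach (ratio averaging,
local-regression smoothing, algebraic inversion — fast, no error bars) and
the naive per-cell subtraction used for bacterial promoter libraries, kept as
a comparison baseline because it assumes equal autofluorescence per cell and
equal growth and goes systematically negative in yeast when those fail. The
fully Bayesian route with error bars is in :mod:`platemix.bayes`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .errors import EstimationError, LayoutError
from .gp import (
    GPPosterior,
    NeuralNetwork,
    SquaredExponential,
    empirical_noise,
    gp_fit,
    gp_predict,
    gp_sample,
)
from .plate import PlateDataset, UnmixingConstants
from .preprocessing import ODCalibration, correct_od

#: Window (points along OD) for the wild-type ratio noise estimate.
RA_NOISE_K = 20

#: Below this |ra - rg| the two-channel inversion is ill-conditioned.
ILL_CONDITIONED_GAP = 1e-6


# --------------------------------------------------------------------------
# Local quadratic regression (rloess)
# --------------------------------------------------------------------------

def loess_smooth(
    x, y, span: float = 0.15, degree: int = 2, robust_iter: int = 2
) -> np.ndarray:
    """Robust local polynomial regression with tricube weights.

    At each point the ``span`` fraction of nearest neighbours is fitted with a
    weighted degree-``degree`` polynomial; ``robust_iter`` bisquare
    reweighting passes damp outliers. Matches the classic "rloess" smoother.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    robust_w = np.ones(n)
    fitted = y.copy()
    for iteration in range(robust_iter + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            idx = np.argsort(d, kind="stable")[:k]
            dmax = d[idx].max()
            if dmax == 0:
                fitted[i] = np.average(y[idx], weights=robust_w[idx])
                continue
            w = (1 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 0, None) * robust_w[idx]
            if w.sum() <= 0:
                w = np.ones_like(w)
            coef = np.polynomial.polynomial.polyfit(
                x[idx] - x[i], y[idx], deg=degree, w=np.sqrt(w)
            )
            fitted[i] = coef[0]
        if iteration < robust_iter:
            resid = y - fitted
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            robust_w = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return fitted


# --------------------------------------------------------------------------
# r_a(OD) estimation from wild-type wells
# --------------------------------------------------------------------------

@dataclass
class RaCurve:
    """GP posterior of the autofluorescence emission ratio versus OD.

    ``gp`` is the neural-network-kernel fit of the wild-type f585/f525 ratio
    against media-corrected OD; ``noise_interp`` is a squared-exponential GP
    of the empirical per-point measurement error, so the expected ratio error
    can be interpolated to the tagged strain's ODs.
    """

    gp: GPPosterior
    noise_interp: GPPosterior
    od_support: tuple[float, float]


def fit_ra(
    dataset: PlateDataset, seed: int = 0, noise_k: int = RA_NOISE_K
) -> RaCurve:
    """Estimate ra(OD) from the media-corrected wild-type wells.

    Pools pointwise f585/f525 ratios of every wild-type well, orders them by
    media-corrected OD, estimates the per-point measurement error from the
    ``noise_k`` nearest points along OD, and fits the neural-network-kernel GP
    (sigmoid-like prior samples). The error magnitudes themselves are fitted
    against OD with a squared-exponential GP for later interpolation.
    Points with non-positive f525 are excluded with a warning.
    """
    wt = dataset.wells_by_role("wildtype")
    if not wt:
        raise LayoutError("no wildtype wells in layout; cannot estimate ra(OD)")
    od_all = np.concatenate([w.od for w in wt])
    f525 = np.concatenate([w.f525 for w in wt])
    f585 = np.concatenate([w.f585 for w in wt])
    usable = f525 > 0
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        warnings.warn(
            f"fit_ra: excluded {n_dropped} wild-type points with f525 <= 0 "
            "after media correction",
            stacklevel=2,
        )
    if not np.any(usable):
        raise EstimationError("all wild-type points have f525 <= 0; cannot fit ra")
    od_all, ratio = od_all[usable], f585[usable] / f525[usable]
    order = np.argsort(od_all, kind="stable")
    od_all, ratio = od_all[order], ratio[order]

    k = min(noise_k, len(ratio))
    noise = empirical_noise(od_all, ratio, k=k)
    gp = gp_fit(od_all, ratio, noise, NeuralNetwork(), seed=seed)
    noise_gp = gp_fit(od_all, noise, "learn", SquaredExponential(), seed=seed)
    return RaCurve(
        gp=gp,
        noise_interp=noise_gp,
        od_support=(float(od_all.min()), float(od_all.max())),
    )


def ra_at(
    ra: RaCurve, od, n_samples: int, seed
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the ra posterior at the tagged strain's ODs.

    Returns (posterior mean, ``n_samples`` joint posterior function draws of
    shape (n_samples, len(od)), interpolated measurement-error sd, and a
    boolean extrapolation flag for ODs outside the wild-type support).
    """
    od = np.atleast_1d(np.asarray(od, dtype=float))
    mean, _ = gp_predict(ra.gp, od)
    samples = gp_sample(ra.gp, od, n_samples, seed)
    noise_sd, _ = gp_predict(ra.noise_interp, od)
    noise_sd = np.maximum(noise_sd, 1e-12)
    lo, hi = ra.od_support
    extrapolated = (od < lo) | (od > hi)
    return mean, samples, noise_sd, extrapolated


# --------------------------------------------------------------------------
# Point-estimate unmixing
# --------------------------------------------------------------------------

def direct_unmix(f525, f585, ra, rg) -> np.ndarray | float:
    """Solve the two-channel linear model for the reporter signal g.

    g = (ra*f525 - f585)/(ra - rg). Negative results are legitimate noise
    excursions and are reported, not clipped.
    """
    ra_arr = np.asarray(ra, dtype=float)
    rg_arr = np.asarray(rg, dtype=float)
    if np.any(np.abs(ra_arr - rg_arr) < ILL_CONDITIONED_GAP):
        raise ValueError(
            "ra is within 1e-6 of rg: the unmixing system is ill-conditioned"
        )
    out = (ra_arr * np.asarray(f525, float) - np.asarray(f585, float)) / (
        ra_arr - rg_arr
    )
    return out if out.ndim else float(out)


@dataclass
class FluorescenceEstimate:
    """Per-time-point reporter signal and per-cell fluorescence for one group."""

    times: np.ndarray
    g_mean: np.ndarray
    g_sd: np.ndarray
    per_cell_mean: np.ndarray
    per_cell_sd: np.ndarray
    method: str
    strain: str = ""
    condition: str = ""
    replicate_group: str = ""
    n_replicates: int = 1
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def _wildtype_od_ra_tables(dataset: PlateDataset, smooth: bool):
    """Replicate-averaged wild-type ratio and monotone smoothed OD vs time."""
    wt = dataset.wells_by_role("wildtype")
    if not wt:
        raise LayoutError("no wildtype wells in layout")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.vstack([w.f585 / w.f525 for w in wt])
    ra_t = np.nanmean(ratios, axis=0)
    od_avg = np.mean(np.vstack([w.od for w in wt]), axis=0)
    times = dataset.times
    od_sm = loess_smooth(times, od_avg) if smooth else od_avg
    # growth can plateau or dip late; project onto the nearest monotone curve
    od_mono = IsotonicRegression(increasing=True).fit_transform(times, od_sm)
    return times, ra_t, od_mono


def direct_pipeline(
    dataset: PlateDataset,
    cal: ODCalibration,
    constants: UnmixingConstants = UnmixingConstants(),
    smooth: bool = True,
) -> list[FluorescenceEstimate]:
    """Direct (non-Bayesian) unmixing of every tagged replicate group.

    Per time point the wild-type ratio f585/f525 is averaged over replicates;
    the replicate-averaged wild-type OD is smoothed by local quadratic
    regression and made monotone, giving an OD -> ra lookup. Tagged ODs are
    mapped through that lookup (clamped, with a flag, beyond the wild-type OD
    range), g is unmixed per replicate, averaged, smoothed, and divided by the
    calibrated relative cell density. No error bars — ``g_sd`` is NaN.
    """
    times, ra_t, od_mono = _wildtype_od_ra_tables(dataset, smooth)
    results = []
    for group, well_ids in dataset.replicate_groups("tagged").items():
        wells = [dataset.wells[w] for w in well_ids]
        od_tag = np.mean(np.vstack([w.od for w in wells]), axis=0)
        out_of_range = (od_tag < od_mono.min()) | (od_tag > od_mono.max())
        g_reps = []
        for w in wells:
            ra_w = np.interp(w.od, od_mono, ra_t)
            g_reps.append(direct_unmix(w.f525, w.f585, ra_w, constants.rg))
        g_mean = np.mean(np.vstack(g_reps), axis=0)
        if smooth:
            g_mean = loess_smooth(times, g_mean)
        density, _, extrapolated_od = correct_od(cal, od_tag)
        per_cell = g_mean / density
        ann = dataset.layout[well_ids[0]]
        nan = np.full_like(per_cell, np.nan)
        results.append(
            FluorescenceEstimate(
                times=times,
                g_mean=g_mean,
                g_sd=nan.copy(),
                per_cell_mean=per_cell,
                per_cell_sd=nan.copy(),
                method="direct",
                strain=ann.strain,
                condition=ann.condition,
                replicate_group=group,
                n_replicates=len(wells),
                flags={
                    "negative_estimate": g_mean < 0,
                    "extrapolated_ra": out_of_range,
                    "extrapolated_od": extrapolated_od,
                },
            )
        )
    return results


def subtraction_baseline(
    dataset: PlateDataset,
    cal: ODCalibration,
) -> list[FluorescenceEstimate]:
    """Per-cell subtraction method used for bacterial promoter libraries.

    per_cell(t) = f525_tagged/density_tagged - mean_WT(f525_WT/density_WT),
    with densities from the OD calibration. Valid only when tagged and
    wild-type strains share growth curves and per-cell autofluorescence;
    provided for comparison plots and tests.
    """
    wt = dataset.wells_by_role("wildtype")
    if not wt:
        raise LayoutError("no wildtype wells in layout")
    times = dataset.times

    def per_cell_of(well):
        density, _, _ = correct_od(cal, well.od)
        ok = density > 0
        out = np.full(len(times), np.nan)
        out[ok] = well.f525[ok] / density[ok]
        return out, ~ok

    wt_pc = np.vstack([per_cell_of(w)[0] for w in wt])
    wt_mean = np.nanmean(wt_pc, axis=0)
    results = []
    for group, well_ids in dataset.replicate_groups("tagged").items():
        wells = [dataset.wells[w] for w in well_ids]
        rows, skip_flags = [], []
        for w in wells:
            pc, skipped = per_cell_of(w)
            rows.append(pc - wt_mean)
            skip_flags.append(skipped)
        per_cell = np.nanmean(np.vstack(rows), axis=0)
        ann = dataset.layout[well_ids[0]]
        nan = np.full_like(per_cell, np.nan)
        results.append(
            FluorescenceEstimate(
                times=times,
                g_mean=nan.copy(),
                g_sd=nan.copy(),
                per_cell_mean=per_cell,
                per_cell_sd=nan.copy(),
                method="subtraction",
                strain=ann.strain,
                condition=ann.condition,
                replicate_group=group,
                n_replicates=len(wells),
                flags={
                    "negative_estimate": per_cell < 0,
                    "skipped_nonpositive_od": np.any(np.vstack(skip_flags), axis=0),
                },
            )
        )
    return results
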