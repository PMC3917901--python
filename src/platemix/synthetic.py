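"""Forward-model generator of synthetic plate experiments with known truth.

Emulates a microbial microplate run the way the measurement model sees it:
logistic growth of relative cell density, a saturating (compressive) map from
density to measured OD, OD-dependent cellular autofluorescence with an
emission ratio ra(OD), reporter expression per cell (off / constant / delayed
induction ramp), slowly drifting media background in all three channels, and
independent Gaussian measurement noise. The measured channels follow the
two-channel linear mixing model exactly:

    f525 = g + a + media_525 + noise
    f585 = rg*g + ra(OD_cells)*a + media_585 + noise

so every pipeline stage can be tested against exact ground truth without any
external data. Defaults mirror a galactose-induction run on a 96-well reader:
starting OD ~0.25 (wild-type, deliberately lower) and ~0.3 (tagged), readings
every 12 minutes for ~20 h, ra rising sigmoidally from ~0.4 to ~0.6 across
the OD range, EGFP rg = 0.114.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .plate import PlateDataset, WellAnnotation, WellTimeSeries


@dataclass
class Logistic:
    """Logistic growth of relative density: d(t) = K / (1 + (K/d0 - 1) e^{-r t})."""

    initial_density: float
    rate_per_h: float = 0.5
    capacity: float = 1.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        d0, r, K = self.initial_density, self.rate_per_h, self.capacity
        return K / (1.0 + (K / d0 - 1.0) * np.exp(-r * np.asarray(t, float)))


@dataclass
class SaturatingODMap:
    """density -> OD: linear at low density, compressive above the shoulder.

    od(d) = slope * d / (1 + d / sat_density). With the defaults an undiluted
    calibration culture (relative density 1.0) reads OD 1.2 and deviation
    from linearity becomes visible around OD 0.5.
    """

    slope: float = 1.8
    sat_density: float = 2.0

    def __call__(self, density) -> np.ndarray:
        d = np.asarray(density, dtype=float)
        return self.slope * d / (1.0 + d / self.sat_density)


@dataclass
class RaProfile:
    """Autofluorescence emission ratio as a function of cell OD.

    ``shape="constant"`` uses ``low`` everywhere; ``shape="sigmoid"`` rises
    from ``low`` to ``high`` around ``od_mid`` with logistic width ``od_width``.
    """

    shape: str = "sigmoid"
    low: float = 0.4
    high: float = 0.6
    od_mid: float = 0.6
    od_width: float = 0.2

    def __call__(self, od) -> np.ndarray:
        od = np.asarray(od, dtype=float)
        if self.shape == "constant":
            return np.full_like(od, self.low)
        if self.shape == "sigmoid":
            return self.low + (self.high - self.low) / (
                1.0 + np.exp(-(od - self.od_mid) / self.od_width)
            )
        raise ValueError(f"unknown ra profile shape {self.shape!r}")


@dataclass
class Expression:
    """True reporter signal per cell versus time.

    ``mode="off"``: zero. ``mode="constant"``: ``level`` throughout.
    ``mode="ramp"``: zero until ``delay_h``, smooth monotone rise
    (smoothstep) reaching ``level`` at ``plateau_h``, flat after — the shape
    of a delayed induction response.
    """

    mode: str = "ramp"
    level: float = 150.0
    delay_h: float = 2.0
    plateau_h: float = 10.0

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.mode == "off":
            return np.zeros_like(t)
        if self.mode == "constant":
            return np.full_like(t, self.level)
        if self.mode == "ramp":
            u = np.clip((t - self.delay_h) / (self.plateau_h - self.delay_h), 0, 1)
            return self.level * u**2 * (3.0 - 2.0 * u)
        raise ValueError(f"unknown expression mode {self.mode!r}")


@dataclass
class SyntheticScenario:
    """Everything the forward model needs; defaults emulate a galactose run."""

    growth_wildtype: Logistic = field(
        default_factory=lambda: Logistic(initial_density=0.149)
    )
    growth_tagged: Logistic = field(
        default_factory=lambda: Logistic(initial_density=0.182)
    )
    od_map: SaturatingODMap = field(default_factory=SaturatingODMap)
    ra_profile: RaProfile = field(default_factory=RaProfile)
    #: autofluorescence per relative-density unit (a.u.), may differ for tagged
    autofl_per_cell: float = 100.0
    autofl_tagged_factor: float = 1.0
    expression: Expression = field(default_factory=Expression)
    #: media background (base, drift per hour) per channel
    media_od: tuple[float, float] = (0.04, 0.001)
    media_f525: tuple[float, float] = (30.0, 0.2)
    media_f585: tuple[float, float] = (12.0, 0.08)
    #: per-reading Gaussian measurement sd per channel
    noise_od: float = 0.003
    noise_f525: float = 1.0
    noise_f585: float = 0.5
    #: multiplicative noise fraction (0 = the model the estimators assume)
    multiplicative_noise_cv: float = 0.0
    rg_true: float = 0.114
    seed: int = 0

    def validate(self) -> None:
        for g in (self.growth_wildtype, self.growth_tagged):
            if g.initial_density <= 0 or g.capacity <= 0 or g.rate_per_h <= 0:
                raise ValueError("growth parameters must be strictly positive")
            if g.initial_density >= g.capacity:
                raise ValueError("initial density must be below carrying capacity")
        if min(self.noise_od, self.noise_f525, self.noise_f585) < 0:
            raise ValueError("noise sds must be non-negative")
        if not 0 <= self.rg_true < 1:
            raise ValueError("rg_true must be in [0, 1)")
        if self.od_map.slope <= 0 or self.od_map.sat_density <= 0:
            raise ValueError("OD map parameters must be strictly positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        d = dict(d)
        for key, sub in (
            ("growth_wildtype", Logistic),
            ("growth_tagged", Logistic),
            ("od_map", SaturatingODMap),
            ("ra_profile", RaProfile),
            ("expression", Expression),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("media_od", "media_f525", "media_f585"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth aligned with the generated dataset's time grid."""

    times: np.ndarray
    density: dict[str, np.ndarray]
    a_total: dict[str, np.ndarray]
    g_total: dict[str, np.ndarray]
    per_cell: dict[str, np.ndarray]
    ra_profile: RaProfile
    od_map: SaturatingODMap

    def frame(self) -> pd.DataFrame:
        rows = []
        for wid in sorted(self.density):
            rows.append(
                pd.DataFrame(
                    {
                        "well": wid,
                        "time_h": self.times,
                        "density": self.density[wid],
                        "a": self.a_total[wid],
                        "g": self.g_total[wid],
                        "per_cell": self.per_cell[wid],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def generate(
    scenario: SyntheticScenario,
    n_media: int = 3,
    n_wildtype: int = 3,
    n_tagged: int = 3,
    n_timepoints: int = 100,
    dt_h: float = 0.2,
) -> tuple[PlateDataset, SyntheticTruth]:
    """Generate a complete plate experiment plus aligned ground truth."""
    scenario.validate()
    if n_media < 1 or n_wildtype < 1:
        raise ValueError("need at least one media and one wildtype well")
    if n_timepoints < 25:
        raise ValueError(f"need >= 25 time points, got {n_timepoints}")
    rng = np.random.default_rng(scenario.seed)
    t = np.arange(n_timepoints) * dt_h

    media = {
        "od": scenario.media_od[0] + scenario.media_od[1] * t,
        "f525": scenario.media_f525[0] + scenario.media_f525[1] * t,
        "f585": scenario.media_f585[0] + scenario.media_f585[1] * t,
    }
    noise = {
        "od": scenario.noise_od,
        "f525": scenario.noise_f525,
        "f585": scenario.noise_f585,
    }

    def measure(clean: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for ch, v in clean.items():
            y = v + rng.normal(0.0, noise[ch], size=v.shape)
            if scenario.multiplicative_noise_cv > 0:
                y = y * (
                    1.0
                    + rng.normal(
                        0.0, scenario.multiplicative_noise_cv, size=v.shape
                    )
                )
            out[ch] = y
        return out

    wells: dict[str, WellTimeSeries] = {}
    layout: dict[str, WellAnnotation] = {}
    density: dict[str, np.ndarray] = {}
    a_tot: dict[str, np.ndarray] = {}
    g_tot: dict[str, np.ndarray] = {}
    per_cell: dict[str, np.ndarray] = {}

    def add_well(wid, ann, clean, dens, a, g):
        m = measure(clean)
        wells[wid] = WellTimeSeries(wid, t, m["od"], m["f525"], m["f585"])
        layout[wid] = ann
        density[wid] = dens
        a_tot[wid] = a
        g_tot[wid] = g
        per_cell[wid] = np.divide(g, dens, out=np.zeros_like(g), where=dens > 0)

    for i in range(n_media):
        wid = f"M{i + 1}"
        add_well(
            wid,
            WellAnnotation(wid, "media", "", "", "media"),
            dict(media),
            np.zeros_like(t),
            np.zeros_like(t),
            np.zeros_like(t),
        )

    def cell_channels(dens, apc, expr_per_cell):
        od_cells = scenario.od_map(dens)
        a = apc * dens
        g = expr_per_cell * dens
        ra = scenario.ra_profile(od_cells)
        return (
            {
                "od": od_cells + media["od"],
                "f525": g + a + media["f525"],
                "f585": scenario.rg_true * g + ra * a + media["f585"],
            },
            a,
            g,
        )

    for i in range(n_wildtype):
        wid = f"W{i + 1}"
        dens = scenario.growth_wildtype(t)
        clean, a, g = cell_channels(dens, scenario.autofl_per_cell, np.zeros_like(t))
        add_well(wid, WellAnnotation(wid, "wildtype", "WT", "", "WT"), clean, dens, a, g)

    for i in range(n_tagged):
        wid = f"T{i + 1}"
        dens = scenario.growth_tagged(t)
        apc = scenario.autofl_per_cell * scenario.autofl_tagged_factor
        clean, a, g = cell_channels(dens, apc, scenario.expression(t))
        add_well(
            wid,
            WellAnnotation(wid, "tagged", "TAG", "", "TAG"),
            clean,
            dens,
            a,
            g,
        )

    dataset = PlateDataset(
        wells=wells, layout=layout, meta={"synthetic": True, "seed": scenario.seed}
    )
    truth = SyntheticTruth(
        times=t,
        density=density,
        a_total=a_tot,
        g_total=g_tot,
        per_cell=per_cell,
        ra_profile=scenario.ra_profile,
        od_map=scenario.od_map,
    )
    return dataset, truth


def generate_dilution_series(
    od_map: SaturatingODMap,
    n_dilutions: int = 9,
    noise_cv: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Doubling dilution series through the OD map, e.g. 1x ... 256x for n=9.

    The undiluted sample has relative density 1.0; measured OD carries
    multiplicative noise of fractional sd ``noise_cv``. Columns: od,
    dilution_factor, true_density.
    """
    if n_dilutions < 4:
        raise ValueError(f"need >= 4 dilutions, got {n_dilutions}")
    rng = np.random.default_rng(seed)
    factor = 2.0 ** np.arange(n_dilutions)
    density = 1.0 / factor
    od_true = od_map(density)
    od = od_true * (1.0 + rng.normal(0.0, noise_cv, size=od_true.shape))
    return pd.DataFrame(
        {"od": od, "dilution_factor": factor, "true_density": density}
    )
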