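"""Synthetic cohorts of stenosed vessels with paired reference FFR.

No clinical data ship with the package; this module generates parametric
cohorts that exercise the full pipeline end to end.  Each case is a
straight vessel with one cosine-tapered stenosis (area severity drawn
from 30–90%, the severity band of lesions that reach functional
testing).  SmartFFR is computed through the full staged-flow +
curve pipeline.  The "invasive" reference FFR comes from coupling the
same pressure-drop model to a constant hyperemic microvascular
resistance: the hyperemic operating flow solves

    Pa = f*Q + s*Q^2 + Q*R_micro

and FFR = Pd(Q*)/Pa = Q*R_micro/Pa.  The default R_micro = 25
mmHg/(ml/s) makes a healthy vessel's hyperemic flow exactly 4 ml/s at
Pa = 100 mmHg, the canonical per-branch peak flow.  Measurement noise is
additive Gaussian on the reference only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .geometry import StenosisSpec, apply_stenosis, make_straight_vessel
from .hemodynamics import FluidProperties, PressureDropModel, SimulationConfig, pressure_drop_model, run_single_vessel_protocol
from .index import compute_smartffr

__all__ = [
    "Constant",
    "Uniform",
    "LogNormal",
    "CohortSpec",
    "SyntheticCase",
    "simulate_reference_ffr",
    "generate_cohort",
    "cohort_dataframe",
    "write_cohort_csv",
]

COHORT_COLUMNS = [
    "case_id",
    "diameter_mm",
    "length_mm",
    "area_stenosis",
    "f_mmhg_per_mls",
    "s_mmhg_per_mls2",
    "ffr_true",
    "ffr_measured",
    "smartffr",
]


# --- tiny distribution vocabulary (kept explicit so cohort YAML specs are
# self-describing and every draw is reproducible from (seed, case index)).

@dataclass(frozen=True)
class Constant:
    value: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.value)


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise InvalidArgumentError("uniform distribution needs low < high")

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class LogNormal:
    """Parameterised by the median (exp of the log-mean) and log-sd."""

    median: float
    sigma: float

    def __post_init__(self):
        if self.median <= 0 or self.sigma < 0:
            raise InvalidArgumentError("lognormal needs median > 0 and sigma >= 0")

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.median * math.exp(self.sigma * rng.standard_normal()))


def distribution_from_dict(doc) -> Constant | Uniform | LogNormal:
    """Parse {"constant": v} / {"uniform": [lo, hi]} /
    {"lognormal": {"median": m, "sigma": s}} (bare numbers = constant)."""
    if isinstance(doc, (int, float)):
        return Constant(float(doc))
    if not isinstance(doc, dict) or len(doc) != 1:
        raise InvalidArgumentError(f"cannot parse distribution spec {doc!r}")
    (kind, params), = doc.items()
    if kind == "constant":
        return Constant(float(params))
    if kind == "uniform":
        lo, hi = params
        return Uniform(float(lo), float(hi))
    if kind == "lognormal":
        return LogNormal(float(params["median"]), float(params["sigma"]))
    raise InvalidArgumentError(f"unknown distribution kind {kind!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings of one synthetic cohort.

    Defaults give a realistic epicardial population: diameters lognormal
    around a 3 mm median, segment lengths 20–60 mm, area-stenosis
    severities uniform on the 30–90% study band, and a 0.03 FFR
    measurement noise sd (the scale of repeat-measurement variability of
    pressure-wire FFR).
    """

    n_vessels: int
    seed: int = 0
    diameter_mm: Constant | Uniform | LogNormal = LogNormal(median=3.0, sigma=0.15)
    length_mm: Constant | Uniform | LogNormal = Uniform(20.0, 60.0)
    area_stenosis: Constant | Uniform | LogNormal = Uniform(0.30, 0.90)
    stenosis_length_mm: Constant | Uniform | LogNormal = Uniform(10.0, 20.0)
    r_micro: Constant | Uniform | LogNormal = Constant(25.0)
    ffr_noise_sd: float = 0.03
    n_centerline_samples: int = 201

    def __post_init__(self):
        if self.n_vessels < 1:
            raise InvalidArgumentError("cohort needs n_vessels >= 1")
        if self.ffr_noise_sd < 0:
            raise InvalidArgumentError("ffr_noise_sd must be non-negative")

    @classmethod
    def from_dict(cls, doc: dict) -> "CohortSpec":
        kwargs = dict(doc)
        for key in ("diameter_mm", "length_mm", "area_stenosis", "stenosis_length_mm", "r_micro"):
            if key in kwargs:
                kwargs[key] = distribution_from_dict(kwargs[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class SyntheticCase:
    case_id: str
    diameter_mm: float
    length_mm: float
    area_stenosis: float
    model: PressureDropModel
    ffr_true: float
    ffr_measured: float
    smartffr: float


def simulate_reference_ffr(model: PressureDropModel, r_micro: float, inlet_pressure: float = 100.0) -> float:
    """Reference FFR under hyperemia with a constant distal-bed resistance.

    The operating flow is the positive root of
    s*Q^2 + (f + R)*Q - Pa = 0 (or Pa/(f+R) when s = 0), and
    FFR = Q* R / Pa, i.e. the distal pressure fraction at that flow.
    """
    if r_micro <= 0:
        raise InvalidArgumentError("r_micro must be positive")
    fr = model.f + r_micro
    if model.s == 0.0:
        q_star = inlet_pressure / fr
    else:
        q_star = (-fr + math.sqrt(fr**2 + 4.0 * model.s * inlet_pressure)) / (2.0 * model.s)
    return q_star * r_micro / inlet_pressure


def _case_rng(seed: int, index: int) -> np.random.Generator:
    # one stream per (seed, case index): extending a cohort never reshuffles
    return np.random.default_rng([seed, index])


def generate_cohort(
    spec: CohortSpec,
    config: SimulationConfig = SimulationConfig(),
    fluid: FluidProperties = FluidProperties(),
) -> list[SyntheticCase]:
    cases = []
    for i in range(spec.n_vessels):
        rng = _case_rng(spec.seed, i)
        diameter = spec.diameter_mm.sample(rng)
        length = spec.length_mm.sample(rng)
        sa = spec.area_stenosis.sample(rng)
        sten_len = min(spec.stenosis_length_mm.sample(rng), 0.6 * length)
        r_micro = spec.r_micro.sample(rng)
        noise = rng.normal(0.0, spec.ffr_noise_sd) if spec.ffr_noise_sd > 0 else 0.0

        vessel = make_straight_vessel(diameter, length, spec.n_centerline_samples, segment_id=f"case{i:04d}")
        lesion = apply_stenosis(vessel, StenosisSpec(center_mm=length / 2.0, length_mm=sten_len, area_stenosis=sa))
        model = pressure_drop_model(lesion, fluid)
        samples = run_single_vessel_protocol(lesion, config=config, fluid=fluid)
        smartffr = compute_smartffr(samples, config, vessel_id=lesion.segment_id).value
        ffr_true = simulate_reference_ffr(model, r_micro, config.inlet_pressure)
        ffr_measured = float(np.clip(ffr_true + noise, 0.0, 1.0))
        cases.append(
            SyntheticCase(
                case_id=lesion.segment_id,
                diameter_mm=diameter,
                length_mm=length,
                area_stenosis=sa,
                model=model,
                ffr_true=ffr_true,
                ffr_measured=ffr_measured,
                smartffr=smartffr,
            )
        )
    return cases


def cohort_dataframe(cases: list[SyntheticCase]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "diameter_mm": c.diameter_mm,
                "length_mm": c.length_mm,
                "area_stenosis": c.area_stenosis,
                "f_mmhg_per_mls": c.model.f,
                "s_mmhg_per_mls2": c.model.s,
                "ffr_true": c.ffr_true,
                "ffr_measured": c.ffr_measured,
                "smartffr": c.smartffr,
            }
            for c in cases
        ],
        columns=COHORT_COLUMNS,
    )


def write_cohort_csv(cases: list[SyntheticCase], path: str | Path) -> None:
    cohort_dataframe(cases).to_csv(path, index=False, float_format="%.9g", lineterminator="\n")
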