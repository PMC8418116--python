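"""The SmartFFR index: Pd/Pa-versus-flow curve and its normalised AUC.

For a single segment the distal-to-proximal pressure ratio is computed at
each staged flow, anchored at (0, 1) — zero flow drops no pressure — and
connected by a smooth interpolating spline evaluated at ``n_grid`` points
on the standard 0–4 ml/s range.  SmartFFR is the area under that curve
divided by the area under the healthy reference curve (identically 1, so
the reference area equals the flow range, 4).  Branch curves of a
bifurcation, whose flows generally do not land on 1–4 ml/s, are rebased
onto the standard range through an origin-forced quadratic pressure-drop
fit before integration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import FormatError, InvalidArgumentError, OutOfDomainError, UnsupportedTopologyError
from .hemodynamics import PressureDropModel, PressureFlowSample, SimulationConfig, fit_pressure_drop

__all__ = [
    "PdPaCurve",
    "SmartFFRResult",
    "build_curve",
    "smartffr_from_curve",
    "smartffr_closed_form",
    "rebase_branch_curve",
    "smartffr_bifurcation",
    "compute_smartffr",
    "read_solver_samples",
    "write_solver_samples",
]


@dataclass(frozen=True)
class PdPaCurve:
    """Pd/Pa ratio sampled on a uniform flow grid spanning [0, flow_max].

    The ratio is 1 exactly at zero flow and clipped to [0, 1] everywhere.
    """

    flow: np.ndarray
    ratio: np.ndarray
    source: str = "single-vessel"

    def __post_init__(self):
        flow = np.asarray(self.flow, dtype=float)
        ratio = np.asarray(self.ratio, dtype=float)
        object.__setattr__(self, "flow", flow)
        object.__setattr__(self, "ratio", ratio)
        if flow.shape != ratio.shape or flow.ndim != 1 or flow.size < 4:
            raise InvalidArgumentError("flow and ratio must be matching 1D arrays (>= 4 points)")
        if flow[0] != 0.0:
            raise InvalidArgumentError("curve must start at zero flow")
        if abs(ratio[0] - 1.0) > 0:
            raise InvalidArgumentError("ratio at zero flow must be exactly 1")
        if np.any(ratio < 0) or np.any(ratio > 1):
            raise InvalidArgumentError("ratio values must lie in [0, 1]")


@dataclass(frozen=True)
class SmartFFRResult:
    """SmartFFR value (= auc / flow range) for one vessel or branch."""

    value: float
    auc: float
    vessel_id: str = ""
    branch_id: str | None = None


def _spline_curve(flows: np.ndarray, ratios: np.ndarray, config: SimulationConfig, source: str) -> PdPaCurve:
    grid = np.linspace(0.0, config.flow_max, config.n_grid)
    # not-a-knot ends: exact on the quadratic dP model class, and free of
    # the end-flattening a natural spline imposes
    spline = CubicSpline(flows, ratios, bc_type="not-a-knot")
    values = np.clip(spline(grid), 0.0, 1.0)
    values[0] = 1.0
    return PdPaCurve(flow=grid, ratio=values, source=source)


def build_curve(samples: list[PressureFlowSample], config: SimulationConfig = SimulationConfig()) -> PdPaCurve:
    """Spline the per-stage Pd/Pa ratios (anchored at (0, 1)) onto the
    standard flow grid."""
    if len(samples) < 2:
        raise InvalidArgumentError("need at least 2 pressure-flow samples")
    order = np.argsort([s.flow for s in samples])
    flows = np.array([samples[i].flow for i in order])
    ratios = np.array([samples[i].ratio for i in order])
    if np.unique(flows).size != flows.size:
        raise InvalidArgumentError("duplicate flow values in samples")
    if flows[0] > 0.0:
        flows = np.insert(flows, 0, 0.0)
        ratios = np.insert(ratios, 0, 1.0)
    return _spline_curve(flows, ratios, config, "single-vessel")


def smartffr_from_curve(curve: PdPaCurve, vessel_id: str = "", branch_id: str | None = None) -> SmartFFRResult:
    """Integrate the curve (composite trapezoid) and normalise by the
    healthy-reference area, i.e. the width of the flow range."""
    auc = float(np.trapezoid(curve.ratio, curve.flow))
    value = auc / float(curve.flow[-1])
    return SmartFFRResult(value=value, auc=auc, vessel_id=vessel_id, branch_id=branch_id)


def smartffr_closed_form(model: PressureDropModel, inlet_pressure: float = 100.0, flow_max: float = 4.0) -> float:
    """Analytic SmartFFR of the quadratic engine, valid while the distal
    pressure stays positive over the whole flow range:

    SmartFFR = 1 - (f*flow_max/2 + s*flow_max^2/3) / inlet_pressure
    """
    if model.pressure_drop(flow_max) > inlet_pressure:
        raise OutOfDomainError("dP at peak flow exceeds inlet pressure; clamped pipeline value diverges from closed form")
    return 1.0 - (model.f * flow_max / 2.0 + model.s * flow_max**2 / 3.0) / inlet_pressure


def rebase_branch_curve(samples: list[PressureFlowSample], config: SimulationConfig = SimulationConfig()) -> PdPaCurve:
    """Map branch samples, whose flows need not reach (or may exceed)
    the standard range, onto the standard [0, flow_max] grid.

    The origin-forced quadratic dP fit is evaluated against the branch's
    proximal pressure (mean over stages); this interpolates when the
    branch flows exceed the range and extrapolates when they fall short,
    staying within the physical model class either way.
    """
    model = fit_pressure_drop(samples)
    pa_ref = float(np.mean([s.pa for s in samples]))
    grid = np.linspace(0.0, config.flow_max, config.n_grid)
    ratio = np.clip(1.0 - model.pressure_drop(grid) / pa_ref, 0.0, 1.0)
    ratio[0] = 1.0
    return PdPaCurve(flow=grid, ratio=ratio, source="branch")


def smartffr_bifurcation(
    branch_samples: dict[str, list[PressureFlowSample]],
    config: SimulationConfig = SimulationConfig(),
) -> dict[str, SmartFFRResult]:
    """SmartFFR per daughter branch, each from its own rebased curve."""
    if len(branch_samples) != 2:
        raise UnsupportedTopologyError("bifurcation index needs exactly 2 branches")
    out = {}
    for branch_id, samples in branch_samples.items():
        curve = rebase_branch_curve(samples, config)
        out[branch_id] = smartffr_from_curve(curve, vessel_id=branch_id, branch_id=branch_id)
    return out


def compute_smartffr(samples: list[PressureFlowSample], config: SimulationConfig = SimulationConfig(), vessel_id: str = "") -> SmartFFRResult:
    """Single-vessel pipeline: samples -> curve -> normalised AUC."""
    return smartffr_from_curve(build_curve(samples, config), vessel_id=vessel_id)


# ---------------------------------------------------------------------------
# Solver-sample adapter: externally computed (Q, Pa, Pd) rows, e.g. from a
# 3D CFD run, enter the index pipeline through this CSV format.

def read_solver_samples(path: str | Path) -> list[PressureFlowSample]:
    """Read `flow_mls,pa_mmhg,pd_mmhg` CSV; returns samples sorted by flow."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise FormatError(f"{path}: empty solver-sample file")
    header = [c.strip().lower() for c in rows[0]]
    try:
        idx = [header.index(c) for c in ("flow_mls", "pa_mmhg", "pd_mmhg")]
    except ValueError:
        raise FormatError(f"{path}: header must contain flow_mls,pa_mmhg,pd_mmhg") from None
    samples = []
    for n, row in enumerate(rows[1:], start=1):
        try:
            q, pa, pd = (float(row[i]) for i in idx)
        except (ValueError, IndexError):
            raise FormatError(f"{path}: unparseable numeric fields", row=n) from None
        if q < 0:
            raise FormatError(f"{path}: negative flow {q}", row=n)
        if pd > pa:
            raise FormatError(f"{path}: Pd {pd} exceeds Pa {pa}", row=n)
        if pd < 0:
            raise FormatError(f"{path}: negative distal pressure {pd}", row=n)
        samples.append(PressureFlowSample(flow=q, pa=pa, pd=pd))
    return sorted(samples, key=lambda s: s.flow)


def write_solver_samples(samples: list[PressureFlowSample], path: str | Path) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("flow_mls,pa_mmhg,pd_mmhg\n")
        for s in samples:
            fh.write(f"{s.flow:.9g},{s.pa:.9g},{s.pd:.9g}\n")


def result_report(
    result: SmartFFRResult,
    samples: list[PressureFlowSample],
    config: SimulationConfig,
    engine: str = "reduced-order",
) -> dict:
    """JSON-ready report embedding the result, raw samples and config."""
    from . import __version__

    return {
        "vessel_id": result.vessel_id,
        "branch_id": result.branch_id,
        "smartffr": result.value,
        "auc": result.auc,
        "samples": [{"flow_mls": s.flow, "pa_mmhg": s.pa, "pd_mmhg": s.pd} for s in samples],
        "engine": engine,
        "config": {
            "inlet_pressure_mmhg": config.inlet_pressure,
            "flow_max_mls": config.flow_max,
            "n_grid": config.n_grid,
            "pd_floor_mmhg": config.pd_floor,
        },
        "version": __version__,
    }
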