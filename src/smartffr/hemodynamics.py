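"""Reduced-order pressure-drop engine.

The full 3D incompressible Navier–Stokes problem on a stenosed coronary
segment is collapsed to a quadratic pressure-drop law

    dP(Q) = f*Q + s*Q**2        [mmHg, Q in ml/s]

with a viscous (Poiseuille) coefficient f obtained by integrating the
local D^-4 resistance along the centerline, and a separation-loss
coefficient s of Young–Tsai form driven by the throat-to-reference area
ratio.  Pd/Pa–flow samples are produced by imposing a staged flow
protocol at a fixed proximal pressure, exactly the quantity the SmartFFR
index consumes.  Bifurcations split the imposed total flow between the
two daughter branches by Murray's cubic-diameter law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .errors import InvalidArgumentError, UnsupportedTopologyError
from .geometry import CoronaryTree, VesselSegment, reference_radius

__all__ = [
    "FluidProperties",
    "SimulationConfig",
    "FlowProtocol",
    "PressureDropModel",
    "PressureFlowSample",
    "BifurcationSplit",
    "viscous_coefficient",
    "separation_coefficient",
    "pressure_drop_model",
    "fit_pressure_drop",
    "murray_split",
    "run_single_vessel_protocol",
    "run_bifurcation_protocol",
]

MMHG_PER_PA = 1.0 / 133.322
#: Young–Tsai turbulent/separation loss constant for blunt stenoses.
K_T = 1.52


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood: dynamic viscosity in Pa*s, density in kg/m^3."""

    dynamic_viscosity: float = 0.0035
    density: float = 1050.0

    def __post_init__(self):
        if self.dynamic_viscosity <= 0 or self.density <= 0:
            raise InvalidArgumentError("fluid properties must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol-independent solver settings.

    inlet_pressure: proximal static pressure (mmHg), applied at the
        segment (or parent-vessel) inlet.
    flow_max: upper end of the standard Pd/Pa-curve flow range (ml/s).
    n_grid: number of interpolation points of the Pd/Pa curve.
    pd_floor: lower clamp on computed distal pressure (mmHg).
    """

    inlet_pressure: float = 100.0
    flow_max: float = 4.0
    n_grid: int = 100
    pd_floor: float = 0.0

    def __post_init__(self):
        if self.inlet_pressure <= 0:
            raise InvalidArgumentError("inlet_pressure must be positive")
        if self.n_grid < 4:
            raise InvalidArgumentError("n_grid must be at least 4")


@dataclass(frozen=True)
class FlowProtocol:
    """Staged flow values (ml/s), one quasi-steady state per stage.

    The timestep duration is retained as metadata only: with no inertial
    or compliance terms each stage is an independent steady state.
    """

    flows: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    timestep_duration: float = 0.25

    def __post_init__(self):
        flows = tuple(float(q) for q in self.flows)
        object.__setattr__(self, "flows", flows)
        if len(flows) < 1 or any(q <= 0 for q in flows):
            raise InvalidArgumentError("protocol flows must be positive")
        if any(b <= a for a, b in zip(flows, flows[1:])):
            raise InvalidArgumentError("protocol flows must be strictly increasing")


#: Default bifurcation protocol: total flow staged to the 8 ml/s peak
#: hyperemic flow of a healthy left coronary system.
BIFURCATION_TOTAL_FLOWS = (2.0, 4.0, 6.0, 8.0)


@dataclass(frozen=True)
class PressureDropModel:
    """Coefficients of dP(Q) = f*Q + s*Q^2 (mmHg, ml/s)."""

    f: float
    s: float

    def __post_init__(self):
        if self.f < 0 or self.s < 0:
            raise InvalidArgumentError("f and s must be non-negative")

    def pressure_drop(self, q):
        """dP at flow q (ml/s), in mmHg."""
        q = np.asarray(q, dtype=float)
        out = self.f * q + self.s * q**2
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PressureFlowSample:
    """One quasi-steady observation: flow (ml/s), proximal and distal
    pressures (mmHg)."""

    flow: float
    pa: float
    pd: float

    def __post_init__(self):
        if self.flow < 0:
            raise InvalidArgumentError("flow must be non-negative")
        if not 0.0 <= self.pd <= self.pa:
            raise InvalidArgumentError("need 0 <= Pd <= Pa")

    @property
    def ratio(self) -> float:
        return self.pd / self.pa


@dataclass(frozen=True)
class BifurcationSplit:
    """Murray's-law flow division between two daughter branches."""

    d1: float
    d2: float
    fraction_1: float
    fraction_2: float


def viscous_coefficient(segment: VesselSegment, fluid: FluidProperties = FluidProperties()) -> float:
    """Poiseuille coefficient f (mmHg per ml/s).

    f = (128*mu/pi) * integral D(z)^-4 dz, trapezoidal along the sampled
    centerline, SI inside, converted to mmHg/(ml/s) at the end.
    """
    d_m = 2.0 * segment.radius_mm * 1e-3
    z_m = segment.arc_mm * 1e-3
    integral = np.trapezoid(d_m**-4, z_m)
    f_si = 128.0 * fluid.dynamic_viscosity / math.pi * integral  # Pa/(m^3/s)
    return f_si * 1e-6 * MMHG_PER_PA


def separation_coefficient(segment: VesselSegment, fluid: FluidProperties = FluidProperties()) -> float:
    """Separation-loss coefficient s (mmHg per (ml/s)^2), Young–Tsai form:

    s = rho*K_t/(2*A0^2) * (A0/As - 1)^2

    with A0 the reference (healthy) area and As the throat area.  Zero for
    an unobstructed vessel.
    """
    r0_m = reference_radius(segment) * 1e-3
    rs_m = float(segment.radius_mm.min()) * 1e-3
    a0 = math.pi * r0_m**2
    a_s = math.pi * rs_m**2
    if a_s >= a0:
        return 0.0
    s_si = fluid.density * K_T / (2.0 * a0**2) * (a0 / a_s - 1.0) ** 2  # Pa/(m^3/s)^2
    return s_si * 1e-12 * MMHG_PER_PA


def pressure_drop_model(segment: VesselSegment, fluid: FluidProperties = FluidProperties()) -> PressureDropModel:
    """Convenience: both coefficients of a segment at once."""
    return PressureDropModel(viscous_coefficient(segment, fluid), separation_coefficient(segment, fluid))


def fit_pressure_drop(samples: list[PressureFlowSample]) -> PressureDropModel:
    """Least-squares fit of dP = f*Q + s*Q^2 through the origin, f,s >= 0.

    Solved as a non-negative least-squares problem, i.e. the
    residual-minimising coefficients on the physical domain.
    """
    q = np.array([s.flow for s in samples], dtype=float)
    dp = np.array([s.pa - s.pd for s in samples], dtype=float)
    positive = q > 0
    if np.unique(q[positive]).size < 2:
        raise InvalidArgumentError("need at least 2 samples with distinct positive flows")
    design = np.column_stack([q, q**2])
    coef, _ = nnls(design, dp)
    return PressureDropModel(f=float(coef[0]), s=float(coef[1]))


def murray_split(d1: float, d2: float) -> BifurcationSplit:
    """Murray's law: daughter flows scale with the cube of their diameters,
    q2/q1 = (d2/d1)^3; fractions are normalised to sum to 1."""
    if d1 <= 0 or d2 <= 0:
        raise InvalidArgumentError("branch diameters must be positive")
    c1, c2 = d1**3, d2**3
    total = c1 + c2
    return BifurcationSplit(d1=d1, d2=d2, fraction_1=c1 / total, fraction_2=c2 / total)


def run_single_vessel_protocol(
    segment: VesselSegment,
    protocol: FlowProtocol = FlowProtocol(),
    config: SimulationConfig = SimulationConfig(),
    fluid: FluidProperties = FluidProperties(),
) -> list[PressureFlowSample]:
    """Impose the staged flows at fixed proximal pressure and record the
    distal pressure from the quadratic pressure-drop law."""
    model = pressure_drop_model(segment, fluid)
    samples = []
    for q in protocol.flows:
        pd = max(config.pd_floor, config.inlet_pressure - model.pressure_drop(q))
        samples.append(PressureFlowSample(flow=q, pa=config.inlet_pressure, pd=pd))
    return samples


def run_bifurcation_protocol(
    tree: CoronaryTree,
    total_flows: tuple[float, ...] = BIFURCATION_TOTAL_FLOWS,
    config: SimulationConfig = SimulationConfig(),
    fluid: FluidProperties = FluidProperties(),
) -> dict[str, list[PressureFlowSample]]:
    """Staged total flows through a parent segment dividing into two
    branches.

    At each total flow Q_tot the branch flows are Murray fractions of
    Q_tot; the branch proximal pressure is the parent's distal pressure
    (pressure continuity), and each branch's distal pressure follows its
    own quadratic law at its own flow.
    """
    kids = tree.children.get(tree.root, [])
    if len(kids) != 2:
        raise UnsupportedTopologyError("bifurcation protocol needs a root segment with exactly 2 children")
    parent = tree.segments[tree.root]
    b1, b2 = (tree.segments[k] for k in kids)
    split = murray_split(2.0 * reference_radius(b1), 2.0 * reference_radius(b2))
    parent_model = pressure_drop_model(parent, fluid)
    branch_models = {kids[0]: pressure_drop_model(b1, fluid), kids[1]: pressure_drop_model(b2, fluid)}
    fractions = {kids[0]: split.fraction_1, kids[1]: split.fraction_2}

    out: dict[str, list[PressureFlowSample]] = {k: [] for k in kids}
    for q_tot in total_flows:
        pa_branch = max(config.pd_floor, config.inlet_pressure - parent_model.pressure_drop(q_tot))
        for k in kids:
            q_b = fractions[k] * q_tot
            pd = max(config.pd_floor, pa_branch - branch_models[k].pressure_drop(q_b))
            out[k].append(PressureFlowSample(flow=q_b, pa=pa_branch, pd=pd))
    return out
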