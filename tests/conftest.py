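import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import smartffr as sf

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def straight_vessel():
    """Healthy 3 mm x 30 mm reference tube."""
    return sf.make_straight_vessel(3.0, 30.0, 201, segment_id="healthy")


@pytest.fixture
def stenosed_vessel(straight_vessel):
    """70% area stenosis (45.2% diameter stenosis) over 15 mm mid-segment."""
    return sf.apply_stenosis(
        straight_vessel, sf.StenosisSpec(center_mm=15.0, length_mm=15.0, area_stenosis=0.70)
    )


@pytest.fixture
def quadratic_samples():
    """Exact samples of dP = 2Q + Q^2 at the standard staged flows, Pa=100."""
    model = sf.PressureDropModel(2.0, 1.0)
    return [
        sf.PressureFlowSample(flow=q, pa=100.0, pd=100.0 - model.pressure_drop(q))
        for q in (1.0, 2.0, 3.0, 4.0)
    ]


def make_symmetric_tree(branch_sa: float = 0.0) -> sf.CoronaryTree:
    """Short wide parent feeding two identical 3 mm branches."""
    parent = sf.make_straight_vessel(4.0, 10.0, 51, segment_id="LM")
    branches = {}
    for name in ("LAD", "LCX"):
        seg = sf.make_straight_vessel(3.0, 30.0, 201, segment_id=name)
        if branch_sa > 0:
            seg = sf.apply_stenosis(seg, sf.StenosisSpec(15.0, 15.0, branch_sa))
        branches[name] = seg
    return sf.CoronaryTree(
        segments={"LM": parent, **branches}, root="LM", children={"LM": ["LAD", "LCX"]}
    )


def brute_force_auc(scores, labels) -> float:
    """Mann-Whitney probability that a diseased (low) score ranks below a
    healthy one, ties counting one half — the textbook AUC definition."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] < neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins) / (len(pos) * len(neg))
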