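# smartffr

Virtual functional assessment of coronary stenosis from vessel geometry.

Invasive fractional flow reserve (FFR) — the ratio of distal to
proximal coronary pressure under drug-induced maximal hyperemia — is
the reference standard for deciding whether a stenosis causes ischemia
(FFR ≤ 0.80), but it needs a pressure wire and adenosine.  This package
computes **SmartFFR**, a geometry-derived surrogate: the vessel is
driven through staged flows Q = 1…4 ml/s at a fixed proximal pressure
of 100 mmHg, the resulting Pd/Pa-versus-flow curve is interpolated on
100 points over 0–4 ml/s, and the index is its area under the curve
normalised by the healthy-vessel area of 4:

    SmartFFR = (1/4) ∫₀⁴ (Pd/Pa)(Q) dQ

A healthy vessel scores 1; increasingly flow-limiting lesions push the
index down.  Bifurcations are handled by splitting the total staged
flow (2…8 ml/s) between the daughter branches with Murray's cubic-
diameter law and rebasing each branch's curve onto the standard flow
range.

Pressure–flow samples come from a built-in reduced-order engine — a
quadratic stenosis pressure-drop law ΔP(Q) = f·Q + s·Q² with a
Poiseuille viscous coefficient and a Young–Tsai separation loss — or
from any external CFD solver via a small CSV adapter.  A
diagnostic-validation layer (confusion metrics, Pearson correlation,
Bland–Altman agreement, ROC with Youden-optimal cutoff, DeLong
comparison of correlated AUCs) and a synthetic cohort generator round
out the pipeline, so the whole validation workflow runs with no
clinical data.  It is aimed at researchers prototyping virtual-FFR
methodology and at anyone needing a fast, transparent baseline against
which to compare full 3D CFD results.

## Worked example

A 3 mm × 30 mm vessel with a 70% area stenosis (45.2% diameter
stenosis) over 15 mm:

```python
import smartffr as sf

seg = sf.apply_stenosis(
    sf.make_straight_vessel(3.0, 30.0, 201, segment_id="LAD"),
    sf.StenosisSpec(center_mm=15.0, length_mm=15.0, area_stenosis=0.70),
)
sf.write_centerline(seg, "lad.csv")
```

```sh
$ smartffr compute --centerline lad.csv
{
  "vessel_id": "lad",
  "smartffr": 0.9442212366041977,
  "auc": 3.7768849464167906,
  "samples": [
    {"flow_mls": 1.0, "pa_mmhg": 100.0, "pd_mmhg": 98.29817325089614},
    {"flow_mls": 2.0, "pa_mmhg": 100.0, "pd_mmhg": 95.29191926995983},
    ...
  ],
  "engine": "reduced-order",
  ...
}
```

The four `samples` are the staged-flow states: at 1 ml/s the lesion
drops 1.7 mmHg, at 4 ml/s about 14.6 mmHg (the separation loss grows
with Q²).  The Pd/Pa curve through these points has area 3.777, giving
SmartFFR = 3.777/4 ≈ **0.944** — a hemodynamically non-significant
lesion by the usual ischemic cutoffs, despite looking moderately severe
anatomically.  Other entry points:

```sh
smartffr bifurcation --tree tree.json            # per-branch SmartFFR, Murray split
smartffr from-samples --samples cfd.csv          # index from external solver output
smartffr evaluate --pairs pairs.csv              # ROC/Youden, Table-style metrics, Bland–Altman
smartffr simulate-cohort --n 200 --seed 1 --out cohort.csv
```

See `docs/methods.md` for the model, its assumptions and limitations.

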