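# caphys

Angiography-derived coronary physiology — caFFR and caIMR computed from
vessel geometry, aortic pressure and contrast kinematics — together with a
synthetic STEMI cohort simulator and the clinical statistics pipeline used
to analyze such cohorts (propensity-score matching, 2×2 effect measures,
logistic prediction of adverse events, ROC analysis).

## Who this is for

Researchers in computational hemodynamics and interventional-cardiology
biostatistics who want a fully testable, wire-free model of the index of
microcirculatory resistance (IMR) pipeline: after primary PCI for STEMI,
microvascular injury drives prognosis, but wire-based IMR (distal pressure
× thermodilution transit time at maximal hyperemia) is rarely measured.
The angiographic surrogate needs only two cine projections, the aortic
pressure trace and the contrast transit — all of which this package
synthesizes with known ground truth, so every stage can be validated
without patient data.

## The model

From two angiographic postures at least 30° apart, the vessel centerline is
reconstructed in 3-D (orthographic projections, least-squares ray
intersection) and discretized into a 1-D lumen-area profile. The indices
are

```
MAP       = time-average of the aortic pressure over whole cardiac cycles
Pa_hyp    = MAP − 0.20·MAP   (MAP ≥ 95 mmHg)         hyperemic aortic pressure
          = MAP − 0.15·MAP   (MAP < 95 mmHg)
Vdiastole = (contrast passing length) / (diastolic time interval)   [mm/s]
Vhyp      = K · Vdiastole,                K = 1.1
ΔP        = pressure drop along the vessel at inlet velocity Vhyp
caFFR     = (Pa_hyp − ΔP) / Pa_hyp
caIMR     = (Pa_hyp − ΔP) · L / (K · Vdiastole),     L = 75 mm
```

with caIMR > 40 U flagging abnormal microcirculatory resistance. ΔP comes
from a reduced-order steady laminar model — a per-cell Hagen–Poiseuille
viscous term `8μQ/(πr⁴)·ds` plus Borda–Carnot separation losses
`ρ(V_up − V_down)²/2` over each expanding region — guarded in the test
suite by an independent finite-difference solution of the axisymmetric
Stokes equations on the same geometry.

The cohort side simulates the study design such indices are used in: a
213-patient STEMI cohort (129 drug-eluting stent / 84 drug-coated balloon)
with confounded treatment assignment, covariate marginals matching the
published baseline table, MACE drawn from a logistic model on
symptom-to-balloon and door-to-balloon times, and CV-death/HF-readmission
linked to the caIMR > 40 U indicator.

## Worked example

`python examples/compute_caimr.py` builds a synthetic acquisition (50%
stenosis, MAP 100 mmHg, diastolic velocity 100 mm/s) and runs the full
pipeline:

```
MAP        =  100.00 mmHg   (mean aortic pressure over whole cycles)
Pa_hyp     =   80.00 mmHg   (hyperemic aortic pressure, 20% rule)
Vdiastole  =  100.00 mm/s   (frame-count diastolic velocity)
dP         =  1.5000 mmHg  (computed drop along the vessel)
caFFR      =  0.9812        (distal/aortic pressure ratio)
caIMR      =   53.52 U      (microcirculatory resistance index)
abnormal   = True           (caIMR > 40 U flags microvascular injury)

ground-truth caIMR = 53.52 U; pipeline error = 0.008%
```

The 80 mmHg hyperemic pressure is the 20% reduction of MAP 100; the 1.5
mmHg drop across the stenosis barely dents caFFR (0.98, no flow-limiting
epicardial lesion) while the caIMR of 53.5 U — distal pressure times the
L/Vhyp transit-time surrogate — exceeds the 40 U normal limit, the
signature of microvascular rather than epicardial disease. The other
examples (`reconstruct_vessel.py`, `pressure_drop.py`, `cohort_study.py`)
demonstrate the two-view round trip, the solver cross-check and the full
matched-cohort analysis; a thin CLI (`caphys simulate-cohort`,
`compute-caimr`, `run-study`, `make-fixture`) wraps the same calls for
shell use.

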