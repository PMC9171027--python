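"""Pressure drop across a stenosis: reduced-order model vs the Stokes oracle.

The production model sums a per-cell Poiseuille viscous term and
Borda-Carnot expansion losses.  The independent check is a finite-
difference solution of axisymmetric creeping flow; it is valid at low
Reynolds number, so the comparison runs at a creeping inlet velocity.
"""

from caphys import (
    FlowProblem,
    StenosisSpec,
    discretize,
    make_vessel,
    solve_pressure_drop,
    stokes_oracle,
)

vessel = make_vessel(75.0, 1.5, StenosisSpec(center_s=40.0, length=12.0, severity=0.4),
                     tortuosity_amplitude_mm=0.0, n_points=601)
mesh = discretize(vessel, 300)

# physiologic velocity: reduced-order model with both loss mechanisms
fast = solve_pressure_drop(FlowProblem(mesh, 110.0))
print(f"V = 110 mm/s: dP = {fast.total_dp:.3f} mmHg "
      f"(viscous {fast.viscous_component:.3f} + separation loss {fast.loss_component:.3f})")

# creeping velocity: cross-check against the axisymmetric Stokes solution
slow = solve_pressure_drop(FlowProblem(mesh, 5.0))
oracle = stokes_oracle(FlowProblem(mesh, 5.0))
rel = 100 * abs(oracle.total_dp - slow.total_dp) / slow.total_dp
print(f"V =   5 mm/s: reduced dP = {slow.total_dp:.4f} mmHg, "
      f"Stokes oracle dP = {oracle.total_dp:.4f} mmHg ({rel:.1f}% apart)")
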