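"""One full clearance simulation: centralized tracer bolus, baseline flow.

Runs the transient advection-diffusion transport until 95% of the initial
mass has left the unit, then prints the clearance curve landmarks, the flux
decomposition and the global Péclet number (ratio of volume-integrated
convective to diffusive flux).
"""
import numpy as np

from glymphsim.scenarios import ScenarioConfig, run_scenario

cfg = ScenarioConfig(condition="baseline", solute="tracer",
                     distribution="centralized", resolution=10.0)
res = run_scenario(cfg)
s = res.series
print(f"t95 = {res.t95:.1f} s after {s.meta['steps']} implicit steps")
print(f"initial mass {s.mass[0]:.3e} mol; "
      f"mass audit residual {res.provenance['mass_audit_residual']:.2e}")
for frac in (0.75, 0.50, 0.25, 0.05):
    t = float(np.interp(-frac, -s.fraction_remaining, s.times))
    print(f"  {100 * (1 - frac):3.0f}% cleared at t = {t:8.1f} s")
print(f"peak convective flux {res.fluxes.peak_conv:.3e} mol·m/s at "
      f"t = {res.fluxes.peak_conv_time:.1f} s")
print(f"peak diffusive  flux {res.fluxes.peak_diff:.3e} mol·m/s at "
      f"t = {res.fluxes.peak_diff_time:.1f} s")
print(f"Péclet: time-mean {res.peclet.pe_mean:.3f}, "
      f"terminal {res.peclet.pe_terminal:.3f}, peak {res.peclet.pe_peak:.3f}")
# Pe < 1 at baseline: most of the instantaneous solute motion is diffusive,
# with convection concentrated in the perivascular spaces.
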