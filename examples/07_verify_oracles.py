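"""Run the closed-form verification oracles.

Each oracle pushes a degenerate configuration through the production solver
kernels and compares against an independent closed form: Darcy's law,
plane Poiseuille flow, the heat-kernel variance law, and an eigenfunction
series for absorbing-boundary clearance.
"""
from glymphsim.verification import run_all

for rep in run_all():
    print(f"{rep['name']:<26} measured={rep['measured']:.4g}  "
          f"expected={rep['expected']:.4g}  rel_err={rep['rel_error']:.2%}  "
          f"{'PASS' if rep['passed'] else 'FAIL'} (tol {rep['tolerance']:.0%})")
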