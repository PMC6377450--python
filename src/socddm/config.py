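"""Shared numerical conventions and tolerances.

These are the package-wide defaults; every public entry point that depends
on one of them accepts an override.
"""

#: Diffusion coefficient (within-trial noise SD per sqrt(s)).  The scaling
#: constant of the diffusion model is not identifiable jointly with v, a and
#: z; it is fixed by convention and recorded in all outputs.
S_DEFAULT = 0.1

#: Absolute truncation tolerance per series evaluation.
SERIES_EPS = 1e-7

#: Nodes for Gauss-Hermite (drift variability) and Gauss-Legendre (start and
#: non-decision-time variability) quadrature.
QUAD_NODES = 10

#: Quantile set defining the multinomial RT bins in the fitting objective.
QUANTILE_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)

#: Euler-Maruyama step (s) and absorption cap (s) for the path simulator.
DT_DEFAULT = 1e-4
T_MAX_DEFAULT = 30.0
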