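"""Shared numerical tolerances and defaults, referenced by code and tests."""

# Absolute error budget (in log-density units) for recovering log p0 along a
# probability-flow path with an exact analytic score.
FLOW_ORACLE_ATOL = 1e-3

# Default adaptive-solver tolerances for the probability-flow ODE.
FLOW_RTOL = 1e-6
FLOW_ATOL = 1e-8

# Default lower time cutoff for learned scores.  Networks are least reliable as
# t -> 0; analytic scores support t_min = 0 exactly.
DEFAULT_T_MIN = 1e-4

# Relative tolerance for agreement between an analytic derivative and a central
# finite difference at probe points.
FD_CHECK_RTOL = 1e-4
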