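"""Published summary statistics used as reference inputs.

These values are transcribed from the published case–control study of
resting-state EEG in schizophrenia (32 patients, 28 matched controls) whose
analysis pipeline this package implements. They are *inputs*, not results:
the demographic row feeds the summary-statistics Welch test, and the 36
uncorrected p-values (6 global measures x 6 bands) feed the
Benjamini–Hochberg reconstruction used to validate the FDR stage. Printed
values are rounded to 4 decimals, which bounds how precisely the corrected
values can be reproduced.
"""

from __future__ import annotations

#: Age comparison: (mean, sd, n) per group; the published |t| is 0.299.
AGE_PATIENTS = (33.22, 10.78, 32)
AGE_CONTROLS = (34.04, 10.24, 28)
AGE_T_PUBLISHED = 0.299

#: Uncorrected two-sided p-values of the 36-test family
#: (global measure x band), as printed.
FAMILY_PVALUES: dict[tuple[str, str], float] = {
    ("connectivity", "delta"): 0.0132,
    ("connectivity", "theta"): 0.4320,
    ("connectivity", "alpha"): 0.0017,
    ("connectivity", "beta"): 0.1892,
    ("connectivity", "gamma1"): 0.3135,
    ("connectivity", "gamma2"): 0.1116,
    ("max_bc", "delta"): 0.0599,
    ("max_bc", "theta"): 0.1418,
    ("max_bc", "alpha"): 0.6315,
    ("max_bc", "beta"): 0.6456,
    ("max_bc", "gamma1"): 0.0045,
    ("max_bc", "gamma2"): 0.1974,
    ("max_degree", "delta"): 0.0120,
    ("max_degree", "theta"): 0.0248,
    ("max_degree", "alpha"): 0.7977,
    ("max_degree", "beta"): 0.7001,
    ("max_degree", "gamma1"): 0.0209,
    ("max_degree", "gamma2"): 0.2739,
    ("diameter", "delta"): 0.0016,
    ("diameter", "theta"): 0.0093,
    ("diameter", "alpha"): 0.8352,
    ("diameter", "beta"): 0.4954,
    ("diameter", "gamma1"): 0.0161,
    ("diameter", "gamma2"): 0.5109,
    ("leaf_fraction", "delta"): 0.0006,
    ("leaf_fraction", "theta"): 0.0045,
    ("leaf_fraction", "alpha"): 0.7760,
    ("leaf_fraction", "beta"): 0.8067,
    ("leaf_fraction", "gamma1"): 0.0403,
    ("leaf_fraction", "gamma2"): 0.0780,
    ("assortativity", "delta"): 0.0004,
    ("assortativity", "theta"): 0.0264,
    ("assortativity", "alpha"): 0.0236,
    ("assortativity", "beta"): 0.0130,
    ("assortativity", "gamma1"): 0.1190,
    ("assortativity", "gamma2"): 0.0514,
}

#: Published BH-corrected values recoverable from the rounded inputs
#: (rank-1/2 cells depend on digits beyond the printed precision and are
#: therefore not pinned).
CORRECTED_PUBLISHED: dict[tuple[str, str], float] = {
    ("connectivity", "alpha"): 0.0153,
    ("diameter", "delta"): 0.0153,
    ("max_bc", "gamma1"): 0.0270,
    ("leaf_fraction", "theta"): 0.0270,
    ("connectivity", "delta"): 0.0474,
    ("max_degree", "delta"): 0.0474,
    ("diameter", "theta"): 0.0474,
    ("assortativity", "beta"): 0.0474,
}
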