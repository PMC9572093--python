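"""Bundled reference measurements for two chromane-type antioxidants (AO1, AO2).

Initial oxygen-uptake rates for the AIBN-initiated oxidation of 1,4-dioxane
at 348 K (Vi = 1e-7 mol L^-1 s^-1) at increasing inhibitor concentrations,
together with the reported stoichiometric inhibition coefficients, effective
inhibition constants and consensus-model log k7 predictions for the same two
compounds.  These serve as the worked-example inputs for the kinetics
pipeline and the prediction-vs-experiment bookkeeping.
"""

from __future__ import annotations

import numpy as np

from .kinetics import KineticConstants, RateTable

#: experimental conditions of the rate tables below
REFERENCE_CONSTANTS = KineticConstants(
    two_k6=6.67e7, k2=7.9, RH_conc=11.75, Vi=1e-7, T=348.0
)

#: concentration (mol/L) vs initial uptake rate (mol L^-1 s^-1); conc 0 row = V0
AO1_RATE_TABLE = RateTable(
    inhibitor_id="AO1",
    conc=np.array([0.00, 0.44, 1.24, 1.88, 2.50, 3.13]) * 1e-6,
    rates=np.array([2.30, 1.86, 1.66, 1.53, 1.20, 1.13]) * 1e-6,
)

AO2_RATE_TABLE = RateTable(
    inhibitor_id="AO2",
    conc=np.array([0.00, 0.44, 0.94, 1.25, 1.88, 3.13]) * 1e-6,
    rates=np.array([2.36, 1.95, 1.89, 1.77, 1.53, 1.44]) * 1e-6,
)

#: stoichiometric inhibition coefficients f (value, standard error),
#: from the induction-period dependence on inhibitor concentration
STOICH_FACTORS: dict[str, tuple[float, float]] = {
    "AO1": (30.0, 4.0),
    "AO2": (40.0, 2.0),
}

#: reported effective inhibition constants f*k7 (value, SE), L mol^-1 s^-1
REPORTED_FK7: dict[str, tuple[float, float]] = {
    "AO1": (1.32e6, 0.3e6),
    "AO2": (1.08e6, 0.2e6),
}

#: reported k7 (value, SE), L mol^-1 s^-1
REPORTED_K7: dict[str, tuple[float, float]] = {
    "AO1": (4.3e4, 1.0e4),
    "AO2": (2.7e4, 0.5e4),
}

#: consensus-model predictions of log k7 for AO1/AO2 (models M1-M6)
CONSENSUS_LOGK7_PRED: dict[str, dict[str, float]] = {
    "M1": {"AO1": 5.21, "AO2": 5.10},
    "M2": {"AO1": 4.79, "AO2": 5.32},
    "M3": {"AO1": 5.17, "AO2": 5.21},
    "M4": {"AO1": 5.25, "AO2": 5.23},
    "M5": {"AO1": 5.07, "AO2": 5.20},
    "M6": {"AO1": 5.19, "AO2": 5.15},
}

#: training activity range delta-logk7 of the reference QSPR models and the
#: derived MAE thresholds (10/15/20/25% of the range)
TRAINING_ACTIVITY_RANGE = 7.057
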