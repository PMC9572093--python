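"""Inhibited radical-chain oxidation kinetics.

The chain-termination activity of an antioxidant InH is quantified from
oxygen-uptake data in four steps:

1. initiation rate of the azo-initiator (AIBN):
   Vi = 2 e kp [AIBN], with log10 kp = 17.70 - 35 / (4.575e-3 T);
2. the dimensionless inhibition parameter F = V0/V - V/V0, linear in the
   inhibitor concentration under quasi-steady-state chain oxidation:
   F = f k7 [InH] / sqrt(2 k6 Vi), so a through-origin fit of F against
   [InH] yields the effective inhibition constant f k7;
3. the induction period tau = f [InH] / Vi gives the stoichiometric
   inhibition coefficient f (chains terminated per inhibitor molecule);
4. k7 = f k7 / f, reported as log10 k7.

Units are mol, L, s throughout.  Standard errors come from ordinary
least-squares slope errors with quadrature propagation for the final ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class KineticConstants:
    """Rate constants and conditions of the model oxidation (1,4-dioxane, 348 K)."""

    two_k6: float = 6.67e7       # L mol^-1 s^-1, quadratic chain termination
    k2: float = 7.9              # L mol^-1 s^-1, chain propagation
    RH_conc: float = 11.75       # mol/L, substrate
    Vi: float = 1e-7             # mol L^-1 s^-1, initiation rate
    T: float = 348.0             # K

    def __post_init__(self) -> None:
        for name in ("two_k6", "k2", "RH_conc", "Vi", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RateTable:
    """(inhibitor concentration, initial oxygen-uptake rate) observations.

    Exactly one zero-concentration row designates the uninhibited rate V0.
    """

    inhibitor_id: str
    conc: np.ndarray            # mol/L
    rates: np.ndarray           # mol L^-1 s^-1

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.conc.shape != self.rates.shape or self.conc.ndim != 1:
            raise ValueError("conc and rates must be 1-d arrays of equal length")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be positive")
        if int(np.sum(self.conc == 0)) != 1:
            raise ValueError("exactly one conc = 0 row (the uninhibited rate) is required")
        inhibited = self.rates[self.conc > 0][np.argsort(self.conc[self.conc > 0])]
        if np.any(np.diff(inhibited) > 0):
            warnings.warn(
                f"{self.inhibitor_id}: inhibited rate is not monotonically "
                "non-increasing with concentration"
            )

    @property
    def V0(self) -> float:
        return float(self.rates[self.conc == 0][0])


@dataclass
class KineticCurve:
    """Oxygen-uptake curve: time (s) vs absorbed oxygen (mol/L)."""

    time: np.ndarray
    uptake: np.ndarray
    inhibitor_conc: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.uptake = np.asarray(self.uptake, dtype=float)
        if self.time.shape != self.uptake.shape or self.time.ndim != 1:
            raise ValueError("time and uptake must be 1-d arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class FK7Fit:
    fk7: float
    fk7_se: float
    slope: float                # F per (mol/L)
    slope_se: float
    conc: np.ndarray
    F_values: np.ndarray


@dataclass
class InductionPeriod:
    tau: float                  # s
    distinct_regimes: bool
    slope_initial: float
    slope_final: float


@dataclass
class StoichFit:
    f_stoich: float
    f_se: float


@dataclass
class InhibitionResult:
    """Fitted antioxidant parameters: f k7, f, k7 = f k7 / f and log10 k7."""

    fk7: float
    fk7_se: float
    f_stoich: float
    f_se: float
    k7: float
    k7_se: float
    logk7: float


def initiation_rate(T: float, AIBN_conc: float, e: float = 0.5) -> float:
    """Initiation rate Vi = 2 e kp [AIBN] with log10 kp = 17.70 - 35/(4.575e-3 T)."""
    if T <= 0:
        raise ValueError("T must be positive")
    if AIBN_conc < 0:
        raise ValueError("AIBN concentration must be >= 0")
    if not 0 < e <= 1:
        raise ValueError("radical escape probability e must be in (0, 1]")
    kp = 10.0 ** (17.70 - 35.0 / (4.575e-3 * T))
    return 2.0 * e * kp * AIBN_conc


def initiator_decay_constant(T: float) -> float:
    """AIBN decay rate constant kp (s^-1) at temperature T."""
    return 10.0 ** (17.70 - 35.0 / (4.575e-3 * T))


def initial_rate(
    curve: KineticCurve,
    window: Optional[float] = None,
    n_points: Optional[int] = None,
) -> tuple[float, float, float]:
    """Least-squares slope of the initial section of an uptake curve.

    ``window`` selects points with t <= window (seconds); ``n_points``
    selects the first n points; by default the first 20% of the points
    (at least 3) are used.  Returns (rate, standard error, window R^2).
    """
    t, u = curve.time, curve.uptake
    if window is not None:
        mask = t <= window
        if window > t[-1]:
            raise ValueError("window exceeds the recorded time span")
        t, u = t[mask], u[mask]
    elif n_points is not None:
        if n_points > t.size:
            raise ValueError("window exceeds the recorded data")
        t, u = t[:n_points], u[:n_points]
    else:
        k = max(3, t.size // 5)
        t, u = t[:k], u[:k]
    if t.size < 3:
        raise ValueError(f"initial window must contain >= 3 points, got {t.size}")
    fit = stats.linregress(t, u)
    return float(fit.slope), float(fit.stderr), float(fit.rvalue**2)


def f_parameter(V0: float, V: float) -> float:
    """Inhibition parameter F = V0/V - V/V0."""
    if V0 <= 0 or V <= 0:
        raise ValueError("rates must be positive")
    if V > V0:
        warnings.warn("inhibited rate exceeds the uninhibited rate (F < 0)")
    return V0 / V - V / V0


def _through_origin_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Through-origin OLS slope of y on x with its standard error."""
    sxx = float(np.dot(x, x))
    slope = float(np.dot(x, y)) / sxx
    if x.size > 1:
        rss = float(np.sum((y - slope * x) ** 2))
        se = math.sqrt(rss / (x.size - 1) / sxx)
    else:
        se = 0.0
    return slope, se


def fit_fk7(table: RateTable, constants: Optional[KineticConstants] = None) -> FK7Fit:
    """Effective inhibition constant f k7 from a rate table.

    F is computed per inhibited row and fitted through the origin against
    concentration; f k7 = slope * sqrt(2 k6 Vi).
    """
    constants = constants or KineticConstants()
    mask = table.conc > 0
    conc = table.conc[mask]
    if conc.size < 2:
        raise ValueError("need at least 2 nonzero concentrations")
    V0 = table.V0
    F = np.array([f_parameter(V0, v) for v in table.rates[mask]])
    slope, slope_se = _through_origin_slope(conc, F)
    if np.all(F == 0):
        warnings.warn("all F values are zero; fk7 = 0")
    elif slope < 0:
        warnings.warn(f"{table.inhibitor_id}: negative F slope (non-inhibitor?)")
    scale = math.sqrt(constants.two_k6 * constants.Vi)
    return FK7Fit(
        fk7=slope * scale,
        fk7_se=slope_se * scale,
        slope=slope,
        slope_se=slope_se,
        conc=conc,
        F_values=F,
    )


def induction_period(curve: KineticCurve, slope_rtol: float = 0.05) -> InductionPeriod:
    """Induction period by the two-tangent construction.

    The curve is split into an initial (inhibited) and final (uninhibited)
    linear segment at the breakpoint minimizing the total two-line squared
    error; tau is the abscissa of the intersection of the two fitted lines.
    Curves whose two slopes agree within ``slope_rtol`` have no induction
    period (tau = 0, flagged).
    """
    t, u = curve.time, curve.uptake
    n = t.size
    if n < 6:
        raise ValueError("need at least 6 points to detect two regimes")
    best = None
    for k in range(3, n - 2):
        a1, b1 = np.polyfit(t[:k], u[:k], 1)
        a2, b2 = np.polyfit(t[k:], u[k:], 1)
        sse = float(np.sum((u[:k] - (a1 * t[:k] + b1)) ** 2)) + float(
            np.sum((u[k:] - (a2 * t[k:] + b2)) ** 2)
        )
        if best is None or sse < best[0]:
            best = (sse, a1, b1, a2, b2)
    _, a1, b1, a2, b2 = best
    scale = max(abs(a1), abs(a2), 1e-300)
    if abs(a2 - a1) / scale < slope_rtol:
        return InductionPeriod(0.0, False, a1, a2)
    tau = (b1 - b2) / (a2 - a1)
    return InductionPeriod(float(tau), True, float(a1), float(a2))


def fit_f_stoich(points: Sequence[tuple[float, float]], Vi: float) -> StoichFit:
    """Stoichiometric coefficient f from (concentration, tau) points: tau = f [InH] / Vi."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (conc, tau) points")
    conc, tau = pts[:, 0], pts[:, 1]
    slope, slope_se = _through_origin_slope(conc, tau)
    if slope < 0:
        raise ValueError("negative tau-vs-concentration slope")
    return StoichFit(f_stoich=slope * Vi, f_se=slope_se * Vi)


def k7_from(
    fk7: float, f_stoich: float, fk7_se: float = 0.0, f_se: float = 0.0
) -> InhibitionResult:
    """k7 = f k7 / f with quadrature error propagation; logk7 = log10 k7."""
    if f_stoich <= 0:
        raise ValueError("stoichiometric coefficient f must be positive")
    k7 = fk7 / f_stoich
    rel = 0.0
    if fk7 != 0:
        rel = math.sqrt((fk7_se / fk7) ** 2 + (f_se / f_stoich) ** 2)
    return InhibitionResult(
        fk7=fk7,
        fk7_se=fk7_se,
        f_stoich=f_stoich,
        f_se=f_se,
        k7=k7,
        k7_se=abs(k7) * rel,
        logk7=math.log10(k7),
    )


def analyze_rate_table(
    table: RateTable,
    f_stoich: float,
    f_se: float = 0.0,
    constants: Optional[KineticConstants] = None,
) -> InhibitionResult:
    """Full chain: fit f k7 from the rate table, then k7 = f k7 / f."""
    fit = fit_fk7(table, constants)
    return k7_from(fit.fk7, f_stoich, fk7_se=fit.fk7_se, f_se=f_se)
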