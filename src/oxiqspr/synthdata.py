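"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators:

* kinetics — rate tables and oxygen-uptake curves produced from the
  quasi-steady-state law of inhibited chain oxidation.  Given the true
  effective inhibition constant fk7, F = fk7 c / sqrt(2 k6 Vi) and the
  rate ratio x = V/V0 solves x^2 + F x - 1 = 0, i.e.
  x = (-F + sqrt(F^2 + 4)) / 2.  Curves are piecewise linear: inhibited
  slope before the induction period tau = f c / Vi, uninhibited slope V0
  after, continuous at the corner (optionally smoothed).

* QSPR — structure-activity datasets over a combinatorial phenol grammar
  (ortho/para alkyl, alkylthio, methoxy and chroman-2-yl substituents)
  where log k7 is an exact affine function of MNA descriptor counts plus
  Gaussian noise, so every modelling stage can be checked by parameter
  recovery against known ground truth.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem_graph import MolecularGraph, parse_structures
from .dataset import ActivityRecord
from .descriptors import mna_descriptors
from .kinetics import KineticConstants, KineticCurve, RateTable

#: default inhibitor concentration grid, mol/L
DEFAULT_CONC_GRID = tuple(c * 1e-6 for c in (0.44, 0.94, 1.24, 1.88, 2.50, 3.13))


@dataclass
class KineticSimSpec:
    fk7_true: float = 1.32e6          # L mol^-1 s^-1
    f_true: float = 30.0              # chains terminated per inhibitor molecule
    V0: float = 2.30e-6               # uninhibited rate, mol L^-1 s^-1
    constants: KineticConstants = field(default_factory=KineticConstants)
    conc_grid: Sequence[float] = DEFAULT_CONC_GRID
    noise_sd: float = 0.0             # relative (multiplicative) noise fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fk7_true, self.f_true, self.V0) <= 0:
            raise ValueError("fk7_true, f_true and V0 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def steady_state_rate_ratio(F: float) -> float:
    """Positive root x = V/V0 of x^2 + F x - 1 = 0."""
    return (-F + math.sqrt(F * F + 4.0)) / 2.0


def generate_rate_table(spec: KineticSimSpec) -> RateTable:
    """Rate table from the quasi-steady-state law, including the conc = 0 row."""
    rng = np.random.default_rng(spec.seed)
    scale = math.sqrt(spec.constants.two_k6 * spec.constants.Vi)
    conc = np.concatenate([[0.0], np.asarray(spec.conc_grid, dtype=float)])
    rates = []
    for c in conc:
        F = spec.fk7_true * c / scale
        v = spec.V0 * steady_state_rate_ratio(F)
        if spec.noise_sd > 0:
            v *= 1.0 + rng.normal(0.0, spec.noise_sd)
        rates.append(v)
    return RateTable(inhibitor_id="synthetic", conc=conc, rates=np.array(rates))


def generate_curves(
    spec: KineticSimSpec,
    n_points: int = 200,
    smoothing_halfwidth: float = 0.0,
) -> list[KineticCurve]:
    """Oxygen-uptake curves, one per concentration in the grid (plus conc 0).

    Each inhibited curve rises with the suppressed rate until
    tau = f_true * c / Vi, then with the uninhibited rate V0, continuous at
    the corner.  ``smoothing_halfwidth`` (seconds) optionally rounds the
    corner with a quadratic blend, mimicking real curves.  Noise is additive
    Gaussian with sd = noise_sd * max uptake.
    """
    rng = np.random.default_rng(spec.seed + 1)
    scale = math.sqrt(spec.constants.two_k6 * spec.constants.Vi)
    curves = []
    for c in [0.0, *spec.conc_grid]:
        tau = spec.f_true * c / spec.constants.Vi
        v_inh = spec.V0 * steady_state_rate_ratio(spec.fk7_true * c / scale)
        t_max = max(1.6 * tau, 3000.0)
        t = np.linspace(0.0, t_max, n_points)
        if tau == 0:
            u = spec.V0 * t
        else:
            u = np.where(t < tau, v_inh * t, v_inh * tau + spec.V0 * (t - tau))
            w = smoothing_halfwidth
            if w > 0:
                inside = np.abs(t - tau) < w
                # quadratic blend matching both slopes and the corner value
                u[inside] = (
                    v_inh * tau
                    + v_inh * (t[inside] - tau)
                    + (spec.V0 - v_inh) * (t[inside] - tau + w) ** 2 / (4.0 * w)
                )
        if spec.noise_sd > 0:
            u = u + rng.normal(0.0, spec.noise_sd * float(u.max()), u.shape)
        curves.append(KineticCurve(time=t, uptake=u, inhibitor_conc=c))
    return curves


# ---------------------------------------------------------------------------
# structure-activity generator
# ---------------------------------------------------------------------------

#: substituents attached at the 2-, 4- and 6-positions of a phenol core;
#: "[H]" leaves the position unsubstituted
PHENOL_SUBSTITUENTS = (
    "[H]", "C", "CC", "C(C)C", "C(C)(C)C", "CCC",
    "SC", "SCC", "SCCC", "OC", "C2CCc3ccccc3O2",
)

_PHENOL_TEMPLATE = "Oc1c({a})cc({b})cc1{c}"


@dataclass
class QsprSimSpec:
    n_compounds: int = 120
    descriptor_level: int = 2
    n_support: int = 8                # descriptors carrying true signal
    noise_sd: float = 0.3             # log-unit Gaussian noise on the activity
    activity_offset: float = 1.0      # minimum of the noise-free activity
    activity_range: float = 7.0       # span of the noise-free activity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 30:
            raise ValueError("n_compounds must be >= 30")
        if self.noise_sd < 0 or self.activity_range <= 0:
            raise ValueError("invalid noise_sd or activity_range")


def _grammar_smiles() -> list[str]:
    combos = itertools.product(PHENOL_SUBSTITUENTS, repeat=3)
    return [_PHENOL_TEMPLATE.format(a=a, b=b, c=c) for a, b, c in combos]


@dataclass
class QsprDataset:
    structures: list[MolecularGraph]
    records: list[ActivityRecord]
    support: list[str]                # descriptor texts carrying signal
    weights: np.ndarray               # effective per-count weights (post-scaling)
    intercept: float
    noise_free: np.ndarray            # activities before noise


def generate_qspr_dataset(spec: QsprSimSpec) -> QsprDataset:
    """Deterministic structure-activity dataset with known linear ground truth."""
    rng = np.random.default_rng(spec.seed)
    pool = _grammar_smiles()
    if spec.n_compounds > len(pool):
        warnings.warn("requested n exceeds grammar capacity; sampling with replacement")
        idx = rng.choice(len(pool), size=spec.n_compounds, replace=True)
    else:
        idx = rng.choice(len(pool), size=spec.n_compounds, replace=False)
    smiles = [pool[i] for i in sorted(idx.tolist())]
    source = "\n".join(f"{s} cmpd{k + 1}" for k, s in enumerate(smiles))
    structures = parse_structures(source, format="smiles")

    counts = [mna_descriptors(g, spec.descriptor_level) for g in structures]
    # support: descriptors present in 20-80% of compounds, so they vary
    presence: Counter = Counter()
    for ct in counts:
        for d in ct:
            presence[d.text] += 1
    n = len(structures)
    candidates = sorted(
        t for t, k in presence.items() if 0.2 * n <= k <= 0.8 * n
    )
    if len(candidates) < spec.n_support:
        candidates = sorted(presence)
    support = [
        candidates[i]
        for i in sorted(rng.choice(len(candidates), size=spec.n_support, replace=False))
    ]
    raw_w = rng.normal(0.0, 1.0, size=spec.n_support)

    X = np.array(
        [[sum(c for d, c in ct.items() if d.text == s) for s in support] for ct in counts],
        dtype=float,
    )
    raw = X @ raw_w
    span = float(raw.max() - raw.min())
    if span == 0:
        raise RuntimeError("degenerate grammar sample: no activity variation")
    scale = spec.activity_range / span
    weights = raw_w * scale
    intercept = spec.activity_offset - float(raw.min()) * scale
    noise_free = intercept + X @ weights
    y = noise_free + rng.normal(0.0, spec.noise_sd, size=n)

    records = [
        ActivityRecord(id=g.id, logk7=float(v), structure=g)
        for g, v in zip(structures, y)
    ]
    return QsprDataset(
        structures=structures,
        records=records,
        support=support,
        weights=weights,
        intercept=intercept,
        noise_free=noise_free,
    )
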