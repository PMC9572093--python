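"""Self-consistent-regression consensus QSPR models for log k7.

A partial model is produced by self-consistent regression (SCR): iterative
ridge-regularized least squares with backward elimination of descriptors
whose coefficient |t| falls below a significance threshold, until a compact
equation of significant variables remains (the surviving equation is refit
by ordinary least squares, so exact linear signals are recovered without
ridge bias).  An optional radial-basis refinement (RBF-SCR) interpolates the
SCR residuals with a Gaussian kernel over the selected-descriptor subspace.

A consensus model is an ensemble of such partial models, each fitted on a
random 80% of the training rows and, for the mixed preset, on alternating
descriptor-family variants (MNA neighborhood levels with and without RBF
refinement).  The consensus prediction is the arithmetic mean of the
partial predictions that lie inside the applicability domain (AD); internal
predictivity Q^2_LMO comes from each partial's own held-out 20%.

The AD combines a leverage check in each partial's selected-column space
(threshold 3 p / n with p the hat dimension) with the fraction of a query
compound's descriptor occurrences that fall outside the training
vocabulary (threshold 0.2).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .chem_graph import MolecularGraph, parse_structures
from .dataset import ActivityRecord
from .descriptors import DescriptorMatrix, matrix_for_graphs

DEFAULT_SEED = 20191


@dataclass
class SCRConfig:
    ridge_lambda: Optional[float] = None   # None -> 1e-4 * trace(X'X)/p
    t_threshold: float = 2.0
    max_vars: int = 30


@dataclass
class PartialModel:
    """One regression equation: selected descriptors, coefficients, fit stats."""

    columns: list[str]
    coef: np.ndarray
    intercept: float
    r2: float
    f_stat: float
    sd: float
    col_means: np.ndarray          # selected-column means on the fitting rows
    gram_inv: np.ndarray           # inv(Xc'Xc + eps I), for leverage
    n_fit: int
    family: int = 0
    holdout: list[int] = field(default_factory=list)
    rbf: Optional["RBFPart"] = None

    @property
    def n_vars(self) -> int:
        return len(self.columns)

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        if not self.columns:
            return np.zeros((len(X), 0))
        return X.reindex(columns=self.columns, fill_value=0.0).to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = self._design(X)
        out = self.intercept + (Z @ self.coef if self.n_vars else 0.0)
        out = np.full(len(X), self.intercept) if self.n_vars == 0 else out
        if self.rbf is not None:
            out = out + self.rbf.correction(Z)
        return np.asarray(out, dtype=float)

    def leverage(self, X: pd.DataFrame) -> np.ndarray:
        if self.n_vars == 0:
            return np.full(len(X), 1.0 / self.n_fit)
        Zc = self._design(X) - self.col_means
        return 1.0 / self.n_fit + np.einsum("ij,jk,ik->i", Zc, self.gram_inv, Zc)

    @property
    def leverage_threshold(self) -> float:
        return 3.0 * (self.n_vars + 1) / self.n_fit


@dataclass
class RBFPart:
    """Gaussian radial-basis interpolator of SCR residuals."""

    centers: np.ndarray
    alpha: np.ndarray
    width: float

    def correction(self, Z: np.ndarray) -> np.ndarray:
        if self.centers.shape[1] == 0:
            return np.zeros(Z.shape[0])
        d2 = cdist(Z, self.centers, "sqeuclidean")
        return np.exp(-d2 / (2.0 * self.width**2)) @ self.alpha


def _ridge_solve(Xc: np.ndarray, yc: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    p = Xc.shape[1]
    A = Xc.T @ Xc + lam * np.eye(p)
    A_inv = np.linalg.inv(A)
    return A_inv @ (Xc.T @ yc), A_inv


def fit_scr(
    X: Union[pd.DataFrame, DescriptorMatrix],
    y: Sequence[float],
    config: Optional[SCRConfig] = None,
) -> PartialModel:
    """Self-consistent regression: ridge fits with |t|-backward elimination.

    Columns with |t| below the threshold are dropped (all at once); when all
    survivors are significant but more than ``max_vars`` remain, the single
    worst is dropped.  The final equation is refit by OLS on the surviving
    columns and reported with R^2, the regression F statistic and the
    residual SD.  An empty selection yields an intercept-only model.
    """
    config = config or SCRConfig()
    frame = X.values if isinstance(X, DescriptorMatrix) else X
    y = np.asarray(y, dtype=float)
    n = len(frame)
    if y.shape != (n,):
        raise ValueError("y length must match the number of rows in X")
    if n < 10:
        raise ValueError(f"need at least 10 rows, got {n}")
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValueError("zero variance in y")
    max_vars = min(config.max_vars, n // 2 - 1)

    # pre-drop constant columns
    arr = frame.to_numpy(dtype=float)
    keep = np.where(arr.std(axis=0) > 0)[0]
    cols = [frame.columns[i] for i in keep]
    arr = arr[:, keep]
    y_mean = float(y.mean())
    yc = y - y_mean

    active = list(range(len(cols)))
    while active:
        Xa = arr[:, active]
        mu = Xa.mean(axis=0)
        Xc = Xa - mu
        p = len(active)
        lam = config.ridge_lambda
        if lam is None:
            lam = 1e-4 * float(np.trace(Xc.T @ Xc)) / p
        coef, A_inv = _ridge_solve(Xc, yc, max(lam, 1e-12))
        rss = float(np.sum((yc - Xc @ coef) ** 2))
        dof = max(n - p - 1, 1)
        sigma2 = max(rss / dof, 1e-12 * var_y)
        se = np.sqrt(sigma2 * np.clip(np.diag(A_inv), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(coef) / np.where(se > 0, se, np.inf)
        below = np.where(t < config.t_threshold)[0]
        if below.size == 0:
            if p > max_vars:
                active.pop(int(np.argmin(t)))
                continue
            break
        # drop the worst insignificant columns, at most a quarter of the
        # active set per pass: mass-dropping correlated descriptors on an
        # inflated noise estimate destabilizes the selection
        n_drop = min(below.size, max(1, p // 4))
        worst = set(below[np.argsort(t[below])][:n_drop].tolist())
        if n_drop == p:
            active = []
            break
        active = [a for i, a in enumerate(active) if i not in worst]

    return _final_fit(arr, cols, active, y, family=0)


def _final_fit(
    arr: np.ndarray,
    cols: list[str],
    active: list[int],
    y: np.ndarray,
    family: int,
) -> PartialModel:
    """OLS refit on the selected columns plus leverage bookkeeping."""
    n = len(y)
    y_mean = float(y.mean())
    ss_tot = float(np.sum((y - y_mean) ** 2))
    if not active:
        return PartialModel(
            columns=[], coef=np.zeros(0), intercept=y_mean,
            r2=0.0, f_stat=0.0, sd=float(np.std(y, ddof=1)) if n > 1 else 0.0,
            col_means=np.zeros(0), gram_inv=np.zeros((0, 0)), n_fit=n, family=family,
        )
    Xa = arr[:, active]
    mu = Xa.mean(axis=0)
    Xc = Xa - mu
    coef, *_ = np.linalg.lstsq(Xc, y - y_mean, rcond=None)
    intercept = y_mean - float(mu @ coef)
    resid = y - (intercept + Xa @ coef)
    rss = float(np.sum(resid**2))
    p = len(active)
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 0.0
    dof = max(n - p - 1, 1)
    f_stat = (r2 / p) / max((1.0 - r2) / dof, 1e-300) if p else 0.0
    sd = math.sqrt(rss / dof)
    gram = Xc.T @ Xc
    eps = 1e-10 * max(float(np.trace(gram)) / p, 1.0)
    gram_inv = np.linalg.inv(gram + eps * np.eye(p))
    return PartialModel(
        columns=[cols[i] for i in active],
        coef=coef,
        intercept=intercept,
        r2=float(np.clip(r2, 0.0, 1.0)),
        f_stat=float(f_stat),
        sd=sd,
        col_means=mu,
        gram_inv=gram_inv,
        n_fit=n,
        family=family,
    )


def fit_rbf_scr(
    X: Union[pd.DataFrame, DescriptorMatrix],
    y: Sequence[float],
    base: PartialModel,
    kernel_width: Union[float, str] = "auto",
) -> PartialModel:
    """Attach a Gaussian RBF interpolator of the residuals to a fitted SCR model.

    ``kernel_width="auto"`` uses the median pairwise Euclidean distance of
    the training rows in the selected-column subspace.  The kernel solve is
    ridge-stabilized, so duplicate rows with conflicting y are tolerated.
    """
    frame = X.values if isinstance(X, DescriptorMatrix) else X
    y = np.asarray(y, dtype=float)
    Z = base._design(frame)
    resid = y - base.predict(frame)
    if Z.shape[1] == 0:
        rbf = RBFPart(centers=np.zeros((0, 0)), alpha=np.zeros(0), width=1.0)
    else:
        if kernel_width == "auto":
            dists = pdist(Z)
            positive = dists[dists > 0]
            width = float(np.median(positive)) if positive.size else 1.0
        else:
            width = float(kernel_width)
            if width <= 0:
                raise ValueError("kernel_width must be positive")
        K = np.exp(-cdist(Z, Z, "sqeuclidean") / (2.0 * width**2))
        # smooth Gaussian kernels are numerically rank-deficient: solve in the
        # least-squares sense (SVD) so duplicate/near-duplicate rows and
        # ill-conditioning degrade gracefully instead of exploding
        alpha, *_ = np.linalg.lstsq(K + 1e-10 * np.eye(len(Z)), resid, rcond=None)
        rbf = RBFPart(centers=Z, alpha=alpha, width=width)
    out = PartialModel(
        columns=list(base.columns),
        coef=base.coef.copy(),
        intercept=base.intercept,
        r2=base.r2,
        f_stat=base.f_stat,
        sd=base.sd,
        col_means=base.col_means.copy(),
        gram_inv=base.gram_inv.copy(),
        n_fit=base.n_fit,
        family=base.family,
        rbf=rbf,
    )
    return out


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    """One descriptor-family variant: MNA neighborhood level +- RBF refinement."""

    level: int
    use_rbf: bool
    vocabulary: Optional[list[str]] = None


_PRESETS = {
    "mna": lambda level, use_rbf: [FamilySpec(level, use_rbf)],
    "qna-like": lambda level, use_rbf: [FamilySpec(max(1, level - 1), True)],
    "both": lambda level, use_rbf: [
        FamilySpec(1, False), FamilySpec(2, False), FamilySpec(3, False),
        FamilySpec(1, True), FamilySpec(2, True), FamilySpec(3, True),
    ],
}


@dataclass
class ADCheck:
    in_ad: bool
    leverage: float               # mean partial leverage / threshold ratio
    unseen_descriptor_fraction: float


@dataclass
class ConsensusModel:
    families: list[FamilySpec]
    partials: list[PartialModel]
    scr_config: SCRConfig
    seed: int
    train_mean: float
    train_range: float
    q2_lmo: Optional[float]
    training_r2: float
    ad_unseen_threshold: float = 0.2

    @property
    def n_partials(self) -> int:
        return len(self.partials)

    # -- prediction -------------------------------------------------------

    def _family_matrices(self, graphs: Sequence[MolecularGraph]) -> list[DescriptorMatrix]:
        return [
            matrix_for_graphs(graphs, level=f.level, vocabulary=f.vocabulary)
            for f in self.families
        ]

    def predict(self, compounds) -> pd.DataFrame:
        """Consensus prediction with applicability-domain assessment.

        ``compounds`` may be molecular graphs, SMILES strings, or SMILES
        flat-file text.  Returns a DataFrame with columns id, logk7_pred,
        sd_partials, in_ad, leverage, unseen_fraction.
        """
        graphs = _as_graphs(compounds)
        mats = self._family_matrices(graphs)
        n = len(graphs)
        preds = np.zeros((self.n_partials, n))
        in_lev = np.zeros((self.n_partials, n), dtype=bool)
        lev_ratio = np.zeros((self.n_partials, n))
        for k, pm in enumerate(self.partials):
            frame = mats[pm.family].values
            preds[k] = pm.predict(frame)
            lev = pm.leverage(frame)
            lev_ratio[k] = lev / pm.leverage_threshold
            in_lev[k] = lev <= pm.leverage_threshold
        unseen = np.mean(
            [m.unseen_fraction.to_numpy() for m in mats if m.unseen_fraction is not None],
            axis=0,
        )
        rows = []
        for j, g in enumerate(graphs):
            ok = in_lev[:, j]
            use = preds[ok, j] if ok.any() else preds[:, j]
            in_ad = bool(
                unseen[j] <= self.ad_unseen_threshold and ok.mean() >= 0.5
            )
            rows.append(
                {
                    "id": g.id,
                    "logk7_pred": float(use.mean()),
                    "sd_partials": float(use.std(ddof=1)) if use.size > 1 else 0.0,
                    "in_ad": in_ad,
                    "leverage": float(lev_ratio[:, j].mean()),
                    "unseen_fraction": float(unseen[j]),
                }
            )
        return pd.DataFrame(rows)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        def _pm(pm: PartialModel) -> dict:
            d = {
                "columns": pm.columns,
                "coef": pm.coef.tolist(),
                "intercept": pm.intercept,
                "r2": pm.r2,
                "f_stat": pm.f_stat,
                "sd": pm.sd,
                "col_means": pm.col_means.tolist(),
                "gram_inv": pm.gram_inv.tolist(),
                "n_fit": pm.n_fit,
                "family": pm.family,
                "holdout": pm.holdout,
                "rbf": None,
            }
            if pm.rbf is not None:
                d["rbf"] = {
                    "centers": pm.rbf.centers.tolist(),
                    "alpha": pm.rbf.alpha.tolist(),
                    "width": pm.rbf.width,
                }
            return d

        doc = {
            "families": [
                {"level": f.level, "use_rbf": f.use_rbf, "vocabulary": f.vocabulary}
                for f in self.families
            ],
            "partials": [_pm(pm) for pm in self.partials],
            "scr_config": {
                "ridge_lambda": self.scr_config.ridge_lambda,
                "t_threshold": self.scr_config.t_threshold,
                "max_vars": self.scr_config.max_vars,
            },
            "seed": self.seed,
            "train_mean": self.train_mean,
            "train_range": self.train_range,
            "q2_lmo": self.q2_lmo,
            "training_r2": self.training_r2,
            "ad_unseen_threshold": self.ad_unseen_threshold,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ConsensusModel":
        doc = json.loads(text)

        def _pm(d: dict) -> PartialModel:
            rbf = None
            if d["rbf"] is not None:
                rbf = RBFPart(
                    centers=np.array(d["rbf"]["centers"], dtype=float).reshape(
                        len(d["rbf"]["alpha"]), -1
                    )
                    if d["rbf"]["alpha"]
                    else np.zeros((0, 0)),
                    alpha=np.array(d["rbf"]["alpha"], dtype=float),
                    width=d["rbf"]["width"],
                )
            p = len(d["columns"])
            return PartialModel(
                columns=d["columns"],
                coef=np.array(d["coef"], dtype=float),
                intercept=d["intercept"],
                r2=d["r2"],
                f_stat=d["f_stat"],
                sd=d["sd"],
                col_means=np.array(d["col_means"], dtype=float),
                gram_inv=np.array(d["gram_inv"], dtype=float).reshape(p, p),
                n_fit=d["n_fit"],
                family=d["family"],
                holdout=list(d["holdout"]),
                rbf=rbf,
            )

        return cls(
            families=[FamilySpec(**f) for f in doc["families"]],
            partials=[_pm(d) for d in doc["partials"]],
            scr_config=SCRConfig(**doc["scr_config"]),
            seed=doc["seed"],
            train_mean=doc["train_mean"],
            train_range=doc["train_range"],
            q2_lmo=doc["q2_lmo"],
            training_r2=doc["training_r2"],
            ad_unseen_threshold=doc["ad_unseen_threshold"],
        )


def _as_graphs(compounds) -> list[MolecularGraph]:
    if isinstance(compounds, str):
        return parse_structures(compounds, format="smiles")
    out = []
    for k, c in enumerate(compounds):
        if isinstance(c, MolecularGraph):
            out.append(c)
        elif isinstance(c, str):
            out.extend(parse_structures(c, format="smiles"))
        else:
            raise TypeError(f"cannot interpret compound {k}: {type(c)}")
    return out


def fit_consensus(
    records: Sequence[ActivityRecord],
    preset: str = "mna",
    n_partials: Optional[int] = None,
    level: int = 2,
    use_rbf: bool = False,
    leave_fraction: float = 0.2,
    seed: int = DEFAULT_SEED,
    scr_config: Optional[SCRConfig] = None,
) -> ConsensusModel:
    """Fit a consensus ensemble of SCR partial models.

    Each partial leaves out a random ``leave_fraction`` of the training rows
    (0 disables resampling, making all partials of one family identical) and
    uses the descriptor-family variant assigned by the preset: "mna" (one
    family at ``level``), "qna-like" (the stand-in second family), or "both"
    (alternating MNA levels 1-3 with and without RBF refinement; default
    320 partials).
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    if n_partials is None:
        n_partials = 320 if preset == "both" else 20
    if n_partials < 2:
        raise ValueError("n_partials must be >= 2")
    if len(records) < 30:
        raise ValueError(f"need at least 30 training records, got {len(records)}")
    scr_config = scr_config or SCRConfig()
    graphs = _as_graphs([r.structure for r in records])
    for g, r in zip(graphs, records):
        if g.id is None or g.id.startswith("mol"):
            g.id = r.id
    y = np.asarray([r.logk7 for r in records], dtype=float)
    n = len(y)

    families = _PRESETS[preset](level, use_rbf)
    mats: list[DescriptorMatrix] = []
    for f in families:
        m = matrix_for_graphs(graphs, level=f.level)
        f.vocabulary = list(m.vocabulary)
        mats.append(m)

    rng = np.random.default_rng(seed)
    m_hold = int(round(leave_fraction * n))
    partials: list[PartialModel] = []
    q2_terms: list[float] = []
    for k in range(n_partials):
        fam_idx = k % len(families)
        fam = families[fam_idx]
        frame = mats[fam_idx].values
        if m_hold > 0:
            hold = np.sort(rng.choice(n, size=m_hold, replace=False))
        else:
            hold = np.array([], dtype=int)
        fit_rows = np.setdiff1d(np.arange(n), hold)
        pm = fit_scr(frame.iloc[fit_rows], y[fit_rows], scr_config)
        pm.family = fam_idx
        if fam.use_rbf:
            pm = fit_rbf_scr(frame.iloc[fit_rows], y[fit_rows], pm)
        pm.holdout = hold.tolist()
        if hold.size:
            y_hat = pm.predict(frame.iloc[hold])
            press = float(np.sum((y[hold] - y_hat) ** 2))
            ss = float(np.sum((y[hold] - y[fit_rows].mean()) ** 2))
            if ss > 0:
                q2_terms.append(1.0 - press / ss)
        partials.append(pm)

    # training-set consensus R^2 (plain mean over all partials)
    train_preds = np.mean(
        [pm.predict(mats[pm.family].values) for pm in partials], axis=0
    )
    ss_res = float(np.sum((y - train_preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    training_r2 = 1.0 - ss_res / ss_tot

    return ConsensusModel(
        families=families,
        partials=partials,
        scr_config=scr_config,
        seed=seed,
        train_mean=float(y.mean()),
        train_range=float(y.max() - y.min()),
        q2_lmo=float(np.mean(q2_terms)) if q2_terms else None,
        training_r2=float(training_r2),
    )


def cross_validate_lmo(
    X: Union[pd.DataFrame, DescriptorMatrix],
    y: Sequence[float],
    scr_config: Optional[SCRConfig] = None,
    n_rounds: int = 20,
    leave_fraction: float = 0.20,
    seed: int = DEFAULT_SEED,
    use_rbf: bool = False,
) -> float:
    """Leave-many-out cross-validation: mean over rounds of 1 - PRESS/SS_tot
    on a randomly held-out ``leave_fraction`` of the rows (defaults: 20
    rounds of 20%)."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if not 0 < leave_fraction < 0.5:
        raise ValueError("leave_fraction must be in (0, 0.5)")
    frame = X.values if isinstance(X, DescriptorMatrix) else X
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    m = max(1, int(round(leave_fraction * n)))
    scores = []
    for _ in range(n_rounds):
        hold = np.sort(rng.choice(n, size=m, replace=False))
        fit_rows = np.setdiff1d(np.arange(n), hold)
        pm = fit_scr(frame.iloc[fit_rows], y[fit_rows], scr_config)
        if use_rbf:
            pm = fit_rbf_scr(frame.iloc[fit_rows], y[fit_rows], pm)
        y_hat = pm.predict(frame.iloc[hold])
        press = float(np.sum((y[hold] - y_hat) ** 2))
        ss = float(np.sum((y[hold] - y[fit_rows].mean()) ** 2))
        if ss > 0:
            scores.append(1.0 - press / ss)
    return float(np.mean(scores))
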