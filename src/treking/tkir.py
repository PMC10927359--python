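"""Temporal kinase regression (tKiR): per-window elastic-net deconvolution
of a kinase-inhibitor screen.

Kinase-inhibitor polypharmacology lets a small screen interrogate a large
kinome: each inhibitor partially inhibits many kinases, with the residual
in-vitro activity tabulated in an inhibitor x kinase specificity panel. KiR
regresses the phenotype readout (here, normalized per-window AUC of the
cell-index curve) on that panel with an elastic-net penalty; kinases with
nonzero coefficients are implicated, the coefficient sign giving the
functionality: positive = barrier-strengthening (+1), negative =
barrier-weakening (-1). tKiR repeats the fit independently in each sliding
time window, yielding a kinase x window functionality matrix; kinases called
with both signs over time are "switch kinases".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import LeaveOneOut

from .kinetics import AUCMatrix, WindowGrid

logger = logging.getLogger("treking.tkir")

NONZERO_TOL = 1e-8


@dataclass
class KinaseActivityPanel:
    """Inhibitor x kinase residual activity (percent remaining, 0-100)."""

    matrix: pd.DataFrame  # index inhibitor, columns kinase

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 100):
            raise ValueError("residual activities must lie in [0, 100]")
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate kinase names in panel")

    @property
    def kinases(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def inhibitors(self) -> list[str]:
        return list(self.matrix.index)

    def fractions(self) -> pd.DataFrame:
        """Panel rescaled to fraction activity in [0, 1] (the design matrix)."""
        return self.matrix / 100.0

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, index_label="inhibitor")

    @classmethod
    def from_csv(cls, path) -> "KinaseActivityPanel":
        return cls(pd.read_csv(path, index_col="inhibitor"))


@dataclass
class TkirConfig:
    """Penalty and cross-validation settings for the per-window fits.

    alpha is the L1/L2 mixing (near-lasso default 0.9 keeps kinase sets
    sparse); lam fixes the penalty strength, or None to choose it at the
    minimum leave-one-out CV error over a 50-point log grid. n=28 screens
    favor leave-one-out.
    """

    alpha: float = 0.9
    lam: float | None = None
    n_lambdas: int = 50
    lambda_eps: float = 1e-3
    lambda_rule: str = "1se"      # "1se" (sparser, glmnet-style) or "min"
    cv: str = "loo"
    max_iter: int = 100_000
    tol: float = 1e-6
    nonzero_tol: float = NONZERO_TOL
    call_rule: str = "dominant"   # "dominant" (|b| >= call_frac * window max)
    call_frac: float = 0.5        # or "nonzero" (|b| > nonzero_tol)
    seed: int = 0


@dataclass
class WindowFit:
    window_id: float
    intercept: float
    coef: pd.Series            # one coefficient per panel kinase
    lam: float
    alpha: float
    cv_error: np.ndarray | None = None
    informative: bool = True   # CV beat the intercept-only null by > 1 SE

    @property
    def selected(self) -> list[str]:
        return list(self.coef.index[np.abs(self.coef.to_numpy()) > NONZERO_TOL])


@dataclass
class FunctionalityMatrix:
    """Kinase x window calls in {-1, 0, +1}.

    -1: barrier-weakening; +1: barrier-strengthening; 0: not predicted.
    Columns are window midpoints in increasing order.
    """

    calls: pd.DataFrame        # index kinase, columns window midpoint, int entries
    condition: str = ""
    grid: WindowGrid | None = None

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("functionality entries must be in {-1, 0, +1}")
        mids = list(self.calls.columns)
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise ValueError("columns must be ordered by window midpoint")

    def to_csv(self, path) -> None:
        self.calls.to_csv(path, index_label="kinase")

    @classmethod
    def from_csv(cls, path, condition: str = "") -> "FunctionalityMatrix":
        df = pd.read_csv(path, index_col="kinase")
        df.columns = df.columns.astype(float)
        return cls(calls=df.astype(int), condition=condition)

    def drop_never_selected(self) -> "FunctionalityMatrix":
        keep = (self.calls != 0).any(axis=1)
        return FunctionalityMatrix(
            calls=self.calls.loc[keep], condition=self.condition, grid=self.grid
        )


# ---------------------------------------------------------------------------
# Per-window fits
# ---------------------------------------------------------------------------

def fit_window(
    y: pd.Series,
    panel: KinaseActivityPanel,
    config: TkirConfig | None = None,
    window_id: float = float("nan"),
) -> WindowFit:
    """Elastic-net fit of one window's normalized AUC on fraction activity.

    Minimizes (1/2n)·Σ(yᵢ−β₀−xᵢβ)² + λ(α‖β‖₁ + (1−α)/2·‖β‖₂²); the
    intercept is always fit and never penalized, and columns are not
    standardized so slope signs stay interpretable. λ=0 (or below 1e-15) is
    the unpenalized least-squares limit.

    When λ is chosen by cross-validation, two guards keep calls honest:
    a window whose best CV error does not beat the intercept-only null by
    more than one standard error carries no kinase information (its
    anchored 0-100 response is amplified noise) and returns all-zero
    coefficients; otherwise λ defaults to the sparsest value within one
    standard error of the CV minimum (glmnet's lambda.1se;
    config.lambda_rule="min" selects the plain CV minimum).
    """
    config = config or TkirConfig()
    if y.isna().any():
        raise ValueError("NaN in response vector")
    if len(y) < 3:
        raise ValueError("need at least 3 observations per window")
    X = panel.fractions().loc[y.index].to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)

    cv_error = None
    if np.ptp(yv) == 0:
        # no variance to explain: all-zero coefficients, intercept = mean
        coef = np.zeros(X.shape[1])
        intercept = float(yv.mean())
        lam = config.lam if config.lam is not None else 0.0
    elif config.lam is not None and config.lam < 1e-15:
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(yv)), X]), yv, rcond=None
        )
        intercept, coef, lam = float(beta[0]), beta[1:], 0.0
    elif config.lam is not None:
        model = ElasticNet(
            alpha=config.lam, l1_ratio=config.alpha, fit_intercept=True,
            max_iter=config.max_iter, tol=config.tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, yv)
        intercept, coef, lam = float(model.intercept_), model.coef_, config.lam
    else:
        cv = LeaveOneOut() if config.cv == "loo" else int(config.cv)
        model = ElasticNetCV(
            l1_ratio=config.alpha, alphas=config.n_lambdas,
            eps=config.lambda_eps, cv=cv, fit_intercept=True,
            max_iter=config.max_iter, tol=config.tol, n_jobs=None,
            random_state=config.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, yv)
        cv_error = model.mse_path_.mean(axis=-1)
        se = model.mse_path_.std(axis=-1, ddof=1) / np.sqrt(
            model.mse_path_.shape[-1])
        # null gate: alphas_ descend, so index 0 is the intercept-only
        # (all-coefficients-zero) model; a window is informative only when
        # the best CV error beats the null by more than one standard error
        best = int(np.argmin(cv_error))
        informative = cv_error[best] < cv_error[0] - se[0]
        if not informative:
            return WindowFit(
                window_id=window_id, intercept=float(yv.mean()),
                coef=pd.Series(np.zeros(X.shape[1]), index=panel.kinases),
                lam=float(model.alphas_[0]), alpha=config.alpha,
                cv_error=cv_error, informative=False,
            )
        if config.lambda_rule == "1se":
            # sparsest lambda whose CV error is within one standard error of
            # the minimum (glmnet's lambda.1se)
            cutoff = cv_error[best] + se[best]
            ok = np.nonzero(cv_error <= cutoff)[0]
            lam = float(model.alphas_[ok[0]])   # alphas_ descend: first = largest
            if lam != float(model.alpha_):
                refit = ElasticNet(
                    alpha=lam, l1_ratio=config.alpha, fit_intercept=True,
                    max_iter=config.max_iter, tol=config.tol,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    refit.fit(X, yv)
                model = refit
        elif config.lambda_rule == "min":
            lam = float(model.alpha_)
        else:
            raise ValueError(f"unknown lambda_rule {config.lambda_rule!r}")
        intercept, coef = float(model.intercept_), model.coef_

    return WindowFit(
        window_id=window_id,
        intercept=intercept,
        coef=pd.Series(coef, index=panel.kinases),
        lam=lam,
        alpha=config.alpha,
        cv_error=cv_error,
    )


def classify_functionality(
    fit: WindowFit,
    tol: float = NONZERO_TOL,
    call_rule: str = "nonzero",
    call_frac: float = 0.5,
) -> pd.Series:
    """Sign rule: β > tol → +1 (strengthening); β < −tol → −1 (weakening).

    call_rule="dominant" additionally requires |β| within a factor
    1/call_frac of the window's largest coefficient. Elastic net shares
    weight across kinases whose inhibition profiles are correlated, so
    small satellite coefficients shadow every real signal; the dominant
    rule keeps only the coefficients that carry the window's signal.
    """
    coef = fit.coef.to_numpy()
    thresh = tol
    if call_rule == "dominant":
        mx = float(np.max(np.abs(coef))) if coef.size else 0.0
        thresh = max(tol, call_frac * mx)
    elif call_rule != "nonzero":
        raise ValueError(f"unknown call_rule {call_rule!r}")
    calls = np.zeros(len(coef), dtype=int)
    calls[coef > thresh] = 1
    calls[coef < -thresh] = -1
    return pd.Series(calls, index=fit.coef.index)


def build_functionality_matrix(
    auc: AUCMatrix,
    panel: KinaseActivityPanel,
    grid: WindowGrid | None = None,
    config: TkirConfig | None = None,
    condition: str = "",
    drop_never_selected: bool = False,
) -> FunctionalityMatrix:
    """One elastic-net fit per window; calls assembled column-wise.

    The control (DMSO) row is excluded from every fit's response.
    """
    config = config or TkirConfig()
    grid = grid or auc.grid
    if grid is not None and len(grid) != auc.normalized.shape[1]:
        raise ValueError("AUC matrix windows do not match the window grid")
    y_index = [i for i in auc.normalized.index if i != auc.control_id]
    cols: dict[float, pd.Series] = {}
    for mid in auc.normalized.columns:
        try:
            fit = fit_window(auc.normalized.loc[y_index, mid], panel, config,
                             window_id=mid)
        except Exception as exc:  # attach window id for diagnosis
            raise type(exc)(f"window {mid}: {exc}") from exc
        cols[mid] = classify_functionality(
            fit, config.nonzero_tol, config.call_rule, config.call_frac)
    calls = pd.DataFrame(cols, index=panel.kinases).astype(int)
    m = FunctionalityMatrix(calls=calls, condition=condition, grid=grid)
    return m.drop_never_selected() if drop_never_selected else m


def detect_switch_kinases(m: FunctionalityMatrix) -> set[str]:
    """Kinases called with both signs over time (−1 and +1 in one row)."""
    has_neg = (m.calls == -1).any(axis=1)
    has_pos = (m.calls == 1).any(axis=1)
    return set(m.calls.index[has_neg & has_pos])


# ---------------------------------------------------------------------------
# Phase summaries and cross-condition comparison
# ---------------------------------------------------------------------------

def summarize_phases(
    m: FunctionalityMatrix, phases: dict[str, tuple[int, int]]
) -> pd.DataFrame:
    """Per-phase counts of kinases with any weakening / strengthening call.

    phases maps a name to an inclusive (first, last) window-index range;
    ranges must be disjoint and lie within the grid.
    """
    n = m.calls.shape[1]
    spans = sorted(phases.values())
    for (a, b) in spans:
        if a < 0 or b >= n or a > b:
            raise ValueError(f"phase range ({a}, {b}) outside the window grid")
    for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
        if a1 <= b0:
            raise ValueError("phase ranges must be disjoint")
    rows = {}
    for name, (a, b) in phases.items():
        block = m.calls.iloc[:, a : b + 1]
        rows[name] = {
            "weakening": int(((block == -1).any(axis=1)).sum()),
            "strengthening": int(((block == 1).any(axis=1)).sum()),
        }
    return pd.DataFrame(rows).T


def phase_kinase_sets(
    m: FunctionalityMatrix, phase: tuple[int, int]
) -> dict[str, set[str]]:
    a, b = phase
    block = m.calls.iloc[:, a : b + 1]
    return {
        "weakening": set(block.index[(block == -1).any(axis=1)]),
        "strengthening": set(block.index[(block == 1).any(axis=1)]),
    }


def venn_counts(setA: set[str], setB: set[str]) -> dict[str, int]:
    """Common / unique counts across two conditions' kinase sets."""
    return {
        "A_only": len(setA - setB),
        "B_only": len(setB - setA),
        "common": len(setA & setB),
        "union": len(setA | setB),
    }


def condition_correlation(
    aucA: AUCMatrix, aucB: AUCMatrix, exclude_control: bool = True
) -> pd.Series:
    """Per-window Pearson r between two conditions' inhibitor AUC vectors.

    The DMSO control is excluded by default (it is pinned to 100 in both
    conditions and would inflate r). Zero-variance windows yield NaN with a
    warning.
    """
    if list(aucA.normalized.index) != list(aucB.normalized.index):
        raise ValueError("conditions must share the inhibitor set")
    if list(aucA.normalized.columns) != list(aucB.normalized.columns):
        raise ValueError("conditions must share the window grid")
    idx = [
        i for i in aucA.normalized.index
        if not (exclude_control and i == aucA.control_id)
    ]
    out = {}
    for mid in aucA.normalized.columns:
        a = aucA.normalized.loc[idx, mid].to_numpy(dtype=float)
        b = aucB.normalized.loc[idx, mid].to_numpy(dtype=float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            logger.warning("zero variance in window %s; Pearson r undefined", mid)
            out[mid] = np.nan
        else:
            out[mid] = float(stats.pearsonr(a, b).statistic)
    return pd.Series(out)


@dataclass
class ConditionComparison:
    """Cross-condition summary: per-window r, kinase-set overlaps, switches."""

    pearson_r: pd.Series
    overlaps: dict[str, dict[str, int]] = field(default_factory=dict)
    phase_counts: dict[str, pd.DataFrame] = field(default_factory=dict)
    switch_kinases: dict[str, set[str]] = field(default_factory=dict)


def compare_conditions(
    aucA: AUCMatrix, aucB: AUCMatrix,
    mA: FunctionalityMatrix, mB: FunctionalityMatrix,
    phases: dict[str, tuple[int, int]] | None = None,
) -> ConditionComparison:
    r = condition_correlation(aucA, aucB)
    predA = set(mA.drop_never_selected().calls.index)
    predB = set(mB.drop_never_selected().calls.index)
    comp = ConditionComparison(pearson_r=r)
    comp.overlaps["predicted"] = venn_counts(predA, predB)
    comp.switch_kinases = {
        mA.condition or "A": detect_switch_kinases(mA),
        mB.condition or "B": detect_switch_kinases(mB),
    }
    if phases:
        comp.phase_counts = {
            mA.condition or "A": summarize_phases(mA, phases),
            mB.condition or "B": summarize_phases(mB, phases),
        }
    return comp
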