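"""Residual diagnostics and the outlier-exclusion refit loop.

The published regression was accepted only after its residuals passed a
Lilliefors normality test and a graphical homoscedasticity check; seven
outlying specimens were removed and the model refitted on the pruned tree.
This module operationalizes that loop: a Monte-Carlo Lilliefors test, a
normalized-residual outlier rule (|z| > 2 by default), and
:func:`refit_excluding`, which prunes the tree, refits the lambda-model PGLS
and re-runs the diagnostics.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import pcm
from .treedata import CalibratedTree, SpecimenTable, prune_tips

log = logging.getLogger(__name__)

__all__ = [
    "LILLIEFORS_SEED",
    "lilliefors_test",
    "flag_outliers",
    "DiagnosticsReport",
    "diagnose",
    "refit_excluding",
]

LILLIEFORS_SEED = 20190627
MC_REPS = 10_000
OUTLIER_THRESHOLD = 2.0


def _lilliefors_statistic(x: np.ndarray) -> float:
    """sup |empirical CDF - fitted normal CDF| with estimated mean and sd."""
    n = len(x)
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


@functools.lru_cache(maxsize=32)
def _null_distribution(n: int, reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic."""
    rng = np.random.default_rng(seed)
    samples = rng.standard_normal((reps, n))
    z = (samples - samples.mean(axis=1, keepdims=True)) / samples.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
    return np.sort(d)


def _dallal_wilkinson_p(d: float, n: int) -> float:
    """Closed-form approximation to the Lilliefors p-value (option)."""
    if n > 100:
        d = d * (n / 100.0) ** 0.49
        n = 100
    p = np.exp(
        -7.01256 * d * d * (n + 2.78019)
        + 2.99587 * d * np.sqrt(n + 2.78019)
        - 0.122119
        + 0.974598 / np.sqrt(n)
        + 1.67997 / n
    )
    return float(min(max(p, 0.0), 1.0))


def lilliefors_test(
    residuals,
    mc_reps: int = MC_REPS,
    seed: int = LILLIEFORS_SEED,
    method: str = "mc",
) -> tuple[float, float]:
    """Lilliefors normality test; returns (statistic, p-value).

    ``method="mc"`` (default) estimates the p-value as the proportion of
    ``mc_reps`` standard-normal samples of the same size whose statistic
    reaches the observed one, with a fixed seed for reproducibility;
    ``method="dallal-wilkinson"`` uses the published closed-form
    approximation instead.
    """
    x = np.asarray(residuals, float)
    if len(x) < 4:
        raise ValueError("Lilliefors test needs n >= 4")
    if x.std(ddof=1) == 0:
        raise ValueError("degenerate sample: zero variance")
    d = _lilliefors_statistic(x)
    if method == "dallal-wilkinson":
        return d, _dallal_wilkinson_p(d, len(x))
    if method != "mc":
        raise ValueError("method must be 'mc' or 'dallal-wilkinson'")
    null = _null_distribution(len(x), mc_reps, seed)
    p = float(np.mean(null >= d))
    return d, p


def flag_outliers(fit: pcm.GLSFit, threshold: float = OUTLIER_THRESHOLD) -> list[str]:
    """Specimens whose |normalized residual| exceeds ``threshold``.

    Returned in decreasing order of |residual| magnitude.
    """
    z = np.abs(fit.resid_norm)
    order = np.argsort(-z)
    return [fit.tip_order[i] for i in order if z[i] > threshold]


@dataclass
class DiagnosticsReport:
    """Residual diagnostics of one PGLS fit."""

    lilliefors_d: float
    lilliefors_p: float
    normal_at_05: bool
    outliers: list[str]
    residual_vs_fitted: pd.DataFrame
    spearman_rho: float       # |residual| vs fitted (auxiliary homoscedasticity check)
    spearman_p: float

    def to_dict(self) -> dict:
        return {
            "lilliefors_d": self.lilliefors_d,
            "lilliefors_p": self.lilliefors_p,
            "normal_at_05": self.normal_at_05,
            "outliers": list(self.outliers),
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "residual_vs_fitted": self.residual_vs_fitted.to_dict(orient="list"),
        }


def diagnose(
    fit: pcm.GLSFit,
    threshold: float = OUTLIER_THRESHOLD,
    mc_reps: int = MC_REPS,
    seed: int = LILLIEFORS_SEED,
) -> DiagnosticsReport:
    """Normality, outlier and homoscedasticity diagnostics for a fit."""
    d, p = lilliefors_test(fit.resid_norm, mc_reps=mc_reps, seed=seed)
    rho, rho_p = stats.spearmanr(np.abs(fit.resid_norm), fit.fitted)
    pairs = pd.DataFrame({
        "specimen_id": list(fit.tip_order),
        "fitted": fit.fitted,
        "residual": fit.resid,
        "residual_normalized": fit.resid_norm,
    })
    return DiagnosticsReport(
        lilliefors_d=d,
        lilliefors_p=p,
        normal_at_05=bool(p > 0.05),
        outliers=flag_outliers(fit, threshold),
        residual_vs_fitted=pairs,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
    )


def refit_excluding(
    tree: CalibratedTree,
    table: SpecimenTable,
    excluded_ids,
    kind: str = "LAMBDA",
) -> tuple[pcm.GLSFit, DiagnosticsReport]:
    """Prune the excluded specimens from tree and table and refit.

    Branch lengths along retained paths are unchanged by pruning, so the
    covariance among retained tips is the exact submatrix of the original.
    """
    excluded = list(excluded_ids)
    pruned = prune_tips(tree, excluded) if excluded else tree
    if pruned.n_tips < 5:
        raise ValueError(f"over-pruning: only {pruned.n_tips} tips would remain")
    sub = table.exclude(excluded)
    df = sub.df.set_index("specimen_id")
    order = pruned.tip_labels
    missing = [t for t in order if t not in df.index]
    if missing:
        raise ValueError(f"tree tips without specimen rows: {missing}")
    brain = df["brain_g"].astype(float)
    if "brain_g_recomputed" in df:
        brain = brain.fillna(df["brain_g_recomputed"].astype(float))
    if brain.loc[order].isna().any():
        raise ValueError("retained specimens without brain mass; run compute_eq_table first")
    x = np.log10(df.loc[order, "body_g"].astype(float).to_numpy())
    y = np.log10(brain.loc[order].to_numpy())
    fit = pcm.ml_fit(pruned, x, y, kind, tip_order=order)
    return fit, diagnose(fit)
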