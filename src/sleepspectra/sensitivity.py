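"""Disorder-vs-medication sensitivity analyses.

Two tools for separating disease effects from treatment effects in an
observational cohort:

* :func:`stratified_correlation` reruns the age-partialled PSD screen
  inside a stratum (e.g. depression-score correlations restricted to
  antidepressant-naive participants);
* :func:`group_contrast` fits, per frequency bin, an ordinary least
  squares model ``rel_log_psd ~ 1 + age + group`` and reports the
  age-corrected group coefficient with BH-FDR across bins (e.g. comparing
  benzodiazepine users with vs without a diagnosed sleep disorder).

:func:`scalar_outcome_model` applies the same age-corrected regression to
a single scalar outcome such as a sleep-questionnaire score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import association
from .data import CohortTables, SpectraSet

logger = logging.getLogger(__name__)

MIN_STRATUM_N = 10


@dataclass
class SubgroupContrast:
    """Per-bin age-corrected group contrast.

    ``table`` holds one row per bin x channel x state with the OLS group
    coefficient, its standard error, two-sided p, and BH-FDR adjusted p
    across the bins of each channel/state family.
    """

    table: pd.DataFrame
    group_sizes: tuple[int, int]
    alpha: float = association.DEFAULT_ALPHA

    def n_significant(self) -> int:
        return int(self.table["sig"].sum())


def stratified_correlation(
    cohort: CohortTables,
    spectra: SpectraSet,
    stratum: np.ndarray | pd.Series,
    exposure: str | pd.Series,
    alpha: float = association.DEFAULT_ALPHA,
) -> association.AssociationMatrix:
    """Age-partialled PSD screen of one exposure within a stratum.

    ``stratum`` is a boolean mask over subjects; ``exposure`` either names
    an indicator column or supplies a continuous score aligned on the
    cohort index. Strata smaller than 10 subjects are refused: estimates
    at such sizes are not informative.
    """
    mask = np.asarray(stratum, dtype=bool)
    if mask.shape != (cohort.n_subjects,):
        raise ValueError("stratum mask must have one entry per subject")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty stratum")
    if n < MIN_STRATUM_N:
        raise ValueError(
            f"stratum has only {n} subjects (< {MIN_STRATUM_N}); refusing an "
            "underpowered subgroup analysis"
        )
    if isinstance(exposure, str):
        exp_series = cohort.indicators[exposure]
    else:
        exp_series = pd.Series(exposure, index=cohort.subjects)
    sub_idx = cohort.subjects[mask]
    sub_cohort = CohortTables(
        cohort.age.loc[sub_idx],
        exp_series.loc[sub_idx].to_frame(),
        cohort.macrostructure.loc[sub_idx],
    )
    sub_spectra = SpectraSet(
        spectra.values[mask], sub_idx, spectra.channels, spectra.states, spectra.freqs
    )
    return association.screen_psd(sub_cohort, sub_spectra, alpha=alpha)


def _ols_group_block(
    Y: np.ndarray, age: np.ndarray, group: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column OLS of Y on [1, age, group]; returns (beta_group, se, p)."""
    n = len(age)
    X = np.column_stack([np.ones(n), age, group])
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)
    resid = Y - X @ B
    dof = n - X.shape[1]
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[2, 2])
    beta = B[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, p


def group_contrast(
    spectra: SpectraSet,
    group: np.ndarray | pd.Series,
    age: np.ndarray | pd.Series,
    alpha: float = association.DEFAULT_ALPHA,
) -> SubgroupContrast:
    """Age-corrected per-bin OLS contrast between two groups.

    For every bin, channel and state fits ``psd ~ 1 + age + group`` and
    reports the group coefficient; BH-FDR is applied across bins within
    each channel x state family. Subjects with missing group, age or
    spectra are dropped per family. Raises if either group has fewer than
    2 members or the group indicator is constant.
    """
    g = np.asarray(group, dtype=float)
    a = np.asarray(age, dtype=float)
    n1 = int(np.nansum(g == 1))
    n0 = int(np.nansum(g == 0))
    if n0 < 2 or n1 < 2:
        raise ValueError(f"both groups need >= 2 subjects (got {n0} and {n1})")
    rows = []
    for channel in spectra.channels:
        for state in spectra.states:
            Y_full = spectra.get(channel, state)
            mask = (
                np.isfinite(g) & np.isfinite(a) & np.all(np.isfinite(Y_full), axis=1)
            )
            if np.unique(g[mask]).size < 2:
                raise ValueError(f"group constant within ({channel}, {state}) complete cases")
            beta, se, p = _ols_group_block(Y_full[mask], a[mask], g[mask])
            adj, rej = association.bh_fdr(p, alpha)
            for f, b, s, pi, pf, sg in zip(spectra.freqs, beta, se, p, adj, rej):
                rows.append((f, channel, state, b, s, int(mask.sum()), pi, pf, bool(sg)))
    table = pd.DataFrame(
        rows,
        columns=["variable", "channel", "state", "coef", "se", "n", "p", "p_fdr", "sig"],
    )
    return SubgroupContrast(table, (n0, n1), alpha=alpha)


def scalar_outcome_model(
    outcome: np.ndarray | pd.Series,
    group: np.ndarray | pd.Series,
    age: np.ndarray | pd.Series,
) -> dict[str, float]:
    """Age-corrected OLS of a scalar outcome (e.g. questionnaire score).

    Returns the group coefficient B, its standard error, two-sided p and
    the complete-case n from ``outcome ~ 1 + age + group``.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group, dtype=float)
    a = np.asarray(age, dtype=float)
    mask = np.isfinite(y) & np.isfinite(g) & np.isfinite(a)
    if np.unique(g[mask]).size < 2:
        raise ValueError("group constant among complete cases")
    beta, se, p = _ols_group_block(y[mask, None], a[mask], g[mask])
    return {"B": float(beta[0]), "se": float(se[0]), "p": float(p[0]), "n": int(mask.sum())}
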