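"""Age-partialled correlation screens with per-family BH-FDR.

Every health indicator is screened against every sleep-macrostructure
variable and every PSD frequency bin with partial Pearson correlations
controlling for age (point-biserial for 0/1 indicators, which enter the
same formula). p-values come from the t distribution with n - 3 degrees
of freedom and are two-sided. False-discovery control is Benjamini-
Hochberg step-up within a family: the 15 macrostructure variables per
indicator, or the frequency bins per indicator x channel x state.

Missing data is handled pairwise-complete per (indicator, variable) pair;
undefined correlations (zero residual variance) are excluded from the FDR
family and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CohortTables, SpectraSet

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

TABLE_COLUMNS = ["indicator", "variable", "channel", "state", "r", "n", "p", "p_fdr", "sig"]


@dataclass
class AssociationMatrix:
    """Long-format screen results with FDR-adjusted significance masks.

    One row per (indicator, variable/bin, channel, state) with the partial
    correlation ``r``, pairwise-complete ``n``, raw and FDR-adjusted
    p-values and the boolean ``sig`` mask at level ``alpha``.
    """

    table: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    kind: str = "psd"
    bin_freqs: np.ndarray | None = field(default=None, repr=False)

    def coefficient_matrix(self, state: str, channel: str) -> pd.DataFrame:
        """indicators x variables pivot of coefficients for one channel/state."""
        sub = self.table[(self.table.state == state) & (self.table.channel == channel)]
        mat = sub.pivot(index="indicator", columns="variable", values="r")
        if self.bin_freqs is not None:
            mat = mat[[f for f in self.bin_freqs]]
        return mat

    def significant_counts(self) -> pd.Series:
        """Total bandwidth per indicator: number of significant bins across
        all channels and states, regardless of contiguity."""
        return (
            self.table.groupby("indicator", sort=False)["sig"].sum().astype(int)
        )

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, alpha: float = DEFAULT_ALPHA, kind: str = "psd") -> "AssociationMatrix":
        return cls(pd.read_csv(path, sep="\t", comment="#"), alpha=alpha, kind=kind)


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------


def partial_correlation(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float, int]:
    """First-order partial correlation of x and y controlling for z.

    Computed as the Pearson correlation of the residuals of x and y each
    regressed on [1, z]; equivalent to the closed form
    (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)). A 0/1-coded x yields
    the age-partialled point-biserial correlation. Returns (r, two-sided
    p from t with n-3 df, pairwise-complete n); (nan, nan, n) when fewer
    than 4 complete cases or a residual has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    n = int(mask.sum())
    if n < 4:
        return np.nan, np.nan, n
    r, p = _partial_corr_block(x[mask], y[mask, None], z[mask])
    return float(r[0]), float(p[0]), n


def _partial_corr_block(
    x: np.ndarray, Y: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised partial correlation of x with each column of Y given z.

    Inputs must already be complete cases. Returns (r, p) arrays of length
    Y.shape[1]; undefined entries (zero residual variance) are NaN.
    """
    n = len(x)
    X = np.column_stack([np.ones(n), z])
    coef_x, *_ = np.linalg.lstsq(X, x, rcond=None)
    rx = x - X @ coef_x
    coef_y, *_ = np.linalg.lstsq(X, Y, rcond=None)
    RY = Y - X @ coef_y
    sx = np.linalg.norm(rx)
    sy = np.linalg.norm(RY, axis=0)
    # residuals that vanish relative to the data scale (constant input or
    # collinearity with the covariate) leave the correlation undefined
    sx_ok = sx > 1e-12 * np.linalg.norm(x) + 1e-300
    sy_ok = sy > 1e-12 * np.linalg.norm(Y, axis=0) + 1e-300
    denom = sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (RY.T @ rx) / denom
    r = np.where(sx_ok & sy_ok, r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    df = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    p = np.where(np.isfinite(r), p, np.nan)
    return r, p


def bh_fdr(
    p_values: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up with monotonicity enforcement.

    NaN p-values are excluded from the family (they do not count towards
    the family size m) and come back as NaN / not rejected. Returns
    (adjusted p-values, rejection mask).
    """
    p = np.asarray(p_values, dtype=float)
    adj = np.full(p.shape, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    mask = np.isfinite(p)
    if mask.any():
        rej_m, adj_m, _, _ = multipletests(p[mask], alpha=alpha, method="fdr_bh")
        adj[mask] = adj_m
        rej[mask] = rej_m
    return adj, rej


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------


def screen_macrostructure(
    cohort: CohortTables, alpha: float = DEFAULT_ALPHA
) -> AssociationMatrix:
    """Screen every indicator against the 15 macrostructure variables.

    FDR is applied within each indicator's 15-test family at ``alpha``.
    Indicators without at least two distinct observed values are skipped
    with a log entry.
    """
    rows = []
    age = cohort.age.values
    for ind in cohort.indicators.columns:
        x = cohort.indicators[ind].values.astype(float)
        if pd.Series(x).dropna().nunique() < 2:
            logger.warning("indicator %s has < 2 distinct observed values; skipped", ind)
            continue
        family = []
        for var in cohort.macrostructure.columns:
            y = cohort.macrostructure[var].values.astype(float)
            r, p, n = partial_correlation(x, y, age)
            if not np.isfinite(r):
                logger.info("undefined correlation for (%s, %s); excluded from FDR", ind, var)
            family.append((var, r, p, n))
        adj, rej = bh_fdr(np.array([f[2] for f in family]), alpha)
        for (var, r, p, n), pf, sg in zip(family, adj, rej):
            rows.append((ind, var, "", "", r, n, p, pf, bool(sg)))
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return AssociationMatrix(table, alpha=alpha, kind="macrostructure")


def screen_psd(
    cohort: CohortTables, spectra: SpectraSet, alpha: float = DEFAULT_ALPHA
) -> AssociationMatrix:
    """Screen every indicator against relative log-PSD at every bin.

    One BH-FDR family per indicator x channel x state, across the
    frequency bins (193 on the native grid, 48 on the reduced grid).
    Degenerate bins (zero residual variance) are excluded from the family.
    Subjects missing the indicator, age, or that channel/state spectrum
    are dropped per family (spectra are missing as whole vectors, so this
    is pairwise-complete).
    """
    if not cohort.subjects.equals(spectra.subjects):
        raise ValueError("cohort and spectra must be aligned on subjects")
    age = cohort.age.values
    rows = []
    for ind in cohort.indicators.columns:
        x_full = cohort.indicators[ind].values.astype(float)
        if pd.Series(x_full).dropna().nunique() < 2:
            logger.warning("indicator %s has < 2 distinct observed values; skipped", ind)
            continue
        for channel in spectra.channels:
            for state in spectra.states:
                Y_full = spectra.get(channel, state)
                mask = (
                    np.isfinite(x_full) & np.isfinite(age)
                    & np.all(np.isfinite(Y_full), axis=1)
                )
                n = int(mask.sum())
                if n < 4:
                    logger.warning(
                        "family (%s, %s, %s) has n=%d < 4; skipped", ind, channel, state, n
                    )
                    continue
                r, p = _partial_corr_block(x_full[mask], Y_full[mask], age[mask])
                n_undef = int(np.sum(~np.isfinite(r)))
                if n_undef:
                    logger.info(
                        "%d degenerate bins excluded from family (%s, %s, %s)",
                        n_undef, ind, channel, state,
                    )
                adj, rej = bh_fdr(p, alpha)
                for f, ri, pi, pf, sg in zip(spectra.freqs, r, p, adj, rej):
                    rows.append((ind, f, channel, state, ri, n, pi, pf, bool(sg)))
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return AssociationMatrix(table, alpha=alpha, kind="psd", bin_freqs=spectra.freqs.copy())
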