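"""Stereotypical PSD-health patterns: co-correlation, PCA, clustering.

The indicator x bin matrix of age-partialled correlation coefficients is
treated as data in its own right: bins are variables, health indicators
observations. Coefficients from the C3 and C4 channels are averaged;
NREM and REM are analysed separately. A PCA of this matrix (on the
correlation matrix of the 48 reduced bins by default) extracts the
dominant association patterns; components with eigenvalue > 1 are
retained (Kaiser's rule). Indicator scores on the first two NREM and REM
components, together with the total number of significant PSD
correlations, feed a seeded K-means with k=3 to group indicators into
phenotypes (retained sleep / mid-frequency change / accelerated EEG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import association
from .data import CohortTables, SpectraSet
from .spectral import FREQS_REDUCED

logger = logging.getLogger(__name__)

#: Sign convention: flip each PC so its summed loadings above this
#: frequency (Hz) are positive; makes the "acceleration" component stable.
SIGN_PIVOT_HZ = 25.0


@dataclass
class PatternModel:
    """Retained principal components of a coefficient matrix.

    ``loadings``: bins x retained PCs (orthonormal columns);
    ``eigenvalues`` / ``variance_fraction`` cover *all* components (the
    fractions sum to 1); ``scores``: indicators x retained PCs.
    """

    state: str
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    scores: pd.DataFrame
    variant: str = "correlation"

    @property
    def n_retained(self) -> int:
        return self.loadings.shape[1]

    def top2_variance_fraction(self) -> float:
        """Joint variance fraction of the first two components."""
        return float(self.variance_fraction[:2].sum())


@dataclass
class ClusterAssignment:
    """K-means grouping of health indicators.

    Labels are 1-based and canonicalised by descending cluster size.
    ``centroids`` are in z-scored feature space.
    """

    labels: pd.Series
    centroids: pd.DataFrame
    features: pd.DataFrame
    inertia: float

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


# ---------------------------------------------------------------------------
# Coefficient matrices
# ---------------------------------------------------------------------------


def average_channels(assoc: association.AssociationMatrix) -> dict[str, pd.DataFrame]:
    """Element-wise mean of C3 and C4 coefficient matrices, per state.

    If one channel is missing its coefficients, the available channel is
    used with a warning.
    """
    out: dict[str, pd.DataFrame] = {}
    for state in sorted(assoc.table.state.unique()):
        mats = []
        for channel in sorted(assoc.table.channel.unique()):
            mat = assoc.coefficient_matrix(state, channel)
            if mat.empty:
                logger.warning("state %s: channel %s missing, using remaining channel", state, channel)
                continue
            mats.append(mat)
        if not mats:
            raise ValueError(f"no coefficients for state {state}")
        aligned = [m.reindex_like(mats[0]) for m in mats]
        out[state] = sum(aligned) / len(aligned)
    return out


def psd_coefficients_48(
    cohort: CohortTables,
    spectra: SpectraSet,
    alpha: float = association.DEFAULT_ALPHA,
) -> dict[str, pd.DataFrame]:
    """Channel-averaged indicator x 48-bin coefficient matrices per state.

    Coefficients are recomputed on the 4-bin-reduced spectra (rather than
    reducing 193-bin coefficients), then averaged across C3 and C4.
    """
    if spectra.n_bins != 48:
        spectra = spectra.reduced()
    screen = association.screen_psd(cohort, spectra, alpha=alpha)
    return average_channels(screen)


# ---------------------------------------------------------------------------
# Co-correlation and PCA
# ---------------------------------------------------------------------------


def cocorrelation(coeff_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of correlations between bins, across indicators.

    Entry (i, j) correlates bin i's and bin j's coefficient vectors over
    health indicators; symmetric with unit diagonal. Zero-variance bin
    columns give NaN rows/columns (flagged in the log).
    """
    if coeff_matrix.shape[0] < 3:
        raise ValueError("need at least 3 indicators")
    X = coeff_matrix.values
    sd = X.std(axis=0)
    if np.any(sd == 0):
        logger.warning("%d zero-variance bin columns in co-correlation", int(np.sum(sd == 0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(C, index=coeff_matrix.columns, columns=coeff_matrix.columns)


def pca_of_coefficients(
    coeff_matrix: pd.DataFrame,
    state: str = "NREM",
    variant: str = "correlation",
) -> PatternModel:
    """PCA of an indicator x bin coefficient matrix.

    ``variant="correlation"`` (default) standardises bin columns across
    indicators and eigendecomposes their correlation matrix, so the total
    variance equals the number of bins; ``"covariance"`` centres only.
    Components with eigenvalue > 1 are retained (Kaiser); at least one
    component is always kept. Each retained PC is sign-flipped so that its
    summed loadings above 25 Hz are positive, and indicator scores are the
    projections of the (standardised) rows onto the loadings.
    """
    X = coeff_matrix.values.astype(float)
    n_obs, n_bins = X.shape
    if n_obs < 3:
        raise ValueError("need at least 3 indicators (observations) for PCA")
    if n_obs < n_bins:
        logger.warning(
            "PCA with %d observations for %d variables: eigenvectors beyond "
            "rank %d are noise", n_obs, n_bins, n_obs - 1,
        )
    Xc = X - X.mean(axis=0)
    if variant == "correlation":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance bin column; correlation PCA undefined")
        Z = Xc / sd
        C = (Z.T @ Z) / (n_obs - 1)
    elif variant == "covariance":
        Z = Xc
        C = (Z.T @ Z) / (n_obs - 1)
    else:
        raise ValueError(f"unknown PCA variant {variant!r}")
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    variance_fraction = evals / total
    retained = int(np.sum(evals > 1.0)) if variant == "correlation" else int(np.sum(evals > evals.mean()))
    retained = max(retained, 1)

    loadings = evecs[:, :retained].copy()
    freqs = np.asarray(coeff_matrix.columns, dtype=float)
    high = freqs > SIGN_PIVOT_HZ
    for j in range(retained):
        if loadings[high, j].sum() < 0:
            loadings[:, j] *= -1.0
    scores = Z @ loadings
    pc_names = [f"PC{j + 1}" for j in range(retained)]
    return PatternModel(
        state=state,
        loadings=pd.DataFrame(loadings, index=coeff_matrix.columns, columns=pc_names),
        eigenvalues=evals,
        variance_fraction=variance_fraction,
        scores=pd.DataFrame(scores, index=coeff_matrix.index, columns=pc_names),
        variant=variant,
    )


def score_concordance(
    model_nrem: PatternModel, model_rem: PatternModel
) -> pd.DataFrame:
    """Pearson correlations between NREM and REM PC scores of indicators.

    Signs are reported as-is: the sign of PC loadings is arbitrary, so
    only magnitudes are interpretable.
    """
    s1 = model_nrem.scores
    s2 = model_rem.scores.reindex(s1.index)
    out = pd.DataFrame(
        np.nan,
        index=[f"NREM{j + 1}" for j in range(s1.shape[1])],
        columns=[f"REM{j + 1}" for j in range(s2.shape[1])],
    )
    for i, c1 in enumerate(s1.columns):
        for j, c2 in enumerate(s2.columns):
            out.iloc[i, j] = np.corrcoef(s1[c1], s2[c2])[0, 1]
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_features(
    model_nrem: PatternModel,
    model_rem: PatternModel,
    screen_193: association.AssociationMatrix,
) -> pd.DataFrame:
    """The five K-means features per indicator.

    First two NREM PC scores, first two REM PC scores, and the total count
    of FDR-significant PSD bins across both channels and states from the
    native-resolution screen.
    """
    feats = pd.DataFrame(index=model_nrem.scores.index)
    for k in (1, 2):
        col = f"PC{k}"
        feats[f"nrem_pc{k}"] = model_nrem.scores[col] if col in model_nrem.scores else 0.0
        feats[f"rem_pc{k}"] = (
            model_rem.scores[col].reindex(feats.index) if col in model_rem.scores else 0.0
        )
    counts = screen_193.significant_counts()
    feats["n_significant"] = counts.reindex(feats.index).fillna(0).astype(float)
    return feats


def cluster_indicators(
    features: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_init: int = 50,
) -> ClusterAssignment:
    """Seeded K-means of indicators on z-scored features.

    Runs ``n_init`` restarts and keeps the best within-cluster sum of
    squares; labels are 1-based and relabelled by descending cluster size.
    Indicators with missing features are excluded with a log entry.
    """
    feats = features.dropna(axis=0)
    if len(feats) < len(features):
        logger.warning("excluding %d indicators with missing features", len(features) - len(feats))
    if k > len(feats):
        raise ValueError(f"k={k} exceeds number of indicators ({len(feats)})")
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = (feats - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2**32))
    raw_labels = km.fit_predict(Z.values)
    sizes = pd.Series(raw_labels).value_counts()
    order = sizes.sort_values(ascending=False, kind="stable").index.tolist()
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[l] for l in raw_labels], index=feats.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=range(1, k + 1), columns=feats.columns
    )
    return ClusterAssignment(labels, centroids, feats, float(km.inertia_))
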