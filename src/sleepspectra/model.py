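"""Model/Results interface tying the analysis stages together.

:class:`SleepHealthModel` is built from a cohort table and a spectra set;
``fit()`` runs the three analysis steps in order — (1) age-partialled
correlation screens of macrostructure and PSD with per-family BH-FDR,
(2) PCA of the channel-averaged indicator x 48-bin coefficient matrices
per vigilance state, (3) K-means clustering of indicators on PC scores
and significant-correlation counts — and returns a
:class:`SleepHealthResults` with estimates, diagnostics, a ``summary()``
table and TSV export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, patterns
from .data import CohortTables, SpectraSet
from .io import PipelineConfig, provenance_header

logger = logging.getLogger(__name__)


class SleepHealthModel:
    """Association model between health indicators and sleep measures.

    Parameters
    ----------
    cohort
        Aligned age / health-indicator / macrostructure tables.
    spectra
        Relative log-PSD spectra on the 193-bin grid (subject-aligned).
    alpha
        FDR level for every screening family.
    n_clusters, kmeans_restarts
        K-means settings for the indicator clustering step.
    pca_variant
        "correlation" (standardised bins; default) or "covariance".
    """

    def __init__(
        self,
        cohort: CohortTables,
        spectra: SpectraSet | None,
        alpha: float = 0.05,
        n_clusters: int = 3,
        kmeans_restarts: int = 50,
        pca_variant: str = "correlation",
    ) -> None:
        if spectra is not None and not cohort.subjects.equals(spectra.subjects):
            raise ValueError("cohort and spectra must share the subject index")
        self.cohort = cohort
        self.spectra = spectra
        self.alpha = alpha
        self.n_clusters = n_clusters
        self.kmeans_restarts = kmeans_restarts
        self.pca_variant = pca_variant

    @classmethod
    def from_tables(
        cls, cohort_path: str | Path, spectra_path: str | Path | None = None, **kwargs
    ) -> "SleepHealthModel":
        """Build a model from cohort (and optionally spectra) TSV files."""
        cohort = CohortTables.from_tsv(cohort_path)
        spectra = SpectraSet.from_tsv(spectra_path) if spectra_path else None
        if spectra is not None:
            spectra.subjects = pd.Index(
                [str(s) for s in spectra.subjects], name="subject_id"
            )
        return cls(cohort, spectra, **kwargs)

    def fit(self, seed: int = 0) -> "SleepHealthResults":
        """Run the full screen -> patterns -> clusters pipeline."""
        logger.info("step 1: macrostructure screen")
        macro = association.screen_macrostructure(self.cohort, alpha=self.alpha)
        psd = coeffs = pattern_models = concordance = features = clusters = None
        if self.spectra is not None:
            logger.info("step 1b: PSD screen (%d bins)", self.spectra.n_bins)
            psd = association.screen_psd(self.cohort, self.spectra, alpha=self.alpha)
            logger.info("step 2: coefficient PCA per state")
            coeffs = patterns.psd_coefficients_48(self.cohort, self.spectra, alpha=self.alpha)
            pattern_models = {
                state: patterns.pca_of_coefficients(mat, state=state, variant=self.pca_variant)
                for state, mat in coeffs.items()
            }
            if {"NREM", "REM"} <= set(pattern_models):
                concordance = patterns.score_concordance(
                    pattern_models["NREM"], pattern_models["REM"]
                )
                logger.info("step 3: K-means clustering (k=%d)", self.n_clusters)
                features = patterns.cluster_features(
                    pattern_models["NREM"], pattern_models["REM"], psd
                )
                clusters = patterns.cluster_indicators(
                    features, k=self.n_clusters, seed=seed, n_init=self.kmeans_restarts
                )
        return SleepHealthResults(
            model=self,
            macrostructure_screen=macro,
            psd_screen=psd,
            coefficients=coeffs,
            patterns=pattern_models,
            concordance=concordance,
            cluster_features_=features,
            clusters=clusters,
            seed=seed,
        )


@dataclass
class SleepHealthResults:
    """Fitted association screens, PSD-pattern PCA and indicator clusters."""

    model: SleepHealthModel
    macrostructure_screen: association.AssociationMatrix
    psd_screen: association.AssociationMatrix | None
    coefficients: dict[str, pd.DataFrame] | None
    patterns: dict[str, patterns.PatternModel] | None
    concordance: pd.DataFrame | None
    cluster_features_: pd.DataFrame | None
    clusters: patterns.ClusterAssignment | None
    seed: int = 0

    def summary(self) -> str:
        """Human-readable overview of the fitted results."""
        lines = ["Sleep-EEG / health association results", "=" * 40]
        macro = self.macrostructure_screen.table
        n_ind = macro["indicator"].nunique()
        any_sig = macro.groupby("indicator")["sig"].any().sum()
        lines.append(
            f"Macrostructure screen: {n_ind} indicators x "
            f"{macro['variable'].nunique()} variables; "
            f"{any_sig} indicators with >= 1 FDR-significant correlation"
        )
        if self.psd_screen is not None:
            counts = self.psd_screen.significant_counts()
            zero_frac = (counts == 0).mean()
            lines.append(
                f"PSD screen: {len(counts)} indicators; "
                f"{zero_frac:.0%} with zero significant bins; "
                f"max total bandwidth {counts.max()} bins"
            )
        if self.patterns:
            for state in sorted(self.patterns):
                pm = self.patterns[state]
                vf = pm.variance_fraction
                lines.append(
                    f"{state} PCA: {pm.n_retained} PCs retained (Kaiser); "
                    f"PC1 {vf[0]:.1%}, PC2 {vf[1]:.1%} of between-bin variance "
                    f"(first two jointly {pm.top2_variance_fraction():.1%})"
                )
        if self.concordance is not None:
            diag = [
                abs(self.concordance.iloc[i, i])
                for i in range(min(2, *self.concordance.shape))
            ]
            lines.append(
                "NREM/REM score concordance |r|: "
                + ", ".join(f"PC{i + 1} {v:.2f}" for i, v in enumerate(diag))
            )
        if self.clusters is not None:
            sizes = self.clusters.sizes()
            lines.append(
                "Indicator clusters (k-means): "
                + ", ".join(f"cluster {c}: n={n}" for c, n in sizes.items())
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path, config_hash: str = "unset") -> None:
        """Write all result tables as TSV with provenance headers."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = provenance_header(config_hash)

        def _write(frame: pd.DataFrame, name: str, **kw) -> None:
            path = outdir / name
            with open(path, "w") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                frame.to_csv(fh, sep="\t", **kw)

        _write(self.macrostructure_screen.table, "macrostructure_screen.tsv", index=False)
        if self.psd_screen is not None:
            _write(self.psd_screen.table, "psd_screen.tsv", index=False)
        if self.patterns:
            for state, pm in self.patterns.items():
                _write(pm.loadings, f"loadings_{state}.tsv")
                _write(pm.scores, f"scores_{state}.tsv")
                eig = pd.DataFrame(
                    {"eigenvalue": pm.eigenvalues, "variance_fraction": pm.variance_fraction}
                )
                _write(eig, f"eigenvalues_{state}.tsv", index_label="component")
        if self.concordance is not None:
            _write(self.concordance, "concordance.tsv")
        if self.clusters is not None:
            _write(self.clusters.labels.to_frame(), "clusters.tsv")
            _write(self.clusters.centroids, "cluster_centroids.tsv", index_label="cluster")
        if self.cluster_features_ is not None:
            _write(self.cluster_features_, "cluster_features.tsv")

    # -- plotting -----------------------------------------------------------

    def plot_loadings(self, state: str = "NREM", ax=None):
        """Line plot of retained PC loadings over frequency."""
        import matplotlib.pyplot as plt

        pm = self.patterns[state]
        if ax is None:
            _, ax = plt.subplots()
        freqs = pm.loadings.index.astype(float)
        for j, col in enumerate(pm.loadings.columns):
            ax.plot(freqs, pm.loadings[col], label=f"{col} ({pm.variance_fraction[j]:.0%})")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("loading")
        ax.set_title(f"{state} PC loadings")
        ax.legend()
        return ax

    def plot_scores(self, ax=None):
        """Scatter of indicators on NREM PC1/PC2, coloured by cluster."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scores = self.patterns["NREM"].scores
        labels = (
            self.clusters.labels.reindex(scores.index)
            if self.clusters is not None
            else pd.Series(1, index=scores.index)
        )
        sc = ax.scatter(scores["PC1"], scores["PC2"], c=labels, cmap="viridis", s=18)
        ax.set_xlabel("NREM PC1 score")
        ax.set_ylabel("NREM PC2 score")
        ax.figure.colorbar(sc, ax=ax, label="cluster")
        return ax


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> SleepHealthResults:
    """End-to-end run from files per a :class:`PipelineConfig`.

    Reads the cohort table and either a spectra TSV (spectra mode) or a
    directory of EDF + hypnogram pairs (raw mode, ``<subject>.edf`` with
    ``<subject>.hypnogram.txt``), fits the model, and writes all outputs
    plus a run log into ``config.output_dir``. Deterministic for a fixed
    config; every output carries the config hash.
    """
    from . import __version__, io, spectral
    from .data import SpectraSet

    cohort = CohortTables.from_tsv(config.cohort_path)
    if config.mode == "spectra":
        spectra = SpectraSet.from_tsv(config.spectra_path)
    elif config.mode == "raw":
        subject_spectra = []
        for edf in sorted(Path(config.edf_dir).glob("*.edf")):
            hyp = edf.with_suffix("").with_suffix(".hypnogram.txt")
            rec = io.load_recording(edf, hyp, staging_epoch_s=config.staging_epoch_s)
            subject_spectra.append(
                spectral.compute_subject_spectra(rec, floor_factor=config.psd_floor_factor)
            )
        spectra = SpectraSet.from_subject_spectra(subject_spectra)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    spectra.subjects = pd.Index([str(s) for s in spectra.subjects], name="subject_id")
    cohort_sub = CohortTables(
        cohort.age.loc[spectra.subjects],
        cohort.indicators.loc[spectra.subjects],
        cohort.macrostructure.loc[spectra.subjects],
    )
    model = SleepHealthModel(
        cohort_sub,
        spectra,
        alpha=config.alpha,
        n_clusters=config.k,
        kmeans_restarts=config.kmeans_restarts,
        pca_variant=config.pca_variant,
    )
    results = model.fit(seed=config.seed)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    results.save(outdir, config_hash=chash)
    if config.mode == "raw":
        spectra.to_tsv(outdir / "spectra.tsv")
    if config.run_sensitivity and config.sensitivity_group:
        from . import sensitivity

        group_col = cohort_sub.indicators[config.sensitivity_group]
        if config.sensitivity_within:
            within = cohort_sub.indicators[config.sensitivity_within] == 1
            mask = within.values & group_col.notna().values
            contrast = sensitivity.group_contrast(
                SpectraSet(
                    spectra.values[mask], spectra.subjects[mask],
                    spectra.channels, spectra.states, spectra.freqs,
                ),
                group_col.values[mask],
                cohort_sub.age.values[mask],
                alpha=config.alpha,
            )
        else:
            contrast = sensitivity.group_contrast(
                spectra, group_col.values, cohort_sub.age.values, alpha=config.alpha
            )
        with open(outdir / "sensitivity_contrast.tsv", "w") as fh:
            for line in provenance_header(chash):
                fh.write(f"# {line}\n")
            contrast.table.to_csv(fh, sep="\t", index=False)
    (outdir / "run_log.txt").write_text(
        "\n".join(
            [
                f"sleepspectra version: {__version__}",
                f"config hash: {chash}",
                "config:",
                yaml_dump_config(config),
                "summary:",
                results.summary(),
            ]
        )
        + "\n"
    )
    return results


def yaml_dump_config(config: PipelineConfig) -> str:
    import yaml
    from dataclasses import asdict

    return yaml.safe_dump(asdict(config), sort_keys=True)
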