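"""Per-gene biomarker regression of the combined essentiality score.

For one gene, the fitted CES across cell lines is regressed on the
gene's four molecular features (mutation, copy number, array expression,
RNA-seq expression) by ordinary least squares with an intercept.  A
significant coefficient marks the feature as a candidate biomarker of
essentiality; because lower CES means stronger essentiality, a negative
weight indicates that the feature promotes essentiality.  P-values are
nominal two-sided t-tests with n - p degrees of freedom; a
Benjamini-Hochberg helper is provided for callers who screen many genes
but no correction is applied inside the regression itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .containers import FEATURE_NAMES, FeaturePanel
from .model import CESFit

__all__ = ["BiomarkerResult", "FeatureEffect", "biomarker_regression", "bh_adjust"]


@dataclass
class FeatureEffect:
    feature: str
    estimate: float
    std_error: float
    p_value: float


@dataclass
class BiomarkerResult:
    gene_id: str
    effects: list[FeatureEffect]
    n_cell_lines: int
    dropped_features: list[str]

    def effect(self, feature: str) -> FeatureEffect:
        for rec in self.effects:
            if rec.feature == feature:
                return rec
        raise KeyError(f"feature {feature!r} not in result (dropped or unknown)")


def biomarker_regression(fit: CESFit, features: FeaturePanel,
                         gene: str, min_cell_lines: int = 8) -> BiomarkerResult:
    """OLS of one gene's CES on its molecular features across cell lines.

    Features are expected on the per-cell-line z-score scale used for
    fitting.  Zero-variance features across the usable cell lines are
    dropped and reported in ``dropped_features``.
    """
    if gene not in fit.gene_ids:
        raise KeyError(f"gene {gene!r} not present in the fitted model")
    if features.gene_ids != fit.gene_ids or features.cell_line_ids != fit.cell_line_ids:
        raise ValueError("feature panel is not aligned with the fit")
    i = fit.gene_ids.index(gene)
    y = fit.ces[i, :]
    X_all = np.column_stack([features.layer(name)[i, :] for name in FEATURE_NAMES])
    usable = ~np.isnan(y) & ~np.isnan(X_all).any(axis=1)
    n = int(usable.sum())
    if n < min_cell_lines:
        raise ValueError(
            f"gene {gene!r}: only {n} cell lines with complete data; "
            f"at least {min_cell_lines} required"
        )
    y = y[usable]
    X_all = X_all[usable]

    keep, dropped = [], []
    for k, name in enumerate(FEATURE_NAMES):
        if np.ptp(X_all[:, k]) == 0.0:
            dropped.append(name)
        else:
            keep.append(k)
    if n <= len(keep) + 1:
        raise ValueError(
            f"gene {gene!r}: fewer usable cell lines ({n}) than parameters"
        )
    X = sm.add_constant(X_all[:, keep], has_constant="add")
    res = sm.OLS(y, X).fit()
    effects = []
    for pos, k in enumerate(keep, start=1):
        effects.append(
            FeatureEffect(
                feature=FEATURE_NAMES[k],
                estimate=float(res.params[pos]),
                std_error=float(res.bse[pos]),
                p_value=float(res.pvalues[pos]),
            )
        )
    return BiomarkerResult(
        gene_id=gene, effects=effects, n_cell_lines=n, dropped_features=dropped
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default everywhere)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
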