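"""The combined essentiality score (CES) model and its baselines.

CES predicts the CRISPR essentiality score of gene *i* in cell line *j*
from the shRNA score and four molecular features through a fixed-effect
linear model with one intercept per cell line::

    CES_ij = beta_j + theta_s * shRNA_ij + theta_m * MUT_ij
             + theta_c * CNV_ij + theta_a * EXParray_ij
             + theta_r * EXPrnaseq_ij

The coefficients minimize the sum of squared differences between CES and
the CRISPR scores over all complete (gene, cell line) cells.  The theta
coefficients are global; only the intercept varies by cell line, so one
model is fitted per dataset.  The linear least-squares problem is solved
with a column-pivoted QR decomposition; exactly collinear design columns
are dropped (in pivot order) and reported.

The fitted value can be rewritten as a feature-dependent weighted
average of the two screens,

    CES_ij = (1 - alpha_ij) * CRISPR_ij + alpha_ij * shRNA_ij,

with ``alpha_ij = (CES_ij - CRISPR_ij) / (shRNA_ij - CRISPR_ij)``
wherever the two screens disagree.  Three baselines share the same
machinery: the simple average SA (alpha fixed at 1/2), the null model
without molecular features, and a permutation model in which the feature
vectors are deranged across (gene, cell line) cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .containers import FEATURE_NAMES, FeaturePanel, ScreenMatrix

__all__ = [
    "CESFit",
    "AlphaMatrix",
    "PermutationPlan",
    "fit_ces",
    "fit_ces_null",
    "fit_ces_perm",
    "sa_score",
    "compute_alpha",
]

logger = logging.getLogger(__name__)

#: theta coefficient names in design order.
THETA_NAMES = ("shrna", "mutation", "cnv", "exp_array", "exp_rnaseq")


@dataclass
class CESFit:
    """A fitted combined-essentiality model.

    Attributes
    ----------
    beta
        Per-cell-line intercepts, aligned with ``cell_line_ids``.
    theta
        Mapping from coefficient name (``shrna``, ``mutation``, ``cnv``,
        ``exp_array``, ``exp_rnaseq``) to its fitted value.  For the
        null variant the four feature coefficients are exactly zero.
    theta_se
        Conventional OLS standard errors for the theta coefficients
        (``NaN`` for dropped or fixed-at-zero columns).
    ces
        Fitted score matrix, same shape and identifiers as the input
        screens; cells with any missing predictor are ``NaN``.
    residual_ss
        Sum of squared residuals of the fit over complete cells.
    dropped_columns
        Names of design columns removed for exact rank deficiency.
    model_variant
        One of ``"CES"``, ``"CES_null"``, ``"CES_perm"``.
    """

    gene_ids: list[str]
    cell_line_ids: list[str]
    beta: np.ndarray
    theta: dict[str, float]
    theta_se: dict[str, float]
    ces: np.ndarray
    residual_ss: float
    n_obs: int
    dropped_columns: list[str] = field(default_factory=list)
    model_variant: str = "CES"

    def __post_init__(self) -> None:
        if self.residual_ss < 0:
            raise ValueError("residual_ss must be non-negative")
        if self.model_variant == "CES_null":
            for name in THETA_NAMES[1:]:
                if self.theta[name] != 0.0:
                    raise ValueError(
                        "CES_null variant must have zero feature coefficients"
                    )

    @property
    def theta_s(self) -> float:
        return self.theta["shrna"]

    def ces_matrix(self) -> ScreenMatrix:
        return ScreenMatrix(
            gene_ids=list(self.gene_ids),
            cell_line_ids=list(self.cell_line_ids),
            values=self.ces,
            screen_label=self.model_variant,
        )


@dataclass
class AlphaMatrix:
    """Weights of the shRNA screen in the CES weighted-average form.

    ``values[i, j]`` is ``NaN`` (undefined) where the CES is missing or
    the two screens agree exactly, making the weight indeterminate.
    Alpha is not clipped: values outside [0, 1] indicate extrapolation
    driven by the molecular features.
    """

    gene_ids: list[str]
    cell_line_ids: list[str]
    values: np.ndarray
    undefined_mask: np.ndarray


class PermutationPlan:
    """A seeded derangement of the (gene, cell line) cell index set.

    The mapping sends every flat cell index to a different one (no fixed
    points) and is a bijection, so the permuted feature panel is a
    reshuffled copy of the original with every cell displaced.  The four
    feature layers are shuffled jointly with the same mapping, which
    preserves within-cell feature correlation while breaking the link to
    the cell's own screens.
    """

    def __init__(self, n_genes: int, n_cell_lines: int, mapping: np.ndarray, seed: int | None = None):
        mapping = np.asarray(mapping, dtype=np.int64)
        size = n_genes * n_cell_lines
        if mapping.shape != (size,):
            raise ValueError("mapping must cover every (gene, cell line) pair")
        if not np.array_equal(np.sort(mapping), np.arange(size)):
            raise ValueError("mapping is not a bijection on the cell index set")
        if np.any(mapping == np.arange(size)):
            raise ValueError("mapping has fixed points; a derangement is required")
        self.n_genes = n_genes
        self.n_cell_lines = n_cell_lines
        self.mapping = mapping
        self.seed = seed

    @classmethod
    def generate(cls, n_genes: int, n_cell_lines: int, seed: int = 20191112):
        """Draw a uniformly random cyclic derangement (Sattolo's algorithm)."""
        size = n_genes * n_cell_lines
        if size < 2:
            raise ValueError("need at least two cells to build a derangement")
        rng = np.random.default_rng(seed)
        perm = np.arange(size)
        # Sattolo: every output is a single cycle, hence fixed-point free.
        for i in range(size - 1, 0, -1):
            j = int(rng.integers(0, i))
            perm[i], perm[j] = perm[j], perm[i]
        return cls(n_genes, n_cell_lines, perm, seed=seed)

    def apply(self, layer: np.ndarray) -> np.ndarray:
        """Return the layer with cell (i, j) holding the value of its image."""
        flat = np.asarray(layer, dtype=float).ravel()
        return flat[self.mapping].reshape(self.n_genes, self.n_cell_lines)


def _require_aligned(*mats) -> None:
    first = mats[0]
    for other in mats[1:]:
        if not first.aligned_with(other):
            raise ValueError(
                "inputs are not aligned on identical gene and cell-line sets; "
                "run io.align first"
            )


def _solve_pivoted(X: np.ndarray, y: np.ndarray, column_names: list[str]):
    """Least squares via column-pivoted QR with exact-collinearity pruning.

    Returns (coef, dropped_names, kept_index, XtX_inv_diag) where ``coef``
    has one entry per original column (zero for dropped columns).
    """
    n, p = X.shape
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    kept = np.sort(piv[:rank])
    dropped = [column_names[k] for k in np.sort(piv[rank:])]
    if dropped:
        logger.warning(
            "rank-deficient design: dropping %d dependent column(s): %s",
            len(dropped), ", ".join(dropped),
        )
    Xk = X[:, kept]
    sol, _, _, _ = scipy.linalg.lstsq(Xk, y, lapack_driver="gelsy")
    coef = np.zeros(p)
    coef[kept] = sol
    return coef, dropped, kept


def _fit_linear(crispr: ScreenMatrix, shrna: ScreenMatrix,
                features: FeaturePanel | None, variant: str) -> CESFit:
    """Shared fitting path for the CES, null and permuted variants."""
    M, N = crispr.n_genes, crispr.n_cell_lines
    y_full = crispr.values
    predictors = [shrna.values]
    names = ["shrna"]
    if features is not None:
        for name in FEATURE_NAMES:
            predictors.append(features.layer(name))
            names.append(name)

    complete = ~np.isnan(y_full)
    for layer in predictors:
        complete &= ~np.isnan(layer)
    n_obs = int(complete.sum())
    if n_obs == 0:
        raise ValueError("no complete (gene, cell line) observations to fit")
    if n_obs <= N + 5:
        # Under- or barely determined: the projection (fitted values) is
        # still unique, but individual coefficients may not be.
        logger.warning(
            "only %d complete observations for %d cell-line intercepts; "
            "coefficients may be unidentifiable", n_obs, N,
        )

    rows, cols = np.nonzero(complete)
    y = y_full[rows, cols]
    # Design: N per-cell-line intercept indicators then the slope columns.
    p_slope = len(predictors)
    X = np.zeros((n_obs, N + p_slope))
    X[np.arange(n_obs), cols] = 1.0
    for k, layer in enumerate(predictors):
        X[:, N + k] = layer[rows, cols]
    column_names = [f"beta:{line}" for line in crispr.cell_line_ids] + names

    coef, dropped, kept = _solve_pivoted(X, y, column_names)
    beta = coef[:N]
    slopes = coef[N:]

    fitted = X @ coef
    resid = y - fitted
    residual_ss = float(resid @ resid)

    # Conventional OLS standard errors on the retained columns.
    theta_se = {name: float("nan") for name in THETA_NAMES}
    dof = n_obs - len(kept)
    if dof > 0:
        sigma2 = residual_ss / dof
        Xk = X[:, kept]
        try:
            cov = sigma2 * np.linalg.inv(Xk.T @ Xk)
            se = np.sqrt(np.diag(cov))
            for pos, k in enumerate(kept):
                if k >= N:
                    theta_se[names[k - N]] = float(se[pos])
        except np.linalg.LinAlgError:  # pragma: no cover - kept set is full rank
            pass

    theta = {name: 0.0 for name in THETA_NAMES}
    for k, name in enumerate(names):
        theta[name] = float(slopes[k])

    ces = np.full((M, N), np.nan)
    ces[rows, cols] = fitted

    return CESFit(
        gene_ids=list(crispr.gene_ids),
        cell_line_ids=list(crispr.cell_line_ids),
        beta=beta,
        theta=theta,
        theta_se=theta_se,
        ces=ces,
        residual_ss=residual_ss,
        n_obs=n_obs,
        dropped_columns=dropped,
        model_variant=variant,
    )


def fit_ces(crispr: ScreenMatrix, shrna: ScreenMatrix,
            features: FeaturePanel) -> CESFit:
    """Fit the full CES model.

    All inputs must be per-cell-line z-scored and aligned on identical
    gene and cell-line orderings.  Cells with any missing predictor are
    excluded from the objective and receive a missing fitted score.
    """
    _require_aligned(crispr, shrna, features)
    return _fit_linear(crispr, shrna, features, "CES")


def fit_ces_null(crispr: ScreenMatrix, shrna: ScreenMatrix) -> CESFit:
    """Fit the feature-free baseline ``beta_j + theta_s * shRNA_ij``."""
    _require_aligned(crispr, shrna)
    return _fit_linear(crispr, shrna, None, "CES_null")


def fit_ces_perm(crispr: ScreenMatrix, shrna: ScreenMatrix,
                 features: FeaturePanel, plan: PermutationPlan) -> CESFit:
    """Fit CES with the feature panel deranged across cells.

    Every molecular feature value at cell (i, j) is replaced by the
    value at the cell ``plan.mapping`` sends it to; the same mapping is
    applied jointly to all four layers.  Deterministic given the plan.
    """
    _require_aligned(crispr, shrna, features)
    if (plan.n_genes, plan.n_cell_lines) != (crispr.n_genes, crispr.n_cell_lines):
        raise ValueError("permutation plan shape does not match the dataset")
    permuted = FeaturePanel(
        gene_ids=list(features.gene_ids),
        cell_line_ids=list(features.cell_line_ids),
        normalized=True,
        **{name: plan.apply(features.layer(name)) for name in FEATURE_NAMES},
    )
    fit = _fit_linear(crispr, shrna, permuted, "CES_perm")
    return fit


def sa_score(crispr: ScreenMatrix, shrna: ScreenMatrix) -> ScreenMatrix:
    """Simple-average baseline: the two screens weighted equally.

    ``SA_ij = (CRISPR_ij + shRNA_ij) / 2``; missing wherever either
    screen is missing.
    """
    _require_aligned(crispr, shrna)
    values = (crispr.values + shrna.values) / 2.0
    return ScreenMatrix(
        gene_ids=list(crispr.gene_ids),
        cell_line_ids=list(crispr.cell_line_ids),
        values=values,
        screen_label="SA",
    )


def compute_alpha(fit: CESFit, crispr: ScreenMatrix,
                  shrna: ScreenMatrix) -> AlphaMatrix:
    """Recover the per-cell shRNA weight from a fitted model.

    ``alpha_ij = (CES_ij - CRISPR_ij) / (shRNA_ij - CRISPR_ij)``.  Cells
    where the two screens agree exactly have an indeterminate weight and
    are flagged in ``undefined_mask`` rather than raising.
    """
    if fit.gene_ids != crispr.gene_ids or fit.cell_line_ids != crispr.cell_line_ids:
        raise ValueError("fit is not aligned with the screen matrices")
    _require_aligned(crispr, shrna)
    denom = shrna.values - crispr.values
    numer = fit.ces - crispr.values
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(denom != 0.0, numer / denom, np.nan)
    undefined = np.isnan(fit.ces) | (denom == 0.0) | np.isnan(denom)
    alpha[undefined] = np.nan
    return AlphaMatrix(
        gene_ids=list(fit.gene_ids),
        cell_line_ids=list(fit.cell_line_ids),
        values=alpha,
        undefined_mask=undefined,
    )
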