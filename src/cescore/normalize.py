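"""Per-cell-line z-score normalization.

Every input matrix (screen scores and each molecular feature layer) is
standardized within each cell line before model fitting, so that scores
from different platforms are on a comparable scale.  The sample standard
deviation (denominator ``n - 1``) is used.  A column with no variation is
mapped to all zeros: zero is the post-normalization mean, and a globally
constant column carries no information for the downstream regression.
"""

from __future__ import annotations

import numpy as np

from .containers import FEATURE_NAMES, FeaturePanel, ScreenMatrix

__all__ = ["zscore_normalize", "zscore_columns"]


def zscore_columns(values: np.ndarray, cell_line_ids=None) -> np.ndarray:
    """Z-score each column of ``values`` over its non-missing entries.

    Raises ``ValueError`` naming the cell line for any column with fewer
    than two non-missing values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-d gene x cell-line matrix")
    if cell_line_ids is None:
        cell_line_ids = [str(j) for j in range(values.shape[1])]
    out = values.copy()
    for j, line in enumerate(cell_line_ids):
        col = values[:, j]
        obs = ~np.isnan(col)
        n = int(obs.sum())
        if n < 2:
            raise ValueError(
                f"cell line {line!r} has {n} non-missing value(s); "
                "at least 2 are required for z-score normalization"
            )
        mu = col[obs].mean()
        sd = col[obs].std(ddof=1)
        if sd == 0.0:
            out[obs, j] = 0.0
        else:
            out[obs, j] = (col[obs] - mu) / sd
    return out


def zscore_normalize(data):
    """Return a per-cell-line z-scored copy of a matrix container.

    Accepts a :class:`ScreenMatrix`, a :class:`FeaturePanel` (all four
    layers are normalized independently) or a bare 2-d array.  Missing
    entries stay missing.  The operation is idempotent up to floating
    point: z-scoring an already z-scored column leaves it unchanged.
    """
    if isinstance(data, ScreenMatrix):
        out = data.copy()
        out.values = zscore_columns(data.values, data.cell_line_ids)
        return out
    if isinstance(data, FeaturePanel):
        layers = {
            name: zscore_columns(getattr(data, name), data.cell_line_ids)
            for name in FEATURE_NAMES
        }
        return FeaturePanel(
            gene_ids=list(data.gene_ids),
            cell_line_ids=list(data.cell_line_ids),
            normalized=True,
            **layers,
        )
    return zscore_columns(data)
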