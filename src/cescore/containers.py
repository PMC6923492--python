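"""In-memory containers for gene x cell-line screen and feature matrices.

All matrices are dense ``float64`` arrays with ``NaN`` marking missing
entries.  Rows are genes, columns are cell lines, following the layout of
public dependency-map releases.  The sign convention used throughout the
package is that a lower, more negative essentiality score indicates
stronger depletion and hence higher essentiality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ScreenMatrix",
    "FeaturePanel",
    "FEATURE_NAMES",
]

#: Canonical order of the molecular feature layers.
FEATURE_NAMES = ("mutation", "cnv", "exp_array", "exp_rnaseq")


def _check_ids(ids, what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for x in ids:
            if x in seen:
                dupes.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dupes))}")
    return ids


def _check_values(values, n_genes: int, n_lines: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape != (n_genes, n_lines):
        raise ValueError(
            f"{what} must be a {n_genes} x {n_lines} matrix, got shape {arr.shape}"
        )
    if np.isinf(arr).any():
        raise ValueError(f"{what} contains non-finite (infinite) values")
    return arr


@dataclass
class ScreenMatrix:
    """Gene x cell-line essentiality scores from one screen technology.

    Parameters
    ----------
    gene_ids
        Gene symbols, one per row, no duplicates.
    cell_line_ids
        Cell-line identifiers, one per column, no duplicates.
    values
        Real matrix of scores; ``NaN`` marks missing entries.  Lower
        values mean stronger essentiality.
    screen_label
        Which technology produced the scores (``"CRISPR"`` or
        ``"shRNA"``), or any other short tag for derived score matrices.
    """

    gene_ids: list[str]
    cell_line_ids: list[str]
    values: np.ndarray
    screen_label: str = "CRISPR"

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_line_ids = _check_ids(self.cell_line_ids, "cell line")
        self.values = _check_values(
            self.values, len(self.gene_ids), len(self.cell_line_ids), "values"
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_line_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.cell_line_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, screen_label: str = "CRISPR"):
        return cls(
            gene_ids=list(frame.index),
            cell_line_ids=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            screen_label=screen_label,
        )

    def copy(self) -> "ScreenMatrix":
        return replace(self, values=self.values.copy())

    def aligned_with(self, other: "ScreenMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.cell_line_ids == other.cell_line_ids
        )


@dataclass
class FeaturePanel:
    """Four aligned gene x cell-line molecular feature matrices.

    The layers are: ``mutation`` (raw counts, non-negative before
    normalization), ``cnv`` (log2 CN/2 ratios), ``exp_array`` (log2
    microarray intensities) and ``exp_rnaseq`` (RNA-seq RPKM).  All four
    share the gene and cell-line ordering.
    """

    gene_ids: list[str]
    cell_line_ids: list[str]
    mutation: np.ndarray
    cnv: np.ndarray
    exp_array: np.ndarray
    exp_rnaseq: np.ndarray
    #: True once mutation counts have been normalized (drops the
    #: non-negativity invariant on that layer).
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_line_ids = _check_ids(self.cell_line_ids, "cell line")
        m, n = len(self.gene_ids), len(self.cell_line_ids)
        for name in FEATURE_NAMES:
            setattr(self, name, _check_values(getattr(self, name), m, n, name))
        if not self.normalized:
            mut = self.mutation
            if np.nanmin(mut, initial=0.0) < 0:
                raise ValueError("raw mutation counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_line_ids)

    def layers(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def layer(self, name: str) -> np.ndarray:
        if name not in FEATURE_NAMES:
            raise KeyError(f"unknown feature layer {name!r}")
        return getattr(self, name)

    def copy(self) -> "FeaturePanel":
        return replace(
            self, **{name: getattr(self, name).copy() for name in FEATURE_NAMES}
        )

    def aligned_with(self, other) -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.cell_line_ids == other.cell_line_ids
        )
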