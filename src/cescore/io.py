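"""Readers and writers for the TSV dialects used by the pipeline.

Score and feature matrices are UTF-8 TSV files whose first column is
headed ``gene`` and whose remaining headers are cell-line identifiers;
missing values are encoded as ``NA``.  Gene sets are plain-text symbol
lists, one per line, with ``#`` comments.  Gene identifiers are opaque,
case-sensitive strings; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FEATURE_NAMES, FeaturePanel, ScreenMatrix
from .model import CESFit, THETA_NAMES

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_feature_panel",
    "read_gene_set",
    "write_gene_set",
    "align",
    "write_fit",
    "RunConfig",
]

logger = logging.getLogger(__name__)


def read_matrix(path, screen_label: str = "CRISPR") -> ScreenMatrix:
    """Read a gene x cell-line TSV matrix.

    Raises ``ValueError`` with a line number for malformed headers,
    non-numeric cells and duplicated gene rows.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2 or raw.columns[0] != "gene":
        raise ValueError(
            f"{path}:1: malformed header; expected 'gene' followed by "
            "cell-line identifiers"
        )
    genes = raw.iloc[:, 0].tolist()
    seen: set[str] = set()
    for row, gene in enumerate(genes, start=2):
        if gene in seen:
            raise ValueError(f"{path}:{row}: duplicated gene {gene!r}")
        seen.add(gene)
    lines = list(raw.columns[1:])
    values = np.empty((len(genes), len(lines)))
    for j, col in enumerate(lines):
        cells = raw[col].to_numpy()
        for i, cell in enumerate(cells):
            if cell == "NA" or cell == "":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}:{i + 2}: non-numeric value {cell!r} in column "
                    f"{col!r}"
                ) from None
    return ScreenMatrix(genes, lines, values, screen_label)


def write_matrix(matrix, path) -> None:
    """Write a ScreenMatrix (or any gene x line container) as TSV."""
    frame = pd.DataFrame(matrix.values, index=matrix.gene_ids,
                         columns=matrix.cell_line_ids)
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", na_rep="NA")


def read_feature_panel(paths: dict[str, str | Path]) -> FeaturePanel:
    """Assemble a FeaturePanel from one TSV per layer.

    ``paths`` maps each of ``mutation``, ``cnv``, ``exp_array`` and
    ``exp_rnaseq`` to a file.  All four must share identical gene and
    cell-line orderings (use :func:`align` otherwise).
    """
    missing = [name for name in FEATURE_NAMES if name not in paths]
    if missing:
        raise ValueError(f"feature panel requires files for: {missing}")
    layers = {name: read_matrix(paths[name], screen_label=name)
              for name in FEATURE_NAMES}
    first = layers[FEATURE_NAMES[0]]
    for name in FEATURE_NAMES[1:]:
        if not first.aligned_with(layers[name]):
            raise ValueError(
                f"feature layer {name!r} is not aligned with "
                f"{FEATURE_NAMES[0]!r}; run align on the inputs first"
            )
    return FeaturePanel(
        gene_ids=list(first.gene_ids),
        cell_line_ids=list(first.cell_line_ids),
        **{name: layers[name].values for name in FEATURE_NAMES},
    )


def read_gene_set(path) -> set[str]:
    symbols = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            symbols.add(entry)
    return symbols


def write_gene_set(symbols, path) -> None:
    Path(path).write_text("\n".join(sorted(symbols)) + "\n", encoding="utf-8")


def align(crispr: ScreenMatrix, shrna: ScreenMatrix,
          features: FeaturePanel | None = None):
    """Restrict all inputs to their shared genes and cell lines.

    Outputs use a canonical sorted order.  Returns ``(crispr, shrna,
    features, report)`` where ``report`` records how many identifiers
    each input lost.  Raises on an empty intersection.
    """
    inputs: list[tuple[str, object]] = [("crispr", crispr), ("shrna", shrna)]
    if features is not None:
        inputs.append(("features", features))

    genes = set(crispr.gene_ids)
    lines = set(crispr.cell_line_ids)
    for _, obj in inputs[1:]:
        genes &= set(obj.gene_ids)
        lines &= set(obj.cell_line_ids)
    if not genes or not lines:
        raise ValueError("empty gene or cell-line intersection across inputs")
    if len(genes) < 2 or len(lines) < 2:
        raise ValueError(
            "need at least 2 shared genes and 2 shared cell lines; got "
            f"{len(genes)} gene(s) and {len(lines)} line(s)"
        )
    genes_sorted = sorted(genes)
    lines_sorted = sorted(lines)

    report = {}
    for name, obj in inputs:
        report[name] = {
            "genes_dropped": len(obj.gene_ids) - len(genes_sorted),
            "cell_lines_dropped": len(obj.cell_line_ids) - len(lines_sorted),
        }
        logger.info(
            "align: %s loses %d gene(s), %d cell line(s)", name,
            report[name]["genes_dropped"], report[name]["cell_lines_dropped"],
        )

    def take(values, gene_ids, cell_line_ids):
        gi = [gene_ids.index(g) for g in genes_sorted]
        ci = [cell_line_ids.index(c) for c in lines_sorted]
        return values[np.ix_(gi, ci)]

    crispr_out = ScreenMatrix(
        genes_sorted, lines_sorted,
        take(crispr.values, crispr.gene_ids, crispr.cell_line_ids),
        crispr.screen_label,
    )
    shrna_out = ScreenMatrix(
        list(genes_sorted), list(lines_sorted),
        take(shrna.values, shrna.gene_ids, shrna.cell_line_ids),
        shrna.screen_label,
    )
    features_out = None
    if features is not None:
        features_out = FeaturePanel(
            gene_ids=list(genes_sorted), cell_line_ids=list(lines_sorted),
            normalized=features.normalized,
            **{
                name: take(features.layer(name), features.gene_ids,
                           features.cell_line_ids)
                for name in FEATURE_NAMES
            },
        )
    return crispr_out, shrna_out, features_out, report


def write_fit(fit: CESFit, out_dir) -> None:
    """Serialize a CESFit: beta TSV, theta TSV and the CES matrix TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"cell_line": fit.cell_line_ids, "beta": fit.beta}
    ).to_csv(out / "beta.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "feature": list(THETA_NAMES),
            "estimate": [fit.theta[t] for t in THETA_NAMES],
            "std_error": [fit.theta_se[t] for t in THETA_NAMES],
        }
    ).to_csv(out / "theta.tsv", sep="\t", index=False, na_rep="NA")
    write_matrix(fit.ces_matrix(), out / "ces.tsv")


@dataclass
class RunConfig:
    """Pipeline configuration read from a YAML key-value manifest."""

    crispr: Path
    shrna: Path
    mutation: Path | None = None
    cnv: Path | None = None
    exp_array: Path | None = None
    exp_rnaseq: Path | None = None
    positive_set: Path | None = None
    negative_set: Path | None = None
    seed: int = 20191112
    top_k: int = 100
    overall_min: int = 5000
    novelty_cutoff: int = 2000
    t_max: int = 1000
    n_perm: int = 100
    out_dir: Path = Path("cescore_out")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("crispr", "shrna", "mutation", "cnv", "exp_array",
                     "exp_rnaseq", "positive_set", "negative_set"):
            value = getattr(self, name)
            if value is None:
                continue
            value = Path(value)
            setattr(self, name, value)
            if not value.exists():
                raise ValueError(f"config path for {name!r} does not exist: {value}")
        for name in ("top_k", "overall_min", "novelty_cutoff", "t_max", "n_perm"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"threshold {name!r} must be a positive integer")
        self.out_dir = Path(self.out_dir)

    def feature_paths(self) -> dict[str, Path] | None:
        paths = {name: getattr(self, name) for name in FEATURE_NAMES}
        if any(v is None for v in paths.values()):
            return None
        return paths
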