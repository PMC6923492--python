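"""Concordance diagnostics and performance metrics for essentiality scores.

The evaluation machinery works on the package's sign convention: a lower
score (and hence a smaller numeric rank) means stronger essentiality.
Genes are ranked within each cell line, the average rank across cell
lines serves as the overall essentiality score, and scoring methods are
compared on gold-standard essential/non-essential gene sets with
ROC/AUC, the paired DeLong test, the strictly standardized mean
difference (SSMD), hit-rate curves for individual genes, and a
cell-specific essential-gene filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_curve

from .containers import ScreenMatrix

__all__ = [
    "RankTable",
    "GeneSetLabels",
    "ConsistencyReport",
    "CellSpecificHit",
    "CellSpecificHits",
    "ROCResult",
    "DeLongResult",
    "consistency_report",
    "rank_genes",
    "roc_auc",
    "delong_test",
    "ssmd",
    "hit_rate_curve",
    "HitRateCurve",
    "select_cell_specific",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Ranking


@dataclass
class RankTable:
    """Within-cell-line ranks and the across-line average rank per gene.

    Rank 1 is the most essential (lowest) score in a cell line; ties get
    the average of the ranks they span, so the ranks over K scored genes
    always sum to K(K+1)/2.  ``overall_score`` is the mean rank of the
    gene over the cell lines where it was scored.
    """

    gene_ids: list[str]
    cell_line_ids: list[str]
    ranks: np.ndarray
    overall_score: np.ndarray
    n_lines_used: np.ndarray

    def overall_series(self) -> pd.Series:
        return pd.Series(self.overall_score, index=self.gene_ids, name="overall_score")

    def ranks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranks, index=self.gene_ids, columns=self.cell_line_ids)


def rank_genes(scores: ScreenMatrix) -> RankTable:
    """Rank genes within each cell line, most essential first."""
    values = scores.values
    M, N = values.shape
    ranks = np.full((M, N), np.nan)
    for j in range(N):
        col = values[:, j]
        obs = ~np.isnan(col)
        if not obs.any():
            raise ValueError(
                f"cell line {scores.cell_line_ids[j]!r} has no non-missing scores"
            )
        ranks[obs, j] = scipy.stats.rankdata(col[obs], method="average")
    n_lines = (~np.isnan(ranks)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        overall = np.nanmean(ranks, axis=1)
    return RankTable(
        gene_ids=list(scores.gene_ids),
        cell_line_ids=list(scores.cell_line_ids),
        ranks=ranks,
        overall_score=overall,
        n_lines_used=n_lines,
    )


# ---------------------------------------------------------------------------
# Gold-standard gene sets


@dataclass
class GeneSetLabels:
    """A positive (essential) and negative (non-essential) gene set.

    Genes present in both sets are ambiguous and removed from both at
    construction time.
    """

    positive: set[str]
    negative: set[str]
    positive_name: str = "essential"
    negative_name: str = "non-essential"

    def __post_init__(self) -> None:
        self.positive = set(self.positive)
        self.negative = set(self.negative)
        ambiguous = self.positive & self.negative
        if ambiguous:
            logger.info("removing %d ambiguous gene(s) present in both sets", len(ambiguous))
            self.positive -= ambiguous
            self.negative -= ambiguous

    def mask(self, scores: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        """Return (y_true, score_values) for labelled genes with finite scores."""
        genes = scores.index
        labelled = genes.isin(self.positive) | genes.isin(self.negative)
        finite = np.isfinite(scores.to_numpy(dtype=float))
        use = labelled & finite
        y = np.asarray(genes[use].isin(self.positive), dtype=int)
        x = scores.to_numpy(dtype=float)[use]
        if y.sum() == 0:
            raise ValueError("no positive-set genes with scores")
        if (1 - y).sum() == 0:
            raise ValueError("no negative-set genes with scores")
        return y, x


# ---------------------------------------------------------------------------
# Between-screen consistency


@dataclass
class ConsistencyReport:
    """Per-cell-line Pearson r and MSE between screens, with a permutation null."""

    per_line: pd.DataFrame
    mean_r: float
    mean_mse: float
    mean_perm_mse: float


def consistency_report(crispr: ScreenMatrix, shrna: ScreenMatrix,
                       n_perm: int = 100, seed: int = 0) -> ConsistencyReport:
    """Quantify between-screen concordance per cell line.

    For each cell line the Pearson correlation and the mean squared
    error between the two screens are computed over genes scored by
    both.  The permutation null re-pairs the shRNA scores within the
    cell line uniformly at random ``n_perm`` times and reports the mean
    permuted MSE, which for independent z-scored screens concentrates
    near 2 (the sum of the two unit variances).
    """
    if not crispr.aligned_with(shrna):
        raise ValueError("screen matrices are not aligned")
    rng = np.random.default_rng(seed)
    rows = []
    for j, line in enumerate(crispr.cell_line_ids):
        x = crispr.values[:, j]
        y = shrna.values[:, j]
        obs = ~np.isnan(x) & ~np.isnan(y)
        k = int(obs.sum())
        if k < 3:
            logger.warning("cell line %s: only %d shared genes; skipped", line, k)
            continue
        xs, ys = x[obs], y[obs]
        r = float(scipy.stats.pearsonr(xs, ys).statistic)
        mse = float(np.mean((xs - ys) ** 2))
        perm_mses = np.empty(n_perm)
        for b in range(n_perm):
            perm_mses[b] = np.mean((xs - rng.permutation(ys)) ** 2)
        rows.append(
            {"cell_line": line, "pearson_r": r, "mse": mse,
             "perm_mse": float(perm_mses.mean()), "n_genes": k}
        )
    if not rows:
        raise ValueError("no cell line had at least 3 shared non-missing genes")
    per_line = pd.DataFrame(rows)
    return ConsistencyReport(
        per_line=per_line,
        mean_r=float(per_line["pearson_r"].mean()),
        mean_mse=float(per_line["mse"].mean()),
        mean_perm_mse=float(per_line["perm_mse"].mean()),
    )


# ---------------------------------------------------------------------------
# ROC / AUC and the DeLong test


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_positive: int
    n_negative: int


def roc_auc(scores: pd.Series, labels: GeneSetLabels) -> ROCResult:
    """AUC for separating the positive from the negative gene set.

    Lower scores count as stronger predictions of essentiality, so a
    method under which positives score lower than negatives yields an
    AUC above 0.5.  Tied pairs contribute one half.
    """
    y, x = labels.mask(scores)
    # Negate so that the conventional "higher = positive" AUC applies.
    fpr, tpr, _ = roc_curve(y, -x)
    auc = _mann_whitney_auc(-x[y == 1], -x[y == 0])
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr,
                     n_positive=int(y.sum()), n_negative=int((1 - y).sum()))


def _midrank(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, method="average")


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    return float((all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_placements(pos: np.ndarray, neg: np.ndarray):
    """AUC with its positive- and negative-class placement values.

    The placement of a positive observation is the fraction of
    negatives it beats (ties counting one half), and symmetrically for
    negatives.  These are the structural components whose empirical
    covariance yields the DeLong variance of the AUC.
    """
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    rk_all = _midrank(combined)
    rk_pos = _midrank(pos)
    rk_neg = _midrank(neg)
    auc = (rk_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (rk_all[:m] - rk_pos) / n          # placements of positives
    v_neg = 1.0 - (rk_all[m:] - rk_neg) / m    # placements of negatives
    return float(auc), v_pos, v_neg


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float
    degenerate: bool = False


def delong_test(scores_a: pd.Series, scores_b: pd.Series,
                labels: GeneSetLabels) -> DeLongResult:
    """Paired DeLong comparison of two scoring methods' AUCs.

    Both methods must score the same labelled genes; the covariance
    between the two AUCs is estimated from the shared placement values,
    and the two-sided p-value comes from the standard normal.  If the
    estimated variance of the AUC difference is zero (e.g. identical
    methods) the comparison is degenerate and p = 1 is reported with a
    warning.
    """
    common = scores_a.index.intersection(scores_b.index)
    a = scores_a.loc[common]
    b = scores_b.loc[common]
    y, xa = labels.mask(a)
    y2, xb = labels.mask(b)
    if len(y) != len(y2) or not np.array_equal(y, y2):
        raise ValueError("the two score vectors must cover the same labelled genes")
    # Lower score = more essential; flip for the standard orientation.
    auc_a, vp_a, vn_a = _delong_placements(-xa[y == 1], -xa[y == 0])
    auc_b, vp_b, vn_b = _delong_placements(-xb[y == 1], -xb[y == 0])
    m, n = len(vp_a), len(vn_a)
    s_pos = np.cov(np.vstack([vp_a, vp_b]))
    s_neg = np.cov(np.vstack([vn_a, vn_b]))
    var_diff = (
        (s_pos[0, 0] + s_pos[1, 1] - 2 * s_pos[0, 1]) / m
        + (s_neg[0, 0] + s_neg[1, 1] - 2 * s_neg[0, 1]) / n
    )
    if var_diff <= 0 or not np.isfinite(var_diff):
        logger.warning("degenerate DeLong variance; reporting p = 1")
        return DeLongResult(auc_a, auc_b, max(var_diff, 0.0), 0.0, 1.0, True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2.0 * scipy.stats.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, float(var_diff), float(z), p)


def delong_auc_variance(scores: pd.Series, labels: GeneSetLabels) -> tuple[float, float]:
    """Single-method DeLong AUC and variance (used for diagnostics)."""
    y, x = labels.mask(scores)
    auc, v_pos, v_neg = _delong_placements(-x[y == 1], -x[y == 0])
    var = np.var(v_pos, ddof=1) / len(v_pos) + np.var(v_neg, ddof=1) / len(v_neg)
    return auc, float(var)


# ---------------------------------------------------------------------------
# SSMD


def ssmd(scores: ScreenMatrix, labels: GeneSetLabels) -> pd.Series:
    """Strictly standardized mean difference per cell line.

    ``SSMD = (mean_pos - mean_neg) / sqrt(var_pos + var_neg)`` with
    sample variances.  Under the sign convention a more negative SSMD
    means the essential genes are better separated below the
    non-essential ones.  Cell lines with fewer than two scored members
    of either class get a missing SSMD.
    """
    gene_index = pd.Index(scores.gene_ids)
    pos_rows = gene_index.isin(labels.positive)
    neg_rows = gene_index.isin(labels.negative)
    out = {}
    for j, line in enumerate(scores.cell_line_ids):
        col = scores.values[:, j]
        pos = col[pos_rows & ~np.isnan(col)]
        neg = col[neg_rows & ~np.isnan(col)]
        if len(pos) < 2 or len(neg) < 2:
            out[line] = np.nan
            continue
        denom = np.sqrt(pos.var(ddof=1) + neg.var(ddof=1))
        out[line] = np.nan if denom == 0 else (pos.mean() - neg.mean()) / denom
    return pd.Series(out, name="ssmd")


# ---------------------------------------------------------------------------
# Hit-rate curves


@dataclass
class HitRateCurve:
    """Fraction of cell lines in which a gene beats each rank threshold."""

    gene_id: str
    thresholds: np.ndarray
    hit_rate: np.ndarray
    auc: float
    n_lines: int


def hit_rate_curve(gene: str, ranks: RankTable, t_max: int = 1000) -> HitRateCurve:
    """Hit rate of one gene at integer rank cut-offs 1..t_max.

    The normalized AUC is the mean hit rate over the threshold grid and
    lies in [0, 1]; the curve is monotone non-decreasing in the
    threshold.
    """
    if gene not in ranks.gene_ids:
        raise KeyError(f"gene {gene!r} not present in the rank table")
    if t_max < 1:
        raise ValueError("t_max must be a positive integer")
    i = ranks.gene_ids.index(gene)
    row = ranks.ranks[i, :]
    row = row[~np.isnan(row)]
    if row.size == 0:
        raise ValueError(f"gene {gene!r} is not ranked in any cell line")
    thresholds = np.arange(1, t_max + 1)
    rate = (row[None, :] <= thresholds[:, None]).mean(axis=1)
    return HitRateCurve(
        gene_id=gene,
        thresholds=thresholds,
        hit_rate=rate,
        auc=float(rate.mean()),
        n_lines=row.size,
    )


# ---------------------------------------------------------------------------
# Cell-specific essential genes


@dataclass
class CellSpecificHit:
    gene_id: str
    cell_line: str
    within_rank: float
    overall_score: float
    crispr_rank: float
    shrna_rank: float
    novel: bool


@dataclass
class CellSpecificHits:
    hits: list[CellSpecificHit] = field(default_factory=list)
    top_k: int = 100
    overall_min: float = 5000
    novelty_cutoff: float = 2000

    def to_frame(self) -> pd.DataFrame:
        cols = ["gene_id", "cell_line", "within_rank", "overall_score",
                "crispr_rank", "shrna_rank", "novel"]
        return pd.DataFrame(
            [[getattr(h, c) for c in cols] for h in self.hits], columns=cols
        )

    def novel_genes(self) -> set[str]:
        return {h.gene_id for h in self.hits if h.novel}


def select_cell_specific(ces_ranks: RankTable, crispr_ranks: RankTable,
                         shrna_ranks: RankTable, top_k: int = 100,
                         overall_min: float = 5000,
                         novelty_cutoff: float = 2000) -> CellSpecificHits:
    """Find genes essential in one cell line but not across the panel.

    A (gene, cell line) pair is a hit when the gene's within-line CES
    rank is at most ``top_k`` while its average rank across cell lines
    is numerically greater than ``overall_min`` (i.e. the gene looks
    unremarkable panel-wide).  A hit is flagged novel when the gene's
    within-line rank exceeds ``novelty_cutoff`` in both the CRISPR-only
    and shRNA-only rankings, meaning neither single screen would have
    called it.
    """
    M = len(ces_ranks.gene_ids)
    for name, value in (("top_k", top_k), ("overall_min", overall_min),
                        ("novelty_cutoff", novelty_cutoff)):
        if not (1 <= value <= M):
            raise ValueError(f"{name}={value} outside the valid rank range [1, {M}]")
    if (ces_ranks.gene_ids != crispr_ranks.gene_ids
            or ces_ranks.gene_ids != shrna_ranks.gene_ids
            or ces_ranks.cell_line_ids != crispr_ranks.cell_line_ids
            or ces_ranks.cell_line_ids != shrna_ranks.cell_line_ids):
        raise ValueError("rank tables are not aligned")
    hits = CellSpecificHits(top_k=top_k, overall_min=overall_min,
                            novelty_cutoff=novelty_cutoff)
    overall = ces_ranks.overall_score
    for i, gene in enumerate(ces_ranks.gene_ids):
        if not (overall[i] > overall_min):
            continue
        for j, line in enumerate(ces_ranks.cell_line_ids):
            r = ces_ranks.ranks[i, j]
            if np.isnan(r) or r > top_k:
                continue
            cr = crispr_ranks.ranks[i, j]
            sr = shrna_ranks.ranks[i, j]
            novel = bool(
                np.isfinite(cr) and np.isfinite(sr)
                and cr > novelty_cutoff and sr > novelty_cutoff
            )
            hits.hits.append(
                CellSpecificHit(
                    gene_id=gene, cell_line=line, within_rank=float(r),
                    overall_score=float(overall[i]),
                    crispr_rank=float(cr), shrna_rank=float(sr), novel=novel,
                )
            )
    return hits
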