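"""Derivation of immune cell-type-specific signature genes and metagenes.

Starting from a labeled reference compendium of purified immune-cell
expression profiles, a gene becomes *cell-type specific* when it passes,
in order:

1. one-way ANOVA across cell types (p < alpha),
2. a fold-dominance filter: the top cell type's median expression must
   exceed the runner-up type's median by at least ``min_fold`` on the
   linear scale,
3. a label-permutation test on the top-vs-runner-up median difference,
4. (descriptively) a Jensen-Shannon specificity score against the
   one-hot "expressed in a single type" pattern.

Surviving genes are then pruned per cell type by greedy backward
elimination until every remaining gene has average pairwise Pearson
correlation >= ``r_min`` (test p < ``p_max``) with the rest; cell types
ending with fewer than ``min_genes`` genes are dropped.  The retained
sets are the *metagenes*, each gene carrying as weight its median log2
intensity in its own cell type — the denominator of the downstream
relative-abundance statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import LINEAR, LOG2, ExpressionMatrix

__all__ = [
    "GeneSpecificityRecord",
    "MetageneSet",
    "anova_filter",
    "fold_dominance_filter",
    "permutation_specificity_test",
    "jsd_specificity",
    "select_metagenes",
    "build_compendium",
]


@dataclass
class GeneSpecificityRecord:
    """Per-gene filter statistics accumulated along the specificity chain."""

    gene_id: str
    anova_p: float
    top_type: str
    fold_ratio: float  # top median / runner-up median, linear scale (may be inf)
    perm_p: float = float("nan")
    jsd_specificity: float = float("nan")


@dataclass
class MetageneSet:
    """A cell type's metagene list with per-gene reference weights.

    Weights are median log2 intensities of each gene in its own cell
    type; they must be positive because they divide the abundance sum.
    """

    cell_type: str
    gene_ids: list[str]
    weights: dict[str, float]
    mean_pairwise_r: float = float("nan")

    def __post_init__(self) -> None:
        missing = [g for g in self.gene_ids if g not in self.weights]
        if missing:
            raise ValueError(f"genes without weights: {missing}")
        bad = [g for g in self.gene_ids if self.weights[g] <= 0]
        if bad:
            raise ValueError(f"non-positive weights for genes: {bad}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_dict(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "gene_ids": list(self.gene_ids),
            "weights": {g: float(self.weights[g]) for g in self.gene_ids},
            "mean_pairwise_r": float(self.mean_pairwise_r),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetageneSet":
        return cls(
            cell_type=d["cell_type"],
            gene_ids=list(d["gene_ids"]),
            weights={k: float(v) for k, v in d["weights"].items()},
            mean_pairwise_r=float(d.get("mean_pairwise_r", float("nan"))),
        )


def _groups_linear(expr: ExpressionMatrix) -> dict[str, pd.DataFrame]:
    """Split the linear-scale matrix into per-cell-type sub-frames."""
    lin = expr.to_linear()
    by_type = lin.labels_by_type()
    if len(by_type) < 2:
        raise ValueError("need at least 2 labeled cell types")
    return {t: lin.values[cols] for t, cols in by_type.items()}


def anova_filter(expr: ExpressionMatrix, alpha: float = 0.05) -> set[str]:
    """Genes differentially expressed across cell types (one-way ANOVA).

    The F-test runs on the log2 scale (log2(x + 1) for linear input),
    where expression noise is closest to Gaussian.  Constant genes
    (zero variance everywhere) have an undefined F statistic and are
    assigned p = 1, i.e. excluded.
    """
    if expr.scale == LOG2:
        log_values = expr.values
    else:
        log_values = np.log2(expr.values + 1.0)
    by_type = expr.labels_by_type()
    if len(by_type) < 2:
        raise ValueError("need at least 2 labeled cell types")
    groups = {t: log_values[cols] for t, cols in by_type.items()}
    for t, sub in groups.items():
        if sub.shape[1] < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 replicates")
    arrays = [sub.to_numpy() for sub in groups.values()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows warn; handled below
        f, p = stats.f_oneway(*arrays, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    genes = np.asarray(expr.gene_ids)
    return set(genes[p < alpha])


def fold_dominance_filter(
    expr: ExpressionMatrix,
    genes: set[str] | list[str],
    min_fold: float = 2.0,
    anova_p: dict[str, float] | None = None,
) -> list[GeneSpecificityRecord]:
    """Keep genes whose top cell-type median dominates the runner-up.

    The ratio is taken on the linear scale (log2 inputs are
    exponentiated first); the threshold is inclusive, so a ratio of
    exactly ``min_fold`` passes.  A runner-up median of zero with a
    positive top median yields an infinite ratio and is kept.
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    genes = [g for g in expr.gene_ids if g in set(genes)]
    unknown = set(genes) - set(expr.gene_ids)
    if unknown:
        raise ValueError(f"unknown genes: {sorted(unknown)}")
    groups = _groups_linear(expr)
    medians = pd.DataFrame(
        {t: sub.loc[genes].median(axis=1) for t, sub in groups.items()}
    )
    anova_ps = anova_p or {}
    out: list[GeneSpecificityRecord] = []
    for g in genes:
        row = medians.loc[g]
        order = row.sort_values(ascending=False)
        top_type, top = order.index[0], order.iloc[0]
        runner = order.iloc[1]
        if runner == 0:
            ratio = float("inf") if top > 0 else 1.0
        else:
            ratio = float(top / runner)
        if ratio >= min_fold:
            out.append(
                GeneSpecificityRecord(
                    gene_id=g,
                    anova_p=anova_ps.get(g, float("nan")),
                    top_type=str(top_type),
                    fold_ratio=ratio,
                )
            )
    return out


def _perm_null_stats(
    values: np.ndarray, n_top: int, n_runner: int, perm_idx: np.ndarray
) -> np.ndarray:
    """Median(top block) - median(runner-up block) under label permutations."""
    take = perm_idx[:, : n_top + n_runner]
    permuted = values[take]
    return np.median(permuted[:, :n_top], axis=1) - np.median(
        permuted[:, n_top:], axis=1
    )


def permutation_specificity_test(
    expr: ExpressionMatrix,
    gene: str,
    n_perm: int = 10_000,
    seed: int = 0,
    _perm_idx: np.ndarray | None = None,
) -> float:
    """Label-permutation p-value for top-vs-runner-up dominance of a gene.

    The observed statistic is the difference between the top cell
    type's median and the runner-up type's median.  All sample labels
    are permuted ``n_perm`` times and the p-value uses the add-one
    estimator (b + 1) / (n_perm + 1), which can never be zero.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    groups = _groups_linear(expr)
    meds = {t: float(np.median(sub.loc[gene])) for t, sub in groups.items()}
    order = sorted(meds, key=meds.get, reverse=True)
    top, runner = order[0], order[1]
    observed = meds[top] - meds[runner]
    values = expr.to_linear().values.loc[gene].to_numpy()
    n_top, n_runner = len(groups[top].columns), len(groups[runner].columns)
    if _perm_idx is None:
        rng = np.random.default_rng(seed)
        _perm_idx = np.argsort(
            rng.random((n_perm, values.size)), axis=1
        )
    null = _perm_null_stats(values, n_top, n_runner, _perm_idx)
    b = int(np.sum(null >= observed))
    return (b + 1) / (len(null) + 1)


def jsd_specificity(
    pattern: np.ndarray | list[float], extreme: np.ndarray | list[float]
) -> tuple[float, float]:
    """Jensen-Shannon divergence (bits) and the derived specificity score.

    Both inputs are probability vectors over cell types; ``extreme`` is
    normally one-hot.  Returns ``(jsd, 1 - sqrt(jsd))``.  Base-2 logs
    bound the divergence by 1 bit, so the score lies in [0, 1].
    """
    p = np.asarray(pattern, dtype=float)
    q = np.asarray(extreme, dtype=float)
    if p.shape != q.shape:
        raise ValueError("pattern and extreme pattern differ in length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be non-negative")
    for v in (p, q):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("probability vectors must sum to 1")
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    jsd = 0.5 * _kl(p, m) + 0.5 * _kl(q, m)
    jsd = float(min(max(jsd, 0.0), 1.0))
    return jsd, 1.0 - float(np.sqrt(jsd))


def expression_pattern(expr: ExpressionMatrix, gene: str) -> pd.Series:
    """Per-type median expression normalized to a probability vector."""
    groups = _groups_linear(expr)
    meds = pd.Series({t: float(np.median(sub.loc[gene])) for t, sub in groups.items()})
    total = meds.sum()
    if total <= 0:
        # a silent gene carries no pattern; uniform is the least-informative call
        return pd.Series(1.0 / len(meds), index=meds.index)
    return meds / total


def select_metagenes(
    expr: ExpressionMatrix,
    candidates: dict[str, list[str]],
    r_min: float = 0.6,
    p_max: float = 0.01,
    min_genes: int = 11,
) -> list[MetageneSet]:
    """Prune candidate genes per cell type by average pairwise correlation.

    Greedy backward elimination: repeatedly drop the gene with the
    lowest average Pearson correlation to the others until every
    remaining gene has average r >= ``r_min`` with correlation-test
    p < ``p_max``.  Cell types finishing below ``min_genes`` genes are
    dropped with a warning.  Weights are median log2 intensities of
    each gene within its own cell type.
    """
    if not candidates:
        raise ValueError("no candidate gene sets supplied")
    if len(expr.sample_ids) < 3:
        raise ValueError("need at least 3 samples for correlation pruning")
    lin = expr.to_linear()
    log2_all = np.log2(lin.values + 1.0)
    n = len(expr.sample_ids)
    # two-sided p of a Pearson r with n samples, via the exact t transform
    df = n - 2

    def _r_pvalue(r: float) -> float:
        r = min(max(r, -0.999999), 0.999999)
        t = r * np.sqrt(df / (1 - r * r))
        return 2 * stats.t.sf(abs(t), df)

    by_type = lin.labels_by_type()
    out: list[MetageneSet] = []
    for cell_type, genes in candidates.items():
        genes = [g for g in genes if g in lin.values.index]
        keep = list(genes)
        while len(keep) >= 2:
            sub = log2_all.loc[keep].T  # samples x genes
            corr = sub.corr().to_numpy()
            np.fill_diagonal(corr, np.nan)
            avg_r = np.nanmean(corr, axis=1)
            worst = int(np.nanargmin(avg_r))
            if avg_r[worst] >= r_min and _r_pvalue(avg_r[worst]) < p_max:
                break
            keep.pop(worst)
        if len(keep) < min_genes:
            warnings.warn(
                f"cell type {cell_type!r} retained only {len(keep)} genes "
                f"(< {min_genes}); excluded from the compendium"
            )
            continue
        own_samples = by_type.get(cell_type, [])
        if not own_samples:
            warnings.warn(f"no reference samples labeled {cell_type!r}; skipped")
            continue
        weights = {
            g: float(np.median(np.log2(lin.values.loc[g, own_samples] + 1.0)))
            for g in keep
        }
        sub = log2_all.loc[keep].T
        corr = sub.corr().to_numpy()
        np.fill_diagonal(corr, np.nan)
        mean_r = float(np.nanmean(corr))
        out.append(MetageneSet(cell_type, keep, weights, mean_r))
    return out


def build_compendium(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    n_perm: int = 10_000,
    perm_alpha: float = 0.05,
    r_min: float = 0.6,
    p_max: float = 0.01,
    min_genes: int = 11,
    seed: int = 0,
) -> tuple[list[MetageneSet], list[GeneSpecificityRecord]]:
    """Run the full specificity chain and return metagene sets + records.

    One permutation-index block is drawn once and shared across genes;
    p-values remain valid per gene and the whole chain stays
    reproducible for a given seed.
    """
    anova_pass = anova_filter(expr, alpha)
    records = fold_dominance_filter(expr, anova_pass, min_fold)
    if not records:
        return [], []
    n_samples = len(expr.sample_ids)
    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perm, n_samples)), axis=1)
    survivors: list[GeneSpecificityRecord] = []
    n_types = len(expr.labels_by_type())
    for rec in records:
        rec.perm_p = permutation_specificity_test(
            expr, rec.gene_id, n_perm=n_perm, _perm_idx=perm_idx
        )
        if rec.perm_p >= perm_alpha:
            continue
        pattern = expression_pattern(expr, rec.gene_id)
        one_hot = (pattern.index == rec.top_type).astype(float)
        _, rec.jsd_specificity = jsd_specificity(pattern.to_numpy(), one_hot)
        survivors.append(rec)
    candidates: dict[str, list[str]] = {}
    for rec in survivors:
        candidates.setdefault(rec.top_type, []).append(rec.gene_id)
    sets = select_metagenes(expr, candidates, r_min, p_max, min_genes)
    return sets, survivors
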