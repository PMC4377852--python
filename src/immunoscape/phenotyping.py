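"""Per-sample TIL enrichment and quantification from bulk expression.

Two complementary read-outs per immune cell type:

* a single-sample gene-set enrichment score (weighted Kolmogorov-
  Smirnov running sum over the sample's z-score ranking, gene-set
  permutation null, NES normalization, BH q-values within sample), and
* the relative abundance

      I_c = sum_i log10(x_i + 1) / w_i

  over the cell type's metagenes, where x_i is the gene's linear
  (TPM-like) expression in the sample and w_i its reference weight
  (median log2 intensity in the purifying cell type).  I_c is
  proportional to the number of cells of type c in the mixture and is
  comparable across samples but not across cell types.

Phenotype association maps (Fisher odds ratios of enrichment flags vs
molecular phenotype classes), the hypermutation classifier, and
tumor-group-vs-normal enrichment/depletion summaries live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .compendium import MetageneSet
from .matrix import ExpressionMatrix

__all__ = [
    "SampleRanking",
    "EnrichmentResult",
    "zscore_normalize",
    "sample_ranking",
    "group_ranking",
    "enrichment_score",
    "ssgsea_enrich",
    "enrich_cohort",
    "relative_abundance",
    "phenotype_association",
    "classify_hypermutation",
    "group_vs_normal_summary",
]

HYPERMUTATION_THRESHOLD = 8.24  # non-silent mutations per covered Mb


@dataclass
class SampleRanking:
    """A sample's genes ordered by descending z-score.

    Ties are broken by ascending gene ID so rankings are deterministic.
    """

    sample_id: str
    genes: list[str]
    z: pd.Series  # indexed by gene, ordered like `genes`


@dataclass
class EnrichmentResult:
    sample_id: str
    cell_type: str
    es: float
    nes: float
    p: float
    q: float = float("nan")
    enriched: bool = False


def zscore_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene across samples (population sd).

    Constant genes become all-zero rows; their IDs are recorded under
    ``sample_labels``-independent attribute ``flagged_constant`` on the
    returned values frame (``.attrs``).
    """
    if len(expr.sample_ids) < 2:
        raise ValueError("z-score normalization needs at least 2 samples")
    vals = expr.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population sd
    constant = (sd == 0).ravel()
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    z[constant, :] = 0.0
    out = pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns)
    out.attrs["flagged_constant"] = list(np.asarray(expr.gene_ids)[constant])
    return ExpressionMatrix(out, dict(expr.sample_labels), "log2")


def _rank_from_z(sample_id: str, z: pd.Series) -> SampleRanking:
    order = sorted(z.index, key=lambda g: (-z[g], g))
    return SampleRanking(sample_id, order, z.loc[order])


def sample_ranking(expr_z: ExpressionMatrix, sample_id: str) -> SampleRanking:
    if sample_id not in expr_z.values.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    return _rank_from_z(sample_id, expr_z.values[sample_id])


def group_ranking(expr_z: ExpressionMatrix, sample_ids: list[str]) -> SampleRanking:
    """Rank genes by the mean z-score over a group of samples."""
    if not sample_ids:
        raise ValueError("empty sample group")
    unknown = set(sample_ids) - set(expr_z.values.columns)
    if unknown:
        raise KeyError(f"unknown samples: {sorted(unknown)}")
    mean_z = expr_z.values[list(sample_ids)].mean(axis=1)
    return _rank_from_z("+".join(sample_ids), mean_z)


def enrichment_score(
    positions: np.ndarray, weights: np.ndarray, n_genes: int
) -> float:
    """Weighted KS running-sum ES for a set at `positions` (0-based) in a
    ranking of ``n_genes`` genes, with per-hit weights (|z|, exponent 1).

    The running sum increments by w/sum(w) at each hit and decrements by
    1/(N - m) at each miss; the ES is the extreme deviation from zero
    (sign preserved).  Only hit boundaries need inspecting, which keeps
    the scan O(m) instead of O(N).
    """
    m = positions.size
    if m == 0:
        raise ValueError("empty gene set")
    if m > n_genes:
        raise ValueError("gene set larger than the ranked universe")
    order = np.argsort(positions)
    pos = positions[order]
    w = np.abs(weights[order]).astype(float)
    total_w = w.sum()
    if total_w == 0:
        w = np.ones(m)
        total_w = float(m)
    miss_step = 1.0 / (n_genes - m) if n_genes > m else 0.0
    hit_cum = np.cumsum(w) / total_w
    # misses before (and at) each hit index i: pos[i] - i of them precede it
    miss_before = (pos - np.arange(m)) * miss_step
    dev_at_hit = hit_cum - miss_before  # after the hit increment
    dev_before_hit = np.concatenate(([0.0], hit_cum[:-1])) - miss_before
    # extremes occur only at hit boundaries; order them as the scan visits
    # them so |.|-ties resolve to the earlier deviation, like a full scan
    seq = np.empty(2 * m)
    seq[0::2] = dev_before_hit
    seq[1::2] = dev_at_hit
    a = np.abs(seq)
    # earliest scan position within float tolerance of the extreme, so
    # sign ties resolve identically to a sequential full scan
    best = int(np.argmax(a >= a.max() - 1e-12))
    return float(seq[best]) if a[best] > 0 else 0.0


def _set_positions(ranking: SampleRanking, genes: list[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(ranking.genes)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise KeyError(f"metagenes missing from ranking universe: {missing}")
    return np.array([index[g] for g in genes], dtype=int)


def ssgsea_enrich(
    ranking: SampleRanking,
    sets: list[MetageneSet],
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.10,
) -> list[EnrichmentResult]:
    """Score each metagene set against one ranking.

    Null model: random gene sets of equal size drawn from the ranked
    universe (a phenotype-permutation null is impossible for a single
    sample).  NES = ES / mean(|null ES| of the same sign); p-values come
    from the same-sign null tail with the add-one estimator; q-values
    are BH-adjusted across the cell types tested for this ranking, and
    a set is flagged when q <= ``q_threshold``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    n_genes = len(ranking.genes)
    abs_z = np.abs(ranking.z.to_numpy())
    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    for mg in sets:
        pos = _set_positions(ranking, mg.gene_ids)
        es = enrichment_score(pos, abs_z[pos], n_genes)
        m = pos.size
        null = np.empty(n_perm)
        for b in range(n_perm):
            rpos = rng.choice(n_genes, size=m, replace=False)
            null[b] = enrichment_score(rpos, abs_z[rpos], n_genes)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size == 0:
            nes, p = 0.0, 1.0
        else:
            nes = es / np.mean(np.abs(same_sign))
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (same_sign.size + 1)
        results.append(EnrichmentResult(ranking.sample_id, mg.cell_type, es, nes, p))
    ps = np.array([r.p for r in results])
    qs = multipletests(ps, method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q = float(q)
        r.enriched = bool(q <= q_threshold)
    return results


def enrich_cohort(
    expr: ExpressionMatrix,
    sets: list[MetageneSet],
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.10,
) -> pd.DataFrame:
    """ssGSEA over every sample of a cohort; returns a tidy frame."""
    expr_z = zscore_normalize(expr)
    rows = []
    for i, s in enumerate(expr.sample_ids):
        ranking = sample_ranking(expr_z, s)
        for r in ssgsea_enrich(ranking, sets, n_perm, seed + i, q_threshold):
            rows.append(
                (r.sample_id, r.cell_type, r.es, r.nes, r.p, r.q, r.enriched)
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "es", "nes", "p", "q", "enriched"]
    )


def relative_abundance(
    expr: ExpressionMatrix, sets: list[MetageneSet]
) -> pd.DataFrame:
    """Relative immune-cell abundance I_c per sample and cell type.

    Requires linear-scale (TPM-like) expression; every metagene must be
    present with a positive weight.
    """
    if expr.scale != "linear":
        raise ValueError("relative abundance is defined on linear-scale TPM")
    out = pd.DataFrame(index=expr.sample_ids, dtype=float)
    for mg in sets:
        missing = [g for g in mg.gene_ids if g not in expr.values.index]
        if missing:
            raise KeyError(
                f"metagenes of {mg.cell_type!r} absent from expression: {missing}"
            )
        w = np.array([mg.weights[g] for g in mg.gene_ids])
        if (w <= 0).any():
            raise ValueError(f"non-positive weight in {mg.cell_type!r}")
        x = expr.values.loc[mg.gene_ids].to_numpy()
        out[mg.cell_type] = (np.log10(x + 1.0) / w[:, None]).sum(axis=0)
    out.index.name = "sample_id"
    return out


def _corrected_or(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with Haldane-Anscombe 0.5 correction on zeros."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def phenotype_association(
    enriched: pd.DataFrame,
    phenotype: dict[str, str] | pd.Series,
) -> dict:
    """Fisher association between phenotype classes and enrichment flags.

    ``enriched`` is a samples x cell-types boolean frame.  For each
    (class, cell type) a 2x2 table (in-class enriched/not vs out-of-class
    enriched/not) gives a Fisher exact p and a continuity-corrected
    odds ratio.  The log-OR matrix is clustered on both axes
    (Euclidean, average linkage).
    """
    phenotype = pd.Series(phenotype)
    phenotype = phenotype.loc[[s for s in enriched.index if s in phenotype.index]]
    classes = sorted(phenotype.unique())
    counts = phenotype.value_counts()
    empty = [c for c in classes if counts.get(c, 0) == 0]
    if empty or len(phenotype) < len(enriched.index):
        missing = set(enriched.index) - set(phenotype.index)
        if missing:
            raise ValueError(f"samples without phenotype class: {sorted(missing)}")
    log_or = pd.DataFrame(index=classes, columns=enriched.columns, dtype=float)
    fisher_p = pd.DataFrame(index=classes, columns=enriched.columns, dtype=float)
    for cls in classes:
        in_cls = phenotype.index[phenotype == cls]
        out_cls = phenotype.index[phenotype != cls]
        for ct in enriched.columns:
            a = int(enriched.loc[in_cls, ct].sum())
            b = len(in_cls) - a
            c = int(enriched.loc[out_cls, ct].sum())
            d = len(out_cls) - c
            _, p = stats.fisher_exact([[a, b], [c, d]])
            log_or.loc[cls, ct] = np.log(_corrected_or(a, b, c, d))
            fisher_p.loc[cls, ct] = p

    def _leaf_order(mat: np.ndarray) -> list[int]:
        if mat.shape[0] < 2:
            return list(range(mat.shape[0]))
        link = hierarchy.linkage(pdist(mat, metric="euclidean"), method="average")
        return list(hierarchy.leaves_list(link))

    row_order = _leaf_order(log_or.to_numpy())
    col_order = _leaf_order(log_or.to_numpy().T)
    return {
        "log_or": log_or,
        "fisher_p": fisher_p,
        "row_order": [classes[i] for i in row_order],
        "col_order": [enriched.columns[i] for i in col_order],
    }


def classify_hypermutation(
    n_nonsilent: int, covered_mb: float, threshold: float = HYPERMUTATION_THRESHOLD
) -> tuple[float, bool]:
    """Coverage-normalized mutation rate and the hypermutation call.

    The boundary is strict: a rate exactly at the threshold is called
    non-hypermutated.
    """
    if covered_mb <= 0:
        raise ValueError("covered_mb must be positive")
    rate = n_nonsilent / covered_mb
    return rate, rate > threshold


def rank_sum_de(
    expr: ExpressionMatrix, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Built-in two-group differential test: Wilcoxon rank-sum + BH.

    Returns per-gene log2 fold change with +1 pseudocounts on the group
    means (zero-safe on TPM-like values) and adjusted p-values.  Model-
    based engines can replace this via an external results table.
    """
    lin = expr.to_linear()
    a = lin.values[group_a].to_numpy()
    b = lin.values[group_b].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    p = np.where(np.isnan(p), 1.0, p)  # genes constant in both groups
    log2fc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q}, index=lin.values.index
    )


def group_vs_normal_summary(
    tumor_group: list[str],
    normals: list[str],
    expr: ExpressionMatrix,
    sets: list[MetageneSet],
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.10,
) -> dict:
    """Enrichment/depletion of TIL types in a tumor group vs normals,
    plus per-gene log2 fold changes.

    Genes are ranked by the difference of mean z-scores (tumor group
    minus normals); the enrichment engine is run on that ranking and on
    its reverse, so a cell type can be flagged enriched, depleted, or
    neither at the given q threshold.
    """
    if not tumor_group or not normals:
        raise ValueError("both tumor group and normals must be non-empty")
    expr_z = zscore_normalize(expr)
    diff = (
        expr_z.values[tumor_group].mean(axis=1)
        - expr_z.values[normals].mean(axis=1)
    )
    if (diff == 0).all():
        # self-comparison carries no signal; report every type as neutral
        cells = pd.DataFrame(
            [(mg.cell_type, "none", 0.0, 1.0, 1.0) for mg in sets],
            columns=["cell_type", "direction", "nes", "p", "q"],
        )
        genes = rank_sum_de(expr, tumor_group, normals)
        return {"cell_types": cells, "genes": genes}
    fwd = _rank_from_z("group_vs_normal", diff)
    rev = _rank_from_z("normal_vs_group", -diff)
    enr = ssgsea_enrich(fwd, sets, n_perm, seed, q_threshold)
    dep = ssgsea_enrich(rev, sets, n_perm, seed, q_threshold)
    cell_rows = []
    for e, d in zip(enr, dep):
        if e.enriched and e.es > 0:
            direction = "enriched"
            eff, p, q = e.nes, e.p, e.q
        elif d.enriched and d.es > 0:
            direction = "depleted"
            eff, p, q = d.nes, d.p, d.q
        else:
            direction = "none"
            eff, p, q = e.nes, e.p, e.q
        cell_rows.append((e.cell_type, direction, eff, p, q))
    cells = pd.DataFrame(
        cell_rows, columns=["cell_type", "direction", "nes", "p", "q"]
    )
    genes = rank_sum_de(expr, tumor_group, normals)
    return {"cell_types": cells, "genes": genes}
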