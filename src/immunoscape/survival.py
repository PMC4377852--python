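"""Survival machinery and the TIL-immunomodulator network.

The marker-dichotomization workflow: candidate cutpoints are the
midpoints between consecutive distinct marker values whose induced
split keeps both groups within the inner 80% of patients; the chosen
cutpoint either minimizes the two-group log-rank p-value — in which
case the minimal p is corrected for the selection with the
Miller-Siegmund/Altman approximation

    p_cor = phi(z) * (z - 1/z) * ln[(1 - e)^2 / e^2] + 4 * phi(z) / z

with selection fraction e = 0.1 and z the observed maximal log-rank
statistic — or maximizes Harrell's concordance of the dichotomized
marker.  Kaplan-Meier curves, log-rank tests and Cox hazard ratios
delegate to lifelines; the cutpoint scan, the correction, Harrell's C
and the network assembly are implemented here.

The network links immune cell types (relative abundance) to
immunomodulator genes by Pearson correlation (default r >= 0.6,
p < 0.05); every node carries its overall-survival hazard ratio,
log-rank p and prognosis direction, and gene nodes that are not
survival-significant are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache as _lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "CutpointResult",
    "optimal_cutpoint",
    "altman_corrected_p",
    "harrell_c",
    "km_logrank",
    "build_network",
    "read_survival",
    "write_survival",
]


@dataclass
class SurvivalRecord:
    patient_id: str
    time: float
    event: int
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.patient_id}: survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1")


@dataclass
class CutpointResult:
    marker: str
    cutpoint: float
    p_uncorrected: float
    p_corrected: float
    harrell_c: float
    n_low: int
    n_high: int
    criterion: str = "min_p"


def _as_arrays(survival: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([s.time for s in survival], dtype=float)
    e = np.array([s.event for s in survival], dtype=int)
    return t, e


def _logrank_scan(
    times: np.ndarray, events: np.ndarray, group_matrix: np.ndarray
) -> np.ndarray:
    """Log-rank chi-square for many two-group splits at once.

    ``group_matrix`` is (n_splits, n_patients) boolean, True = group 1.
    Exact tie handling via per-unique-time aggregation; returns one
    chi-square (1 df) per split, NaN when a split has zero variance.
    """
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order].astype(float)
    g = group_matrix[:, order].astype(float)
    n = t.size
    uniq, starts = np.unique(t, return_index=True)
    # totals at risk and events per unique time
    n_at_risk = n - starts
    d = np.add.reduceat(e, starts)
    # per-split: group-1 at risk (suffix counts) and group-1 events
    suffix = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]
    n1_at_risk = suffix[:, starts]
    d1 = np.add.reduceat(g * e, starts, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n1_at_risk / n_at_risk
        expected = d * frac
        var = d * frac * (1 - frac) * (n_at_risk - d) / np.maximum(n_at_risk - 1, 1)
    usable = n_at_risk > 1
    o_minus_e = ((d1 - expected)[:, usable]).sum(axis=1)
    v = var[:, usable].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(v > 0, o_minus_e**2 / v, np.nan)
    return chi2


def _ms_formula(z: float, log_term: float) -> float:
    phi = stats.norm.pdf(z)
    return phi * (z - 1 / z) * log_term + 4 * phi / z


@_lru_cache(maxsize=16)
def _ms_mode(log_term: float) -> float:
    """z below which the asymptotic tail formula stops being monotone."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda z: -_ms_formula(z, log_term), bounds=(0.5, 3.0), method="bounded"
    )
    return float(res.x)


def altman_corrected_p(p_min: float, epsilon: float = 0.1) -> float:
    """Minimal-p correction for an optimally selected cutpoint.

    Asymptotic formula for the supremum of the standardized log-rank
    process over the selection interval (epsilon, 1-epsilon).  The
    formula is a tail approximation, valid for small p; below its mode
    in z the monotone envelope is used, and the result is clipped to
    [p_min, 1], so the corrected value is monotone in the uncorrected
    one and never undercuts it.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    if not 0 < p_min <= 1:
        raise ValueError("p_min must be in (0, 1]")
    z = stats.norm.isf(p_min / 2)  # two-sided
    log_term = float(np.log((1 - epsilon) ** 2 / epsilon**2))
    z_eff = max(z, _ms_mode(log_term))
    p_cor = _ms_formula(z_eff, log_term)
    return float(min(max(p_cor, p_min), 1.0))


def _candidate_cutpoints(marker: np.ndarray, inner: float = 0.8) -> np.ndarray:
    """Midpoints between consecutive distinct values keeping both groups
    within the inner ``inner`` fraction of patients."""
    n = marker.size
    lo_frac = (1 - inner) / 2
    sorted_vals = np.sort(marker)
    distinct = np.unique(sorted_vals)
    mids = (distinct[:-1] + distinct[1:]) / 2
    below = np.searchsorted(sorted_vals, mids)  # count of values <= cutpoint
    frac = below / n
    return mids[(frac >= lo_frac) & (frac <= 1 - lo_frac)]


def optimal_cutpoint(
    marker: pd.Series | np.ndarray,
    survival: list[SurvivalRecord],
    criterion: str = "min_p",
    epsilon: float = 0.1,
    marker_name: str = "marker",
) -> CutpointResult:
    """Optimal dichotomization of a continuous marker against survival.

    ``min_p`` minimizes the log-rank p over candidate cutpoints and
    reports the Altman-corrected p; ``max_c`` maximizes Harrell's C of
    the dichotomized marker.  Both restrict candidates to the inner
    80% selection interval (for epsilon = 0.1).
    """
    if isinstance(marker, pd.Series):
        order = [s.patient_id for s in survival]
        marker = marker.loc[order].to_numpy(dtype=float)
    marker = np.asarray(marker, dtype=float)
    times, events = _as_arrays(survival)
    if marker.size != times.size:
        raise ValueError("marker and survival lengths differ")
    if events.sum() == 0:
        raise ValueError("no events in the cohort")
    if np.unique(marker).size < 2:
        raise ValueError("all marker values identical; no cutpoint exists")
    cuts = _candidate_cutpoints(marker, inner=1 - 2 * epsilon)
    if cuts.size == 0:
        raise ValueError("no candidate cutpoints inside the selection interval")
    groups = marker[None, :] > cuts[:, None]  # True = high group
    chi2 = _logrank_scan(times, events, groups)
    ps = stats.chi2.sf(chi2, df=1)
    ps = np.where(np.isnan(ps), 1.0, ps)
    if criterion == "min_p":
        best = int(np.argmin(ps))
    elif criterion == "max_c":
        cs = np.array(
            [harrell_c(groups[i].astype(float), survival) for i in range(cuts.size)]
        )
        cs = np.maximum(cs, 1 - cs)  # direction-free discrimination
        best = int(np.argmax(cs))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    cut = float(cuts[best])
    hi = marker > cut
    p_unc = float(ps[best])
    return CutpointResult(
        marker=marker_name,
        cutpoint=cut,
        p_uncorrected=p_unc,
        p_corrected=altman_corrected_p(p_unc, epsilon),
        harrell_c=float(harrell_c(hi.astype(float), survival)),
        n_low=int((~hi).sum()),
        n_high=int(hi.sum()),
        criterion=criterion,
    )


def harrell_c(risk: np.ndarray | pd.Series, survival: list[SurvivalRecord]) -> float:
    """Harrell's concordance index of a risk score vs censored survival.

    Pairs are comparable when the earlier time is an event; a pair is
    concordant when the patient with the shorter survival has the
    higher risk score; score ties count 0.5.  Time-tied double events
    are not comparable (standard convention).
    """
    if isinstance(risk, pd.Series):
        risk = risk.loc[[s.patient_id for s in survival]].to_numpy(dtype=float)
    risk = np.asarray(risk, dtype=float)
    t, e = _as_arrays(survival)
    n = t.size
    ti = t[:, None]
    tj = t[None, :]
    # i is the earlier, observed event; j survives longer (or is censored later)
    comparable = (e[:, None] == 1) & (ti < tj)
    ri = risk[:, None]
    rj = risk[None, :]
    concordant = comparable & (ri > rj)
    tied = comparable & (ri == rj)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def km_logrank(
    groups: dict[str, str],
    survival: list[SurvivalRecord],
) -> dict:
    """Kaplan-Meier curves, log-rank p and hazard ratio for a hi/lo split.

    ``groups`` maps patient -> {"hi", "lo"}.  The hazard ratio is for
    the hi group relative to lo, from a univariate Cox fit.
    """
    by_group: dict[str, list[SurvivalRecord]] = {"hi": [], "lo": []}
    for s in survival:
        g = groups.get(s.patient_id)
        if g not in by_group:
            raise ValueError(f"patient {s.patient_id!r} has no hi/lo assignment")
        by_group[g].append(s)
    if not by_group["hi"] or not by_group["lo"]:
        raise ValueError("both groups must be non-empty")
    t, e = _as_arrays(survival)
    if e.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")
    curves = {}
    for g, recs in by_group.items():
        tg, eg = _as_arrays(recs)
        kmf = KaplanMeierFitter()
        kmf.fit(tg, eg, label=g)
        curves[g] = kmf
    t_hi, e_hi = _as_arrays(by_group["hi"])
    t_lo, e_lo = _as_arrays(by_group["lo"])
    lr = logrank_test(t_hi, t_lo, event_observed_A=e_hi, event_observed_B=e_lo)
    df = pd.DataFrame(
        {
            "time": t,
            "event": e,
            "hi": [1 if groups[s.patient_id] == "hi" else 0 for s in survival],
        }
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["hi"]))
    return {"curves": curves, "logrank_p": float(lr.p_value), "hazard_ratio": hr}


def build_network(
    abundance: pd.DataFrame,
    gene_expr: pd.DataFrame,
    survival: list[SurvivalRecord],
    r_min: float = 0.6,
    p_max: float = 0.05,
    significance_alpha: float = 0.05,
    filter_cell_types: bool = False,
) -> nx.Graph:
    """TIL-immunomodulator network with survival-annotated nodes.

    ``abundance``: patients x cell types (relative abundance);
    ``gene_expr``: patients x immunomodulator genes (linear scale).
    Edges connect a cell type and a gene when their Pearson r >= r_min
    with correlation-test p < p_max over the shared patients.  Cell
    types are dichotomized at their median abundance, genes at the
    optimal (min-p) cutpoint with corrected p; nodes carry hazard
    ratio, log-rank p, significance flag and prognosis direction.
    Gene nodes that are not survival-significant are dropped (cell
    types too when ``filter_cell_types``).
    """
    patients = [
        s.patient_id
        for s in survival
        if s.patient_id in abundance.index and s.patient_id in gene_expr.index
    ]
    if len(patients) < 10:
        raise ValueError("need at least 10 patients shared by all inputs")
    survival = [s for s in survival if s.patient_id in set(patients)]
    ab = abundance.loc[patients]
    gx = gene_expr.loc[patients]

    def _node_survival(values: pd.Series, use_cutpoint: bool) -> dict:
        try:
            if use_cutpoint:
                res = optimal_cutpoint(values, survival, criterion="min_p")
                cut, p = res.cutpoint, res.p_corrected
            else:
                cut = float(values.median())
                p = None
            hi = {
                s.patient_id: ("hi" if values[s.patient_id] > cut else "lo")
                for s in survival
            }
            km = km_logrank(hi, survival)
            p_final = p if p is not None else km["logrank_p"]
            hr = km["hazard_ratio"]
            return {
                "cutoff": cut,
                "hazard_ratio": hr,
                "logrank_p": p_final,
                "significant": bool(p_final < significance_alpha),
                "prognosis": "bad" if hr > 1 else "good",
            }
        except ValueError:
            return {
                "cutoff": float("nan"),
                "hazard_ratio": float("nan"),
                "logrank_p": 1.0,
                "significant": False,
                "prognosis": "none",
            }

    g = nx.Graph()
    for ct in ab.columns:
        attrs = _node_survival(ab[ct], use_cutpoint=False)
        g.add_node(ct, kind="cell_type", **attrs)
    for ct in ab.columns:
        for gene in gx.columns:
            r, p = stats.pearsonr(ab[ct], gx[gene])
            if r >= r_min and p < p_max:
                if gene not in g:
                    # survival annotation only for genes that enter the graph
                    g.add_node(
                        gene, kind="gene", **_node_survival(gx[gene], use_cutpoint=True)
                    )
                g.add_edge(ct, gene, weight=float(r), p=float(p))
    drop = [
        n
        for n, d in g.nodes(data=True)
        if not d["significant"]
        and (d["kind"] == "gene" or (filter_cell_types and d["kind"] == "cell_type"))
    ]
    g.remove_nodes_from(drop)
    return g


def read_survival(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    core = {"patient", "time", "event"}
    cov_cols = [c for c in df.columns if c not in core]
    return [
        SurvivalRecord(
            patient_id=str(r["patient"]),
            time=float(r["time"]),
            event=int(r["event"]),
            covariates={c: float(r[c]) for c in cov_cols},
        )
        for _, r in df.iterrows()
    ]


def write_survival(records: list[SurvivalRecord], path) -> None:
    cov_cols = sorted({k for r in records for k in r.covariates})
    rows = [
        [r.patient_id, r.time, r.event] + [r.covariates.get(c, "") for c in cov_cols]
        for r in records
    ]
    pd.DataFrame(rows, columns=["patient", "time", "event"] + cov_cols).to_csv(
        path, sep="\t", index=False
    )
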