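"""Synthetic cohort generator with planted ground truth.

Every input the pipeline consumes can be generated here at desk scale:
a labeled reference compendium with planted cell-type markers, bulk
tumor/normal mixtures with known immune-cell fractions, coding
transcripts with mutations of every class (including decoys that the
neo-antigen filters must remove), a deterministic mock binding
predictor with planted binders, per-tumor CCF tables with planted
clonal groups, and survival times with a planted hazard effect.

Design choices: expression noise is multiplicative log-normal (the
standard abundance noise model); reference marker genes dominate their
own cell type by ``marker_fold`` on the linear scale plus a noise
margin, so the fold filter passes by construction; bulk profiles are
convex mixtures of the reference cell-type mean profiles plus a
tumor-cell background profile.  Identical configs and seeds give
bit-identical outputs (each generator derives an independent stream
from ``(seed, stage_tag)``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .antigenome import (
    MutationRecord,
    ProteomeIndex,
    TranscriptModel,
    enumerate_windows,
    filter_mutations,
    translate_mutation,
)
from .matrix import ExpressionMatrix
from .survival import SurvivalRecord

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "MockBindingPredictor",
    "generate_reference_profiles",
    "generate_tumor_cohort",
    "generate_mutation_set",
    "generate_hla_table",
    "plant_binders",
    "generate_ccf_tables",
    "generate_survival",
    "generate_feature_model",
]

MUTATION_CLASSES = (
    "missense",
    "nonstop",
    "frameshift",
    "non_frameshift",
    "start_codon",
    "splice",
    "exon_border",
)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

# four clearly distinct clonal architectures: from near-clonal to
# dominantly subclonal, as Beta mixtures over the CCF in (0, 1]
DEFAULT_CCF_COMPONENTS: dict[str, list[tuple[float, float, float]]] = {
    "clonal": [(40.0, 2.0, 1.0)],
    "clonal_plus_mid_subclone": [(40.0, 2.0, 0.55), (12.0, 10.0, 0.45)],
    "subclonal_dominant": [(40.0, 2.0, 0.3), (6.0, 14.0, 0.7)],
    "heterogeneous_low_ccf": [(2.0, 8.0, 0.85), (40.0, 2.0, 0.15)],
}

DEFAULT_CLASS_PROPORTIONS = {
    "missense": 0.40,
    "nonstop": 0.08,
    "frameshift": 0.15,
    "non_frameshift": 0.12,
    "start_codon": 0.08,
    "splice": 0.09,
    "exon_border": 0.08,
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort."""

    seed: int = 0
    n_cell_types: int = 10
    n_marker_genes_per_type: int = 15
    n_background_genes: int = 1850
    n_replicates_per_type: int = 5
    n_tumors: int = 60
    n_normals: int = 20
    marker_fold: float = 4.0  # linear-scale dominance of markers in own type
    noise_sd: float = 0.2  # log2-scale sd
    mixture_dirichlet_alpha: tuple[float, ...] | None = None  # tumor first
    normal_dirichlet_alpha: tuple[float, ...] | None = None
    n_transcripts: int = 30
    n_mutations: int = 70
    mutation_class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    ccf_components: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CCF_COMPONENTS.items()}
    )
    n_tumors_per_clonal_group: int = 25
    n_ccf_per_tumor: int = 200
    survival_marker: str = "MK00_00"
    survival_effect: float = 2.0  # hazard ratio for marker-high patients
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.25
    transcript_codon_range: tuple[int, int] = (40, 80)

    def validate(self) -> None:
        counts = (
            self.n_cell_types,
            self.n_marker_genes_per_type,
            self.n_background_genes,
            self.n_replicates_per_type,
            self.n_tumors,
            self.n_normals,
            self.n_transcripts,
            self.n_mutations,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.marker_fold <= 0:
            raise ValueError("marker_fold must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        props = self.mutation_class_proportions
        if set(props) - set(MUTATION_CLASSES):
            raise ValueError(f"unknown mutation classes: {set(props) - set(MUTATION_CLASSES)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("mutation class proportions must sum to 1")
        for group, comps in self.ccf_components.items():
            for a, b, w in comps:
                if a <= 0 or b <= 0:
                    raise ValueError(f"group {group!r}: Beta parameters must be > 0")
                if w < 0:
                    raise ValueError(f"group {group!r}: component weight < 0")
        if self.survival_effect <= 0:
            raise ValueError("hazard ratio must be positive")
        if self.mixture_dirichlet_alpha is not None:
            if len(self.mixture_dirichlet_alpha) != self.n_cell_types + 1:
                raise ValueError("mixture alpha needs n_cell_types + 1 entries")
            if any(a <= 0 for a in self.mixture_dirichlet_alpha):
                raise ValueError("Dirichlet alphas must be positive")


@dataclass
class GroundTruth:
    """Everything planted, serialized alongside the generated data."""

    marker_map: dict[str, list[str]] = field(default_factory=dict)
    mixture_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    phenotype: dict[str, str] = field(default_factory=dict)
    planted_binders: set[tuple[str, str]] = field(default_factory=set)
    clonal_group: dict[str, str] = field(default_factory=dict)
    true_model_coefficients: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        data = {
            "marker_map": self.marker_map,
            "mixture_fractions": self.mixture_fractions,
            "phenotype": self.phenotype,
            "planted_binders": sorted(list(b) for b in self.planted_binders),
            "clonal_group": self.clonal_group,
            "true_model_coefficients": self.true_model_coefficients,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            marker_map=d.get("marker_map", {}),
            mixture_fractions=d.get("mixture_fractions", {}),
            phenotype=d.get("phenotype", {}),
            planted_binders={tuple(b) for b in d.get("planted_binders", [])},
            clonal_group=d.get("clonal_group", {}),
            true_model_coefficients=d.get("true_model_coefficients", {}),
        )


def _rng(config_seed: int, tag: str) -> np.random.Generator:
    digest = hashlib.blake2b(tag.encode(), digest_size=4).digest()
    return np.random.default_rng([config_seed, int.from_bytes(digest, "little")])


def _cell_type(i: int) -> str:
    return f"CT{i:02d}"


def _marker_gene(t: int, j: int) -> str:
    return f"MK{t:02d}_{j:02d}"


# ---------------------------------------------------------------------------
# Reference profiles and bulk cohort


def generate_reference_profiles(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Labeled log2-scale reference compendium with planted markers.

    Each marker gene is expressed ``marker_fold`` above its off level
    (plus a noise margin) in its own cell type only; background genes
    are exchangeable across types.
    """
    config.validate()
    if config.n_replicates_per_type < 3:
        raise ValueError("need >= 3 replicates per cell type for ANOVA filters")
    rng = _rng(config.seed, "reference")
    types = [_cell_type(i) for i in range(config.n_cell_types)]
    n_rep = config.n_replicates_per_type
    samples, labels = [], {}
    for t in types:
        for r in range(n_rep):
            sid = f"{t}_r{r}"
            samples.append(sid)
            labels[sid] = t
    marker_map = {
        t: [_marker_gene(i, j) for j in range(config.n_marker_genes_per_type)]
        for i, t in enumerate(types)
    }
    genes = [g for t in types for g in marker_map[t]] + [
        f"BG{j:04d}" for j in range(config.n_background_genes)
    ]
    n_genes = len(genes)
    gap = np.log2(config.marker_fold) + 6 * config.noise_sd + 0.5
    base = rng.uniform(3.0, 7.0, size=n_genes)
    mat = np.tile(base[:, None], (1, len(samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    col_index = {s: j for j, s in enumerate(samples)}
    for t in types:
        own_cols = [col_index[s] for s in samples if labels[s] == t]
        for g in marker_map[t]:
            mat[gene_index[g], own_cols] += gap
    mat += rng.normal(0.0, config.noise_sd, size=mat.shape)
    expr = ExpressionMatrix(
        pd.DataFrame(mat, index=genes, columns=samples), labels, "log2"
    )
    return expr, GroundTruth(marker_map=marker_map)


def generate_tumor_cohort(
    config: SyntheticConfig, reference: ExpressionMatrix
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Bulk tumor/normal mixtures of the reference cell-type profiles.

    Each sample is a Dirichlet-weighted convex mixture of the per-type
    mean linear profiles plus a tumor-cell background profile (markers
    off, background genes on), under multiplicative log-normal noise.
    Normals use a distinct fraction prior (more epithelium, less
    immune).  Molecular phenotype labels are planted on tumors.
    """
    config.validate()
    rng = _rng(config.seed, "cohort")
    lin = reference.to_linear()
    by_type = lin.labels_by_type()
    types = sorted(by_type)
    profiles = np.column_stack(
        [lin.values[cols].mean(axis=1).to_numpy() for t, cols in
         ((t, by_type[t]) for t in types)]
    )
    tumor_profile = profiles.min(axis=1)  # markers off, background on
    k = len(types)
    alpha_t = config.mixture_dirichlet_alpha or tuple([12.0] + [0.8] * k)
    alpha_n = config.normal_dirichlet_alpha or tuple([30.0] + [0.3] * k)
    if any(a <= 0 for a in alpha_t) or any(a <= 0 for a in alpha_n):
        raise ValueError("mixture weights must be positive")
    gt = GroundTruth()
    cols, data, labels = [], [], {}
    scale = float(np.median(tumor_profile[tumor_profile > 0])) if (
        tumor_profile > 0
    ).any() else 1.0

    def _one_sample(sid: str, alpha, label: str) -> None:
        frac = rng.dirichlet(alpha)
        if (frac < 0).any():
            raise ValueError("mixture fractions must be non-negative")
        mix = tumor_profile * frac[0] + profiles @ frac[1:]
        noise = np.exp2(rng.normal(0.0, config.noise_sd, size=mix.size))
        cols.append(sid)
        data.append(mix * noise)
        labels[sid] = label
        gt.mixture_fractions[sid] = {
            "tumor": float(frac[0]),
            **{t: float(f) for t, f in zip(types, frac[1:])},
        }

    for i in range(config.n_tumors):
        _one_sample(f"P{i:03d}", alpha_t, "tumor")
    for i in range(config.n_normals):
        _one_sample(f"N{i:03d}", alpha_n, "normal")
    phenos = rng.choice(
        ["MSI-H", "MSS^", "MSS"], size=config.n_tumors, p=[0.15, 0.05, 0.80]
    )
    for i in range(config.n_tumors):
        gt.phenotype[f"P{i:03d}"] = str(phenos[i])
    expr = ExpressionMatrix(
        pd.DataFrame(np.column_stack(data), index=reference.gene_ids, columns=cols),
        labels,
        "linear",
    )
    return expr, gt


# ---------------------------------------------------------------------------
# Transcripts, mutations, proteome


def _random_codon(rng: np.random.Generator, avoid_stop: bool = True) -> str:
    while True:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if not (avoid_stop and codon in _STOPS):
            return codon


def _class_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment, so counts hit proportions +/- 1."""
    items = [(c, proportions.get(c, 0.0) * n) for c in MUTATION_CLASSES]
    counts = {c: int(np.floor(v)) for c, v in items}
    remainder = n - sum(counts.values())
    by_frac = sorted(items, key=lambda cv: cv[1] - np.floor(cv[1]), reverse=True)
    for c, _ in by_frac[:remainder]:
        counts[c] += 1
    return counts


def generate_mutation_set(
    config: SyntheticConfig,
) -> tuple[dict[str, TranscriptModel], list[MutationRecord], dict[str, str]]:
    """Random transcripts, classified mutations and the wild-type proteome.

    Every mutation class appears at its configured proportion (largest
    remainder, so +/- 1 count), including the decoy classes the filters
    must remove.  CDSs have >= 2 exons, an ATG start and a single
    in-frame stop; the downstream UTR carries an in-frame stop so
    nonstop read-through terminates.
    """
    config.validate()
    rng = _rng(config.seed, "mutations")
    lo, hi = config.transcript_codon_range
    if lo * 3 < 33:
        raise ValueError("transcripts must have at least 33 coding nt")
    transcripts: dict[str, TranscriptModel] = {}
    offset = 1000
    for i in range(config.n_transcripts):
        n_codons = int(rng.integers(lo, hi + 1))
        body = "".join(_random_codon(rng) for _ in range(n_codons - 2))
        stop = str(rng.choice(sorted(_STOPS)))
        cds = "ATG" + body + stop
        n_exons = int(rng.integers(2, 5))
        # split the CDS into exon chunks of >= 9 nt
        while True:
            edges = np.sort(rng.choice(np.arange(9, len(cds) - 8), size=n_exons - 1,
                                       replace=False))
            lens = np.diff(np.concatenate(([0], edges, [len(cds)])))
            if (lens >= 9).all():
                break
        exons, pos = [], offset
        for L in lens:
            exons.append((pos, pos + int(L) - 1))
            pos += int(L) + int(rng.integers(50, 500))  # intron gap
        offset = pos + 1000
        n_utr_codons = int(rng.integers(8, 20))
        utr_body = "".join(_random_codon(rng) for _ in range(n_utr_codons))
        utr = utr_body + str(rng.choice(sorted(_STOPS))) + "".join(
            rng.choice(list(_BASES), size=6)
        )
        tid = f"TX{i:03d}"
        transcripts[tid] = TranscriptModel(tid, "+", exons, cds, utr)
    proteome = {f"{tid}_wt": t.protein() for tid, t in transcripts.items()}
    counts = _class_counts(config.mutation_class_proportions, config.n_mutations)
    tids = sorted(transcripts)
    mutations: list[MutationRecord] = []
    serial = 0

    def _patient() -> str:
        return f"P{int(rng.integers(config.n_tumors)):03d}"

    def _add(m: MutationRecord) -> None:
        nonlocal serial
        m.mutation_id = f"MUT{serial:04d}"
        serial += 1
        mutations.append(m)

    def _try_make(mclass: str) -> MutationRecord | None:
        tid = str(rng.choice(tids))
        t = transcripts[tid]
        L = len(t.cds_sequence)
        breaks = set(t.exon_cds_breaks[:-1])
        expressed = bool(rng.random() < 0.9)
        if mclass == "missense":
            codon_i = int(rng.integers(1, L // 3 - 1))  # 0-based, skip start & stop
            base_i = int(rng.integers(3))
            pos = codon_i * 3 + base_i  # 0-based CDS
            old = t.cds_sequence[pos]
            for new in rng.permutation(list(_BASES)):
                if new == old:
                    continue
                codon = list(t.cds_sequence[codon_i * 3 : codon_i * 3 + 3])
                codon[base_i] = new
                if "".join(codon) in _STOPS:
                    continue
                m = MutationRecord(_patient(), tid, "missense", pos + 1, old, new,
                                   expressed)
                try:
                    translate_mutation(t, m)
                except ValueError:
                    continue
                return m
            return None
        if mclass == "nonstop":
            pos = L - 3  # first base of the stop codon, 0-based
            return MutationRecord(
                _patient(), tid, "nonstop", pos + 1, t.cds_sequence[pos], "C",
                expressed,
            )
        if mclass == "frameshift":
            d = int(rng.integers(1, 3))
            pos = int(rng.integers(4, L - 6 - d))  # 0-based, interior
            if rng.random() < 0.5:
                if any(pos + 1 <= b < pos + d for b in breaks):
                    return None  # deletion would span an exon border
                ref, alt = t.cds_sequence[pos : pos + d], ""
            else:
                ref, alt = "", "".join(rng.choice(list(_BASES), size=d))
            m = MutationRecord(_patient(), tid, "frameshift", pos + 1, ref, alt,
                               expressed)
            try:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    translate_mutation(t, m)
            except ValueError:
                return None
            return m
        if mclass == "non_frameshift":
            pos = int(rng.integers(4, L - 9))
            if rng.random() < 0.5:
                ref, alt = t.cds_sequence[pos : pos + 3], ""
            else:
                ref, alt = "", "".join(rng.choice(list(_BASES), size=3))
            if ref and any(pos + 1 <= b < pos + 3 for b in breaks):
                return None
            m = MutationRecord(_patient(), tid, "non_frameshift", pos + 1, ref, alt,
                               expressed)
            try:
                translate_mutation(t, m)
            except ValueError:
                return None
            return m
        if mclass == "start_codon":
            base_i = int(rng.integers(3))
            old = t.cds_sequence[base_i]
            new = "T" if old != "T" else "G"
            return MutationRecord(_patient(), tid, "start_codon", base_i + 1, old,
                                  new, expressed)
        if mclass == "splice":
            b = int(rng.choice(sorted(breaks)))
            old = t.cds_sequence[b - 1]
            new = "A" if old != "A" else "G"
            return MutationRecord(_patient(), tid, "splice", b, old, new, expressed)
        if mclass == "exon_border":
            interior = [b for b in sorted(breaks) if b >= 6 and b <= L - 6]
            if not interior:
                return None
            b = int(rng.choice(interior))
            pos = b - 2  # 1-based start of a 5-nt deletion spanning the junction
            ref = t.cds_sequence[pos - 1 : pos + 4]
            return MutationRecord(_patient(), tid, "exon_border", pos, ref, "",
                                  expressed)
        raise ValueError(mclass)

    for mclass in MUTATION_CLASSES:
        made = 0
        attempts = 0
        while made < counts[mclass]:
            attempts += 1
            if attempts > 200 * max(counts[mclass], 1):
                raise RuntimeError(f"could not generate {mclass} mutations")
            m = _try_make(mclass)
            if m is not None:
                _add(m)
                made += 1
    return transcripts, mutations, proteome


def generate_hla_table(
    config: SyntheticConfig, n_alleles: int = 2
) -> dict[str, list[str]]:
    """Assign each patient HLA class I alleles from a small pool."""
    rng = _rng(config.seed, "hla")
    pool = [f"HLA-A*{i:02d}:01" for i in range(1, 7)] + [
        f"HLA-B*{i:02d}:01" for i in range(7, 13)
    ]
    return {
        f"P{i:03d}": sorted(rng.choice(pool, size=n_alleles, replace=False))
        for i in range(config.n_tumors)
    }


def plant_binders(
    config: SyntheticConfig,
    mutations: list[MutationRecord],
    transcripts: dict[str, TranscriptModel],
    proteome: dict[str, str],
    hla: dict[str, list[str]],
    fraction: float = 0.1,
) -> set[tuple[str, str]]:
    """Choose a random subset of novel mutant peptides as true binders.

    Each planted binder is a (peptide, allele) pair where the allele
    belongs to a patient carrying the peptide's source mutation, and the
    peptide is absent from the wild-type proteome.
    """
    import warnings as _w

    rng = _rng(config.seed, "binders")
    index = ProteomeIndex(proteome)
    kept, _ = filter_mutations(mutations, transcripts)
    candidates: list[tuple[str, str]] = []
    seen = set()
    for m in kept:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            protein, span = translate_mutation(transcripts[m.transcript_id], m)
        for pep in enumerate_windows(protein, span):
            if pep in index:
                continue
            for allele in hla.get(m.patient_id, []):
                if (pep, allele) not in seen:
                    seen.add((pep, allele))
                    candidates.append((pep, allele))
    n_pick = max(1, int(round(fraction * len(candidates)))) if candidates else 0
    if n_pick == 0:
        return set()
    picks = rng.choice(len(candidates), size=n_pick, replace=False)
    return {candidates[i] for i in picks}


class MockBindingPredictor:
    """Deterministic stand-in for an MHC binding predictor.

    Maps (peptide, allele) to a percentile rank via a seeded 64-bit
    hash.  With no planted binders, ranks are uniform on (0, 100].
    With planted binders, planted pairs land in (0, 2] and everything
    else in (2, 100], so the rank <= 2 rule recovers exactly the
    planted set.
    """

    def __init__(self, seed: int = 0, planted: set[tuple[str, str]] | None = None):
        self.seed = int(seed)
        self.planted = frozenset(planted or ())

    def __call__(self, peptide: str, allele: str) -> float:
        if not 8 <= len(peptide) <= 11:
            raise ValueError(f"peptide length {len(peptide)} outside 8-11")
        bad = set(peptide) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {peptide!r}")
        h = hashlib.blake2b(
            f"{peptide}|{allele}".encode(),
            key=self.seed.to_bytes(8, "little"),
            digest_size=8,
        ).digest()
        u = (int.from_bytes(h, "little") + 1) / 2**64  # in (0, 1]
        if self.planted:
            if (peptide, allele) in self.planted:
                return 2.0 * u
            return 2.0 + 98.0 * u
        return 100.0 * u


# ---------------------------------------------------------------------------
# CCF tables and survival


def generate_ccf_tables(
    config: SyntheticConfig,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Per-tumor CCF draws from the configured Beta-mixture clonal groups."""
    config.validate()
    rng = _rng(config.seed, "ccf")
    gt = GroundTruth()
    tables: dict[str, np.ndarray] = {}
    idx = 0
    for group, comps in config.ccf_components.items():
        weights = np.array([w for _, _, w in comps], dtype=float)
        weights = weights / weights.sum()
        for _ in range(config.n_tumors_per_clonal_group):
            tumor = f"T{idx:03d}"
            idx += 1
            which = rng.choice(len(comps), size=config.n_ccf_per_tumor, p=weights)
            draws = np.empty(config.n_ccf_per_tumor)
            for c, (a, b, _) in enumerate(comps):
                mask = which == c
                draws[mask] = rng.beta(a, b, size=int(mask.sum()))
            draws = np.clip(draws, 1e-9, 1.0)
            tables[tumor] = draws
            gt.clonal_group[tumor] = group
    return tables, gt


def generate_survival(
    config: SyntheticConfig, cohort: ExpressionMatrix
) -> list[SurvivalRecord]:
    """Exponential event times with a planted hazard effect.

    Patients whose expression of ``config.survival_marker`` exceeds the
    tumor-cohort median get hazard multiplied by ``survival_effect``.
    Censoring is an independent exponential race tuned to the requested
    censoring fraction; a censoring rate of 1 censors everyone.
    """
    config.validate()
    rng = _rng(config.seed, "survival")
    marker = config.survival_marker
    if marker not in cohort.values.index:
        raise KeyError(f"survival marker {marker!r} absent from cohort")
    tumors = [s for s in cohort.sample_ids
              if cohort.sample_labels.get(s, "tumor") == "tumor"]
    values = cohort.values.loc[marker, tumors]
    median = float(values.median())
    out: list[SurvivalRecord] = []
    cr = config.censoring_rate
    for s in tumors:
        hi = float(values[s]) > median
        hazard = config.baseline_hazard * (config.survival_effect if hi else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        if cr >= 1.0:
            time, event = t_event, 0
        elif cr <= 0.0:
            time, event = t_event, 1
        else:
            mu = config.baseline_hazard * cr / (1.0 - cr)
            t_cens = rng.exponential(1.0 / mu)
            time, event = min(t_event, t_cens), int(t_event <= t_cens)
        out.append(
            SurvivalRecord(s, float(time), event, {"marker_high": float(hi)})
        )
    return out


def generate_feature_model(
    n_patients: int = 400,
    n_features: int = 221,
    coefficients: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Design matrix with a planted sparse linear response.

    Features are independent standard normals named F000..; the
    response is the planted linear combination plus Gaussian noise.
    """
    rng = np.random.default_rng([seed, 77])
    names = [f"F{i:03d}" for i in range(n_features)]
    if coefficients is None:
        coefficients = {"F000": 2.0, "F001": -1.0}
    unknown = set(coefficients) - set(names)
    if unknown:
        raise ValueError(f"coefficients on unknown features: {sorted(unknown)}")
    x = pd.DataFrame(
        rng.standard_normal((n_patients, n_features)),
        index=[f"P{i:03d}" for i in range(n_patients)],
        columns=names,
    )
    y = pd.Series(0.0, index=x.index, name="cytotoxicity")
    for f, b in coefficients.items():
        y = y + b * x[f]
    y = y + rng.normal(0.0, noise_sd, size=n_patients)
    gt = GroundTruth(true_model_coefficients=dict(coefficients))
    return x, y, gt
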