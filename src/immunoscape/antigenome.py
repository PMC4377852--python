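"""Characterization of the tumor antigenome.

Two antigen classes are handled:

* **Neo-antigens** — mutant 8-11-mer peptides arising from expressed,
  protein-altering coding mutations (missense, nonstop, frameshift,
  in-frame indel), predicted to bind one of the patient's HLA class I
  alleles at percentile rank <= 2 and absent from the reference
  proteome.  Start-codon changes, splice-site mutations and indels
  spanning exon borders are excluded before translation.

* **Cancer-germline antigens (CGA)** — normally germline-restricted
  genes called positive in a tumor when expression exceeds the normal
  baseline of median + 3 standard deviations; genes with zero normal
  standard deviation or significant tumor downregulation are excluded.

Genomic intervals in files are 1-based inclusive; CDS positions are
1-based.  Binding prediction is a pluggable callable
``(peptide, allele) -> percentile rank``; a deterministic mock lives in
:mod:`immunoscape.synthetic`, and :func:`load_netmhcpan_ranks` adapts
pre-computed netMHCpan-style output tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix
from .phenotyping import rank_sum_de

__all__ = [
    "TranscriptModel",
    "MutationRecord",
    "NeoAntigen",
    "CGARecord",
    "filter_mutations",
    "translate_mutation",
    "enumerate_windows",
    "call_neoantigens",
    "neoantigen_frequency",
    "shared_neoantigens",
    "call_cga",
    "load_netmhcpan_ranks",
]

PROTEIN_ALTERING = {"missense", "nonstop", "frameshift", "non_frameshift"}
EXCLUDED_CLASSES = {"start_codon", "splice", "silent", "other"}
PEPTIDE_LENGTHS = (8, 9, 10, 11)
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class TranscriptModel:
    """A coding transcript: exon structure plus the spliced CDS.

    The CDS starts with ATG, ends with a single in-frame stop, and its
    length is divisible by 3.  ``exons`` are genomic 1-based inclusive
    intervals whose summed length equals the CDS length (the simplified
    model treats whole exons as coding).  ``downstream_utr`` supports
    read-through translation of nonstop mutations.
    """

    transcript_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_sequence: str
    downstream_utr: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")
        if not self.cds_sequence.startswith("ATG"):
            raise ValueError(f"{self.transcript_id}: CDS must start with ATG")
        protein = str(Seq(self.cds_sequence).translate())
        if not protein.endswith("*") or "*" in protein[:-1]:
            raise ValueError(
                f"{self.transcript_id}: CDS must end with its only stop codon"
            )

    @property
    def exon_cds_breaks(self) -> list[int]:
        """CDS positions (1-based, inclusive ends) where each exon ends."""
        breaks, total = [], 0
        for start, end in self.exons:
            total += end - start + 1
            breaks.append(total)
        return breaks

    def protein(self) -> str:
        return str(Seq(self.cds_sequence).translate())[:-1]

    def to_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "strand": self.strand,
            "exons": [list(e) for e in self.exons],
            "cds_sequence": self.cds_sequence,
            "downstream_utr": self.downstream_utr,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TranscriptModel":
        return cls(
            transcript_id=d["transcript_id"],
            strand=d["strand"],
            exons=[tuple(e) for e in d["exons"]],
            cds_sequence=d["cds_sequence"],
            downstream_utr=d.get("downstream_utr", ""),
        )


def write_transcripts(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in transcripts], fh, indent=1)


def read_transcripts(path) -> dict[str, TranscriptModel]:
    with open(path) as fh:
        data = json.load(fh)
    models = [TranscriptModel.from_dict(d) for d in data]
    return {t.transcript_id: t for t in models}


@dataclass
class MutationRecord:
    """A classified coding mutation in CDS coordinates (1-based).

    ``ref``/``alt`` follow a simple convention: substitutions have equal
    non-empty lengths, deletions have empty ``alt``, insertions empty
    ``ref`` (inserted *before* ``cds_pos``).
    """

    patient_id: str
    transcript_id: str
    mclass: str
    cds_pos: int
    ref: str
    alt: str
    expressed: bool = True
    mutation_id: str = ""

    def __post_init__(self) -> None:
        if not self.mutation_id:
            self.mutation_id = (
                f"{self.patient_id}:{self.transcript_id}:{self.cds_pos}"
                f":{self.ref or '-'}>{self.alt or '-'}"
            )
        delta = abs(len(self.ref) - len(self.alt))
        if self.mclass == "frameshift" and delta % 3 == 0:
            raise ValueError(f"{self.mutation_id}: frameshift indel length % 3 == 0")
        if self.mclass == "non_frameshift" and (delta == 0 or delta % 3 != 0):
            raise ValueError(f"{self.mutation_id}: non-frameshift indel must be in-frame")

    @property
    def span(self) -> tuple[int, int]:
        """CDS interval touched by the edit (1-based inclusive)."""
        if self.ref:
            return self.cds_pos, self.cds_pos + len(self.ref) - 1
        return self.cds_pos, self.cds_pos  # insertion point


def write_mutations(mutations: Iterable[MutationRecord], path) -> None:
    rows = [
        (m.patient_id, m.transcript_id, m.mclass, m.cds_pos, m.ref or "-",
         m.alt or "-", int(m.expressed), m.mutation_id)
        for m in mutations
    ]
    pd.DataFrame(
        rows,
        columns=["patient", "transcript_id", "class", "cds_pos", "ref", "alt",
                 "expressed", "mutation_id"],
    ).to_csv(path, sep="\t", index=False)


def read_mutations(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        out.append(
            MutationRecord(
                patient_id=r["patient"],
                transcript_id=r["transcript_id"],
                mclass=r["class"],
                cds_pos=int(r["cds_pos"]),
                ref="" if r["ref"] == "-" else r["ref"],
                alt="" if r["alt"] == "-" else r["alt"],
                expressed=bool(int(r.get("expressed", 1))),
                mutation_id=r.get("mutation_id", ""),
            )
        )
    return out


@dataclass
class NeoAntigen:
    peptide: str
    patient_id: str
    mutation_id: str
    transcript_id: str
    hla_allele: str
    rank: float
    novel: bool = True


@dataclass
class CGARecord:
    gene_id: str
    normal_median: float
    normal_sd: float
    baseline: float
    positive: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Mutation filtering and translation


def filter_mutations(
    mutations: list[MutationRecord],
    transcripts: dict[str, TranscriptModel],
) -> tuple[list[MutationRecord], list[tuple[str, str]]]:
    """Keep exonic, protein-altering mutations suitable for translation.

    Excluded, with a logged reason: start-codon changes, splice-site
    mutations, indels spanning an exon border, silent and otherwise
    non-protein-altering classes.
    """
    kept: list[MutationRecord] = []
    excluded: list[tuple[str, str]] = []
    for m in mutations:
        t = transcripts.get(m.transcript_id)
        if t is None:
            raise KeyError(f"unknown transcript {m.transcript_id!r}")
        if m.mclass in ("splice",):
            excluded.append((m.mutation_id, "splice"))
            continue
        lo, hi = m.span
        if m.mclass == "start_codon" or (m.ref and lo <= 3):
            excluded.append((m.mutation_id, "start_codon"))
            continue
        if hi > len(t.cds_sequence) or lo < 1:
            excluded.append((m.mutation_id, "outside_cds"))
            continue
        breaks = t.exon_cds_breaks[:-1]  # junctions interior to the CDS
        if m.ref and any(lo <= b < hi for b in breaks):
            excluded.append((m.mutation_id, "exon_border"))
            continue
        if m.mclass == "exon_border":
            excluded.append((m.mutation_id, "exon_border"))
            continue
        if m.mclass not in PROTEIN_ALTERING:
            excluded.append((m.mutation_id, m.mclass or "other"))
            continue
        kept.append(m)
    return kept, excluded


def _apply_edit(cds: str, m: MutationRecord) -> str:
    i = m.cds_pos - 1
    if m.ref:
        observed = cds[i : i + len(m.ref)]
        if observed != m.ref:
            raise ValueError(
                f"{m.mutation_id}: ref {m.ref!r} does not match CDS {observed!r}"
            )
        return cds[:i] + m.alt + cds[i + len(m.ref):]
    return cds[:i] + m.alt + cds[i:]


def _translate_to_stop(nt: str) -> tuple[str, bool]:
    """Translate until the first stop; returns (peptides, saw_stop)."""
    usable = len(nt) - len(nt) % 3
    aa = str(Seq(nt[:usable]).translate())
    stop = aa.find("*")
    if stop >= 0:
        return aa[:stop], True
    return aa, False


def translate_mutation(
    transcript: TranscriptModel, mutation: MutationRecord
) -> tuple[str, tuple[int, int]]:
    """Mutant protein and the altered residue span (1-based inclusive).

    Missense and in-frame indels alter a local stretch found by
    trimming the common prefix and suffix against the wild-type
    protein.  Frameshifts translate in the new frame from the edit
    onward (running into the downstream UTR if the CDS ends first)
    until the first stop; nonstop mutations read through the mutated
    stop codon into the UTR.  If no stop is reached before the
    available sequence ends, translation truncates with a warning.
    """
    wt_protein = transcript.protein()
    mutant_cds = _apply_edit(transcript.cds_sequence, mutation)
    if mutation.mclass in ("missense", "non_frameshift"):
        mut_protein, saw_stop = _translate_to_stop(mutant_cds)
        a = 0
        limit = min(len(wt_protein), len(mut_protein))
        while a < limit and wt_protein[a] == mut_protein[a]:
            a += 1
        b = 0
        while (
            b < limit - a
            and wt_protein[len(wt_protein) - 1 - b] == mut_protein[len(mut_protein) - 1 - b]
        ):
            b += 1
        if a == len(mut_protein) - b and len(mut_protein) == len(wt_protein):
            raise ValueError(f"{mutation.mutation_id}: edit is silent at protein level")
        # a pure C-terminal truncation has no novel residues; the altered
        # context is the new junction residue at the end
        lo = min(a + 1, len(mut_protein))
        span = (lo, max(len(mut_protein) - b, lo))
        return mut_protein, span
    if mutation.mclass == "frameshift":
        extended = mutant_cds + transcript.downstream_utr
        mut_protein, saw_stop = _translate_to_stop(extended)
        if not saw_stop:
            warnings.warn(
                f"{mutation.mutation_id}: no stop codon reached; "
                "truncating at sequence end"
            )
        a = 0
        limit = min(len(wt_protein), len(mut_protein))
        while a < limit and wt_protein[a] == mut_protein[a]:
            a += 1
        if a >= len(mut_protein):
            raise ValueError(
                f"{mutation.mutation_id}: frameshift produced no novel residues"
            )
        return mut_protein, (a + 1, len(mut_protein))
    if mutation.mclass == "nonstop":
        # the edit removes the terminal stop; read through into the UTR
        extended = mutant_cds + transcript.downstream_utr
        mut_protein, saw_stop = _translate_to_stop(extended)
        if not saw_stop:
            warnings.warn(
                f"{mutation.mutation_id}: no downstream stop; "
                "truncating at sequence end"
            )
        if len(mut_protein) <= len(wt_protein):
            raise ValueError(f"{mutation.mutation_id}: nonstop added no residues")
        return mut_protein, (len(wt_protein) + 1, len(mut_protein))
    raise ValueError(f"cannot translate mutation class {mutation.mclass!r}")


def enumerate_windows(
    mutant_protein: str,
    altered_span: tuple[int, int],
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
) -> dict[str, int]:
    """All 8-11-mer substrings overlapping >=1 altered residue.

    Windows must lie fully within the protein.  Duplicate peptide
    strings are collapsed; the value records their multiplicity.
    """
    lo, hi = altered_span
    if lo > hi or lo < 1 or hi > len(mutant_protein):
        raise ValueError(f"altered span {altered_span} outside protein bounds")
    out: dict[str, int] = {}
    n = len(mutant_protein)
    for L in sorted(lengths):
        start_min = max(0, lo - 1 - (L - 1))
        start_max = min(hi - 1, n - L)
        for s in range(start_min, start_max + 1):
            pep = mutant_protein[s : s + L]
            out[pep] = out.get(pep, 0) + 1
    return out


def flag_expressed_mutations(
    mutations: list[MutationRecord],
    expr: ExpressionMatrix,
    transcript_to_gene: dict[str, str] | None = None,
    min_tpm: float = 1.0,
) -> list[MutationRecord]:
    """Set each mutation's expressed flag from patient gene expression.

    A mutation counts as expressed when its gene exceeds ``min_tpm``
    (linear scale) in the carrying patient.  ``transcript_to_gene``
    maps transcript IDs onto expression rows (identity by default).
    Mutations whose patient or gene is absent from the matrix keep
    their current flag.
    """
    mapping = transcript_to_gene or {}
    for m in mutations:
        gene = mapping.get(m.transcript_id, m.transcript_id)
        if gene in expr.values.index and m.patient_id in expr.values.columns:
            m.expressed = bool(expr.values.loc[gene, m.patient_id] > min_tpm)
    return mutations


# ---------------------------------------------------------------------------
# Neo-antigen calling


class ProteomeIndex:
    """Exact-substring membership over a reference proteome."""

    def __init__(self, proteins: dict[str, str] | Iterable[str]):
        if isinstance(proteins, dict):
            seqs = proteins.values()
        else:
            seqs = list(proteins)
        self._blob = "#" + "#".join(seqs) + "#"

    def __contains__(self, peptide: str) -> bool:
        return peptide in self._blob


def call_neoantigens(
    peptides: list[tuple[str, MutationRecord]],
    hla_alleles: dict[str, list[str]],
    predictor: Callable[[str, str], float],
    proteome: ProteomeIndex | dict[str, str],
    rank_threshold: float = 2.0,
) -> list[NeoAntigen]:
    """Filter mutant peptides to predicted HLA binders novel to the proteome.

    A peptide is called for every (patient allele) with predicted
    percentile rank <= ``rank_threshold`` (inclusive, covering both
    strong and weak binders), provided it is not an exact substring of
    any reference protein.
    """
    if not isinstance(proteome, ProteomeIndex):
        proteome = ProteomeIndex(proteome)
    out: list[NeoAntigen] = []
    for peptide, m in peptides:
        alleles = hla_alleles.get(m.patient_id)
        if not alleles:
            raise ValueError(f"patient {m.patient_id!r} has no HLA alleles")
        if peptide in proteome:
            continue
        for allele in alleles:
            rank = predictor(peptide, allele)
            if rank <= rank_threshold:
                out.append(
                    NeoAntigen(
                        peptide=peptide,
                        patient_id=m.patient_id,
                        mutation_id=m.mutation_id,
                        transcript_id=m.transcript_id,
                        hla_allele=allele,
                        rank=float(rank),
                    )
                )
    return out


def mutant_peptides(
    mutations: list[MutationRecord],
    transcripts: dict[str, TranscriptModel],
) -> list[tuple[str, MutationRecord]]:
    """Translate filtered mutations and enumerate candidate windows."""
    out: list[tuple[str, MutationRecord]] = []
    for m in mutations:
        t = transcripts[m.transcript_id]
        protein, span = translate_mutation(t, m)
        for pep in enumerate_windows(protein, span):
            out.append((pep, m))
    return out


def neoantigen_frequency(
    mutations: list[MutationRecord],
    neoantigens: list[NeoAntigen],
    per_mutation_counts: bool = False,
) -> dict[str, float | None]:
    """Per-patient neo-antigen frequency.

    Default definition: among a patient's *expressed protein-altering*
    mutations, the fraction yielding at least one called neo-antigen.
    With ``per_mutation_counts`` the alternative read-out — called
    neo-antigens per expressed protein-altering mutation — is returned.
    Patients with zero eligible mutations get ``None`` (undefined, not
    zero).
    """
    eligible: dict[str, set[str]] = {}
    for m in mutations:
        if m.expressed and m.mclass in PROTEIN_ALTERING:
            eligible.setdefault(m.patient_id, set()).add(m.mutation_id)
    hits: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for na in neoantigens:
        hits.setdefault(na.patient_id, set()).add(na.mutation_id)
        counts[na.patient_id] = counts.get(na.patient_id, 0) + 1
    out: dict[str, float | None] = {}
    for patient, muts in eligible.items():
        if not muts:
            out[patient] = None
        elif per_mutation_counts:
            out[patient] = counts.get(patient, 0) / len(muts)
        else:
            immunogenic = hits.get(patient, set()) & muts
            out[patient] = len(immunogenic) / len(muts)
    return out


def shared_neoantigens(neoantigens: list[NeoAntigen]) -> dict:
    """Peptides recurring across patients, with a clustered incidence map.

    Returns the shared-peptide table (peptide, patient count, source
    transcripts) and row/column leaf orders of a two-way hierarchical
    clustering (binary incidence, Euclidean, average linkage).
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    by_peptide: dict[str, dict] = {}
    for na in neoantigens:
        d = by_peptide.setdefault(
            na.peptide, {"patients": set(), "transcripts": set()}
        )
        d["patients"].add(na.patient_id)
        d["transcripts"].add(na.transcript_id)
    rows = [
        (pep, len(d["patients"]), sorted(d["patients"]), sorted(d["transcripts"]))
        for pep, d in by_peptide.items()
        if len(d["patients"]) >= 2
    ]
    table = pd.DataFrame(
        rows, columns=["peptide", "n_patients", "patients", "transcripts"]
    ).sort_values(["n_patients", "peptide"], ascending=[False, True], ignore_index=True)
    if table.empty:
        return {"table": table, "incidence": pd.DataFrame(), "row_order": [],
                "col_order": []}
    patients = sorted({p for ps in table["patients"] for p in ps})
    incidence = pd.DataFrame(
        0, index=table["peptide"], columns=patients, dtype=int
    )
    for _, r in table.iterrows():
        incidence.loc[r["peptide"], list(r["patients"])] = 1

    def _order(mat: np.ndarray, labels: list) -> list:
        if mat.shape[0] < 2:
            return list(labels)
        link = hierarchy.linkage(pdist(mat, metric="euclidean"), method="average")
        return [labels[i] for i in hierarchy.leaves_list(link)]

    return {
        "table": table,
        "incidence": incidence,
        "row_order": _order(incidence.to_numpy(), list(incidence.index)),
        "col_order": _order(incidence.to_numpy().T, list(incidence.columns)),
    }


# ---------------------------------------------------------------------------
# Cancer-germline antigens


def call_cga(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    cga_genes: list[str],
    de_results: pd.DataFrame | None = None,
    de_alpha: float = 0.05,
    k: int = 3,
    seed: int = 0,
) -> dict:
    """Cancer-germline antigen calls against a normal-tissue baseline.

    A gene is dropped when significantly downregulated in tumors
    (supplied DE table with ``log2fc``/``q`` columns, or the built-in
    rank-sum test) or when its normal standard deviation is zero.
    The remaining genes get baseline = normal median + 3 * normal sd
    (sample sd); a tumor is positive for a gene iff expression strictly
    exceeds the baseline.  K-means (k-means++ init, seeded) groups the
    positive-call expression profiles of the retained genes.
    """
    if len(normal.sample_ids) < 2:
        raise ValueError("need at least 2 normal samples for a baseline sd")
    missing = [g for g in cga_genes if g not in tumor.values.index]
    if missing:
        raise KeyError(f"CGA genes absent from expression matrix: {missing}")
    if de_results is None:
        combined = pd.concat([tumor.values, normal.values], axis=1)
        merged = ExpressionMatrix(combined, scale=tumor.scale)
        de_results = rank_sum_de(merged, tumor.sample_ids, normal.sample_ids)
    dropped: dict[str, str] = {}
    records: list[CGARecord] = []
    for g in cga_genes:
        if g in de_results.index:
            row = de_results.loc[g]
            if row["q"] < de_alpha and row["log2fc"] < 0:
                dropped[g] = "downregulated_in_tumor"
                continue
        nvals = normal.values.loc[g].to_numpy(dtype=float)
        sd = float(np.std(nvals, ddof=1))
        if sd == 0:
            dropped[g] = "zero_normal_sd"
            continue
        med = float(np.median(nvals))
        baseline = med + 3.0 * sd
        calls = {
            s: bool(tumor.values.loc[g, s] > baseline) for s in tumor.sample_ids
        }
        records.append(CGARecord(g, med, sd, baseline, calls))
    clusters: dict[str, int] = {}
    if records and k >= 1:
        genes = [r.gene_id for r in records]
        mat = tumor.values.loc[genes].to_numpy(dtype=float)
        k_eff = min(k, len(genes))
        km = KMeans(n_clusters=k_eff, init="k-means++", n_init=10, random_state=seed)
        labels = km.fit_predict(np.log10(mat + 1.0))
        clusters = dict(zip(genes, (int(x) for x in labels)))
    return {"records": records, "dropped": dropped, "clusters": clusters}


def load_netmhcpan_ranks(path) -> Callable[[str, str], float]:
    """Adapter for pre-computed binding ranks.

    Reads a whitespace- or tab-separated table with columns including
    ``Peptide``, an allele column (``HLA``, ``Allele`` or ``MHC``) and a
    percentile-rank column (``Rank`` / ``%Rank`` / ``EL_Rank``), as
    printed by netMHCpan-style tools, and returns a predictor callable.
    Unseen (peptide, allele) pairs raise ``KeyError``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().lstrip("%"): c for c in df.columns}
    pep_col = cols.get("peptide")
    allele_col = next(
        (cols[k] for k in ("hla", "allele", "mhc") if k in cols), None
    )
    rank_col = next(
        (cols[k] for k in ("rank", "el_rank", "rank_el") if k in cols), None
    )
    if pep_col is None or allele_col is None or rank_col is None:
        raise ValueError("could not locate Peptide/Allele/Rank columns")
    table = {
        (str(r[pep_col]), str(r[allele_col])): float(r[rank_col])
        for _, r in df.iterrows()
    }

    def predictor(peptide: str, allele: str) -> float:
        return table[(peptide, allele)]

    return predictor
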