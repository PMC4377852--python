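"""Mutation filtering, mutant translation, window enumeration and
antigen calling, checked against independent brute-force oracles."""

import warnings

import numpy as np
import pytest

from immunoscape import antigenome as ag
from immunoscape import synthetic as syn

# independent codon-table translator (oracle; deliberately not Biopython)
_CODON_TABLE = {}


def _build_codon_table():
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()


def oracle_translate(nt: str) -> str:
    """Translate codon by codon until the first stop."""
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aa = _CODON_TABLE[nt[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def oracle_windows(protein: str, span: tuple[int, int]) -> dict[str, int]:
    """All 8-11-mers overlapping the span, by exhaustive enumeration."""
    lo, hi = span
    out: dict[str, int] = {}
    for L in (8, 9, 10, 11):
        for s in range(0, len(protein) - L + 1):
            window = range(s + 1, s + L + 1)
            if any(lo <= r <= hi for r in window):
                pep = protein[s : s + L]
                out[pep] = out.get(pep, 0) + 1
    return out


@pytest.fixture(scope="module")
def mutation_world():
    cfg = syn.SyntheticConfig(seed=42, n_mutations=200, n_transcripts=40)
    transcripts, mutations, proteome = syn.generate_mutation_set(cfg)
    return cfg, transcripts, mutations, proteome


class TestGeneratorInvariants:
    def test_transcripts_translate_cleanly(self, mutation_world):
        _, transcripts, _, proteome = mutation_world
        for tid, t in transcripts.items():
            protein = oracle_translate(t.cds_sequence)
            assert protein == t.protein()  # second, table-driven translator
            assert "*" not in protein
            assert proteome[f"{tid}_wt"] == protein

    def test_class_proportions_match_configuration(self, mutation_world):
        cfg, _, mutations, _ = mutation_world
        from collections import Counter

        counts = Counter(m.mclass for m in mutations)
        for mclass, p in cfg.mutation_class_proportions.items():
            assert abs(counts[mclass] - p * cfg.n_mutations) <= 1

    def test_determinism(self, mutation_world):
        cfg, transcripts, mutations, _ = mutation_world
        tx2, muts2, prot2 = syn.generate_mutation_set(cfg)
        assert [t.cds_sequence for t in tx2.values()] == [
            t.cds_sequence for t in transcripts.values()
        ]
        assert [(m.mutation_id, m.ref, m.alt) for m in muts2] == [
            (m.mutation_id, m.ref, m.alt) for m in mutations
        ]

    def test_short_transcript_config_errors(self):
        cfg = syn.SyntheticConfig(seed=0, transcript_codon_range=(5, 8))
        with pytest.raises(ValueError, match="33"):
            syn.generate_mutation_set(cfg)


class TestFilterMutations:
    def test_decoys_excluded_with_reasons(self, mutation_world):
        _, transcripts, mutations, _ = mutation_world
        kept, excluded = ag.filter_mutations(mutations, transcripts)
        reasons = {}
        for mid, reason in excluded:
            reasons.setdefault(reason, 0)
            reasons[reason] += 1
        by_id = {m.mutation_id: m for m in mutations}
        for mid, reason in excluded:
            assert by_id[mid].mclass in {"start_codon", "splice", "exon_border"}
            assert reason == by_id[mid].mclass
        assert all(m.mclass in ag.PROTEIN_ALTERING for m in kept)

    def test_start_codon_change_excluded(self):
        t = ag.TranscriptModel("t", "+", [(1, 15), (100, 120)],
                               "ATG" + "GGA" * 10 + "TAA", "")
        m = ag.MutationRecord("p", "t", "missense", 2, "T", "A")
        kept, excl = ag.filter_mutations([m], {"t": t})
        assert kept == [] and excl == [(m.mutation_id, "start_codon")]

    def test_deletion_spanning_exon_border_excluded(self):
        t = ag.TranscriptModel("t", "+", [(1, 15), (100, 120)],
                               "ATG" + "GGA" * 10 + "TAA", "")
        # exon 1 covers CDS 1..15; a 5-bp deletion across position 15
        ref = t.cds_sequence[12:17]
        m = ag.MutationRecord("p", "t", "frameshift", 13, ref, "")
        kept, excl = ag.filter_mutations([m], {"t": t})
        assert excl == [(m.mutation_id, "exon_border")]

    def test_interior_missense_retained(self):
        t = ag.TranscriptModel("t", "+", [(1, 15), (100, 120)],
                               "ATG" + "GGA" * 10 + "TAA", "")
        m = ag.MutationRecord("p", "t", "missense", 8, "G", "T")
        kept, _ = ag.filter_mutations([m], {"t": t})
        assert kept == [m]

    def test_unknown_transcript_errors(self):
        m = ag.MutationRecord("p", "nope", "missense", 8, "G", "T")
        with pytest.raises(KeyError):
            ag.filter_mutations([m], {})


class TestTranslateMutation:
    def _transcript(self, cds, utr=""):
        return ag.TranscriptModel("t", "+", [(1, 9), (100, 100 + len(cds) - 10)],
                                  cds, utr)

    def test_missense_single_residue(self):
        cds = "ATG" + "GGT" + "CCC" * 8 + "TAA"
        t = self._transcript(cds)
        m = ag.MutationRecord("p", "t", "missense", 5, "G", "A")  # GGT -> GAT
        protein, span = ag.translate_mutation(t, m)
        assert protein[1] == "D" and span == (2, 2)
        assert protein == oracle_translate(ag._apply_edit(cds, m))

    def test_nonstop_reads_through_to_next_stop(self):
        cds = "ATG" + "CCC" * 5 + "TAA"
        utr = "GCTGCA" + "TAG" + "AAAAAA"
        t = self._transcript(cds, utr)
        m = ag.MutationRecord("p", "t", "nonstop", len(cds) - 2, "T", "C")
        protein, span = ag.translate_mutation(t, m)
        assert protein == oracle_translate(ag._apply_edit(cds, m) + utr)
        assert span == (7, len(protein))
        assert protein.endswith("AA")  # GCT GCA appended, stops at TAG

    def test_translations_match_oracle_on_random_cases(self, mutation_world):
        _, transcripts, mutations, _ = mutation_world
        kept, _ = ag.filter_mutations(mutations, transcripts)
        assert len(kept) >= 100
        for m in kept:
            t = transcripts[m.transcript_id]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                protein, span = ag.translate_mutation(t, m)
            edited = ag._apply_edit(t.cds_sequence, m)
            expected = oracle_translate(edited + t.downstream_utr)
            if m.mclass in ("missense", "non_frameshift"):
                # translation stops inside the edited CDS for in-frame edits
                expected = oracle_translate(edited)
            assert protein == expected, m.mutation_id
            lo, hi = span
            assert 1 <= lo <= hi <= len(protein)
            wt = t.protein()
            # residues outside the span match the wild type (prefix side)
            assert protein[: lo - 1] == wt[: lo - 1]

    def test_silent_edit_rejected(self):
        cds = "ATG" + "CTT" + "CCC" * 8 + "TAA"
        t = self._transcript(cds)
        m = ag.MutationRecord("p", "t", "missense", 6, "T", "G")  # CTT -> CTG (Leu)
        with pytest.raises(ValueError, match="silent"):
            ag.translate_mutation(t, m)


class TestEnumerateWindows:
    def test_interior_missense_yields_38_windows(self):
        protein = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(60)
        )
        windows = ag.enumerate_windows(protein, (30, 30))
        assert sum(windows.values()) == 8 + 9 + 10 + 11 == 38
        assert windows == oracle_windows(protein, (30, 30))

    def test_near_terminus_truncates_window_count(self):
        protein = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(60))
        windows = ag.enumerate_windows(protein, (2, 2))
        assert sum(windows.values()) == 8  # only starts 1 and 2 fit each length
        assert windows == oracle_windows(protein, (2, 2))

    def test_matches_oracle_for_all_generated_mutations(self, mutation_world):
        _, transcripts, mutations, _ = mutation_world
        kept, _ = ag.filter_mutations(mutations, transcripts)
        for m in kept:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                protein, span = ag.translate_mutation(
                    transcripts[m.transcript_id], m
                )
            if len(protein) < 8:
                continue
            assert ag.enumerate_windows(protein, span) == oracle_windows(
                protein, span
            ), m.mutation_id

    def test_empty_span_errors(self):
        with pytest.raises(ValueError):
            ag.enumerate_windows("A" * 30, (5, 4))


class TestMockPredictor:
    def test_deterministic_and_validated(self):
        pred = syn.MockBindingPredictor(seed=1)
        assert pred("SIINFEKLL", "HLA-A*02:01") == pred("SIINFEKLL", "HLA-A*02:01")
        with pytest.raises(ValueError):
            pred("SIINFEKLB", "HLA-A*02:01")
        with pytest.raises(ValueError):
            pred("SHORT", "HLA-A*02:01")

    def test_planted_binder_within_rank_2(self):
        pred = syn.MockBindingPredictor(seed=1,
                                        planted={("SIINFEKLL", "HLA-A*02:01")})
        assert pred("SIINFEKLL", "HLA-A*02:01") <= 2.0
        assert pred("SIINFEKLA", "HLA-A*02:01") > 2.0

    def test_rank_distribution_uniform(self):
        pred = syn.MockBindingPredictor(seed=3)
        rng = np.random.default_rng(1)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        ranks = np.array(
            [pred("".join(rng.choice(aas, 9)), "HLA-A*01:01")
             for _ in range(10_000)]
        )
        from scipy import stats

        assert stats.kstest(ranks / 100, "uniform").pvalue > 0.01
        assert ranks.min() > 0 and ranks.max() <= 100


class TestCallNeoantigens:
    def _simple_case(self):
        m = ag.MutationRecord("p1", "t1", "missense", 10, "A", "C")
        hla = {"p1": ["HLA-A*02:01"]}
        proteome = {"ref": "MKWVTFISLLFLFSSAYS"}
        return m, hla, proteome

    def test_rank_boundary_inclusive(self):
        m, hla, proteome = self._simple_case()
        calls = ag.call_neoantigens(
            [("SIINFEKLL", m)], hla, lambda p, a: 2.0, proteome
        )
        assert len(calls) == 1 and calls[0].rank == 2.0
        calls = ag.call_neoantigens(
            [("SIINFEKLL", m)], hla, lambda p, a: 2.0 + 1e-9, proteome
        )
        assert calls == []

    def test_proteome_substring_rejected(self):
        m, hla, proteome = self._simple_case()
        calls = ag.call_neoantigens(
            [("WVTFISLL", m)], hla, lambda p, a: 0.5, proteome
        )
        assert calls == []

    def test_monotone_in_rank_threshold(self):
        m, hla, proteome = self._simple_case()
        peps = [(f"SIINFEKL{c}", m) for c in "LAVGIK"]
        pred = syn.MockBindingPredictor(seed=5)
        loose = {c.peptide for c in
                 ag.call_neoantigens(peps, hla, pred, proteome, 50.0)}
        tight = {c.peptide for c in
                 ag.call_neoantigens(peps, hla, pred, proteome, 10.0)}
        assert tight <= loose

    def test_missing_hla_errors(self):
        m, _, proteome = self._simple_case()
        with pytest.raises(ValueError, match="p1"):
            ag.call_neoantigens([("SIINFEKLL", m)], {}, lambda p, a: 1.0, proteome)

    def test_end_to_end_planted_recovery(self, mutation_world):
        """Called neo-antigens equal planted (reachable) binders exactly."""
        cfg, transcripts, mutations, proteome = mutation_world
        hla = syn.generate_hla_table(cfg)
        binders = syn.plant_binders(cfg, mutations, transcripts, proteome, hla,
                                    fraction=0.05)
        pred = syn.MockBindingPredictor(seed=cfg.seed, planted=binders)
        kept, _ = ag.filter_mutations(mutations, transcripts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            peps = ag.mutant_peptides(kept, transcripts)
        calls = ag.call_neoantigens(peps, hla, pred, proteome)
        called = {(c.peptide, c.hla_allele) for c in calls}
        index = ag.ProteomeIndex(proteome)
        reachable = set()
        for pep, m in peps:
            if pep in index:
                continue
            for allele in hla[m.patient_id]:
                if (pep, allele) in binders:
                    reachable.add((pep, allele))
        assert called == reachable
        # post-hoc: no called peptide is a proteome substring
        blob = "#".join(proteome.values())
        assert all(c.peptide not in blob for c in calls)


class TestNeoantigenFrequency:
    def _mutations(self, n, patient="p"):
        return [
            ag.MutationRecord(patient, "t", "missense", 10 + 3 * i, "A", "C",
                              expressed=True, mutation_id=f"m{i}")
            for i in range(n)
        ]

    def _na(self, mid, patient="p"):
        return ag.NeoAntigen("SIINFEKLL", patient, mid, "t", "HLA-A*01:01", 1.0)

    def test_fraction_definition(self):
        muts = self._mutations(10)
        nas = [self._na(f"m{i}") for i in range(4)]
        assert ag.neoantigen_frequency(muts, nas)["p"] == pytest.approx(0.4)

    def test_bounds(self):
        muts = self._mutations(3)
        assert ag.neoantigen_frequency(muts, [])["p"] == 0.0
        nas = [self._na(f"m{i}") for i in range(3)]
        assert ag.neoantigen_frequency(muts, nas)["p"] == 1.0

    def test_unexpressed_patient_missing(self):
        muts = self._mutations(2)
        for m in muts:
            m.expressed = False
        assert "p" not in ag.neoantigen_frequency(muts, [])

    def test_per_mutation_counts_variant(self):
        muts = self._mutations(2)
        nas = [self._na("m0"), self._na("m0"), self._na("m1")]
        out = ag.neoantigen_frequency(muts, nas, per_mutation_counts=True)
        assert out["p"] == pytest.approx(1.5)


class TestExpressedFlag:
    def test_flags_follow_gene_tpm(self):
        import pandas as pd
        from immunoscape.matrix import ExpressionMatrix

        expr = ExpressionMatrix(
            pd.DataFrame({"p1": [5.0, 0.2]}, index=["t1", "t2"])
        )
        muts = [
            ag.MutationRecord("p1", "t1", "missense", 10, "A", "C"),
            ag.MutationRecord("p1", "t2", "missense", 10, "A", "C"),
        ]
        ag.flag_expressed_mutations(muts, expr, min_tpm=1.0)
        assert muts[0].expressed is True
        assert muts[1].expressed is False


class TestSharedNeoantigens:
    def _na(self, pep, patient, tx="t1"):
        return ag.NeoAntigen(pep, patient, "m", tx, "HLA-A*01:01", 1.0)

    def test_identity_grouping(self):
        nas = [self._na("SIINFEKLL", "p1", "t1"), self._na("SIINFEKLL", "p2", "t2")]
        out = ag.shared_neoantigens(nas)
        assert len(out["table"]) == 1
        row = out["table"].iloc[0]
        assert row["n_patients"] == 2 and set(row["transcripts"]) == {"t1", "t2"}

    def test_all_unique_empty(self):
        nas = [self._na("SIINFEKLL", "p1"), self._na("SIINFEKLA", "p2")]
        assert ag.shared_neoantigens(nas)["table"].empty

    def test_planted_hotspot_recovered(self):
        rng = np.random.default_rng(9)
        nas = []
        carriers = [f"p{i}" for i in range(100) if rng.random() < 0.3]
        for p in carriers:
            nas.append(self._na("HOTSPOTPEP", p))
        for i in range(100):
            nas.append(self._na(f"PRIVATE{i:03d}"[:10].ljust(8, "A"), f"p{i}"))
        out = ag.shared_neoantigens(nas)
        row = out["table"].set_index("peptide").loc["HOTSPOTPEP"]
        assert row["n_patients"] == len(carriers)


class TestCGA:
    def _matrices(self, normal_rows, tumor_rows, genes):
        import pandas as pd
        from immunoscape.matrix import ExpressionMatrix

        normal = ExpressionMatrix(
            pd.DataFrame(normal_rows, index=genes,
                         columns=[f"n{i}" for i in range(len(normal_rows[0]))])
        )
        tumor = ExpressionMatrix(
            pd.DataFrame(tumor_rows, index=genes,
                         columns=[f"t{i}" for i in range(len(tumor_rows[0]))])
        )
        return tumor, normal

    def test_baseline_rule_and_boundary(self):
        # normal: median 5, sd 1 (values chosen to give these exactly)
        normal_vals = [np.array([4.0, 5.0, 6.0])]
        genes = ["cga1"]
        for tumor_value, expected in [(8.5, True), (8.0, False)]:
            tumor, normal = self._matrices(
                normal_vals, [np.array([tumor_value, 0.0])], genes
            )
            sd = float(np.std([4, 5, 6], ddof=1))
            out = ag.call_cga(tumor, normal, genes, de_results="skip" and None,
                              de_alpha=0.0, k=1)
            rec = out["records"][0]
            assert rec.baseline == pytest.approx(5 + 3 * sd)
            assert rec.positive["t0"] is (tumor_value > rec.baseline)

    def test_zero_sd_excluded(self):
        tumor, normal = self._matrices(
            [np.array([5.0, 5.0, 5.0])], [np.array([50.0, 60.0])], ["flat"]
        )
        out = ag.call_cga(tumor, normal, ["flat"], de_alpha=0.0, k=1)
        assert out["dropped"] == {"flat": "zero_normal_sd"}
        assert out["records"] == []

    def test_downregulated_gene_removed(self):
        rng = np.random.default_rng(2)
        genes = ["down", "up"]
        normal = [rng.uniform(100, 110, 10), rng.uniform(1, 2, 10)]
        tumor = [rng.uniform(1, 2, 10), rng.uniform(100, 110, 10)]
        t, n = self._matrices(normal, tumor, genes)
        out = ag.call_cga(t, n, genes, de_alpha=0.05, k=1)
        assert out["dropped"].get("down") == "downregulated_in_tumor"
        assert [r.gene_id for r in out["records"]] == ["up"]

    def test_too_few_normals_errors(self):
        tumor, normal = self._matrices([np.array([5.0])], [np.array([9.0])], ["g"])
        with pytest.raises(ValueError):
            ag.call_cga(tumor, normal, ["g"])
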