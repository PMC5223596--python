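import numpy as np
import pytest

from conftest import record
from glutenprofiler.digestion import peptide_mz
from glutenprofiler.evidence import (
    DigestIndex,
    EvidenceRow,
    InferenceConfig,
    Modification,
    ProteinIdentification,
    assign_uniqueness,
    collapse_modification_variants,
    filter_evidence,
    format_modifications,
    infer_proteins,
    load_and_validate_evidence,
    parse_modifications,
    platform_overlap,
    reliable_peptides,
    sequence_coverage,
)
from glutenprofiler.seqdb import curate_database

RULE = "chymotrypsin-expasy"

# two 140+ aa proteins sharing the prolamin repeat QPQQPF but each
# carrying one private digest peptide
SHARED = "QPQQPF" * 20
SEQ_A = "M" + "QQSQQAGY" + SHARED + "HHHHHHHHGY"
SEQ_B = "M" + "QQCQQAGY" + SHARED + "HHHHHHHHGY"


@pytest.fixture(scope="module")
def toy_index():
    db = curate_database([record("PA", SEQ_A), record("PB", SEQ_B)])
    return DigestIndex(db, RULE, max_missed=2)


def row(seq, mods=(), platform="QTOF", extract="E1", seed="S1", tech_rep=1,
        charge=2, score=20.0, intensity=1e5, observed_mz=None):
    mods = tuple(mods)
    if observed_mz is None:
        r = EvidenceRow(platform=platform, extract=extract, seed=seed,
                        tech_rep=tech_rep, peptide_sequence=seq,
                        modifications=mods, charge=charge, observed_mz=0.0,
                        score=score, intensity=intensity)
        observed_mz = r.theoretical_mz()
    return EvidenceRow(platform=platform, extract=extract, seed=seed,
                       tech_rep=tech_rep, peptide_sequence=seq,
                       modifications=mods, charge=charge,
                       observed_mz=observed_mz, score=score,
                       intensity=intensity)


class TestModificationGrammar:
    def test_roundtrip(self):
        mods = parse_modifications("Deamidation@{3|5};Oxidation@7")
        assert mods == [
            Modification("Deamidation", frozenset({3, 5})),
            Modification("Oxidation", frozenset({7})),
        ]
        assert format_modifications(mods) == "Deamidation@{3|5};Oxidation@7"

    def test_empty_string(self):
        assert parse_modifications("") == []

    @pytest.mark.parametrize("bad", ["Deamidation", "Deamidation@", "Foo@3",
                                     "Deamidation@{3|}", "Deamidation@x"])
    def test_malformed_rejected(self, bad):
        with pytest.raises((ValueError, KeyError)):
            parse_modifications(bad)


class TestLoadAndValidate:
    HEADER = ("platform,extract,seed,tech_rep,peptide_sequence,modifications,"
              "charge,observed_mz,score,intensity,retention_time\n")

    def _write(self, tmp_path, lines):
        path = tmp_path / "ev.csv"
        path.write_text(self.HEADER + "".join(lines))
        return path

    def test_well_formed_rows(self, tmp_path):
        path = self._write(tmp_path, [
            "QTOF,E1,S1,1,PQQF,,2,500.1,12.5,1e5,35.2\n",
            "LTQ,E2,S2,2,QPQQPF,Deamidation@3,2,600.2,8.0,2e4,\n",
            "QTOF,E3,S3,3,MQNQ,Deamidation@{2|3},3,400.0,5.0,1e3,10.0\n",
        ])
        rows, rejects = load_and_validate_evidence(path)
        assert len(rows) == 3 and rejects == []
        assert rows[2].modifications[0].positions == frozenset({2, 3})

    def test_invalid_rows_rejected_with_line_numbers(self, tmp_path):
        path = self._write(tmp_path, [
            "QTOF,E1,S1,1,PQQF,Deamidation@9,2,500.1,12.5,1e5,\n",   # pos > len
            "QTOF,E1,S1,1,PQQF,Deamidation@1,2,500.1,12.5,1e5,\n",   # P not N/Q
            "QTOF,E1,S1,1,PQQF,Oxidation#3,2,500.1,12.5,1e5,\n",     # grammar
            "QTOF,E1,S1,1,PQQF,,0,500.1,12.5,1e5,\n",                # charge
            "QTOF,E1,S1,1,PQQF,,2,500.1,-1,1e5,\n",                  # score < 0
            "QTOF,E1,S1,1,PQQF,,2,500.1,12.5,1e5,\n",                # fine
        ])
        rows, rejects = load_and_validate_evidence(path)
        assert len(rows) == 1
        assert [line for line, _ in rejects] == [1, 2, 3, 4, 5]

    def test_missing_column_is_an_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("platform,extract\nQTOF,E1\n")
        with pytest.raises(ValueError, match="missing required columns"):
            load_and_validate_evidence(path)


class TestFilterEvidence:
    def test_score_threshold_inclusive(self, toy_index):
        cfg = InferenceConfig()
        kept, rej = filter_evidence(
            [row("QPQQPF", score=5.0), row("QPQQPF", score=4.99)],
            cfg, toy_index)
        assert len(kept) == 1 and kept[0].score == 5.0
        assert rej[0][1] == "score"

    def test_ppm_boundary(self, toy_index):
        cfg = InferenceConfig()
        theo = peptide_mz("QPQQPF", 2)
        good = row("QPQQPF", observed_mz=theo * (1 + 9e-6))
        bad = row("QPQQPF", observed_mz=theo * (1 + 11e-6))
        kept, rej = filter_evidence([good, bad], cfg, toy_index)
        assert kept == [good]
        assert rej == [(bad, "ppm")]

    def test_unmatched_peptide_tagged_not_raised(self, toy_index):
        kept, rej = filter_evidence(
            [row("WWWWWW")], InferenceConfig(), toy_index)
        assert kept == [] and rej[0][1] == "unmatched"

    def test_excess_missed_cleavages_rejected(self, toy_index):
        # QPQQPFQPQQPFQPQQPF spans 3 internal sites at max_missed=2?
        # no: 2 internal sites; use 4 repeats -> 3 internal sites
        seq = "QPQQPF" * 4
        kept, rej = filter_evidence(
            [row(seq)], InferenceConfig(max_missed=2), toy_index)
        assert kept == [] and rej[0][1] == "missed_cleavages"

    def test_retained_set_equals_conjunction_of_criteria(self, toy_index):
        # order independence: retention is the AND of the three criteria
        rng = np.random.default_rng(3)
        cfg = InferenceConfig()
        rows = []
        for _ in range(50):
            seq = "QPQQPF" * int(rng.integers(1, 5))
            theo = peptide_mz(seq, 2)
            rows.append(row(
                seq,
                score=float(rng.uniform(0, 10)),
                observed_mz=theo * (1 + float(rng.uniform(-2e-5, 2e-5))),
            ))
        kept, _ = filter_evidence(rows, cfg, toy_index)
        expected = [
            r for r in rows
            if r.score >= 5
            and abs(r.observed_mz - r.theoretical_mz()) / r.theoretical_mz() * 1e6 <= 10
            and r.peptide_sequence in toy_index
            and toy_index.min_missed(r.peptide_sequence) <= 2
        ]
        assert kept == expected


class TestCollapse:
    def test_positional_deamidation_isomers_collapse(self):
        rows = [
            row("PQQF", [Modification("Deamidation", frozenset({2}))]),
            row("PQQF", [Modification("Deamidation", frozenset({3}))]),
        ]
        ents = collapse_modification_variants(rows, "sequence_with_mods")
        assert len(ents) == 1
        assert len(ents[0].rows) == 2

    def test_deamidation_count_separates_entities(self):
        rows = [
            row("PQQF"),
            row("PQQF", [Modification("Deamidation", frozenset({2}))]),
        ]
        assert len(collapse_modification_variants(rows, "sequence_with_mods")) == 2
        assert len(collapse_modification_variants(rows, "sequence_only")) == 1

    def test_oxidation_position_also_ignored(self):
        rows = [
            row("MQMF", [Modification("Oxidation", frozenset({1}))]),
            row("MQMF", [Modification("Oxidation", frozenset({3}))]),
        ]
        assert len(collapse_modification_variants(rows, "sequence_with_mods")) == 1


class TestReliability:
    CFG = InferenceConfig()

    def _entity(self, observations):
        rows = [row("QPQQPF", extract=e, seed=s, tech_rep=t, platform=p)
                for (p, e, s, t) in observations]
        (ent,) = collapse_modification_variants(rows, "sequence_only")
        reliable_peptides([ent], self.CFG)
        return ent

    def test_two_seeds_two_reps_reliable(self):
        ent = self._entity([("QTOF", "E2", "SA", 1), ("QTOF", "E2", "SA", 2),
                            ("QTOF", "E2", "SB", 1), ("QTOF", "E2", "SB", 3)])
        assert ent.reliable_extracts == frozenset({"E2"})

    def test_single_seed_not_reliable(self):
        ent = self._entity([("QTOF", "E1", "SA", t) for t in (1, 2, 3)]
                           + [("LTQ", "E1", "SA", 1)])
        assert ent.reliable_extracts == frozenset()

    def test_one_rep_per_seed_not_reliable(self):
        ent = self._entity([("QTOF", "E1", s, 1) for s in ("SA", "SB", "SC")])
        assert ent.reliable_extracts == frozenset()

    def test_platform_pooling_counts_distinct_pairs(self):
        # one QTOF rep + one LTQ rep in each of two seeds: pooled reliable
        ent = self._entity([("QTOF", "E1", "SA", 1), ("LTQ", "E1", "SA", 1),
                            ("QTOF", "E1", "SB", 2), ("LTQ", "E1", "SB", 2)])
        assert ent.reliable_extracts == frozenset({"E1"})

    def test_strict_per_platform_mode(self):
        rows = [row("QPQQPF", extract="E1", seed=s, tech_rep=t, platform=p)
                for s in ("SA", "SB") for (p, t) in
                (("QTOF", 1), ("LTQ", 1))]
        (ent,) = collapse_modification_variants(rows, "sequence_only")
        reliable_peptides([ent], InferenceConfig(reliability_per_platform=True))
        assert ent.reliable_extracts == frozenset()


class TestUniquenessAndInference:
    def test_private_peptide_unique_shared_repeat_not(self, toy_index):
        rows = [row("QQSQQAGY"), row("QPQQPF")]
        ents = collapse_modification_variants(rows, "sequence_only")
        assign_uniqueness(ents, toy_index)
        by_seq = {e.sequence: e for e in ents}
        assert by_seq["QQSQQAGY"].is_unique
        assert by_seq["QQSQQAGY"].accessions == frozenset({"PA"})
        assert not by_seq["QPQQPF"].is_unique
        assert by_seq["QPQQPF"].accessions == frozenset({"PA", "PB"})

    def test_orphan_flagged(self, toy_index):
        ents = collapse_modification_variants([row("WWWWWW")], "sequence_only")
        assign_uniqueness(ents, toy_index)
        assert ents[0].is_orphan

    def test_uncurated_duplicates_trigger_warning(self):
        from glutenprofiler.seqdb import SequenceDatabase

        db = SequenceDatabase(records=[record("D1", SEQ_A), record("D2", SEQ_A)])
        index = DigestIndex(db, RULE, 2)
        ents = collapse_modification_variants([row("QQSQQAGY")], "sequence_only")
        warn = []
        assign_uniqueness(ents, index, warn)
        assert not ents[0].is_unique
        assert warn and "curation" in warn[0]

    def test_threshold_semantics(self, toy_index):
        # PA supported by exactly 2 reliable unique entities (the plain
        # and singly-deamidated forms of its private peptide): reported
        # at min=1, absent at min=3
        rows = []
        for mods in ((), (Modification("Deamidation", frozenset({2})),)):
            rows += [row("QQSQQAGY", mods, extract="E1", seed=s, tech_rep=t)
                     for s in ("SA", "SB") for t in (1, 2)]
        ents = collapse_modification_variants(rows, "sequence_with_mods")
        assert len(ents) == 2
        reliable_peptides(ents, InferenceConfig())
        assign_uniqueness(ents, toy_index)
        idents, counts = infer_proteins(ents, InferenceConfig(min_unique_peptides=1))
        assert counts[1] >= 1 and counts[3] == 0
        assert any(i.accession == "PA" for i in idents)
        idents3, _ = infer_proteins(ents, InferenceConfig(min_unique_peptides=3))
        assert idents3 == []

    def test_unreliable_unique_peptide_never_counts(self, toy_index):
        rows = [row("QQSQQAGY", extract="E1", seed="SA", tech_rep=t)
                for t in (1, 2, 3)]  # one seed only -> unreliable
        ents = collapse_modification_variants(rows, "sequence_only")
        reliable_peptides(ents, InferenceConfig())
        assign_uniqueness(ents, toy_index)
        _, counts = infer_proteins(ents, InferenceConfig())
        assert counts[1] == 0 and counts[3] == 0

    def test_monotonicity_on_scenario(self, scenario_pipeline):
        sp = scenario_pipeline
        idents1, _ = infer_proteins(
            sp["entities"], InferenceConfig(min_unique_peptides=1), sp["index"])
        idents3, _ = infer_proteins(
            sp["entities"], InferenceConfig(min_unique_peptides=3), sp["index"])
        accs1 = {i.accession for i in idents1}
        accs3 = {i.accession for i in idents3}
        assert accs3 <= accs1


class TestCoverageAndOverlap:
    def test_overlapping_spans_union(self):
        # one peptide sequence occurring at [0,20) and [10,30) of a
        # 100-residue protein: union of all occurrences covers 30 residues
        from glutenprofiler.seqdb import SequenceDatabase

        seq = ("A" * 9 + "F") * 3 + "A" * 70
        db = SequenceDatabase(records=[record("PX", seq)])
        index = DigestIndex(db, RULE, 2)
        ents = collapse_modification_variants([row(seq[0:20])], "sequence_only")
        assert seq[0:20] == seq[10:30]  # repeat structure
        ident = ProteinIdentification(accession="PX", peptides=ents)
        cov, mask = sequence_coverage(ident, index)
        covered = np.flatnonzero(mask)
        assert covered.min() == 0 and covered.max() == 29
        assert cov == pytest.approx(0.30)

    def test_tiling_gives_full_coverage(self, toy_index):
        from glutenprofiler.digestion import digest

        ents = collapse_modification_variants(
            [row(s.sequence) for s in digest(SEQ_A, RULE, 0)], "sequence_only")
        pa_ents = [e for e in ents]
        ident = ProteinIdentification(accession="PA", peptides=pa_ents)
        cov, _ = sequence_coverage(ident, toy_index)
        assert cov == pytest.approx(1.0)

    def test_platform_overlap_set_arithmetic(self):
        rows_a = [row("PQQF", platform=p) for p in ("QTOF", "LTQ")]
        rows_b = [row("QQPF", platform="QTOF")]
        rows_c = [row("QNPF", platform="LTQ")]
        ents = collapse_modification_variants(
            rows_a + rows_b + rows_c, "sequence_only")
        counts = platform_overlap(ents)
        assert counts["total"] == 3
        assert counts["per_platform"] == {"QTOF": 2, "LTQ": 2}
        assert counts["shared"] == 1
        assert (counts["per_platform"]["QTOF"] + counts["per_platform"]["LTQ"]
                - counts["shared"]) == counts["total"]

    def test_union_identity_on_scenario(self, scenario_pipeline):
        counts = platform_overlap(scenario_pipeline["entities"])
        assert (sum(counts["per_platform"].values()) - counts["shared"]
                == counts["total"])
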