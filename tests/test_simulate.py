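import pytest

from corkosc import (
    ExpressionSpec,
    FamilySpec,
    LabeledMsa,
    QpcrSpec,
    TranscriptSpec,
    segregating_positions,
    simulate_expression,
    simulate_labeled_family,
    simulate_qpcr,
    simulate_transcripts,
)
from corkosc.seq import translate


class TestFamilySimulation:
    def test_same_seed_byte_identical(self):
        a = simulate_labeled_family(FamilySpec(seed=42))
        b = simulate_labeled_family(FamilySpec(seed=42))
        assert [r.residues for r in a.protein_msa.records] == [
            r.residues for r in b.protein_msa.records
        ]
        assert [r.residues for r in a.codon_msa.records] == [
            r.residues for r in b.codon_msa.records
        ]

    def test_noise_free_construction_fixes_planted_columns(self):
        spec = FamilySpec(within_group_noise=0.0, background_divergence=0.0, gap_fraction=0.0, seed=1)
        fam = simulate_labeled_family(spec)
        for col, (grp, res) in fam.truth.items():
            for rec in fam.protein_msa.records:
                if fam.labels[rec.id] == grp:
                    assert rec.residues[col - 1] == res
                else:
                    assert rec.residues[col - 1] != res

    def test_codon_alignment_translates_to_protein_alignment(self):
        fam = simulate_labeled_family(FamilySpec(seed=8))
        for prot, codons in zip(fam.protein_msa.records, fam.codon_msa.records):
            assert prot.id == codons.id
            for k, aa in enumerate(prot.residues):
                codon = codons.residues[3 * k : 3 * k + 3]
                if aa == "-":
                    assert codon == "---"
                else:
                    assert translate(codon, 1) == aa

    def test_planted_column_outside_alignment_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            FamilySpec(length=100, planted={200: ("LUP", "W")})

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            FamilySpec(background_divergence=1.5)

    def test_planted_columns_never_gapped(self):
        fam = simulate_labeled_family(FamilySpec(gap_fraction=0.3, seed=4))
        for col in fam.truth:
            assert "-" not in fam.protein_msa.column(col)

    def test_write_and_reload_round_trip(self, tmp_path):
        from corkosc.seq import Msa
        from corkosc.segregation import read_label_table

        fam = simulate_labeled_family(FamilySpec(seed=7))
        fam.write(tmp_path)
        msa = Msa.from_fasta(tmp_path / "protein_msa.fasta")
        labels = read_label_table(tmp_path / "labels.tsv")
        lm = LabeledMsa(msa, labels)
        rep = segregating_positions(lm, "FRS")
        assert rep.columns == fam.planted_columns("FRS")


class TestTranscriptSimulation:
    def test_deterministic(self):
        spec = TranscriptSpec(seed=11)
        a = simulate_transcripts(spec)
        b = simulate_transcripts(spec)
        assert [r.residues for r in a.records] == [r.residues for r in b.records]

    def test_single_start_codon_per_record(self):
        """The construction plants exactly one ATG (either strand) per record."""
        sim = simulate_transcripts(TranscriptSpec(seed=3))
        for rec, truth in zip(sim.records, sim.truth):
            seq = rec.residues
            if truth.strand == "+":
                assert seq.count("ATG") == 1
                assert "CAT" not in seq  # no reverse-strand start anywhere
            else:
                assert seq.count("CAT") == 1
                assert "ATG" not in seq

    def test_motif_encoded_in_frame_when_requested(self):
        sim = simulate_transcripts(
            TranscriptSpec(orf_lengths=(600,), include_motif=(True,), seed=2)
        )
        truth = sim.truth[0]
        orf_nt = sim.records[0].residues[truth.orf_start - 1 : truth.orf_end]
        assert "SDCTAE" in translate(orf_nt, 1)

    def test_inverted_duplicate_recorded_on_opposite_strand(self):
        sim = simulate_transcripts(
            TranscriptSpec(orf_lengths=(300,), include_motif=(False,),
                           duplications=((0, "inverted"),), seed=6)
        )
        (scaffold,) = sim.scaffolds
        _, layout = scaffold
        assert [s for _, s in layout] == ["+", "-"]
        assert sim.truth_for("rec0_dup0").strand == "-"

    def test_truncation_shortens_orf_and_marks_truth(self):
        sim = simulate_transcripts(
            TranscriptSpec(orf_lengths=(1800,), include_motif=(False,),
                           truncate=((0, 660),), seed=6)
        )
        truth = sim.truth[0]
        assert truth.truncated and truth.open_ended
        assert truth.orf_length_bp == 1140

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            TranscriptSpec(orf_lengths=(1499,), include_motif=(True,))
        with pytest.raises(ValueError):
            TranscriptSpec(orf_lengths=(300,), include_motif=(False,),
                           truncate=((0, 300),))
        with pytest.raises(ValueError):
            TranscriptSpec(orf_lengths=(300,), include_motif=(False,),
                           duplications=((5, "tandem"),))


class TestExpressionSimulation:
    def test_deterministic(self):
        a = simulate_expression(ExpressionSpec(seed=9))
        b = simulate_expression(ExpressionSpec(seed=9))
        assert a.tpm.equals(b.tpm)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            ExpressionSpec(genes=())
        with pytest.raises(ValueError):
            ExpressionSpec(tissues=())

    def test_enhanced_tissue_must_exist(self):
        with pytest.raises(ValueError, match="not in tissue list"):
            ExpressionSpec(
                genes=("g",), tissues=(("leaf", 2),), enhanced={"g": "root"}
            )

    def test_effect_present_in_raw_tpm(self):
        sim = simulate_expression(ExpressionSpec(noise_sd=0.0, effect_size=10.0, seed=1))
        for gene, tissue in sim.truth.items():
            if tissue is None:
                continue
            row = sim.tpm.loc[gene]
            enhanced = [s for s, t in sim.tissue_map.items() if t == tissue]
            others = [s for s in sim.tpm.columns if s not in enhanced]
            assert row[enhanced].mean() == pytest.approx(10.0 * row[others].mean())


class TestQpcrSimulation:
    def test_deterministic(self):
        a = simulate_qpcr(QpcrSpec(replicate_sd=0.3, seed=5))
        b = simulate_qpcr(QpcrSpec(replicate_sd=0.3, seed=5))
        assert a.dilution_series == b.dilution_series
        assert a.ct_table == b.ct_table

    def test_efficiency_bounds_enforced(self):
        with pytest.raises(ValueError):
            QpcrSpec(efficiency_target=2.5)
        with pytest.raises(ValueError):
            QpcrSpec(efficiency_reference=1.0)

    def test_truth_reports_generating_parameters(self):
        spec = QpcrSpec(true_ratio=3.0, efficiency_target=1.9, seed=2)
        sim = simulate_qpcr(spec)
        assert sim.truth["true_ratio"] == 3.0
        assert sim.truth["efficiency_target"] == 1.9
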