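"""One-hot/PSSM encoding, profile providers, database modes, CNN baseline.

tests/data/example.pssm is a real PSI-BLAST ``-out_ascii_pssm`` output for the
30-residue query KEGGISDHRRLDHVYPDVDHDEAHWDIAID against a 18-sequence
synthetic database (dialect reference for the parser).
"""

import shutil
from pathlib import Path

import numpy as np
import pytest

from protlm.corpus import make_split
from protlm.pssm import (
    CLEAN,
    INPUT_WIDTH,
    LEAKY,
    MAX_LEN,
    BaselineCNN,
    CNNSpec,
    PSSMatrix,
    build_pssm_database,
    encode_input,
    one_hot,
    parse_ascii_pssm,
    predict_cnn,
    profile_search_pssm,
    psiblast_command,
    psiblast_pssm,
    pssm_from_alignment,
    train_cnn,
)
from protlm.synthetic import SyntheticCorpusConfig, generate_corpus
from protlm.vocab import STANDARD_RESIDUES, AminoAcidVocabulary, ProteinRecord

VOCAB = AminoAcidVocabulary()
FIXTURE = Path(__file__).parent / "data" / "example.pssm"
FIXTURE_QUERY = "KEGGISDHRRLDHVYPDVDHDEAHWDIAID"


class TestOneHot:
    def test_single_residue_row(self):
        m = one_hot(ProteinRecord("m", "M"))
        assert m.shape == (1, 26)
        assert m.sum() == 1.0
        assert m[0, VOCAB.residue_index("M")] == 1.0

    def test_row_sums_and_argmax_decoding(self):
        seq = "MSLRXB"
        m = one_hot(ProteinRecord("q", seq))
        np.testing.assert_array_equal(m.sum(axis=1), np.ones(len(seq)))
        decoded = "".join(VOCAB.residue_tokens[i] for i in m.argmax(axis=1))
        assert decoded == seq


class TestAlignmentPSSM:
    def test_uniform_column_scores_zero(self):
        aligned = [aa * 3 for aa in STANDARD_RESIDUES]  # each column uniform
        pssm = pssm_from_alignment(aligned)
        np.testing.assert_allclose(pssm.scores, 0.0, atol=1e-12)

    def test_single_sequence_matches_hand_computed_log_odds(self):
        pssm = pssm_from_alignment(["AC"], pseudocount=1.0)
        # count 1 + 1/20 over N=2 total for the observed residue
        obs = np.log(((1 + 0.05) / 2) / 0.05)
        other = np.log((0.05 / 2) / 0.05)
        assert pssm.scores[0, STANDARD_RESIDUES.index("A")] == pytest.approx(obs)
        assert pssm.scores[0, STANDARD_RESIDUES.index("C")] == pytest.approx(other)

    def test_score_increases_with_frequency(self):
        low = pssm_from_alignment(["A", "C", "C", "C"])
        high = pssm_from_alignment(["A", "A", "A", "C"])
        a = STANDARD_RESIDUES.index("A")
        assert high.scores[0, a] > low.scores[0, a]

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            pssm_from_alignment([])


class TestProfileSearch:
    def test_iterative_search_reaches_remote_family_members(self):
        cfg = SyntheticCorpusConfig(clusters_per_family=6,
                                    members_per_cluster=3,
                                    length_range=(60, 60), seed=13)
        corpus = generate_corpus(cfg)
        query = corpus.records[0]
        pssm = profile_search_pssm(query, corpus.records)
        assert pssm.provenance["n_hits"] >= 2  # beyond the query's own cluster
        assert len(pssm) == len(query.sequence)


class TestPsiblastAdapter:
    def test_command_includes_three_iterations_and_evalue(self):
        cmd = psiblast_command("q.fasta", "db", "out.pssm")
        assert cmd[cmd.index("-num_iterations") + 1] == "3"
        assert cmd[cmd.index("-evalue") + 1] == "0.001"

    def test_ascii_pssm_fixture_parsed_and_remapped(self):
        pssm = parse_ascii_pssm(FIXTURE.read_text())
        assert pssm.scores.shape == (len(FIXTURE_QUERY), 20)
        # the query residue should score highly at most positions of a
        # near-identity profile; check it beats the row mean at position 0
        k = STANDARD_RESIDUES.index(FIXTURE_QUERY[0])
        assert pssm.scores[0, k] > pssm.scores[0].mean()

    def test_missing_executable_reported_by_name(self, monkeypatch):
        monkeypatch.setattr(shutil, "which", lambda _: None)
        with pytest.raises(Exception, match="psiblast"):
            psiblast_pssm(ProteinRecord("q", "MSLR"), "db")

    @pytest.mark.skipif(shutil.which("psiblast") is None,
                        reason="BLAST+ not installed")
    def test_end_to_end_against_real_psiblast(self, tmp_path):
        cfg = SyntheticCorpusConfig(n_families=2, clusters_per_family=3,
                                    members_per_cluster=3,
                                    length_range=(30, 40), seed=77)
        corpus = generate_corpus(cfg)
        split = make_split(corpus.clusters, mode="cluster", seed=0)
        db = build_pssm_database(corpus.records, split, corpus.clusters,
                                 LEAKY, tmp_path)
        pssm = psiblast_pssm(corpus.records[0], db, mode=LEAKY)
        assert pssm.scores.shape == (len(corpus.records[0].sequence), 20)
        assert pssm.provenance["mode"] == LEAKY


class TestDatabaseModes:
    def test_clean_database_excludes_every_test_cluster_member(self, tmp_path):
        cfg = SyntheticCorpusConfig(clusters_per_family=5,
                                    members_per_cluster=3, seed=14)
        corpus = generate_corpus(cfg)
        split = make_split(corpus.clusters, mode="cluster", seed=1)
        fasta = build_pssm_database(corpus.records, split, corpus.clusters,
                                    CLEAN, tmp_path)
        from protlm.corpus import read_fasta

        db_ids = {r.id for r in read_fasta(fasta)}
        forbidden = split.valid | split.test
        assert not (db_ids & forbidden)
        train_clusters = {corpus.clusters.member_of[s] for s in split.train}
        expected = {s for s, c in corpus.clusters.member_of.items()
                    if c in train_clusters}
        assert db_ids == expected

    def test_leaky_database_contains_full_corpus(self, tmp_path):
        cfg = SyntheticCorpusConfig(clusters_per_family=4,
                                    members_per_cluster=2, seed=15)
        corpus = generate_corpus(cfg)
        split = make_split(corpus.clusters, mode="cluster", seed=1)
        fasta = build_pssm_database(corpus.records, split, corpus.clusters,
                                    LEAKY, tmp_path)
        from protlm.corpus import read_fasta

        assert {r.id for r in read_fasta(fasta)} == {r.id for r in corpus.records}

    def test_unknown_mode_rejected(self, tmp_path):
        cfg = SyntheticCorpusConfig(clusters_per_family=3,
                                    members_per_cluster=2, seed=16)
        corpus = generate_corpus(cfg)
        split = make_split(corpus.clusters, mode="cluster", seed=1)
        with pytest.raises(ValueError):
            build_pssm_database(corpus.records, split, corpus.clusters,
                                "partial", tmp_path)


class TestEncodeInput:
    def test_shape_padding_and_width(self):
        rec = ProteinRecord("r", "MSLRACDEFG")
        x = encode_input(rec)
        assert x.shape == (MAX_LEN, INPUT_WIDTH) == (1024, 46)
        assert np.all(x[10:] == 0.0)  # rows beyond L are zero
        np.testing.assert_array_equal(x[:10, :26].sum(axis=1), np.ones(10))

    def test_sequence_only_mode_zeroes_pssm_block(self):
        x = encode_input(ProteinRecord("r", "MSLR"), pssm=None)
        assert np.all(x[:, 26:] == 0.0)

    def test_pssm_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encode_input(ProteinRecord("r", "MSLR"),
                         PSSMatrix(np.zeros((5, 20))))

    def test_long_sequences_keep_n_terminus(self):
        seq = "A" * 1030 + "WWWWW"
        x = encode_input(ProteinRecord("r", seq))
        assert x.shape == (1024, 46)
        a = VOCAB.residue_index("A")
        assert np.all(x[:1024, a] == 1.0)  # only the N-terminal block kept


class TestCNN:
    def test_structure_has_seven_conv_and_three_dense_plus_output(self):
        spec = CNNSpec(n_outputs=6, width_scale=1 / 32, input_len=1024)
        model = BaselineCNN(spec)
        structure = model.layer_structure()
        assert structure["n_conv"] == 7
        assert structure["n_dense"] == 4  # 3 hidden dense + softmax output
        assert model.out.weight.shape[1] == 6  # Level-1 enzyme output size

    def test_full_spec_parameter_count_computed(self):
        model = BaselineCNN(CNNSpec(n_outputs=6, width_scale=1.0))
        structure = model.layer_structure()
        assert structure["conv_filters"] == [1024, 512, 512, 512, 256, 256, 256]
        assert structure["dense_units"] == [512, 256, 128]
        assert model.n_parameters() > 5_000_000

    def test_tiny_profile_separates_two_families(self):
        cfg = SyntheticCorpusConfig(n_families=2, clusters_per_family=20,
                                    members_per_cluster=3, seed=31)
        corpus = generate_corpus(cfg)
        from protlm.corpus import expand_members

        split = make_split(corpus.clusters, (0.7, 0.1, 0.2), "cluster", seed=3)
        by_id = {r.id: r for r in corpus.records}
        train, _, test = expand_members(split, corpus.clusters, "all_members")
        Xtr = np.array([encode_input(by_id[i], max_len=512) for i in train])
        ytr = np.array([by_id[i].labels for i in train])
        Xte = np.array([encode_input(by_id[i], max_len=512) for i in test])
        yte = np.array([by_id[i].labels for i in test])
        spec = CNNSpec(n_outputs=2, width_scale=1 / 16, input_len=512, seed=0)
        model, _ = train_cnn(spec, Xtr, ytr, epochs=15)
        acc = float((predict_cnn(model, Xte).argmax(1) == yte).mean())
        assert acc > 0.9
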