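"""Dataset IO, curation rules, statistics and generators."""

import logging

import numpy as np
import pytest
from scipy import stats as sps

import bepiscan as bp
from bepiscan.datasets import FastaParseError, pairwise_identity_shorter

from conftest import make_dataset


# ---------------------------------------------------------------------------
# FASTA + metadata IO
# ---------------------------------------------------------------------------


class TestReadFasta:
    def test_parses_records_and_neutralizing_flag(self, tmp_path):
        f = tmp_path / "db.fasta"
        f.write_text(">e1\nACDEFGHI\n>e2 neutralizing=true\nWLPKKYIVW\n")
        ds = bp.read_fasta(f)
        assert len(ds) == 2
        assert ds.get("e1").sequence == "ACDEFGHI"
        assert not ds.get("e1").neutralizing
        assert ds.get("e2").neutralizing

    def test_empty_file_gives_empty_dataset_with_warning(self, tmp_path, caplog):
        f = tmp_path / "empty.fasta"
        f.write_text("")
        with caplog.at_level(logging.WARNING):
            ds = bp.read_fasta(f)
        assert len(ds) == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_lowercase_sequences_are_uppercased(self, tmp_path):
        f = tmp_path / "lc.fasta"
        f.write_text(">e1\nacdefghi\n")
        assert bp.read_fasta(f).get("e1").sequence == "ACDEFGHI"

    def test_non_fasta_content_raises_with_line_number(self, tmp_path):
        f = tmp_path / "bad.fasta"
        f.write_text("ACDEFGHI\n")
        with pytest.raises(FastaParseError, match="line 1"):
            bp.read_fasta(f)

    def test_duplicate_ids_raise(self, tmp_path):
        f = tmp_path / "dup.fasta"
        f.write_text(">e1\nACDEFGHI\n>e1\nWLPKKYIVW\n")
        with pytest.raises(ValueError, match="duplicate"):
            bp.read_fasta(f)

    def test_nonstandard_residues_dropped_with_warning(self, tmp_path, caplog):
        f = tmp_path / "x.fasta"
        f.write_text(">good\nACDEFGHI\n>bad\nACDEFGHX\n")
        with caplog.at_level(logging.WARNING):
            ds = bp.read_fasta(f)
        assert ds.ids == ["good"]
        assert any("bad" in r.message for r in caplog.records)

    def test_sibling_meta_tsv_is_merged(self, tmp_path):
        (tmp_path / "db.fasta").write_text(">e1\nACDEFGHI\n>e2\nWLPKKYIVW\n")
        (tmp_path / "db.meta.tsv").write_text(
            "id\tsource\tneutralizing\ne2\tInfluenza HA\ttrue\n"
        )
        ds = bp.read_fasta(tmp_path / "db.fasta")
        assert ds.get("e2").neutralizing
        assert ds.get("e2").source == "Influenza HA"

    def test_roundtrip_through_write_fasta(self, tmp_path):
        ds = make_dataset(["ACDEFGHI", "WLPKKYIVW"], neutralizing=[1])
        bp.write_fasta(ds, tmp_path / "out.fasta")
        back = bp.read_fasta(tmp_path / "out.fasta")
        assert back.sequences == ds.sequences
        assert [r.neutralizing for r in back] == [False, True]


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------


class TestCuration:
    def test_length_filter_boundaries_inclusive(self):
        ds = make_dataset(["A" * 7, "C" * 8, "D" * 25, "E" * 26])
        out = bp.filter_by_length(ds, 8, 25)
        assert [len(r) for r in out] == [8, 25]

    def test_length_filter_identity_on_in_range_input(self):
        ds = make_dataset(["ACDEFGHI", "WLPKKYIVW"])
        assert bp.filter_by_length(ds).sequences == ds.sequences

    def test_length_filter_empty_input(self):
        assert len(bp.filter_by_length(make_dataset([]))) == 0

    def test_identical_pair_reduces_to_one(self):
        ds = make_dataset(["AAAAAAAAAA", "AAAAAAAAAA"], prefix="d")
        assert len(bp.reduce_redundancy(ds)) == 1

    def test_identity_at_threshold_is_discarded(self):
        # 9/10 identical = 90%: the >= 90% rule discards the second record
        ds = make_dataset(["AAAAAAAAAA", "AAAAAAAAAC"])
        assert len(bp.reduce_redundancy(ds, 90)) == 1

    def test_unrelated_sequences_are_both_kept(self):
        ds = make_dataset(["WLPKKYIVDENS", "MKTAYIAKQRQI"])
        assert len(bp.reduce_redundancy(ds, 90)) == 2

    def test_reduction_verified_by_brute_force(self, rng):
        from oracles import random_dataset

        ds = random_dataset(rng, 40, len_lo=8, len_hi=14)
        # salt in some near-duplicates so the filter actually fires
        recs = list(ds.records)
        for i in range(10):
            parent = recs[i].sequence
            recs.append(
                bp.EpitopeRecord(f"dup{i}", parent[:-1] + "A")
            )
        ds = bp.EpitopeDataset(recs)
        out = bp.reduce_redundancy(ds, 90)
        assert len(out) < len(ds)
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                ident = pairwise_identity_shorter(
                    out[i].sequence, out[j].sequence
                )
                assert ident < 90

    def test_curation_pipeline_is_idempotent(self, rng):
        from oracles import random_dataset

        ds = random_dataset(rng, 30)
        once = bp.reduce_redundancy(bp.filter_by_length(ds), 90)
        twice = bp.reduce_redundancy(bp.filter_by_length(once), 90)
        assert twice.sequences == once.sequences


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


class TestStats:
    def test_frequencies_of_two_homopolymers(self):
        ds = make_dataset(["AAAA", "CCCC"])
        comp = bp.aa_frequencies(ds)
        assert comp["A"] == pytest.approx(0.5)
        assert comp["C"] == pytest.approx(0.5)
        assert comp["W"] == 0

    def test_single_residue_record(self):
        assert bp.aa_frequencies(make_dataset(["W"]))["W"] == 1.0

    def test_frequencies_sum_to_one(self, rng):
        from oracles import random_dataset

        comp = bp.aa_frequencies(random_dataset(rng, 25))
        assert sum(comp.frequencies) == pytest.approx(1.0, abs=1e-9)

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            bp.aa_frequencies(make_dataset([]))

    def test_enrichment_examples(self):
        base = {aa: 0.9 / 18 for aa in "DEFGHIKLMNPQRSTVWY"}
        f = bp.CompositionTable.from_dict({**base, "A": 0.08, "C": 0.02})
        g = bp.CompositionTable.from_dict({**base, "A": 0.04, "C": 0.06})
        enr = bp.aa_enrichment(f, g)
        assert enr["A"] == pytest.approx(1.0)
        # identical tables -> all-zero enrichment
        zero = bp.aa_enrichment(f, f)
        assert all(v == pytest.approx(0.0) for v in zero.values())

    def test_enrichment_quarter_ratio(self):
        base = {aa: 0.9 / 18 for aa in "DEFGHIKLMNPQRSTVWY"}
        f = bp.CompositionTable.from_dict({**base, "A": 0.02, "C": 0.08})
        g = bp.CompositionTable.from_dict({**base, "A": 0.08, "C": 0.02})
        assert bp.aa_enrichment(f, g)["A"] == pytest.approx(-2.0)

    def test_zero_background_errors(self):
        f = bp.CompositionTable.from_dict({"A": 1.0})
        with pytest.raises(ValueError):
            bp.aa_enrichment(f, f)  # background has zeros for 19 residues

    def test_length_stats_examples(self):
        ds = make_dataset(["A" * 8, "C" * 12, "D" * 16])
        ls = bp.length_stats(ds)
        assert ls["mean"] == pytest.approx(12)
        assert ls["median"] == pytest.approx(12)
        single = bp.length_stats(make_dataset(["A" * 10]))
        assert single["std"] == 0.0


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


class TestGenerators:
    def test_random_peptides_deterministic(self):
        a = bp.random_peptides(5, seed=1)
        b = bp.random_peptides(5, seed=1)
        assert a.sequences == b.sequences

    def test_degenerate_background_gives_homopolymers(self):
        bg = bp.CompositionTable.from_dict({"A": 1.0})
        ds = bp.random_peptides(10, background=bg, seed=3)
        assert all(set(s) == {"A"} for s in ds.sequences)

    def test_composition_converges_to_background(self):
        # law of large numbers: pooled frequencies within 0.5 pp at n=50,000
        bg = bp.CompositionTable.from_dict({aa: 0.05 for aa in
                                            "ACDEFGHIKLMNPQRSTVWY"})
        ds = bp.random_peptides(50_000, background=bg, seed=7)
        comp = bp.aa_frequencies(ds)
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            assert abs(comp[aa] - 0.05) < 0.005

    def test_length_histogram_matches_distribution(self):
        # chi-square goodness of fit not rejected at alpha = 0.001
        ds = bp.random_peptides(50_000, seed=11)
        lengths = np.array([len(r) for r in ds])
        dist = bp.DEFAULT_EPITOPE_LENGTHS
        observed = np.array([(lengths == l).sum() for l in dist.lengths])
        expected = dist.probs * len(lengths)
        keep = expected >= 5  # standard chi-square validity rule
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = sps.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.001

    def test_fixture_positives_exact_copies_classify_positive(self):
        db = bp.random_peptides(30, seed=5, id_prefix="db")
        fix = bp.make_fixture_positives(db, 20, 0.0, seed=6)
        for rec in fix:
            pred = bp.classify_peptide(rec.sequence, db)
            assert pred.verdict == "epitope"

    def test_fixture_positives_deterministic_and_bounded_mismatch(self):
        db = bp.random_peptides(10, seed=5, id_prefix="db")
        a = bp.make_fixture_positives(db, 15, 0.15, seed=9)
        b = bp.make_fixture_positives(db, 15, 0.15, seed=9)
        assert a.sequences == b.sequences
        parents = {r.id: r.sequence for r in db}
        for rec in a:
            parent = parents[rec.source.split("=", 1)[1]]
            assert len(rec.sequence) == len(parent)
            n_diff = sum(1 for x, y in zip(rec.sequence, parent) if x != y)
            assert n_diff <= int(0.15 * len(parent))

    def test_default_length_distribution_matches_reference_stats(self):
        dist = bp.DEFAULT_EPITOPE_LENGTHS
        L, p = dist.lengths, dist.probs
        mean = (L * p).sum()
        std = np.sqrt(((L - mean) ** 2 * p).sum())
        cdf = np.cumsum(p)
        median = L[np.searchsorted(cdf, 0.5)]
        assert mean == pytest.approx(13.91, abs=0.01)
        assert std == pytest.approx(2.85, abs=0.01)
        assert median == 12

    def test_swissprot_background_is_normalized(self):
        bg = bp.swissprot_background()
        assert sum(bg.frequencies) == pytest.approx(1.0, abs=1e-9)
        assert bg["L"] > bg["W"]  # leucine common, tryptophan rare
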