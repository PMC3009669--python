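"""Transcriptome I/O, exact 19-mer off-target scoring, secondary design."""

import numpy as np
import pytest

from glycoscreen.errors import BoundsError, FastaParseError, IntegrityError
from glycoscreen.seqcore import (
    DsRNAConstruct,
    Transcript,
    Transcriptome,
    count_offtarget_kmers,
    design_secondary_construct,
    extract_construct,
    query_kmers,
    read_fasta,
    reverse_complement,
    write_fasta,
)

from conftest import random_sequence, random_transcriptome


def brute_force_counts(construct, txome, k=19):
    """All-positions scan, written independently of the package scorers."""
    queries = set()
    for strand in (construct.sequence, reverse_complement(construct.sequence)):
        for i in range(len(strand) - k + 1):
            if "N" not in strand[i : i + k]:
                queries.add(strand[i : i + k])
    counts = {}
    for t in txome:
        if t.gene_id == construct.target_gene:
            continue
        hits = {q for q in queries if q in t.sequence}
        if hits:
            prev = counts.setdefault(t.gene_id, set())
            prev |= hits
    return {g: len(hits) for g, hits in counts.items()}


# ---------------------------------------------------------------------------
# FASTA I/O


class TestFastaIO:
    def test_single_record_read_back(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">g1|t1\nACGT\n")
        txome = read_fasta(path)
        assert txome.genes == ["g1"]
        assert len(txome.get("t1")) == 4

    def test_empty_file_gives_empty_transcriptome(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        txome = read_fasta(path)
        assert len(txome) == 0 and txome.genes == []

    def test_bare_header_maps_gene_to_transcript(self, tmp_path):
        path = tmp_path / "bare.fasta"
        path.write_text(">cg123\nacgtacgt\n")
        txome = read_fasta(path)
        assert txome.get("cg123").gene_id == "cg123"
        assert txome.get("cg123").sequence == "ACGTACGT"  # uppercased

    @pytest.mark.parametrize("content", [">g1|\nACGT\n", ">|t1\nACGT\n", ">a|b|c\nACGT\n"])
    def test_malformed_header_rejected(self, tmp_path, content):
        path = tmp_path / "bad.fasta"
        path.write_text(content)
        with pytest.raises(FastaParseError):
            read_fasta(path)

    def test_invalid_characters_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">g1|t1\nACGU\n")
        with pytest.raises(FastaParseError):
            read_fasta(path)

    def test_duplicate_transcript_id_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">g1|t1\nACGT\n>g2|t1\nTTTT\n")
        with pytest.raises(IntegrityError):
            read_fasta(path)

    def test_round_trip_is_byte_identical_on_random_records(self, tmp_path):
        rng = np.random.default_rng(7)
        txome = Transcriptome(
            Transcript(f"t{i}", f"g{i % 10}", random_sequence(rng, int(rng.integers(20, 300))))
            for i in range(50)
        )
        path = tmp_path / "rt.fasta"
        write_fasta(txome, path)
        back = read_fasta(path)
        assert len(back) == len(txome)
        for t in txome:
            assert back.get(t.transcript_id).sequence == t.sequence
            assert back.get(t.transcript_id).gene_id == t.gene_id


# ---------------------------------------------------------------------------
# Construct extraction


class TestExtractConstruct:
    def test_whole_transcript(self):
        txome = Transcriptome([Transcript("t1", "g1", "ACGTACGT")])
        c = extract_construct(txome, "t1", (0, 8))
        assert c.sequence == "ACGTACGT" and c.target_gene == "g1"

    def test_empty_interval_rejected(self):
        txome = Transcriptome([Transcript("t1", "g1", "ACGTACGT")])
        with pytest.raises(BoundsError):
            extract_construct(txome, "t1", (3, 3))

    def test_out_of_bounds_rejected(self):
        txome = Transcriptome([Transcript("t1", "g1", "ACGTACGT")])
        with pytest.raises(BoundsError):
            extract_construct(txome, "t1", (4, 20))

    def test_extracted_sequence_relocates_by_exact_search(self):
        rng = np.random.default_rng(11)
        txome = random_transcriptome(rng, 3, (300, 500))
        for _ in range(20):
            t = txome.get("g0.t")
            start = int(rng.integers(0, len(t) - 60))
            c = extract_construct(txome, "g0.t", (start, start + 60))
            assert t.sequence.find(c.sequence) != -1
            # at least the construct's own interval matches
            assert t.sequence[c.start : c.end] == c.sequence


# ---------------------------------------------------------------------------
# Off-target scoring


class TestOffTargetScoring:
    def test_disjoint_sequences_score_zero(self):
        txome = Transcriptome(
            [Transcript("t1", "g1", "A" * 100), Transcript("t2", "g2", "C" * 100)]
        )
        c = extract_construct(txome, "t1", (0, 50))
        report = count_offtarget_kmers(c, txome)
        assert report.per_gene_counts == {} and report.otps == 0

    def test_25nt_shared_block_yields_seven_19mers(self):
        rng = np.random.default_rng(3)
        block = random_sequence(rng, 25)
        # forced distinct flanks pin the shared identity run to exactly 25 nt
        s1 = random_sequence(rng, 99) + "A" + block + "A" + random_sequence(rng, 99)
        s2 = random_sequence(rng, 79) + "C" + block + "C" + random_sequence(rng, 119)
        txome = Transcriptome([Transcript("t1", "g1", s1), Transcript("t2", "g2", s2)])
        c = extract_construct(txome, "t1", (50, 175))
        report = count_offtarget_kmers(c, txome)
        assert report.per_gene_counts == {"g2": 7}
        assert report.otps == 7
        assert brute_force_counts(c, txome) == {"g2": 7}

    def test_otps_below_three_flags_rescreen_path(self):
        rng = np.random.default_rng(4)
        block = random_sequence(rng, 20)  # 20 - 19 + 1 = 2 shared 19-mers
        s1 = random_sequence(rng, 89) + "A" + block + "A" + random_sequence(rng, 89)
        s2 = random_sequence(rng, 89) + "C" + block + "C" + random_sequence(rng, 89)
        txome = Transcriptome([Transcript("t1", "g1", s1), Transcript("t2", "g2", s2)])
        c = extract_construct(txome, "t1", (60, 140))
        report = count_offtarget_kmers(c, txome)
        assert report.otps == 2
        assert report.otps < 3  # eligible for the off-target rescreen path

    def test_construct_shorter_than_k_rejected(self):
        txome = Transcriptome([Transcript("t1", "g1", "ACGTACGTACGT")])
        c = extract_construct(txome, "t1", (0, 10))
        with pytest.raises(BoundsError):
            count_offtarget_kmers(c, txome, k=19)

    def test_kmers_containing_n_never_match(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        txome = Transcriptome(
            [Transcript("t1", "g1", seq), Transcript("t2", "g2", seq)]
        )
        c = DsRNAConstruct("c", "g1", "t1", 0, 24, seq[:10] + "N" + seq[11:])
        assert "N" not in "".join(query_kmers(seq, 19))
        report = count_offtarget_kmers(c, txome, k=19)
        # only N-free query k-mers may match
        assert all("N" not in q for q in query_kmers(c.sequence, 19))
        assert report.per_gene_counts.get("g2", 0) == len(
            {q for q in query_kmers(c.sequence, 19) if q in seq}
        )

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for case in range(30):
            txome = random_transcriptome(
                rng, int(rng.integers(5, 21)), (200, 1000),
                shared_block=int(rng.integers(0, 40)) if case % 2 else 0,
            )
            t = txome.get("g0.t")
            length = int(rng.integers(50, min(400, len(t))))
            start = int(rng.integers(0, len(t) - length + 1))
            c = extract_construct(txome, "g0.t", (start, start + length))
            report = count_offtarget_kmers(c, txome)
            assert report.per_gene_counts == brute_force_counts(c, txome)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        txome = random_transcriptome(rng, 8, (300, 600), shared_block=30)
        c = extract_construct(txome, "g0.t", (0, 200))
        baseline = count_offtarget_kmers(c, txome)
        transcripts = list(txome)
        rng.shuffle(transcripts)
        shuffled = Transcriptome(transcripts)
        assert count_offtarget_kmers(c, shuffled).per_gene_counts == baseline.per_gene_counts

    def test_strand_symmetry(self):
        rng = np.random.default_rng(8)
        txome = random_transcriptome(rng, 6, (300, 600), shared_block=28)
        c = extract_construct(txome, "g0.t", (10, 250))
        flipped = DsRNAConstruct(
            c.construct_id, c.target_gene, c.source_transcript_id, c.start, c.end,
            reverse_complement(c.sequence),
        )
        assert (
            count_offtarget_kmers(flipped, txome).per_gene_counts
            == count_offtarget_kmers(c, txome).per_gene_counts
        )

    def test_appending_sequence_never_decreases_counts(self):
        rng = np.random.default_rng(9)
        txome = random_transcriptome(rng, 6, (400, 700), shared_block=35)
        t = txome.get("g0.t")
        short = extract_construct(txome, "g0.t", (0, 150))
        longer = extract_construct(txome, "g0.t", (0, 350))
        counts_short = count_offtarget_kmers(short, txome).per_gene_counts
        counts_long = count_offtarget_kmers(longer, txome).per_gene_counts
        for gene, n in counts_short.items():
            assert counts_long.get(gene, 0) >= n


# ---------------------------------------------------------------------------
# Secondary design


class TestSecondaryDesign:
    def _txome_with_primary(self, rng, cdna_len, primary_iv, n_other=3):
        seqs = {"g0": random_sequence(rng, cdna_len)}
        for i in range(1, n_other + 1):
            seqs[f"g{i}"] = random_sequence(rng, int(rng.integers(300, 800)))
        txome = Transcriptome(Transcript(f"{g}.t", g, s) for g, s in seqs.items())
        primary = extract_construct(txome, "g0.t", primary_iv)
        return txome, txome.get("g0.t"), primary

    def test_window_avoids_primary_interval(self):
        rng = np.random.default_rng(12)
        txome, cdna, primary = self._txome_with_primary(rng, 1000, (0, 500))
        sec = design_secondary_construct(cdna, primary, txome, min_len=300)
        assert sec is not None
        assert sec.start >= 500 and sec.end <= 1000
        assert not sec.overlaps(primary)

    def test_too_short_cdna_is_infeasible(self):
        rng = np.random.default_rng(13)
        txome, cdna, primary = self._txome_with_primary(rng, 400, (50, 350))
        assert design_secondary_construct(cdna, primary, txome, min_len=300) is None

    def test_primary_not_on_cdna_rejected(self):
        rng = np.random.default_rng(14)
        txome, cdna, _ = self._txome_with_primary(rng, 800, (0, 300))
        alien = DsRNAConstruct("x", "g1", "g1.t", 0, 300, txome.get("g1.t").sequence[:300])
        with pytest.raises(IntegrityError):
            design_secondary_construct(cdna, alien, txome, min_len=200)

    def test_chosen_window_minimizes_otps_exhaustively(self):
        rng = np.random.default_rng(15)
        for _ in range(5):
            cdna_len = int(rng.integers(900, 2000))
            p0 = int(rng.integers(0, cdna_len - 500))
            txome, cdna, primary = self._txome_with_primary(rng, cdna_len, (p0, p0 + 400))
            # implant an off-target block into part of the free region so
            # window choice matters
            other = txome.get("g1.t")
            block = other.sequence[100:140]
            free_start = primary.end if cdna_len - primary.end >= 400 else 0
            seq = cdna.sequence
            insert_at = min(free_start + 20, cdna_len - 40)
            mutated = seq[:insert_at] + block + seq[insert_at + 40 :]
            txome2 = Transcriptome(
                [Transcript("g0.t", "g0", mutated)]
                + [t for t in txome if t.gene_id != "g0"]
            )
            cdna2 = txome2.get("g0.t")
            primary2 = extract_construct(txome2, "g0.t", (primary.start, primary.end))
            min_len = 300
            sec = design_secondary_construct(cdna2, primary2, txome2, min_len=min_len)
            if sec is None:
                continue
            assert not sec.overlaps(primary2)
            best = min(
                count_offtarget_kmers(
                    extract_construct(txome2, "g0.t", (s, s + min_len)), txome2
                ).otps
                for lo, hi in [(0, primary2.start), (primary2.end, len(cdna2))]
                for s in range(lo, hi - min_len + 1)
            )
            assert count_offtarget_kmers(sec, txome2).otps == best
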