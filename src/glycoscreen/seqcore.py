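"""Transcriptome model, FASTA I/O, exact 19-mer off-target scoring, dsRNA design.

An in-vivo dsRNA construct is diced into short siRNAs, and a perfect 19-mer
identity between any of those siRNAs and an unintended transcript is the
canonical predictor of off-target silencing.  The off-target probability
score (OTPS) of a construct is therefore the maximum, over all genes other
than its target, of the number of distinct 19-mers (from either strand of
the construct) found verbatim in that gene's transcripts.

Coordinates are 0-based half-open throughout.  FASTA headers use the
``gene_id|transcript_id`` dialect; a bare header is read as a gene with a
single identically-named transcript.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import BoundsError, FastaParseError, IntegrityError

DEFAULT_K = 19

_VALID_CHARS = frozenset("ACGTN")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return sequence.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class Transcript:
    """A single transcript: id, owning gene, and its nucleotide sequence."""

    transcript_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise IntegrityError(f"transcript {self.transcript_id!r}: empty sequence")
        invalid = set(seq) - _VALID_CHARS
        if invalid:
            raise FastaParseError(
                f"transcript {self.transcript_id!r}: invalid characters "
                f"{sorted(invalid)} (alphabet is A,C,G,T,N)"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


class Transcriptome:
    """A collection of transcripts indexed by transcript and by gene.

    Also owns a lazily-built exact k-mer index (k-mer -> set of gene ids)
    used by the off-target scorer; the index is invalidated whenever a
    transcript is added.
    """

    def __init__(self, transcripts: Iterable[Transcript] = ()) -> None:
        self._transcripts: dict[str, Transcript] = {}
        self.gene_index: dict[str, set[str]] = {}
        self._kmer_cache: dict[int, dict[str, set[str]]] = {}
        for t in transcripts:
            self.add(t)

    def add(self, transcript: Transcript) -> None:
        if transcript.transcript_id in self._transcripts:
            raise IntegrityError(
                f"duplicate transcript_id {transcript.transcript_id!r}"
            )
        self._transcripts[transcript.transcript_id] = transcript
        self.gene_index.setdefault(transcript.gene_id, set()).add(
            transcript.transcript_id
        )
        self._kmer_cache.clear()

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def get(self, transcript_id: str) -> Transcript:
        try:
            return self._transcripts[transcript_id]
        except KeyError:
            raise IntegrityError(f"unknown transcript_id {transcript_id!r}") from None

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_index)

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [self._transcripts[tid] for tid in sorted(self.gene_index.get(gene_id, ()))]

    def kmer_gene_index(self, k: int) -> dict[str, set[str]]:
        """Exact substring index: every k-mer of the sense strand -> gene ids.

        k-mers containing N are excluded (N never matches).
        """
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        idx = self._kmer_cache.get(k)
        if idx is None:
            idx = {}
            for t in self:
                seq = t.sequence
                gid = t.gene_id
                for i in range(len(seq) - k + 1):
                    kmer = seq[i : i + k]
                    if "N" in kmer:
                        continue
                    idx.setdefault(kmer, set()).add(gid)
            self._kmer_cache[k] = idx
        return idx


@dataclass(frozen=True)
class DsRNAConstruct:
    """A dsRNA targeting interval on a transcript; the unit of knockdown."""

    construct_id: str
    target_gene: str
    source_transcript_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise BoundsError(
                f"construct {self.construct_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        seq = self.sequence.upper()
        if len(seq) != self.end - self.start:
            raise IntegrityError(
                f"construct {self.construct_id!r}: sequence length {len(seq)} "
                f"does not match interval [{self.start}, {self.end})"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "DsRNAConstruct") -> bool:
        return (
            self.source_transcript_id == other.source_transcript_id
            and max(self.start, other.start) < min(self.end, other.end)
        )


@dataclass(frozen=True)
class OffTargetReport:
    """Per-gene distinct matched k-mer counts and the resulting OTPS."""

    construct_id: str
    per_gene_counts: dict[str, int] = field(default_factory=dict)

    @property
    def otps(self) -> int:
        return max(self.per_gene_counts.values(), default=0)

    def suspected_genes(self) -> list[str]:
        """Genes with at least one matched k-mer, most-shared first."""
        return sorted(self.per_gene_counts, key=lambda g: (-self.per_gene_counts[g], g))


# ---------------------------------------------------------------------------
# FASTA I/O


def _parse_header(header: str) -> tuple[str, str]:
    if "|" in header:
        gene_id, _, transcript_id = header.partition("|")
        if not gene_id or not transcript_id or "|" in transcript_id:
            raise FastaParseError(f"malformed FASTA header {header!r}")
        return gene_id, transcript_id
    return header, header


def read_fasta(path: str | Path) -> Transcriptome:
    """Read a transcriptome from FASTA (``gene|transcript`` header dialect)."""
    path = Path(path)
    txome = Transcriptome()
    for record in SeqIO.parse(str(path), "fasta"):
        if not record.id:
            raise FastaParseError(f"{path}: record with empty header")
        gene_id, transcript_id = _parse_header(record.id)
        txome.add(Transcript(transcript_id, gene_id, str(record.seq)))
    return txome


def write_fasta(txome: Transcriptome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=f"{t.gene_id}|{t.transcript_id}", description="")
        for t in txome
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Construct extraction and off-target scoring


def extract_construct(
    txome: Transcriptome,
    transcript_id: str,
    interval: tuple[int, int],
    construct_id: Optional[str] = None,
) -> DsRNAConstruct:
    """Cut a construct out of a transcript at a 0-based half-open interval."""
    start, end = interval
    transcript = txome.get(transcript_id)
    if start == end:
        raise BoundsError(f"empty interval [{start}, {end}) on {transcript_id!r}")
    if not (0 <= start < end <= len(transcript)):
        raise BoundsError(
            f"interval [{start}, {end}) outside transcript {transcript_id!r} "
            f"of length {len(transcript)}"
        )
    return DsRNAConstruct(
        construct_id=construct_id or f"{transcript.gene_id}:{start}-{end}",
        target_gene=transcript.gene_id,
        source_transcript_id=transcript_id,
        start=start,
        end=end,
        sequence=transcript.sequence[start:end],
    )


def query_kmers(sequence: str, k: int) -> set[str]:
    """Distinct k-mers of a construct pooled across both strands, N-free.

    A dsRNA is processed from both strands, so the query set is the union of
    the sense k-mers and the k-mers of the reverse complement; repeated
    k-mers collapse (they yield the same siRNA pool).
    """
    kmers: set[str] = set()
    for strand in (sequence, reverse_complement(sequence)):
        for i in range(len(strand) - k + 1):
            kmer = strand[i : i + k]
            if "N" not in kmer:
                kmers.add(kmer)
    return kmers


def count_offtarget_kmers(
    construct: DsRNAConstruct, txome: Transcriptome, k: int = DEFAULT_K
) -> OffTargetReport:
    """Count distinct query k-mers matching each non-target gene; OTPS = max.

    Matching is exact, against the sense strand of transcripts only (the
    query set already contains the construct's reverse complement).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(construct) < k:
        raise BoundsError(
            f"construct {construct.construct_id!r} of length {len(construct)} "
            f"is shorter than k={k}"
        )
    index = txome.kmer_gene_index(k)
    counts: Counter[str] = Counter()
    for kmer in query_kmers(construct.sequence, k):
        for gene_id in index.get(kmer, ()):
            counts[gene_id] += 1
    counts.pop(construct.target_gene, None)
    return OffTargetReport(construct.construct_id, dict(counts))


def count_offtarget_kmers_naive(
    construct: DsRNAConstruct, txome: Transcriptome, k: int = DEFAULT_K
) -> OffTargetReport:
    """Index-free all-positions scan; used to verify generated ground truth."""
    if len(construct) < k:
        raise BoundsError(
            f"construct {construct.construct_id!r} shorter than k={k}"
        )
    queries = query_kmers(construct.sequence, k)
    counts: dict[str, int] = {}
    for gene_id in sorted(txome.gene_index):
        if gene_id == construct.target_gene:
            continue
        matched: set[str] = set()
        for t in txome.transcripts_of(gene_id):
            seq = t.sequence
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer in queries:
                    matched.add(kmer)
        if matched:
            counts[gene_id] = len(matched)
    return OffTargetReport(construct.construct_id, counts)


# ---------------------------------------------------------------------------
# Secondary dsRNA design


def design_secondary_construct(
    cdna: Transcript,
    primary: DsRNAConstruct,
    txome: Transcriptome,
    min_len: int = 300,
    k: int = DEFAULT_K,
    construct_id: Optional[str] = None,
) -> Optional[DsRNAConstruct]:
    """Pick a non-overlapping secondary targeting window with minimal OTPS.

    Candidate windows of length exactly ``min_len`` are scanned at stride 1
    within the parts of the cDNA outside the primary interval; ties on OTPS
    break to the leftmost start.  Returns None when no contiguous region
    outside the primary interval is at least ``min_len`` long (too-short
    cDNA: secondary design infeasible).
    """
    if min_len < k:
        raise ValueError(f"min_len ({min_len}) must be >= k ({k})")
    if (
        primary.source_transcript_id != cdna.transcript_id
        or primary.end > len(cdna)
        or cdna.sequence[primary.start : primary.end] != primary.sequence
    ):
        raise IntegrityError(
            f"primary construct {primary.construct_id!r} does not lie on "
            f"transcript {cdna.transcript_id!r}"
        )
    regions = [(0, primary.start), (primary.end, len(cdna))]
    best: Optional[DsRNAConstruct] = None
    best_otps = -1
    for lo, hi in regions:
        for start in range(lo, hi - min_len + 1):
            candidate = DsRNAConstruct(
                construct_id=construct_id or f"{primary.construct_id}_sec",
                target_gene=cdna.gene_id,
                source_transcript_id=cdna.transcript_id,
                start=start,
                end=start + min_len,
                sequence=cdna.sequence[start : start + min_len],
            )
            otps = count_offtarget_kmers(candidate, txome, k).otps
            if best is None or otps < best_otps:
                best, best_otps = candidate, otps
    return best


# ---------------------------------------------------------------------------
# TSV interfaces

CONSTRUCT_COLUMNS = ["construct_id", "target_gene", "transcript_id", "start", "end"]


def read_construct_table(path: str | Path, txome: Transcriptome) -> list[DsRNAConstruct]:
    """Read a construct table (TSV) and materialize sequences from ``txome``."""
    df = pd.read_csv(path, sep="\t", dtype={"construct_id": str, "target_gene": str})
    missing = set(CONSTRUCT_COLUMNS) - set(df.columns)
    if missing:
        raise FastaParseError(f"{path}: construct table missing columns {sorted(missing)}")
    constructs = []
    for row in df.itertuples(index=False):
        c = extract_construct(
            txome,
            str(row.transcript_id),
            (int(row.start), int(row.end)),
            construct_id=str(row.construct_id),
        )
        if c.target_gene != str(row.target_gene):
            raise IntegrityError(
                f"construct {row.construct_id!r}: declared target_gene "
                f"{row.target_gene!r} but transcript belongs to {c.target_gene!r}"
            )
        constructs.append(c)
    return constructs


def write_construct_table(constructs: Iterable[DsRNAConstruct], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "construct_id": c.construct_id,
                "target_gene": c.target_gene,
                "transcript_id": c.source_transcript_id,
                "start": c.start,
                "end": c.end,
            }
            for c in constructs
        ],
        columns=CONSTRUCT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_offtarget_report(report: OffTargetReport, path: str | Path) -> None:
    """Serialize per-gene counts plus an OTPS summary row."""
    rows = [
        {"construct_id": report.construct_id, "gene_id": g, "count": n}
        for g, n in sorted(report.per_gene_counts.items())
    ]
    rows.append({"construct_id": report.construct_id, "gene_id": "OTPS", "count": report.otps})
    pd.DataFrame(rows, columns=["construct_id", "gene_id", "count"]).to_csv(
        path, sep="\t", index=False
    )
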