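"""Non-redundant transcript database construction.

Public cDNA collections contain many nearly identical records per gene, which
confounds unique assignment of short sequence tags.  The collapse rule used
here removes, for every pair of transcripts aligning at greater than 94%
identity over more than 70% of the shorter sequence, the smaller of the two —
leaving one representative per redundancy cluster.

Similarity evidence can come from an external all-vs-all BLAST run (tabular
``-outfmt 6``) via :func:`parse_hits`, or, for small sets, from
:func:`all_vs_all_identity`, which computes best local alignments directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Transcript",
    "TranscriptSet",
    "SimilarityHit",
    "CollapseDecision",
    "ParseError",
    "parse_hits",
    "all_vs_all_identity",
    "collapse",
]

_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Raised for malformed similarity-hit input, with line location."""


@dataclass(frozen=True)
class Transcript:
    """A nucleotide sequence record (A/C/G/T/N)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has empty sequence")
        bad = set(self.sequence.upper()) - _ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id!r} contains non-nucleotide symbols {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


class TranscriptSet:
    """An ordered collection of transcripts with unique ids."""

    def __init__(self, transcripts: Iterable[Transcript] = ()):
        self._records: dict[str, Transcript] = {}
        for t in transcripts:
            if t.id in self._records:
                raise ValueError(f"duplicate transcript id {t.id!r}")
            self._records[t.id] = t

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._records.values())

    def __contains__(self, tid: str) -> bool:
        return tid in self._records

    def __getitem__(self, tid: str) -> Transcript:
        return self._records[tid]

    def ids(self) -> list[str]:
        return list(self._records)

    def subset(self, ids: Iterable[str]) -> "TranscriptSet":
        keep = set(ids)
        return TranscriptSet(t for t in self if t.id in keep)

    @classmethod
    def from_fasta(cls, path: str | Path | TextIO) -> "TranscriptSet":
        records = SeqIO.parse(path, "fasta")
        return cls(Transcript(r.id, str(r.seq).upper()) for r in records)

    def to_fasta(self, path: str | Path | TextIO) -> None:
        records = [
            SeqRecord(Seq(t.sequence), id=t.id, description="") for t in self
        ]
        SeqIO.write(records, path, "fasta")


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise alignment record (BLAST outfmt-6 compatible)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int | None = None
    gap_opens: int | None = None
    qstart: int | None = None
    qend: int | None = None
    sstart: int | None = None
    send: int | None = None
    evalue: float | None = None
    bitscore: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise ValueError("alignment length must be >= 1")


@dataclass(frozen=True)
class CollapseDecision:
    """One removal performed by :func:`collapse`."""

    removed_id: str
    kept_id: str
    identity: float
    coverage_fraction: float


def parse_hits(source: str | Path | TextIO | Iterable[str]) -> list[SimilarityHit]:
    """Parse tab-separated similarity hits (BLAST ``-outfmt 6`` dialect).

    Requires at least the first four columns (query, subject, percent
    identity, alignment length); the remaining eight standard columns are
    kept when present.  Self-hits (query == subject) are dropped.  Malformed
    lines raise :class:`ParseError` naming the line number.
    """
    close = False
    if isinstance(source, (str, Path)):
        source = open(source)
        close = True
    try:
        hits: list[SimilarityHit] = []
        for lineno, line in enumerate(source, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"line {lineno}: expected >= 4 tab-separated columns, got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            try:
                ident = float(fields[2])
                alen = int(fields[3])
                opt: dict[str, float | int | None] = {}
                names = (
                    "mismatches", "gap_opens", "qstart", "qend",
                    "sstart", "send", "evalue", "bitscore",
                )
                casts = (int, int, int, int, int, int, float, float)
                for name, cast, value in zip(names, casts, fields[4:12]):
                    opt[name] = cast(value)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if q == s:
                continue
            hits.append(SimilarityHit(q, s, ident, alen, **opt))
        return hits
    finally:
        if close:
            source.close()


def all_vs_all_identity(
    transcripts: TranscriptSet,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    min_score: float = 10.0,
) -> list[SimilarityHit]:
    """Best local-alignment identity for every unordered transcript pair.

    A desk-scale stand-in for an all-vs-all BLAST search: Smith-Waterman
    local alignment (via Biopython's ``PairwiseAligner``) with the stated
    scoring, reporting ``identity = matches / alignment columns * 100`` and
    the alignment length in columns.  Pairs whose best local score falls
    below ``min_score`` are not reported, mimicking BLAST's failure to seed
    an extended alignment between unrelated sequences.  Quadratic in both
    sequence number and length; intended for at most a few hundred records.
    """
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap

    items = list(transcripts)
    hits: list[SimilarityHit] = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i], items[j]
            alns = aligner.align(a.sequence, b.sequence)
            if alns.score < min_score:
                continue
            aln = alns[0]
            counts = aln.counts()
            columns = counts.gaps + counts.identities + counts.mismatches
            if columns == 0:
                continue
            identity = 100.0 * counts.identities / columns
            hits.append(SimilarityHit(a.id, b.id, identity, columns))
    return hits


def _merge_undirected(hits: Sequence[SimilarityHit]) -> list[SimilarityHit]:
    """Keep one record per unordered pair: the max-identity (then max-length) one."""
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (min(h.query_id, h.subject_id), max(h.query_id, h.subject_id))
        prev = best.get(key)
        if prev is None or (h.percent_identity, h.alignment_length) > (
            prev.percent_identity, prev.alignment_length
        ):
            best[key] = h
    return list(best.values())


def collapse(
    transcripts: TranscriptSet,
    hits: Sequence[SimilarityHit],
    *,
    identity_min: float = 94.0,
    coverage_min: float = 0.70,
    coverage_ref: str = "shorter",
) -> tuple[TranscriptSet, list[CollapseDecision]]:
    """Remove the smaller member of every sufficiently similar pair.

    A pair triggers removal when its identity is strictly greater than
    ``identity_min`` percent AND its alignment length is strictly greater
    than ``coverage_min`` times the reference length.  ``coverage_ref``
    selects which transcript's length anchors the coverage test:
    ``"shorter"`` (default — the reading consistent with removing the
    smaller record), ``"longer"``, or ``"subject"``.

    Pairs are processed greedily in a deterministic order (descending
    identity, then descending alignment length, then id order); a pair is
    skipped if either member was already removed, so a removed transcript
    never causes further removals.  The kept set is a fixpoint: re-running
    with the same hits removes nothing.  Length ties remove the
    lexicographically larger id.
    """
    if coverage_ref not in ("shorter", "longer", "subject"):
        raise ValueError(f"unknown coverage_ref {coverage_ref!r}")

    for h in hits:
        for tid in (h.query_id, h.subject_id):
            if tid not in transcripts:
                raise KeyError(f"hit references unknown transcript id {tid!r}")

    candidates = []
    for h in _merge_undirected(hits):
        lq = transcripts[h.query_id].length
        ls = transcripts[h.subject_id].length
        ref_len = {
            "shorter": min(lq, ls),
            "longer": max(lq, ls),
            "subject": ls,
        }[coverage_ref]
        if h.percent_identity > identity_min and h.alignment_length > coverage_min * ref_len:
            candidates.append(h)

    candidates.sort(
        key=lambda h: (
            -h.percent_identity,
            -h.alignment_length,
            min(h.query_id, h.subject_id),
            max(h.query_id, h.subject_id),
        )
    )

    removed: set[str] = set()
    decisions: list[CollapseDecision] = []
    for h in candidates:
        if h.query_id in removed or h.subject_id in removed:
            continue
        tq, ts = transcripts[h.query_id], transcripts[h.subject_id]
        if tq.length != ts.length:
            loser = tq if tq.length < ts.length else ts
        else:
            loser = tq if tq.id > ts.id else ts
        winner = ts if loser is tq else tq
        removed.add(loser.id)
        decisions.append(
            CollapseDecision(
                removed_id=loser.id,
                kept_id=winner.id,
                identity=h.percent_identity,
                coverage_fraction=h.alignment_length / min(tq.length, ts.length),
            )
        )

    kept = TranscriptSet(t for t in transcripts if t.id not in removed)
    return kept, decisions


def write_decisions(decisions: Sequence[CollapseDecision], path: str | Path | TextIO) -> None:
    """Write collapse decisions as TSV (removed_id, kept_id, identity, coverage)."""
    close = False
    if isinstance(path, (str, Path)):
        path = open(path, "w")
        close = True
    try:
        path.write("removed_id\tkept_id\tidentity\tcoverage_fraction\n")
        for d in decisions:
            path.write(
                f"{d.removed_id}\t{d.kept_id}\t{d.identity:.4f}\t{d.coverage_fraction:.4f}\n"
            )
    finally:
        if close:
            path.close()
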