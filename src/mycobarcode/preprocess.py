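"""Locus-specific preprocessing.

ITS sequences are trimmed to conserved flanking motifs of the SSU/LSU
termini and the ~120 bp 5.8S gene between ITS1 and ITS2 is excised
(coordinates supplied per record, annotation-driven).  COI sequences may
carry large (~100-3000 bp) group-I introns at unpredictable exon
positions; these are located by exact-anchor chaining against an
intron-free reference exon and excised before alignment.  Degenerate
primers are expanded/matched under IUPAC semantics and amplicon lengths
predicted from primer hits.

All coordinates are 1-based, fully closed.
"""

from __future__ import annotations

import csv
from bisect import bisect_left
from dataclasses import dataclass, replace
from pathlib import Path

from .io import SequenceRecord, packaged_data_path

IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class PreprocessError(ValueError):
    pass


class StartMotifAbsentError(PreprocessError):
    pass


class EndMotifAbsentError(PreprocessError):
    pass


class MotifOrderError(PreprocessError):
    pass


@dataclass(frozen=True)
class ItsTrimConfig:
    """Conserved motifs delimiting the ITS region (SSU 3' end, LSU 5' end)."""

    start_motif: str = "CATTA"
    end_motif: str = "GACCT"

    def __post_init__(self) -> None:
        for motif in (self.start_motif, self.end_motif):
            if not motif or any(ch not in "ACGT" for ch in motif):
                raise PreprocessError(f"motif must be non-empty, non-degenerate DNA: {motif!r}")


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    direction: str  # "forward" | "reverse"
    start_position: int | None = None  # 1-based on the reference exon, if known

    def __post_init__(self) -> None:
        if len(self.sequence) < 10:
            raise PreprocessError(f"primer {self.name!r}: sequence shorter than 10 bases")
        if self.direction not in ("forward", "reverse"):
            raise PreprocessError(f"primer {self.name!r}: direction must be forward/reverse")
        for ch in self.sequence:
            if ch not in IUPAC_CLASSES:
                raise PreprocessError(f"primer {self.name!r}: invalid symbol {ch!r}")


@dataclass(frozen=True)
class IntronCall:
    """One inserted block in a query relative to the reference exon.

    ``position`` is the 1-based reference coordinate of the exon base
    immediately 5' of the insertion (0 = insertion before the first
    anchored reference base); ``query_start`` is the 1-based query
    coordinate of the first inserted base.
    """

    query_id: str
    position: int
    length: int
    query_start: int


def trim_its(record: SequenceRecord, config: ItsTrimConfig = ItsTrimConfig()) -> SequenceRecord:
    """Trim an ITS read to begin/end with its conserved flanking motifs.

    Keeps the substring from the first occurrence of the start motif
    through the last occurrence of the end motif, motifs included.
    """
    seq = record.residues
    start = seq.find(config.start_motif)
    if start < 0:
        raise StartMotifAbsentError(
            f"{record.id}: start motif {config.start_motif!r} not found"
        )
    end = seq.rfind(config.end_motif)
    if end < 0:
        raise EndMotifAbsentError(
            f"{record.id}: end motif {config.end_motif!r} not found"
        )
    if end < start:
        raise MotifOrderError(
            f"{record.id}: last {config.end_motif!r} precedes first {config.start_motif!r}"
        )
    return replace(record, residues=seq[start:end + len(config.end_motif)])


def excise_58s(record: SequenceRecord, its1_end: int, its2_start: int) -> SequenceRecord:
    """Concatenate ITS1 and ITS2, dropping the conserved 5.8S between them.

    ``its1_end`` is the last base of ITS1 and ``its2_start`` the first
    base of ITS2 (1-based, closed).
    """
    L = len(record.residues)
    if not (1 <= its1_end < its2_start <= L):
        raise PreprocessError(
            f"{record.id}: invalid 5.8S coordinates its1_end={its1_end}, "
            f"its2_start={its2_start} on length {L}"
        )
    return replace(
        record,
        residues=record.residues[:its1_end] + record.residues[its2_start - 1:],
    )


# ---------------------------------------------------------------------------
# intron localization


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    first: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if kmer in first:
            dup.add(kmer)
        else:
            first[kmer] = i
    return {kmer: pos for kmer, pos in first.items() if kmer not in dup}


def detect_introns(query: SequenceRecord, reference_exon: SequenceRecord,
                   min_intron_len: int = 50, anchor_len: int = 12) -> list[IntronCall]:
    """Locate large insertions in a query relative to an intron-free exon.

    Exact ``anchor_len``-mers unique in both sequences are chained by a
    longest-increasing-subsequence on (reference, query) positions; any
    inter-anchor query surplus of at least ``min_intron_len`` bases is
    reported as an intron at the reference coordinate of the last
    anchored base before the gap.
    """
    ref, qry = reference_exon.residues, query.residues
    ref_kmers = _unique_kmer_positions(ref, anchor_len)
    qry_kmers = _unique_kmer_positions(qry, anchor_len)
    matches = sorted(
        (ref_kmers[kmer], qpos) for kmer, qpos in qry_kmers.items() if kmer in ref_kmers
    )
    if not matches:
        raise PreprocessError(f"{query.id}: unalignable against {reference_exon.id}")
    # longest strictly-increasing chain in query position (ref already sorted,
    # unique); patience sorting with parent pointers
    tails: list[int] = []           # q-values of chain tails
    tail_idx: list[int] = []        # match index of each tail
    parent = [-1] * len(matches)
    for idx, (_, q) in enumerate(matches):
        pos = bisect_left(tails, q)
        if pos == len(tails):
            tails.append(q)
            tail_idx.append(idx)
        else:
            tails[pos] = q
            tail_idx[pos] = idx
        parent[idx] = tail_idx[pos - 1] if pos > 0 else -1
    chain: list[tuple[int, int]] = []
    idx = tail_idx[-1]
    while idx != -1:
        chain.append(matches[idx])
        idx = parent[idx]
    chain.reverse()

    # Genuine exon anchors share the query-minus-reference offset of their
    # segment; a chain element whose offset matches neither neighbor is
    # almost always a chance k-mer hit inside an inserted block and would
    # corrupt the gap arithmetic, so drop it.
    if len(chain) > 2:
        diag = [q - r for r, q in chain]
        kept = [
            a for i, a in enumerate(chain)
            if (i > 0 and diag[i] == diag[i - 1])
            or (i < len(chain) - 1 and diag[i] == diag[i + 1])
        ]
        if kept:
            chain = kept

    calls: list[IntronCall] = []

    def add_call(ref_pos: int, q_start: int, length: int) -> None:
        calls.append(IntronCall(query_id=query.id, position=ref_pos,
                                length=length, query_start=q_start))

    # before the first anchor
    r0, q0 = chain[0]
    lead = q0 - r0
    if lead >= min_intron_len:
        add_call(0, q0 - lead + 1, lead)
    # between consecutive anchors
    for (r1, q1), (r2, q2) in zip(chain, chain[1:]):
        surplus = (q2 - q1) - (r2 - r1)
        if surplus >= min_intron_len:
            add_call(r1 + anchor_len, q1 + anchor_len + 1, surplus)
    # after the last anchor
    rl, ql = chain[-1]
    ref_tail = len(ref) - (rl + anchor_len)
    qry_tail = len(qry) - (ql + anchor_len)
    surplus = qry_tail - ref_tail
    if surplus >= min_intron_len:
        add_call(len(ref), ql + anchor_len + ref_tail + 1, surplus)
    return sorted(calls, key=lambda c: c.position)


def excise_introns(query: SequenceRecord, calls: list[IntronCall]) -> SequenceRecord:
    """Remove all called insertions from the query."""
    if not calls:
        return query
    spans = sorted((c.query_start, c.query_start + c.length - 1) for c in calls)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise PreprocessError(
                f"{query.id}: overlapping intron calls at query positions {s1}-{e1} and {s2}-{e2}"
            )
    out = []
    prev_end = 0
    for s, e in spans:
        out.append(query.residues[prev_end:s - 1])
        prev_end = e
    out.append(query.residues[prev_end:])
    return replace(query, residues="".join(out))


# ---------------------------------------------------------------------------
# primers


def primer_degeneracy(primer: Primer) -> int:
    """Number of exact sequences the degenerate primer encodes."""
    deg = 1
    for ch in primer.sequence:
        deg *= len(IUPAC_CLASSES[ch])
    return deg


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _window_mismatches(primer_seq: str, window: str) -> int:
    mm = 0
    for p, t in zip(primer_seq, window):
        if IUPAC_CLASSES[p].isdisjoint(IUPAC_CLASSES.get(t, frozenset())):
            mm += 1
    return mm


def map_primer(primer: Primer, template: SequenceRecord,
               max_mismatches: int = 0) -> list[tuple[int, str, int]]:
    """All binding sites of a primer on the plus strand of a template.

    Forward primers are matched directly; reverse primers as their
    reverse complement.  A template base matches a primer symbol when
    their IUPAC classes intersect.  Returns ``(start, strand, mismatches)``
    tuples, ``start`` being the 5'-most template coordinate of the window,
    sorted by start then strand.
    """
    if template.is_aligned:
        raise PreprocessError(f"{template.id}: template must be unaligned")
    probe = primer.sequence if primer.direction == "forward" else reverse_complement(primer.sequence)
    strand = "+" if primer.direction == "forward" else "-"
    L, k = len(template.residues), len(probe)
    if k > L:
        raise PreprocessError(
            f"primer {primer.name!r} ({k} nt) longer than template {template.id!r} ({L} nt)"
        )
    hits = []
    tpl = template.residues
    for start in range(L - k + 1):
        mm = _window_mismatches(probe, tpl[start:start + k])
        if mm <= max_mismatches:
            hits.append((start + 1, strand, mm))
    return hits


def predict_amplicon(fwd_start: int, rev_start: int, rev_primer_len: int) -> int:
    """Amplicon length for a forward hit and a reverse-strand hit.

    Both primers are included: length spans from the forward window start
    through the last base of the reverse window.
    """
    if rev_start <= fwd_start:
        raise PreprocessError(
            f"reverse window (start {rev_start}) not strictly downstream of forward (start {fwd_start})"
        )
    return (rev_start + rev_primer_len - 1) - fwd_start + 1


def load_primer_table(path: str | Path | None = None) -> list[Primer]:
    """Load the packaged COI primer panel (or a like-formatted TSV)."""
    if path is None:
        path = packaged_data_path("coi_primers.tsv")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        primers = []
        for row in reader:
            start = row.get("start_position", "").strip()
            primers.append(Primer(
                name=row["name"].strip(),
                sequence=row["sequence"].strip().upper(),
                direction=row["direction"].strip(),
                start_position=int(start) if start else None,
            ))
    return primers


def write_intron_calls(calls: list[IntronCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tposition\tlength\tquery_start\n")
        for c in calls:
            fh.write(f"{c.query_id}\t{c.position}\t{c.length}\t{c.query_start}\n")
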