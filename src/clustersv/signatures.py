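"""Collection of structural-variant signatures from long-read alignments.

A *signature* is the signal of one SV carried by one read.  Intra-alignment
signatures are deletion (``D``) and insertion (``I``) runs embedded in a
single alignment's CIGAR.  Inter-alignment signatures are reconstructed from
a read's discordant partial alignments (primary + supplementary records):
a reference gap between consecutive partials implies a deletion, a long
soft clip at the junction of two adjacent partials implies an insertion,
and a strand-flipped middle partial flanked by two same-strand partials
implies an inversion.

Coordinates are 1-based with half-open spans ``[first, last)``; for
deletions and inversions ``length == last - first``, insertions are point
events with ``last == first`` anchored at the base preceding the inserted
sequence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pysam

logger = logging.getLogger(__name__)

SV_DEL = "DEL"
SV_INS = "INS"
SV_INV = "INV"
SV_DUP = "DUP"

ORIGIN_INTRA = "intra"
ORIGIN_INTER = "inter"

# CIGAR op codes as encoded by htslib.
_CIGAR_MIDNSHP = "MIDNSHP=X"
_REF_CONSUMERS = {0, 2, 3, 7, 8}  # M, D, N, =, X
_QUERY_CONSUMERS = {0, 1, 4, 7, 8}  # M, I, S, =, X
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class Signature:
    """One read-level SV signal on the reference."""

    chrom: str
    first: int
    last: int
    length: int
    sv_type: str
    origin: str
    read_id: str
    uid: Optional[int] = None

    def __post_init__(self) -> None:
        if self.first < 1:
            raise ValueError(f"signature first coordinate must be >= 1, got {self.first}")
        if self.sv_type in (SV_DEL, SV_INV) and self.last - self.first != self.length:
            raise ValueError(
                f"{self.sv_type} signature requires last - first == length "
                f"({self.last} - {self.first} != {self.length})"
            )
        if self.sv_type == SV_INS and (self.last != self.first or self.length < 1):
            raise ValueError("INS signature requires last == first and length >= 1")


@dataclass
class CompactAlignment:
    """Minimal per-read alignment record kept for genotyping.

    ``ref_start``/``ref_end`` are 1-based inclusive and cover the union of
    the read's aligned segments on ``chrom``; ``signature_refs`` holds the
    uids of the signatures this read contributed there.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    signature_refs: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise ValueError("CompactAlignment requires ref_start <= ref_end")


@dataclass
class CallerParams:
    """Tunable parameters of signature collection.

    min_sv_length
        Events shorter than this are discarded (bp).
    min_mapping_quality
        Alignments below this MAPQ are skipped (supplementary records kept).
    adjacency_max_gap
        Maximum reference gap (bp) between two partials for them to count
        as *adjacent* when reconstructing inter-alignment insertions.
    max_deletion_span
        Upper bound (bp) on the reference gap considered for
        inter-alignment deletions.
    """

    min_sv_length: int = 50
    min_mapping_quality: int = 20
    adjacency_max_gap: int = 100
    max_deletion_span: int = 100_000


@dataclass
class PartialAlignment:
    """One aligned segment of a read, in reference orientation.

    ``query_start``/``query_end`` are 0-based half-open positions on the
    original (sequencer) read orientation; ``left_clip``/``right_clip`` are
    the clip lengths (soft or hard) at the reference-left/right ends of the
    record.
    """

    read_id: str
    chrom: str
    strand: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    left_clip: int
    right_clip: int


@dataclass
class SignatureCollections:
    """Per-type signature lists sorted by (chrom, first) plus the alignment store."""

    by_type: dict[str, list[Signature]]
    alignments: list[CompactAlignment]
    n_skipped: int = 0

    def all_signatures(self) -> list[Signature]:
        return [s for sigs in self.by_type.values() for s in sigs]


def parse_cigar(cigar: str) -> list[tuple[int, int]]:
    """Parse a CIGAR string into (op, length) tuples using htslib op codes."""
    tuples = [(_CIGAR_MIDNSHP.index(op), int(n)) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{_CIGAR_MIDNSHP[op]}" for op, n in tuples) != cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    return tuples


def intra_signatures_from_cigar(
    chrom: str,
    pos: int,
    cigar: str | list[tuple[int, int]],
    read_id: str,
    min_len: int,
) -> list[Signature]:
    """Deletion/insertion signatures from one alignment's CIGAR.

    ``pos`` is the 1-based reference position of the first aligned base.
    A deletion run of length ``d`` at reference cursor ``r`` yields
    ``[r, r + d)``; an insertion run is anchored at the base preceding it.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if isinstance(cigar, str):
        try:
            ops = parse_cigar(cigar)
        except ValueError as exc:
            raise ValueError(f"read {read_id}: {exc}") from exc
    else:
        ops = cigar
    out: list[Signature] = []
    ref = pos
    for op, n in ops:
        if op == 2 and n >= min_len:  # D
            out.append(Signature(chrom, ref, ref + n, n, SV_DEL, ORIGIN_INTRA, read_id))
        elif op == 1 and n >= min_len:  # I
            anchor = max(ref - 1, 1)
            out.append(Signature(chrom, anchor, anchor, n, SV_INS, ORIGIN_INTRA, read_id))
        if op in _REF_CONSUMERS:
            ref += n
    return out


def extract_intra_signatures(aln: pysam.AlignedSegment, min_len: int) -> list[Signature]:
    """Intra-alignment signatures of a mapped pysam record."""
    if aln.is_unmapped or aln.cigartuples is None:
        raise ValueError(f"read {aln.query_name}: no usable CIGAR")
    return intra_signatures_from_cigar(
        aln.reference_name, aln.reference_start + 1, aln.cigartuples, aln.query_name, min_len
    )


def extract_inter_deletion(
    aln1: PartialAlignment,
    aln2: PartialAlignment,
    min_len: int,
    max_span: int = 100_000,
) -> Optional[Signature]:
    """Deletion implied by the unaligned reference gap between two partials.

    The gap between the end of the reference-left partial and the start of
    the reference-right partial is the deletion length; pairs on different
    chromosomes or strands, or with a gap outside ``[min_len, max_span]``,
    yield nothing.
    """
    if aln1.chrom != aln2.chrom or aln1.strand != aln2.strand:
        return None
    left, right = (aln1, aln2) if aln1.ref_start <= aln2.ref_start else (aln2, aln1)
    gap = right.ref_start - left.ref_end - 1
    if gap < min_len or gap > max_span:
        return None
    return Signature(
        left.chrom, left.ref_end + 1, right.ref_start, gap, SV_DEL, ORIGIN_INTER, aln1.read_id
    )


def extract_inter_insertion(
    aln1: PartialAlignment,
    aln2: PartialAlignment,
    min_len: int,
    adjacency_max_gap: int = 100,
) -> Optional[Signature]:
    """Insertion implied by the longest soft clip (LSC) at a split junction.

    For two adjacent partials the LSC is the larger of the two
    junction-facing clips; the aligned reference length of the partial that
    does *not* carry the LSC is subtracted from it to estimate the inserted
    length.  The signature is anchored at the start of the reference-right
    partial.
    """
    if aln1.chrom != aln2.chrom or aln1.strand != aln2.strand:
        return None
    left, right = (aln1, aln2) if aln1.ref_start <= aln2.ref_start else (aln2, aln1)
    gap = right.ref_start - left.ref_end - 1
    if abs(gap) > adjacency_max_gap:
        return None
    clip_left = left.right_clip  # clip facing the junction
    clip_right = right.left_clip
    if clip_left == 0 and clip_right == 0:
        return None
    if clip_left >= clip_right:
        lsc, other = clip_left, right
    else:
        lsc, other = clip_right, left
    length = lsc - (other.ref_end - other.ref_start + 1)
    if length < min_len:
        return None
    return Signature(
        left.chrom, right.ref_start, right.ref_start, length, SV_INS, ORIGIN_INTER, aln1.read_id
    )


def extract_inversion(
    partials: tuple[PartialAlignment, PartialAlignment, PartialAlignment],
    min_len: int = 1,
) -> Optional[Signature]:
    """Inversion implied by a strand-flipped middle partial.

    Three consecutive partials of one read with strand pattern +/-/+
    (or -/+/-) mark an inversion whose span and length are those of the
    middle alignment.
    """
    a, b, c = partials
    if not (a.chrom == b.chrom == c.chrom):
        return None
    if not (a.strand == c.strand and b.strand != a.strand):
        return None
    length = b.ref_end - b.ref_start + 1
    if length < min_len:
        return None
    return Signature(
        b.chrom, b.ref_start, b.ref_end + 1, length, SV_INV, ORIGIN_INTER, b.read_id
    )


def partial_from_record(aln: pysam.AlignedSegment) -> PartialAlignment:
    """Reduce a pysam record to the fields the inter-alignment rules use."""
    cig = aln.cigartuples
    left_clip = cig[0][1] if cig[0][0] in (4, 5) else 0
    right_clip = cig[-1][1] if cig[-1][0] in (4, 5) else 0
    read_len = left_clip + right_clip + sum(n for op, n in cig if op in (0, 1, 7, 8))
    if aln.is_reverse:
        q_start, q_end = right_clip, read_len - left_clip
        strand = "-"
    else:
        q_start, q_end = left_clip, read_len - right_clip
        strand = "+"
    return PartialAlignment(
        read_id=aln.query_name,
        chrom=aln.reference_name,
        strand=strand,
        ref_start=aln.reference_start + 1,
        ref_end=aln.reference_end,
        query_start=q_start,
        query_end=q_end,
        left_clip=left_clip,
        right_clip=right_clip,
    )


def inter_signatures_for_read(
    partials: list[PartialAlignment], params: CallerParams
) -> list[Signature]:
    """Apply the inter-alignment rules to one read's partials.

    Partials are re-sorted by query coordinate first, so the result does not
    depend on the order records appear in the input file.
    """
    if len(partials) < 2:
        return []
    parts = sorted(partials, key=lambda p: (p.query_start, p.query_end, p.ref_start))
    out: list[Signature] = []
    for a, b in zip(parts, parts[1:]):
        sig = extract_inter_deletion(a, b, params.min_sv_length, params.max_deletion_span)
        if sig is not None:
            out.append(sig)
        sig = extract_inter_insertion(a, b, params.min_sv_length, params.adjacency_max_gap)
        if sig is not None:
            out.append(sig)
    for trio in zip(parts, parts[1:], parts[2:]):
        sig = extract_inversion(trio, params.min_sv_length)
        if sig is not None:
            out.append(sig)
    return out


def _signature_sort_key(sig: Signature) -> tuple:
    return (sig.chrom, sig.first, sig.last, sig.length, sig.read_id)


def collect_signatures(
    bam_path: str, params: CallerParams | None = None
) -> SignatureCollections:
    """Stream a coordinate-sorted SAM/BAM and collect all SV signatures.

    Returns per-type signature lists sorted by (chrom, first) and one
    :class:`CompactAlignment` per (read, chromosome) spanning the union of
    that read's aligned segments, with back-references to its signatures.
    Unmapped and secondary records, and records below the mapping-quality
    cutoff, are skipped (counted); an unsorted file raises ``ValueError``.
    """
    params = params or CallerParams()
    by_type: dict[str, list[Signature]] = {SV_DEL: [], SV_INS: [], SV_INV: []}
    # read -> chrom -> (partials, intra signatures)
    per_read: dict[tuple[str, str], tuple[list[PartialAlignment], list[Signature]]] = {}
    n_skipped = 0
    seen_chroms: list[str] = []
    last_pos = -1

    with pysam.AlignmentFile(bam_path, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary:
                n_skipped += 1
                continue
            if aln.mapping_quality < params.min_mapping_quality:
                n_skipped += 1
                continue
            chrom = aln.reference_name
            if not seen_chroms or seen_chroms[-1] != chrom:
                if chrom in seen_chroms:
                    raise ValueError(f"input not coordinate-sorted: {chrom} seen twice")
                seen_chroms.append(chrom)
                last_pos = -1
            if aln.reference_start < last_pos:
                raise ValueError(
                    f"input not coordinate-sorted at {chrom}:{aln.reference_start + 1}"
                )
            last_pos = aln.reference_start

            key = (aln.query_name, chrom)
            partials, intra = per_read.setdefault(key, ([], []))
            partials.append(partial_from_record(aln))
            intra.extend(extract_intra_signatures(aln, params.min_sv_length))

    if n_skipped:
        logger.info("skipped %d unmapped/secondary/low-MAPQ records", n_skipped)

    alignments: list[CompactAlignment] = []
    uid = 0
    for (read_id, chrom), (partials, intra) in per_read.items():
        sigs = intra + inter_signatures_for_read(partials, params)
        refs = []
        for sig in sigs:
            sig.uid = uid
            refs.append(uid)
            by_type[sig.sv_type].append(sig)
            uid += 1
        alignments.append(
            CompactAlignment(
                read_id=read_id,
                chrom=chrom,
                ref_start=min(p.ref_start for p in partials),
                ref_end=max(p.ref_end for p in partials),
                signature_refs=refs,
            )
        )

    for sigs in by_type.values():
        sigs.sort(key=_signature_sort_key)
    alignments.sort(key=lambda a: (a.chrom, a.ref_start, a.ref_end, a.read_id))
    return SignatureCollections(by_type=by_type, alignments=alignments, n_skipped=n_skipped)
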