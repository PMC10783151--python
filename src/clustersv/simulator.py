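"""Synthetic long-read alignment generator with implanted SVs of known genotype.

The simulator builds a random reference sequence, implants non-overlapping
deletions, insertions, and inversions (heterozygous events on one
haplotype, homozygous on both), and emits read alignments *directly in
reference coordinates*: each read is sampled uniformly from one haplotype
and its alignment against the reference is constructed analytically.
Implanted events inside a read appear as CIGAR ``D``/``I`` runs when
shorter than the split-alignment threshold, and as split partial alignments
otherwise (reference gap for large deletions, long junction soft clips for
large insertions, a reverse-strand middle partial for inversions).
Sequencing noise follows a configurable profile of base mismatches, small
(< 50 bp) read indels, and per-read breakpoint jitter that shifts where an
intra-alignment event sits in the CIGAR without changing its length.

Every stage is deterministic for a fixed seed.  Alongside the SAM, the
simulator writes the reference FASTA, a truth VCF, and a TSV ledger of the
events each read is expected to signal.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pysam

from clustersv.signatures import SV_DEL, SV_INS, SV_INV

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

CHROM = "sim1"
_ANCHOR = 30  # min aligned flank (bp) for a read to count as spanning an event


@dataclass
class SvTruth:
    """One implanted event; coordinates follow the caller's convention.

    ``first`` is the first affected base (1-based) for DEL/INV and the base
    preceding the inserted sequence for INS; ``[first, last)`` is half-open.
    """

    chrom: str
    first: int
    last: int
    length: int
    sv_type: str
    genotype: str  # "0/1" or "1/1"


@dataclass
class ErrorProfile:
    """Read-level noise model.

    mismatch_rate / indel_rate
        Per-base probabilities of a substitution or of starting a small
        read indel (geometric lengths with mean ``indel_mean_len``, capped
        below 50 bp so errors never masquerade as SVs).
    read_length_mean / read_length_sd
        Normal read-length distribution, truncated at ``min_read_length``.
    breakpoint_jitter_sd
        Per-read shift (bp) of where an intra-alignment event sits in the
        CIGAR, emulating alignment ambiguity at junctions.
    split_threshold
        Events at least this long are represented as split partial
        alignments instead of CIGAR runs.
    """

    name: str = "ont"
    mismatch_rate: float = 0.04
    indel_rate: float = 0.05
    indel_mean_len: float = 2.0
    read_length_mean: float = 15_000.0
    read_length_sd: float = 3_000.0
    min_read_length: int = 1_000
    breakpoint_jitter_sd: float = 10.0
    split_threshold: int = 1_000

    def __post_init__(self) -> None:
        if not (0 <= self.mismatch_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("error rates must lie in [0, 1)")


ONT_PROFILE = ErrorProfile()
HIFI_PROFILE = ErrorProfile(
    name="hifi", mismatch_rate=0.002, indel_rate=0.005, breakpoint_jitter_sd=2.0
)
ERROR_FREE = ErrorProfile(
    name="error_free", mismatch_rate=0.0, indel_rate=0.0, breakpoint_jitter_sd=0.0
)
PROFILES = {"ont": ONT_PROFILE, "hifi": HIFI_PROFILE, "error_free": ERROR_FREE}


@dataclass
class SimSpec:
    """What to implant: event counts, length range, genotype mix, spacing."""

    n_del: int = 0
    n_ins: int = 0
    n_inv: int = 0
    length_range: tuple[int, int] = (50, 500)
    min_spacing: int = 1_000
    het_fraction: float = 0.5

    @property
    def total(self) -> int:
        return self.n_del + self.n_ins + self.n_inv


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random reference sequence of exactly ``length`` bases."""
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def implant_svs(
    genome: str, spec: SimSpec, seed: int = 0
) -> tuple[list[SvTruth], list[SvTruth], list[SvTruth]]:
    """Place events on the reference; returns (truth, hap1 events, hap2 events).

    Events are pairwise separated by at least ``spec.min_spacing`` reference
    bases and kept away from the genome ends.  Heterozygous events land on
    one haplotype at random; homozygous events on both.  Raises
    ``ValueError`` when the requested events cannot be placed.
    """
    rng = np.random.default_rng(seed)
    types = [SV_DEL] * spec.n_del + [SV_INS] * spec.n_ins + [SV_INV] * spec.n_inv
    rng.shuffle(types)
    lo, hi = spec.length_range
    margin = 20_000
    if len(genome) <= 2 * margin + hi:
        raise ValueError("genome too short for the requested margin and event lengths")
    placed: list[tuple[int, int]] = []
    truth: list[SvTruth] = []
    attempts, max_attempts = 0, 200 * max(len(types), 1)
    for sv_type in types:
        length = int(rng.integers(lo, hi + 1))
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"cannot place {len(types)} events with spacing {spec.min_spacing} "
                    f"in a {len(genome)} bp genome"
                )
            first = int(rng.integers(margin, len(genome) - margin - length))
            span = length if sv_type != SV_INS else 0
            lo_edge, hi_edge = first - spec.min_spacing, first + span + spec.min_spacing
            if all(e < lo_edge or s > hi_edge for s, e in placed):
                placed.append((first, first + span))
                break
        genotype = "0/1" if rng.random() < spec.het_fraction else "1/1"
        truth.append(SvTruth(CHROM, first, first + span, length, sv_type, genotype))
    truth.sort(key=lambda t: t.first)
    hap1: list[SvTruth] = []
    hap2: list[SvTruth] = []
    for t in truth:
        if t.genotype == "1/1":
            hap1.append(t)
            hap2.append(t)
        elif rng.random() < 0.5:
            hap1.append(t)
        else:
            hap2.append(t)
    return truth, hap1, hap2


@dataclass
class _Block:
    """One block of the haplotype→reference map.

    ``del_after`` marks an implanted deletion between this block and the
    next (deletions occupy no haplotype space).
    """

    kind: str  # "M", "INS", "INV"
    hap_start: int  # 0-based
    hap_len: int
    ref_start: int  # 1-based first reference base (INS: anchor base)
    event: Optional[SvTruth] = None
    del_after: Optional[SvTruth] = None


def make_insert_sequences(truth: list[SvTruth], seed: int) -> dict[int, str]:
    """Random inserted sequences, one per insertion event (shared by haplotypes)."""
    rng = np.random.default_rng(seed)
    return {
        id(t): rng.choice(_BASES, size=t.length).tobytes().decode()
        for t in truth
        if t.sv_type == SV_INS
    }


def haplotype_blocks(genome_len: int, events: list[SvTruth]) -> list[_Block]:
    """Block map of one haplotype given its (sorted) events."""
    blocks: list[_Block] = []
    hap, ref = 0, 1
    for ev in events:
        seg = (ev.first - ref + 1) if ev.sv_type == SV_INS else (ev.first - ref)
        if seg < 0:
            raise ValueError("events overlap or are unsorted")
        if seg > 0:
            blocks.append(_Block("M", hap, seg, ref))
            hap += seg
            ref += seg
        if ev.sv_type == SV_DEL:
            if blocks and blocks[-1].kind == "M":
                blocks[-1].del_after = ev
            ref += ev.length
        elif ev.sv_type == SV_INS:
            blocks.append(_Block("INS", hap, ev.length, ev.first, ev))
            hap += ev.length
        else:
            blocks.append(_Block("INV", hap, ev.length, ev.first, ev))
            hap += ev.length
            ref += ev.length
    if ref <= genome_len:
        blocks.append(_Block("M", hap, genome_len - ref + 1, ref))
    return blocks


def _haplotype_length(blocks: list[_Block]) -> int:
    last = blocks[-1]
    return last.hap_start + last.hap_len


@dataclass
class _Piece:
    """One partial alignment under construction (reference orientation)."""

    ref_start: int
    strand: str
    ops: list[list[int]] = field(default_factory=list)  # [op, len]; M=0 I=1 D=2
    q_start: int = 0
    q_end: int = 0

    def add(self, op: int, n: int) -> None:
        if n <= 0:
            return
        if self.ops and self.ops[-1][0] == op:
            self.ops[-1][1] += n
        else:
            self.ops.append([op, n])

    @property
    def query_len(self) -> int:
        return sum(n for op, n in self.ops if op in (0, 1))

    @property
    def ref_len(self) -> int:
        return sum(n for op, n in self.ops if op in (0, 2))


class _ReadBuilder:
    """Accumulates one read's sequence and partial alignments."""

    def __init__(self, genome: str, profile: ErrorProfile, rng):
        self.genome = genome
        self.profile = profile
        self.rng = rng
        self.seq_parts: list[str] = []
        self.qpos = 0
        self.pieces: list[_Piece] = []
        self.piece: Optional[_Piece] = None

    def left_anchor(self) -> int:
        return self.piece.ref_len if self.piece is not None else 0

    def _open(self, ref_start: int, strand: str = "+") -> None:
        self.piece = _Piece(ref_start=ref_start, strand=strand, q_start=self.qpos)

    def _close(self) -> None:
        if self.piece is not None and self.piece.query_len > 0:
            self.piece.q_end = self.qpos
            self.pieces.append(self.piece)
        self.piece = None

    def _append_seq(self, seq: str) -> None:
        self.seq_parts.append(seq)
        self.qpos += len(seq)

    def match(self, ref_start: int, length: int) -> None:
        """Aligned block [ref_start, ref_start+length) with profile errors."""
        if length <= 0:
            return
        if self.piece is None:
            self._open(ref_start)
        prof, rng = self.profile, self.rng
        ref_seq = self.genome[ref_start - 1 : ref_start - 1 + length]
        n_err = rng.binomial(length, prof.indel_rate) if prof.indel_rate > 0 else 0
        cuts = np.sort(rng.integers(1, length, size=n_err)) if n_err and length > 1 else []
        prev = 0
        for cut in map(int, cuts):
            if cut <= prev:
                continue
            self._emit_match_run(ref_seq[prev:cut])
            err_len = min(int(rng.geometric(1.0 / prof.indel_mean_len)), 49)
            if rng.random() < 0.5:  # read insertion: extra read bases
                self._append_seq(rng.choice(_BASES, size=err_len).tobytes().decode())
                self.piece.add(1, err_len)
                prev = cut
            else:  # read deletion: reference bases skipped by the read
                err_len = min(err_len, length - cut)
                self.piece.add(2, err_len)
                prev = cut + err_len
        self._emit_match_run(ref_seq[prev:])

    def _emit_match_run(self, ref_seq: str) -> None:
        if not ref_seq:
            return
        prof, rng = self.profile, self.rng
        if prof.mismatch_rate > 0:
            arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8).copy()
            k = rng.binomial(len(arr), prof.mismatch_rate)
            if k:
                idx = rng.integers(0, len(arr), size=k)
                arr[idx] = _BASES[rng.integers(0, 4, size=k)]
            ref_seq = arr.tobytes().decode()
        self._append_seq(ref_seq)
        self.piece.add(0, len(ref_seq))

    def deletion(self, length: int) -> None:
        self.piece.add(2, length)

    def insertion(self, seq: str) -> None:
        self._append_seq(seq)
        self.piece.add(1, len(seq))

    def split_deletion(self, next_ref_start: int) -> None:
        self._close()
        self._open(next_ref_start)

    def split_insertion(self, seq: str, next_ref_start: int) -> None:
        # inserted bases stay soft-clipped in both flanking partials
        self._close()
        self._append_seq(seq)
        self._open(next_ref_start)

    def clip(self, seq: str) -> None:
        """Unaligned read bases (partial overlap of a large event)."""
        self._close()
        self._append_seq(seq)

    def inversion(self, ref_start: int, length: int) -> None:
        """Fully spanned inversion: reverse-strand middle piece, error-free."""
        self._close()
        mid = _Piece(ref_start=ref_start, strand="-", q_start=self.qpos)
        mid.add(0, length)
        self._append_seq(_revcomp(self.genome[ref_start - 1 : ref_start - 1 + length]))
        mid.q_end = self.qpos
        self.pieces.append(mid)
        self._open(ref_start + length)

    def finish(self) -> tuple[str, list[_Piece]]:
        self._close()
        return "".join(self.seq_parts), self.pieces


def _apply_jitter(pieces: list[_Piece], min_event_len: int, sd: float, rng) -> None:
    """Shift implanted intra-alignment events within their CIGAR context.

    Transfers matched bases across each D/I run of at least
    ``min_event_len`` bp, preserving query and reference lengths exactly.
    """
    if sd <= 0:
        return
    for piece in pieces:
        ops = piece.ops
        for i in range(1, len(ops) - 1):
            op, n = ops[i]
            if op not in (1, 2) or n < min_event_len:
                continue
            if ops[i - 1][0] != 0 or ops[i + 1][0] != 0:
                continue
            room_left, room_right = ops[i - 1][1] - 1, ops[i + 1][1] - 1
            shift = int(round(rng.normal(0.0, sd)))
            shift = max(-room_left, min(room_right, shift))
            ops[i - 1][1] += shift
            ops[i + 1][1] -= shift


def build_read(
    genome: str,
    blocks: list[_Block],
    ins_seqs: dict[int, str],
    hap_start: int,
    hap_end: int,
    profile: ErrorProfile,
    rng,
) -> tuple[str, list[_Piece], list[tuple[SvTruth, str]]]:
    """Construct one read (hap coordinates [hap_start, hap_end)).

    Returns the read sequence, its partial alignments, and the implanted
    events the read spans with enough anchor, tagged with the evidence
    route ("intra" or "split").
    """
    builder = _ReadBuilder(genome, profile, rng)
    covered: list[tuple[SvTruth, str]] = []

    for blk in blocks:
        b_lo, b_hi = blk.hap_start, blk.hap_start + blk.hap_len
        if b_hi <= hap_start or b_lo >= hap_end:
            continue
        lo, hi = max(b_lo, hap_start), min(b_hi, hap_end)
        off, seg = lo - b_lo, hi - lo
        if blk.kind == "M":
            builder.match(blk.ref_start + off, seg)
            ev = blk.del_after
            if ev is not None and hi == b_hi and hap_end > b_hi:
                left = builder.left_anchor()
                right_avail = hap_end - b_hi
                if ev.length >= profile.split_threshold:
                    builder.split_deletion(blk.ref_start + blk.hap_len + ev.length)
                    route = "split"
                else:
                    builder.deletion(ev.length)
                    route = "intra"
                if left >= _ANCHOR and right_avail >= _ANCHOR:
                    covered.append((ev, route))
        elif blk.kind == "INS":
            seq = ins_seqs[id(blk.event)][off : off + seg]
            full = off == 0 and seg == blk.hap_len
            left = builder.left_anchor()
            right_avail = hap_end - b_hi
            if full and left >= 1 and right_avail >= 1:
                if blk.event.length >= profile.split_threshold:
                    builder.split_insertion(seq, blk.ref_start + 1)
                    route = "split"
                else:
                    builder.insertion(seq)
                    route = "intra"
                if left >= _ANCHOR and right_avail >= _ANCHOR:
                    covered.append((blk.event, route))
            else:
                builder.clip(seq)
        else:  # INV
            full = off == 0 and seg == blk.hap_len
            left = builder.left_anchor()
            right_avail = hap_end - b_hi
            if full and left >= 1 and right_avail >= 1:
                builder.inversion(blk.ref_start, blk.hap_len)
                if left >= _ANCHOR and right_avail >= _ANCHOR:
                    covered.append((blk.event, "split"))
            else:
                # the inverted haplotype segment [off, off+seg) reads as the
                # reverse complement of ref [last-off-seg, last-off)
                r_hi = blk.ref_start + blk.hap_len - off
                builder.clip(_revcomp(genome[r_hi - seg - 1 : r_hi - 1]))

    seq, pieces = builder.finish()
    _apply_jitter(pieces, 50, profile.breakpoint_jitter_sd, rng)
    return seq, pieces, covered


def _pieces_to_records(
    read_id: str, seq: str, pieces: list[_Piece], header: pysam.AlignmentHeader
) -> list[pysam.AlignedSegment]:
    """Emit one primary + supplementary SAM records for a read's pieces."""
    if not pieces:
        return []
    read_len = len(seq)
    pieces = sorted(pieces, key=lambda p: p.q_start)
    primary = max(range(len(pieces)), key=lambda i: (pieces[i].query_len, -i))
    rc_seq = None
    records = []
    for i, piece in enumerate(pieces):
        a = pysam.AlignedSegment(header)
        a.query_name = read_id
        flag = 0
        if i != primary:
            flag |= 0x800
        if piece.strand == "-":
            flag |= 0x10
        a.flag = flag
        a.reference_id = 0
        a.reference_start = piece.ref_start - 1
        a.mapping_quality = 60
        core = [(op, n) for op, n in piece.ops if n > 0]
        if piece.strand == "+":
            lead, tail = piece.q_start, read_len - piece.q_end
            a.query_sequence = seq
        else:
            lead, tail = read_len - piece.q_end, piece.q_start
            if rc_seq is None:
                rc_seq = _revcomp(seq)
            a.query_sequence = rc_seq
        cigar = ([(4, lead)] if lead else []) + core + ([(4, tail)] if tail else [])
        a.cigartuples = cigar
        records.append(a)
    return records


def simulate_alignments(
    genome: str,
    hap_events: tuple[list[SvTruth], list[SvTruth]],
    ins_seqs: dict[int, str],
    depth: float,
    profile: ErrorProfile,
    seed: int,
    sam_path: str,
    ledger_path: Optional[str] = None,
) -> None:
    """Sample reads from both haplotypes and write a coordinate-sorted SAM.

    Total sequenced bases target ``depth/2 ×`` genome length per haplotype.
    The optional ledger TSV records, per read, the implanted events it
    spans and the evidence route each should produce.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": CHROM, "LN": len(genome)}],
        }
    )
    records: list[pysam.AlignedSegment] = []
    ledger_rows: list[tuple] = []
    read_idx = 0
    for hap_i, events in enumerate(hap_events):
        blocks = haplotype_blocks(len(genome), events)
        hap_len = _haplotype_length(blocks)
        target = depth / 2.0 * len(genome)
        sequenced = 0
        while sequenced < target:
            rl = int(rng.normal(profile.read_length_mean, profile.read_length_sd))
            rl = max(profile.min_read_length, min(rl, hap_len))
            start = int(rng.integers(0, hap_len - rl + 1))
            read_id = f"read{read_idx}_h{hap_i + 1}"
            read_idx += 1
            seq, pieces, covered = build_read(
                genome, blocks, ins_seqs, start, start + rl, profile, rng
            )
            records.extend(_pieces_to_records(read_id, seq, pieces, header))
            for ev, route in covered:
                ledger_rows.append(
                    (read_id, ev.sv_type, ev.first, ev.last, ev.length, ev.genotype, route)
                )
            sequenced += rl

    records.sort(key=lambda a: a.reference_start)
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for rec in records:
            out.write(rec)

    if ledger_path:
        with open(ledger_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(
                ["read_id", "sv_type", "first", "last", "length", "genotype", "route"]
            )
            writer.writerows(sorted(ledger_rows))


def simulate_dataset(
    outdir: str,
    genome_length: int = 2_000_000,
    n_del: int = 0,
    n_ins: int = 0,
    n_inv: int = 0,
    depth: float = 20.0,
    profile: ErrorProfile | str = "ont",
    gc: float = 0.4,
    length_range: tuple[int, int] = (50, 500),
    het_fraction: float = 0.5,
    seed: int = 0,
) -> dict[str, object]:
    """Run the full simulation and write reference, SAM, truth VCF, ledger.

    Returns a dict with the output paths and the in-memory truth list.
    """
    from clustersv.vcf_io import write_truth_vcf

    if isinstance(profile, str):
        profile = PROFILES[profile]
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    genome = simulate_genome(genome_length, gc=gc, seed=seeds[0])
    spec = SimSpec(
        n_del=n_del, n_ins=n_ins, n_inv=n_inv,
        length_range=length_range, het_fraction=het_fraction,
    )
    truth, hap1, hap2 = implant_svs(genome, spec, seed=seeds[1])
    ins_seqs = make_insert_sequences(truth, seed=seeds[2])

    ref_path = os.path.join(outdir, "reference.fa")
    with open(ref_path, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i : i + 80] + "\n")
    pysam.faidx(ref_path)

    sam_path = os.path.join(outdir, "reads.sam")
    ledger_path = os.path.join(outdir, "ledger.tsv")
    simulate_alignments(
        genome, (hap1, hap2), ins_seqs, depth, profile, seeds[3], sam_path, ledger_path
    )

    truth_vcf = os.path.join(outdir, "truth.vcf")
    write_truth_vcf(truth, {CHROM: len(genome)}, truth_vcf, reference=ref_path)

    return {
        "reference": ref_path,
        "sam": sam_path,
        "truth_vcf": truth_vcf,
        "ledger": ledger_path,
        "truth": truth,
        "genome_length": genome_length,
    }
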