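"""Reading and writing structural variants as VCF 4.2 with symbolic alleles.

Output records use the standard symbolic-allele anchoring: POS is the base
before the event (``first - 1`` for deletions and inversions, ``first`` for
insertions/duplications, whose internal coordinate is already the base
preceding the inserted sequence), SVLEN is negative for deletions, and END
satisfies ``END - POS == |SVLEN|`` for spanning types and ``END == POS``
for point events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pysam

from clustersv.genotyping import GenotypedSV
from clustersv.signatures import SV_DEL, SV_DUP, SV_INS, SV_INV

logger = logging.getLogger(__name__)

_SPANNING_TYPES = (SV_DEL, SV_INV)
_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant, negative for deletions">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End coordinate of the variant">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Phred-scaled genotype quality">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth at the locus">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Reads supporting the reference and alternative alleles">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=INV,Description="Inversion">',
    '##ALT=<ID=DUP,Description="Duplication">',
]


@dataclass
class VcfSvRecord:
    """Normalized SV record as used by the benchmark module."""

    chrom: str
    pos: int  # 1-based anchor
    id: str
    svtype: str
    svlen: int  # signed: negative for DEL
    end: int
    qual: Optional[float]
    gt: Optional[str]  # "0/1", "1/1", "0/0" or None

    @property
    def span(self) -> tuple[int, int]:
        """(pos, end) interval used for reciprocal overlap."""
        return self.pos, self.end


def _build_header(contigs: dict[str, int], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for line in _HEADER_LINES:
        header.add_line(line)
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_sample(sample)
    return header


def _anchor_base(fasta: Optional[pysam.FastaFile], chrom: str, pos: int) -> str:
    if fasta is None:
        return "N"
    try:
        base = fasta.fetch(chrom, pos - 1, pos).upper()
    except (KeyError, ValueError):
        base = ""
    if not base:
        logger.warning("anchor base unavailable at %s:%d; writing N", chrom, pos)
        return "N"
    return base


def write_vcf(
    calls: list[GenotypedSV],
    contigs: dict[str, int],
    out_path: str,
    reference: Optional[str] = None,
    sample: str = "SAMPLE",
) -> None:
    """Write genotyped SVs as a sorted VCF 4.2 with symbolic alleles."""
    header = _build_header(contigs, sample)
    fasta = pysam.FastaFile(reference) if reference else None
    calls = sorted(calls, key=lambda c: (list(contigs).index(c.chrom), c.first))
    with pysam.VariantFile(out_path, "w", header=header) as out:
        for i, call in enumerate(calls):
            pos = call.first - 1 if call.sv_type in _SPANNING_TYPES else call.first
            svlen = -call.length if call.sv_type == SV_DEL else call.length
            end = pos + abs(svlen) if call.sv_type in _SPANNING_TYPES else pos
            rec = out.new_record(
                contig=call.chrom,
                start=pos - 1,
                alleles=(_anchor_base(fasta, call.chrom, pos), f"<{call.final_type}>"),
                id=f"{call.final_type}_{i}",
                qual=round(call.quality, 2),
            )
            rec.info["SVTYPE"] = call.final_type
            rec.info["SVLEN"] = svlen
            rec.stop = end  # writes INFO/END
            gt = tuple(int(a) for a in call.genotype.split("/"))
            rec.samples[sample]["GT"] = gt
            rec.samples[sample]["GQ"] = int(round(call.quality))
            rec.samples[sample]["DP"] = call.n_sv_reads + call.n_ref_reads
            rec.samples[sample]["AD"] = (call.n_ref_reads, call.n_sv_reads)
            out.write(rec)
    if fasta is not None:
        fasta.close()


def _normalize_gt(sample) -> Optional[str]:
    gt = sample.get("GT") if sample is not None else None
    if gt is None or all(a is None for a in gt):
        return None
    alleles = sorted(0 if a is None else int(a) for a in gt)
    return "/".join(str(a) for a in alleles)


def read_vcf(path: str, truth_mode: bool = False) -> list[VcfSvRecord]:
    """Read SV records from a VCF, normalizing to symbolic form.

    Sequence-resolved indels are converted to symbolic records with SVLEN
    taken from the allele-length difference.  In ``truth_mode`` (benchmark
    ground-truth side) homozygous-reference records are excluded, matching
    the convention that 0/0 truth entries are not counted.
    """
    out: list[VcfSvRecord] = []
    with pysam.VariantFile(path) as fh:
        has_sample = len(fh.header.samples) > 0
        for rec in fh:
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                continue
            svtype = rec.info.get("SVTYPE")
            if isinstance(svtype, tuple):
                svtype = svtype[0]
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if alt.startswith("<") and alt.endswith(">"):
                svtype = svtype or alt.strip("<>")
                if svlen is None:
                    # rec.stop is the 1-based inclusive END
                    svlen = (rec.stop - rec.pos) if svtype in _SPANNING_TYPES else 0
            else:
                diff = len(alt) - len(rec.ref)
                if diff < 0:
                    svtype, svlen = SV_DEL, diff
                elif diff > 0:
                    svtype, svlen = svtype or SV_INS, diff
                elif svtype is None:
                    logger.warning(
                        "skipping %s:%d: equal-length alleles without SVTYPE", rec.chrom, rec.pos
                    )
                    continue
            svlen = int(svlen)
            if svtype == SV_DEL and svlen > 0:
                svlen = -svlen
            if svtype in _SPANNING_TYPES:
                end = rec.pos + abs(svlen)
            else:
                end = rec.pos
            gt = _normalize_gt(rec.samples[0] if has_sample else None)
            if truth_mode and gt == "0/0":
                continue
            out.append(
                VcfSvRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    id=rec.id or f"{rec.chrom}:{rec.pos}",
                    svtype=svtype,
                    svlen=svlen,
                    end=end,
                    qual=rec.qual,
                    gt=gt,
                )
            )
    out.sort(key=lambda r: (r.chrom, r.pos))
    return out


def write_truth_vcf(
    truths,
    contigs: dict[str, int],
    out_path: str,
    reference: Optional[str] = None,
    sample: str = "TRUTH",
) -> None:
    """Write simulator truth events (chrom/first/last/length/type/genotype) as VCF."""
    calls = [
        GenotypedSV(
            chrom=t.chrom,
            first=t.first,
            last=t.last,
            length=t.length,
            sv_type=t.sv_type,
            final_type=t.sv_type,
            genotype=t.genotype,
            quality=99.0,
            n_sv_reads=1,
            n_ref_reads=0,
        )
        for t in truths
    ]
    write_vcf(calls, contigs, out_path, reference=reference, sample=sample)
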