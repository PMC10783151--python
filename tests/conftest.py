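from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from clustersv.signatures import Signature


def make_sig(
    first: int,
    last: int,
    length: int,
    sv_type: str = "DEL",
    chrom: str = "chr1",
    read_id: str = "r",
    origin: str = "intra",
    uid: int | None = None,
) -> Signature:
    return Signature(
        chrom=chrom, first=first, last=last, length=length,
        sv_type=sv_type, origin=origin, read_id=read_id, uid=uid,
    )


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:1000000\n"


def write_sam(path, body: str, header: str = SAM_HEADER) -> str:
    path = Path(path)
    path.write_text(header + body)
    return str(path)


def sam_line(
    name: str,
    pos: int,
    cigar: str,
    seq_len: int | None = None,
    flag: int = 0,
    mapq: int = 60,
    chrom: str = "chr1",
) -> str:
    """One SAM record with a sequence length consistent with the CIGAR."""
    if seq_len is None:
        seq_len = 0
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
            else:
                if ch in "MIS=X":
                    seq_len += int(num)
                num = ""
    seq = "A" * seq_len
    return f"{name}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*\n"


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small seeded ONT-like simulation shared across tests."""
    from clustersv.simulator import simulate_dataset

    outdir = tmp_path_factory.mktemp("small_sim")
    return simulate_dataset(
        str(outdir),
        genome_length=400_000,
        n_del=15,
        n_ins=10,
        n_inv=5,
        depth=20,
        profile="ont",
        seed=11,
    )
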