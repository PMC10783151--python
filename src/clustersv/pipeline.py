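"""End-to-end calling pipeline: ingest → cluster → genotype → VCF."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pysam

from clustersv.clustering import cluster_signatures
from clustersv.genotyping import GenotypedSV, GenotypingParams, genotype_clusters
from clustersv.signatures import CallerParams, collect_signatures
from clustersv.vcf_io import write_vcf

logger = logging.getLogger(__name__)


@dataclass
class CallConfig:
    """Parameters of one `call` run.

    ``min_pts=None`` selects the depth-scaled default
    max(2, mean_depth // 10), which keeps the clustering support
    requirement proportional to coverage.
    """

    min_sv_length: int = 50
    epsilon: float = 250.0
    min_pts: Optional[int] = None
    technology: str = "hifi"
    min_mapping_quality: int = 20


def estimate_depth(bam_path: str, contigs: dict[str, int]) -> float:
    """Mean aligned depth: total aligned reference bases / genome size."""
    total = 0
    with pysam.AlignmentFile(bam_path, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary:
                continue
            total += aln.reference_length or 0
    genome = sum(contigs.values())
    return total / genome if genome else 0.0


def reference_contigs(reference: str) -> dict[str, int]:
    with pysam.FastaFile(reference) as fa:
        return dict(zip(fa.references, fa.lengths))


def call_svs(
    bam_path: str,
    contigs: dict[str, int],
    config: CallConfig | None = None,
) -> list[GenotypedSV]:
    """Run the full caller on a coordinate-sorted SAM/BAM."""
    config = config or CallConfig()
    params = CallerParams(
        min_sv_length=config.min_sv_length,
        min_mapping_quality=config.min_mapping_quality,
    )
    collections = collect_signatures(bam_path, params)
    n_sigs = {t: len(s) for t, s in collections.by_type.items()}
    min_pts = config.min_pts
    if min_pts is None:
        depth = estimate_depth(bam_path, contigs)
        min_pts = max(2, int(depth // 10))
        logger.info("estimated depth %.1f -> min_pts %d", depth, min_pts)
    clusters = cluster_signatures(collections.by_type, config.epsilon, min_pts)
    n_clusters = {t: len(c) for t, c in clusters.items()}
    gt_params = GenotypingParams.for_technology(config.technology)
    calls = genotype_clusters(
        clusters, collections.alignments, gt_params, epsilon=config.epsilon
    )
    logger.info(
        "signatures %s, clusters %s, calls %d", n_sigs, n_clusters, len(calls)
    )
    return calls


def run_call(
    bam_path: str,
    reference: str,
    out_vcf: str,
    config: CallConfig | None = None,
    sample: str = "SAMPLE",
) -> list[GenotypedSV]:
    contigs = reference_contigs(reference)
    calls = call_svs(bam_path, contigs, config)
    write_vcf(calls, contigs, out_vcf, reference=reference, sample=sample)
    return calls
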