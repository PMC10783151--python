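"""Bayesian genotyping of candidate SVs from clustered signatures.

Each signature cluster is consolidated into one candidate SV whose
breakpoints are the rounded means of the member coordinates.  Genotyping
then revisits every read alignment spanning the candidate locus: a read
carrying one of the cluster's signatures is an alternative-allele (SV)
call, a spanning read without one is a reference (REF) call.  Four
likelihoods combine the two possible sequenced alleles with the two call
types:

  P(SV call  | SV allele)  — density of the observed signature length under
                             the cluster's length distribution, scaled by a
                             technology-dependent normalization (HTS factor)
  P(SV call  | REF allele) — fixed misalignment/error probability (1e-4)
  P(REF call | SV allele)  — fixed probability of an error reverting the SV (1e-3)
  P(REF call | REF allele) — fixed (0.999)

Per diploid genotype g in {0/0, 0/1, 1/1}, the log10-likelihood sums over
calls the log of the equal-weight mixture of the two allele copies;
posteriors follow from a genotype prior, the maximum a posteriori genotype
is reported with a phred-scaled quality, and homozygous-reference calls are
filtered out.  Genotyped insertions whose supporting intra-alignment
signatures are spread widely in reference coordinates are reclassified as
duplications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import norm

from clustersv.clustering import SignatureCluster
from clustersv.signatures import (
    SV_DEL,
    SV_DUP,
    SV_INS,
    SV_INV,
    ORIGIN_INTRA,
    CompactAlignment,
)

GT_HOM_REF = "0/0"
GT_HET = "0/1"
GT_HOM_ALT = "1/1"
_GENOTYPES = (GT_HOM_REF, GT_HET, GT_HOM_ALT)
_LOG10 = math.log(10.0)


def _round_half_down(x: float) -> int:
    """Nearest integer, ties toward the lower value (deterministic)."""
    return math.ceil(x - 0.5)


@dataclass
class CandidateSV:
    chrom: str
    first: int
    last: int
    length: int
    sv_type: str
    source_cluster: SignatureCluster
    length_mean: float
    length_sd: float
    intra_firsts: list[int] = field(default_factory=list)


@dataclass
class AlleleCall:
    read_id: str
    supports: str  # "SV" or "REF"
    observed_length: Optional[int] = None


@dataclass
class GenotypingParams:
    """Constants of the four-case likelihood model.

    ``hts_factor`` normalizes the length-model density for the sequencing
    technology and its error rate (1.0 for HiFi-like, 0.5 for ONT-like
    inputs); ``genotype_prior`` is over (0/0, 0/1, 1/1).
    """

    p_sv_call_given_ref: float = 0.0001
    p_ref_call_given_sv: float = 0.001
    p_ref_call_given_ref: float = 0.999
    hts_factor: float = 1.0
    genotype_prior: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    length_sd_floor: float = 5.0
    density_floor: float = 1e-6
    quality_cap: float = 255.0

    def __post_init__(self) -> None:
        for p in (self.p_sv_call_given_ref, self.p_ref_call_given_sv, self.p_ref_call_given_ref):
            if not 0.0 < p < 1.0:
                raise ValueError("likelihood constants must lie in (0, 1)")
        if abs(sum(self.genotype_prior) - 1.0) > 1e-9:
            raise ValueError("genotype prior must sum to 1")

    @classmethod
    def for_technology(cls, technology: str, **kwargs) -> "GenotypingParams":
        factors = {"hifi": 1.0, "ont": 0.5}
        try:
            return cls(hts_factor=factors[technology.lower()], **kwargs)
        except KeyError:
            raise ValueError(f"unknown technology {technology!r}; expected 'hifi' or 'ont'")


@dataclass
class GenotypedSV:
    chrom: str
    first: int
    last: int
    length: int
    sv_type: str
    final_type: str
    genotype: str
    quality: float
    n_sv_reads: int
    n_ref_reads: int
    intra_firsts: list[int] = field(default_factory=list)


def cluster_to_candidate(cluster: SignatureCluster) -> CandidateSV:
    """Consolidate a cluster into one candidate SV.

    Breakpoints are the means of the member first/last coordinates, rounded
    to the nearest integer (ties toward the lower coordinate).  The length
    is ``last - first`` except for insertions, where it is the rounded mean
    of the member signature lengths.
    """
    if not cluster.members:
        raise ValueError("cannot consolidate an empty cluster")
    firsts = [s.first for s in cluster.members]
    lasts = [s.last for s in cluster.members]
    lengths = np.array([s.length for s in cluster.members], dtype=float)
    first = _round_half_down(sum(firsts) / len(firsts))
    if cluster.sv_type == SV_INS:
        last = first
        length = _round_half_down(float(lengths.mean()))
    else:
        last = _round_half_down(sum(lasts) / len(lasts))
        length = last - first
    return CandidateSV(
        chrom=cluster.chrom,
        first=first,
        last=last,
        length=length,
        sv_type=cluster.sv_type,
        source_cluster=cluster,
        length_mean=float(lengths.mean()),
        length_sd=float(lengths.std()),
        intra_firsts=[s.first for s in cluster.members if s.origin == ORIGIN_INTRA],
    )


class AlignmentIndex:
    """Interval index over compact alignments for spanning-read queries."""

    def __init__(self, alignments: list[CompactAlignment]):
        self._trees: dict[str, IntervalTree] = {}
        for ca in alignments:
            tree = self._trees.setdefault(ca.chrom, IntervalTree())
            tree.addi(ca.ref_start, ca.ref_end + 1, ca)

    def spanning(self, chrom: str, first: int, last: int) -> list[CompactAlignment]:
        """Alignments whose span covers [first, last] entirely."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(first, last + 1)]
        hits = [ca for ca in hits if ca.ref_start <= first and ca.ref_end >= last]
        hits.sort(key=lambda ca: (ca.ref_start, ca.ref_end, ca.read_id))
        return hits


def collect_allele_calls(candidate: CandidateSV, index: AlignmentIndex) -> list[AlleleCall]:
    """One allele call per read alignment spanning the candidate locus.

    A spanning alignment supports the SV allele iff it carries a member
    signature of the candidate's own source cluster; signatures of other
    clusters at the locus do not count.
    """
    uids = candidate.source_cluster.member_uids
    sig_len = {s.uid: s.length for s in candidate.source_cluster.members}
    span_end = candidate.last if candidate.sv_type != SV_INS else candidate.first + 1
    calls: list[AlleleCall] = []
    for ca in index.spanning(candidate.chrom, candidate.first, span_end):
        carried = [u for u in ca.signature_refs if u in uids]
        if carried:
            calls.append(AlleleCall(ca.read_id, "SV", observed_length=sig_len[carried[0]]))
        else:
            calls.append(AlleleCall(ca.read_id, "REF"))
    return calls


def call_likelihoods(
    call: AlleleCall, candidate: CandidateSV, params: GenotypingParams
) -> tuple[float, float]:
    """log10 P(call | SV allele), log10 P(call | REF allele)."""
    if call.supports == "SV":
        sd = max(candidate.length_sd, params.length_sd_floor)
        density = norm.pdf(call.observed_length, loc=candidate.length_mean, scale=sd)
        p_sv = max(density * params.hts_factor, params.density_floor)
        return math.log10(p_sv), math.log10(params.p_sv_call_given_ref)
    return math.log10(params.p_ref_call_given_sv), math.log10(params.p_ref_call_given_ref)


def genotype_posteriors(
    candidate: CandidateSV, calls: list[AlleleCall], params: GenotypingParams
) -> np.ndarray:
    """Posterior probabilities over (0/0, 0/1, 1/1); sums to 1."""
    loglik = np.zeros(3)
    for call in calls:
        lsv, lref = call_likelihoods(call, candidate, params)
        loglik[0] += lref
        loglik[2] += lsv
        # heterozygous: equal-weight mixture of the two allele copies
        m = max(lsv, lref)
        loglik[1] += math.log10(0.5) + m + math.log10(
            10.0 ** (lsv - m) + 10.0 ** (lref - m)
        )
    logpost = loglik + np.log10(params.genotype_prior)
    logpost -= logpost.max()
    post = 10.0 ** logpost
    return post / post.sum()


def genotype_candidate(
    candidate: CandidateSV, calls: list[AlleleCall], params: GenotypingParams
) -> Optional[GenotypedSV]:
    """Maximum-a-posteriori genotype of a candidate, or None.

    Returns None when no alignment spans the locus, when no read supports
    the SV, or when the best genotype is homozygous reference (such calls
    are considered unsupported and filtered).
    """
    if not calls:
        return None
    n_sv = sum(1 for c in calls if c.supports == "SV")
    if n_sv == 0:
        return None
    post = genotype_posteriors(candidate, calls, params)
    best = int(post.argmax())
    if _GENOTYPES[best] == GT_HOM_REF:
        return None
    err = 1.0 - post[best]
    quality = params.quality_cap if err <= 0 else min(-10.0 * math.log10(err), params.quality_cap)
    return GenotypedSV(
        chrom=candidate.chrom,
        first=candidate.first,
        last=candidate.last,
        length=candidate.length,
        sv_type=candidate.sv_type,
        final_type=candidate.sv_type,
        genotype=_GENOTYPES[best],
        quality=quality,
        n_sv_reads=n_sv,
        n_ref_reads=len(calls) - n_sv,
        intra_firsts=list(candidate.intra_firsts),
    )


def reclassify_duplications(
    genotyped: list[GenotypedSV], epsilon: float = 250.0
) -> list[GenotypedSV]:
    """Relabel insertions with widely spread intra signatures as duplications.

    An insertion whose supporting intra-alignment signatures span a
    first-coordinate range exceeding max(epsilon, call length) is taken to
    be a tandem/dispersed duplication rather than a novel insertion.
    """
    for sv in genotyped:
        if sv.final_type == SV_INS and len(sv.intra_firsts) >= 2:
            spread = max(sv.intra_firsts) - min(sv.intra_firsts)
            if spread > max(epsilon, sv.length):
                sv.final_type = SV_DUP
    return genotyped


def genotype_clusters(
    clusters_by_type: dict[str, list[SignatureCluster]],
    alignments: list[CompactAlignment],
    params: GenotypingParams | None = None,
    epsilon: float = 250.0,
) -> list[GenotypedSV]:
    """Full cluster → genotyped-SV stage, sorted by (chrom, first)."""
    params = params or GenotypingParams()
    index = AlignmentIndex(alignments)
    out: list[GenotypedSV] = []
    for clusters in clusters_by_type.values():
        for cluster in clusters:
            candidate = cluster_to_candidate(cluster)
            calls = collect_allele_calls(candidate, index)
            sv = genotype_candidate(candidate, calls, params)
            if sv is not None:
                out.append(sv)
    out = reclassify_duplications(out, epsilon=epsilon)
    out.sort(key=lambda sv: (sv.chrom, sv.first, sv.last, sv.final_type))
    return out
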