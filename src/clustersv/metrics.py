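"""Benchmark metrics: call matching and precision/recall/genotype scores.

Test calls are matched one-to-one against a truth set under breakpoint
distance and reciprocal-overlap criteria, then summarized as

    Precision = TP / (TP + FP)          Recall = TP / (TP + FN)
    Fscore    = harmonic mean of precision and recall
    GTAccuracy = (HOM^HOM + HET^HET) / (all genotyped TP cells)
    GTFscore  = harmonic mean of GTAccuracy and recall

where the genotype cells classify true positives by truth genotype
(superscript: HOM = 1/1, HET = 0/1) against the called genotype.
Homozygous-reference truth records are excluded before matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from clustersv.signatures import SV_DEL, SV_DUP, SV_INS, SV_INV
from clustersv.vcf_io import VcfSvRecord

_SPANNING = (SV_DEL, SV_INV)


@dataclass
class MatchCriteria:
    """Criteria for calling a test/truth pair a match.

    Spanning types (DEL/INV) must reciprocally overlap by at least
    ``reciprocal_overlap``; point types (INS/DUP) must instead satisfy the
    same threshold on their length ratio min(L1,L2)/max(L1,L2).  All pairs
    must have breakpoints within ``max_breakpoint_distance`` bp.
    """

    max_breakpoint_distance: int = 500
    reciprocal_overlap: float = 0.70
    require_type_match: bool = True
    regions: Optional[list[tuple[str, int, int]]] = None

    def __post_init__(self) -> None:
        if not 0 < self.reciprocal_overlap <= 1:
            raise ValueError("reciprocal_overlap must lie in (0, 1]")


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]  # (test index, truth index)
    fp: list[int]
    fn: list[int]


@dataclass
class PerformanceReport:
    tp: int
    fp: int
    fn: int
    hom_tp_hom: int  # called HOM, truth HOM
    het_tp_het: int  # called HET, truth HET
    hom_tp_het: int  # called HOM, truth HET
    het_tp_hom: int  # called HET, truth HOM
    precision: float
    recall: float
    f_score: float
    gt_accuracy: float
    gtf_score: float
    precision_defined: bool = True
    recall_defined: bool = True

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _types_compatible(a: str, b: str) -> bool:
    # duplications are a subclass of insertion evidence
    ins_like = {SV_INS, SV_DUP}
    return a == b or (a in ins_like and b in ins_like)


def _similarity(test: VcfSvRecord, truth: VcfSvRecord) -> float:
    """Reciprocal overlap for spanning types, length ratio for point types."""
    if test.svtype in _SPANNING and truth.svtype in _SPANNING:
        s1, e1 = test.span
        s2, e2 = truth.span
        inter = min(e1, e2) - max(s1, s2)
        if inter <= 0 or e1 <= s1 or e2 <= s2:
            return 0.0
        return min(inter / (e1 - s1), inter / (e2 - s2))
    l1, l2 = abs(test.svlen), abs(truth.svlen)
    if l1 == 0 or l2 == 0:
        return 0.0
    return min(l1, l2) / max(l1, l2)


def _breakpoint_distance(test: VcfSvRecord, truth: VcfSvRecord) -> int:
    if test.svtype in _SPANNING and truth.svtype in _SPANNING:
        return max(abs(test.pos - truth.pos), abs(test.end - truth.end))
    return abs(test.pos - truth.pos)


def _restrict(records: list[VcfSvRecord], regions) -> list[VcfSvRecord]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    return [r for r in records if r.chrom in trees and trees[r.chrom].overlaps(r.pos)]


def match_calls(
    test: list[VcfSvRecord], truth: list[VcfSvRecord], criteria: MatchCriteria | None = None
) -> MatchResult:
    """Greedy one-to-one matching of test calls against truth calls.

    Candidate pairs share a compatible SV type (when required), lie within
    the breakpoint-distance bound, and pass the reciprocal-overlap /
    length-ratio threshold.  Pairs are consumed by ascending breakpoint
    distance (ties toward larger overlap); each record matches at most
    once.  Unmatched test records are FP, unmatched truth records FN.
    """
    criteria = criteria or MatchCriteria()
    if criteria.regions is not None:
        test = _restrict(test, criteria.regions)
        truth = _restrict(truth, criteria.regions)

    candidates = []
    for ti, t in enumerate(test):
        for gi, g in enumerate(truth):
            if t.chrom != g.chrom:
                continue
            if criteria.require_type_match and not _types_compatible(t.svtype, g.svtype):
                continue
            dist = _breakpoint_distance(t, g)
            if dist > criteria.max_breakpoint_distance:
                continue
            sim = _similarity(t, g)
            if sim < criteria.reciprocal_overlap:
                continue
            candidates.append((dist, -sim, ti, gi))

    candidates.sort()
    used_test: set[int] = set()
    used_truth: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, ti, gi in candidates:
        if ti in used_test or gi in used_truth:
            continue
        used_test.add(ti)
        used_truth.add(gi)
        pairs.append((ti, gi))
    fp = [i for i in range(len(test)) if i not in used_test]
    fn = [i for i in range(len(truth)) if i not in used_truth]
    return MatchResult(pairs=sorted(pairs), fp=fp, fn=fn)


def _harmonic(a: float, b: float) -> float:
    return 0.0 if a + b == 0 else 2 * a * b / (a + b)


def performance_report(
    matches: MatchResult, test: list[VcfSvRecord], truth: list[VcfSvRecord],
    criteria: MatchCriteria | None = None,
) -> PerformanceReport:
    """Compute the five benchmark metrics from a match assignment.

    Genotype cells only count true positives where both sides carry a
    non-reference genotype call.  When TP + FP (or TP + FN) is zero the
    corresponding rate is reported as 0 and flagged undefined.
    """
    if criteria is not None and criteria.regions is not None:
        test = _restrict(test, criteria.regions)
        truth = _restrict(truth, criteria.regions)
    tp, fp, fn = len(matches.pairs), len(matches.fp), len(matches.fn)
    cells = {"hom_hom": 0, "het_het": 0, "hom_het": 0, "het_hom": 0}
    for ti, gi in matches.pairs:
        called, true = test[ti].gt, truth[gi].gt
        if called not in ("0/1", "1/1") or true not in ("0/1", "1/1"):
            continue
        true_k = "hom" if true == "1/1" else "het"
        called_k = "hom" if called == "1/1" else "het"
        cells[f"{true_k}_{called_k}"] += 1

    precision_defined = tp + fp > 0
    recall_defined = tp + fn > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    recall = tp / (tp + fn) if recall_defined else 0.0
    n_cells = sum(cells.values())
    gt_accuracy = (cells["hom_hom"] + cells["het_het"]) / n_cells if n_cells else 0.0
    return PerformanceReport(
        tp=tp,
        fp=fp,
        fn=fn,
        hom_tp_hom=cells["hom_hom"],
        het_tp_het=cells["het_het"],
        hom_tp_het=cells["het_hom"],
        het_tp_hom=cells["hom_het"],
        precision=precision,
        recall=recall,
        f_score=_harmonic(precision, recall),
        gt_accuracy=gt_accuracy,
        gtf_score=_harmonic(gt_accuracy, recall),
        precision_defined=precision_defined,
        recall_defined=recall_defined,
    )


def benchmark_vcfs(
    test_path: str, truth_path: str, criteria: MatchCriteria | None = None
) -> PerformanceReport:
    """Convenience wrapper: read both VCFs, match, and report."""
    from clustersv.vcf_io import read_vcf

    criteria = criteria or MatchCriteria()
    test = read_vcf(test_path)
    truth = read_vcf(truth_path, truth_mode=True)
    matches = match_calls(test, truth, criteria)
    return performance_report(matches, test, truth, criteria)
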