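# Methods

This note documents the models, conventions, and numerical choices behind
`clustersv`, and what the bundled simulator does and does not emulate.

## Coordinates and data model

All internal coordinates are 1-based with half-open spans `[first, last)`.
For deletions and inversions `length == last − first` holds exactly;
insertions are point events with `last == first`, anchored at the base
preceding the inserted sequence. On VCF output, POS is the anchor base
before the event (`first − 1` for DEL/INV, `first` for INS/DUP), SVLEN is
negative for deletions, and `END − POS == |SVLEN|` for spanning types while
`END == POS` for point events. Averaged cluster coordinates are rounded to
the nearest integer with ties toward the lower coordinate, so results are
deterministic.

A `Signature` is one read-level SV signal; a `CompactAlignment` is the
minimal per-(read, chromosome) record kept for genotyping — the union span
of the read's aligned segments plus references to the signatures it
contributed. Using the union span (rather than one record per SAM line)
means reads that detect a large deletion through split alignments still
count as spanning that locus when it is genotyped.

## Signature collection

Intra-alignment deletions and insertions are read off CIGAR `D`/`I` runs at
least `min_sv_length` (default 50 bp, the conventional SV size floor).
Secondary alignments and records below mapping quality 20 (configurable)
are skipped; supplementary alignments are kept as partial alignments.
Partials of one read are grouped by name and re-sorted by query coordinate
before the inter-alignment rules run, so results do not depend on file
order.

Inter-alignment rules, applied to consecutive partials on one chromosome
and strand:

- **Deletion**: reference gap between the end of the left partial and the
  start of the right partial, kept when `min_sv_length ≤ gap ≤ 100 kb`.
  The upper bound (configurable) exists only to avoid pairing partials
  that almost certainly belong to different events.
- **Insertion**: requires *adjacent* partials (reference gap ≤ 100 bp,
  configurable; the notion of adjacency needs a quantitative cutoff and
  100 bp comfortably covers breakpoint ambiguity at a junction). The
  longest junction-facing soft clip (LSC) is taken over both partials, and
  the aligned reference length of the partial *not* carrying the LSC is
  subtracted from it. Hard clips are counted like soft clips, since
  aligners may emit either for supplementary records. The signature is
  anchored at the start of the reference-right partial.
- **Inversion**: three consecutive partials with strand pattern +/−/+ or
  −/+/−; the signature takes the middle alignment's span and length.

## Clustering

Signatures are embedded as (start, end, length) vectors and clustered with
DBSCAN under the Euclidean distance, independently per SV type and per
chromosome (signatures on different chromosomes can never describe the
same event). Neighborhood is strict (`m < ε`); a point is core when it has
at least `min_pts` neighbors, the point itself not counted. Clusters are
connected components of core points under ε-adjacency together with their
non-core neighbors; a non-core point adjacent to cores of two clusters is
assigned to the cluster of the core point earliest in canonical
(chrom, first, last, length, read id) order, which removes the classic
order-dependence of DBSCAN border points and makes output permutation
invariant.

Neighbor search is a sliding window over signatures sorted by start
coordinate: since |ΔB| is a lower bound on the distance, pairs with
|ΔB| ≥ ε need never be compared, and the windowed graph is provably
identical to the complete-graph construction (the test suite asserts exact
equivalence against a brute-force density-reachability closure).

Defaults: `ε = 250` bp, and `min_pts = max(2, depth/10)` where mean depth
is estimated from the input alignments (total aligned bases over genome
size); both are CLI-exposed. The depth scaling keeps the support
requirement proportional to coverage: a heterozygous event at depth *d*
contributes on average *d*/2 signatures, so a fixed support threshold
either drops real heterozygotes at low depth or admits noise at high
depth. With the 50 bp signature floor, clusters of ≥ 3 coincident
signatures are already very unlikely to arise from sequencing error.

## Genotyping

For each candidate (averaged cluster), allele calls are collected from all
compact alignments spanning the locus: SV if the alignment carries a
member signature of that candidate's own cluster (signatures of other
clusters at the same locus count as REF), REF otherwise. Four likelihoods
cover the {call} × {sequenced allele} combinations:

| Call | Allele | Likelihood |
| ---- | ------ | ---------- |
| SV   | SV     | Normal(observed length; μ = cluster mean length, σ = max(cluster SD, 5 bp)) × HTS factor, floored at 10⁻⁶ |
| SV   | REF    | 10⁻⁴ (misalignment / error mimicking the SV) |
| REF  | SV     | 10⁻³ (error reverting the SV) |
| REF  | REF    | 0.999 |

The length model treats the cluster's observed signature lengths as draws
around the true allele length; a Normal with a 5 bp dispersion floor is
robust to single-length clusters, and the density floor keeps
log-likelihoods finite for far outliers. The HTS factor is a
technology-dependent normalization of the length-model density — 1.0 for
HiFi, 0.5 for ONT (selected by `--technology`), reflecting the broader
length scatter of noisier reads. These two constants are deliberately
simple; they rescale all SV-supporting evidence uniformly and mainly
affect borderline het/hom decisions.

Per genotype, the log₁₀-likelihood sums over calls the equal-weight (0.5)
mixture of the two allele-copy likelihoods — the standard diploid mixture.
Posteriors use a uniform prior over {0/0, 0/1, 1/1} by default
(configurable). The maximum-a-posteriori genotype is emitted with quality
−10·log₁₀(1 − posterior), capped at phred 255 to avoid infinities;
candidates whose best genotype is 0/0, with no spanning reads, or with no
SV-supporting read are filtered as unsupported.

Duplication reclassification runs after genotyping: an insertion call
whose supporting intra-alignment signatures span a first-coordinate range
greater than max(ε, call length) is relabeled DUP — reads sampling
different copies of a duplicated segment report the same inserted sequence
at scattered anchor points, unlike a novel insertion whose signatures pile
up at one anchor.

## Benchmarking

Matching is greedy one-to-one by ascending breakpoint distance (ties
toward larger overlap): pairs must share a compatible SV type (DUP matches
INS), lie within 500 bp breakpoint distance (Truvari's documented default,
configurable), and pass the 70% reciprocal-overlap threshold — computed as
the min of the two mutual span-overlap fractions for deletions/inversions,
and as the length ratio min(L₁,L₂)/max(L₁,L₂) for insertions, which have
no span. Truth records with genotype 0/0 are excluded. An optional BED
restricts both sides. GT accuracy is computed over true positives where
both sides carry a non-reference genotype; GTF score is the harmonic mean
of GT accuracy and recall. When TP + FP (or TP + FN) is zero the rate is
reported as 0 and flagged undefined rather than NaN.

## Simulator

The simulator emulates the structure of a long-read SV benchmark — a
diploid genome with implanted, non-overlapping events and reads whose
alignments carry exactly the signatures a mapper would produce — without
any mapping step: alignments are constructed analytically in reference
coordinates. Defaults: events 50–500 bp spaced ≥ 1 kb and kept 20 kb from
genome ends, half heterozygous; reads Normal(15 kb, 3 kb) truncated at
1 kb; depth split evenly between haplotypes. Events ≥ 1 kb (split
threshold) become split partial alignments — mirroring mappers, which
represent large events as supplementary records — and smaller ones CIGAR
runs. The ONT-like profile uses 4% mismatches, a 5% small-indel rate with
geometric lengths (mean 2 bp, capped at 49 bp so errors never reach SV
size), and 10 bp breakpoint jitter; the HiFi-like profile 0.2%/0.5%/2 bp;
an error-free profile disables all three. Jitter shifts where an implanted
event sits inside the CIGAR (transferring matched bases across the run)
without changing its length, emulating alignment ambiguity at junctions.

What the simulator does **not** emulate, and what passing tests therefore
do not demonstrate about real data: reference repeats and segmental
duplications (the main cause of ambiguous mappings and false calls in real
genomes), context-dependent error hotspots such as homopolymers, mapper
idiosyncrasies in clip placement and supplementary-record generation,
chimeric reads, and breakpoint-length co-variation. Accuracy on the
simulator is accordingly an upper bound; the depth-scaled `min_pts`
default is conservative partly for this reason.

Determinism: a fixed seed fixes the genome, truth set, read set, SAM
bytes, and ledger bytes. Internal seeds are spawned per stage from the
user seed, so changing one stage's parameters does not perturb another's
random stream.

## Test and benchmark problem sizes

The acceptance-level checks run a 2 Mb genome with 380 indel events at 20×
(ONT profile) for the F-score and genotype-concordance checks, and a 1 Mb
genome at 30× (error-free) for the high-depth concordance check — sizes
chosen so the full suite completes in about a minute while each event
still receives realistic per-locus coverage. Clustering is verified
exactly against a brute-force density-reachability oracle on 200+ random
instances of up to 100 points, and signature extraction against an
independent CIGAR walker on 1,000 random CIGARs.

## Known limitations

- Translocations and breakend (BND) records are out of scope; copy-number
  estimation is not performed (duplications are detected only via the
  insertion-signature spread heuristic).
- One sample, germline, diploid; no joint calling or phasing.
- Insertion comparison in the benchmark uses length ratio, not inserted
  sequence similarity.
- The genotype prior is uniform by default; a population-informed prior
  would sharpen low-depth calls.
- Single-threaded; per-chromosome parallelism would be straightforward but
  is not implemented.
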