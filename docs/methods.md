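# Methods

This note documents the models, parameter choices and numerical decisions
behind `cagesel`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and input model

CTSS tables use 1-based single positions (the CAGEr/FANTOM dialect); all
internal interval arithmetic is 0-based half-open, and the conversion is an
involution. A tag's 27-nt body runs 3′-ward from its 5′ end, so on the
minus strand the body spans the 27 nt *ending* at the 5′-end coordinate
(CAGE reads run 5′→3′ from the cap). The pipeline deliberately starts at
mapped CTSS counts: read QC, trimming and alignment are upstream concerns,
and BAM ingestion is out of scope.

The optional G-addition correction stage uses a deterministic single-base
rule — a tag whose sequenced first base is G over a non-G genomic base is
moved 1 nt 3′-ward — rather than probabilistic reallocation. It requires a
per-row `first_nt` column, because a 4-column CTSS table carries no read
sequence; it is off by default.

## Tag clustering

Merging is single-linkage over same-strand tag bodies that overlap by ≥ 1
nt; clustering is therefore order-independent and matches a transitive
closure of pairwise overlaps (property-tested against a brute-force
union-find oracle). The ≥ 4-tag rule is a *global* threshold justified by
the Poisson background model λ = (n−1)·tag_length·T/N, not a per-cluster
filter: every kept cluster's background p-value is computed and asserted
≤ α (0.001), and the run aborts loudly if the configured (N, T) cannot
support the threshold.

N defaults to the GRCh37 assembly length (3,095,693,983 nt) even when a
FASTA is supplied, because a synthetic genome contains only gene loci —
its literal length would violate the uniform-background assumption the
model encodes. T defaults to the sample's summed tag count and can be
overridden with an external uniquely-mapped total.

## Representative TSS and feature assignment

A TC's single position is its representative TSS, the position of maximal
tag count. Ties break toward the 5′-most position; this favours the
longest 5′UTR and is therefore conservative for downstream-AUG analyses.
Feature priority is 5′UTR > 3′UTR > CDS > intron, with the 100 nt upstream
of each annotated 5′UTR counted as 5′UTR; assignment is deterministic and
priority-monotone. The feature distribution is tallied per TC (not per
tag).

5′UTR length is the strand-aware distance from the representative TSS to
the first base of the nearest downstream annotated start codon of the TC's
gene. When several transcripts of the gene contain the TSS in their
extended 5′UTR, the transcript whose annotated TSS is nearest wins — the
least surprising resolution where annotation is ambiguous. Lengths are
genomic distances; the generator's gene models keep the 5′UTR and start
codon on one exon (the two-exon variants place the intron inside the
5′UTR), so no spliced-distance correction is attempted.

## Shape classes

Classification applies only to TCs with ≥ 100 tags (configurable) and
evaluates the criteria strictly in order, first match wins:

1. **SP** if q75 − q25 < 4 nt or q85 − q15 < 6 nt;
2. **DP** if peak1/peak2 > 2 and peak1 > 20% of tags;
3. **MP** if ≥ 2 peaks each hold > 15% of tags and every consecutive pair
   (sorted by coordinate) is > 5 nt apart;
4. **BP** otherwise.

Percentiles use the nearest-rank method on the tag-weighted position
multiset — positions are integers and no interpolation rule is implied by
the criteria. A "peak" is the count at a single genomic position, and
"distance" is the absolute coordinate difference. The implementation is
required (by an acceptance test) to agree exactly with an independently
coded literal transcription of these rules on 1000 random clusters.

## Disparity testing

Translatome/transcriptome TCs are paired by same-strand span overlap;
many-to-many overlaps resolve greedily to the pair with maximal
shared-position tag mass (ties by overlap length, then ids, for
determinism). Pairs with ≥ 100 tags on both sides are tested with a
two-sample KS test on the tag-position multisets, each tag one sample
point. p-values use the asymptotic KS distribution despite ties; ties on a
discrete support make the test conservative, which the Monte-Carlo
calibration confirms (null rejection at p < 0.001 stays below 0.005 with
500-tag pairs). A permutation fallback is available for small clusters
(default off). `changed` uses the raw p < 0.001 rule; BH-adjusted q-values
are reported alongside, since both conventions appear in practice.

## Differential abundance and gene scores

The two-library comparison uses an exact binomial test: conditional on the
pair total k₁ + k₂, k₁ is Binomial with success probability T₁/(T₁+T₂)
under the null of equal relative abundance. This replaces a named
R-package dependency with a reproducible, oracle-checkable statistic of
the same spirit (two libraries, no replicates). The test is exact and
hence slightly conservative on discrete counts; at the depths where TCs
are tested (hundreds of tags) the type-I error at α = 0.05 sits near
0.044, within the calibration band the acceptance suite enforces. The
calibration null draws pair totals around 500 tags, a typical tested-TC
depth.

A TC pair is enriched at log₂ FC ≥ 1 and p < 0.05, depleted at ≤ −1;
single-sided pairs become `translatome_only`/`transcriptome_only` with FC
undefined rather than infinite. Gene-level S_fc is reported on RPM but its
p-value comes from the binomial test on *summed raw counts* — tests need
counts, ratios need normalisation. A gene's promoter list is its matched
5′UTR TC pairs, with unmatched single-sample TCs entering as 0 on the
absent side; this is what makes S_du = 1 (disjoint support) reachable.
S_du is computed for all genes but reported for genes with ≥ 2 promoters,
where it is informative; for n = 1 the equation gives 0 identically.

The RPM-matched gene-group selection ranks the "unchanged" band
(0.9 < S_fc < 1.1) by transcriptome RPM *descending*, which is what makes
the three groups' average transcriptome abundance comparable to the
enriched/depleted groups drawn from the top of their p-value rankings.

From the disparity stage onward the analysis is restricted to TCs assigned
to (extended) 5′UTRs — those are the TCs that act as core promoters; the
transcriptome member's assignment governs a matched pair.

## Sequence windows

The downstream window is positions 1–100 in transcript orientation with
the representative TSS at position 1; the upstream window is the 100 nt
immediately 5′ of it. AUG counting is overlap-aware (sliding scan). The
TATA detector defaults to the TATAWAW consensus `TATA[AT]A[AT]`,
configurable because no single canonical detector exists; enrichment is
the ratio of windows-containing-a-match rates with a Fisher exact p. The
control group is drawn uniformly (fixed seed) from the FC ∈ (0.95, 1.05)
band.

## Synthetic data generator

The generator emulates the statistical structure each stage consumes:

* **Gene models**: single- or two-exon transcripts with explicit
  UTR/CDS so feature priority and intron assignment are both exercised;
  1–3 promoters per gene (default mix 0.3/0.4/0.3, mean 2.0); genes laid
  out contiguously on two chromosomes.
* **Shape emitters**: SP (85% of mass on one position, ±2 nt tails), DP
  (35% dominant peak over a σ = 8 nt base), MP (2–3 peaks ≥ 15% separated
  > 5 nt), BP (discretised normal, σ ∈ [8, 12] nt); default mix
  0.45/0.25/0.10/0.20, in line with published promoter-architecture
  surveys.
* **Abundance**: log-normal baselines (median 30 tags, σ_log = 1.2);
  30% of TCs (or genes, configurable scope) carry a planted log₂ fold
  change of magnitude 1–3 split symmetrically between conditions; an
  independent 20% of genes get their translatome promoter usage
  redistributed by a Dirichlet draw that preserves the gene total, so
  abundance and usage effects are independent by construction.
* **Disparity**: 30% of TCs have the transcriptome emitter shifted 5–10 nt
  downstream.
* **Sequence context**: i.i.d. genome with planted first-nucleotide
  composition at representative TSSs, TATAWAW boxes at −31 (50% of
  enriched vs 8% of other promoters), and downstream GC of 0.35/0.45/0.55
  for enriched/neutral/depleted promoters plus extra planted AUGs for
  enriched ones.
* **Noise**: 1% of each library as uniform single-tag background.
* **Testability**: any truth TC that would draw fewer than 4 tags in both
  conditions is topped up in its better condition from that condition's
  most abundant TC, so the truth key contains no silently untestable
  entries and library sizes are preserved.

Default scale is ~2×10⁴ TCs and 10⁶ tags per condition, sized so the full
pipeline completes in a couple of minutes on one CPU; tests and the
analysis scripts use smaller instances of the same conditions. Identical
configs produce byte-identical files.

What passing on synthetic data does **not** show: robustness to
mappability artefacts, sequencing error, G-addition bias (the generator
plants none), real promoter sequence grammar, overlapping/antisense gene
structure, or replicate-level biological variability (the two-library
design has no replicates, which is exactly why the exact binomial test is
used).

## Known limitations

* The KS p-values are asymptotic and conservative under heavy ties; very
  sharp (SP) promoter pairs lose power, so disparity sensitivity is
  quoted for distributions with spread.
* Cluster matching is 1:1 greedy; a promoter that genuinely splits into
  two clusters in one condition contributes one matched pair plus one
  single-sided record rather than a 2:1 match.
* 5′UTR lengths are genomic, not spliced, distances.
* Motif discovery and logo rendering are out of scope; group FASTAs are
  exported for external tools.
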