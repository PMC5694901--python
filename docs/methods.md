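# Methods

This note documents the statistical models, parameter choices and known
limitations of starrkit, and what the synthetic-data generator does and
does not emulate.

## Coordinates and overlap conventions

All coordinates are 0-based half-open (BED convention).  Strand is
carried on reads and genes but ignored by every fragment/peak overlap
operation: genomic-DNA inserts and peak regions are unstranded objects.
"Overlap" always means ≥ 1 shared base pair.  Nearest-gene assignment
minimizes |region centre − TSS| with ties broken toward the smaller TSS
coordinate, then lexicographic gene id; the choice of a TSS-to-centre
metric (rather than gene-body distance) is a documented package decision.
`nearest_gene` is undefined across chromosomes and errors when no gene
shares the region's chromosome.

## Duplicate handling

PCR/sequencing duplicates cannot be distinguished from biological
duplicates within a single amplified library, so the pipeline collapses
identical `(chrom, start, end)` coordinates within each index
sublibrary to one distinct fragment and then pools distinct fragments
across the index sublibraries, treating cross-index coordinate matches
as independent molecules.  Fragment identity deliberately ignores
strand.  Biological replicates are collapsed per replicate before
pooling; fragments duplicated across replicates count as independent
observations.  There is no UMI support: without molecular barcodes the
multiplicity of a fragment is capped at (indexes × replicates), which
systematically understates the abundance of extremely strong enhancers.

## Peak calling

The caller is a transparent re-implementation of treatment-vs-input
Poisson enrichment scanning:

* windows of `window_size` = 500 bp, stepped by 100 bp, per chromosome;
* expected output count `λ = max(k_in, λ_floor) · N_out / N_in`, where
  the floor defaults to the genome-wide mean input window count and
  guards zero-input windows;
* upper-tail p-value `P(X ≥ k_out)` via the Poisson survival function
  (log-space stable; tails below 1e-250 do not underflow);
* Benjamini–Hochberg step-up across *all* tested windows, q < 0.05
  (0.01 available in config);
* significant windows merged when their gap ≤ 200 bp, merged spans
  trimmed to the outermost base covered by ≥ 1 output fragment (avoids
  window-quantized edges), re-tested on exact fragment counts, and
  BH-corrected again across candidate regions;
* peaks shorter than 200 bp dropped.

Fragments count toward a window or peak when they overlap it by ≥ 1 bp
(containment is not required; this is a documented choice).  Activity is
the scaled distinct-fragment ratio
`(out/N_out)/(in/N_in)` with the input count floored at a 1-fragment
pseudocount.  The estimator is exactly invariant to uniform duplication
of both libraries.

**Edge bias.** Because fragments that only partially overlap a region
are counted in full, a region of length `L` measured with fragments of
length `F` has expected estimated activity
`≈ 1 + (A − 1) · L/(L + F)` for a true fold `A`: sub-kilobase elements
are shrunk toward 1.  This resolution limit is intrinsic to
fragment-level counting and is why the generator's default planted
regions are several-fold longer than the fragments (below).

## Meta-profiles and center enrichment

Regions are aligned on their centres and extended ±10 kb; each 100-bp
bin accumulates pooled read counts across all regions for the signal and
its matched input, both scaled to a nominal 50-M depth; the bin's fold
enrichment is the ratio of the scaled pooled counts (a ratio of means —
the per-region mean-of-ratios alternative is noisier and is not used;
this is a documented choice where the averaging order was ambiguous).
Input bins with zero reads are floored at one read pre-scaling and
flagged; the floor is the only operation that breaks exact scale
invariance, and only in empty bins.  Regions whose centre sits closer
than the half-width to a chromosome edge are dropped and counted.
Per-region ±200-bp centre enrichments use the same scaling and floor.
Heat-map matrices support seeded down-sampling of regions; all summary
statistics always use every region.

## ATAC-seq handling

Aligned ATAC reads are converted to Tn5 cut sites: plus-strand reads
shifted +4 bp, minus-strand reads −5 bp, each then represented as the
1-bp corrected cut site (the centre of the transposition event).  The
operation is not idempotent and must be applied exactly once.

## Differential accessibility

Between-condition testing uses a *common-dispersion negative-binomial
exact test*: counts are library-size normalized to the mean depth,
summed within condition (the sum of n iid NB(μ, α) variables is
NB(nμ, α/n)), and the two condition sums are tested conditionally on
their total, summing the probabilities of all splits no more likely
than the observed one.  The common dispersion is estimated by pooled
method of moments, `α = Σ(v_g − m_g)/Σ m_g²` across regions and groups
(per-region moment estimates at 2–3 replicates are far too noisy, and
their median is biased low).  With fewer than two replicates per
condition the test falls back to Poisson (α = 0); the α → 0 limit of
the NB test reproduces the Poisson exact test.  This deliberately
simple test makes **no claim of equivalence** to per-region GLM
tagwise-dispersion modeling; it is fully specified, exactly testable,
and sufficient for the package's validation surface (simulated truth).

## TSA-response integration

Closed (inaccessible) STARR-active peaks are tabulated against closed
inactive regions by overlap with TSA-induced (accessibility-gain) sites
in a 2×2 table, tested one-sided for enrichment by Fisher's exact test
or by a binomial tail `P(X ≥ a)` against a configurable background rate
(summed in log space so astronomically small p-values survive).  Odds
ratios use the Haldane–Anscombe 0.5 correction when a cell is zero.
Genes are labeled **Class I** when ≥ 1 closed-active region opened by
TSA lies within 50 kb of the TSS (closest region edge to TSS) and no
accessibility-loss site does, **Class II** by the same rule with
closed-*inactive* opened regions (and no closed-active one nearby).
"Translational start site" in the originating description is read as
the annotated TSS; a CDS-start variant is not modeled.  The classes are
disjoint by construction.

## Expression linkage

RPKM = count / (exonic kb × mapped reads in millions).  Rank binning
sorts values ascending (stable ties), splits ranks into contiguous
near-equal bins (remainder to the lowest bins).  Binned summaries report
both mean and median RPKM per bin; tests assert on the median for
robustness, since the source analyses do not state which was used.  Each
peak contributes one observation (its nearest gene's expression, reused
when several peaks share a gene).  The rank-sum test is exact by full
enumeration for tie-free pooled samples of ≤ 12 observations, otherwise
a tie- and continuity-corrected normal approximation; all-identical
pooled values return p = 1.

## The synthetic-data generator

The generator produces a single-chromosome genome (10 Mb default) with
non-overlapping planted regions (minimum 2-kb separation, 12-kb edge
margin): enhancers, closed inactive background regions, and background
accessibility peaks.  Defaults encode the assay's stated conditions:
fragment lengths truncated-normal(500, 60) on [350, 650] bp; 16 index
sublibraries, 2 replicates; 12.7% of enhancers open; activities
log-uniform on [1.5, 20]; 500k fragments per library at full scale
(fixtures and the validation suite use 60k–350k to keep runs fast; the
problem sizes used are stated in each test).

**Activity scale.**  Enhancer activity is *defined* as enrichment of a
region's fragment share relative to the pooled library.  The generator
therefore solves a one-line fixed point for the total sampling weight
`B = G(G − ΣL_e)/(G − ΣA_e L_e)` and plants per-enhancer weights
`w_e = A_e B/G`, so a fragment fully inside an enhancer of activity `A`
is exactly `A`-fold enriched *on the estimator's scale*.  Without this
normalization, the planted-enrichment mass (enhancers cover ~10% of the
toy genome, unlike the real genome where they are a vanishing fraction)
would deflate every measured activity by a common factor.  Output
fragments are sampled with weight `1 + (w_e − 1) · overlap_fraction`,
so partially overlapping fragments are proportionally enriched.

**Planted region length.**  Default U[4000, 6000] bp — several-fold the
fragment length, so the edge bias above stays under ~10% and planted
activities are recoverable by the ratio estimator.  Real enhancers are
often sub-kilobase; at that scale the estimator is biased low as
described, which is a property of fragment-level counting, not of the
generator.

**PCR duplicates** add `Poisson(d/(1−d))` extra reads per molecule
within its index (d = 0.15 default), and the truth object records exact
per-index distinct counts and pooled multiplicities for bookkeeping
tests.

**TSA condition.**  20% of closed *active* enhancers and 5% of closed
*inactive* regions gain accessibility (5-fold) upon treatment — the
asymmetry encodes the observed preferential TSA-inducibility of
STARR-active closed chromatin and yields a desk-scale odds ratio near
4.8.  The real-data fractions (below 1%) would plant ~1 region at 200
enhancers and are not usable at this scale.  Expression levels are
`baseline + coupling · Σ activity` over open (and, under treatment,
TSA-opened) enhancers within 50 kb of the TSS — the same proximity rule
the gene classification uses; expected counts scale with exonic length
(so RPKM recovers the level) and are drawn negative-binomial
(dispersion 0.1) for 3 replicates per condition.

**What the generator does not emulate:** mappability and alignment
artifacts, GC and fragmentation bias, multi-chromosome genomes, isoform
structure, promoter-choice effects, trans effects of TSA beyond local
accessibility, and composition-normalization issues of RPKM (library
size is taken as the column sum, so strong global expression shifts
bleed into per-gene RPKM — visible as a negative median response of
unaffected genes in the TSA example).  Passing the validation suite
therefore demonstrates correctness of the statistics and bookkeeping
under the generative model, not robustness to real-data artifacts.

## Numerical choices

* Poisson and binomial tails computed via survival functions /
  log-space summation; no tail underflows to zero above ~1e-300.
* BH q-values via the standard step-up with monotonicity enforcement;
  input order preserved.
* The NB exact test includes splits tying the observed probability
  (within 1e-10 relative) in the rejection mass.
* Rank-bin ties break by stable input order; bin sizes differ by ≤ 1.
* The window caller requires output > expected in addition to q <
  threshold (one-sided enrichment only).
* All generator randomness flows from one seed through per-operation
  independent streams, so outputs are byte-identical across reruns and
  independent of call order.

## Problem sizes

The validation suite runs at desk scale by design: 10-Mb genomes,
50k–350k fragments, 100–200 planted enhancers, 2000-region
differential-accessibility panels, and 100-replicate power studies for
the gene-class comparison.  The full default configuration (500k
fragments per library) completes the end-to-end pipeline in well under
five minutes on one CPU.
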