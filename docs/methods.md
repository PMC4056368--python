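# Methods

This note documents the models, thresholds and design choices behind
`epivariant`, and what the synthetic cohort does and does not emulate.

## Coordinate and format conventions

All in-memory coordinates are 0-based half-open. GFF3 and the SNP table
are 1-based closed on disk; BED and bedGraph are 0-based half-open.
Conversion happens only in `core_io` readers/writers. Region merging is
strict: intervals combine when the gap between them is *smaller than*
the threshold (300 bp for array regions, 200 bp for sequencing islands),
so a gap exactly at the threshold does not merge. Abutting intervals
(gap 0) merge under any positive threshold. Genes must be stranded
(metagene orientation); TEs and regions may be unstranded.

## Probe placement and admission

Probes are short and ungapped, so placement is Hamming distance on both
strands with a ceiling of two mismatches. Two interchangeable engines
exist: an exhaustive sliding-window scan (the reference and test oracle)
and a pigeonhole seed index — a probe placed with ≤ 2 mismatches must
match one of three near-equal probe thirds exactly, so exact k-mer
lookups generate a complete candidate set which is then verified. Both
produce identical output (equivalence-tested).

Admission for the global target analysis requires a unique best hit in
genome A whose next-best site is ≥ 2 mismatches away, interpreting
second-best separation as a Hamming-space gap; gapped alignment is
deliberately not reproduced at the array stage. The B-specific
(Ler-direction) differential mode additionally requires a unique
placement in genome B at ≤ 2 mismatches, keeping homologous genes with
moderate divergence analyzable; the A-specific (Col-direction) mode
requires perfect unique matches in both genomes, because a SNP under a
probe depresses hybridization and would otherwise be read as
accession-specific methylation. Whether the second-best separation rule
should also apply in genome B is genuinely open; it is applied in both
genomes by default with a switch (`require_separation_in_B`).

## Array stage

Normalization is loess-then-scale: within each array a lowess curve of
log-ratio against mean log-intensity is fitted (span 0.15, two
robustifying iterations — the small span is needed to track curvature in
the intensity tails; robust iterations protect the enriched-probe
minority from being absorbed into the trend) and subtracted; between
arrays each column is scaled so its MAD equals the geometric mean of all
MADs. Positive probes: each probe's value (replicate mean by default; a
per-replicate-intersection mode exists) is smoothed by a running median
of up to 3 probes within 600 bp; the threshold is the mode of the
smoothed distribution plus z = 4 left-half standard deviations (the left
half mirrored about the mode estimates the null spread without
contamination from the enriched tail); runs of ≥ 3 consecutive positive
probes are required. This is a declared, fully parameterised positive-
probe model, not a reproduction of any specific array package.

The gene rule is a disjunction: covered fraction ≥ 30% AND covered bp ≥
300, OR covered bp ≥ 1,000. The second clause is an absolute-coverage
alternative for very long genes (genes > 3,333 bp are exactly those that
can qualify only through it). Probe coverage uses the full placement
interval of each probe.

## Rank-product differential stage

Genes get a median enrichment per replicate and accession over admitted
probes covering the body; genes with < 3 probes or < 40% probe coverage
are dropped, and genes that are targets in neither accession are
excluded so that differential calls ride on high signal in at least one
genome. With r_A and r_B replicates, all r_A × r_B cross pairings form
the k difference columns (two-class unpaired convention). Ranks use
average tie-breaking, making RP exactly invariant under monotone
transforms. The null permutes values independently within each column
(1,000 permutations by default); pfp_g = E[# null RP ≤ RP_g] / rank(RP_g),
monotonised along the RP order so a worse RP never receives a smaller
pfp. Calls use pfp < 0.15.

A geometric caveat documented here because it shaped the generator
defaults: when true positives are a large fraction of the candidate
list, the deepest true positive sits at a rank where the expected null
count is comparable to the rank itself, and no noise level rescues
pfp < 0.15. Accession-specific targets are therefore simulated as rare
(5% per direction against 30% shared targets), which also matches the
biology the pipeline addresses — accession-specific Polycomb targets are
a small minority of all targets.

## Sequencing stage

Alignment is upstream plumbing; the module ingests read-start tables
(chrom, position, strand, count). Deduplication caps each key at one
read (PCR-artifact removal; idempotent). Island calling tiles the genome
into 200 bp windows; a window is eligible when the Poisson upper tail of
its ChIP count against λ = library-size-scaled input count — floored at
the genome-average ChIP rate so empty input cannot produce infinite
enrichment — is ≤ 0.01; eligible windows join across ≤ 1 ineligible
window (= 200 bp, matching the merge rule) and the joined island must
pass the same test on aggregate counts. This is a declared simplified
island model; externally produced island BED files can be imported
instead (`core_io.read_bed`). Under library-size rescaling the calling
is not strictly monotone in chip counts (adding reads anywhere raises
the scaled background); monotonicity holds at a fixed background model,
which `call_islands(fixed_scale=...)` exposes and the tests check. The
hybrid gene rule is ≥ 20% and ≥ 200 bp, or ≥ 800 bp, boundaries
inclusive.

## Allele-specific inheritance

Reads not matching either parental allele count as `reads_other` and are
excluded entirely — they contribute to neither allele nor the ≥ 3-read
threshold. The per-class summary statistic is the median of per-SNP
Col-allele frequencies (a mean option exists). The resampling null draws
|specific SNPs| SNPs without replacement from the common-target pool,
100,000 times by default; p uses the add-one estimator
(1 + #{null ≤ observed}) / (n + 1), which can never report zero from
finite draws. SNPs (not genes) are resampled, treating SNPs within one
gene as exchangeable with the pool. Reference-mapping bias toward the A
allele is not corrected; the generator could inject it but no correction
is implemented (known limitation).

## Metagene profiles

Each gene contributes 10 upstream 500 bp bins, 10 body bins of one tenth
of the gene length (the remainder of the division goes to the 3′-most
bins — arbitrary but fixed and tested), and 10 downstream 500 bp bins,
ordered 5′→3′. Flank bins running off a chromosome end are excluded from
that gene's contribution for that bin (bin means run over contributing
genes only), avoiding zero-padding bias. Quantitative tracks are
averaged per base with length weighting; uncovered bases count as zero.
`fraction_overlap` scores a bin by ≥ 1 bp contact with the region set;
`normalized_count` apportions feature counts by overlap fraction,
converts to counts per kb and divides by the profile grand mean.

## TE association

"Flanked by a TE" defaults to a TE intersecting the 5,000 bp window on
either side of the gene body; TEs overlapping the body are reported
separately, and a nearest-annotated-neighbour mode is also computed
since the window definition is not the only reasonable one. The
permutation test draws 28-gene samples from the background 200 times
(both configurable) and is one-sided toward enrichment.

Cross-assembly presence calls replace whole-genome alignment with anchor
matching: unique exact 35-mers are sought walking outward through the
flanks (re-seeding past mismatched positions) and located in genome B;
a TE is present when the B anchors span ≥ 80% of the A-side span, absent
when they leave < 20% of the TE length between the flank offsets and no
TE-internal anchor maps between them, and unresolved otherwise. The
80%/20% thresholds are declared and configurable. TSD inference then
looks for the longest motif t (≤ 10 bp) such that A reads X t [TE] t Y
and B reads X t Y at the junction mapped through the left anchor; the
motif comparisons are exact, while the 20 bp junction-continuation check
tolerates ~10% point substitutions so a stray SNP in Y cannot mask a
real duplication. Longest-motif preference makes ties impossible (nested
motifs).

## Synthetic cohort

The generator emulates: two genomes related by SNPs (rate 0.005/bp,
roughly the Col/Ler genome-wide scale) and TE presence/absence
polymorphisms; A-only insertions carry a 4–10 bp TSD with probability
0.8, written as duplicated copies in A and a single junction copy in B,
with SNPs excluded from the TSD copies and the deleted span so each
polymorphism stays interpretable. Gene states (30% shared H3K27me3, 5%
per accession-specific, 10% H3K9me2 heterochromatic, 20% active
H3K4me3, rest unmarked) drive every downstream signal: array log-ratios
(effect 2.0, noise SD 0.5, 3 replicates, plus a mean-zero quadratic
intensity bias so normalization has real work), allele-resolved hybrid
coverage (mean depth 20 per SNP, halved per allele; the A-allele rate at
B-specific genes is ε·depth with ε = 0 by default, 1% of reads become
non-parental), mark region tracks with a 500 bp heterochromatin
spreading margin (a free knob, not an estimate — no quantitative
spreading model is claimed), a siRNA count track conserved exactly over
TE bodies, and hybrid ChIP/input read starts (background 0.02 reads/bp,
8-fold enrichment over biallelic targets, halved for single-allele
targets). 80% of B-specific genes are placed adjacent to an A-only TE,
encoding the flanking-TE association the pipeline is meant to recover.
A fifth generator operation, `simulate_read_starts`, exists so the
sequencing stage has first-class synthetic input.

Default scale is 2 chromosomes × 500 kb, 200 genes, 60 A-frame TEs: the
full pipeline runs in well under a minute, and these are the problem
sizes used throughout the tests and the acceptance script. What passing
tests show is that the algorithms recover the structure the generator
encodes; they do not show robustness to features the generator omits —
real probe cross-hybridization families, indel polymorphism outside TE
events, mapping bias toward the reference allele, copy-number variation,
or non-Poisson overdispersion of sequencing coverage.

## Pipeline and determinism

Every random choice flows from explicit seeds (`SimulationParams.rng_seed`
per-operation streams; `PipelineConfig.rng_seed` for the statistical
stages), and a rerun with the same config produces a byte-identical run
report. `run_pipeline(resume=True)` reloads the simulated inputs and
cached probe placements instead of recomputing them, with outputs
identical to a cold run (tested). Real-data mode reads the same file
formats the synthetic stage writes (FASTA genomes, GFF3 annotation,
probe FASTA, long-format signal table, read-start TSVs, SNP table), so
both modes share one code path from the first analysis stage onward.
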