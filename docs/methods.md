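# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic genomes do and do not emulate, and the
numerical conventions a maintainer needs to know.

## Coordinates and containers

Everything in memory is 0-based half-open; GFF3 (1-based inclusive) is
converted at the I/O boundary only, and the GFF3→internal→GFF3 round trip is
the identity. A gene's **rank** is its 0-based position among *all* annotated
genes on its chromosome ordered by start; the tandem rule counts intervening
loci as rank difference minus one over all annotated genes (a
`family_loci_only` switch restricts the count to family genes, since usage
of "gene loci" differs between studies). One transcript per gene is assumed;
extra isoforms keep the longest exon set with a warning. A terminal stop
codon on a CDS is tolerated and stripped before translation.

## Identification

*Candidate search.* Each labeled reference protein is aligned to every
proteome entry by Smith–Waterman (BLOSUM62, gap open −11 / extend −1, via
Biopython's PairwiseAligner). Significance uses the ungapped Karlin–Altschul
form E = K·m·n·e^(−λS) with λ = 0.3176, K = 0.134 — the classic BLOSUM62
constants — even though the alignment is gapped, as early heuristic search
tools did; the E-value is monotone in the score, so the 1e-5 cutoff behaves
as expected. Proteins with E ≤ 1e-5 against any reference proceed to the
domain scan.

*Domain scan.* Pfam/SMART HMM scanning is replaced by a log-odds PSSM built
from a packaged 54-column AP2 seed alignment (columns with >50% gaps are
dropped; per column, score(a) = log2(((count + pc·bg)/(total + pc))/bg) with
pseudocount 0.5 and Robinson–Robinson background). The scan is **glocal** —
the whole profile against any protein substring — by affine-gap dynamic
programming (gap open −6, extend −1.5 bits), with the insertion state
vectorized as a running maximum. Non-overlapping hits above 25 bits are
reported best-first by re-scanning the flanking segments. 25 bits sits far
above the empirical null (shuffled proteins score no hits in ≥99/100 seeds)
and far below true-domain scores (~150–210 bits). The traceback records a
profile-column → residue map; the family filter reads **columns 14 and 19 in
profile numbering** (a gap at column 14 counts as "not V"), because the
diagnostic positions refer to the conserved domain model, not raw query
offsets. Acceptance requires exactly one hit and V at column 14; rejection
reasons are `no_domain`, `multiple_domains`, `not_V14`.

*Physicochemistry.* Molecular weight is the sum of average residue masses
plus one water; pI is the unique root of the Henderson–Hasselbalch net
charge by bisection on [0, 14] to |charge| < 1e-4. The packaged pKa table is
the Bjellqvist-style set used by common web calculators, including the
residue-specific N/C-terminal adjustments; the test suite cross-checks both
quantities against Biopython's ProtParam. Note that proteins with few
ionizable groups have a nearly flat charge curve near the root, so two
correct implementations can return pI values that differ by ~0.2 pH units
while both satisfying the charge criterion.

## Phylogeny and subgroup assignment

The aligner is a deterministic center-star progressive method: the sequence
maximizing total pairwise global-alignment score is the center (ties by id),
and the others are merged under "once a gap, always a gap". It replaces an
iterative-refinement aligner to keep the pipeline self-contained; a
precomputed MSA can be supplied instead wherever an MSA is consumed.
Distances are Poisson-corrected, d = −ln(1−p), with **pairwise deletion**
(only columns ungapped in both sequences count); a pair with no shared
columns or p = 1 is a hard error. Neighbor joining follows Saitou–Nei with
two conventions: Q-criterion ties break toward the smallest index pair in
the current node ordering (first minimum in row-major order), and a negative
pendant length is clamped to zero with the deficit moved to the sibling so
the pair sum is preserved (display- and patristic-friendly, as in common
tree software). On additive matrices the algorithm is exact — topology and
all path lengths — which the suite verifies against generating trees and,
for four taxa, an exhaustive four-point-condition oracle.

The bootstrap resamples alignment columns with replacement, rebuilds
distance + NJ per replicate, and reports each internal bipartition as a
percent of *valid* replicates; replicates that produce an undefined distance
are discarded (more than 10% discarded is an error). Default 1,000
replicates; tests use fewer.

Subgroup assignment: for each query leaf, the smallest edge-induced split
side containing the query and at least one reference decides. Unanimous
references give the label directly (method "clade"); mixed references fall
back to the patristically nearest reference *within that side* (method
"nearest", ties by reference id). The fallback is this package's explicit
rule for clades without a clean reference neighborhood — classification
schemes in the literature leave this case unstated.

## Gene structure and motifs

Intron phases are computed in transcription order on CDS-only gene models:
phase of intron k = cumulative coding length upstream mod 3. Minus-strand
genes therefore read their genomic exons right to left.

Motif discovery fits the ZOOPS model by EM: per sequence, a latent variable
ranges over {no site} ∪ offsets; the M-step re-estimates the position weight
matrix (pseudocount 0.25·background) and the site prior γ. Because the
pseudocount makes this MAP rather than pure maximum likelihood, the
objective may wobble below 1e-4 relative; anything larger is logged. Widths
come from a grid ({6, 9, …, 48, 50} by default — the bounds are the standard
6–50 range, the stride is for tractability) and the winner maximizes
llr − width·log(total positions). Seeding is MEME-like: 150 candidate
windows (skipping masked regions) are screened in one vectorized E-step,
the top 10 get a 5-iteration burn-in, and the best two run to convergence.
Discovery is sequential with hard masking of posterior sites (≥0.5), up to
15 motifs. Two caveats: EM can settle one or two columns off the planted
register (site recall is therefore judged by window overlap), and the
penalized width choice happily extends a short planted motif into
moderately conserved surrounding columns, so "recovery" of a planted
consensus means containment at ≥80% identity within a discovered consensus.
Background frequencies are estimated from the input set, matching
discovery-tool convention.

## Duplication, Ka/Ks, dating, synteny

Homolog pairs for collinearity are found by local alignment with a 4-mer
prefilter (≥5 shared 4-mers) and the same E ≤ 1e-5 rule. For *within-genome*
block detection the pairs are reduced to **reciprocal best hits**: without
this, every within-subgroup family pair is a significant hit and dense
subgroups generate spurious "collinear" chains; RBH isolates one-to-one
duplicate partners, which is what segmental-duplication calling needs. For
*cross-genome* synteny all significant pairs are kept, because RBH would
drop a recent tandem duplicate whose best cross-genome hit is its partner's
ortholog. Chaining is MCScanX-like: per chromosome pair and orientation, the
maximum-bitscore chain with strictly monotone ranks and rank gaps ≤ 25 on
both sides; chains with ≥ 5 anchors become blocks, best chain first, each
anchor used once. Classification order is tandem first, then segmental
(family pairs anchored in a within-genome block); the sets are disjoint by
construction.

Ka/Ks is Nei–Gojobori (1986): fractional synonymous sites per codon
(synonymous one-step changes / 3 per position, averaged between the two
sequences), pathway-averaged differences for codons differing at 2–3
positions with stop-crossing pathways excluded (if every pathway crosses a
stop, all pathways are used with stop steps counted nonsynonymous — this
keeps Sd + Nd equal to the number of differences), and Jukes–Cantor
correction d = −(3/4)ln(1 − (4/3)p), undefined at p ≥ 3/4 (saturation
error). Changes *to* stop codons count as nonsynonymous so that S + N = 3
per codon exactly. The implementation agrees with an exhaustive brute-force
pathway oracle to 1e-9 over all 61×61 sense-codon pairs. Divergence time is
T = Ks/(2x) with x = 6.56 × 10⁻⁹ synonymous substitutions/site/year,
reported in MYA; the 10⁻⁶ in the textbook form of the formula is read as the
years→MYA unit conversion, the only reading consistent with plant
divergence-time ranges.

## The synthetic genomes

`simulate_genome` emulates the input data of a family survey with known
truth. A family ancestor protein (70-residue flanks around the 54-column
domain consensus) is diversified into six subgroup ancestors (35% flank /
12% domain substitution) and then into members (22% flank / 2% domain);
the diagnostic V14 is frozen everywhere, and E19 is kept in a configurable
fraction of members (default 40/66, chosen to echo the published V+E/V-only
split; duplicate pairs share their ancestor's E19 state). Each member gets a
55-residue random C-terminal tail; planted motifs (defaults: widths 9/12/21,
5% column noise, one subgroup each, assigned to the largest subgroups) live
in the tails so they are conserved-in-random-context — planting them in the
flanks makes them indistinguishable from the flanks' own conservation, which
discovery legitimately reports as wide motifs first. Decoys split three
ways: a family-like protein with a non-V residue at column 14, a two-domain
protein, and a random no-domain protein.

Duplicate pairs evolve from a member ancestor by `evolve_codon_pair`: per
lineage, Poisson numbers of synonymous and nonsynonymous events (expected
ds = Ks/2 per synonymous site, dn = ω·ds per nonsynonymous site, sites
counted NG86-style on the ancestor) applied in random order, each event
drawn uniformly from the currently possible stop-avoiding one-step changes
of its kind. This is deliberately not a full codon model — it is calibrated
so NG86 recovers the targets (median within ±25% at 300 codons), which is
all the downstream analysis consumes. Target Ks values above 4 are refused:
the expected mismatch fraction is then within a percent of the 3/4
saturation bound and the correction is numerically meaningless. After
evolution the two diagnostic codons are re-pinned to the ancestral amino
acids so the planted V14/E19 truth stays exact.

Layout: ten tandem arrays (0–5 intervening background genes, drawn
uniformly) and eight segmental blocks (six anchor pairs each — one family
pair plus five evolved background pairs — on distinct chromosomes, ~30%
inverted) are placed on 12 chromosomes of 60 genes; family-bearing units are
kept ≥ 7 background loci apart so the only tandem-rule pairs are planted
ones, and the recorded truth is *re-derived from final ranks* with the same
positional rule, so truth and annotation can never disagree. Gene models get
random strands, 0–3 introns (phases recorded from construction) and random
intergenic spacers; chromosome sequences are materialized so CDS extraction
is testable. `simulate_ortholog_genome` copies windows of consecutive genes
centered on family members into a second genome at ~Ks 0.5 to plant
cross-genome collinear blocks with a known ortholog count.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: no indels in coding sequence (codon alignments
of simulated pairs are gap-free), no gene loss or pseudogenes, no
alternative splicing or UTRs, no rate heterogeneity across sites or
lineages, no compositional bias, and real AP2 families are noisier at the
identification boundary than the planted decoys. The pipeline's value on
real inputs rests on the component-level checks (NG86 oracle, NJ exactness,
ProtParam agreement), not on the planted-recovery results.

## Problem sizes and determinism

Default analysis scale: 720 genes, 66-member family, 84 scan candidates,
84-taxon phylogeny, 1,000 bootstrap replicates, 15 motifs over a 16-width
grid, ~65 reciprocal-best-hit pairs for collinearity. The acceptance script
uses 200 additive matrices (4–8 taxa), all 3,721 codon pairs for the oracle
check, and 20 simulated pairs per Ks target at 300 codons. Every stage is
deterministic given the config seed; stage seeds are fixed offsets of it.
Sets are never iterated for order-dependent output; ties break
lexicographically.
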