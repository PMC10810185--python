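# Methods

This note records the model behind each stage, the conventions that a reader
must know to interpret coordinates and offsets, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
design choices made where the methodology was genuinely open.

## Coordinates and orientation

All intervals are 0-based half-open (BED convention), internally and in
every file. Read sequences are stored read-oriented (5′→3′ of the excised
oligomer): a minus-strand read's sequence is the reverse complement of its
reference slice. Every positional rule about the damage signature is defined
on the oligo, not the reference, so this orientation is load-bearing.

3′-offsets are 1-based from the 3′ terminus (offset 1 = the 3′-terminal
base). A dinucleotide is addressed by the offset of its 3′ base: the pair
"at offset 5" occupies offsets 5 and 6.

## Damage signature filter

Nucleotide excision repair incises ~5–6 nt 3′ of the lesion; UV lesions form
at adjacent pyrimidines. A read passes the filter when some adjacent
pyrimidine pair has both bases at 3′-offsets within [4, 10]. The window
endpoints are parameters; a `require_both=False` switch implements the
alternative reading in which only the pair's 3′ base must fall inside the
window. Any `N` inside the window disqualifies the positions it touches;
bases outside the window never affect the verdict, so prepending sequence at
the 5′ end cannot change it.

Note the filter is deliberately permissive: ~73% of uniform-random 20-mers
contain some pyrimidine pair in the window (P = 1 − F₉/2⁷ with Fibonacci
F₉ = 34 for no two adjacent pyrimidines among 7 bases). It suppresses
background, it does not eliminate it; quantification therefore always
reports background libraries alongside signal ones.

## Length handling

Species defaults for the retained length range are human 24–30, worm 20–28,
fly 25–30 nt (the ranges with the best pyrimidine enrichment at the damage
positions); the assay-wide range is 19–30 (12 lengths). `auto_select_range`
scores each length by the fraction of its reads carrying a pyrimidine pair
at 3′-offsets 5–6 and returns the contiguous run around the best length
whose members score ≥ half the maximum. Two guards force the configured
default instead: fewer than 100 reads at every length (sparse), or a maximum
score below 0.5 (no length rises clearly above the ~0.25 chance level, i.e.
the score table is flat at background — a flat-but-high table, by contrast,
legitimately selects all lengths).

Trimming to a common 20 nt anchors the **3′ terminus**: bases are removed
from the 5′ side (+-strand interval (s, e) → (e−20, e)). This is what keeps
the damage signature at fixed offsets across read lengths; a 5′-anchored
trim (`anchor="five_prime"`) is available but shifts the signature out of
frame for longer reads and is not used by the pipeline.

Filter order is trim → dedup → align → length filter → trim-to-20; whether
deduplication preceded or followed adaptor trimming upstream of this package
is immaterial for exact duplicates, since trimming is deterministic per
sequence.

## Alignment

The built-in aligner is an exact-substring, unique-hit-only matcher over
both strands (12-mer seed index, verified hits). It is adequate for
synthetic genomes where reads are error-free by construction; real libraries
should be aligned with a production aligner and ingested as BED6 plus the
genome FASTA. Multi-locus and unmapped reads are dropped with logged counts.
A palindromic read maps to one locus, reported once on the plus strand.

## Composition profiles

Per-length nucleotide matrices (4 × L, 5′-anchored positions) are computed
for each of the 12 assay lengths. Dinucleotide profiles (16 × 19) are
computed on 20-nt-trimmed reads and reported with both 5′-anchored pair
positions and 3′-offsets; the aggregate pyrimidine-pair curve (CC+CT+TC+TT)
is the signature readout. Reads are split into nuclear vs mitochondrial
compartments by contig name (`chrM`, `MT`, `M`, `mtDNA`; configurable).

Composition is computed **before** the damage filter: conditioning the
mitochondrial control on containing a dipyrimidine would inflate its
in-window frequencies and destroy its value as a specificity control. The
flatness statistic (max/median of the pyrimidine-pair curve) is ~1 for
signature-free reads.

## Metagene (TCR) profiles

Gene selection keeps genes of at least the species' minimum length whose
nearest neighbour (edge-to-edge, strand-ignorant) is at least the species'
minimum distance away: human 5 kb/5 kb, worm 1 kb/500 bp, fly 1 kb/100 bp.
Genes whose 2 kb flank crosses a contig edge are kept but flagged; their
flank bins are clipped.

Each gene gets 150 bins in gene orientation: 25 × 80 bp upstream of the TSS,
100 body bins partitioning the gene length into near-equal integers (the
remainder r goes to the *last* r body bins, making the partition
deterministic), 25 × 80 bp downstream. Because the remainder rule is
gene-oriented, the bin partition of a strand-flipped gene is the exact
mirror only when the gene length is a multiple of 100; the strand-swap
symmetry checks therefore use such genes.

**Strand convention (the reverse of naive intuition):** an oligo excised
from the transcribed strand is complementary to the mRNA-template strand and
maps *antisense* to the gene annotation. Antisense reads count as TS, sense
reads as NTS — the `-S` / `-s` convention of strand-aware interval
intersection.

A read counts in a bin when the overlap is ≥ 0.5 of the read length
(fraction-of-read, inclusive, so a perfect half-half split counts in both
bins; one read can reach at most ⌊1/f⌋ bins). Ranking uses the
pseudocounted per-gene ratio (TS+1)/(NTS+1) on the reference sample, ties
broken by total reads then gene id; the top 5000 (or all, if fewer) genes
enter the profile. Per-bin values are RPKM with the sample's total aligned,
length- and damage-filtered read count as the denominator, averaged over the
selected genes. Flank bins of one gene may overlap a neighbouring gene
whenever genes sit closer than 2 kb; TS/NTS recovery statements are
therefore made on gene-body bins.

## Spike-in quantification

Reads are assigned to the species in whose genome they map uniquely
(and nowhere in the other); cross-mapping reads are dropped, not
fractionally assigned — conservative and order-preserving. The calibration
is a least-squares line through the origin of ratio on dilution
(slope = Σ dR / Σ d²): the ratio must vanish at dilution zero, and on the
linear scale the fit is dominated by the best-measured (least dilute)
points. The reported r² is the uncentered (through-origin) coefficient; a
warning fires below 0.9. A free-intercept fit and a slope-one log-log fit
(geometric mean of R/d, appropriate when the series spans decades and
relative errors matter more) are available as flags.

`percent_of_wt = 100 · (R / slope) / input_scale` applies the loading
correction at quantification time, never at counting, so raw ratios stay
inspectable. Quantification is invariant to uniform sequencing-depth
scaling. Fold-over-background is a plain ratio of percentages and requires
a positive background.

## Synthetic data generator

The generator is the package's study-condition definition, not a test
convenience: defaults are one nuclear 100 kb contig plus an 8 kb `chrM`,
20 genes of 0.8–4 kb (straddling the worm selection thresholds) with ≥400 bp
gaps, 6,000 reads with uniform lengths over 19–30 nt, signal fraction 0.85,
damage offsets {5: 0.5, 6: 0.5}, TS:NTS odds 4, 5% mitochondrial reads,
10% duplicate rate, a TruSeq small-RNA 3′ adaptor, and the printed worm
dilution series 1…1/10,000. Signal reads are placed by rejection sampling on
the *unmodified* genome until the read-oriented sequence carries the planted
pyrimidine pair, so coordinates and sequences always agree and alignment
stays exact. chrM reads are background by construction (the mitochondrial
genome is never a repair substrate here). Dilution series are Binomial
thinnings of the base library plus exactly `spike_reads` reads sampled from
the spike library; the manifest records the true relative amount.

What it does **not** emulate: sequencing errors and quality scores, GC or
mappability biases, non-uniform empirical length distributions (weights are
overridable), photoproduct-specific chemistry (the positional model covers
CPD and 6–4PP at this resolution), and genome-scale repeat structure.
Passing tests therefore certify the *computation* — filters, conventions,
calibration algebra, recovery under counting noise — not robustness to
error-laden real reads, which must arrive pre-trimmed and pre-aligned.

## Tree annotation

Internal nodes are labelled with the lineage LCA: the deepest taxon shared
by the root→species lineages of all leaves below the node (an alternative
"most frequent lowest taxon" reading exists; the LCA reading is implemented
as it is monotone down the tree). Duplication nodes require **more than
one** species shared between child clades (`min_shared=2`), a deliberately
stricter rule than the classical ≥1 species-overlap criterion; the threshold
is a parameter, and at multifurcations any qualifying child pair flags the
node. Rooting, outgroup choice and pruning remain manual inputs: the module
annotates, it does not root. The signature screen maps 1-based ungapped
reference positions (default: the conserved cysteines at 105–108, 126–128,
261–264 of the human reference row) through the reference's gap structure
and passes a sequence when ≥70% of signature columns carry the residue.

## Numerical and degenerate-input choices

Frequencies over empty columns are reported as 0, not NaN. Zero-length
(edge-clipped) bins contribute 0 RPKM. A zero spike count makes the ratio an
error, never infinity. All randomness flows from numpy Generators seeded
explicitly; the pipeline spawns per-stage child seeds from one root seed and
its outputs are byte-identical across reruns (checksums in the report).
Simulation sizes throughout the tests and the acceptance script (tens of kb
of genome, thousands of reads, 10–20 seeds) are chosen so that binomial /
Poisson sampling error — against which all recovery claims are stated — is a
few percent, which the 3-SD test bands make explicit.

## Known limitations

* The exact aligner cannot ingest mismatched or clipped real-data reads;
  BED ingestion is the supported path for real libraries.
* Fraction-of-read overlap is implemented (`-F`); fraction-of-bin is not.
* Gene flanks are not deduplicated against neighbouring genes; profiles of
  densely packed annotations mix adjacent-gene signal in the flank bins,
  exactly as the underlying interval-intersection approach does.
* The dilution-series fit assumes the constant-spike design; it does not
  model spike-in pipetting error beyond what the counts show.
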