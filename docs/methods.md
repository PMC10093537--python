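# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `orfamily`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic study design

The generator (`orfamily.synthetic`) emulates the statistical structure that
an olfactory-receptor (OR) family analysis assumes, at a desk scale where
ground truth is exact.

**Gene templates.** Each phylogenetic group (β, γ, δ, ε, ζ, η) has a fixed
ancestral architecture: a start methionine, an N-terminal polar segment
carrying the N-X-[TS]-X glycosylation motif, seven 19-residue hydrophobic
blocks (alphabet L/V/F/M/A) separated by strongly polar linkers (alphabet
D/E/N/Q/K/R), and the canonical OR motifs at their usual positions —
MA-[FY]-[DE]-RYVAIC after TM3, the conserved extracellular cysteine (scanned
as [ST]C[ST]; the pattern itself is a package choice, as only the conserved
cysteine is canonical), KAFSTC-X-SH after TM5, and PMLNPFIY near the C
terminus. Type II (η) templates omit the motif-5 cysteine context,
mirroring the reduced motif repertoire of type II ORs. Segment lengths were
chosen so that (a) the minimal template is ≤ 250 codons and (b) under the
package's own Kyte–Doolittle predictor (window 19, threshold 1.6) the seven
blocks segment cleanly: a boundary window needs ≥ ~15 hydrophobic residues
to clear the threshold, so runs extend at most ~4 residues into a linker and
inter-run gaps stay at or above the 5-residue merge limit.

The ancestral architecture is also realized as an ancestral *codon*
sequence (uniform choice among synonymous codons; no codon-usage bias —
NG86's assumptions need degeneracy structure, not realism). Every group
member descends from that ancestral CDS by the same substitution engine used
for duplicates, at per-branch rates Ks = 0.35, Ka = 0.12. Sharing codon
ancestry matters: independently back-translated siblings would be nearly
random at synonymous positions, saturating pS ≥ 3/4 and making within-group
Ka/Ks undefined. At these branch rates two founders sit at ~78–80 %
nucleotide identity — inside the 75 % duplicate screen, so subfamily pairs
are reported as duplicates with purifying ratios around 0.3, while
between-group identity (~25 % at the protein level) is far outside it.
Motif codons are restored after mutation and candidates are resampled until
the TM predictor confirms ≥ 7 segments, so planted structure is true under
the package's own tools.

**Degradation.** Pseudogenes receive one recorded disruption: a premature
stop codon at an internal position, or a 1–2 nt insertion / 1 nt deletion.
Truncated genes lose the start codon (ATG→CTG), the terminal stop
(stop→Tyr), or both, with a clean interior.

**Planted divergence.** `mutate_duplicate` resamples random codons among
their single-nucleotide synonymous or non-synonymous neighbors (stop codons
never created; multiple hits allowed). Because multiple hits and
mixed-pathway codons erode *observed* differences, events are added until
the NG86-counted difference proportions reach the Jukes–Cantor-inverted
targets p* = (3/4)(1 − exp(−4·rate/3)), with the discrete stopping grid
dithered by half an event so the realized divergence is unbiased; the
engine's contract is that the estimator recovers the planted rates, and the
acceptance grid verifies this to within 3 Monte-Carlo standard errors.
Non-synonymous replacements prefer the residue's hydropathy class
(hydrophobic / strongly polar / weak) and cap hydrophobicity at phenylalanine
level in TM blocks, so duplicated copies keep their 7-TM architecture; they
also avoid revisiting the parent's amino acid, which would masquerade as
synonymous divergence.

**Geometry.** Default: 4 chromosomes × 10 Mb, 60 intact (18 of them
children of recorded duplication events: 15 purifying at Ks ≈ 0.24–0.35 /
Ka ≈ 0.08–0.14, 3 positive at Ka ≈ 0.22–0.28 / Ks ≈ 0.08–0.12), 15
truncated, 5 pseudogenes; 7 tandem clusters with intra-cluster gaps of
5–30 kb; all other genes and clusters separated by 1.5 Mb so the 1 Mb
single-linkage rule recovers exactly the planted clusters. 20 % of
classified genes are multi-exon (2–5 exons, GT…AG introns of 80–2000 nt).
Placement infeasibility (genes that cannot fit) raises a config error.

**Expression.** Gill/heart/liver × control/hypoxia/re-oxygenation × 3
replicates. Counts are negative binomial with dispersion 0.1 around
log-normal baseline means (median ≈ 300); 44 % of classified genes carry a
4-fold planted effect (up and down balanced) in one tissue, in one or both
stress conditions. 200 stable background genes dominate the library totals,
as the real transcriptome does — without them, planted fold changes shift
every FPKM in the column and inflate false flags.

## Analysis stages

**Translated search.** Six-frame translation (codons containing N → X,
stops → `*`); exact 4-mer amino-acid seeds; ungapped X-drop (20) extension
on the seed diagonal; then exact local DP (BLOSUM62 with X/`*` scoring 0,
gaps 11/1) on a window around the extended segment — a superset of a banded
search with the same scores, which the Smith–Waterman oracle tests confirm.
Significance is the ungapped Karlin–Altschul expectation E = K·m·n·e^(−λS)
with published BLOSUM62 constants (λ = 0.318, K = 0.13) treated as
calibration values; the search space is query length × total translated
length with no edge correction. Default cutoff 1e-5. Hits on one
chromosome and strand within 2 kb merge into candidate loci (the intron-span
allowance is a package default; it bounds the intron size a single locus can
bridge without annotation).

**Gene models and classification.** An annotated gene overlapping a locus
contributes its exon structure; otherwise the longest ORF (≥ 150 nt, any
frame or strand) becomes a single-exon model. Disruptions are in-frame
premature stops, CDS length ≢ 0 (mod 3), or supporting hits that jump
reading frames (only hits at ≥ 40 % identity count as evidence, so a stray
off-frame hit cannot fake a frameshift). Precedence: any disruption ⇒
pseudogene; else start + stop + ≥ 250 aa + ≥ 7 predicted TM ⇒ intact; else
best query identity ≥ 0.40 over ≥ 100 aa ⇒ truncated; else rejected
non-OR. The 0.40 floor is a package choice ("well matched" has no published
number); min_tm is configurable because hydropathy segmentation is cruder
than profile-based TM predictors. When several loci resolve to one
annotated gene (e.g. a weak opposite-strand hit), the locus with the best
supporting identity wins.

**Protein properties.** Molecular weight uses average residue masses plus
one water; pI is bisection of the Henderson–Hasselbalch net charge with the
Bjellqvist pKa set (termini residue-specific) to 0.01 pH; the instability
index is the Guruprasad dipeptide sum. Constants come from Biopython's
published data tables; the algorithms are implemented here and checked
against both a charge-grid oracle and Biopython's ProtParam.

**Phylogeny.** Progressive alignment: UPGMA guide tree on fractional-common
3-mer distances, profile–profile global DP (BLOSUM62, affine 11/1, end gaps
penalized), leaves pre-sorted so the result is input-order invariant.
Distances are pairwise-deletion p-distances (Poisson −ln(1−p) selectable);
trees are Saitou–Nei neighbor joining with negative branch lengths clamped
to zero (amount logged); bootstrap resamples columns and counts recovered
bipartitions (default 100 replicates at desk scale; 1000, as commonly
published, via `--bootstrap-reps`). Groups are assigned by majority vote of
the k = 3 nearest labeled reference leaves by patristic distance (ties →
smallest summed distance) — robust when reference groups are not perfectly
monophyletic, and exact for a zero-length attachment.

**Duplication and selection.** All-vs-all local DNA alignment (match +2 /
mismatch −3, affine 5/2, 12-mer prefilter); pairs need coverage ≥ 75 % of
the longer CDS, identity ≥ 75 % in the aligned region (both inclusive) and
E ≤ 1e-20 (λ solved exactly for the score scheme at uniform composition;
K = 0.3 calibration). Unequal-length pairs are codon-aligned through their
protein global alignment before NG86; gap and ambiguous codons are skipped
and counted. Ratios are undefined at Ks = 0 and excluded from percentage
denominators. Clusters chain start-to-start distances < 1 Mb per
chromosome (end-to-start mode available); "major" clusters have ≥ 5 members.
"Expanded" genes are members of at least one retained duplicate pair.

**Collinearity.** Reciprocal-best protein homologs (E ≤ 1e-10 — strict
because ungapped statistics ignore composition bias; shuffled decoys reach
E ≈ 1e-5 while genuine orthologs sit below 1e-100), then longest strictly
monotone chains of gene ranks per chromosome pair (rank gaps ≤ 25, blocks
≥ 5 anchors, increasing = same orientation, decreasing = inverted),
extracted best-first by quadratic DP. The partner gene set for synthetic
runs is a deterministic stand-in related genome: same gene order with one
inverted segment per chromosome and 2 % protein perturbation.

**Expression.** FPKM = count × 1e9 / (library total × transcript length);
replicates average within a condition; log2 fold change against the
tissue's control with pseudo-count 1; a gene is differentially expressed
when |log2FC| ≥ 1 in ≥ 1 stress condition. The threshold and pseudo-count
are configuration values surfaced in the report — no published criterion
exists for the percentages the report format mirrors, so the package
reproduces the percentage arithmetic and treats the criterion as free.

**Pipeline.** One master seed fans out per stage via SHA-256 of
(seed, stage name), so toggling a stage never shifts another's randomness;
reruns with the same config are byte-identical. Report percentages are
re-derived from their printed numerator/denominator by an automatic
consistency check before rendering. Percentage rounding follows the
conventions of the tables the report mirrors: two decimals for
expansion/DE, one-decimal-or-integer for selection fractions, nearest
integer for the multi-exon share.

## Problem sizes

Defaults were chosen as the package's standard study: 80 genes on 40 Mb of
genome for recovery runs; 20+5+2 genes on 12 Mb for the shared test
dataset; 500 random codon pairs for the NG86 oracle; an 8 × 8 planted-rate
grid at 20–24 seeds for Ka/Ks recovery; 100 random quartets for topology
recovery; 50 random peptides for the pI oracle; 10 generator seeds for
differential-expression recovery.

## What passing tests do and do not show

The generator plants exactly the signals the analysis assumes: clean splice
boundaries, uniform base composition outside genes, no repeats or
low-complexity DNA, no sequencing error, no assembly gaps, and OR-like
proteins whose TM architecture is true *under the package's own hydropathy
predictor*. Perfect recovery on this material validates the algorithms and
their wiring, not performance on real genomes, where repeat-rich DNA,
fragmented assemblies, non-OR GPCR paralogs and profile-quality TM
prediction dominate the error budget. Likewise the NG86 recovery grid
validates estimator/generator consistency under NG86's own site model, not
robustness to transition/transversion or codon-usage bias (classic NG86
deliberately ignores both). CAFE-style birth–death family-size inference
across species, MEME-style de novo motif discovery and ML/Bayesian trees
are out of scope.

## Numerical notes

- NG86 site counting excludes changes to stop codons from the per-position
  denominator, so N + S = 3 × compared codons exactly; pathway averaging is
  unweighted over stop-free orderings (all orderings if every pathway is
  blocked). Saturation (pS or pN ≥ 3/4) raises an error; a single-codon
  wobble pair is *inherently* saturated because S < 1 site.
- The Karlin–Altschul λ for the DNA scheme is solved by root-finding at
  import time; E-values are rankings, not calibrated p-values.
- UPGMA and chain-extraction tie-breaks are lexicographic; NJ tie-breaks
  take the first minimal Q entry, and bootstrap column draws come from the
  stage generator — all deterministic for a fixed seed.
- Genome assembly uses byte arrays; generated chromosomes are identical
  across runs of the same seed, as are all TSV/GFF3/FASTA artifacts.
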