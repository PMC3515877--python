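# Methods

Conventions used throughout: DNA sequences are upper-cased on input; codon
columns are triplets aligned in frame; "-" is an alignment/deletion gap;
IUPAC ambiguity codes other than ACGT are treated as missing data. The
standard nuclear genetic code is used everywhere.

## Divergence: Ka/Ks by the Nei–Gojobori (1986) method

For each sense codon, every position contributes a synonymous-site fraction
equal to the fraction of its three possible single-base changes that are
synonymous; changes creating stop codons are excluded from the denominator.
Per codon the synonymous (S) and nonsynonymous (N) site counts sum to 3.
Optionally, site fractions are transition/transversion-weighted by a kappa
supplied by the caller or estimated from the alignment (transitions weighted
kappa, transversions 1).

Differences between two codons separated by k > 1 changes are averaged over
all k! orderings of the changes, discarding any pathway that passes through
a stop codon; if every pathway is discarded, all pathways are used. Codon
columns containing a gap, an ambiguous base, or a stop codon in either
sequence are dropped pairwise.

Proportions pN = Nd/N and pS = Sd/S are corrected with the Jukes–Cantor
formula d = −(3/4)·ln(1 − (4/3)·p); p ≥ 3/4 yields NaN and a `saturated`
flag. Ka/Ks is their ratio (NaN when Ks is 0 or undefined).

## Diversity: π, π_a, π_s

Variant tables (SNPs and deletions) are applied to the reference to build
per-accession pseudochromosomes. Deletions are written as "-" so coordinates
are preserved; the reference allele is checked and mismatches raise with the
position. CDS rows are extracted from the pseudochromosomes using the gene
model (exons concatenated; minus-strand genes reverse-complemented with gaps
preserved).

π is the mean pairwise proportion of differing sites over all accession
pairs (Tajima's estimator, no n/(n−1) sample-size correction). π_a and π_s
are means over pairs of Nd/N and Sd/S computed with the same NG86 machinery
as Ka/Ks, so within- and between-species quantities are directly comparable.
Per pair, codon columns with gaps, ambiguity, or stops are dropped.

Large-effect variants (premature stop, lost start, lost terminal stop,
frame-disrupting deletions) are detected per accession; the exclusion policy
can keep all rows, drop affected accessions, or drop affected genes.

## Sliding windows

Windows of fixed nucleotide width and step (defaults 51 and 9) are laid
along the CDS; each window is trimmed inward to whole codons before
counting. Each window reports π, π_a, π_s from the ingroup rows and Ka, Ks
against an optional outgroup row, plus the raw mismatch/site counts so that
non-overlapping windows (width = step ≡ 0 mod 3) aggregate exactly to the
whole-gene counts.

## Family scan

A profile is a per-column log-odds matrix ln(freq/background) built from a
seed alignment with pseudocount 0.5 per residue; columns that are more than
50% gaps are dropped. The background is the seed alignment's overall residue
frequency unless supplied. A protein is scored by the best ungapped
placement of the profile along it.

Reporting threshold: each seed sequence is scored against a profile built
from the other seeds (leave-one-out); the threshold is half the mean of
these self-scores. If that mean is not positive the threshold falls back to
mean − 3·SD of the self-scores. This rule is robust to the in-fold score
inflation that makes naive mean − 3·SD thresholds overfit small seed sets.

Hits are classified by their activation loop: the TxY motif matched within
the profile window (regex `T[A-Z]YV[A-Z][A-Z]RWYRAPE`, classes TEY/TDY, or
literal TxY otherwise), with an MEY fallback (`MEY[A-Z][A-Z]RWYRAPE`).
Species-specific refinement rebuilds the profile from the loop segments of
its own hits and rescans until the hit set reaches a fixed point (bounded
iteration count).

## Orthologs and codon alignments

CDSs are translated (terminal stop stripped; internal stops are an error
naming the codon). Best hits use Biopython global alignment with BLOSUM62
and affine gaps (11/1); reciprocal best hits are required for an ortholog
call, ties broken by smallest target id. Protein alignments are
back-translated to codon alignments (residue → source codon, gap → "---"),
verifying the translation at each position.

## Trees and clustering

Protein distances are p-distance or Poisson-corrected (−ln(1 − p)),
computed over ungapped column pairs. Neighbor-joining uses the standard Q
criterion with deterministic tie-breaking (lexicographic); negative branch
lengths are clamped to zero with the deficit moved to the sister branch, so
NJ is exact on additive matrices. UPGMA merges the closest pair with
size-weighted averaging; node height is d/2, giving ultrametric trees.

Bootstrap support resamples alignment columns with replacement, rebuilds the
tree, and labels each internal edge of the original tree with the percentage
of replicates containing the same bipartition (canonicalized as the side not
containing the first leaf). Expression clustering is UPGMA on
1 − Pearson correlation between gene expression profiles.

## Family vs. background statistics

The Wilcoxon rank-sum test uses scipy's `mannwhitneyu`: exact when both
samples have n ≤ 12 and there are no ties, otherwise the normal
approximation with continuity correction. The family is removed from the
background before testing; non-finite values are excluded and counted.
Boxplot summaries report quartiles (linear interpolation) and 1.5·IQR
whiskers; the Ka-on-Ks relationship is summarized by least-squares
regression.

## Synthetic data

- **Coding genes**: random sense codons, ATG start, single terminal stop,
  no internal stops.
- **Population samples**: infinite-sites model. The number of segregating
  mutations is Poisson(θ·L·a_n) with a_n = Σ 1/i; each mutation's carrier
  count is drawn from the neutral 1/i spectrum; proposed changes are uniform
  over positions and non-stop alternative bases, and nonsynonymous proposals
  are accepted with probability ω. This makes E[π] = θ and E[π_a/π_s] ≈ ω
  under the same NG86 site definitions used by the estimators. Optional stop
  injections and CDS deletions are planted and ledgered.
- **Ortholog pairs**: each lineage proposes Poisson(t/2 · n_codons)
  kappa-weighted single-base changes; synonymous proposals are always
  accepted, nonsynonymous ones with relative probability ω, so the realized
  Ka/Ks matches the planted ω.
- **Genome bundles**: multi-exon genes placed on both strands of two
  pseudochromosomes, with GFF3, per-accession variant tables, ortholog
  CDS/protein sets, a proteome with planted family members (TEY/TDY/MEY) and
  motif-free decoys, a seed alignment, an expression matrix with planted
  co-expression clusters, and a JSON truth ledger recording every planted
  fact.
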