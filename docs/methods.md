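# Methods

This note documents the models and procedures implemented in `pletools`, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical and design choices made where the underlying
procedures are underspecified in common practice.

## Candidate element mining (`ple_discovery`)

Homology hits (12-column BLAST tabular) are filtered to at most `n_max`
(default 30) pairwise nonoverlapping loci with E-value strictly below 10⁻⁵,
selected greedily by descending bitscore; overlap means at least one shared
base pair on the same contig, strand-blind. Fewer than `n_min` (default 10)
survivors is a warning, not an error, since sparse genomes legitimately
yield few loci. Hits are widened by 500 bp flanks (clipped at contig
bounds).

ORF calling is deliberately simple and exhaustive: every ATG in all six
frames, read to its nearest in-frame stop with the standard genetic code;
ORFs without an in-frame stop inside the sequence are discarded (no
open-ended calls), nested ORFs sharing a stop are all reported, and codons
containing N are untranslatable (such ORFs are dropped). Transposase
candidacy additionally requires a DDE_Tnp_1_7 domain hit with bit score
strictly above 150 and aligned length strictly above 275 aa — both strict
inequalities, matching the selection rule for this domain family.

Domain boundaries established on one transposase (e.g. piggyBac's cleavage
points) are transferred to a new one by a single global pairwise alignment:
BLOSUM62, gap open 10, gap extend 0.5, end gaps penalized. A reference
residue aligned against a gap maps to the nearest preceding target residue
and is flagged, so callers can distinguish exact from interpolated
boundaries. The mapping is monotone by construction.

## TIR detection (`tir_finder`)

The detector formalizes a k-mer screen for terminal inverted repeats: take
the flanks upstream and downstream of the candidate ORF (2 kb by default),
compare every upstream k-mer (k = 10) against the reverse complement of
every downstream k-mer, and keep pairs with at most 2 mismatches ("fewer
than 3"). For a fixed paired segment, upstream offset i and downstream
offset j of matching windows satisfy i + j = constant, so matches are
grouped by this anti-diagonal key, overlapping or adjacent windows within a
group are merged, and merged spans are trimmed to their outermost matching
base pair before applying the 12 bp reporting threshold. Candidates are
ranked by (length desc, mismatches asc, position asc); no mismatch filter is
applied to merged segments — ranking replaces the manual verification such
screens otherwise need.

Two numerical choices deserve emphasis:

* **Trimming.** A window overlapping a true repeat by ≥ k − 2 bases passes
  on the repeat bases alone, so the raw union of passing windows would
  systematically overhang the repeat by a few background bases on each side.
  Trimming to the outermost matching pair restores the repeat's actual
  extent; interior mismatches are retained and counted.
* **Grouping tolerance.** Matches are grouped per exact anti-diagonal.
  Merging across staggered diagonals (to absorb indels) would produce
  up/down segments of unequal length, which is incoherent for an
  ungapped inverted-repeat pair; instead a `diag_tol` option suppresses
  near-duplicate candidates from diagonals within ±2 whose upstream spans
  overlap, keeping only the best-ranked. The default is exact grouping,
  under which the detector is provably equivalent to a per-diagonal
  enumeration oracle (tested).

The TTAA target-site duplication is its own reverse complement, so the TSD
copies flanking a real element pair with each other and extend the
detectable repeat by 4 bp at its outer ends. The TSD check therefore strips
terminal motif copies from a detected repeat before asking whether the
element is motif-flanked.

## Phylogenetics (`phylo`)

Distances are amino-acid p-distances with pairwise deletion — columns
containing '-', 'X' or '?' in either member of a pair are dropped for that
pair only — Poisson-corrected as d = −ln(1 − p). Saturated pairs (p = 1) are
an error rather than silently capped. Trees come from Saitou–Nei neighbor
joining with the standard Q criterion; ties on Q break by the
lexicographically smallest taxon pair, making output deterministic on
degenerate inputs. Negative branch lengths are clamped to zero with a
warning. On additive matrices the algorithm recovers the generating topology
and exact path lengths (property-tested on random 5–8-taxon trees and
cross-checked against scikit-bio's independent implementation).

Bootstrap consensus resamples alignment columns with replacement; replicate
r draws from the independent stream (seed, r), so replicates are reproducible
and order-independent. The consensus is plain majority rule: bipartitions
occurring in less than the cutoff (default 50%, strict '<') are collapsed;
retained ones are added to a star tree in frequency order, skipping
incompatible ones. Support values are percentages on internal nodes.

## Integration-site analysis (`integration`)

Sites are called from read alignments by discarding MAPQ < 20, grouping
positions per contig, absorbing positions within ±3 bp into the locally
modal position (radius configurable; 0 disables), and requiring at least 11
supporting reads — "more than 10" read strictly. Minus-strand alignments
report their rightmost aligned base, because tagmentation libraries read
outward from both transposon ends and both orientations should collapse near
the same TTAA.

Target logos are per-position base frequencies over site-centered windows
(minus-strand sites reverse-complemented) with information content
IC = 2 + Σ f·log₂ f, using 0·log 0 = 0.

Enrichment compares an observed site set against a uniformly random baseline
drawn over the concatenated genome: FC = (obs fraction in feature)/(random
fraction in feature), with a two-sided Fisher exact test (scipy) on the 2×2
table. Point features such as TSSs use a symmetric window (default ±5 kb
in the CLI, parameter elsewhere); interval features use direct overlap.
Features are tested independently without multiple-testing correction,
mirroring per-feature comparisons common in vector-integration studies; a
Bonferroni flag can be layered on by callers.

The genomic-safe-harbor classifier applies five criteria, measured from the
site midpoint (distance 0 if inside a feature), all with strict-≥ semantics
at the boundary: ≥ 50 kb from every gene's strand-aware 5′ end; ≥ 300 kb
from the nearest cancer-gene interval edge; ≥ 300 kb from the nearest miRNA;
outside all transcription units; outside all ultraconserved regions. The
measuring conventions (5′ end point for genes, nearest edge for
cancer genes/miRNAs) are the package's choices where the criteria
themselves do not fix one; they are deliberately simple and are verified
against a brute-force all-intervals scan.

Excision footprints are typed against the expected restored donor
(left flank + TTAA + right flank): equality is `seamless`; a junction formed
by inserting one contiguous block is `insertion`; by deleting one contiguous
block, `deletion`; anything else `other`.

## Mutagenesis prioritization (`mutagenesis`)

Docking poses are ranked by the composite score
1.0·Evdw + 0.2·Elec + 1.0·Edesol + 0.1·Eair and clustered by greedy
best-first leader clustering on Kabsch RMSD (SVD superposition, proper
rotations only) over protein Cα plus DNA phosphate atoms: walking poses
best-first, a pose joins the first cluster whose leader is within 5 Å
(inclusive — the boundary is ambiguous in common usage and inclusion is
documented here), else founds a new cluster; the top 4 by score per cluster
are retained. Single-linkage clustering is deliberately not the default, as
leader clustering is the behavior of the docking suites this emulates.

Interface residues are defined by buried surface area: Shrake–Rupley
accessible surface (probe 1.4 Å, deterministic golden-angle spiral of 256
points per atom, element vdW radii) computed for the protein alone and in
complex; a residue is interfacial iff ΔASA exceeds 1.0 Å² (strict). A
`contact` mode (any protein heavy atom within 5 Å of DNA) is provided for
coarse-grained structures, including the synthetic ensembles used in tests.
Consensus targets are residues interfacial in strictly more than 2/3 of the
supplied models (exactly 2/3 is excluded), minus a caller-supplied conserved
mask; a helper marks alignment columns with ≥ 90% identity as conserved.
Whether consensus should run over all poses or only the selected
top-per-cluster set is left to the caller — the function consensuses over
whatever ensemble it is given.

Substitutions follow three rules, each tagging its proposals: hydrophobic
{A,V,L,I,M,F,W,C} → hydrophilic {S,T,N,Q,K,R,E,D,H}; acidic {D,E} → basic
{K,R,H}; and every non-wild-type residue observed at the position in a
homolog alignment column (natural variants).

## Copy number (`copy_number`)

Standard curves are least-squares fits of Ct on log₁₀(copies) over at least
three dilution levels; replicate Ct values are averaged (arithmetic mean)
before fitting. A slope of −1/log₁₀2 ≈ −3.32 corresponds to 100%
amplification efficiency; fitted slopes outside [−3.6, −3.1] (90–110%
efficiency) warn but never reject, since mildly inefficient assays are still
quantifiable. Copies follow by inversion, and per-cell values by
normalization to the RNaseP reference at 2 copies per diploid human genome:
copies/cell = 2 × target/reference — hence target = reference gives exactly
2.0 and the estimate is invariant to the amount of input DNA.

## Synthetic data (`synthetic_data`)

Every generator is a pure function of its configuration; each draws from its
own substream of the master seed (so adding a generator never perturbs
another), and truth records carry all planted coordinates and parameters.

* **Genome with element** — uniform-random background (25% each base)
  carrying TSD + 5′TIR + ORF + 3′TIR + TSD. Defaults: 8 kb contig, 626-aa
  ORF, 16 bp TIRs with 0 mismatches, TTAA TSDs. An in-frame stop codon is
  placed just before the planted ATG so no upstream ORF can chain through
  it. Plants are *crisp*: the 10 base pairs beyond each end of the
  TSD-extended repeat (along its anti-diagonal) are forced to mismatch, so
  detection recovers exactly the planted extent rather than lucky background
  bases; planted TIR mismatches are placed so that the union of
  within-budget k-windows still covers the whole repeat (otherwise the k-mer
  rule itself would truncate the plant — an undetectable plant says nothing
  about the detector). Finally the generator polices its background: random
  2 kb flank pairs contain roughly one degenerate ≥ 20 bp inverted repeat by
  chance, so an independent in-generator scan disrupts any background repeat
  long enough to outrank the plant. These guarantees are what make exact
  round-trip assertions meaningful; they also mean the generator does not
  emulate the ambiguity of real flanks, where top-ranked candidates still
  need inspection.
* **Tracks and sites** — random interval tracks plus a mixture sampler: each
  site falls inside feature f with probability θ_f (uniform within f,
  length-weighted), else uniformly on the genome, giving expected
  FC = (θ + (1 − θ_total)·ρ)/ρ for a feature covering genome fraction ρ.
  No chromatin structure, GC bias or TTAA placement preference is modeled.
* **Reads** — SAM text with a configurable number of reads per site, half on
  each strand placed so both collapse at the site position, optional
  positional jitter and low-count decoy positions. No sequencing-error or
  mapping-ambiguity model.
* **Docking ensembles** — a Cα-trace helix and a straight phosphate-spaced
  DNA chain ~18 Å away; planted contact residues are moved to ~3 Å of the
  DNA in a configurable fraction of models; optional second pose shifted
  20 Å; Gaussian coordinate jitter; energies drawn so contact poses score
  best. Coarse-grained on purpose — it exercises geometry and consensus
  logic, not force fields.
* **qPCR** — seven 10-fold dilution standards per assay at 100% efficiency
  with Gaussian Ct noise (σ = 0.1 by default), and a sample planted at 3.2
  transgene copies per cell against 2 reference copies per cell.

Passing tests on these generators demonstrates correctness of the
algorithms and their boundary behavior under known ground truth; it does
not demonstrate robustness to real-data artifacts (mapping ambiguity,
assembly gaps, chromatin-biased integration, primer efficiency drift),
which the generators deliberately do not model.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence batteries run at reduced, statistically adequate sizes
chosen as desk-scale study conditions: 200 random flank pairs (≤ 300 bp) for
the TIR oracle; all 2×2 tables with total ≤ 30 for Fisher enumeration; 100
random annotations for the safe-harbor oracle; 100 random additive matrices
(5–8 taxa) for NJ; 100 bootstrap replicates for the planted-clade check; 20
replicates of n = 2000 sites for enrichment recovery, each against a fresh
50 000-site random baseline (fresh baselines keep replicates independent —
a shared baseline would correlate their errors and invalidate the
standard-error comparison). Genome-scale analyses (hg38 tracks, published
integration-site libraries) use the same code paths but require external
accessions and are out of desk scope.
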