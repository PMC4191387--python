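# Methods

## Model and assumptions

The core quantity is a per-category observed-vs-expected comparison of
variant hits on functional sites.  Under the null, nsSNVs fall uniformly
over the proteome's L residues, so a category with n(F) annotated positions
captures each variant independently with probability p(F) = n(F)/L, and the
disrupted count among the N variants of a stratum is Binomial(N, p(F)) with
expectation n(E) = N·p(F).  Reported per cell: n(O), n(F), N, L, p(F),
n(E), the difference n(O) − n(E), the direction of deviation and the exact
one-sided tail probability inclusive of n(O) in that direction
(P(X ≥ n(O)) for over-representation, P(X ≤ n(O)) for under).  Tails are
evaluated through scipy's regularised incomplete beta function, which works
in log space internally; printed survey values as extreme as 4.5e-273 are
reproduced exactly rather than by normal approximation.  Raw P-values are
reported; Benjamini–Hochberg adjustment is available as an optional column
and is off by default.

The binomial null deliberately ignores two features of reality, both
inherited from the survey design this package models: residue composition
(a phospho-site can only exist on S/T/Y, yet p(F) is a proteome-wide
fraction) and the motif footprint of N-linked glycosylation.  A sequon's
n(F) counts one position (the anchor asparagine) per site, while variants
can break the motif from offsets 0, 1 and 2.  With a uniform alternate
allele, the effective per-sequon target is roughly 1 + 1/19 + 18/19 ≈ 2
positions, so sequon categories appear over-represented even under uniform
variant placement.  This is a property of the statistic, not a bug, and it
is why the null-calibration check (below) is defined over direct-residue
categories only.

## Disruption rules

* Direct-residue categories: a variant at the annotated position disrupts
  the site unless the alternate residue appears in the category's tolerated
  set.  The shipped default tolerates nothing: the published tolerance
  tables are not available in machine-readable form, and phospho S↔T is
  intentionally not tolerated because serine and threonine losses are
  tallied separately.  The rules file (`data/rules.yaml`) makes every
  tolerance configurable.
* N-linked glycosylation: evaluated against the live sequence as the
  N-X-S/T sequon (X ≠ P) anchored at the asparagine.  Offset 0 → any
  replacement disrupts (`motif_break_N`); offset 1 → only introduction of
  proline disrupts (`motif_break_proline`); offset 2 → disrupts unless the
  new residue is S or T (`motif_break_ST`), so the T↔S exchange is
  tolerated.  Non-proline changes at X are treated as tolerated; only the
  proline rule is attested.
* O-linked glycosylation is a direct S/T residue site, not a motif.
* A residue annotated with k categories yields k calls for one variant;
  count cubes tally distinct variants per (category, source) and
  (category, origin), with germline defined as dbSNP membership.

## Synthetic data: what it emulates, what it does not

The generator stands in for the merged public catalogs and is itself a
first-class, tested module.  Defaults define the study conditions: 30
proteins of mean length 200 (Poisson, floor 20; L ≈ 6000 residues), uniform
amino-acid composition; site densities per 1000 residues of 12
(phosphorylation), 8 (acetylation, ubiquitylation), 5 (methylation,
N-glycosylation sequons), 3 (O-glycosylation, active sites) and 10 (binding
sites); 4000 variants; a 0.5 germline fraction; 12 collapsed Disease
Ontology cancer labels assigned to 60% of variants; five ortholog species
at 0.9 per-site identity; cohorts of 8 samples with ~25 mutations per tree
branch.  Sites never overlap, and sequences are edited at planting time so
every site is rule-compatible (full valid sequons are written for
N-glycosylation).  Variants are drawn without replacement from the
(position × 19 alternates) cell space by Gumbel top-k weighted sampling,
with cell weight λ_c on category-c site positions — so planted enrichment
factors are exact rate multipliers and all variant keys are distinct.
All randomness derives from the single config seed through fixed per-stage
streams; identical configs are byte-identical.

Not emulated: realistic amino-acid composition or mutational signatures,
codon-level (single-nucleotide-reachable) substitutions, linkage between
variants, indels in orthologs (the 1:1 positional map is exact by
construction), and recurrent mutation in cohorts.  Passing tests therefore
demonstrate correctness of the statistics and plumbing under the stated
null and planted alternatives, not robustness to compositional biases of
real proteomes.

## Calibration and recovery checks

* Null calibration: with all λ = 1 and the four direct-residue categories
  above, the fixed upper-tail P-values pooled over 200 replicate data sets
  are checked for uniformity (Kolmogorov–Smirnov) and for a ~5% empirical
  type-I rate at α = 0.05.  The *reported* P-value — one-sided in the
  direction of deviation — is intentionally not the calibration quantity:
  choosing the tail after looking at the deviation makes it a two-sided
  object whose rejection rate at α approaches 2α in the continuous limit,
  so uniformity can only be expected of a fixed-direction tail.
* Planted recovery: λ = 4 on methylation at 20,000 variants must be flagged
  over-represented at P < 1e-3 in ≥95% of 50 replicates.
* Oracle equivalence: the indexed scanner is compared against an exhaustive
  variant × site double loop; binomial tails are compared against direct
  pmf summation in 40-digit arithmetic (the float lgamma oracle itself
  carries ~3e-12 relative error at N = 10⁴, above the 1e-12 bound checked).
* Tree recovery: neighbor joining on condensed cohorts must reproduce the
  generating topology (Robinson–Foulds distance 0) in ≥95% of 50 seeds.

These replicate counts and problem sizes (200×4000 variants; 50×20,000;
50 cohorts of 8 samples) were chosen so that each check has clear power
while the whole suite stays in the minutes range.

## Conservation

Best homolog per (query, species) by minimal E-value (< 1e-5), ties broken
by bit score then subject accession.  A position's conservation count is
the number of species whose best homolog carries the identical residue at
the aligned position; "conserved" requires all configured species, and a
missing homolog or alignment gap contributes zero (gap handling is an
assumption; the source procedure does not state it).  Ratios are fractions
of conserved positions per (group, residue, category) with groups G/S/T
(germline/somatic/total).  Enrichment of conserved positions among
site-impacted variants uses the same binomial tail with p = the global
conserved fraction.  The hit-table position map uses ungapped coordinate
arithmetic (sstart + qpos − qstart), exact for the indel-free synthetic
orthologs and an approximation otherwise.  The built-in pairwise aligner
(local alignment, BLOSUM62, gap open −11 / extend −1, Karlin–Altschul
λ = 0.267, K = 0.041) exists so desk-scale runs need no external search
binaries; real studies should supply precomputed hit tables.

## Phylogenetics

Condensation takes the union of variant loci across samples (sorted by
sequence id and position); each sample contributes its allele per locus
flanked by k ∈ 0..3 reference characters, truncated identically at sequence
boundaries, windows of adjacent loci kept independent.  Distances are
p-distances (Hamming / length).  Tree inference is classic neighbor
joining — deterministic lowest-index tie-break, negative branch lengths
clamped to zero, unrooted trifurcating root — rather than approximate
maximum likelihood: the contribution here is the condensation and profile
overlay, and NJ keeps the stage dependency-free and exactly reproducible.
The condensed alignment is also written as FASTA so external ML tools can
be used instead.  Bootstrap support is out of scope.  Because the locus
set is fixed cohort-wide, condensed sequences are positionally homologous
by construction and no realignment is performed.

## Numerical and design choices

* −log10(P) values are capped at 320 when P underflows double precision;
  degenerate cells (empty stratum, p(F) ∉ (0,1)) carry P = 1, contribute 0
  to matrices and are flagged.
* Profile clustering: average linkage on Euclidean distances; a fully tied
  distance matrix keeps input order (documented tie-break); dendrograms are
  exported as newick with heights converted to branch lengths.
* Site features spanning more than five consecutive residues are excluded
  as domain-scale annotations; spans of 2–5 are expanded per residue.
* `in_dbsnp` is an explicit column rather than inferred from a source tag,
  so both origin paths are exercisable with synthetic sources.
* Recurrence is keyed at (gene, site position, category, alternate
  residue); the shipped DO slim (`data/do_slim.tsv`) is a best-effort
  reconstruction and analyses must not depend on its exact content.
* Alternate alleles ignore codon reachability — a documented limitation
  shared by the generator and the disruption rules.

## Known limitations

Protein-space only (no genomic liftover or isoform resolution); no
structure-based impact scores; conservation is identity-based, not
phylogeny-aware; the binomial null is proteome-global rather than
composition-conditional; NJ provides no support values.
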