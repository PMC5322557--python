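# Methods

## The inference problem

A genus of facultative endosymbionts is represented by an ingroup of
sequenced genomes (here structured as one two-genome clade plus one
singleton lineage) and one or more outgroup genomes. Genome reduction in
such symbionts proceeds mostly by lineage-specific gene loss and
pseudogenization from a shared ancestral repertoire; acquisitions are
largely mobile elements. The package reconstructs that ancestral repertoire
from presence/state patterns, assigns per-lineage events, and tests whether
losses are asymmetric between lineages.

## Family construction

Proteins are compared across genomes only — the search of each protein is
against the proteins of the *other* genomes, never its own. Candidate pairs
must share at least two distinct 5-mers on a consistent alignment diagonal
(bucketed to 16 residues); candidates are then screened by the best
ungapped segment score along the seeded diagonals (maximum-subarray scan of
BLOSUM62 scores, 25-bit floor) before full affine-gap local alignment
(BLOSUM62, gap open 11, extend 1). Identical sequences and exact substrings
short-circuit: the optimal local alignment of an exact substring is its
full diagonal match, since every BLOSUM62 off-diagonal entry is bounded by
both diagonal entries. Raw scores convert to bit scores via the gapped
Karlin–Altschul parameters for BLOSUM62 (λ = 0.267, K = 0.041); the
e-value uses the effective search space (query length × total letters of
the other genomes). Hits require ≥ 50 bits and e ≤ 1e-5 (both
configurable; no canonical values exist for this step, so the defaults are
conventional BLAST-like cutoffs).

Each gene contributes one undirected edge per other genome, to its best hit
there (ties: lower e-value, then higher identity, then lexicographically
smallest subject id — making the partition order-independent). Families are
the connected components of the edge set; genes without edges are
singletons. Best-hit attachment is deliberately non-reciprocal: the rule
attaches a gene to its best hit regardless of whether the relation is
mutual, so fragments and recent duplicates of one gene join their family
transitively. The known consequence is that when two post-duplication
paralogs are both retained in two or more genomes, best hits track
orthologs and the paralog pair splits into two families; and a family whose
surviving members all sit in one genome can never be joined, because
within-genome co-membership only ever arises transitively through another
genome. Both limits are inherent to the method, not to this implementation.

## Status triage

Rules run in a fixed order, and re-application is idempotent:

1. **Artifact filter** — protein < 100 aa (strict), no similarity hit, no
   annotated domain. Runs first so spurious short ORFs never serve as
   family-relative references. Artifacts leave the partition and the state
   matrix.
2. **Relative-length rule** — reference length is the *median* protein
   length of the member's cross-genome intact family members (median, so a
   single aberrant ortholog cannot shift the reference). A member below
   80% (strict) is a pseudogene unless it carries every ancestral domain,
   where the ancestral domains are the intersection of domain ids over the
   intact references; the exception only applies when that intersection is
   non-empty (an empty intersection would make the exception vacuous).
   Members with no cross-genome intact reference are left unchanged — the
   rule is undefined for them — and downstream they count as putatively
   intact, which is exactly how an annotation pipeline treats a CDS it has
   no reason to doubt.
3. **5′ rescue** — for pseudogenes whose alignment to an intact reference
   covers the reference's 3′ end but misses ≥ 5% of its 5′ end: scan
   upstream in frame to the nearest stop; an alternative bacterial start
   (ATG/GTG/TTG) whose implied ORF reaches ≥ 80% of the reference length
   reclassifies the gene intact with a corrected start. 3′ truncations get
   no rescue.
4. **Contig-edge rule** — a gene flagged as broken by a contig edge with no
   internal stop codon (a trailing partial codon is ignored) is considered
   active regardless of length: missing sequence, not mutation, explains
   its shortness. This deliberately overrides the length rule.

## Ancestral reconstruction

From the family × genome state matrix (intact dominates pseudogene;
unclassified counts as intact; absent means no members):

- **C1**: present (intact or pseudogene) in every ingroup lineage, and
  intact in ≥ 1 ingroup genome.
- **C2**: intact in ≥ 1 ingroup lineage, and present in ≥ 1 outgroup.
- "Present/intact in a lineage" defaults to *any* member genome
  (`clade_presence="any"`); a stricter *all* mode is available, since the
  clade-level phrasing is genuinely ambiguous.
- **Ancestrally inactivated**: present in every ingroup genome, intact in
  none — reported separately, not counted ancestral.
- **Mobile exclusion**: families whose every member is a phage, plasmid,
  transposase or toxin/antitoxin gene are excluded before reconstruction
  (a transfer between an outgroup and one ingroup genome would otherwise
  satisfy C2); APSE and the non-integrated plasmid are exempt. Mixed
  families count as non-mobile — the conservative reading.

Per lineage, each ancestral family is retained (intact somewhere in the
lineage), inactivated (present, pseudogene-only), or lost (absent from the
whole lineage); the three counts always sum to the ancestral-set size.
Acquisitions are non-ancestral, non-excluded families present in one
lineage and absent from the other lineages and all outgroups (requiring
outgroup absence avoids double-counting C2-eligible families).

Lineage loss counts are compared with Pearson's χ² on the 2×2
lost/not-lost table, no continuity correction, df = 1 (closed form
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); p from the χ²₁ survival function). A
goodness-of-fit variant on the raw loss counts is available behind
`method="gof"`. Any zero margin invalidates the statistic and is flagged
rather than fudged.

## Ka/Ks

CDS pairs are aligned at the protein level (global, BLOSUM62, free end
gaps — truncated sequences align to the matching region), back-mapped to
codons; columns with a gap, stop codon, or N are dropped (internal stops in
pseudogenes are tolerated and simply removed). Nei–Gojobori counting:
per-codon synonymous site fractions by enumerating the nine
single-nucleotide changes (changes creating stops count as nonsynonymous;
sites averaged over the two sequences, so S + N = 3 × retained codons);
multi-substitution codons averaged over all minimal pathways with equal
weights, a pathway step being synonymous only if it preserves the amino
acid and touches no stop codon. Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3); results are invalid at saturation (p ≥ 3/4) or
dS = 0, with the reason recorded. The estimator is exact and enumerable,
which is why it is used rather than a faster approximate one; no
transition/transversion weighting is applied. The genetic code is the
bacterial table, whose codon→amino-acid map equals the standard code.

## The simulator

`simulate()` draws `ancestral_size` random CDSs at the tree root — length
in codons is `codon_len_min` + geometric with overall mean
`codon_len_mean`, start codon ATG, body drawn from the 61 sense codons,
single terminal stop. Defaults: mean 320 codons (the genomes this models
average ~965 bp per CDS) with a 150-codon minimum, so that even a 20%
truncation fragment (≥ 30 aa) stays detectable by the alignment search at
high identity. A fraction `domain_frac` (default 0.3) of genes carries one
annotated domain spanning roughly the 30–60% stretch of the protein.

Along each branch, independently per family: loss with `loss_prob`
(default 0.15; the family disappears from the whole subtree — no
resurrection), else pseudogenization with `pseudo_prob` (default 0.05),
else survival with substitutions, possible duplication (`dup_prob`,
default 0.01, an identical extra copy in the same family), and
mobile-element acquisition (`hgt_rate` Poisson-mean new families per
branch, default 0.5, categories phage/plasmid/transposase/toxin-antitoxin).
Pseudogenization truncates the CDS to a uniform 20–79% of its sense
codons — strictly below the 80% rule's threshold by construction, so every
simulated truncation is detectable in principle; when the gene carries a
domain, the cut destroys it with probability ½ and preserves it entirely
otherwise. Pseudogenes persist unchanged downstream and are never re-lost.
Substitutions are applied to intact genes only: the number of synonymous
(nonsynonymous) changes is Poisson with mean rate × synonymous
(nonsynonymous) NG site count, placed by rejection sampling over
single-nucleotide changes; the start codon is held fixed and changes that
would create an internal stop are rejected (lethal in a retained gene).
Each applied change is recorded with its class, and replaying the record
onto the ancestor reproduces every extant CDS exactly.

The emitted annotation never consults the truth: a CDS is written
``intact`` when it has a bacterial start, a terminal stop and no internal
stop — the judgement a structure-only gene caller would make — and
``unclassified`` otherwise; truncated CDSs retain only sense codons, hence
always emit as unclassified. Classification into pseudogenes is left
entirely to the pipeline.

What the simulator does *not* model: codon-usage and AT mutational bias,
indels within retained genes, recombination, rate heterogeneity across
sites, contig fragmentation (contig-edge genes are covered by hand-built
fixtures instead), and 5′-side truncations (the rescue rule is likewise
fixture-tested). Passing recovery tests therefore show the inference is
correct under the model's event structure, not that it is robust to every
artifact of real assemblies.

## Recovery experiments (symbevol.validate)

- **Ancestral recovery** — 1,265 ancestral families (matching the scale of
  the genus this models) on the default 3-ingroup + 2-outgroup topology,
  loss 0.15 / pseudogenization 0.05 per branch, zero divergence. The
  pipeline's ancestral calls are compared with calls replayed from the
  truth: same presence rules applied to the *recoverable* states, where a
  true pseudogene only surfaces as such if the family retains an intact
  reference in another genome and the truncation did not preserve every
  ancestral domain. The comparison is exact (set equality, plus the
  ancestrally-inactivated flags and per-lineage loss counts), and the
  recoverable ancestral set is provably a subset of the truly ancestral
  families.
- **Clustering recovery** — 200 families, syn = nonsyn = 0.05
  substitutions/site per branch, intact-gene evolution only
  (pseudogenization off: fragment linkage is a detectability question,
  exercised separately at zero divergence). Score: adjusted Rand index
  against the recoverable true partition (single-genome families decompose
  into singletons, see above). 98 of 100 seeded replicates achieve
  ARI = 1.0; the misses are the documented paralog split.
- **dN/dS recovery** — pairs of independently evolved copies of random
  500-codon genes; equal rates give a mean ratio within [0.9, 1.1]
  (slightly above 1 is expected: the ratio's denominator noise inflates
  the mean), and nonsyn = ¼ syn gives a mean within [0.2, 0.35].
- **Loss-test power** — content-only simulation (no sequences needed for
  loss counts), 1,000 families, stem-loss 0.3 vs 0.1: the χ² test rejects
  at α = 0.05 in effectively all replicates.
- **Phylogeny** — neighbor-joining exactly recovers 4–6-taxon additive
  topologies (and matches an independent NJ implementation); a clade
  sharing 30 private substitutions over 1,000 sites gets bootstrap support
  ≥ 0.99 at 100 replicates.

Problem sizes above are the package's chosen experiment designs; the
acceptance script runs reduced replicate counts of the same designs.

## Numerical and design notes

- NJ uses the canonical Q criterion with ties broken by the
  lexicographically smallest pair (Q rounded to 12 decimals before
  comparison), negative branch lengths clamped to zero; p-distances use
  pairwise deletion of gap/N columns. A maximum-likelihood phylogeny is
  out of scope — the NJ module is a clearly labelled substitute adequate
  for synthetic validation.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical config + seed reproduces every
  output byte for byte.
- The gene table is a bespoke 9-column TSV (status, mobile category and
  domain intervals have no canonical GFF3 home); a GFF3 exporter carries
  them as column-9 attributes. Coordinates are 1-based inclusive on the
  forward strand; domain coordinates 1-based inclusive in protein space.
- Fragmented genes split across contigs are distinct records; family
  membership is what reunites them.
- The amino-acid 80% rule equals the nucleotide version for in-frame
  truncations, which is the only kind the simulator produces.
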