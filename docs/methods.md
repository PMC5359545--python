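# Methods

## Model and scope

`varfunnel` operates on unphased biallelic genotype dosages. Multiallelic
records are decomposed into one variant per alternate allele at read time
(a sample's dosage for each decomposed variant is the number of copies of
that allele in its GT, so dosages plus the reference count always sum to
the ploidy). Variant identity is the tuple *(chrom, pos, ref, alt)*;
annotation fields never participate in identity. A missing call is a first
class value distinct from homozygous reference, and no stage ever imputes
one.

The inheritance model throughout is fully penetrant autosomal recessive
with both parents unaffected: the affected offspring carries dosage 2 and
each parent dosage 1. Dominant, X-linked and compound-heterozygous models
are out of scope, as are structural variants, CNVs and phased haplotypes.

### Impact taxonomy

Functional classes follow the SnpEff convention. HIGH collects the
protein-truncating and splice-destroying classes (stop gain, start/stop
loss, splice donor/acceptor, exon deletion, frameshift, rare amino acid);
MODERATE the protein-altering ones (codon alteration, missense, splice
branch, UTR deletion); `low_other` and `modifier` are aggregate buckets for
everything milder, because upstream annotators report those tiers without a
per-class breakdown. The map is total and validated: an unknown label is
rejected with the list of valid ones.

### The cascade

Stages compose in a fixed order (trio sites → outgroup subtraction → panel
subtraction → recessive segregation → gene-list intersection), though each
stage is exposed individually. Two semantics choices matter:

* **Sharing is key-level.** A variant is "in common" with another cohort
  when its site key appears there with at least one carrier. Genotype-level
  matching across species would be ill-defined; site-list subtraction is
  what a cross-species comparison can actually support. The operation is
  idempotent and anti-monotone in the subtracted cohort, and both
  properties are asserted in tests.
* **Missing trio calls disqualify.** At the segregation stage a missing
  call in any trio member removes the variant rather than being imputed —
  conservative, and consistent with candidates being re-genotyped
  downstream anyway.

The per-stage report counts variants per functional class. Reports computed
by the pipeline are monotone non-increasing along stages for every class
and this is enforced; reports *loaded* from external tallies are accepted
without that check, because annotator outputs may count transcript effects
(one variant, several isoforms) and a class can then appear to grow between
stages. The impact-tier cut is applied to the final candidate set but not
to the report's gene-list column, so moderate-impact survivors remain
visible next to the high-impact ones.

## Cohort concordance and allele orientation

The concordance screen applies two literal predicates per variant: an
affected sample with a non-missing dosage ≠ 2, or an unaffected sample with
dosage 2, excludes the candidate. Samples with unknown phenotype are
ignored (they still participate in lineage exclusion); a variant with no
non-missing calls is *uninformative* rather than retained.

Screening tables print raw base pairs and usually leave allele orientation
implicit. The table reader therefore requires each column header to declare
ref and alt (`LABEL:ref>alt`); in the packaged fixture the alternate is the
allele homozygous in the sequenced affected animal. Independently, the
screen by default re-tests an excluded variant with the orientation
flipped (dosage 0 ↔ 2) and only excludes when both orientations are
discordant. For the decisive patterns this is orientation-proof: two
affected animals homozygous for opposite alleles, or a heterozygous
affected, are discordant under every consistent labelling.

**Lineage exclusion** operationalizes "carriers unrelated to the affected
line" as graph disconnection: a carrier with no undirected parent–child
path to the affected individuals' connected component cannot have inherited
the allele from the affected lineage, so the allele it carries cannot be
the (fully penetrant) cause. Genotype exclusion is evaluated first, lineage
exclusion only on survivors; verdicts carry machine-readable offender lists.

## Pedigree engine

The pedigree is a DAG (cycles rejected at parse time) over PLINK-style PED
rows. Obligate carriers are the unaffected parents of affected
individuals — necessarily heterozygous under the recessive model.

**At-risk** is a possibility statement, not a probability: an ungenotyped
individual is at risk when *some* Mendelian-consistent completion of the
pedigree assigns it dosage ≥ 1. Completions are enumerated depth-first in
topological order with pruning against already-assigned parents, and the
known genotypes are validated for internal consistency first. Founders not
ancestral to any known carrier or affected individual are fixed homozygous
reference by default — the single-founder-allele assumption appropriate to
a studbook population — and a flag lifts the assumption for sensitivity
analysis. Enumeration refuses beyond a configurable bound (default 20
unknowns) rather than approximate; numeric carrier probabilities, kinship
and inbreeding coefficients are out of scope.

The packaged studbook is a transcription of a published pedigree *figure*.
It preserves the facts stated in text — the obligate-carrier parents, the
affected siblings and their genotyped littermates, the wild-type lineage
disconnected from the affected component, the carrier crosses that produce
the seven at-risk animals — but edge-level fidelity beyond those facts is
not claimed, and the at-risk reproduction is a fixture-level test, not a
headline result. The related screening fixtures follow the published
per-animal genotype table where the running text disagrees with it (the
text counts five heterozygotes among sighted cats, the table six); the
discrepancy is noted here rather than silently resolved.

## Consequence prediction

`parse_hgvs_c` accepts the deletion subset of HGVS coding notation
(`c.<pos>del<bases>`, with optional range); substitutions, insertions and
duplications are explicitly unsupported. The default stop placement is the
immediate-stop convention — stop at `ceil(pos / 3)`, the codon containing
the first deleted base — appropriate when the species' coding sequence is
unavailable. Supplying a CDS switches to translating the shifted frame to
the first downstream stop, which can never precede the first affected codon
(asserted as a property test); a frame that reaches the end of the CDS
without a stop is an error rather than a guess. Residues lost are
`protein_length − stop + 1`. The worked example uses a 597-residue protein
length because that is the unique value reconciling a stop at codon 428
with 170 lost residues; the orthologous human protein is usually given as
598, and the package records the convention rather than adjudicating the
biology. Without a protein sequence the protein notation degrades from
`p.L428*` to `p.428*`.

## Synthetic cohorts

The simulator emulates the *structure* of a cross-species study, not its
genomics:

* One linear mock chromosome with collision-free uniform positions — the
  cascade's logic never consults coordinates beyond identity.
* Per-variant allele frequency uniform on [0.05, 0.5]; trio, panel and
  extended-cohort genotypes drawn under Hardy–Weinberg proportions,
  independent of phenotype for background variants (a permutation test in
  the suite checks no residual association at α = 0.01).
* Independent outgroup membership at fraction 0.41 — the share of variants
  a single sister-species genome removed in the motivating study — and
  panel membership at 0.80, a plausible value for a large same-lineage
  panel chosen once and documented here.
* Functional classes assigned by a fixed multinomial dominated by
  `modifier`, so funnel reports have a realistic shape.
* The panel has 51 samples and the outgroup one, mirroring the study's
  comparison database.
* The causal variant is a 2 bp deletion (frameshift, HIGH) in a listed
  gene, dosage 2/1/1 in the trio, Mendelian dosages in the extended
  pedigree, absent from outgroup and panel. Decoys are listed-gene missense
  variants with the same trio pattern but a seeded extended-cohort
  discordance (a second affected that is not homozygous alternate, or an
  unaffected homozygote) — they survive the funnel and must die at
  concordance, under either allele orientation.
* The extended pedigree template mirrors the studbook topology (carrier
  founder pair, unrelated wild-type line, one carrier cross with
  ungenotyped litters) without individual-level fidelity.

Identical parameters and seed give byte-identical output files. What
passing simulator-based tests shows is that the cascade's logic is correct
under its own assumptions; it does not show robustness to linkage
disequilibrium, genotyping error, incomplete penetrance or population
structure, none of which the generator models.

## Problem sizes and numerical choices

Genome-scale inputs (tens of millions of variants) are not reproducible
from a desk, so simulator-based checks run at reduced scale chosen as the
package's own defaults: 2,000 background variants per bundle for the
50-seed recovery experiment, and 10,000 for the law-of-large-numbers check
on sharing fractions (tolerance three binomial standard deviations). Ties
and degenerate inputs resolve conservatively throughout: empty gene lists
are an error rather than an empty intersection, an all-missing candidate is
uninformative rather than retained, and enumeration beyond the bound
refuses rather than samples.
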