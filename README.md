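# varfunnel

Trio-based, cross-species variant prioritization for recessive disease in
small captive populations.

## The problem

When a rare inherited disease appears in an endangered species kept in
zoos, there is usually no variant database for that species — but there may
be whole-genome sequence for a handful of animals and a large call set from
a closely related domestic species. `varfunnel` implements the analysis
strategy that identified a 2 bp frameshift deletion in *IQCB1* (the gene
encoding the ciliary protein nephrocystin-5) as the cause of early-onset
progressive retinal atrophy (PRA) in captive African black-footed cats:

1. **Trio filter** — keep variants that are non-reference in a trio of two
   unaffected parents and one affected offspring.
2. **Cross-species subtraction** — remove variants shared with an outgroup
   genome from a sister species and with a panel of related-species
   genomes; what survives is private to the study species.
3. **Recessive segregation** — keep variants where the affected offspring
   is homozygous alternate and both parents are heterozygous
   (aff = 2, sire = 1, dam = 1 in allele-dosage terms).
4. **Impact prioritization** — SnpEff-style functional classes map to
   HIGH / MODERATE / LOW / MODIFIER tiers; candidates are ranked by tier.
5. **Disease-gene intersection** — keep variants in genes from a curated
   retinal-disease gene list.

Candidates are then screened against an extended genotyped cohort
(**recessive concordance**: excluded if any affected is not homozygous
alternate or any unaffected is), and against the studbook pedigree
(**lineage exclusion**: excluded if carriers occur in pedigree components
disconnected from the affected lineage). A pedigree engine infers obligate
carriers and, by exhaustive Mendelian completion of partially genotyped
studbooks, the **at-risk** animals a breeding program should genotype. A
consequence module predicts the protein truncation of a coding deletion
from HGVS notation (`c.1282delCT → p.L428*`, stop codon
`ceil(1282 / 3) = 428`).

Because no external data can be redistributed, the package ships a
synthetic cohort simulator that reproduces the statistical structure the
cascade assumes (species-shared fractions, Hardy–Weinberg background
genotypes, a seeded causal variant, and decoys that pass the trio filter
but fail cohort concordance), so the whole pipeline is testable end to end.

## Worked example

Simulate a cohort and run the funnel from the shell:

```sh
$ varfunnel simulate --seed 42 --n-background 1000 --out demo
bundle 24aced72a1fdb093: 1004 trio variants

$ varfunnel filter --trio-vcf demo/trio.vcf --outgroup-vcf demo/outgroup.vcf \
    --panel-vcf demo/panel.vcf --sire SIRE1 --dam DAM1 --affected AFF1 \
    --genes demo/genes.txt --min-impact HIGH --report demo/funnel.json
...
High-impact variants at Phenotype segregation: 1

Final candidates (HIGH+): 1
  chrS:30470441:ACT>A  gene=IQCB1  class=frameshift
```

The funnel grid shows per-stage attrition: 1,004 simulated trio variants
shrink through cross-species subtraction and recessive segregation until
only the seeded frameshift (plus decoy missense candidates at MODERATE
tier) survive. The extended-cohort screen then removes the decoys:

```sh
$ varfunnel concord --genotypes demo/genotypes.tsv --ped demo/pedigree.ped
IQCB1        retained
RBP3         excluded_genotype  [AFF2 (affected_not_hom_alt)]
AIPL1        excluded_genotype  [UNREL1 (unaffected_hom_alt)]
...
```

The same operations are available as a library, including the packaged
study fixtures (screening tables and the transcribed studbook):

```python
>>> from varfunnel import fixtures, concordance_screen, at_risk_individuals
>>> callset, phenotypes = fixtures.load_missense_panel()
>>> for v in concordance_screen(callset, phenotypes):
...     print(v.variant_key[0], v.status.value)
IQCB1 retained
CHD3 excluded_genotype
CNGB1 excluded_genotype
DTHD1_942 excluded_genotype
RBP3 excluded_genotype
USH1C excluded_genotype
CDH23 retained
DTHD1_144 retained
>>> sorted(at_risk_individuals(fixtures.load_studbook()))
['209', '260', '261', '262', '264', '265', '266']
```

Five of the seven missense candidates fail cohort concordance; lineage
exclusion against the studbook then removes the remaining two (their
carriers include cats unrelated to the affected line), leaving the *IQCB1*
deletion as the sole candidate. The at-risk list names the seven
ungenotyped cats that some Mendelian-consistent completion of the studbook
makes a carrier or affected. The truncation arithmetic:

```sh
$ varfunnel consequence --hgvs c.1282delCT --protein-length 597
c.1282delCT -> p.428*
premature stop at codon 428
wild-type residues abolished: 170
```

## Layout

- `varfunnel.core` — variants, genotype call sets, impact taxonomy
- `varfunnel.io` — VCF / PED / genotype-table / gene-list readers & writers
- `varfunnel.funnel` — the five-stage cascade and its per-class report
- `varfunnel.concordance` — cohort concordance and lineage exclusion
- `varfunnel.pedigree` — obligate carriers, Mendelian checks, at-risk enumeration
- `varfunnel.consequence` — HGVS deletion parsing and truncation prediction
- `varfunnel.simulate` — synthetic cohorts with ground truth
- `varfunnel.cli`, `varfunnel.report` — command-line entry points and rendering
- `varfunnel.fixtures` — loaders for the packaged study tables

See `docs/methods.md` for the model, its assumptions, and the design
choices behind the defaults.
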