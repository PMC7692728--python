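# bgcline

Assembly-line inference for PKS/NRPS biosynthetic gene clusters.

Actinomycete genomes encode their polyketide and nonribosomal-peptide
natural products in modular assembly-line enzymes: type-I polyketide
synthases (PKS) and nonribosomal peptide synthetases (NRPS).  Each module
performs one chain-elongation cycle — minimally KS+AT+ACP for a C2 ketide
unit, C+A+T for one amino-acid residue — and, by the **collinearity rule**,
the order of modules along the line mirrors the order of building blocks in
the product.  `bgcline` turns per-ORF domain-organization annotations (the
kind of table a genome-mining survey prints) into:

* parsed, canonical domain strings (`KS/AT_m/DH/KR/ACP-…`), robust to the
  typographic dialect of printed tables;
* assembly lines whose modules are inferred independently of ORF
  boundaries — essential for genomes where single modules are split over
  many proteins;
* predicted product backbones: monomer chains (`s-x-Asn-Ser-x-Asn-Gly`)
  with methylation (`m`), D-configuration (`d`), dehydroalanine and
  thiazoline rewrites, and polyketide feature summaries (chain length,
  hydroxyls from KR, C=C double bonds from DH-KR pairs, polyene calls);
* cluster classification (type-I/III PKS, NRPS, hybrids) plus signature
  flags for iterative enediyne PKSs (KS/AT/KR/DH order, no ACP) and
  AT-less (trans-AT) lines;
* genus-level sharing statistics over multi-strain inventories;
* exact-mass dereplication of LC-MS ion peaks against known compounds via
  [M+H]+ at a ppm tolerance;
* a synthetic-data generator that inverts the prediction rules, so every
  stage is testable against known ground truth.

The packaged inventory transcribes a published survey of the four
*Phytohabitans* type strains (*P. flavus*, *P. rumicis*, *P. houttuyneae*,
*P. suffuscus*): 56 PKS/NRPS gene clusters in 40 ortholog groups.

## Worked example

```python
>>> import bgcline as bg
>>> inv = bg.packaged_fixture()
>>> s = bg.genus_summary(inv)
>>> s.total_clusters, s.distinct_types, s.shared_groups, s.unshared_clusters
(56, 40, 9, 31)
>>> s.specific_per_strain
{'flavus': 5, 'rumicis': 8, 'houttuyneae': 10, 'suffuscus': 8}
```

56 clusters across the four strains fall into 40 distinct types: 9
ortholog groups are shared by two or more species and 31 clusters are
strain-specific (5/8/10/8 per strain).

```python
>>> line = bg.assemble_line(inv.get("suffuscus", "t1pks-7"))
>>> bg.count_pks_modules(line)
12
>>> bg.predict_polyketide(line)
PolyketideFeatures(module_count=12, chain_carbons=24, double_bonds=6,
                   hydroxyls=3, fully_reduced=2, polyene=True,
                   enediyne_flag=False, type3_starter=False)
```

The 17 ORFs of cluster *t1pks-7* assemble into 12 modules — a C24
polyketide chain; six of its modules carry a DH-KR pair, each yielding a
C=C double bond, so the product is called a polyene.

```python
>>> chain = bg.predict_peptide(bg.assemble_line(inv.get("flavus", "nrps-2")))
>>> str(chain)
's-x-Asn-Ser-x-Asn-Gly'
>>> dict(bg.composition(chain))
{'s': 1, 'x': 2, 'Asn': 2, 'Ser': 1, 'Gly': 1}
```

A heptapeptide with a starter unit, two asparagines, one serine, one
glycine and two unpredicted residues — read directly off the seven-ORF
NRPS by the collinearity rule.

The same operations are exposed on the command line:

```sh
bgcline summarize --json          # genus statistics
bgcline classify                  # categories + enediyne / trans-AT flags
bgcline predict                   # product chains and PKS features
bgcline dereplicate               # [M+H]+ matching of the packaged peaks
bgcline simulate --out syn.tsv --truth truth.json --seed 1
```

## Documentation

* `docs/methods.md` — the inference rules, their assumptions, parameter
  defaults and known limitations.
* `docs/file_formats.md` — the inventory TSV/JSON schema and the peak/
  candidate/specificity-code table formats.
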