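# File formats

## Cluster inventory (TSV)

UTF-8, tab-separated, one row per ORF, with a header row:

| column | meaning |
|---|---|
| `strain` | strain label; clusters of one strain must be contiguous per cluster |
| `cluster_id` | cluster identifier, unique within a strain |
| `ortholog_group` | label shared by orthologous clusters across strains |
| `declared_category` | one of `t1pks`, `t3pks`, `t1pks_t3pks`, `nrps`, `pks_nrps` |
| `locus_tag` | ORF identifier (a locus range stands for one concatenated ORF entry) |
| `strand` | `+` or `-` (cosmetic; row order is biosynthetic order) |
| `length_aa` | protein length in amino acids, or empty when unknown |
| `domain_string` | domain organization in the dialect below |

Rows belonging to one cluster must be consecutive and agree in
`ortholog_group` and `declared_category`.  The equivalent JSON form is
`{"rows": [...]}` with the same field names per row object.

## Domain-organization dialect

* `/` or whitespace between domains; `-` (hyphen or en-dash) between
  modules; stray separators are ignored.
* Domain tokens: `KS`, `KS_1` (first-module KS), `KS3` (type-III PKS; the
  printed form `KS (type-III PKS)` is also accepted), `AT`, `AT_m`, `AT_p`,
  `AT_e`, `ACP`, `KR`, `DH`, `ER`, `MT`, `A`, `A_<monomer>`, `T`, `C`,
  `LCL`, `DCL`, `C_Du`, `C_M`, `C_S`, `C_Cy`, `E`, `TE`, `TD`, `CoL`,
  `CoL_<starter>`, `FkbH`.  Superscript subtype spellings (`^L^C_L`,
  `^D^C_L`) and `C_L`/`C_D` are accepted on input.
* A trailing `?` on an A-domain substrate (e.g. `A_ser?`) marks a tentative
  (single-predictor) prediction; `*` markers from italics extraction are
  accepted on input.

## LC-MS peak list (CSV)

Columns `peak` (label), `rt_min`, `mz`, `strain`, `media`
(semicolon-separated medium labels).

## Candidate compounds (CSV)

Columns `name`, `exact_mass` (neutral monoisotopic mass, Da).

## Specificity codes (TSV)

Columns `monomer`, `code` (10 uppercase residues), optional `source`.
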