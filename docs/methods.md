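# Methods

## Scope and model

`bgcline` models a biosynthetic gene cluster as an ordered list of ORFs,
each an ordered string of catalytic domains; no nucleotide or protein
sequence is represented.  Everything downstream — module assembly, product
backbones, classification, genus statistics — is a deterministic function
of these domain strings plus optional substrate evidence.  The package
deliberately stops at backbones: tailoring enzymes, stereochemistry beyond
the D-prefix, and final-product structures (SMILES) are out of scope, as is
detecting clusters in genomes in the first place (domain annotations from
an upstream annotation tool are the input, not the output).

## Domain grammar

Domains are separated by `/` (or whitespace), modules by `-` (hyphen or
en-dash); stray separators are dropped.  Condensation-domain subtypes are
normalized (`^L^C_L`/`C_L` → `LCL`, `^D^C_L`/`C_D` → `DCL`, `C_Du`, `C_M`,
`C_S`, `C_Cy`), `KS (type-III PKS)` becomes the single token `KS3`, and a
substrate predicted by only one tool (italics in printed tables) carries a
trailing `?` in the ASCII dialect.  Serialization emits one canonical form
and round-trips exactly through the parser.  Printed module separators are
preserved for round-tripping but carry no meaning downstream.

## Module assembly

Modules are segmented on the concatenated domain stream of the whole
cluster, never per ORF, because in these genomes single modules are
frequently split across several proteins and the inference must be
invariant to how a line is split.  Rules:

* `KS` (including `KS_1`) starts a PKS module; `KS3` is a free-standing
  type-III enzyme and goes to the standalone list.
* `C` starts an NRPS module; an `A` or `T` that cannot extend the current
  module starts one (leading carrier/adenylation modules).  An `A` joins an
  NRPS module only when that module has no A, T, E or terminator yet.
* `CoL` and `FkbH` start loading modules.
* Other domains extend the current module when the canonical within-module
  order allows it — for PKS modules the rank order KS < AT < {DH, ER, KR,
  MT} < ACP < TE/TD (reductive domains may appear in any order among
  themselves, which keeps the atypical enediyne `KS/AT/KR/DH` in one
  module) — otherwise they become standalone (trans-acting) entries.  This
  is how free-standing AT didomains (trans-AT systems), ER, and ACP
  proteins are represented.

Counting conventions: the PKS module count is the number of modular KS
domains (loading KS_1 included, KS3 excluded); the NRPS module count is the
number of A domains.  The reduction census classifies every KR domain by
the domain immediately preceding it in the stream: `DH` → DH-KR pair (C=C
double bond), `ER` → full reduction, anything else → bare KR (hydroxyl).
Classifying on the stream rather than per assembled module keeps
trans-acting reductive cassettes in the census; on clean (synthetic) lines
the stream census and the per-module `reduction_state` agree.

## Product backbones

One position per module, in line order: `pk` for a KS module; the A
substrate (or `x` when unknown) for an NRPS module; `y` for a condensation
module with a carrier but no A domain; `s` for a leading loading module
without an A domain (a CoL loading domain with a known starter, e.g. AHBA,
contributes that label instead); condensation-only fragments contribute
nothing.  Rewrites: an embedded MT prefixes `m`; a modifying condensation
domain (C_M) ahead of serine yields dehydroalanine (`Dha`); a
heterocyclization domain (C_Cy) ahead of cysteine yields a thiazoline,
written `Thz(Cys)`.  The D-configuration prefix `d` is asserted only where
two signals agree: the module carries an epimerization (E) domain *and* the
next condensation domain downstream is a D-acceptor (DCL) or dual E/C type;
a terminal epimerase with no downstream acceptor is not expressed.  The
chain is flagged terminated when a TE/TD domain occurs, and flagged
ambiguous when two or more TE-bearing ORFs exist (enterobactin-like lines,
where iterative use of a short DHB-Ser module is plausible; the predictor
never expands a putative multimer).

Substrate evidence enters as explicit per-module calls: two agreeing
predictors confirm a substrate; otherwise a ≥ 90 % identity of the
10-residue selectivity-conferring code against a reference code for the
predicted monomer confirms it (the survey's own flagship example is exactly
9/10, so the published "> 90 %" is implemented as ≥ 0.9; both the threshold
and the comparison table are parameters).  Calls can also be transferred
between orthologous lines — that is how the variant of the siderophore
cluster printed without substrates is predicted.

Polyketide features follow from the counts: chain carbons = 2 × module
count; double bonds = DH-KR pairs; hydroxyls = bare KRs; a product is
called a polyene at ≥ 3 double bonds (the smallest published polyene call
has 4; the threshold is a parameter).

## Classification

Category evidence: modular KS ⇒ type-I PKS; KS3 ⇒ type-III; any A/C/T ⇒
NRPS; both PKS and NRPS evidence ⇒ hybrid.  Type-II PKS systems are not
modelled (none occur in the packaged survey).  The enediyne flag requires a
single-module PKS ORF with KS, AT, KR and DH, KR *before* DH, and no ACP;
the 9- versus 10-membered warhead distinction needs phylogeny and is
reported as "ring size undetermined".  A line is AT-less when some real KS
extension module (two or more domains) lacks an embedded AT while a
free-standing AT exists in the cluster.

## Genus statistics

Ortholog groups are declared in the inventory (assigning them needs
sequence-level similarity, which is out of scope); each strain-specific
cluster is its own group, so the number of distinct metabolite types is the
number of groups.  `architecture_similarity` is provided as a label-free
fallback: a normalized global alignment over module signatures (match 1,
mismatch 0, gap 0 — i.e. the longest-common-subsequence fraction, computed
with Biopython's PairwiseAligner); it is 1 exactly for identical module
sequences and is not used for any published statistic.

## Dereplication

Only the [M+H]+ adduct is modelled, with proton mass 1.00728 Da.  The
matching tolerance defaults to 10 ppm — appropriate for high-resolution
Orbitrap peak lists (70,000 resolution) but not stated by the source
survey; it is a parameter and the headline result (no known compound
matches any observed peak) is robust over orders of magnitude around it.

## Synthetic data

The generator inverts the forward rules: from a product chain (or a
polyketide feature set) it emits domain strings that assemble and predict
back to exactly that product, seed-reproducibly.  `resplit` repartitions a
line over any number of ORFs with random strand marks (strand is cosmetic;
listed order is biosynthetic order).  Monomer labels are restricted to
those appearing in the packaged survey; chains may not end in a `d`-token
and a `d`-token may not precede `pk`/`Dha`/thiazoline, because the forward
rules could never produce them.  Synthetic lines are "clean": every domain
lands in a module, there are no trans-acting cassettes and no
typographical noise, so passing the 1,000-spec recovery test shows the
rules are mutually consistent, not that real annotation noise is handled;
the packaged survey transcription covers the noisy side.

## Known limitations and departures

Printed survey tables are not perfectly self-consistent, and three kinds of
departure are documented in the tests rather than patched over:

* One published product chain (cluster nrps-9) cannot be derived from its
  own printed domain strings by any deterministic per-module rule: the
  strings contain ten A-bearing modules while the printed chain has nine,
  and two modules with identical signatures print differently.  The
  prediction returns the ten-position chain; the corresponding acceptance
  test asserts the printed string and fails, by design.
* A few clusters encoded on the complementary strand were manually
  re-ordered by the survey's authors before reading the product off the
  collinearity rule; the package keeps table order (the only defensible
  order without coordinates), so those printed chains are checked by
  length, or excluded with the discrepancy noted in the test.
* Two prose module-census sentences in the survey (for one hybrid cluster's
  KR counts) do not verify under any counting convention tried; they are
  not asserted.
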