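"""Product-backbone prediction by the assembly-line collinearity rule.

The order of modules along a PKS/NRPS assembly line mirrors the order of
building blocks in the product.  For peptides, each NRPS module contributes
one residue: the A-domain substrate when predicted (``x`` when unknown),
``y`` when a condensation/carrier module lacks an A domain, with prefixes
``m`` (C-methylation by an embedded MT domain) and ``d`` (epimerised to the
D-configuration).  A leading loading module without an A domain contributes
the starter position ``s``; interleaved PKS modules contribute ``pk``.
Special condensation subtypes rewrite their residue: a modifying C (C_M)
in front of a serine yields dehydroalanine (``Dha``); a heterocyclisation C
(C_Cy) in front of a cysteine yields a thiazoline, written ``Thz(Cys)``.

The D-configuration is asserted only where both signals agree: the module
carries an epimerisation (E) domain *and* the next condensation domain
downstream is of the D-acceptor (DCL) or dual E/C type.  A terminal E with
no downstream acceptor is not expressed in the chain.

For polyketides, each module adds a C2 ketide unit whose oxidation state
follows the module's reductive domains: KR alone leaves a hydroxyl, DH-KR
yields a C=C double bond, DH-ER-KR full reduction; many double bonds imply
a polyene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional

from . import classify as _classify
from .assembly import AssemblyLine, count_pks_modules, reduction_census
from .substrates import SubstrateCall
from .tokens import display_monomer


@dataclass(frozen=True)
class MonomerChain:
    """Predicted product backbone as an ordered token chain."""

    tokens: tuple
    terminated: bool = False
    ambiguous_termination: bool = False

    def __post_init__(self):
        for i, t in enumerate(self.tokens):
            if t == "s" and i != 0:
                raise ValueError("starter token 's' only legal in first position")

    def __str__(self) -> str:
        return "-".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def aa_length(self) -> int:
        """Number of amino-acid positions (starter and ketide units excluded).

        Printed peptide-size words mix two conventions: "heptapeptide" for a
        6-residue chain plus starter counts every position, "nonapeptide"
        counts residues after the starter; both lengths are exposed
        (``len(chain)`` and ``aa_length``).
        """
        return sum(1 for t in self.tokens if t not in ("s", "pk"))


@dataclass(frozen=True)
class PolyketideFeatures:
    module_count: int
    chain_carbons: int
    double_bonds: int
    hydroxyls: int
    fully_reduced: int
    polyene: bool
    enediyne_flag: bool
    type3_starter: bool

    def __post_init__(self):
        if self.chain_carbons != 2 * self.module_count:
            raise ValueError("chain_carbons must equal 2 x module_count")


def _substrate_of(module, call: Optional[SubstrateCall]) -> tuple:
    """Resolve (label, tentative) for a module's A domain."""
    if call is not None:
        if call.confidence == "unknown":
            return "x", False
        return call.monomer, call.confidence == "tentative"
    a = module.first("A")
    if a is None or a.qualifier is None:
        return "x", False
    return a.qualifier, a.tentative


def predict_peptide(
    line: AssemblyLine,
    calls: Optional[Mapping[int, SubstrateCall]] = None,
) -> MonomerChain:
    """Predict the monomer chain of an assembly line.

    ``calls`` optionally overrides the substrate of A-bearing modules, keyed
    by the 0-based ordinal of the module among A-bearing modules (this is
    how code-based or ortholog-transferred substrate evidence enters the
    prediction).
    """
    if not line.modules:
        raise ValueError(f"{line.cluster_id}: no modules to predict from")
    calls = calls or {}

    # subtype of the next C domain downstream of each module (for the d rule)
    next_c: list = [None] * len(line.modules)
    upcoming = None
    for i in range(len(line.modules) - 1, -1, -1):
        next_c[i] = upcoming
        c = line.modules[i].first("C")
        if c is not None:
            upcoming = c.qualifier

    tokens: list[str] = []
    a_ordinal = 0
    for i, m in enumerate(line.modules):
        if m.has("KS"):
            tokens.append("pk")
            continue
        has_a = m.has("A")
        if has_a:
            label, _tent = _substrate_of(m, calls.get(a_ordinal))
            a_ordinal += 1
            c = m.first("C")
            subtype = c.qualifier if c is not None else None
            if subtype == "M" and label == "ser":
                tokens.append("Dha")
                continue
            if subtype == "Cy" and label == "cys":
                tokens.append("Thz(Cys)")
                continue
            word = display_monomer(label) if label != "x" else "x"
            if m.has("MT"):
                word = "m" + word
            if m.has("E") and next_c[i] in ("DCL", "Du"):
                word = "d" + word
            tokens.append(word)
            continue
        # no A domain in this module
        if m.kind in ("pks_loading", "nrps_loading") and i == 0:
            col = m.first("CoL")
            if col is not None and col.qualifier is not None:
                tokens.append(display_monomer(col.qualifier))
            else:
                tokens.append("s")
            continue
        if m.has("T") and m.has("C"):
            tokens.append("y")   # expected position lacking an A domain
            continue
        # carrier-only or condensation-only fragments contribute no position

    te_modules = sum(1 for m in line.modules if m.has("TE") or m.has("TD"))
    te_orfs = 0
    if line.cluster is not None:
        te_orfs = sum(
            1 for orf in line.cluster.orfs
            if any(t.kind in ("TE", "TD") for t in orf.tokens))
    return MonomerChain(
        tokens=tuple(tokens),
        terminated=te_modules > 0,
        ambiguous_termination=max(te_modules, te_orfs) >= 2,
    )


def predict_polyketide(
    line: AssemblyLine,
    polyene_threshold: int = 3,
) -> PolyketideFeatures:
    """Summarise the polyketide chemistry implied by an assembly line."""
    n = count_pks_modules(line)
    if n == 0:
        raise ValueError(f"{line.cluster_id}: no PKS modules")
    census = reduction_census(line)
    double_bonds = census["dh_kr"]
    return PolyketideFeatures(
        module_count=n,
        chain_carbons=2 * n,
        double_bonds=double_bonds,
        hydroxyls=census["kr_only"],
        fully_reduced=census["dh_er_kr"],
        polyene=double_bonds >= polyene_threshold,
        enediyne_flag=_classify.is_enediyne_pks(line),
        type3_starter=line.has_type3_ks,
    )


def chain_length(chain: MonomerChain) -> int:
    """Total number of chain positions (starter and ketide units included)."""
    return len(chain)


def composition(chain: MonomerChain) -> Counter:
    """Multiset of monomer labels; D-prefixes are stereochemistry, not
    identity, and are stripped; x/y/s/pk are counted separately."""
    counts: Counter = Counter()
    for t in chain.tokens:
        if t.startswith("d") and len(t) > 1 and t != "dx" and t[1].isupper():
            t = t[1:]
        elif t == "dx":
            t = "x"
        counts[t] += 1
    return counts


def merge_products(a: MonomerChain, b: MonomerChain) -> MonomerChain:
    """Union of two orthologous product chains of equal length.

    Positions that agree are kept; an Asp/Asn pair collapses to the
    ambiguity label Asx; any other disagreement becomes ``x``.  This mirrors
    how a single product string is printed for a cluster shared by strains
    whose variants differ in one substrate.
    """
    if len(a) != len(b):
        raise ValueError("cannot merge chains of different length")
    merged = []
    for x, y in zip(a.tokens, b.tokens):
        if x == y:
            merged.append(x)
        elif {x, y} == {"Asp", "Asn"}:
            merged.append("Asx")
        else:
            merged.append("x")
    return MonomerChain(tuple(merged),
                        terminated=a.terminated and b.terminated,
                        ambiguous_termination=a.ambiguous_termination
                        or b.ambiguous_termination)
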