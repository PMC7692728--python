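"""Merge ordered ORF architectures into one assembly line of modules.

Type-I PKS and NRPS enzymes work as assembly lines: each module performs one
chain-elongation cycle (minimally KS+AT+ACP for a polyketide extension,
C+A+T for a peptide extension).  In the genomes modelled here, single
modules are frequently split over several ORFs, so module inference must be
independent of ORF boundaries.  The segmentation rule is therefore defined
on the concatenated domain stream:

* every KS starts a new PKS module (type-III KS excepted — it is a
  free-standing enzyme and goes to the standalone list);
* every C starts a new NRPS module; an A or T that cannot extend the
  current module starts one as well (leading carrier/adenylation modules);
* CoL and FkbH start loading modules;
* all other domains extend the current module when the canonical
  within-module order allows it (KS < AT < {DH, ER, KR, MT} < ACP < TE/TD
  for PKS modules; C [A] T with optional MT/E then TE/TD for NRPS modules);
  domains that cannot extend anything become standalone (trans-acting)
  entries, which is how free-standing AT, ER or ACP proteins are
  represented.

Because the rule never consults ORF boundaries, module counts and product
predictions are invariant under re-splitting an assembly line into a
different set of ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .inventory import GeneCluster
from .tokens import DomainToken

MODULE_KINDS = (
    "pks_loading", "pks_extension", "nrps_loading", "nrps_extension",
    "termination_only", "trans_acting",
)

# canonical within-module position ranks for PKS domains
_PKS_RANK = {"KS": 0, "CoL": 0, "FkbH": 0, "AT": 1, "DH": 2, "ER": 2,
             "KR": 2, "MT": 2, "ACP": 3, "TE": 4, "TD": 4}
_PKS_MEMBERS = frozenset(_PKS_RANK)


@dataclass
class AssemblyModule:
    """One chain-elongation (or loading) unit of the assembly line."""

    kind: str
    tokens: tuple = ()
    # family used during construction: "pks" | "nrps" | "loading"
    family: str = ""

    def kinds(self) -> list:
        return [t.kind for t in self.tokens]

    def has(self, kind: str) -> bool:
        return any(t.kind == kind for t in self.tokens)

    def first(self, kind: str) -> Optional[DomainToken]:
        for t in self.tokens:
            if t.kind == kind:
                return t
        return None

    @property
    def carrier_present(self) -> bool:
        return self.has("ACP") or self.has("T")

    @property
    def reduction_state(self) -> Optional[str]:
        """Reduction state of a PKS module from its own domain adjacency.

        The state is decided by what immediately precedes the module's KR:
        DH -> one dehydration past the ketoreduction (C=C double bond),
        ER -> full reduction to methylene, anything else -> hydroxyl.
        """
        kinds = self.kinds()
        if "KR" not in kinds:
            return "none" if (self.family == "pks" or self.has("KS")) else None
        i = kinds.index("KR")
        prev = kinds[i - 1] if i > 0 else None
        if prev == "ER":
            return "dh_er_kr"
        if prev == "DH":
            return "dh_kr"
        return "kr_only"

    @property
    def modifications(self) -> frozenset:
        """NRPS-side modification flags carried by this module."""
        mods = set()
        if self.has("MT"):
            mods.add("methylated")
        if self.has("E"):
            mods.add("epimerized")
        c = self.first("C")
        if c is not None:
            if c.qualifier == "Du":
                mods.add("epimerized")
            elif c.qualifier == "M":
                mods.add("dehydrated")
            elif c.qualifier == "Cy":
                mods.add("heterocyclized")
        return frozenset(mods)


@dataclass
class AssemblyLine:
    cluster_id: str
    modules: tuple = ()
    standalone: tuple = ()
    has_type3_ks: bool = False
    tokens: tuple = ()          # full original token stream, in cluster order
    cluster: Optional[GeneCluster] = field(default=None, repr=False, compare=False)


def _can_extend_pks(module: AssemblyModule, kind: str) -> bool:
    if kind not in _PKS_RANK:
        return False
    max_rank = max((_PKS_RANK[k] for k in module.kinds() if k in _PKS_RANK),
                   default=-1)
    return _PKS_RANK[kind] >= max_rank


def assemble_line(cluster: GeneCluster) -> AssemblyLine:
    """Segment a parsed cluster into assembly-line modules plus standalones."""
    modules: list[AssemblyModule] = []
    standalone: list[DomainToken] = []
    has_t3 = False

    def start(family: str, tok: DomainToken) -> None:
        modules.append(AssemblyModule(kind="", tokens=(tok,), family=family))

    def extend(tok: DomainToken) -> None:
        modules[-1].tokens = modules[-1].tokens + (tok,)

    stream = cluster.tokens
    for tok in stream:
        k = tok.kind
        cur = modules[-1] if modules else None
        if k == "KS3":
            has_t3 = True
            standalone.append(tok)
        elif k == "KS":
            start("pks", tok)
        elif k == "C":
            start("nrps", tok)
        elif k in ("CoL", "FkbH"):
            start("loading", tok)
        elif k == "A":
            if (cur is not None and cur.family in ("nrps", "loading")
                    and not any(cur.has(x) for x in ("A", "T", "E", "TE", "TD"))):
                extend(tok)
            else:
                start("nrps", tok)
        elif k == "T":
            if (cur is not None and cur.family in ("nrps", "loading")
                    and not cur.has("TE") and not cur.has("TD")):
                extend(tok)
            else:
                start("nrps", tok)
        elif k == "E":
            if (cur is not None and cur.family == "nrps"
                    and not cur.has("TE") and not cur.has("TD")):
                extend(tok)
            else:
                standalone.append(tok)
        elif k in ("TE", "TD"):
            if (cur is not None and cur.family in ("nrps", "loading")
                    and not cur.has("TE") and not cur.has("TD")):
                extend(tok)
            elif cur is not None and cur.family == "pks" and _can_extend_pks(cur, k):
                extend(tok)
            else:
                standalone.append(tok)
        elif k == "MT":
            if (cur is not None and cur.family == "nrps"
                    and not cur.has("TE") and not cur.has("TD")):
                extend(tok)
            elif (cur is not None and cur.family in ("pks", "loading")
                    and _can_extend_pks(cur, k)):
                extend(tok)
            else:
                standalone.append(tok)
        else:  # AT, DH, ER, KR, ACP
            if cur is not None and cur.family == "loading":
                extend(tok)
            elif cur is not None and cur.family == "pks" and _can_extend_pks(cur, k):
                extend(tok)
            else:
                standalone.append(tok)

    for i, m in enumerate(modules):
        has_ks = m.has("KS")
        has_c = m.has("C")
        ks1 = any(t.kind == "KS" and t.qualifier == "first" for t in m.tokens)
        cs = any(t.kind == "C" and t.qualifier == "S" for t in m.tokens)
        loading = (m.family == "loading" or ks1 or cs
                   or (i == 0 and not has_ks and not has_c))
        if loading:
            if has_ks or m.family == "loading" or (
                    not has_c and not m.has("A") and not m.has("T")
                    and any(k in _PKS_MEMBERS for k in m.kinds())):
                m.kind = "pks_loading"
            else:
                m.kind = "nrps_loading"
        elif has_ks:
            m.kind = "pks_extension"
        elif has_c or m.has("A") or m.has("T"):
            m.kind = "nrps_extension"
        else:
            m.kind = "termination_only"

    return AssemblyLine(
        cluster_id=cluster.cluster_id,
        modules=tuple(modules),
        standalone=tuple(standalone),
        has_type3_ks=has_t3,
        tokens=tuple(stream),
        cluster=cluster,
    )


def count_pks_modules(line: AssemblyLine) -> int:
    """Number of PKS modules = number of modular KS domains (KS3 excluded)."""
    return sum(1 for m in line.modules for t in m.tokens if t.kind == "KS")


def count_nrps_modules(line: AssemblyLine) -> int:
    """Number of NRPS modules = number of A domains in modules."""
    return sum(1 for m in line.modules for t in m.tokens if t.kind == "A")


def reduction_census(line: AssemblyLine) -> dict:
    """Count ketoreduction outcomes over the whole assembly line.

    Every KR domain in the cluster's domain stream is assigned to exactly
    one state by the domain immediately preceding it: ``DH`` gives a DH-KR
    pair (C=C double bond), ``ER`` gives full reduction, anything else a
    bare KR (hydroxyl).  Classifying on the stream rather than per module
    keeps trans-acting reductive domains in the census.
    """
    census = {"kr_only": 0, "dh_kr": 0, "dh_er_kr": 0}
    kinds = [t.kind for t in line.tokens]
    for i, k in enumerate(kinds):
        if k != "KR":
            continue
        prev = kinds[i - 1] if i > 0 else None
        if prev == "ER":
            census["dh_er_kr"] += 1
        elif prev == "DH":
            census["dh_kr"] += 1
        else:
            census["kr_only"] += 1
    return census
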