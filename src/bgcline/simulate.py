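"""Synthetic assembly lines, ORF splittings and inventories with known truth.

The generator inverts the backbone rules: given a product chain (or a
polyketide feature set) it emits a gene cluster whose domain strings, once
assembled and predicted, return exactly that product.  This makes every
pipeline stage testable without sequence data, including the property that
matters most for the genomes modelled here — that re-splitting one assembly
line over arbitrarily many ORFs changes no count and no prediction.

Limitations mirror the forward rules: a D-configured residue needs a
downstream D-acceptor condensation domain, so a chain may not end in a
``d``-token, and a ``d``-token may not directly precede ``pk``, ``Dha`` or
a thiazoline (their condensation subtypes are fixed).  Monomer labels are
restricted to those occurring in the packaged survey.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence, Union

import numpy as np

from .assembly import assemble_line
from .backbone import MonomerChain, PolyketideFeatures, predict_peptide
from .classify import derive_category
from .inventory import ClusterInventory, GeneCluster
from .tokens import MONOMER_DISPLAY, MONOMERS, DomainToken, OrfArchitecture

_DISPLAY_TO_LABEL = {v: k for k, v in MONOMER_DISPLAY.items()}
_PRODUCT_RE = re.compile(r"^(?P<d>d)?(?P<m>m)?(?P<base>x|[A-Z][A-Za-z()]*)$")


class GenerationError(ValueError):
    """A product specification the generator cannot invert."""


def _residue_module(base: str, methylated: bool, epimerized: bool,
                    c_subtype: Optional[str]) -> list:
    toks: list[DomainToken] = []
    if c_subtype is not None:
        toks.append(DomainToken("C", c_subtype))
    if base == "x":
        toks.append(DomainToken("A"))
    else:
        label = _DISPLAY_TO_LABEL.get(base)
        if label is None or label not in MONOMERS:
            raise GenerationError(f"unsupported monomer token {base!r}")
        toks.append(DomainToken("A", label))
    if methylated:
        toks.append(DomainToken("MT"))
    toks.append(DomainToken("T"))
    if epimerized:
        toks.append(DomainToken("E"))
    return toks


def generate_line(
    product: Union[MonomerChain, Sequence[str], None] = None,
    polyketide: Optional[dict] = None,
    seed: int = 0,
    strain: str = "synthetic",
    cluster_id: str = "syn-1",
    ortholog_group: Optional[str] = None,
) -> GeneCluster:
    """Emit a cluster whose assembled prediction equals the given product.

    ``product`` is a peptide chain (MonomerChain or token sequence);
    ``polyketide`` is a mapping with module_count / double_bonds /
    hydroxyls / fully_reduced for a pure PKS line.  Exactly one must be
    given.  Seed-reproducible.
    """
    rng = np.random.default_rng(seed)
    if (product is None) == (polyketide is None):
        raise GenerationError("give exactly one of product or polyketide")

    modules: list[list[DomainToken]] = []
    terminated = False

    if product is not None:
        chain = list(product.tokens if isinstance(product, MonomerChain)
                     else product)
        terminated = bool(getattr(product, "terminated", False))
        if not chain:
            raise GenerationError("empty product chain")
        force_dcl = False
        for i, tok in enumerate(chain):
            first = i == 0
            if tok == "s":
                if not first:
                    raise GenerationError("'s' is only legal as first token")
                modules.append(
                    [DomainToken("T")] if rng.random() < 0.5
                    else [DomainToken("FkbH"), DomainToken("T")])
                continue
            if tok == "pk":
                if force_dcl:
                    raise GenerationError("a d-residue cannot precede 'pk'")
                modules.append([DomainToken("KS"), DomainToken("AT", "m"),
                                DomainToken("ACP")])
                continue
            if tok == "y":
                modules.append([
                    DomainToken("C", "DCL" if force_dcl else "LCL"),
                    DomainToken("T")])
                force_dcl = False
                continue
            if tok == "Dha":
                if force_dcl:
                    raise GenerationError("a d-residue cannot precede 'Dha'")
                modules.append(_residue_module("Ser", False, False, "M"))
                continue
            m = _PRODUCT_RE.match(tok)
            if m and m.group("base").startswith("Thz(") and m.group("base").endswith(")"):
                if m.group("d") or m.group("m"):
                    raise GenerationError(f"prefixes not supported on {tok!r}")
                if force_dcl:
                    raise GenerationError("a d-residue cannot precede a thiazoline")
                inner = m.group("base")[4:-1]
                if inner != "Cys":
                    raise GenerationError(f"unsupported thiazoline residue {inner!r}")
                modules.append(_residue_module("Cys", False, False, "Cy"))
                continue
            if m is None:
                raise GenerationError(f"unsupported product token {tok!r}")
            epimerized = m.group("d") is not None
            if epimerized and i == len(chain) - 1:
                raise GenerationError(
                    "a d-residue needs a downstream D-acceptor module; "
                    "it cannot terminate the chain")
            subtype = "DCL" if force_dcl else ("LCL" if not first else
                                               ("LCL" if rng.random() < 0.8 else None))
            modules.append(_residue_module(
                m.group("base"), m.group("m") is not None, epimerized, subtype))
            force_dcl = epimerized
    else:
        n = int(polyketide["module_count"])
        b = int(polyketide.get("double_bonds", 0))
        h = int(polyketide.get("hydroxyls", 0))
        f = int(polyketide.get("fully_reduced", 0))
        if n < 1 or b + h + f > n:
            raise GenerationError("inconsistent polyketide feature counts")
        terminated = bool(polyketide.get("terminated", False))
        states = (["dh_kr"] * b + ["kr_only"] * h + ["dh_er_kr"] * f
                  + ["none"] * (n - b - h - f))
        rng.shuffle(states)
        for st in states:
            mod = [DomainToken("KS"), DomainToken("AT", "m")]
            if st == "dh_kr":
                mod += [DomainToken("DH"), DomainToken("KR")]
            elif st == "kr_only":
                mod += [DomainToken("KR")]
            elif st == "dh_er_kr":
                mod += [DomainToken("DH"), DomainToken("ER"), DomainToken("KR")]
            mod.append(DomainToken("ACP"))
            modules.append(mod)

    if terminated:
        modules[-1] = modules[-1] + [DomainToken("TE")]

    tokens: list[DomainToken] = []
    boundaries: list[int] = []
    for mod in modules:
        if tokens:
            boundaries.append(len(tokens))
        tokens.extend(mod)
    orf = OrfArchitecture(locus_tag=f"{cluster_id}_0001", strand="+",
                          tokens=tuple(tokens), boundaries=tuple(boundaries))
    probe = GeneCluster(cluster_id=cluster_id, strain=strain,
                        declared_category="nrps", ortholog_group=ortholog_group
                        or cluster_id, orfs=(orf,))
    category = derive_category(assemble_line(probe))
    return GeneCluster(cluster_id=cluster_id, strain=strain,
                       declared_category=category,
                       ortholog_group=ortholog_group or cluster_id, orfs=(orf,))


def resplit(cluster: GeneCluster, n_orfs: int, seed: int = 0) -> GeneCluster:
    """Repartition a cluster's domain stream over ``n_orfs`` ORFs.

    The concatenated token sequence is unchanged; cut points and strand
    marks are random (strand is cosmetic: biosynthetic order is the listed
    order).  Seed-reproducible.
    """
    rng = np.random.default_rng(seed)
    stream = list(cluster.tokens)
    if not (1 <= n_orfs <= len(stream)):
        raise ValueError(f"n_orfs must be in [1, {len(stream)}], got {n_orfs}")
    cuts = sorted(rng.choice(np.arange(1, len(stream)), size=n_orfs - 1,
                             replace=False).tolist())
    edges = [0] + cuts + [len(stream)]
    orfs = []
    for i in range(n_orfs):
        orfs.append(OrfArchitecture(
            locus_tag=f"{cluster.cluster_id}_r{i + 1:04d}",
            strand="-" if rng.random() < 0.3 else "+",
            tokens=tuple(stream[edges[i]:edges[i + 1]]),
            boundaries=()))
    return GeneCluster(cluster_id=cluster.cluster_id, strain=cluster.strain,
                       declared_category=cluster.declared_category,
                       ortholog_group=cluster.ortholog_group, orfs=tuple(orfs))


_RESIDUES = ("Asn", "Ser", "Gly", "Val", "Thr", "Leu", "Ala", "Asp",
             "Phe", "Tyr", "Orn", "Pro", "Gln", "Cys", "x")


def random_chain(rng: np.random.Generator, max_len: int = 8) -> MonomerChain:
    """A random product chain over the supported token alphabet."""
    n = int(rng.integers(1, max_len + 1))
    base = []
    for _ in range(n):
        r = rng.random()
        if r < 0.08:
            base.append("y")
        elif r < 0.14:
            base.append("pk")
        elif r < 0.18:
            base.append("Dha")
        elif r < 0.21:
            base.append("Thz(Cys)")
        else:
            base.append(str(rng.choice(_RESIDUES)))
    if rng.random() < 0.3:
        base = ["s"] + base
    out = []
    for i, tok in enumerate(base):
        if tok in ("s", "y", "pk", "Dha", "Thz(Cys)"):
            out.append(tok)
            continue
        if rng.random() < 0.25:
            tok = "m" + tok
        nxt = base[i + 1] if i + 1 < len(base) else None
        if nxt in _RESIDUES or nxt == "y":
            if rng.random() < 0.2:
                tok = "d" + tok
        out.append(tok)
    return MonomerChain(tuple(out), terminated=bool(rng.random() < 0.5))


def generate_inventory(
    n_strains: int,
    n_shared_groups: int,
    n_specific_per_strain: Union[int, Sequence[int]],
    seed: int = 0,
    group_spans: Optional[Sequence[int]] = None,
) -> ClusterInventory:
    """A multi-strain inventory with controlled sharing structure.

    Each shared ortholog group spans ``group_spans[i]`` strains (drawn in
    [2, n_strains] from the seed when not given) with one architecture
    cloned across members; strain-specific clusters form singleton groups.
    ``genus_summary`` on the result returns exactly the requested
    shared/specific structure.
    """
    if n_strains < 1 or n_shared_groups < 0:
        raise ValueError("counts must be nonnegative (and at least one strain)")
    if n_shared_groups > 0 and n_strains < 2:
        raise ValueError("shared groups need at least two strains")
    rng = np.random.default_rng(seed)
    if isinstance(n_specific_per_strain, int):
        specific = [n_specific_per_strain] * n_strains
    else:
        specific = list(n_specific_per_strain)
        if len(specific) != n_strains:
            raise ValueError("n_specific_per_strain length must equal n_strains")
    strains = tuple(f"strain{i + 1:02d}" for i in range(n_strains))
    if group_spans is None:
        group_spans = [int(rng.integers(2, n_strains + 1))
                       for _ in range(n_shared_groups)]
    if len(group_spans) != n_shared_groups or any(
            not (2 <= s <= n_strains) for s in group_spans):
        raise ValueError("group_spans must give one span in [2, n_strains] "
                         "per shared group")

    clusters = []
    for g, span in enumerate(group_spans):
        members = sorted(rng.choice(n_strains, size=span, replace=False).tolist())
        chain = random_chain(rng)
        template = generate_line(chain, seed=int(rng.integers(2 ** 31)),
                                 cluster_id=f"shared-{g + 1}")
        for s in members:
            clusters.append(GeneCluster(
                cluster_id=template.cluster_id, strain=strains[s],
                declared_category=template.declared_category,
                ortholog_group=template.ortholog_group, orfs=template.orfs))
    for s, k in enumerate(specific):
        for j in range(k):
            cid = f"{strains[s]}-sp{j + 1}"
            clusters.append(generate_line(
                random_chain(rng), seed=int(rng.integers(2 ** 31)),
                strain=strains[s], cluster_id=cid))
    return ClusterInventory(strains=strains, clusters=tuple(clusters))
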