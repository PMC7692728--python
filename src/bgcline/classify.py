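"""Cluster categories and architecture-signature flags.

Categories follow the usual survey taxonomy: type-I PKS (modular KS
domains), type-III PKS (free-standing chalcone-synthase-like KS), hybrid
type-I/type-III, NRPS, and hybrid PKS/NRPS.  Two architecture signatures
are derived: the iterative enediyne PKS (the warhead-initiating PKS of the
9-/10-membered enediyne antibiotics, recognisable by its atypical
KS/AT/KR/DH domain order — KR *before* DH — and missing ACP in the
annotation), and AT-less (trans-AT) lines whose extension modules are
served by a free-standing acyltransferase.  Type-II PKS systems are not
modelled (none occur in the surveyed genomes).
"""

from __future__ import annotations

from .assembly import AssemblyLine
from .inventory import GeneCluster


def derive_category(line: AssemblyLine) -> str:
    """Assign one of t1pks / t3pks / t1pks_t3pks / nrps / pks_nrps."""
    if not line.tokens:
        raise ValueError(f"{line.cluster_id}: empty assembly line")
    kinds = {t.kind for t in line.tokens}
    has_mod = "KS" in kinds
    has_t3 = line.has_type3_ks
    has_nrps = bool(kinds & {"A", "C", "T"})
    if has_nrps and (has_mod or has_t3):
        return "pks_nrps"
    if has_mod and has_t3:
        return "t1pks_t3pks"
    if has_mod:
        return "t1pks"
    if has_t3:
        return "t3pks"
    if has_nrps:
        return "nrps"
    raise ValueError(
        f"{line.cluster_id}: no PKS or NRPS domains; cannot categorize")


def _orfs_of(obj):
    if isinstance(obj, GeneCluster):
        return obj.orfs
    if getattr(obj, "cluster", None) is not None:
        return obj.cluster.orfs
    raise ValueError("need a GeneCluster or an AssemblyLine with its cluster")


def is_enediyne_pks(obj) -> bool:
    """True iff some single-module PKS ORF shows the enediyne signature:
    KS + AT + KR + DH with KR preceding DH and no ACP.

    The 9- versus 10-membered warhead distinction needs phylogeny and is
    not derivable from architecture; flagged lines are reported as
    "enediyne, ring size undetermined".
    """
    for orf in _orfs_of(obj):
        kinds = [t.kind for t in orf.tokens]
        if kinds.count("KS") != 1:
            continue
        if "ACP" in kinds or "AT" not in kinds:
            continue
        if "KR" in kinds and "DH" in kinds and kinds.index("KR") < kinds.index("DH"):
            return True
    return False


def is_at_less(line: AssemblyLine) -> bool:
    """True iff a KS extension module lacks an embedded AT while a
    free-standing (trans-acting) AT is present in the cluster."""
    has_trans_at = any(t.kind == "AT" for t in line.standalone)
    if not has_trans_at:
        return False
    for m in line.modules:
        if m.has("KS") and len(m.tokens) >= 2 and not m.has("AT"):
            return True
    return False
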