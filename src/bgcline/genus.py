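"""Genus-level sharing statistics over a multi-strain cluster inventory.

Ortholog-group labels partition the clusters; a group spanning two or more
strains is *shared*, a singleton group is a strain-specific cluster.  The
number of distinct secondary-metabolite types in the genus is the number of
ortholog groups (each strain-specific cluster counting as its own type).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .assembly import assemble_line
from .classify import derive_category
from .inventory import CATEGORIES, ClusterInventory, GeneCluster


@dataclass(frozen=True)
class GenusSummary:
    per_strain: dict
    total_clusters: int
    distinct_types: int
    shared_groups: int
    unshared_clusters: int
    specific_per_strain: dict

    def __post_init__(self):
        if self.total_clusters != sum(v["total"] for v in self.per_strain.values()):
            raise ValueError("total_clusters must equal the sum of per-strain totals")
        if self.distinct_types != self.shared_groups + self.unshared_clusters:
            raise ValueError("distinct_types must equal shared + unshared")
        if self.unshared_clusters != sum(self.specific_per_strain.values()):
            raise ValueError("unshared_clusters must equal the sum of specifics")


def genus_summary(inv: ClusterInventory) -> GenusSummary:
    """Reconstruct per-strain category counts and sharing statistics."""
    per_strain = {}
    for s in inv.strains:
        counts = Counter(
            derive_category(assemble_line(c)) for c in inv.clusters if c.strain == s)
        row = {cat: counts.get(cat, 0) for cat in CATEGORIES}
        row["total"] = sum(counts.values())
        per_strain[s] = row

    group_strains: dict[str, set] = {}
    group_sizes: Counter = Counter()
    for c in inv.clusters:
        group_strains.setdefault(c.ortholog_group, set()).add(c.strain)
        group_sizes[c.ortholog_group] += 1

    shared = sum(1 for g, ss in group_strains.items() if len(ss) >= 2)
    specific = {s: 0 for s in inv.strains}
    unshared = 0
    for g, ss in group_strains.items():
        if len(ss) < 2:
            unshared += group_sizes[g]
            specific[next(iter(ss))] += group_sizes[g]

    return GenusSummary(
        per_strain=per_strain,
        total_clusters=len(inv.clusters),
        distinct_types=len(group_strains),
        shared_groups=shared,
        unshared_clusters=unshared,
        specific_per_strain=specific,
    )


def sharing_matrix(inv: ClusterInventory) -> pd.DataFrame:
    """Strain x strain counts of co-occurring ortholog groups.

    Off-diagonal cells count ortholog groups present in both strains; the
    diagonal holds per-strain cluster totals.
    """
    group_strains: dict[str, set] = {}
    for c in inv.clusters:
        group_strains.setdefault(c.ortholog_group, set()).add(c.strain)
    strains = list(inv.strains)
    mat = pd.DataFrame(0, index=strains, columns=strains, dtype=int)
    for s in strains:
        mat.loc[s, s] = sum(1 for c in inv.clusters if c.strain == s)
    for ss in group_strains.values():
        members = [s for s in strains if s in ss]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                mat.loc[a, b] += 1
                mat.loc[b, a] += 1
    return mat


def _module_signatures(cluster: GeneCluster) -> list[str]:
    line = assemble_line(cluster)
    return ["/".join(str(t) for t in m.tokens) for m in line.modules]


def architecture_similarity(
    a: GeneCluster,
    b: GeneCluster,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = 0.0,
) -> float:
    """Normalized global alignment score over module-level signatures.

    Modules are compared as opaque symbols (their canonical domain strings);
    the global alignment score is normalized by the longer module count, so
    the score is 1 exactly when the two module sequences are identical.
    With the default costs the score is the longest-common-subsequence
    fraction.
    """
    sig_a = _module_signatures(a)
    sig_b = _module_signatures(b)
    if not sig_a and not sig_b:
        return 1.0
    if not sig_a or not sig_b:
        return 0.0
    alphabet = {s: chr(0x100 + i) for i, s in enumerate(dict.fromkeys(sig_a + sig_b))}
    seq_a = "".join(alphabet[s] for s in sig_a)
    seq_b = "".join(alphabet[s] for s in sig_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    score = aligner.score(seq_a, seq_b)
    return score / (match * max(len(sig_a), len(sig_b)))
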