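"""Cluster inventories: schema, IO and the packaged *Phytohabitans* survey.

An inventory is a multi-strain catalogue of PKS/NRPS gene clusters.  Each
cluster row carries the strain, a cluster id (unique within the strain), an
ortholog-group label (shared by orthologous clusters across strains; each
strain-specific cluster is its own group), a declared category, and the
ordered ORFs with their domain-organization strings.

The packaged fixture transcribes the published survey of the four
*Phytohabitans* type strains (P. flavus NBRC 107702, P. rumicis NBRC 108638,
P. houttuyneae NBRC 108639, P. suffuscus NBRC 105367): 56 gene clusters in
40 ortholog groups.  One naming collision in the source tables (two distinct
clusters both labelled t3pks-4, one shared and one specific to
P. houttuyneae) is resolved by renaming the specific one ``t3pks-4b`` so
that identity-based statistics are well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .tokens import OrfArchitecture, ParseError, parse_architecture, serialize_architecture

CATEGORIES = ("t1pks", "t3pks", "t1pks_t3pks", "nrps", "pks_nrps")

STRAINS = ("flavus", "rumicis", "houttuyneae", "suffuscus")

#: columns of the TSV schema (JSON uses the same field names).
SCHEMA_COLUMNS = (
    "strain", "cluster_id", "ortholog_group", "declared_category",
    "locus_tag", "strand", "length_aa", "domain_string",
)


class InventoryError(ValueError):
    """Schema violation in an inventory file, naming row and field."""


@dataclass(frozen=True)
class GeneCluster:
    """One gene cluster: ordered ORFs in biosynthetic (table) order."""

    cluster_id: str
    strain: str
    declared_category: str
    ortholog_group: str
    orfs: tuple

    def __post_init__(self):
        if self.declared_category not in CATEGORIES:
            raise ValueError(
                f"{self.strain}/{self.cluster_id}: unknown category "
                f"{self.declared_category!r}")
        if not self.orfs:
            raise ValueError(f"{self.strain}/{self.cluster_id}: cluster has no ORFs")

    @property
    def tokens(self) -> tuple:
        return tuple(t for orf in self.orfs for t in orf.tokens)


@dataclass(frozen=True)
class ClusterInventory:
    strains: tuple
    clusters: tuple

    def __post_init__(self):
        seen = set()
        for c in self.clusters:
            if c.strain not in self.strains:
                raise ValueError(f"cluster {c.cluster_id}: strain {c.strain!r} "
                                 "not in inventory strains")
            key = (c.strain, c.cluster_id)
            if key in seen:
                raise ValueError(f"duplicate cluster id {c.cluster_id!r} in {c.strain}")
            seen.add(key)
        groups: dict[str, set] = {}
        for c in self.clusters:
            groups.setdefault(c.ortholog_group, set()).add(c.strain)
        for g, members in groups.items():
            n = sum(1 for c in self.clusters if c.ortholog_group == g)
            if n >= 2 and len(members) < 2:
                raise ValueError(
                    f"ortholog group {g!r} has {n} members but spans one strain")

    def __len__(self) -> int:
        return len(self.clusters)

    def get(self, strain: str, cluster_id: str) -> GeneCluster:
        for c in self.clusters:
            if c.strain == strain and c.cluster_id == cluster_id:
                return c
        raise KeyError(f"{strain}/{cluster_id}")

    def by_group(self, group: str) -> tuple:
        return tuple(c for c in self.clusters if c.ortholog_group == group)

    def restrict(self, strains: Sequence[str]) -> "ClusterInventory":
        keep = tuple(s for s in self.strains if s in strains)
        return ClusterInventory(
            strains=keep,
            clusters=tuple(c for c in self.clusters if c.strain in keep))


# ---------------------------------------------------------------------------
# IO

def _rows_to_inventory(rows: Iterable[dict], source: str = "") -> ClusterInventory:
    strains: list[str] = []
    order: list[tuple] = []
    orfs: dict[tuple, list] = {}
    meta: dict[tuple, tuple] = {}
    for i, row in enumerate(rows, start=1):
        for f in SCHEMA_COLUMNS[:-2]:
            if f not in row or str(row[f]).strip() == "":
                raise InventoryError(f"{source} row {i}: missing field {f!r}")
        strain = str(row["strain"]).strip()
        cid = str(row["cluster_id"]).strip()
        strand = str(row.get("strand", "+")).strip() or "+"
        if strand not in ("+", "-"):
            raise InventoryError(f"{source} row {i}: field 'strand' must be + or -, "
                                 f"got {strand!r}")
        raw_len = str(row.get("length_aa", "")).strip()
        length: Optional[int] = None
        if raw_len not in ("", "n/a", "None", "nan"):
            try:
                length = int(float(raw_len))
            except ValueError as exc:
                raise InventoryError(
                    f"{source} row {i}: field 'length_aa' not an integer: "
                    f"{raw_len!r}") from exc
        try:
            arch = parse_architecture(
                row["domain_string"], locus_tag=str(row["locus_tag"]).strip(),
                strand=strand, length_aa=length)
        except ParseError as exc:
            raise InventoryError(
                f"{source} row {i}: field 'domain_string': {exc}") from exc
        if strain not in strains:
            strains.append(strain)
        key = (strain, cid)
        if key not in orfs:
            order.append(key)
            orfs[key] = []
            meta[key] = (str(row["ortholog_group"]).strip(),
                         str(row["declared_category"]).strip())
        elif (str(row["ortholog_group"]).strip(),
              str(row["declared_category"]).strip()) != meta[key]:
            raise InventoryError(
                f"{source} row {i}: inconsistent ortholog_group/declared_category "
                f"for cluster {cid!r}")
        orfs[key].append(arch)
    clusters = []
    for key in order:
        group, cat = meta[key]
        try:
            clusters.append(GeneCluster(
                cluster_id=key[1], strain=key[0], declared_category=cat,
                ortholog_group=group, orfs=tuple(orfs[key])))
        except ValueError as exc:
            raise InventoryError(f"{source}: {exc}") from exc
    return ClusterInventory(strains=tuple(strains), clusters=tuple(clusters))


def _inventory_to_rows(inv: ClusterInventory) -> list[dict]:
    rows = []
    for c in inv.clusters:
        for orf in c.orfs:
            rows.append({
                "strain": c.strain,
                "cluster_id": c.cluster_id,
                "ortholog_group": c.ortholog_group,
                "declared_category": c.declared_category,
                "locus_tag": orf.locus_tag,
                "strand": orf.strand,
                "length_aa": "" if orf.length_aa is None else orf.length_aa,
                "domain_string": serialize_architecture(orf),
            })
    return rows


def load_inventory(path) -> ClusterInventory:
    """Load an inventory from TSV or JSON (decided by file extension)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        rows = payload["rows"] if isinstance(payload, dict) else payload
        return _rows_to_inventory(rows, source=path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise InventoryError(f"{path}: missing columns {missing}")
    return _rows_to_inventory(df.to_dict("records"), source=path)


def dump_inventory(inv: ClusterInventory, path) -> None:
    path = str(path)
    rows = _inventory_to_rows(inv)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump({"rows": rows}, fh, indent=1)
    else:
        pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS)).to_csv(
            path, sep="\t", index=False)


_FIXTURE_CACHE: Optional[ClusterInventory] = None


def packaged_fixture() -> ClusterInventory:
    """The packaged four-strain *Phytohabitans* cluster inventory."""
    global _FIXTURE_CACHE
    if _FIXTURE_CACHE is None:
        ref = resources.files("bgcline").joinpath("data/phytohabitans_clusters.tsv")
        with resources.as_file(ref) as p:
            _FIXTURE_CACHE = load_inventory(p)
    return _FIXTURE_CACHE


def packaged_products() -> pd.DataFrame:
    """Printed deduced-product annotations for the packaged inventory."""
    ref = resources.files("bgcline").joinpath("data/phytohabitans_products.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
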