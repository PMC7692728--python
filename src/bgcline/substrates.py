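"""A-domain substrate consensus and condensation-subtype semantics.

Adenylation (A) domains select the amino-acid monomer an NRPS module loads.
Bioinformatic substrate prediction combines independent predictors plus the
~10 selectivity-conferring active-site residues ("specificity code").  The
consensus rule implemented here: a substrate is *confirmed* when two
predictors agree, or when the observed specificity code is at least 90 %
identical to a reference code for the predicted monomer; a prediction made
by a single tool only is kept but flagged *tentative* (italics in printed
tables); no prediction at all gives the unknown monomer ``x``.

Note the >90 % phrasing in the literature is applied as >=0.9 here: the
canonical example (DAWEVGLVDK vs the scabichelin reference DAWEGGLVDK,
one mismatch in ten) is exactly 0.9 and is treated as a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import pandas as pd


@dataclass(frozen=True)
class SpecificityCode:
    """Fixed-length (10) selectivity-conferring residue signature."""

    residues: str

    def __post_init__(self):
        if len(self.residues) != 10 or not self.residues.isalpha() \
                or not self.residues.isupper():
            raise ValueError(
                f"specificity code must be 10 uppercase letters, got "
                f"{self.residues!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SubstrateCall:
    monomer: str = "x"
    confidence: str = "unknown"   # confirmed | tentative | unknown
    evidence: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.confidence not in ("confirmed", "tentative", "unknown"):
            raise ValueError(f"bad confidence {self.confidence!r}")
        if (self.monomer == "x") != (self.confidence == "unknown"):
            raise ValueError("monomer 'x' if and only if confidence is unknown")
        if self.confidence == "confirmed" and not self.evidence:
            raise ValueError("confirmed call requires at least one evidence tag")


def code_identity(a: SpecificityCode, b: SpecificityCode) -> float:
    """Fraction of matching positions between two equal-length codes."""
    if len(a) != len(b):
        raise ValueError("specificity codes differ in length")
    return sum(x == y for x, y in zip(a.residues, b.residues)) / len(a)


def consensus_substrate(
    pred_primary: Optional[str],
    pred_secondary: Optional[str],
    code: Optional[SpecificityCode],
    reference_codes: Optional[Mapping[str, SpecificityCode]] = None,
    threshold: float = 0.9,
) -> SubstrateCall:
    """Combine predictor outputs and specificity-code identity into one call."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    reference_codes = reference_codes or {}
    evidence = set()
    if pred_primary is not None and pred_primary == pred_secondary:
        evidence.add("predictor_agreement")
    if (pred_primary is not None and code is not None
            and pred_primary in reference_codes
            and code_identity(code, reference_codes[pred_primary]) >= threshold):
        evidence.add("code_match")
    if pred_primary is None:
        return SubstrateCall()
    if evidence:
        return SubstrateCall(pred_primary, "confirmed", frozenset(evidence))
    return SubstrateCall(pred_primary, "tentative")


_C_EFFECTS = {
    "LCL": "link_L",
    "DCL": "link_after_D",
    "Du": "epimerize_and_link",
    "M": "modify",
    "S": "acylate_start",
    "Cy": "heterocyclize",
}


def c_subtype_effect(subtype: str) -> str:
    """Chemical effect of a condensation-domain subtype on the growing chain."""
    try:
        return _C_EFFECTS[subtype]
    except KeyError:
        raise ValueError(f"unknown C-domain subtype {subtype!r}") from None


def packaged_reference_codes() -> dict:
    """Reference specificity codes shipped with the package (TSV-editable)."""
    ref = resources.files("bgcline").joinpath("data/specificity_codes.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    return {row["monomer"]: SpecificityCode(row["code"]) for _, row in df.iterrows()}
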