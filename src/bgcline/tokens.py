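"""Domain-organization grammar for type-I PKS / NRPS assembly lines.

A biosynthetic gene cluster is annotated here as an ordered series of open
reading frames (ORFs), each carrying an ordered string of catalytic domains.
The notation follows the convention used in cluster-mining surveys of
actinomycete genomes: ``/`` separates domains, ``-`` separates modules, and
subscripts qualify a domain (``AT_m`` = acyltransferase loading malonyl-CoA,
``A_ser`` = adenylation domain activating serine, ``LCL``/``DCL``/``C_Du``/
``C_M``/``C_S``/``C_Cy`` = condensation-domain subtypes).  Printed tables in
the literature are typographically noisy (en-dashes, spaces instead of
slashes, superscript subtype prefixes, italics for low-confidence substrate
predictions); :func:`parse_architecture` accepts that whole dialect and
:func:`serialize_architecture` emits one canonical ASCII form, with a
trailing ``?`` standing in for italics (tentative substrate).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Optional


class ParseError(ValueError):
    """A domain-organization string that does not conform to the grammar."""

    def __init__(self, message: str, token: str = "", position: Optional[int] = None):
        self.token = token
        self.position = position
        super().__init__(message)


#: catalytic-domain classes.  ``KS3`` is the single-domain type-III PKS
#: (chalcone-synthase-like); it is not a module of a type-I assembly line.
DOMAIN_KINDS = frozenset(
    {
        "KS", "KS3", "AT", "ACP", "KR", "DH", "ER", "MT",
        "A", "T", "C", "E", "TE", "TD", "CoL", "FkbH",
    }
)

#: amino-acid / monomer labels legal as A-domain substrate qualifiers.
MONOMERS = frozenset(
    {
        "asn", "ser", "gly", "orn", "haorn", "val", "thr", "tyr", "asp",
        "phe", "leu", "cys", "pro", "gln", "dhb", "aad", "ala",
    }
)

#: CoA-ligase loading domains may carry a starter-unit label.
COL_MONOMERS = MONOMERS | {"ahba"}

AT_QUALIFIERS = frozenset({"m", "p", "e"})
C_SUBTYPES = frozenset({"LCL", "DCL", "Du", "M", "S", "Cy"})
KS_QUALIFIERS = frozenset({"first"})

#: human-readable monomer labels used in product chains.
MONOMER_DISPLAY = {
    "asn": "Asn", "ser": "Ser", "gly": "Gly", "orn": "Orn", "haorn": "HaOrn",
    "horn": "hOrn", "val": "Val", "thr": "Thr", "tyr": "Tyr", "asp": "Asp",
    "phe": "Phe", "leu": "Leu", "cys": "Cys", "pro": "Pro", "gln": "Gln",
    "dhb": "DHB", "aad": "Aad", "ala": "Ala", "ahba": "AHBA", "asx": "Asx",
}


@dataclass(frozen=True)
class DomainToken:
    """One catalytic domain: class, optional qualifier, confidence flag.

    ``tentative`` corresponds to italics in printed tables (substrate
    predicted by a single predictor only) and is legal only on A-domain
    substrate qualifiers.
    """

    kind: str
    qualifier: Optional[str] = None
    tentative: bool = False

    def __post_init__(self):
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        q = self.qualifier
        if q is not None:
            legal = {
                "AT": AT_QUALIFIERS,
                "A": MONOMERS,
                "C": C_SUBTYPES,
                "KS": KS_QUALIFIERS,
                "CoL": COL_MONOMERS,
            }.get(self.kind)
            if legal is None or q not in legal:
                raise ValueError(f"qualifier {q!r} is not legal for kind {self.kind}")
        if self.tentative and not (self.kind == "A" and q is not None):
            raise ValueError("tentative flag is only legal on A-domain substrates")

    def __str__(self) -> str:  # canonical ASCII form
        if self.kind == "C" and self.qualifier is not None:
            if self.qualifier in ("LCL", "DCL"):
                return self.qualifier
            return f"C_{self.qualifier}"
        if self.kind == "KS" and self.qualifier == "first":
            return "KS_1"
        s = self.kind
        if self.qualifier is not None:
            s += f"_{self.qualifier}"
        if self.tentative:
            s += "?"
        return s


@dataclass(frozen=True)
class OrfArchitecture:
    """One ORF: ordered domain tokens plus printed module-separator positions.

    ``boundaries`` holds indices *i* meaning a module separator was printed
    between token *i-1* and token *i*; they are cosmetic (module inference is
    done downstream from domain classes, so that it is invariant to how an
    assembly line is split over ORFs) but preserved for exact round-tripping.
    """

    locus_tag: str = ""
    strand: str = "+"
    length_aa: Optional[int] = None
    tokens: tuple = ()
    boundaries: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.length_aa is not None and self.length_aa <= 0:
            raise ValueError("length_aa must be positive when known")
        prev = 0
        for b in self.boundaries:
            if not (0 < b < len(self.tokens)):
                raise ValueError(f"boundary {b} not interior to {len(self.tokens)} tokens")
            if b <= prev:
                raise ValueError("boundaries must be strictly increasing")
            prev = b

    @property
    def architecture(self) -> str:
        return serialize_architecture(self)


# ---------------------------------------------------------------------------
# tokenization

_DASHES = "‐‑‒–—―−"
_TYPE3_RE = re.compile(r"KS\s*\(\s*type[-\s]?III\s+PKS\s*\)", re.IGNORECASE)

_SIMPLE_KINDS = {
    "KS": ("KS", None), "KS3": ("KS3", None), "KS_1": ("KS", "first"),
    "KS1": ("KS", "first"), "ACP": ("ACP", None), "KR": ("KR", None),
    "DH": ("DH", None), "ER": ("ER", None), "MT": ("MT", None),
    "T": ("T", None), "E": ("E", None), "TE": ("TE", None), "TD": ("TD", None),
    "AT": ("AT", None), "A": ("A", None), "C": ("C", None),
    "COL": ("CoL", None), "FKBH": ("FkbH", None),
    "LCL": ("C", "LCL"), "DCL": ("C", "DCL"), "C_L": ("C", "LCL"),
    "C_D": ("C", "DCL"), "C_DU": ("C", "Du"), "C_M": ("C", "M"),
    "C_S": ("C", "S"), "C_CY": ("C", "Cy"),
}


def _parse_one_token(raw: str, position: int) -> DomainToken:
    text = raw
    tentative = False
    if "*" in text:  # italic markers that survive plain-text extraction
        tentative = True
        text = text.replace("*", "")
    text = text.strip("_")
    text = re.sub(r"_+", "_", text)
    if text.endswith("?"):
        tentative = True
        text = text[:-1]
    # superscript condensation-subtype prefixes: ^L^C_L / ^D^C_L
    m = re.fullmatch(r"\^?([LD])\^?C_?L?", text)
    if m:
        return DomainToken("C", "LCL" if m.group(1) == "L" else "DCL")
    upper = text.upper()
    if upper in _SIMPLE_KINDS:
        kind, qual = _SIMPLE_KINDS[upper]
        if tentative:
            raise ParseError(
                f"tentative marker is only legal on A-domain substrates: {raw!r} "
                f"at token {position}", raw, position)
        return DomainToken(kind, qual)
    m = re.fullmatch(r"AT_([A-Za-z]+)", text)
    if m and m.group(1).lower() in AT_QUALIFIERS:
        return DomainToken("AT", m.group(1).lower())
    m = re.fullmatch(r"A_([A-Za-z]+)", text)
    if m and m.group(1).lower() in MONOMERS:
        return DomainToken("A", m.group(1).lower(), tentative=tentative)
    m = re.fullmatch(r"CoL_([A-Za-z]+)", text, re.IGNORECASE)
    if m and m.group(1).lower() in COL_MONOMERS:
        return DomainToken("CoL", m.group(1).lower())
    raise ParseError(
        f"unparseable domain token {raw!r} at token position {position}", raw, position)


def parse_architecture(
    text: str,
    locus_tag: str = "",
    strand: str = "+",
    length_aa: Optional[int] = None,
) -> OrfArchitecture:
    """Parse one ORF's domain-organization string.

    Accepts the printed dialect: hyphen or en-dash module separators, slash
    or whitespace domain separators, stray separators, superscript C-subtype
    prefixes, ``KS (type-III PKS)``, italic/``?`` tentative substrates.
    Unknown tokens raise :class:`ParseError` naming token and position.
    """
    if text is None:
        raise ParseError("empty domain-organization string")
    s = unicodedata.normalize("NFC", str(text))
    for d in _DASHES:
        s = s.replace(d, "-")
    s = _TYPE3_RE.sub("KS3", s)
    if not s.strip():
        raise ParseError("empty domain-organization string")
    tokens: list[DomainToken] = []
    boundaries: list[int] = []
    position = 0
    first_chunk = True
    for chunk in s.split("-"):
        parts = [p for p in re.split(r"[/\s]+", chunk) if p]
        if not parts:
            continue  # stray separator
        if not first_chunk and tokens:
            boundaries.append(len(tokens))
        first_chunk = False
        for part in parts:
            position += 1
            tokens.append(_parse_one_token(part, position))
    if not tokens:
        raise ParseError(f"no domain tokens in {text!r}")
    return OrfArchitecture(
        locus_tag=locus_tag, strand=strand, length_aa=length_aa,
        tokens=tuple(tokens), boundaries=tuple(boundaries))


def serialize_architecture(arch: OrfArchitecture) -> str:
    """Canonical ASCII form; ``parse_architecture(serialize(x))`` == ``x``."""
    out: list[str] = []
    bset = set(arch.boundaries)
    for i, tok in enumerate(arch.tokens):
        if i > 0:
            out.append("-" if i in bset else "/")
        out.append(str(tok))
    return "".join(out)


def display_monomer(label: str) -> str:
    """Map an internal lowercase monomer label to its chain spelling."""
    return MONOMER_DISPLAY.get(label, label)


def tokens_of(archs: Iterable[OrfArchitecture]):
    for a in archs:
        yield from a.tokens
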