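"""Domain-organization grammar: dialect parsing, canonical serialization."""

import pytest
from hypothesis import given, strategies as st

from bgcline.tokens import (AT_QUALIFIERS, C_SUBTYPES, MONOMERS, DomainToken,
                            OrfArchitecture, ParseError, parse_architecture,
                            serialize_architecture)


@pytest.mark.parametrize("text,kinds,quals,n_bounds", [
    ("KS/AT_m_/KR/DH", ["KS", "AT", "KR", "DH"], [None, "m", None, None], 0),
    ("A_haorn_/MT/T–^D^C_L/A/T", ["A", "MT", "T", "C", "A", "T"],
     ["haorn", None, None, "DCL", None, None], 1),
    ("KS AT_p/KR/ACP", ["KS", "AT", "KR", "ACP"], [None, "p", None, None], 0),
    ("KS (type-III PKS)", ["KS3"], [None], 0),
    ("KS_1/AT/DH/KR/ACP", ["KS", "AT", "DH", "KR", "ACP"],
     ["first", None, None, None, None], 0),
    ("T/–TE", ["T", "TE"], [None, None], 1),
    ("C_Du/A/T-C_Cy/A_cys/T", ["C", "A", "T", "C", "A", "T"],
     ["Du", None, None, "Cy", "cys", None], 1),
    ("CoL_AHBA/ACP-KS/AT_p", ["CoL", "ACP", "KS", "AT"],
     ["ahba", None, None, "p"], 1),
    ("A_aad_/T–^D^C_L/A_cys_/T–^L^C_L/A_val_/T/E–TE",
     ["A", "T", "C", "A", "T", "C", "A", "T", "E", "TE"],
     ["aad", None, "DCL", "cys", None, "LCL", "val", None, None, None], 3),
])
def test_parses_printed_dialect(text, kinds, quals, n_bounds):
    arch = parse_architecture(text)
    assert [t.kind for t in arch.tokens] == kinds
    assert [t.qualifier for t in arch.tokens] == quals
    assert len(arch.boundaries) == n_bounds


def test_italic_and_question_mark_mean_tentative():
    for text in ("A*_ser_*", "A_ser?"):
        (tok,) = parse_architecture(text).tokens
        assert tok == DomainToken("A", "ser", tentative=True)


def test_unknown_token_reports_position():
    with pytest.raises(ParseError) as exc:
        parse_architecture("KS/??/ACP")
    assert exc.value.position == 2
    assert "??" in str(exc.value)


@pytest.mark.parametrize("bad", ["", "   ", "KS/QQ", "A_zzz/T", "AT_q"])
def test_rejects_malformed_strings(bad):
    with pytest.raises(ParseError):
        parse_architecture(bad)


def test_canonical_forms():
    assert str(DomainToken("AT", "m")) == "AT_m"
    assert str(DomainToken("A", "ser", tentative=True)) == "A_ser?"
    assert str(DomainToken("C", "DCL")) == "DCL"
    assert str(DomainToken("C", "M")) == "C_M"
    assert str(DomainToken("KS", "first")) == "KS_1"


def test_token_invariants():
    with pytest.raises(ValueError):
        DomainToken("AT", "ser")          # wrong qualifier namespace
    with pytest.raises(ValueError):
        DomainToken("KR", tentative=True)  # tentative only on A substrates
    with pytest.raises(ValueError):
        OrfArchitecture(tokens=(DomainToken("KS"),), boundaries=(1,))


def _token_strategy():
    def build(draw):
        kind = draw(st.sampled_from(
            ["KS", "KS3", "AT", "ACP", "KR", "DH", "ER", "MT", "A", "T",
             "C", "E", "TE", "TD", "CoL", "FkbH"]))
        qual, tent = None, False
        if kind == "AT" and draw(st.booleans()):
            qual = draw(st.sampled_from(sorted(AT_QUALIFIERS)))
        elif kind == "A" and draw(st.booleans()):
            qual = draw(st.sampled_from(sorted(MONOMERS)))
            tent = draw(st.booleans())
        elif kind == "C" and draw(st.booleans()):
            qual = draw(st.sampled_from(sorted(C_SUBTYPES)))
        elif kind == "KS" and draw(st.booleans()):
            qual = "first"
        return DomainToken(kind, qual, tent)
    return st.composite(build)()


@given(st.data())
def test_roundtrip_random_architectures(data):
    tokens = tuple(data.draw(st.lists(_token_strategy(), min_size=1, max_size=12)))
    positions = sorted(data.draw(st.sets(
        st.integers(1, max(1, len(tokens) - 1)), max_size=len(tokens) - 1)))
    arch = OrfArchitecture(locus_tag="syn", tokens=tokens,
                           boundaries=tuple(positions))
    assert parse_architecture(serialize_architecture(arch),
                              locus_tag="syn") == arch


def test_roundtrip_whole_fixture(inv):
    for c in inv.clusters:
        for o in c.orfs:
            assert parse_architecture(
                serialize_architecture(o), locus_tag=o.locus_tag,
                strand=o.strand, length_aa=o.length_aa) == o
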