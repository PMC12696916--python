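"""Scaffold engineering grammar: substitutions, truncations, loop replacement,
grafting, naming, and the edit-replay / length-conservation invariants."""

import pytest

from abscan import (
    EpitopeWindow,
    ScaffoldTemplate,
    build_panel_constructs,
    constructs_to_fasta,
    enumerate_variants,
    graft,
    make_name,
    parse_name,
    replace_loop,
    replay_edits,
    substitute_cysteines,
    truncate_n_terminus,
)
from abscan.cascade import ParatopeDesign
from abscan.scan import Panel

FULL_LOOP = "GSFETLTLREEE"


class TestSubstituteCysteines:
    def test_aa_scheme(self, sdab_template):
        t = substitute_cysteines(sdab_template, "AA")
        assert t.sequence[t.resolve("C23") - 1] == "A"
        assert t.sequence[t.resolve("C97") - 1] == "A"
        assert make_name(t.edits, "sdab") == "C23AC97A"

    def test_av_scheme(self, sdab_template):
        t = substitute_cysteines(sdab_template, "AV")
        assert t.sequence[t.resolve("C97") - 1] == "V"
        assert make_name(t.edits, "sdab") == "C23AC97V"

    def test_double_application_is_an_error(self, sdab_template):
        t = substitute_cysteines(sdab_template, "AA")
        with pytest.raises(ValueError, match="not 'C'"):
            substitute_cysteines(t, "AA")

    def test_misconfigured_template_is_caught(self, sdab_template):
        with pytest.raises(ValueError, match="expected 'C'"):
            ScaffoldTemplate(
                name="broken",
                kind="sdab",
                sequence=sdab_template.sequence,
                sites=dict(sdab_template.sites),
                numbered_residues={"C23": 24, "C97": 97},
            )


class TestGraft:
    def test_full_loop_graft_is_gs_insert_eee(self, monobody_template):
        c = graft(monobody_template, "BC", "FETLTLR", mode="full_loop")
        assert FULL_LOOP in c.sequence
        s, _e = monobody_template.sites["BC"]
        assert c.sequence[s - 1 : s - 1 + len(FULL_LOOP)] == FULL_LOOP

    def test_core_graft_length_bookkeeping(self, monobody_template):
        c = graft(monobody_template, "BC", "FETLTLR", mode="core")
        s, e = monobody_template.sites["BC"]
        assert len(c.sequence) == len(monobody_template.sequence) - (e - s + 1) + 7
        assert "FETLTLR" in c.sequence

    def test_empty_insert_is_an_error(self, monobody_template):
        with pytest.raises(ValueError):
            graft(monobody_template, "BC", "", mode="core")

    def test_unknown_site_is_an_error(self, monobody_template):
        with pytest.raises(ValueError, match="unknown site"):
            graft(monobody_template, "CDR3", "FETLTLR")


class TestTruncateAndLoops:
    def test_truncation_shifts_sites(self, monobody_template):
        t = truncate_n_terminus(monobody_template, 8)
        assert len(t.sequence) == len(monobody_template.sequence) - 8
        assert t.sites["BC"][0] == monobody_template.sites["BC"][0] - 8
        c = graft(t, "BC", "FETLTLR")
        assert c.name == "N-8-FETLTLR(BC)-wt(FG)"

    def test_truncation_reaching_a_site_is_an_error(self, monobody_template):
        with pytest.raises(ValueError, match="site"):
            truncate_n_terminus(monobody_template, monobody_template.sites["BC"][0])

    @pytest.mark.parametrize("fg", ["AAAAS", "EGYYSSY", "PTSDYG"])
    def test_fg_replacement_updates_site(self, monobody_template, fg):
        t = replace_loop(monobody_template, "FG", fg)
        s, e = t.sites["FG"]
        assert e - s + 1 == len(fg)
        assert t.sequence[s - 1 : e] == fg

    def test_empty_loop_replacement_is_an_error(self, monobody_template):
        with pytest.raises(ValueError):
            replace_loop(monobody_template, "FG", "")


PAPER_MONOBODY_NAMES = [
    "FETLTLR(BC)-wt(FG)",
    "GSFETLTLREEE(BC)-wt(FG)",
    "wt(BC)-FETLTLR(FG)",
    "wt(BC)-GSFETLTLREEE(FG)",
    "N-4-FETLTLR(BC)-wt(FG)",
    "N-8-FETLTLR(BC)-AAAAS(FG)",
    "N-8-GSFETLTLREEE(BC)-AAAAS(FG)",
    "N-8-FETLTLR(BC)-EGYYSSY(FG)",
    "N-8-FETLTLR(BC)-PTSDYG(FG)",
]


def _build_from_parsed(template, parsed):
    t = template
    if "truncate_n" in parsed:
        t = truncate_n_terminus(t, parsed["truncate_n"])
    graft_site, insert = None, None
    for site in ("BC", "FG"):
        token = parsed[site.lower()]
        if token == "wt":
            continue
        if graft_site is None:
            graft_site, insert = site, token
        else:
            t = replace_loop(t, site, token)
    return graft(t, graft_site, insert, mode="core")


class TestNaming:
    @pytest.mark.parametrize("name", PAPER_MONOBODY_NAMES)
    def test_printed_monobody_names_round_trip(self, monobody_template, name):
        """parse -> rebuild -> make_name recovers every printed variant name,
        and replaying the construct's edits reproduces its sequence."""
        parsed = parse_name(name)
        assert parsed["scaffold"] == "monobody"
        construct = _build_from_parsed(monobody_template, parsed)
        assert construct.name == name
        assert parse_name(construct.name) == parsed
        assert replay_edits(monobody_template, construct.edits) == construct.sequence

    @pytest.mark.parametrize("name", PAPER_MONOBODY_NAMES)
    def test_length_conservation(self, monobody_template, name):
        parsed = parse_name(name)
        construct = _build_from_parsed(monobody_template, parsed)
        expected = len(monobody_template.sequence) - parsed.get("truncate_n", 0)
        for site in ("BC", "FG"):
            token = parsed[site.lower()]
            if token != "wt":
                s, e = monobody_template.sites[site]
                expected += len(token) - (e - s + 1)
        assert len(construct.sequence) == expected

    @pytest.mark.parametrize(
        "label", ["9-17", "12-18", "15-22", "19-26", "20-28", "22-29",
                  "26-32", "26-34", "30-37"]
    )
    def test_desab_panel_names(self, label):
        parsed = parse_name(f"DesAb_{label}")
        start, end = (int(x) for x in label.split("-"))
        assert parsed == {"scaffold": "sdab", "window": (start, end)}

    def test_desab_names_accept_en_dash(self):
        assert parse_name("DesAb_9–17") == {"scaffold": "sdab", "window": (9, 17)}

    def test_desab_neg_name(self):
        assert parse_name("DesAb_neg") == {"scaffold": "sdab", "window": "neg"}

    def test_sdab_engineering_variant_names(self, sdab_template):
        t = substitute_cysteines(sdab_template, "AA")
        c = graft(t, "CDR3", "FETLTLR", mode="full_loop")
        assert c.name == "FETLTLR_C23AC97A"
        parsed = parse_name(c.name)
        assert parsed == {"scaffold": "sdab", "cys_scheme": "AA", "insert": "FETLTLR"}

    def test_unparseable_name_is_an_error(self):
        with pytest.raises(ValueError):
            parse_name("not-a-construct")


class TestEnumerateVariants:
    def test_four_original_scaffold_variants(self, monobody_template):
        constructs = enumerate_variants(
            monobody_template, ["FETLTLR", "GSFETLTLREEE"], ["BC", "FG"], mode="core"
        )
        assert [c.name for c in constructs] == [
            "FETLTLR(BC)-wt(FG)",
            "GSFETLTLREEE(BC)-wt(FG)",
            "wt(BC)-FETLTLR(FG)",
            "wt(BC)-GSFETLTLREEE(FG)",
        ]
        for c in constructs:
            assert replay_edits(monobody_template, c.edits) == c.sequence

    def test_single_combination(self, monobody_template):
        assert len(enumerate_variants(monobody_template, ["FETLTLR"], ["BC"])) == 1

    def test_empty_insert_list_is_an_error(self, monobody_template):
        with pytest.raises(ValueError):
            enumerate_variants(monobody_template, [], ["BC"])

    def test_duplicate_names_are_an_error(self, monobody_template):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_variants(monobody_template, ["FETLTLR", "FETLTLR"], ["BC"])


def _design(window, epitope, paratope):
    return ParatopeDesign(
        epitope_seq=epitope,
        paratope_seq=paratope,
        orientation="antiparallel",
        support=(1,) * len(epitope),
        c_score=0.3,
        solubility=0.0,
        fragments_used=(),
        epitope_window=window,
    )


@pytest.fixture()
def iapp_panel(iapp):
    windows = [
        (9, 17), (12, 18), (15, 22), (19, 26), (20, 28),
        (22, 29), (26, 32), (26, 34), (30, 37),
    ]
    designs = []
    for i, (s, e) in enumerate(windows):
        epitope = iapp[s - 1 : e]
        paratope = ("ACDEFGHIKLMNPQRSTVWY" * 2)[i : i + len(epitope)]
        designs.append((EpitopeWindow(s, e), _design((s, e), epitope, paratope)))
    return Panel("IAPP", iapp, designs)


class TestPanelConstructs:
    def test_nine_designs_plus_negative_control(self, iapp_panel, sdab_template, tmp_path):
        template = substitute_cysteines(sdab_template, "AA")
        constructs = build_panel_constructs(iapp_panel, template, site="CDR3")
        assert len(constructs) == 10
        names = [c.name for c in constructs]
        assert names[0] == "DesAb_9-17"
        assert names[-1] == "DesAb_neg"
        neg = constructs[-1]
        assert "SGAAAGSGS" in neg.sequence
        for c in constructs:
            # edit lists replay from the unedited base template
            assert replay_edits(sdab_template, c.edits) == c.sequence
        fasta = tmp_path / "constructs.fasta"
        constructs_to_fasta(constructs, fasta)
        headers = [l[1:].split()[0] for l in fasta.read_text().splitlines() if l.startswith(">")]
        assert headers == names

    def test_unsubstituted_sdab_is_rejected(self, iapp_panel, sdab_template):
        with pytest.raises(ValueError, match="cysteine"):
            build_panel_constructs(iapp_panel, sdab_template, site="CDR3")

    def test_empty_panel_is_an_error(self, iapp, sdab_template):
        template = substitute_cysteines(sdab_template, "AA")
        with pytest.raises(ValueError, match="empty"):
            build_panel_constructs(Panel("IAPP", iapp, []), template)
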