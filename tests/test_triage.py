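"""Effect classification, rarity filtration and alert-concordance matching."""

import itertools

import pytest

from litquery.alerts import DomainInterval, InheritanceMode, VariantClass
from litquery.exceptions import ConfigError, ParseWarning
from litquery.triage import (
    EffectClass,
    SegregationStatus,
    TriageConfig,
    VariantEffect,
    classify_variant_effect,
    filter_rare,
    is_lof_constrained,
    match_candidates,
    parse_segregation_token,
)

from conftest import make_alert, make_row


# ---------------------------------------------------------------------------
# HGVS-p effect classification (examples from the published table)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "protein, effect_class, position",
    [
        ("p.(Arg423*)", EffectClass.PROTEIN_TRUNCATING, 423),
        ("p.(Glu2054Lysfs*14)", EffectClass.PROTEIN_TRUNCATING, 2054),
        ("p.Ala431Hisfs*9", EffectClass.PROTEIN_TRUNCATING, 431),
        ("p.Gln1292*", EffectClass.PROTEIN_TRUNCATING, 1292),
        ("p.(Gly792Glu)", EffectClass.MISSENSE, 792),
        ("p.Gln1377Arg", EffectClass.MISSENSE, 1377),
        ("p.Phe419del", EffectClass.INFRAME_INDEL, 419),
        ("p.?", EffectClass.UNKNOWN_SPLICE, None),
    ],
)
def test_classify_variant_effect(protein, effect_class, position):
    effect = classify_variant_effect(protein)
    assert effect.effect_class is effect_class
    assert effect.protein_position == position


def test_unparseable_protein_string_warns_never_crashes():
    with pytest.warns(ParseWarning):
        effect = classify_variant_effect("c.123+1G>A")
    assert effect.effect_class is EffectClass.UNKNOWN_SPLICE


@pytest.mark.parametrize(
    "token, status",
    [
        ("De novo", SegregationStatus.DE_NOVO),
        ("MATERNALLY INHERITED", SegregationStatus.MATERNALLY_INHERITED),
        ("Paternally and maternally inherited", SegregationStatus.BIPARENTAL),
        ("Not maternally inherited", SegregationStatus.NOT_MATERNAL),
        ("Probable paternal inheritance", SegregationStatus.PATERNALLY_INHERITED),
        ("ND", SegregationStatus.UNKNOWN),
    ],
)
def test_segregation_vocabulary(token, status):
    assert parse_segregation_token(token) is status


# ---------------------------------------------------------------------------
# Rarity filter
# ---------------------------------------------------------------------------


def test_filter_rare_threshold_is_strict():
    common = make_row(pos=1, af=0.02)
    rare = make_row(pos=2, af=0.0001)
    boundary = make_row(pos=3, af=0.01)
    kept = filter_rare([common, rare, boundary])
    assert [r.key.pos for r in kept] == [2]


def test_missing_af_follows_config():
    row = make_row(af=None)
    assert filter_rare([row]) == [row]
    cfg = TriageConfig(treat_missing_af_as_rare=False)
    assert filter_rare([row], cfg) == []


def test_max_across_sources_is_decisive():
    row = make_row(af=0.0001)
    row.af_fields["GNOMAD_GENOME_AF"] = 0.05  # common in another panel
    assert filter_rare([row]) == []


def test_unknown_af_source_is_config_error():
    with pytest.raises(ConfigError, match="NOT_A_SOURCE"):
        TriageConfig(af_sources=("NOT_A_SOURCE",))


def test_rare_filter_monotone_in_threshold():
    rows = [make_row(pos=i, af=af) for i, af in enumerate(
        [None, 1e-6, 0.003, 0.007, 0.009, 0.02, 0.3], start=1
    )]
    tight = {r.key for r in filter_rare(rows, TriageConfig(af_threshold=0.005))}
    loose = {r.key for r in filter_rare(rows, TriageConfig(af_threshold=0.01))}
    assert tight <= loose


def test_lof_constraint_flags():
    assert is_lof_constrained(make_row(PLI=0.99))
    assert is_lof_constrained(make_row(OE=0.1))
    assert not is_lof_constrained(make_row(PLI=0.5, OE=0.8))
    assert not is_lof_constrained(make_row())  # missing metrics: unflagged


# ---------------------------------------------------------------------------
# Candidate matching
# ---------------------------------------------------------------------------


def test_de_novo_truncating_row_is_candidate():
    alert = make_alert("ZNF292")
    row = make_row(gene="ZNF292", protein="p.(Glu2054Lysfs*14)", af=None)
    cands = match_candidates([row], alert, {"S001": SegregationStatus.DE_NOVO})
    assert len(cands) == 1
    assert "class:protein-truncating" in cands[0].match_reasons
    assert "inheritance:de_novo_dominant" in cands[0].match_reasons


def test_common_missense_fails_both_gates():
    alert = make_alert("ZNF292")
    row = make_row(gene="ZNF292", protein="p.(Ala100Gly)", af=0.2)
    assert match_candidates([row], alert, {}) == []


def test_recessive_biparental_pair_both_emitted():
    alert = make_alert(
        "HPDL",
        modes=(InheritanceMode.AUTOSOMAL_RECESSIVE,),
        classes=(VariantClass.MISSENSE_ANY, VariantClass.PROTEIN_TRUNCATING),
    )
    maternal = make_row(gene="HPDL", sample="S009", pos=45793608,
                        protein="p.(Thr263Met)", af=1e-5)
    paternal = make_row(gene="HPDL", sample="S009", pos=45793162,
                        protein="p.(Ala116Cysfs*81)", af=None)
    segregations = {}
    cands_m = match_candidates(
        [maternal, paternal], alert,
        {"S009": SegregationStatus.BIPARENTAL},
    )
    assert len(cands_m) == 2
    assert all("recessive-biparental" in c.match_reasons for c in cands_m)


def test_compound_het_requires_opposite_parental_origins(tmp_path):
    alert = make_alert(
        "TTC5",
        modes=(InheritanceMode.AUTOSOMAL_RECESSIVE,),
        classes=(VariantClass.PROTEIN_TRUNCATING, VariantClass.MISSENSE_ANY),
    )
    pat = make_row(gene="TTC5", sample="S010", pos=100, protein="p.(Arg409*)", af=None)
    mat = make_row(gene="TTC5", sample="S010", pos=200, protein="p.(Ala50Gly)", af=None)
    same_parent = {"S010": SegregationStatus.PATERNALLY_INHERITED}
    # a lone paternal carrier does not satisfy the recessive model
    assert match_candidates([pat], alert, same_parent) == []
    # nor do two carriers phased to the same parent
    assert match_candidates([pat, mat], alert, same_parent) == []
    # opposite parental origins, stated per variant, form a trans pair
    trans = {
        ("S010", pat.key): SegregationStatus.PATERNALLY_INHERITED,
        ("S010", mat.key): SegregationStatus.MATERNALLY_INHERITED,
    }
    cands = match_candidates([pat, mat], alert, trans)
    assert len(cands) == 2
    assert all("recessive-biparental" in c.match_reasons for c in cands)


def test_inherited_under_de_novo_alert_kept_and_tagged():
    """A truncating variant from an asymptomatic parent is retained (the
    VUS stratum), not filtered out."""
    alert = make_alert("TAOK2")
    row = make_row(gene="TAOK2", protein="p.(Arg1068*)", af=None)
    cands = match_candidates(
        [row], alert, {"S001": SegregationStatus.PATERNALLY_INHERITED}
    )
    assert len(cands) == 1
    assert cands[0].match_reasons == [
        "class:protein-truncating", "inherited-from-asymptomatic-parent",
    ]


def test_missense_in_domain_requires_position_inside_interval():
    alert = make_alert(
        "GENE1",
        classes=(VariantClass.MISSENSE_IN_DOMAIN,),
        domains=(DomainInterval(700, 800),),
    )
    inside = make_row(pos=1, protein="p.(Gly792Glu)", af=None)
    outside = make_row(pos=2, protein="p.(Gly92Glu)", af=None)
    cands = match_candidates([inside, outside], alert, {})
    assert [c.row.key.pos for c in cands] == [1]
    assert "class:missense-in-domain" in cands[0].match_reasons


def test_splice_effect_needs_splice_class():
    row = make_row(protein="p.?", af=None)
    no_splice = make_alert("GENE1", classes=(VariantClass.PROTEIN_TRUNCATING,))
    with_splice = make_alert(
        "GENE1", classes=(VariantClass.PROTEIN_TRUNCATING, VariantClass.SPLICE)
    )
    assert match_candidates([row], no_splice, {}) == []
    assert len(match_candidates([row], with_splice, {})) == 1


def test_gene_restriction_enforced():
    alert = make_alert("GENE1")
    row = make_row(gene="GENE2")
    with pytest.raises(ValueError, match="GENE2"):
        match_candidates([row], alert, {})


def test_candidate_set_shrinks_with_alert_classes():
    rows = [
        make_row(pos=1, protein="p.(Arg100*)", af=None),
        make_row(pos=2, protein="p.(Ala50Gly)", af=None),
        make_row(pos=3, protein="p.?", af=None),
    ]
    classes_chain = [
        (VariantClass.PROTEIN_TRUNCATING, VariantClass.MISSENSE_ANY, VariantClass.SPLICE),
        (VariantClass.PROTEIN_TRUNCATING, VariantClass.MISSENSE_ANY),
        (VariantClass.PROTEIN_TRUNCATING,),
    ]
    sizes = [
        len(match_candidates(rows, make_alert("GENE1", classes=cls), {}))
        for cls in classes_chain
    ]
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# Exhaustive small-space oracle
# ---------------------------------------------------------------------------


def _oracle_single_row(effect, position, af, seg, modes, classes, domains):
    """Independent re-statement of the matching conjunction for one row
    (no compound-het pairing)."""
    if af is not None and af >= 0.01:
        return False
    # class gate
    if effect is EffectClass.PROTEIN_TRUNCATING:
        class_ok = VariantClass.PROTEIN_TRUNCATING in classes
    elif effect in (EffectClass.MISSENSE, EffectClass.INFRAME_INDEL):
        class_ok = VariantClass.MISSENSE_ANY in classes or (
            VariantClass.MISSENSE_IN_DOMAIN in classes
            and position is not None
            and any(lo <= position <= hi for lo, hi in domains)
        )
    else:
        class_ok = VariantClass.SPLICE in classes
    if not class_ok:
        return False
    # inheritance gate
    if seg is SegregationStatus.UNKNOWN:
        return True
    compat = {
        InheritanceMode.DE_NOVO_DOMINANT: {
            SegregationStatus.DE_NOVO, SegregationStatus.NOT_MATERNAL,
            SegregationStatus.NOT_PATERNAL,
        },
        InheritanceMode.AUTOSOMAL_DOMINANT_INHERITED: {
            SegregationStatus.DE_NOVO, SegregationStatus.MATERNALLY_INHERITED,
            SegregationStatus.PATERNALLY_INHERITED, SegregationStatus.NOT_MATERNAL,
            SegregationStatus.NOT_PATERNAL,
        },
        InheritanceMode.AUTOSOMAL_RECESSIVE: {SegregationStatus.BIPARENTAL},
        InheritanceMode.X_LINKED: {
            SegregationStatus.DE_NOVO, SegregationStatus.MATERNALLY_INHERITED,
            SegregationStatus.NOT_PATERNAL,
        },
    }
    if any(seg in compat[m] for m in modes):
        return True
    inherited = seg in (
        SegregationStatus.MATERNALLY_INHERITED, SegregationStatus.PATERNALLY_INHERITED,
    )
    return InheritanceMode.DE_NOVO_DOMINANT in modes and inherited


_PROTEINS = {
    "p.(Arg100*)": (EffectClass.PROTEIN_TRUNCATING, 100),
    "p.(Ala150Gly)": (EffectClass.MISSENSE, 150),
    "p.(Ala500Gly)": (EffectClass.MISSENSE, 500),
    "p.?": (EffectClass.UNKNOWN_SPLICE, None),
}
_MODE_SETS = [
    frozenset({InheritanceMode.DE_NOVO_DOMINANT}),
    frozenset({InheritanceMode.AUTOSOMAL_RECESSIVE}),
    frozenset({InheritanceMode.DE_NOVO_DOMINANT, InheritanceMode.AUTOSOMAL_DOMINANT_INHERITED}),
    frozenset({InheritanceMode.X_LINKED}),
]
_CLASS_SETS = [
    frozenset({VariantClass.PROTEIN_TRUNCATING}),
    frozenset({VariantClass.MISSENSE_ANY}),
    frozenset({VariantClass.MISSENSE_IN_DOMAIN}),
    frozenset({VariantClass.PROTEIN_TRUNCATING, VariantClass.SPLICE}),
]


def test_matching_agrees_with_enumerated_oracle():
    """Brute-force the rule conjunction over the full small space of
    (effect x AF x segregation x alert modes x alert classes)."""
    domains = ((120, 200),)
    checked = 0
    for protein, af, seg, modes, classes in itertools.product(
        _PROTEINS, [None, 1e-4, 0.05], SegregationStatus, _MODE_SETS, _CLASS_SETS
    ):
        alert = make_alert(
            "GENE1", modes=modes, classes=classes,
            domains=tuple(DomainInterval(*d) for d in domains),
        )
        row = make_row(protein=protein, af=af)
        got = bool(match_candidates([row], alert, {"S001": seg}))
        effect, position = _PROTEINS[protein]
        want = _oracle_single_row(effect, position, af, seg, modes, classes, domains)
        assert got == want, (protein, af, seg, modes, classes)
        checked += 1
    assert checked == len(_PROTEINS) * 3 * len(SegregationStatus) * 4 * 4
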