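"""Lipid formula/mass arithmetic and ppm annotation.

The formula oracle here assembles each molecule from head-group and backbone
building blocks with explicit condensation bookkeeping (losing one water per
ester/amide/glycosidic bond), independently of the per-class closed-form
offsets the implementation uses.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioims.lipid_chem import (
    Adduct,
    Annotation,
    Hydroxylation,
    LipidClass,
    Panel,
    PanelEntry,
    UnsupportedSpeciesError,
    annotate,
    annotations_to_table,
    build_panel,
    default_panel,
    formula_of,
    monoisotopic_mass,
    parse_shorthand,
    theoretical_mz,
)

# ---------------------------------------------------------------------------
# independent backbone-assembly oracle
# ---------------------------------------------------------------------------

WATER = Counter({"H": 2, "O": 1})
GLYCEROL = Counter({"C": 3, "H": 8, "O": 3})
PHOSPHORIC_ACID = Counter({"H": 3, "O": 4, "P": 1})
HEAD_GROUPS = {
    LipidClass.PC: Counter({"C": 5, "H": 13, "N": 1, "O": 1}),   # choline
    LipidClass.PE: Counter({"C": 2, "H": 7, "N": 1, "O": 1}),    # ethanolamine
    LipidClass.PE_P: Counter({"C": 2, "H": 7, "N": 1, "O": 1}),
    LipidClass.PS: Counter({"C": 3, "H": 7, "N": 1, "O": 3}),    # serine
    LipidClass.PI: Counter({"C": 6, "H": 12, "O": 6}),           # inositol
    LipidClass.PG: GLYCEROL,
}
HEXOSE = Counter({"C": 6, "H": 12, "O": 6})
PHOSPHOCHOLINE = Counter({"C": 5, "H": 14, "N": 1, "O": 4, "P": 1})
SULFUR_TRIOXIDE = Counter({"O": 3, "S": 1})


def fatty_acid(c: int, d: int) -> Counter:
    return Counter({"C": c, "H": 2 * c - 2 * d, "O": 2})


def fatty_aldehyde(c: int) -> Counter:
    return Counter({"C": c, "H": 2 * c, "O": 1})


def sphingoid_base(c: int, d: int, hydroxyls: int) -> Counter:
    # acyclic amino-alcohol: sphinganine C18H39NO2 is the c=18, d=0, 2-OH case
    return Counter({"C": c, "H": 2 * c + 3 - 2 * d, "N": 1, "O": hydroxyls})


def minus(a: Counter, b: Counter) -> Counter:
    out = Counter(a)
    out.subtract(b)
    return out


def oracle_formula(species) -> dict[str, int]:
    """Atom counts by explicit assembly; chain split is irrelevant because
    chain atoms are additive in (C, DB)."""
    c, d = species.total_carbons, species.double_bonds
    cls = species.lipid_class
    if cls in HEAD_GROUPS:
        backbone = minus(GLYCEROL + PHOSPHORIC_ACID, WATER)
        backbone = minus(backbone + HEAD_GROUPS[cls], WATER)
        if cls is LipidClass.PE_P:
            # sn-1 vinyl ether from a fatty aldehyde, sn-2 ester
            c1 = 18 if c > 20 else c // 2
            total = minus(backbone + fatty_aldehyde(c1), WATER)
            total = minus(total + fatty_acid(c - c1, d), WATER)
        else:
            c1 = c // 2
            total = minus(backbone + fatty_acid(c1, 0), WATER)
            total = minus(total + fatty_acid(c - c1, d), WATER)
        return {k: v for k, v in total.items() if v}
    if cls in (LipidClass.DG, LipidClass.TG):
        n_chains = 2 if cls is LipidClass.DG else 3
        total = Counter(GLYCEROL)
        remaining_c, remaining_d = c, d
        for i in range(n_chains):
            ci = remaining_c if i == n_chains - 1 else remaining_c // 2
            di = remaining_d if i == n_chains - 1 else 0
            total = minus(total + fatty_acid(ci, di), WATER)
            remaining_c -= ci
            remaining_d -= di
        return {k: v for k, v in total.items() if v}
    # sphingolipids: base + N-acyl amide, then the head group
    hydroxyls = 2 if species.hydroxylation is Hydroxylation.D else 3
    d_base = min(d, 1)
    ceramide = minus(
        sphingoid_base(18, d_base, hydroxyls) + fatty_acid(c - 18, d - d_base),
        WATER,
    )
    if cls is LipidClass.CER:
        total = ceramide
    elif cls is LipidClass.SM:
        total = minus(ceramide + PHOSPHOCHOLINE, WATER)
    elif cls is LipidClass.HEXCER:
        total = minus(ceramide + HEXOSE, WATER)
    else:  # sulfatide: sulfate ester on the hexose
        total = minus(ceramide + HEXOSE, WATER) + SULFUR_TRIOXIDE
    return {k: v for k, v in total.items() if v}


# ---------------------------------------------------------------------------
# formulas and masses
# ---------------------------------------------------------------------------

def test_formula_examples():
    assert formula_of(parse_shorthand("PI 38:4")) == {
        "C": 47, "H": 83, "O": 13, "P": 1
    }
    assert formula_of(parse_shorthand("PE 34:0")) == {
        "C": 39, "H": 78, "N": 1, "O": 8, "P": 1
    }
    assert monoisotopic_mass(formula_of(parse_shorthand("PI 38:4"))) == pytest.approx(
        886.557, abs=5e-4
    )


@pytest.mark.parametrize(
    "bad",
    [
        ("TG", 0, 0, "none"),       # carbons below the supported minimum
        ("PI", 38, 20, "none"),     # impossible unsaturation
        ("SM", 36, 1, "none"),      # sphingolipid without a base hydroxylation
        ("PE", 36, 1, "d"),         # hydroxylation on a glycerophospholipid
    ],
)
def test_invalid_species_rejected(bad):
    from glioims.lipid_chem import LipidSpecies

    cls, c, d, h = bad
    with pytest.raises(UnsupportedSpeciesError):
        LipidSpecies(LipidClass(cls), c, d, Hydroxylation(h))


def test_formula_matches_backbone_oracle_for_whole_panel(panel):
    for species in panel.species:
        assert formula_of(species) == oracle_formula(species), species.shorthand


def test_printed_pi384_mz():
    mz = theoretical_mz(parse_shorthand("PI 38:4"), Adduct.M_MINUS_H)
    assert round(mz, 2) == 885.55
    assert mz == pytest.approx(885.5499, abs=5e-5)


def test_mass_ladders(panel):
    # each CH2 adds 14.01565 Da; each double bond removes H2 (2.01565 Da)
    pe36 = theoretical_mz(parse_shorthand("PE 36:1"), Adduct.M_MINUS_H)
    pe38 = theoretical_mz(parse_shorthand("PE 38:1"), Adduct.M_MINUS_H)
    assert pe38 - pe36 == pytest.approx(2 * 14.01565, abs=1e-5)
    sm1 = theoretical_mz(parse_shorthand("SM d42:1"), Adduct.M_PLUS_H)
    sm2 = theoretical_mz(parse_shorthand("SM d42:2"), Adduct.M_PLUS_H)
    assert sm1 - sm2 == pytest.approx(2.015650, abs=1e-5)
    # strict monotonicity in carbons at fixed class/DB across the panel
    for cls in panel.classes:
        entries = sorted(panel.by_class(cls), key=lambda e: e.species.total_carbons)
        by_db: dict[tuple, list] = {}
        for e in entries:
            by_db.setdefault(
                (e.species.double_bonds, e.species.hydroxylation), []
            ).append(e)
        for group in by_db.values():
            mzs = [e.mz for e in group]
            assert all(b > a for a, b in zip(mzs, mzs[1:]))


def test_proton_shift_symmetry():
    assert Adduct.M_PLUS_H.mass_shift == pytest.approx(
        -Adduct.M_MINUS_H.mass_shift, abs=1e-9
    )
    assert Adduct.M_PLUS_H.mass_shift - Adduct.M_MINUS_H.mass_shift == pytest.approx(
        2 * 1.007276, abs=1e-6
    )


def test_polarity_enforced():
    with pytest.raises(ValueError, match="negative-ion mode"):
        theoretical_mz(parse_shorthand("PI 38:4"), Adduct.M_PLUS_H)
    with pytest.raises(ValueError, match="positive-ion mode"):
        theoretical_mz(parse_shorthand("SM d36:1"), Adduct.M_MINUS_H)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    cls=st.sampled_from([c for c in LipidClass]),
    carbons=st.integers(min_value=20, max_value=56),
    db=st.integers(min_value=0, max_value=8),
    hydroxy=st.sampled_from([Hydroxylation.D, Hydroxylation.T]),
)
def test_formula_oracle_property(cls, carbons, db, hydroxy):
    from glioims.lipid_chem import SPHINGOLIPID_CLASSES, LipidSpecies

    h = hydroxy if cls in SPHINGOLIPID_CLASSES else Hydroxylation.NONE
    species = LipidSpecies(cls, carbons, db, h)
    assert formula_of(species) == oracle_formula(species)


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------

def test_default_panel_scale(panel):
    assert len(panel) == 124
    assert len({s for s in panel.species}) == 124
    assert len(panel.classes) == 11
    mzs = panel.mzs
    assert np.all(np.diff(mzs) >= 0)


def test_panel_min_ppm_separation(panel):
    # same-polarity species must be distinguishable at the 9 ppm tolerance
    for polarity in ("negative", "positive"):
        mz = np.sort(panel.subset(polarity).mzs)
        gaps_ppm = np.diff(mz) / mz[:-1] * 1e6
        assert gaps_ppm.min() > 2 * 9.0


def test_build_panel_edges():
    assert len(build_panel({})) == 0
    two = build_panel(
        {"classes": {"PC": {"adducts": ["[M+H]+", "[M+Na]+"],
                            "species": ["34:1"]}}}
    )
    assert len(two.entries) == 2
    with pytest.raises(ValueError, match="duplicate"):
        sp = parse_shorthand("PI 38:4")
        e = PanelEntry(sp, Adduct.M_MINUS_H, theoretical_mz(sp, Adduct.M_MINUS_H))
        Panel([e, e])


def test_shorthand_round_trip(panel):
    for species in panel.species:
        assert parse_shorthand(species.shorthand) == species


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def test_annotate_printed_peak(panel):
    (ann,) = annotate([885.552], panel, tol_ppm=9.0)
    assert ann is not None
    assert ann.species.shorthand == "PI 38:4"
    assert ann.adduct is Adduct.M_MINUS_H
    assert abs(ann.ppm_error) <= 9.0
    assert annotate([885.552], panel, tol_ppm=0.1) == [None]


def test_annotate_exact_masses_round_trip(panel):
    anns = annotate(panel.mzs, panel, tol_ppm=9.0)
    assert all(a is not None for a in anns)
    for entry, ann in zip(panel.entries, anns):
        assert ann.species == entry.species
        assert ann.ppm_error == pytest.approx(0.0, abs=1e-9)
        assert not ann.ambiguous


def test_annotate_jittered_panel_recovers_every_species(panel, rng):
    jitter = rng.uniform(-3.0, 3.0, len(panel))
    observed = panel.mzs * (1.0 + jitter * 1e-6)
    anns = annotate(observed, panel, tol_ppm=9.0)
    assert all(a is not None for a in anns)
    recovered = [a.species for a in anns]
    assert recovered == [e.species for e in panel.entries]
    assert max(abs(a.ppm_error) for a in anns) <= 9.0


def test_annotate_flags_ambiguity():
    a = parse_shorthand("PE 38:4")
    b = parse_shorthand("PE 38:5")   # ~2 Da apart: ambiguous at huge tolerance
    entries = [
        PanelEntry(s, Adduct.M_MINUS_H, theoretical_mz(s, Adduct.M_MINUS_H))
        for s in (a, b)
    ]
    panel = Panel(entries)
    (ann,) = annotate([entries[0].mz], panel, tol_ppm=5000.0)
    assert ann.species == a and ann.ambiguous


def test_annotate_input_validation(panel):
    with pytest.raises(ValueError, match="non-positive"):
        annotate([-1.0], panel)
    with pytest.raises(ValueError, match="tol_ppm"):
        annotate([700.0], panel, tol_ppm=0.0)


def test_annotations_table_shape(panel):
    table = annotations_to_table(annotate([885.552, 2.5e3], panel))
    assert list(table["species"]) == ["PI 38:4", None]
    assert {"observed_mz", "ppm_error", "ambiguous"} <= set(table.columns)
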