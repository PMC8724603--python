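"""Mass chemistry: residue constants, ion m/z, enumeration, round-trips."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoims.glycan_chem import (
    AMIDE_DELTA,
    DIMETHYLAMIDE_DELTA,
    ENDOF3_SHIFT,
    ChemistryConfig,
    EnumerationBounds,
    GlycanComposition,
    Linkage,
    Release,
    SialicMode,
    build_database,
    endof3_mz,
    export_database,
    import_database,
    mz_for_key,
    neutral_mass,
    residue_mass,
    theoretical_mz,
)

NATIVE = ChemistryConfig()
AMIDATED = ChemistryConfig(sialic_mode=SialicMode.AMIDATION_AMIDATION)

# printed composition -> sodiated m/z anchors (4 dp)
MASS_ANCHORS = {
    "Hex5HexNAc4": 1663.5814,
    "Hex9HexNAc2": 1905.6339,
    "Hex5dHex1HexNAc4": 1809.6393,
    "Hex6HexNAc5": 2028.7136,
    "Hex7HexNAc6": 2393.8458,
    "Hex6dHex1HexNAc6": 2377.8509,
    "Hex9dHex1HexNAc8": 3270.1681,
    "Hex8dHex1HexNAc7": 2905.0359,
    "Hex7dHex1HexNAc7": 2742.9831,
    "Hex5dHex1HexNAc4NeuAc1": 2100.7347,
}
DERIVATIZED_ANCHORS = {
    "Hex5dHex1HexNAc4NeuAc1(2,3)": 2099.7507,
    "Hex5dHex2HexNAc5NeuAc1(2,6)": 2476.9193,
}


def test_residue_mass_constants():
    assert residue_mass("hex") == pytest.approx(162.052824, abs=1e-5)
    assert residue_mass("dhex") == pytest.approx(146.057909, abs=1e-5)
    assert residue_mass("hexnac") == pytest.approx(203.079373, abs=1e-5)
    assert residue_mass("neuac") == pytest.approx(291.095417, abs=1e-5)
    assert residue_mass("sulfate") == pytest.approx(79.956815, abs=1e-5)
    assert residue_mass("water") == pytest.approx(18.010565, abs=1e-5)
    assert residue_mass("sodium_cation") == pytest.approx(22.989218, abs=1e-5)
    with pytest.raises(ValueError, match="glucose"):
        residue_mass("glucose")


@pytest.mark.parametrize("key,expected", sorted(MASS_ANCHORS.items()))
def test_sodiated_mz_anchors(key, expected):
    assert round(mz_for_key(key), 4) == expected


@pytest.mark.parametrize("key,expected", sorted(DERIVATIZED_ANCHORS.items()))
def test_derivatized_mz_anchors(key, expected):
    c = GlycanComposition.from_key(key)
    assert round(theoretical_mz(c, AMIDATED), 4) == expected


def test_neutral_mass_basics():
    c = GlycanComposition.from_key("Hex5HexNAc4")
    assert neutral_mass(c) == pytest.approx(1640.592190, abs=1e-4)
    assert neutral_mass(GlycanComposition()) == pytest.approx(18.010565, abs=1e-6)


def test_derivatization_deltas_match_printed_pair():
    """Printed native vs alpha-2,3-amidated sodiated values differ by the
    implemented amide shift; the 2,6 shift is the dimethylamide delta."""
    native = mz_for_key("Hex5dHex1HexNAc4NeuAc1")
    amidated = theoretical_mz(
        GlycanComposition.from_key("Hex5dHex1HexNAc4NeuAc1(2,3)"), AMIDATED
    )
    assert native - amidated == pytest.approx(-AMIDE_DELTA, abs=1e-9)
    assert round(native - amidated, 4) == 0.9840
    assert DIMETHYLAMIDE_DELTA == pytest.approx(27.047284, abs=1e-6)
    assert DIMETHYLAMIDE_DELTA - AMIDE_DELTA == pytest.approx(28.031300, abs=1e-6)


def test_amidation_requires_specified_linkages():
    c = GlycanComposition.from_key("Hex5dHex1HexNAc4NeuAc1")  # unspecified
    with pytest.raises(ValueError, match="linkage"):
        neutral_mass(c, SialicMode.AMIDATION_AMIDATION)


def test_endof3_shift_is_composition_independent():
    chem = NATIVE
    for key in ["Hex5dHex1HexNAc4", "Hex6dHex1HexNAc6", "Hex9dHex1HexNAc8"]:
        c = GlycanComposition.from_key(key)
        assert endof3_mz(c, chem) - theoretical_mz(c, chem) == pytest.approx(
            -349.137282, abs=1e-6
        )
    assert round(endof3_mz(GlycanComposition.from_key("Hex5dHex1HexNAc4"), chem), 4) \
        == 1460.5020


def test_endof3_requires_core_fucose():
    with pytest.raises(ValueError, match="core fucose"):
        endof3_mz(GlycanComposition.from_key("Hex5HexNAc4"), NATIVE)


@settings(max_examples=100, deadline=None)
@given(
    base=st.tuples(
        st.integers(0, 8), st.integers(0, 8), st.integers(0, 4), st.integers(0, 3)
    ),
    extra=st.tuples(
        st.integers(0, 4), st.integers(0, 4), st.integers(0, 2), st.integers(0, 2)
    ),
)
def test_mz_additivity(base, extra):
    """Adding residues changes m/z by exactly the sum of their masses."""
    c1 = GlycanComposition(n_hex=base[0], n_hexnac=base[1], n_dhex=base[2],
                           n_neuac=base[3])
    c2 = GlycanComposition(
        n_hex=base[0] + extra[0], n_hexnac=base[1] + extra[1],
        n_dhex=base[2] + extra[2], n_neuac=base[3] + extra[3],
    )
    delta = (
        extra[0] * residue_mass("hex") + extra[1] * residue_mass("hexnac")
        + extra[2] * residue_mass("dhex") + extra[3] * residue_mass("neuac")
    )
    assert theoretical_mz(c2, NATIVE) - theoretical_mz(c1, NATIVE) == pytest.approx(
        delta, abs=1e-9
    )


def test_linkage_swap_delta():
    """Switching one NeuAc from 2,3 to 2,6 adds exactly 28.031300 Da."""
    a = GlycanComposition.from_key("Hex5dHex1HexNAc4NeuAc2(2,3)(2,3)")
    b = GlycanComposition.from_key("Hex5dHex1HexNAc4NeuAc2(2,3)(2,6)")
    assert theoretical_mz(b, AMIDATED) - theoretical_mz(a, AMIDATED) == pytest.approx(
        28.031300, abs=1e-6
    )


def test_key_round_trip_and_ordering():
    c = GlycanComposition.from_key("HexNAc4Hex5dHex1")  # any order parses
    assert c.key == "Hex5dHex1HexNAc4"  # canonical order on output
    assert GlycanComposition.from_key(c.key) == c
    with pytest.raises(ValueError):
        GlycanComposition.from_key("Hex5Xyl2")


def test_build_database_membership_and_order(native_db):
    keys = {e.key for e in native_db}
    assert "Hex5HexNAc4" in keys
    target = next(e for e in native_db if e.key == "Hex5HexNAc4")
    assert round(target.theoretical_mz, 4) == 1663.5814
    mzs = [e.theoretical_mz for e in native_db]
    assert mzs == sorted(mzs)
    assert len(keys) == len(native_db)  # unique on key


def test_build_database_single_admissible():
    bounds = EnumerationBounds(
        hex=(3, 3), hexnac=(2, 2), dhex=(0, 0), neuac=(0, 0), sulfate=(0, 0)
    )
    db = build_database(bounds, ChemistryConfig(mass_range_lo=490, mass_range_hi=4000))
    assert len(db) == 1 and db[0].key == "Hex3HexNAc2"


def test_build_database_matches_bruteforce_count():
    """Entry count equals an exhaustive nested-loop enumeration with the
    same core/antenna rules and mass window."""
    bounds = EnumerationBounds(
        hex=(3, 6), hexnac=(2, 5), dhex=(0, 2), neuac=(0, 2), sulfate=(0, 1)
    )
    chem = ChemistryConfig(mass_range_lo=490, mass_range_hi=2500)
    db = build_database(bounds, chem)
    count = 0
    for nh, nn, nd, ns, nsu in itertools.product(
        range(3, 7), range(2, 6), range(0, 3), range(0, 3), range(0, 2)
    ):
        if nh < 3 or nn < 2 or ns > max(nn - 2, 0):
            continue
        c = GlycanComposition(n_hex=nh, n_hexnac=nn, n_dhex=nd, n_neuac=ns,
                              n_sulfate=nsu)
        if 490 <= theoretical_mz(c, chem) <= 2500:
            count += 1
    assert len(db) == count


def test_database_tsv_round_trip(tmp_path, small_db):
    path = tmp_path / "db.tsv"
    export_database(small_db, path)
    back = import_database(path)
    assert len(back) == len(small_db)
    for orig, re_read in zip(small_db, back):
        assert orig.key == re_read.key
        assert re_read.theoretical_mz == pytest.approx(orig.theoretical_mz, abs=1e-6)
        # recomputable from composition + chemistry
        rechem = ChemistryConfig(
            release=re_read.release, sialic_mode=re_read.sialic_mode,
            sulfate_adduct=re_read.sulfate_adduct,
        )
        assert theoretical_mz(re_read.composition, rechem) == pytest.approx(
            re_read.theoretical_mz, abs=1e-6
        )


def test_derivatized_database_one_entry_per_linkage_multiset():
    bounds = EnumerationBounds(
        hex=(5, 5), hexnac=(4, 4), dhex=(0, 0), neuac=(2, 2), sulfate=(0, 0)
    )
    chem = ChemistryConfig(
        sialic_mode=SialicMode.AMIDATION_AMIDATION,
        mass_range_lo=490, mass_range_hi=4000,
    )
    db = build_database(bounds, chem)
    # 2 NeuAc -> 3 multisets: {23,23}, {23,26}, {26,26}
    assert len(db) == 3
    assert len({e.theoretical_mz for e in db}) == 3


def test_endof3_mixture_emits_both_products():
    bounds = EnumerationBounds(
        hex=(5, 5), hexnac=(4, 4), dhex=(0, 1), neuac=(0, 0), sulfate=(0, 0)
    )
    chem = ChemistryConfig(release=Release.ENDOF3, mass_range_lo=490,
                           mass_range_hi=4000)
    db = build_database(bounds, chem)
    keys = {e.key for e in db}
    assert keys == {"Hex5HexNAc4", "Hex5dHex1HexNAc4", "Hex5dHex1HexNAc4[EndoF3]"}
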