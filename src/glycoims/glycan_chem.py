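"""Theoretical N-glycan masses and the annotation database.

N-glycan compositions are multisets of monosaccharide building blocks
(hexose, N-acetylhexosamine, deoxyhexose/fucose, N-acetylneuraminic acid)
plus optional sulfate groups.  This module computes monoisotopic neutral
masses and sodiated ion m/z values for such compositions under a
configurable chemistry:

* release enzyme — PNGase F releases the intact glycan; Endo F3 cleaves
  between the two core GlcNAc residues when a core fucose is present,
  so its product is lighter by one HexNAc plus one dHex (349.137282 Da);
* sialic-acid derivatization — the amidation–amidation reaction converts
  the carboxyl group of alpha-2,3-linked NeuAc to an amide (−0.984016 Da)
  and of alpha-2,6-linked NeuAc to a dimethylamide (+27.047284 Da),
  making the linkage isomers mass-resolvable;
* adduct — positive-mode sodiated species, with a configurable convention
  for sulfated glycans (default: one sodium replaces one acidic proton
  per sulfate, i.e. [M − nH + (n+1)Na]+ for n sulfates).

All masses are monoisotopic, in Da, built from IUPAC atomic masses with
the electron mass included in the cation.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Atomic and residue masses
# ---------------------------------------------------------------------------

# IUPAC monoisotopic atomic masses (Da)
_ATOM = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "Na": 22.9897692809,
}
ELECTRON_MASS = 0.00054857991


def _formula_mass(formula: dict[str, int]) -> float:
    return sum(_ATOM[el] * n for el, n in formula.items())


#: Monoisotopic masses of the building blocks (Da).  Residue masses are the
#: dehydrated (in-chain) forms; one water is added per glycan for the
#: reducing-end closure.
RESIDUE_MASSES: dict[str, float] = {
    "hex": _formula_mass({"C": 6, "H": 10, "O": 5}),        # 162.052824
    "hexnac": _formula_mass({"C": 8, "H": 13, "N": 1, "O": 5}),  # 203.079373
    "dhex": _formula_mass({"C": 6, "H": 10, "O": 4}),       # 146.057909
    "neuac": _formula_mass({"C": 11, "H": 17, "N": 1, "O": 8}),  # 291.095417
    "sulfate": _formula_mass({"S": 1, "O": 3}),             # 79.956815
    "water": _formula_mass({"H": 2, "O": 1}),               # 18.010565
    "sodium_cation": _ATOM["Na"] - ELECTRON_MASS,           # 22.989221
}

WATER = RESIDUE_MASSES["water"]
SODIUM_CATION = RESIDUE_MASSES["sodium_cation"]
PROTON = _ATOM["H"] - ELECTRON_MASS

#: Amidation (carboxyl -> amide): +NH3 −H2O, applied to alpha-2,3 NeuAc.
AMIDE_DELTA = _formula_mass({"N": 1, "H": 3}) - WATER          # −0.984016
#: Dimethylamidation (carboxyl -> dimethylamide): +HN(CH3)2 −H2O, alpha-2,6.
DIMETHYLAMIDE_DELTA = _formula_mass({"C": 2, "H": 7, "N": 1}) - WATER  # +27.047284

#: Mass removed by Endo F3 release relative to the PNGase F product:
#: one core GlcNAc plus its attached core fucose.
ENDOF3_SHIFT = RESIDUE_MASSES["hexnac"] + RESIDUE_MASSES["dhex"]  # 349.137282


def residue_mass(residue: str) -> float:
    """Monoisotopic mass (Da) of a named building block.

    Recognized tokens: ``hex``, ``hexnac``, ``dhex``, ``neuac``,
    ``sulfate``, ``water``, ``sodium_cation``.
    """
    try:
        return RESIDUE_MASSES[residue]
    except KeyError:
        raise ValueError(
            f"unknown residue token {residue!r}; expected one of "
            f"{sorted(RESIDUE_MASSES)}"
        ) from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class Linkage(str, Enum):
    """Sialic-acid linkage flag carried per NeuAc residue."""

    ALPHA2_3 = "alpha2_3"
    ALPHA2_6 = "alpha2_6"
    UNSPECIFIED = "unspecified"


class Release(str, Enum):
    PNGASEF = "pngasef"
    ENDOF3 = "endof3"


class SialicMode(str, Enum):
    NATIVE = "native"
    AMIDATION_AMIDATION = "amidation_amidation"


_LINKAGE_SUFFIX = {Linkage.ALPHA2_3: "(2,3)", Linkage.ALPHA2_6: "(2,6)"}


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of monosaccharide/sulfate building blocks plus linkage flags.

    ``neuac_linkages`` holds one :class:`Linkage` per NeuAc residue; mass
    depends only on the multiset of linkage values, not their order.
    """

    n_hex: int = 0
    n_hexnac: int = 0
    n_dhex: int = 0
    n_neuac: int = 0
    n_sulfate: int = 0
    neuac_linkages: tuple[Linkage, ...] = ()

    def __post_init__(self) -> None:
        for name in ("n_hex", "n_hexnac", "n_dhex", "n_neuac", "n_sulfate"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        links = tuple(Linkage(l) for l in self.neuac_linkages)
        if not links and self.n_neuac:
            links = (Linkage.UNSPECIFIED,) * self.n_neuac
        if len(links) != self.n_neuac:
            raise ValueError(
                f"neuac_linkages has length {len(links)} but n_neuac={self.n_neuac}"
            )
        object.__setattr__(self, "neuac_linkages", links)

    @property
    def key(self) -> str:
        """Canonical text key, e.g. ``Hex5dHex1HexNAc4NeuAc1``.

        Zero-count terms are omitted; Hex/dHex/HexNAc/NeuAc/SO4 order.
        """
        parts = []
        for label, n in (
            ("Hex", self.n_hex),
            ("dHex", self.n_dhex),
            ("HexNAc", self.n_hexnac),
            ("NeuAc", self.n_neuac),
            ("SO4", self.n_sulfate),
        ):
            if n:
                parts.append(f"{label}{n}")
        return "".join(parts)

    @property
    def key_with_linkages(self) -> str:
        """Key with linkage suffixes, e.g. ``Hex5dHex1HexNAc4NeuAc1(2,3)``."""
        suffix = "".join(
            _LINKAGE_SUFFIX.get(l, "") for l in sorted(self.neuac_linkages, key=str)
        )
        return self.key + suffix

    @classmethod
    def from_key(cls, key: str) -> "GlycanComposition":
        """Parse a composition key; residue terms may appear in any order.

        Trailing ``(2,3)``/``(2,6)`` groups are read as per-NeuAc linkage
        flags (e.g. ``Hex5dHex1HexNAc4NeuAc1(2,3)``).
        """
        links = []
        for m in re.finditer(r"\((2),([36])\)", key):
            links.append(Linkage.ALPHA2_3 if m.group(2) == "3" else Linkage.ALPHA2_6)
        body = re.sub(r"\(2,[36]\)", "", key)
        counts = {"Hex": 0, "dHex": 0, "HexNAc": 0, "NeuAc": 0, "SO4": 0}
        pos = 0
        for m in re.finditer(r"(dHex|HexNAc|NeuAc|Hex|SO4)(\d+)", body):
            if m.start() != pos:
                raise ValueError(f"cannot parse composition key {key!r}")
            counts[m.group(1)] += int(m.group(2))
            pos = m.end()
        if pos != len(body):
            raise ValueError(f"cannot parse composition key {key!r}")
        n_neuac = counts["NeuAc"]
        if links and len(links) != n_neuac:
            raise ValueError(
                f"{key!r}: {len(links)} linkage flags for {n_neuac} NeuAc residues"
            )
        linkages = tuple(links) if links else (Linkage.UNSPECIFIED,) * n_neuac
        return cls(
            n_hex=counts["Hex"],
            n_hexnac=counts["HexNAc"],
            n_dhex=counts["dHex"],
            n_neuac=n_neuac,
            n_sulfate=counts["SO4"],
            neuac_linkages=linkages,
        )


class SulfateAdduct(str, Enum):
    """Ion convention for sulfated glycans.

    ``SODIUM_EXCHANGE`` is [M − nH + (n+1)Na]+ for n sulfates: each acidic
    sulfate proton exchanged for sodium, plus the charging sodium.
    ``SINGLE_SODIUM`` keeps plain [M+Na]+ regardless of sulfation.
    """

    SODIUM_EXCHANGE = "M_minus_H_plus_2Na"
    SINGLE_SODIUM = "M_plus_Na"


@dataclass(frozen=True)
class ChemistryConfig:
    """Release-enzyme, derivatization, adduct and mass-range settings."""

    release: Release = Release.PNGASEF
    sialic_mode: SialicMode = SialicMode.NATIVE
    sulfate_adduct: SulfateAdduct = SulfateAdduct.SODIUM_EXCHANGE
    mass_range_lo: float = 490.0
    mass_range_hi: float = 5000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "release", Release(self.release))
        object.__setattr__(self, "sialic_mode", SialicMode(self.sialic_mode))
        object.__setattr__(self, "sulfate_adduct", SulfateAdduct(self.sulfate_adduct))
        if not self.mass_range_lo < self.mass_range_hi:
            raise ValueError("mass_range_lo must be < mass_range_hi")

    @property
    def summary(self) -> str:
        return f"{self.release.value}/{self.sialic_mode.value}/{self.sulfate_adduct.value}"


@dataclass(frozen=True)
class MassEntry:
    """One annotation-database row: composition, chemistry, theoretical m/z."""

    composition: GlycanComposition
    release: Release
    sialic_mode: SialicMode
    sulfate_adduct: SulfateAdduct
    neutral_mass: float
    theoretical_mz: float
    ambiguity_partners: tuple[str, ...] = ()

    @property
    def key(self) -> str:
        k = (
            self.composition.key_with_linkages
            if self.sialic_mode is SialicMode.AMIDATION_AMIDATION
            else self.composition.key
        )
        if self.release is Release.ENDOF3:
            k += "[EndoF3]"
        return k


# ---------------------------------------------------------------------------
# Mass computation
# ---------------------------------------------------------------------------


def neutral_mass(
    c: GlycanComposition, sialic_mode: SialicMode | str = SialicMode.NATIVE
) -> float:
    """Monoisotopic neutral mass (Da) of a released glycan.

    Sum of residue masses plus one water (reducing-end closure), with the
    per-NeuAc derivatization delta applied under amidation–amidation
    chemistry.  Every NeuAc linkage must then be specified, since the two
    linkage isomers acquire different masses.
    """
    sialic_mode = SialicMode(sialic_mode)
    m = (
        c.n_hex * RESIDUE_MASSES["hex"]
        + c.n_hexnac * RESIDUE_MASSES["hexnac"]
        + c.n_dhex * RESIDUE_MASSES["dhex"]
        + c.n_neuac * RESIDUE_MASSES["neuac"]
        + c.n_sulfate * RESIDUE_MASSES["sulfate"]
        + WATER
    )
    if sialic_mode is SialicMode.AMIDATION_AMIDATION:
        for link in c.neuac_linkages:
            if link is Linkage.ALPHA2_3:
                m += AMIDE_DELTA
            elif link is Linkage.ALPHA2_6:
                m += DIMETHYLAMIDE_DELTA
            else:
                raise ValueError(
                    "amidation_amidation mass is undefined for unspecified "
                    f"NeuAc linkage in {c.key}"
                )
    return m


def theoretical_mz(c: GlycanComposition, chem: ChemistryConfig) -> float:
    """Positive-mode sodiated ion m/z for a composition under ``chem``.

    Default adduct is [M+Na]+; for sulfated glycans the configured
    sulfate convention applies (default sodium exchange of each sulfate
    proton).  Endo F3 release subtracts one HexNAc and one dHex from the
    PNGase F product mass.
    """
    m = neutral_mass(c, chem.sialic_mode) + SODIUM_CATION
    if c.n_sulfate and chem.sulfate_adduct is SulfateAdduct.SODIUM_EXCHANGE:
        m += c.n_sulfate * (_ATOM["Na"] - _ATOM["H"])
    if chem.release is Release.ENDOF3:
        if c.n_dhex < 1 or c.n_hexnac < 2:
            raise ValueError(
                "Endo F3 requires core fucose: composition must have "
                f"n_dhex >= 1 and n_hexnac >= 2, got {c.key or 'empty'}"
            )
        m -= ENDOF3_SHIFT
    return m


def endof3_mz(c: GlycanComposition, chem: ChemistryConfig) -> float:
    """m/z of the Endo F3 release product of ``c``.

    Endo F3 cleaves above the first core GlcNAc when a fucose is attached,
    so the product is the PNGase F ion minus 349.137282 Da (one HexNAc and
    one dHex).
    """
    return theoretical_mz(c, replace(chem, release=Release.ENDOF3))


# ---------------------------------------------------------------------------
# Database construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnumerationBounds:
    """Inclusive per-residue count bounds for database enumeration."""

    hex: tuple[int, int] = (3, 12)
    hexnac: tuple[int, int] = (2, 10)
    dhex: tuple[int, int] = (0, 6)
    neuac: tuple[int, int] = (0, 4)
    sulfate: tuple[int, int] = (0, 2)


def _plausible(c: GlycanComposition) -> bool:
    """Default biosynthetic plausibility rules.

    The N-glycan core requires two GlcNAc and three mannose residues;
    sialic acids cap antennae, of which there are at most HexNAc − 2.
    """
    if c.n_hexnac < 2 or c.n_hex < 3:
        return False
    if c.n_neuac > max(c.n_hexnac - 2, 0):
        return False
    return True


def _linkage_multisets(n: int) -> list[tuple[Linkage, ...]]:
    """Distinct multisets of {alpha2_3, alpha2_6} assignments for n NeuAc."""
    return [
        (Linkage.ALPHA2_3,) * k + (Linkage.ALPHA2_6,) * (n - k)
        for k in range(n, -1, -1)
    ]


def build_database(
    bounds: EnumerationBounds | None = None,
    chem: ChemistryConfig | None = None,
    plausibility=_plausible,
    tol_ppm: float = 5.0,
) -> list[MassEntry]:
    """Enumerate plausible compositions and compute their theoretical m/z.

    Returns one :class:`MassEntry` per admissible composition whose m/z
    falls inside the chemistry's mass range, sorted ascending by m/z.
    Under amidation–amidation derivatization one entry is emitted per
    distinct multiset of NeuAc linkage assignments.  When the release is
    Endo F3, entries for both release products (PNGase F and Endo F3 of
    core-fucosylated species) are emitted, tagged by enzyme, mirroring a
    mixed-enzyme digest.  ``ambiguity_partners`` lists the keys of other
    entries within ``tol_ppm`` of each entry.
    """
    bounds = bounds or EnumerationBounds()
    chem = chem or ChemistryConfig()

    releases = [Release.PNGASEF]
    if chem.release is Release.ENDOF3:
        releases.append(Release.ENDOF3)

    entries: list[MassEntry] = []
    seen: set[tuple[str, Release]] = set()
    for nh, nn, nd, ns, nsu in itertools.product(
        range(bounds.hex[0], bounds.hex[1] + 1),
        range(bounds.hexnac[0], bounds.hexnac[1] + 1),
        range(bounds.dhex[0], bounds.dhex[1] + 1),
        range(bounds.neuac[0], bounds.neuac[1] + 1),
        range(bounds.sulfate[0], bounds.sulfate[1] + 1),
    ):
        if chem.sialic_mode is SialicMode.AMIDATION_AMIDATION:
            linkage_sets = _linkage_multisets(ns)
        else:
            linkage_sets = [(Linkage.UNSPECIFIED,) * ns]
        for links in linkage_sets:
            c = GlycanComposition(
                n_hex=nh, n_hexnac=nn, n_dhex=nd, n_neuac=ns, n_sulfate=nsu,
                neuac_linkages=links,
            )
            if not plausibility(c):
                continue
            for release in releases:
                if release is Release.ENDOF3 and (c.n_dhex < 1 or c.n_hexnac < 2):
                    continue
                rchem = replace(chem, release=release)
                mz = theoretical_mz(c, rchem)
                if not (chem.mass_range_lo <= mz <= chem.mass_range_hi):
                    continue
                entry = MassEntry(
                    composition=c,
                    release=release,
                    sialic_mode=chem.sialic_mode,
                    sulfate_adduct=chem.sulfate_adduct,
                    neutral_mass=neutral_mass(c, chem.sialic_mode),
                    theoretical_mz=mz,
                )
                dedup = (entry.key, release)
                if dedup in seen:
                    continue
                seen.add(dedup)
                entries.append(entry)

    entries.sort(key=lambda e: e.theoretical_mz)
    if not entries:
        logger.warning("database enumeration produced no entries under given bounds")
        return entries
    return _populate_ambiguity(entries, tol_ppm)


def _populate_ambiguity(entries: list[MassEntry], tol_ppm: float) -> list[MassEntry]:
    """Mark entries whose m/z lie within tol_ppm of each other (sorted input)."""
    n = len(entries)
    partners: list[list[str]] = [[] for _ in range(n)]
    for i in range(n):
        mz_i = entries[i].theoretical_mz
        j = i + 1
        while j < n:
            mz_j = entries[j].theoretical_mz
            if (mz_j - mz_i) / mz_i * 1e6 > tol_ppm:
                break
            partners[i].append(entries[j].key)
            partners[j].append(entries[i].key)
            j += 1
    return [
        replace(e, ambiguity_partners=tuple(p)) for e, p in zip(entries, partners)
    ]


# ---------------------------------------------------------------------------
# TSV export / import
# ---------------------------------------------------------------------------

_DB_COLUMNS = [
    "key", "n_hex", "n_dhex", "n_hexnac", "n_neuac", "n_sulfate",
    "linkage_summary", "release", "sialic_mode", "adduct",
    "neutral_mass", "theoretical_mz",
]


def export_database(entries: Sequence[MassEntry], path) -> None:
    """Write a database to UTF-8 TSV with 6-decimal mass columns."""
    rows = []
    for e in entries:
        c = e.composition
        rows.append({
            "key": e.key,
            "n_hex": c.n_hex,
            "n_dhex": c.n_dhex,
            "n_hexnac": c.n_hexnac,
            "n_neuac": c.n_neuac,
            "n_sulfate": c.n_sulfate,
            "linkage_summary": ";".join(l.value for l in c.neuac_linkages),
            "release": e.release.value,
            "sialic_mode": e.sialic_mode.value,
            "adduct": e.sulfate_adduct.value,
            "neutral_mass": f"{e.neutral_mass:.6f}",
            "theoretical_mz": f"{e.theoretical_mz:.6f}",
        })
    pd.DataFrame(rows, columns=_DB_COLUMNS).to_csv(path, sep="\t", index=False)


def import_database(path) -> list[MassEntry]:
    """Read a TSV database written by :func:`export_database`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        links = tuple(
            Linkage(t) for t in str(row.linkage_summary).split(";") if t
        )
        c = GlycanComposition(
            n_hex=int(row.n_hex),
            n_hexnac=int(row.n_hexnac),
            n_dhex=int(row.n_dhex),
            n_neuac=int(row.n_neuac),
            n_sulfate=int(row.n_sulfate),
            neuac_linkages=links,
        )
        entries.append(MassEntry(
            composition=c,
            release=Release(row.release),
            sialic_mode=SialicMode(row.sialic_mode),
            sulfate_adduct=SulfateAdduct(row.adduct),
            neutral_mass=float(row.neutral_mass),
            theoretical_mz=float(row.theoretical_mz),
        ))
    entries.sort(key=lambda e: e.theoretical_mz)
    return _populate_ambiguity(entries, 5.0)


def mz_for_key(key: str, chem: ChemistryConfig | None = None) -> float:
    """Convenience: theoretical m/z for a composition key string."""
    return theoretical_mz(GlycanComposition.from_key(key), chem or ChemistryConfig())
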