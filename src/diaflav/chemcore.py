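"""Exact-mass arithmetic for glycosylated-flavonoid annotation.

Everything downstream of feature detection rests on a small amount of
monoisotopic arithmetic: molecular formulas, adduct m/z values, ppm errors,
and the two families of in-silico glycoside fragments observed in negative
mode:

* **O-glycosides** release the intact glycosyl moiety, yielding either the
  even-electron deprotonated aglycone ``[Agly - H]-`` (heterolytic cleavage)
  or the radical anion ``[Agly - 2H].-`` one hydrogen atom lower (homolytic
  cleavage, where the neutral loss carries the extra hydrogen).
* **C-glycosides** never release the bare aglycone; cross-ring sugar
  cleavage leaves a small residue on the fragment, canonically
  +42.0106 Da (C2H2O, the "etenol" remnant of losing 120 Da from a hexosyl
  or 90 Da from a pentosyl unit) or +72.0211 Da (C3H4O2, losing 90 Da from
  a hexosyl unit).

All fragment m/z values are expressed on the deprotonated ``[M - H]-``
basis.  Element masses come from the NIST table shipped with pyteomics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from pyteomics import mass as _pymass
from pyteomics.auxiliary import PyteomicsError

__all__ = [
    "PROTON_MASS",
    "H_ATOM_MASS",
    "C13_C12_DELTA",
    "ETENOL_RESIDUE",
    "PROPANEDIOL_RESIDUE",
    "ElementComposition",
    "AdductDef",
    "SugarLossDef",
    "FragmentRecord",
    "parse_formula",
    "monoisotopic_mass",
    "formula_mass",
    "adduct_mz",
    "ppm_error",
    "o_glycoside_fragments",
    "c_glycoside_fragments",
    "build_fragment_db",
    "neutral_loss",
    "match_sugar",
    "DEFAULT_ADDUCTS",
    "expand_adducts",
    "DEFAULT_SUGAR_LOSSES",
    "PAPER_AGLYCONES",
]

#: Mass of a proton (charge carrier in deprotonation), Da.
PROTON_MASS = 1.00727646677
#: Mass of a neutral hydrogen atom, Da (radical-loss correction).
H_ATOM_MASS = 1.00782503207
#: 13C - 12C mass difference, Da (isotope-satellite spacing at z = 1).
C13_C12_DELTA = 1.0033548378

#: C2H2O residue retained on C-glycoside fragments ("etenol"), Da.
ETENOL_RESIDUE = 42.0105646863
#: C3H4O2 residue retained on C-glycoside fragments, Da.
PROPANEDIOL_RESIDUE = 72.0211293741


class ElementComposition(dict):
    """Element -> count mapping for a molecular formula.

    A thin dict subclass so compositions can be added together; validation
    (known element symbols, non-negative counts) happens in
    :func:`parse_formula`.
    """

    def __add__(self, other: Mapping[str, int]) -> "ElementComposition":
        out = ElementComposition(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return out


def parse_formula(formula: str) -> ElementComposition:
    """Parse a Hill-style molecular formula (e.g. ``"C15H10O6"``).

    Element symbols are case-sensitive; unknown symbols and empty input
    raise ``ValueError``.
    """
    if not formula or not formula.strip():
        raise ValueError("empty molecular formula")
    try:
        comp = _pymass.Composition(formula=formula.strip())
    except PyteomicsError as exc:
        raise ValueError(f"cannot parse formula {formula!r}: {exc}") from exc
    for el, n in comp.items():
        if n < 0:
            raise ValueError(f"negative count for element {el!r} in {formula!r}")
        if el not in _pymass.nist_mass:
            raise ValueError(f"unknown element symbol {el!r} in {formula!r}")
    return ElementComposition({el: int(n) for el, n in comp.items() if n})


def monoisotopic_mass(comp: Mapping[str, int]) -> float:
    """Monoisotopic mass of a composition (most abundant isotope per
    element), in Da.  Empty composition has mass 0."""
    total = 0.0
    for el, n in comp.items():
        if el not in _pymass.nist_mass:
            raise ValueError(f"unknown element symbol {el!r}")
        total += _pymass.nist_mass[el][0][0] * n
    return total


def formula_mass(formula: str) -> float:
    """Shorthand for ``monoisotopic_mass(parse_formula(formula))``."""
    return monoisotopic_mass(parse_formula(formula))


@dataclass(frozen=True)
class AdductDef:
    """An ESI adduct: m/z = (n_mol * M + delta) / |charge|."""

    name: str
    delta: float
    charge: int = -1
    n_mol: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"adduct {self.name!r}: charge must be nonzero")
        if not math.isfinite(self.delta):
            raise ValueError(f"adduct {self.name!r}: delta must be finite")
        if self.n_mol < 1:
            raise ValueError(f"adduct {self.name!r}: n_mol must be >= 1")


def adduct_mz(neutral_mass: float, adduct: AdductDef) -> float:
    """m/z of ``adduct`` formed from a molecule of ``neutral_mass`` Da."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return (adduct.n_mol * neutral_mass + adduct.delta) / abs(adduct.charge)


# Negative-mode adducts used for the MS1 database search.  Deltas are on the
# electron-mass-ignored convention (deprotonation delta = proton mass), which
# reproduces the observed ppm errors to better than 0.1 ppm.
_CL_MASS = 34.96885268
_BR_MASS = 78.9183376
_FORMATE_DELTA = formula_mass("CH2O2") - PROTON_MASS  # [M + HCOO]- = +44.99820

DEFAULT_ADDUCTS: Tuple[AdductDef, ...] = (
    AdductDef("[M-H]-", -PROTON_MASS, -1, 1),
    AdductDef("[M+Cl]-", _CL_MASS, -1, 1),
    AdductDef("[M+Br]-", _BR_MASS, -1, 1),
    AdductDef("[M+FA]-", _FORMATE_DELTA, -1, 1),
)


def expand_adducts(
    base: Sequence[AdductDef] = DEFAULT_ADDUCTS,
    max_charge: int = 2,
    max_n_mol: int = 2,
) -> List[AdductDef]:
    """Expand base single-charge adducts to multi-molecule clusters and, for
    deprotonation, multiply-charged ions (``[2M-H]-``, ``[M-2H]2-``, ...)."""
    out: List[AdductDef] = []
    for ad in base:
        for n in range(1, max_n_mol + 1):
            prefix = "" if n == 1 else str(n)
            out.append(replace(ad, name=ad.name.replace("M", prefix + "M", 1), n_mol=n))
        if math.isclose(ad.delta, -PROTON_MASS, abs_tol=1e-6):
            for z in range(2, max_charge + 1):
                out.append(
                    AdductDef(f"[M-{z}H]{z}-", -z * PROTON_MASS, -z, 1)
                )
    # deduplicate by name, keep first
    seen: Dict[str, AdductDef] = {}
    for ad in out:
        seen.setdefault(ad.name, ad)
    return list(seen.values())


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# ---------------------------------------------------------------------------
# In-silico glycoside fragments
# ---------------------------------------------------------------------------

HETEROLYTIC_O = "heterolytic-O"
HOMOLYTIC_O = "homolytic-O"
C_RESIDUE = "C-residue"


@dataclass(frozen=True)
class FragmentRecord:
    """One theoretical aglycone fragment on the [M - H]- basis."""

    aglycone: str
    label: str
    mz: float
    cleavage: str  # heterolytic-O | homolytic-O | C-residue
    residue_mass: float = 0.0  # retained sugar residue, 0 for bare aglycone

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"fragment {self.label!r}: m/z must be positive")


def o_glycoside_fragments(aglycone: str, neutral_mass: float) -> Tuple[FragmentRecord, FragmentRecord]:
    """Heterolytic and homolytic O-cleavage fragments of an aglycone.

    Returns ``([Agly - H]-, [Agly - 2H].-)``; the radical ion sits one
    hydrogen atom (1.007825 Da) below the even-electron one.
    """
    if neutral_mass <= 0:
        raise ValueError("aglycone neutral mass must be positive")
    hetero = neutral_mass - PROTON_MASS
    homo = hetero - H_ATOM_MASS
    return (
        FragmentRecord(aglycone, f"{aglycone} [M-H]-", hetero, HETEROLYTIC_O),
        FragmentRecord(aglycone, f"{aglycone} [M-H].-", homo, HOMOLYTIC_O),
    )


_RESIDUE_NAMES = {
    ETENOL_RESIDUE: "etenol",
    PROPANEDIOL_RESIDUE: "C3H4O2",
}
_COUNT_PREFIX = {1: "", 2: "di-", 3: "tri-"}


def _residue_label(combo: Sequence[float]) -> str:
    parts = []
    for res in sorted(set(combo)):
        k = combo.count(res)
        parts.append(_COUNT_PREFIX.get(k, f"{k}x-") + _RESIDUE_NAMES[res])
    return "-".join(parts)


def c_glycoside_fragments(
    aglycone: str, neutral_mass: float, n_sugars: int
) -> List[FragmentRecord]:
    """Cross-ring C-glycoside fragments for ``n_sugars`` C-bound sugars.

    Each sugar leaves either an etenol (C2H2O, +42.0106 Da) or a C3H4O2
    (+72.0211 Da) residue on the deprotonated aglycone; combinations are
    enumerated and deduplicated on the summed residue mass.
    """
    if neutral_mass <= 0:
        raise ValueError("aglycone neutral mass must be positive")
    if n_sugars not in (1, 2):
        raise ValueError(f"n_sugars must be 1 or 2, got {n_sugars}")
    base = neutral_mass - PROTON_MASS
    records: List[FragmentRecord] = []
    seen: set = set()
    for combo in itertools.combinations_with_replacement(
        (ETENOL_RESIDUE, PROPANEDIOL_RESIDUE), n_sugars
    ):
        residue = sum(combo)
        key = round(residue, 6)
        if key in seen:
            continue
        seen.add(key)
        records.append(
            FragmentRecord(
                aglycone,
                f"{aglycone}-{_residue_label(combo)} [M-H]-",
                base + residue,
                C_RESIDUE,
                residue_mass=residue,
            )
        )
    records.sort(key=lambda r: r.mz)
    return records


#: The eight aglycone backbones of the MS2 fragment database.  Exact-mass
#: isomer groups (kaempferol/datiscetin/luteolin; catechin/epicatechin) are
#: represented once at the formula level — m/z alone cannot separate them.
PAPER_AGLYCONES: Tuple[Tuple[str, str], ...] = (
    ("Kaempferol", "C15H10O6"),   # isomers: datiscetin, luteolin
    ("Quercetin", "C15H10O7"),
    ("Catechin", "C15H14O6"),     # isomer: epicatechin
    ("Apigenin", "C15H10O5"),
    ("Taxifolin", "C15H12O7"),
    ("Naringenin", "C15H12O5"),
    ("Myricetin", "C15H10O8"),
)


def build_fragment_db(
    aglycones: Iterable[Tuple[str, str]] = PAPER_AGLYCONES,
) -> List[FragmentRecord]:
    """Build the in-silico MS2 aglycone-fragment database.

    For every ``(name, formula)`` both O-cleavage fragments and all mono- and
    di-C-glycoside residue fragments are generated (7 records per aglycone),
    ordered deterministically by (aglycone, m/z).
    """
    entries = list(aglycones)
    if not entries:
        raise ValueError("aglycone list must not be empty")
    records: List[FragmentRecord] = []
    for name, formula in entries:
        try:
            m = formula_mass(formula)
        except ValueError as exc:
            raise ValueError(f"aglycone {name!r}: {exc}") from exc
        records.extend(o_glycoside_fragments(name, m))
        for n in (1, 2):
            records.extend(c_glycoside_fragments(name, m, n))
    records.sort(key=lambda r: (r.aglycone, r.mz))
    return records


# ---------------------------------------------------------------------------
# Neutral losses and the sugar dictionary
# ---------------------------------------------------------------------------


def neutral_loss(precursor_mz: float, fragment_mz: float) -> float:
    """Neutral loss between a precursor and its fragment (Da)."""
    if fragment_mz >= precursor_mz:
        raise ValueError(
            f"fragment m/z ({fragment_mz}) must be below precursor m/z ({precursor_mz})"
        )
    return precursor_mz - fragment_mz


@dataclass(frozen=True)
class SugarLossDef:
    """A glycosyl neutral-loss dictionary entry.

    ``mass`` is the loss from heterolytic cleavage; for homolytic (radical)
    fragments the observed loss is ``mass + 1.007825`` because the departing
    glycosyl carries the extra hydrogen atom.
    """

    name: str
    mass: float
    composition: str = ""
    bond: str = "O"  # O | C
    acylated: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"sugar loss {self.name!r}: mass must be positive")
        if self.bond not in ("O", "C"):
            raise ValueError(f"sugar loss {self.name!r}: bond must be 'O' or 'C'")
        if self.composition:
            ref = formula_mass(self.composition)
            if abs(ref - self.mass) > 1e-4:
                raise ValueError(
                    f"sugar loss {self.name!r}: mass {self.mass} does not match "
                    f"composition {self.composition} ({ref:.4f})"
                )


_HEXOSE = formula_mass("C6H10O5")          # 162.0528
_PENTOSE = formula_mass("C5H8O4")          # 132.0423
_DEOXYHEXOSE = formula_mass("C6H10O4")     # 146.0579
_COUMAROYL = formula_mass("C9H6O2")        # 146.0368 acyl increment

# Partial (cross-ring) losses per C-bound sugar: hexosyl loses 120 or 90 Da,
# pentosyl loses 90 or 60 Da, the complement staying on the fragment.
C_PARTIAL_LOSSES: Dict[str, float] = {
    "C-hexoside (-120)": formula_mass("C4H8O4"),
    "C-hexoside (-90)": formula_mass("C3H6O3"),
    "C-pentoside (-90)": formula_mass("C3H6O3"),
    "C-pentoside (-60)": formula_mass("C2H4O2"),
}


def _default_sugar_losses() -> Tuple[SugarLossDef, ...]:
    o_entries = [
        SugarLossDef("O-hexoside", _HEXOSE, "C6H10O5"),
        SugarLossDef("O-pentoside", _PENTOSE, "C5H8O4"),
        SugarLossDef("O-deoxyhexoside", _DEOXYHEXOSE, "C6H10O4"),
        SugarLossDef("O-deoxyhexosyl-pentoside", _DEOXYHEXOSE + _PENTOSE, "C11H18O8"),
        SugarLossDef(
            "O-coumaroyl-deoxyhexoside",
            _DEOXYHEXOSE + _COUMAROYL,
            "C15H16O6",
            acylated=True,
        ),
        SugarLossDef(
            "O-di-coumaroyl-deoxyhexoside",
            _DEOXYHEXOSE + 2 * _COUMAROYL,
            "C24H22O8",
            acylated=True,
        ),
    ]
    # Mono-C losses (one partial loss) and di-C losses (sums of two).
    c_entries = [
        SugarLossDef("C-hexoside", C_PARTIAL_LOSSES["C-hexoside (-120)"], "C4H8O4", bond="C"),
        SugarLossDef(
            "C-hexoside or C-pentoside",
            C_PARTIAL_LOSSES["C-hexoside (-90)"],
            "C3H6O3",
            bond="C",
        ),
        SugarLossDef("C-pentoside", C_PARTIAL_LOSSES["C-pentoside (-60)"], "C2H4O2", bond="C"),
        # named explicitly: 90 + 120 Da, diagnostic of schaftoside-type ions
        SugarLossDef(
            "di-C-hexoside or C-hexoside-C-pentoside",
            C_PARTIAL_LOSSES["C-hexoside (-90)"] + C_PARTIAL_LOSSES["C-hexoside (-120)"],
            "C7H14O7",
            bond="C",
        ),
        SugarLossDef(
            "di-C-hexoside",
            2 * C_PARTIAL_LOSSES["C-hexoside (-120)"],
            "C8H16O8",
            bond="C",
        ),
        SugarLossDef(
            "di-C-pentoside",
            C_PARTIAL_LOSSES["C-pentoside (-90)"] + C_PARTIAL_LOSSES["C-pentoside (-60)"],
            "C5H10O5",
            bond="C",
        ),
        SugarLossDef(
            "di-C-pentoside or C-hexoside-C-pentoside (-60-120)",
            C_PARTIAL_LOSSES["C-pentoside (-60)"] + C_PARTIAL_LOSSES["C-hexoside (-120)"],
            "C6H12O6",
            bond="C",
        ),
    ]
    return tuple(o_entries + c_entries)


DEFAULT_SUGAR_LOSSES: Tuple[SugarLossDef, ...] = _default_sugar_losses()


def match_sugar(
    loss: float,
    radical: bool = False,
    tolerance: float = 0.01,
    dictionary: Sequence[SugarLossDef] = DEFAULT_SUGAR_LOSSES,
) -> List[SugarLossDef]:
    """Sugar candidates whose expected neutral loss matches ``loss``.

    When ``radical`` is set the fragment is a homolytic radical aglycone, so
    each O-entry's expected loss is shifted up by one hydrogen atom.
    C-entries are never radical-corrected (C-glycosides do not undergo the
    homolytic pathway at the glycosidic bond).  Candidates are sorted by
    |observed - expected|.
    """
    if loss <= 0:
        raise ValueError("neutral loss must be positive")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    hits: List[Tuple[float, SugarLossDef]] = []
    for entry in dictionary:
        if radical and entry.bond != "O":
            continue
        expected = entry.mass + (H_ATOM_MASS if radical else 0.0)
        dev = abs(loss - expected)
        if dev <= tolerance:
            hits.append((dev, entry))
    hits.sort(key=lambda t: (t[0], t[1].name))
    return [entry for _, entry in hits]
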