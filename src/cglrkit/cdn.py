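"""Cyclic dinucleotide (CDN) enumeration, naming, formulas, masses, adducts.

A CDN is two nucleoside monophosphates closed into a ring by two
phosphodiester bonds. Each nucleotide contributes either its 2' or its 3'
ribose hydroxyl as the donor of its outgoing bond, so a heterodimer base
pair has 4 linkage isomers and a homodimer has 3 (2'2', 3'3', and the
mixed 2'3' which equals 3'2' under the ring's rotational symmetry). Over
the four bases {A, C, G, U} that gives 36 distinct molecules with 10
distinct molecular formulas.

Naming follows the community convention: "2'3'-cGAMP" means
c[G(2',5')pA(3',5')p] — the first linkage digit is the ribose donor of the
first-named base. Base precedence in display names is G < U < C < A (so
guanine leads in cGAMP and adenine always trails, matching 2'3'-cUA for
the uridine-adenine hybrids).

Formulas are free-acid: NMP(base1) + NMP(base2) - 2 H2O, independent of
linkage (isomers). Masses use atomic constants pinned in
``data/atomic_masses.yaml``; ESI adduct m/z follows ion arithmetic
([M-H]- = M - m(H+), etc.), with nominal m/z rounded half away from zero.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import product
from typing import Iterable, Mapping

import yaml

BASES = ("A", "C", "G", "U")
DONORS = (2, 3)
PRIME = "′"

#: Base precedence for display names (A always named last).
_NAME_PRIORITY = {"G": 0, "U": 1, "C": 2, "A": 3}


class CdnError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Formula arithmetic
# ---------------------------------------------------------------------------

_ELEMENT_ORDER = ("C", "H", "N", "O", "P", "Na")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map over {C, H, N, O, P, ...}; counts never negative."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {k: int(v) for k, v in self.counts.items() if v}
        )
        if any(v < 0 for v in self.counts.values()):
            raise CdnError(f"negative element count in {dict(self.counts)}")

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
        return MolecularFormula(merged)  # validates non-negativity

    def __mul__(self, k: int) -> "MolecularFormula":
        return MolecularFormula({el: n * k for el, n in self.counts.items()})

    def __str__(self) -> str:
        parts = []
        for el in _ELEMENT_ORDER:
            n = self.counts.get(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(set(self.counts) - set(_ELEMENT_ORDER)):
            parts.append(el + str(self.counts[el]))
        return "".join(parts)

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        counts: dict[str, int] = {}
        for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", text):
            if el:
                counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        return cls(counts)


#: Free-acid nucleoside-5'-monophosphate formulas.
NMP_FORMULAS = {
    "A": MolecularFormula.parse("C10H14N5O7P"),
    "G": MolecularFormula.parse("C10H14N5O8P"),
    "C": MolecularFormula.parse("C9H14N3O8P"),
    "U": MolecularFormula.parse("C9H13N2O9P"),
}
WATER = MolecularFormula.parse("H2O")


# ---------------------------------------------------------------------------
# The molecules
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Nucleotide:
    """One unit of a CDN: a base and the ribose position (2' or 3') it
    donates to its outgoing phosphodiester bond."""

    base: str
    donor: int

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise CdnError(f"base must be one of {BASES}, got {self.base!r}")
        if self.donor not in DONORS:
            raise CdnError(f"donor must be 2 or 3, got {self.donor!r}")


@dataclass(frozen=True)
class CyclicDinucleotide:
    """A canonical cyclic pair of nucleotides.

    Canonical storage order is lexicographic by (base, donor) with base
    order A < C < G < U; swapping the two units denotes the same ring, so
    construction always goes through :meth:`make`.
    """

    units: tuple[Nucleotide, Nucleotide]

    @classmethod
    def make(cls, u1: Nucleotide, u2: Nucleotide) -> "CyclicDinucleotide":
        return cls(units=min((u1, u2), (u2, u1)))

    @property
    def bases(self) -> frozenset[str]:
        return frozenset(u.base for u in self.units)

    @property
    def is_homodimer(self) -> bool:
        return self.units[0].base == self.units[1].base

    def _display_units(self) -> tuple[Nucleotide, Nucleotide]:
        return tuple(
            sorted(self.units, key=lambda u: (_NAME_PRIORITY[u.base], u.donor))
        )

    @property
    def name(self) -> str:
        """Community-convention name, e.g. 2'3'-cGAMP, 3'3'-cUA, 2'2'-c-di-GMP."""
        first, second = self._display_units()
        prefix = f"{first.donor}{PRIME}{second.donor}{PRIME}-"
        if self.is_homodimer:
            return f"{prefix}c-di-{first.base}MP"
        if (first.base, second.base) == ("G", "A"):
            return f"{prefix}cGAMP"
        return f"{prefix}c{first.base}{second.base}"

    @property
    def chemical_name(self) -> str:
        """Explicit linkage nomenclature, e.g. c[U(2',5')pA(3',5')p]."""
        first, second = self._display_units()
        return (
            f"c[{first.base}({first.donor}{PRIME},5{PRIME})p"
            f"{second.base}({second.donor}{PRIME},5{PRIME})p]"
        )

    def __str__(self) -> str:
        return self.name


_NAME_RE = re.compile(
    rf"^([23])['{PRIME}]([23])['{PRIME}][-\s]?(.+)$"
)


def parse_name(text: str) -> CyclicDinucleotide:
    """Parse a display name back into its canonical molecule.

    Accepts ASCII apostrophes or prime characters, the c-di-XMP homodimer
    style, cGAMP, and compact heterodimer names with or without the MP
    suffix (cUA and cUAMP are equivalent).
    """
    m = _NAME_RE.match(text.strip())
    if not m:
        raise CdnError(f"cannot parse CDN name {text!r}")
    d1, d2 = int(m.group(1)), int(m.group(2))
    core = m.group(3)
    if not core.startswith("c"):
        raise CdnError(f"cannot parse CDN name {text!r}")
    core = core[1:]
    if core.startswith("-di-"):
        base = core[4]
        bases = (base, base)
    else:
        if core.endswith("MP") and len(core) == 4:
            core = core[:2]
        if len(core) != 2:
            raise CdnError(f"cannot parse CDN name {text!r}")
        bases = (core[0], core[1])
    return CyclicDinucleotide.make(
        Nucleotide(bases[0], d1), Nucleotide(bases[1], d2)
    )


def enumerate_candidates(
    bases: Iterable[str] = BASES,
) -> list[CyclicDinucleotide]:
    """All distinct CDNs over the given bases, sorted by name.

    Heterodimer base pairs contribute 4 linkage isomers, homodimers 3;
    all four bases give 36 candidates.
    """
    bases = sorted(set(bases))
    if not bases:
        raise CdnError("bases must be nonempty")
    seen = {
        CyclicDinucleotide.make(Nucleotide(b1, d1), Nucleotide(b2, d2))
        for b1, b2 in product(bases, repeat=2)
        for d1, d2 in product(DONORS, repeat=2)
    }
    return sorted(seen, key=lambda c: c.name)


def formula_of(cdn: CyclicDinucleotide) -> MolecularFormula:
    """Free-acid formula: NMP + NMP - 2 H2O (linkage-independent)."""
    b1, b2 = (u.base for u in cdn.units)
    return NMP_FORMULAS[b1] + NMP_FORMULAS[b2] - WATER * 2


# ---------------------------------------------------------------------------
# Masses and adducts
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _mass_constants() -> dict:
    with resources.files("cglrkit.data").joinpath("atomic_masses.yaml").open() as fh:
        return yaml.safe_load(fh)


def masses(formula: MolecularFormula) -> tuple[float, float]:
    """(average mass in g/mol, monoisotopic mass in Da) of a formula."""
    consts = _mass_constants()
    avg = mono = 0.0
    for el, n in formula.counts.items():
        try:
            avg += n * consts["average"][el]
            mono += n * consts["monoisotopic"][el]
        except KeyError:
            raise CdnError(f"unknown element {el!r}") from None
    return avg, mono


ADDUCTS = ("[M-H]-", "[M-2H+Na]-", "[M+H]+")

_ADDUCT_ALIASES = {
    "M-H": "[M-H]-",
    "(M-H)-": "[M-H]-",
    "M-2H+NA": "[M-2H+Na]-",
    "(M-2H+NA)-": "[M-2H+Na]-",
    "M+H": "[M+H]+",
    "(M+H)+": "[M+H]+",
}


def _normalize_adduct(adduct: str) -> str:
    key = adduct.replace("−", "-").strip()
    if key in ADDUCTS:
        return key
    upper = key.upper().strip("[]")
    canon = _ADDUCT_ALIASES.get(upper) or _ADDUCT_ALIASES.get(upper.rstrip("+-"))
    if canon is None:
        raise CdnError(f"unsupported adduct {adduct!r}")
    return canon


def adduct_mz(monoisotopic_mass: float, adduct: str) -> float:
    """ESI adduct m/z from a neutral monoisotopic mass (singly charged)."""
    consts = _mass_constants()
    proton = consts["particles"]["proton"]
    na_ion = consts["monoisotopic"]["Na"] - consts["particles"]["electron"]
    canon = _normalize_adduct(adduct)
    if canon == "[M-H]-":
        return monoisotopic_mass - proton
    if canon == "[M-2H+Na]-":
        return monoisotopic_mass - 2 * proton + na_ion
    return monoisotopic_mass + proton


def nominal_mz(mz: float) -> int:
    """Integer m/z as printed in ESI-MS reports (round half away from zero)."""
    return int(math.floor(abs(mz) + 0.5)) * (1 if mz >= 0 else -1)


@dataclass(frozen=True)
class MassSpec:
    average_mass: float
    monoisotopic_mass: float
    adduct_mz: Mapping[str, float]


def mass_spec(cdn: CyclicDinucleotide) -> MassSpec:
    """Average/monoisotopic masses and the standard adduct m/z table."""
    avg, mono = masses(formula_of(cdn))
    return MassSpec(
        average_mass=avg,
        monoisotopic_mass=mono,
        adduct_mz={a: adduct_mz(mono, a) for a in ADDUCTS},
    )


def match_mass(
    observed_mz: float,
    adduct: str,
    tolerance_da: float,
    candidates: Iterable[CyclicDinucleotide],
) -> list[CyclicDinucleotide]:
    """Candidates whose predicted adduct m/z is within tolerance of the
    observation. Linkage isomers share a formula, so they always co-match."""
    if tolerance_da <= 0:
        raise CdnError("tolerance must be positive")
    canon = _normalize_adduct(adduct)
    hits = []
    for cand in candidates:
        _, mono = masses(formula_of(cand))
        if abs(adduct_mz(mono, canon) - observed_mz) <= tolerance_da:
            hits.append(cand)
    return hits


def percent_yield(isolated_mol: float, starting_mol: float) -> float:
    """Synthesis yield as a percentage of the theoretical maximum."""
    if starting_mol <= 0:
        raise CdnError("starting amount must be positive")
    return 100.0 * isolated_mol / starting_mol
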