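"""Protein net charge, isoelectric point and pI-based ligand-class labels.

Nucleic-acid-sensing cGLRs (like cGAS) carry positively charged ligand
binding surfaces and show a high isoelectric point (pI > 8.5), while some
auto-active family members are strongly acidic (pI near 5), suggesting
non-nucleic-acid ligands. The pI here is the Henderson-Hasselbalch zero of
the sequence-composition net charge,

    Z(pH) = sum_{pos groups} 1 / (1 + 10^(pH - pKa))
          - sum_{neg groups} 1 / (1 + 10^(pKa - pH)),

counting side chains of D, E, C, Y (negative) and H, K, R (positive) plus
one N- and one C-terminus, solved by bisection on pH in [0, 14]. Z is
strictly decreasing in pH and depends only on residue composition, never
on order. Cysteines are treated as free thiols; disulfides and other
modifications are ignored.

The pKa constants are a named, swappable table (``data/pka_tables.yaml``;
default: EMBOSS). Computed pI shifts by up to ~0.3 pH units between common
tables, so reported values are meaningful only together with the table name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Callable

import yaml


@dataclass(frozen=True)
class PkaTable:
    """Ionizable-group model: side-chain pKa/sign plus the two termini."""

    name: str
    side_chain: dict[str, tuple[float, str]]  # residue -> (pKa, "+" or "-")
    n_terminus: float
    c_terminus: float

    def __post_init__(self) -> None:
        for res, (pka, sign) in self.side_chain.items():
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa for {res} out of (0, 14): {pka}")
            if sign not in ("+", "-"):
                raise ValueError(f"sign for {res} must be '+' or '-'")
        if not (0.0 < self.n_terminus < 14.0 and 0.0 < self.c_terminus < 14.0):
            raise ValueError("terminal pKa values must lie in (0, 14)")


@lru_cache(maxsize=None)
def _pka_config() -> dict:
    with resources.files("cglrkit.data").joinpath("pka_tables.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_pka_table(name: str | None = None) -> PkaTable:
    """Load a named pKa table from the shipped config (default table if None)."""
    cfg = _pka_config()
    name = name or cfg["default"]
    entry = cfg["tables"][name]
    side = {
        res: (float(spec["pka"]), spec["sign"])
        for res, spec in entry["side_chains"].items()
    }
    return PkaTable(
        name=f"{name} ({entry.get('version', 'unversioned')})",
        side_chain=side,
        n_terminus=float(entry["n_terminus"]),
        c_terminus=float(entry["c_terminus"]),
    )


def net_charge(sequence: str, pH: float, table: PkaTable | None = None) -> float:
    """Net charge (elementary charges) of a protein at a given pH."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    table = table or load_pka_table()
    positive = [(table.n_terminus, 1)]
    negative = [(table.c_terminus, 1)]
    for res, (pka, sign) in table.side_chain.items():
        count = sequence.count(res)
        if count:
            (positive if sign == "+" else negative).append((pka, count))
    z = sum(n / (1.0 + 10.0 ** (pH - pka)) for pka, n in positive)
    z -= sum(n / (1.0 + 10.0 ** (pka - pH)) for pka, n in negative)
    return z


def isoelectric_point(
    sequence: str, table: PkaTable | None = None, tol: float = 1e-3
) -> float:
    """pI by bisection of the net-charge sign change on pH in [0, 14].

    The termini guarantee Z(0) > 0 > Z(14), so a crossing always exists and
    the method is deterministic. ``tol`` is the bracket width (pH units) at
    which bisection stops.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    table = table or load_pka_table()
    lo, hi = 0.0, 14.0
    if net_charge(sequence, lo, table) < 0:
        return lo  # unreachable with a protonatable N-terminus; report boundary
    if net_charge(sequence, hi, table) > 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


#: pI class labels: above the basic threshold the protein resembles the
#: positively charged nucleic-acid sensors; below the acidic threshold it is
#: predicted to bind a positively charged (non-nucleic-acid) ligand.
NUCLEIC_ACID_SENSOR_LIKE = "nucleic-acid-sensor-like"
ACIDIC = "acidic"
INTERMEDIATE = "intermediate"


def classify_by_pi(
    pI: float, basic_threshold: float = 8.5, acidic_threshold: float = 7.0
) -> str:
    """Ligand-propensity class from pI (strict inequalities at thresholds)."""
    if not acidic_threshold < basic_threshold:
        raise ValueError("acidic_threshold must be below basic_threshold")
    if pI > basic_threshold:
        return NUCLEIC_ACID_SENSOR_LIKE
    if pI < acidic_threshold:
        return ACIDIC
    return INTERMEDIATE


@dataclass
class ChargeProfile:
    sequence_id: str
    pI: float
    class_label: str
    net_charge_at: Callable[[float], float] = field(repr=False)


def charge_profile(
    sequence_id: str,
    sequence: str,
    table: PkaTable | None = None,
    basic_threshold: float = 8.5,
    acidic_threshold: float = 7.0,
    tol: float = 1e-3,
) -> ChargeProfile:
    """pI, class label and a pH -> charge callable for one sequence."""
    table = table or load_pka_table()
    pi = isoelectric_point(sequence, table, tol=tol)
    return ChargeProfile(
        sequence_id=sequence_id,
        pI=pi,
        class_label=classify_by_pi(pi, basic_threshold, acidic_threshold),
        net_charge_at=lambda pH: net_charge(sequence, pH, table),
    )
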