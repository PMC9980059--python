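"""Deconvolution of cGLR products from radiolabel / CIP / nuclease P1 / MS data.

The biochemical screen identifies an unknown cyclic dinucleotide product
from four orthogonal readouts:

* **labels** — which alpha-32P NTPs label the product (= its base set);
* **CIP** — cyclic products resist phosphatase (no terminal phosphates);
* **P1 retention** — nuclease P1 cleaves only 3'-5' phosphodiester bonds,
  leaving 5'-phosphate termini that CIP then removes; a base's label
  survives P1+CIP iff its alpha-phosphate sits in a P1-protected
  (2'-5') bond;
* **mass** — ESI adduct m/z identifies the base composition.

Bond bookkeeping follows the synthesis convention fixed by the explicit
chemical nomenclature (e.g. c[U(2',5')pA(3',5')p] for 2'3'-cUA): the
alpha-phosphate of base X sits on X's 5' carbon, i.e. inside the bond
donated by X's ring partner. Hence in 2'3'-cUA the adenosine phosphate
lies in the protected 2'-5' bond (A retained after P1+CIP) and the uridine
phosphate in the cleavable 3'-5' bond (U lost).

For a mixed-linkage homodimer (2'3'-c-di-XMP) one of the two identical
labels survives digestion; the binary per-base readout is therefore
"retained", which makes the 2'2' and 2'3' homodimers of a base
indistinguishable by this assay panel — :func:`distinguishability_report`
surfaces exactly that degeneracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cdn import (
    CyclicDinucleotide,
    MolecularFormula,
    adduct_mz,
    enumerate_candidates,
    formula_of,
    masses,
    _normalize_adduct,
)

RETAINED = "retained"
LOST = "lost"

#: Default mass-match tolerances (Da): integer (nominal) observations vs
#: decimal (accurate-mass) observations.
NOMINAL_MASS_TOL = 0.5
ACCURATE_MASS_TOL = 0.02


class ObservationError(ValueError):
    """Raised for internally inconsistent screen observations."""


@dataclass(frozen=True)
class PredictedSignature:
    """The assay readout a candidate CDN would produce."""

    labels: frozenset[str]
    cip_resistant: bool
    p1_retention: Mapping[str, str]  # base -> retained | lost
    formula: MolecularFormula
    monoisotopic_mass: float


def predict_signature(cdn: CyclicDinucleotide) -> PredictedSignature:
    """Apply the bond rules to a candidate.

    The alpha-phosphate of unit *i* sits in the bond donated by the other
    unit; that bond is P1-protected iff the other unit donates its 2'
    hydroxyl. A base is "retained" if at least one of its alpha-phosphates
    survives P1+CIP.
    """
    u1, u2 = cdn.units
    # alpha-phosphate of u1 survives iff u2 donates 2', and vice versa
    survives = {0: u2.donor == 2, 1: u1.donor == 2}
    retention: dict[str, str] = {}
    for idx, unit in enumerate(cdn.units):
        if survives[idx]:
            retention[unit.base] = RETAINED
        else:
            retention.setdefault(unit.base, LOST)
    formula = formula_of(cdn)
    _, mono = masses(formula)
    return PredictedSignature(
        labels=cdn.bases,
        cip_resistant=True,  # cyclic: no terminal phosphate for CIP to remove
        p1_retention=retention,
        formula=formula,
        monoisotopic_mass=mono,
    )


@dataclass(frozen=True)
class ScreenObservation:
    """Possibly partial assay evidence; absent fields constrain nothing."""

    labels_incorporated: frozenset[str] | None = None
    cip_resistant: bool | None = None
    p1_retention: Mapping[str, str] | None = None
    observed_mz: Sequence[tuple[float, str]] | None = None
    substrate_dependency: frozenset[frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if self.p1_retention is not None and self.labels_incorporated is not None:
            stray = set(self.p1_retention) - set(self.labels_incorporated)
            if stray:
                raise ObservationError(
                    f"P1 retention reported for non-incorporated base(s) {sorted(stray)}"
                )
            bad = set(self.p1_retention.values()) - {RETAINED, LOST}
            if bad:
                raise ObservationError(f"retention states must be retained/lost, got {bad}")


def _mass_tolerance(observed: float, tolerance_da: float | None) -> float:
    if tolerance_da is not None:
        return tolerance_da
    return NOMINAL_MASS_TOL if abs(observed - round(observed)) < 1e-9 else ACCURATE_MASS_TOL


def _consistency(
    obs: ScreenObservation, sig: PredictedSignature, tolerance_da: float | None
) -> tuple[bool, int, int]:
    """(fully consistent?, fields satisfied, fields provided)."""
    checks: list[bool] = []
    if obs.labels_incorporated is not None:
        checks.append(sig.labels == obs.labels_incorporated)
    if obs.cip_resistant is not None:
        checks.append(sig.cip_resistant == obs.cip_resistant)
    if obs.p1_retention is not None:
        checks.append(
            all(
                sig.p1_retention.get(base) == state
                for base, state in obs.p1_retention.items()
            )
        )
    if obs.observed_mz:
        ok = True
        for mz, adduct in obs.observed_mz:
            tol = _mass_tolerance(mz, tolerance_da)
            pred = adduct_mz(sig.monoisotopic_mass, _normalize_adduct(adduct))
            ok = ok and abs(pred - mz) <= tol
        checks.append(ok)
    if obs.substrate_dependency is not None:
        checks.append(
            all(sig.labels <= set(subset) for subset in obs.substrate_dependency)
        )
    return all(checks), sum(checks), len(checks)


@dataclass
class InferenceResult:
    """Candidates consistent with an observation (plus a diagnostic when
    nothing is, naming the nearest miss)."""

    consistent: list[CyclicDinucleotide]
    diagnostic: str | None = None

    def __iter__(self):
        return iter(self.consistent)

    def __len__(self) -> int:
        return len(self.consistent)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.consistent]


def infer_product(
    obs: ScreenObservation,
    candidates: Sequence[CyclicDinucleotide] | None = None,
    tolerance_da: float | None = None,
) -> InferenceResult:
    """Invert an observation to the set of consistent candidate products.

    Every provided field must match the candidate's predicted signature
    (mass within ``tolerance_da``, defaulting to 0.5 Da for integer
    observations and 0.02 Da for decimal ones); unprovided fields are
    unconstrained. An empty result carries a closest-candidate diagnostic
    instead of failing silently.
    """
    if candidates is None:
        candidates = enumerate_candidates()
    if not candidates:
        raise ObservationError("candidate list must be nonempty")
    scored = []
    for cand in candidates:
        ok, satisfied, provided = _consistency(obs, predict_signature(cand), tolerance_da)
        scored.append((cand, ok, satisfied, provided))
    consistent = [cand for cand, ok, _, _ in scored if ok]
    diagnostic = None
    if not consistent:
        best = max(scored, key=lambda t: t[2])
        diagnostic = (
            "no candidate matches all observation fields; closest is "
            f"{best[0].name} satisfying {best[2]}/{best[3]} constraints"
        )
    return InferenceResult(consistent=consistent, diagnostic=diagnostic)


ASSAYS = ("labels", "cip", "p1", "mass")


def _restricted_key(sig: PredictedSignature, assays: Iterable[str]):
    key = []
    for assay in assays:
        if assay == "labels":
            key.append(tuple(sorted(sig.labels)))
        elif assay == "cip":
            key.append(sig.cip_resistant)
        elif assay == "p1":
            key.append(tuple(sorted(sig.p1_retention.items())))
        elif assay == "mass":
            key.append(str(sig.formula))
        else:
            raise ValueError(f"unknown assay {assay!r}; choose from {ASSAYS}")
    return tuple(key)


def distinguishability_report(
    candidates: Sequence[CyclicDinucleotide] | None = None,
    assays: Sequence[str] = ASSAYS,
) -> list[list[CyclicDinucleotide]]:
    """Groups of candidates the chosen assay panel cannot tell apart.

    Partitions candidates by their predicted signature restricted to
    ``assays`` and returns every class of size > 1 (sorted, deterministic).
    With the full panel the only degenerate classes are the four
    {2'2', 2'3'} homodimer pairs.
    """
    if not assays:
        raise ValueError("assays must be nonempty")
    if candidates is None:
        candidates = enumerate_candidates()
    groups: dict[tuple, list[CyclicDinucleotide]] = {}
    for cand in candidates:
        groups.setdefault(_restricted_key(predict_signature(cand), assays), []).append(cand)
    unresolved = [sorted(g, key=lambda c: c.name) for g in groups.values() if len(g) > 1]
    unresolved.sort(key=lambda g: g[0].name)
    return unresolved


def signature_partition(
    candidates: Sequence[CyclicDinucleotide] | None = None,
    assays: Sequence[str] = ASSAYS,
) -> list[list[CyclicDinucleotide]]:
    """Full partition (singletons included) under the restricted signature."""
    if candidates is None:
        candidates = enumerate_candidates()
    groups: dict[tuple, list[CyclicDinucleotide]] = {}
    for cand in candidates:
        groups.setdefault(_restricted_key(predict_signature(cand), assays), []).append(cand)
    parts = [sorted(g, key=lambda c: c.name) for g in groups.values()]
    parts.sort(key=lambda g: g[0].name)
    return parts


def full_observation(cdn: CyclicDinucleotide, adduct: str = "[M-H]-") -> ScreenObservation:
    """The complete, noise-free observation a candidate would generate."""
    sig = predict_signature(cdn)
    return ScreenObservation(
        labels_incorporated=sig.labels,
        cip_resistant=sig.cip_resistant,
        p1_retention=dict(sig.p1_retention),
        observed_mz=[(adduct_mz(sig.monoisotopic_mass, adduct), adduct)],
    )
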