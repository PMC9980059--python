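"""Seeded synthetic data with known ground truth for every pipeline stage.

Each generator is a pure function of its arguments plus an integer seed
(numpy ``default_rng``): the same call yields byte-identical output. The
generators emulate the statistical shape each stage consumes —

* proteomes with one active-site motif instance planted at a recorded
  offset in random background, plus composition-matched decoys that are
  rejection-resampled until provably pattern-free;
* screen observations equal to a chosen product's predicted signature,
  optionally restricted to a field subset and mass-jittered;
* binding curves from a known Kd with additive Gaussian noise truncated
  to [0, 1];
* census tables drawn from known copy-number and architecture mixtures,
  with the exact counts recorded as truth.

What these emulate (and what they do not — compositional bias, homologous
families, correlated assay noise) is documented in the methods note;
passing on synthetic data demonstrates correctness of the inference, not
performance on real proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import BindingCurve
from .cdn import CyclicDinucleotide
from .motif import STANDARD_AA, MotifPattern, scan
from .screen import ScreenObservation, full_observation

_AA = sorted(STANDARD_AA)


# ---------------------------------------------------------------------------
# Planted-motif proteomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSequence:
    sequence_id: str
    sequence: str
    label: str  # "positive" | "negative"
    anchor_spans: tuple[tuple[int, int], ...] | None  # None for decoys


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _realize_pattern(
    rng: np.random.Generator, pattern: MotifPattern
) -> tuple[str, tuple[tuple[int, int], ...]]:
    """One concrete instance of a pattern plus its anchor offsets."""
    chunks: list[str] = []
    anchors: list[tuple[int, int]] = []
    pos = 0
    for el in pattern.elements:
        if el.kind == "gap":
            length = int(rng.integers(el.min_len, el.max_len + 1))
            chunks.append(_random_sequence(rng, length))
            pos += length
        else:
            if el.kind == "fixed":
                chunks.append(el.residue)
            else:
                chunks.append(str(rng.choice(sorted(el.members))))
            anchors.append((pos, pos + 1))
            pos += 1
    return "".join(chunks), tuple(anchors)


def gen_motif_proteome(
    n_pos: int,
    n_neg: int,
    pattern: MotifPattern,
    length_range: tuple[int, int] = (250, 450),
    seed: int = 0,
    max_resample: int = 1000,
) -> list[PlantedSequence]:
    """Labeled proteome: motif-planted positives and pattern-free decoys.

    Positives embed one pattern realization (gap lengths uniform within
    bounds) at a random offset; the recorded anchor spans are the ground
    truth for scanner sensitivity. Negatives are composition-matched
    shuffles of the positives (or plain random background when n_pos = 0),
    reshuffled until :func:`~cglrkit.motif.scan` finds nothing, so decoy
    specificity is guaranteed by construction.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be non-negative")
    lo, hi = length_range
    if pattern.min_length > hi:
        raise ValueError(
            f"pattern needs >= {pattern.min_length} residues; length_range max is {hi}"
        )
    rng = np.random.default_rng(seed)
    out: list[PlantedSequence] = []

    positives: list[str] = []
    for i in range(n_pos):
        motif, anchors = _realize_pattern(rng, pattern)
        total = int(rng.integers(max(lo, len(motif)), max(hi, len(motif)) + 1))
        offset = int(rng.integers(0, total - len(motif) + 1))
        background = _random_sequence(rng, total - len(motif))
        seq = background[:offset] + motif + background[offset:]
        spans = tuple((s + offset, e + offset) for s, e in anchors)
        positives.append(seq)
        out.append(PlantedSequence(f"pos_{i:04d}", seq, "positive", spans))

    for i in range(n_neg):
        source = (
            positives[i % n_pos]
            if positives
            else _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        )
        chars = np.array(list(source))
        for _ in range(max_resample):
            rng.shuffle(chars)
            candidate = "".join(chars)
            if not scan(candidate, pattern):
                break
        else:  # pragma: no cover - astronomically unlikely for real motifs
            raise RuntimeError("could not sample a pattern-free decoy")
        out.append(PlantedSequence(f"neg_{i:04d}", candidate, "negative", None))
    return out


def proteome_truth_frame(proteome: list[PlantedSequence]) -> pd.DataFrame:
    """Truth table (id, label, planted spans) for a generated proteome."""
    return pd.DataFrame(
        {
            "sequence_id": p.sequence_id,
            "label": p.label,
            "anchor_spans": ";".join(f"{s}-{e}" for s, e in p.anchor_spans)
            if p.anchor_spans
            else "",
        }
        for p in proteome
    )


# ---------------------------------------------------------------------------
# Screen observations
# ---------------------------------------------------------------------------

def gen_screen_observation(
    cdn: CyclicDinucleotide,
    fields_included: frozenset[str] | set[str] = frozenset({"labels", "cip", "p1", "mass"}),
    seed: int = 0,
    mass_jitter_da: float = 0.0,
    adduct: str = "[M-H]-",
) -> ScreenObservation:
    """The observation a product would generate, restricted to a field subset.

    "labels" is always reported (it anchors the observation); "cip", "p1"
    and "mass" are included on request. ``mass_jitter_da`` adds Gaussian
    noise to the observed m/z, emulating instrument error.
    """
    rng = np.random.default_rng(seed)
    full = full_observation(cdn, adduct=adduct)
    observed_mz = None
    if "mass" in fields_included:
        observed_mz = [
            (mz + float(rng.normal(0.0, mass_jitter_da)) if mass_jitter_da else mz, a)
            for mz, a in full.observed_mz
        ]
    return ScreenObservation(
        labels_incorporated=full.labels_incorporated,
        cip_resistant=full.cip_resistant if "cip" in fields_included else None,
        p1_retention=dict(full.p1_retention) if "p1" in fields_included else None,
        observed_mz=observed_mz,
    )


# ---------------------------------------------------------------------------
# Binding curves
# ---------------------------------------------------------------------------

#: Default titration mirroring the EMSA protein range (0.5 nM - 50 uM),
#: 8 half-log-spaced points.
DEFAULT_CONCENTRATIONS_M = tuple(np.geomspace(5e-10, 5e-5, 8))


def gen_binding_curve(
    Kd: float,
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS_M,
    noise_sd: float = 0.0,
    seed: int = 0,
    ligand_id: str = "synthetic-cdn",
    replicate_id: str = "0",
) -> BindingCurve:
    """Fraction-bound titration from a known Kd with Gaussian noise.

    Values falling outside [0, 1] are truncated and the curve's ``clipped``
    flag records the event.
    """
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations, dtype=float)
    f = c / (c + Kd)
    if noise_sd:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return BindingCurve(
        ligand_id=ligand_id,
        protein_concentrations=c,
        fraction_bound=f,  # BindingCurve clips and flags
        replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# Census tables
# ---------------------------------------------------------------------------

def gen_census_table(
    n_species: int,
    copy_number_distribution: dict[tuple[int, int], float],
    architecture_mixture: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Annotation table drawn from known distributions, plus exact truth.

    ``copy_number_distribution`` maps (n_cGLR, n_STING) pairs to
    probabilities; ``architecture_mixture`` maps "+"-joined architecture
    labels to probabilities for cGLR records (default: all single-domain).
    The truth dict records the sampled per-species counts and the realized
    architecture percentages.
    """
    if abs(sum(copy_number_distribution.values()) - 1.0) > 1e-9:
        raise ValueError("copy_number_distribution must be normalized")
    architecture_mixture = architecture_mixture or {"cGLR": 1.0}
    if abs(sum(architecture_mixture.values()) - 1.0) > 1e-9:
        raise ValueError("architecture_mixture must be normalized")
    rng = np.random.default_rng(seed)
    pairs = sorted(copy_number_distribution)
    pair_p = np.array([copy_number_distribution[p] for p in pairs])
    archs = sorted(architecture_mixture)
    arch_p = np.array([architecture_mixture[a] for a in archs])

    rows = []
    truth_counts: dict[str, tuple[int, int]] = {}
    for i in range(n_species):
        species = f"species_{i:03d}"
        n_cglr, n_sting = pairs[int(rng.choice(len(pairs), p=pair_p))]
        truth_counts[species] = (n_cglr, n_sting)
        for j in range(n_cglr):
            arch = archs[int(rng.choice(len(archs), p=arch_p))]
            rows.append((f"{species}_cGLR_{j}", species, "synthetic", "cGLR", arch))
        for j in range(n_sting):
            rows.append((f"{species}_STING_{j}", species, "synthetic", "STING", "TM+CBD"))
    table = pd.DataFrame(
        rows, columns=["protein_id", "species", "phylum", "family", "architecture"]
    )
    cglr = table[table["family"] == "cGLR"]
    arch_pct = (
        (100.0 * cglr["architecture"].value_counts(normalize=True)).to_dict()
        if not cglr.empty
        else {}
    )
    truth = {
        "species_roster": sorted(truth_counts),
        "copy_numbers": truth_counts,
        "architecture_percentages": arch_pct,
    }
    return table, truth
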