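"""Gene-family census summaries: copy numbers per species and domain
architecture prevalence.

Two family-level views of a curated cGLR/STING annotation table:

* :func:`copy_number_table` — per-species (n_cGLR, n_STING) counts over a
  species roster (zero rows kept for roster species with no records) plus
  the frequency matrix over copy-number pairs that backs the bubble-plot
  view; the matrix total always equals the roster size.
* :func:`architecture_prevalence` — percentage share of each domain
  architecture within a family, with every architecture below the
  threshold (default 0.5%) folded into "Other".

Architecture strings are consumed as labels (e.g. "ANK+cGLR"); domain
detection itself happens upstream. Mab21-like proteins can be excluded
from counting via ``exclude_families``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

FAMILIES = ("cGLR", "STING")
ARCH_SEP = "+"


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    species: str
    phylum: str
    family: str
    architecture: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.species or not self.family:
            raise ValueError("species and family must be nonempty")
        if not self.architecture:
            raise ValueError("architecture must be nonempty")


def records_to_frame(records: Iterable[ProteinRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": r.protein_id,
            "species": r.species,
            "phylum": r.phylum,
            "family": r.family,
            "architecture": ARCH_SEP.join(r.architecture),
        }
        for r in records
    )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def copy_number_table(
    records,
    species_roster: Sequence[str],
    exclude_families: Iterable[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species copy numbers and the (n_cGLR, n_STING) frequency matrix.

    ``records`` is a DataFrame (protein_id, species, family, ...) or an
    iterable of :class:`ProteinRecord`. Every roster species appears in the
    output even with zero records; a record whose species is missing from
    the roster is an error. Families listed in ``exclude_families`` (e.g.
    "Mab21-like") are dropped before counting.
    """
    df = _as_frame(records)
    roster = list(dict.fromkeys(species_roster))
    if df.empty:
        counts = pd.DataFrame(0, index=pd.Index(roster, name="species"),
                              columns=["n_cGLR", "n_STING"])
    else:
        df = df[~df["family"].isin(set(exclude_families))]
        unknown = set(df["species"]) - set(roster)
        if unknown:
            raise ValueError(f"records for species outside roster: {sorted(unknown)}")
        pivot = (
            df[df["family"].isin(FAMILIES)]
            .groupby(["species", "family"])
            .size()
            .unstack(fill_value=0)
        )
        counts = pd.DataFrame(index=pd.Index(roster, name="species"))
        for fam in FAMILIES:
            col = pivot[fam] if fam in pivot else pd.Series(0, index=pivot.index)
            counts[f"n_{fam}"] = col.reindex(roster).fillna(0).astype(int)
    freq = (
        counts.groupby(["n_cGLR", "n_STING"])
        .size()
        .rename("n_species")
        .reset_index()
    )
    assert int(freq["n_species"].sum()) == len(roster)
    return counts, freq


OTHER = "Other"


def architecture_prevalence(
    records,
    other_threshold: float = 0.005,
    family: str = "cGLR",
) -> dict[str, float]:
    """Percentage share of each domain architecture within one family.

    Shares strictly below ``other_threshold`` (a fraction; default 0.5%)
    are folded into "Other". Percentages sum to 100 up to float rounding.
    """
    if not 0.0 < other_threshold < 1.0:
        raise ValueError("other_threshold must be in (0, 1)")
    df = _as_frame(records)
    sub = df[df["family"] == family]
    if sub.empty:
        raise ValueError(f"no records for family {family!r}")
    shares = sub["architecture"].value_counts(normalize=True)
    out: dict[str, float] = {}
    other = 0.0
    for arch, share in shares.items():
        if share < other_threshold:
            other += share
        else:
            out[arch] = 100.0 * share
    if other > 0:
        out[OTHER] = 100.0 * other
    return out
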