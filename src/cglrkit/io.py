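"""File formats: FASTA (Biopython), flags/annotation TSV (pandas), JSON
observations, and the report writers used by the CLI.

FASTA description lines are parsed as ``id species=... phylum=...``; both
key-value tokens are optional. All tabular output is plain TSV with a
header row; coordinates are 0-based, half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import Cluster, CurationRecord, MotifMatch, REQUIRED_FLAGS
from .screen import ScreenObservation
from .synth import PlantedSequence


@dataclass(frozen=True)
class FastaRecord:
    sequence_id: str
    sequence: str
    species: str = ""
    phylum: str = ""


def read_fasta(path) -> list[FastaRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(
            token.split("=", 1)
            for token in rec.description.split()[1:]
            if "=" in token
        )
        records.append(
            FastaRecord(
                sequence_id=rec.id,
                sequence=str(rec.seq).upper(),
                species=meta.get("species", "").replace("_", " "),
                phylum=meta.get("phylum", ""),
            )
        )
    return records


def write_fasta(records: Iterable, path) -> None:
    """Write (id, sequence)-like records (FastaRecord or PlantedSequence)."""
    seqs = []
    for rec in records:
        if isinstance(rec, PlantedSequence):
            seqs.append(SeqRecord(Seq(rec.sequence), id=rec.sequence_id, description=""))
        else:
            desc = []
            if getattr(rec, "species", ""):
                desc.append(f"species={rec.species.replace(' ', '_')}")
            if getattr(rec, "phylum", ""):
                desc.append(f"phylum={rec.phylum}")
            seqs.append(
                SeqRecord(
                    Seq(rec.sequence), id=rec.sequence_id, description=" ".join(desc)
                )
            )
    SeqIO.write(seqs, str(path), "fasta")


def read_flags_tsv(path) -> dict[str, dict[str, bool]]:
    """Per-sequence external curation flags keyed by sequence_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, dict[str, bool]] = {}
    for _, row in df.iterrows():
        out[row["sequence_id"]] = {
            flag: str(row[flag]).strip().lower() in ("1", "true", "yes")
            for flag in REQUIRED_FLAGS
            if flag in df.columns
        }
    return out


def matches_frame(matches: Sequence[MotifMatch], pattern_name: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence_id": m.sequence_id,
            "pattern_name": pattern_name,
            "full_start": m.full_span[0],
            "full_end": m.full_span[1],
            "anchor_spans": ";".join(f"{s}-{e}" for s, e in m.anchor_spans),
        }
        for m in matches
    )


def curation_frame(records: Sequence[CurationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence_id": r.sequence_id,
            "decision": r.decision,
            "reasons": "; ".join(r.reasons),
        }
        for r in records
    )


def clusters_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": c.cluster_id,
            "representative_id": c.representative_id,
            "member_id": member,
        }
        for c in clusters
        for member in c.member_ids
    )


def read_observation(path) -> ScreenObservation:
    """Screen observation from JSON (fields mirror ScreenObservation)."""
    data = json.loads(Path(path).read_text())
    mz = data.get("observed_mz")
    return ScreenObservation(
        labels_incorporated=(
            frozenset(data["labels_incorporated"])
            if data.get("labels_incorporated") is not None
            else None
        ),
        cip_resistant=data.get("cip_resistant"),
        p1_retention=data.get("p1_retention"),
        observed_mz=[(float(m), str(a)) for m, a in mz] if mz else None,
        substrate_dependency=(
            frozenset(frozenset(s) for s in data["substrate_dependency"])
            if data.get("substrate_dependency")
            else None
        ),
    )


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
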