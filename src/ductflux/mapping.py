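"""Transcript evidence records bridging expression data and reactions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import pandas as pd

from .core import Compartment, DbSource

__all__ = [
    "HitRecord",
    "GeneReactionMap",
    "LocalizationRecord",
    "read_hits_tsv",
    "read_localization_tsv",
    "write_gene_reaction_map_tsv",
    "read_gene_reaction_map_tsv",
]

# Priority of reference databases when one transcript hits several:
# the curated Arabidopsis core model outranks AraCyc, which outranks MetaCyc.
DB_PRIORITY = {
    DbSource.ARABIDOPSIS_CORE: 0,
    DbSource.ARACYC: 1,
    DbSource.METACYC: 2,
}


@dataclass(frozen=True)
class HitRecord:
    """One sequence-similarity hit of a transcript against a reference database."""

    transcript_id: str
    target_id: str
    db_source: DbSource
    global_identity: float  # percent, 0-100

    def __post_init__(self) -> None:
        if not isinstance(self.db_source, DbSource):
            object.__setattr__(self, "db_source", DbSource(self.db_source))
        if not 0.0 <= self.global_identity <= 100.0:
            raise ValueError(
                f"global_identity {self.global_identity} outside [0, 100] "
                f"for {self.transcript_id}"
            )


@dataclass
class GeneReactionMap:
    """Reaction id → supporting transcript evidence.

    Each entry is a set of ``(transcript_id, db_source, global_identity)``
    tuples.  Gene sets are flat (no Boolean complex logic), matching a
    transcript-association procedure based on best sequence identity.
    """

    entries: Dict[str, Set[Tuple[str, DbSource, float]]] = field(default_factory=dict)

    def reactions(self) -> List[str]:
        return sorted(self.entries)

    def transcripts_for(self, reaction_id: str) -> Set[str]:
        return {t for t, _, _ in self.entries.get(reaction_id, set())}

    def add(
        self, reaction_id: str, transcript_id: str, db_source: DbSource, identity: float
    ) -> None:
        self.entries.setdefault(reaction_id, set()).add(
            (transcript_id, db_source, identity)
        )

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.entries and len(self.entries[reaction_id]) > 0


@dataclass(frozen=True)
class LocalizationRecord:
    """Predicted subcellular localization of one transcript's product."""

    transcript_id: str
    compartment: Compartment
    score: float  # confidence in [0, 1]

    def __post_init__(self) -> None:
        if not isinstance(self.compartment, Compartment):
            object.__setattr__(self, "compartment", Compartment(self.compartment))
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


def read_hits_tsv(path: str) -> List[HitRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        HitRecord(
            transcript_id=str(row["transcript_id"]),
            target_id=str(row["target_id"]),
            db_source=DbSource(row["db_source"]),
            global_identity=float(row["global_identity"]),
        )
        for _, row in df.iterrows()
    ]


def read_localization_tsv(path: str) -> List[LocalizationRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        LocalizationRecord(
            transcript_id=str(row["transcript_id"]),
            compartment=Compartment(row["compartment"]),
            score=float(row["score"]),
        )
        for _, row in df.iterrows()
    ]


def write_gene_reaction_map_tsv(grmap: GeneReactionMap, path: str) -> None:
    rows = []
    for rid in grmap.reactions():
        for transcript, db, ident in sorted(grmap.entries[rid]):
            rows.append(
                {
                    "reaction_id": rid,
                    "transcript_id": transcript,
                    "db_source": db.value,
                    "global_identity": repr(ident),
                }
            )
    pd.DataFrame(
        rows, columns=["reaction_id", "transcript_id", "db_source", "global_identity"]
    ).to_csv(path, sep="\t", index=False)


def read_gene_reaction_map_tsv(path: str) -> GeneReactionMap:
    df = pd.read_csv(path, sep="\t")
    grmap = GeneReactionMap()
    for _, row in df.iterrows():
        grmap.add(
            str(row["reaction_id"]),
            str(row["transcript_id"]),
            DbSource(row["db_source"]),
            float(row["global_identity"]),
        )
    return grmap
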