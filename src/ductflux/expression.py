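"""Transcript abundance profiles (TPM) for one cell-type sample."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator

import pandas as pd

__all__ = ["ExpressionProfile", "read_expression_tsv", "write_expression_tsv"]

TPM_TOTAL = 1e6


@dataclass
class ExpressionProfile:
    """Transcript id → TPM for a single sample.

    TPM is length- and depth-normalized, so a well-formed profile sums to
    one million; :meth:`normalized` rescales to that total.
    """

    sample_id: str
    tpm: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, transcript_id: str) -> float:
        return self.tpm[transcript_id]

    def get(self, transcript_id: str, default: float = 0.0) -> float:
        return self.tpm.get(transcript_id, default)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.tpm

    def __iter__(self) -> Iterator[str]:
        return iter(self.tpm)

    def __len__(self) -> int:
        return len(self.tpm)

    def total(self) -> float:
        return float(sum(self.tpm.values()))

    def normalized(self) -> "ExpressionProfile":
        tot = self.total()
        if tot <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        scale = TPM_TOTAL / tot
        return ExpressionProfile(
            self.sample_id, {t: v * scale for t, v in self.tpm.items()}
        )


def write_expression_tsv(profile: ExpressionProfile, path: str) -> None:
    df = pd.DataFrame(
        {"transcript_id": sorted(profile.tpm), "tpm": [profile.tpm[t] for t in sorted(profile.tpm)]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str, sample_id: str = "") -> ExpressionProfile:
    df = pd.read_csv(path, sep="\t")
    return ExpressionProfile(
        sample_id or path, dict(zip(df["transcript_id"].astype(str), df["tpm"].astype(float)))
    )
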