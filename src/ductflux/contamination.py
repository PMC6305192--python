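"""Marker-gene-based cross-contamination estimation for paired
laser-capture-microdissection transcriptomes.

When two neighboring cell types are cut from the same tissue sections,
each sample can carry transcripts of the other.  Given a marker gene
assumed absent from the pure target cell type but expressed in the source
cell type, the contaminating fraction is bounded from above by the ratio

    fraction = TPM(marker in target) / TPM(marker in source)

i.e. by attributing the target sample's entire marker signal to admixed
source cells.  A Rubisco small-subunit transcript serves this role for
photosynthetic contamination of a non-green secretory cell type, and a
diterpene synthase for the reverse direction.  Fractions above 1 mean the
marker assumption is violated and are flagged rather than clamped.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Dict, Iterable, List

from .expression import ExpressionProfile

__all__ = ["ContaminationEstimate", "estimate_contamination", "estimate_contamination_multi"]


class UninformativeMarkerError(ValueError):
    pass


@dataclass(frozen=True)
class ContaminationEstimate:
    """Upper-bound estimate of source-cell admixture in a target sample."""

    target_cell_type: str
    source_cell_type: str
    marker_id: str
    target_tpm: float
    source_tpm: float
    fraction: float
    flagged: bool

    @property
    def percent(self) -> float:
        """Fraction rendered as a percentage rounded to one decimal."""
        return round(100.0 * self.fraction, 1)

    def to_dict(self) -> Dict[str, object]:
        return {
            "target_cell_type": self.target_cell_type,
            "source_cell_type": self.source_cell_type,
            "marker_id": self.marker_id,
            "target_tpm": self.target_tpm,
            "source_tpm": self.source_tpm,
            "fraction": self.fraction,
            "percent": self.percent,
            "flagged": self.flagged,
        }


def estimate_contamination(
    target: ExpressionProfile,
    source: ExpressionProfile,
    marker_id: str,
    target_cell_type: str = "",
    source_cell_type: str = "",
) -> ContaminationEstimate:
    """Single-marker ratio estimate of source admixture in the target.

    The marker must be expressed in the source sample (TPM > 0); otherwise
    the ratio is undefined and an ``UninformativeMarkerError`` is raised.
    A marker absent from the target gives fraction 0.  Fractions above 1
    are reported with ``flagged=True``.
    """
    if marker_id not in source or source[marker_id] <= 0.0:
        raise UninformativeMarkerError(
            f"uninformative marker {marker_id!r}: absent or zero in source sample"
        )
    target_tpm = float(target.get(marker_id, 0.0))
    source_tpm = float(source[marker_id])
    fraction = target_tpm / source_tpm
    return ContaminationEstimate(
        target_cell_type=target_cell_type or target.sample_id,
        source_cell_type=source_cell_type or source.sample_id,
        marker_id=marker_id,
        target_tpm=target_tpm,
        source_tpm=source_tpm,
        fraction=fraction,
        flagged=fraction > 1.0,
    )


def estimate_contamination_multi(
    target: ExpressionProfile,
    source: ExpressionProfile,
    marker_ids: Iterable[str],
    target_cell_type: str = "",
    source_cell_type: str = "",
) -> ContaminationEstimate:
    """Median of single-marker ratios over several markers.

    Off the default path; useful when no single marker is trusted.  The
    reported record carries the marker whose ratio is the median (lower of
    the two middle values for even counts).
    """
    estimates: List[ContaminationEstimate] = [
        estimate_contamination(target, source, m, target_cell_type, source_cell_type)
        for m in marker_ids
    ]
    if not estimates:
        raise UninformativeMarkerError("no markers given")
    median_fraction = statistics.median_low([e.fraction for e in estimates])
    chosen = next(e for e in estimates if e.fraction == median_fraction)
    return chosen
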