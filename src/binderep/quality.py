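"""Quality scoring and the purity/length/completeness gates.

Conventions (documented, not derivable from the score alone):
- purity gate is strict: a bin survives iff purity > threshold, i.e.
  contamination < 100 − threshold;
- length gate is inclusive (total_length >= min_length);
- the completeness gate is applied to the FINAL output set, inclusive;
- the high-quality test is strict on both sides (completeness > 90 and
  contamination < 5).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

from .errors import InputError
from .model_io import QualityRecord, SequenceBin

logger = logging.getLogger(__name__)

HIGH_QUALITY_COMPLETENESS = 90.0
HIGH_QUALITY_CONTAMINATION = 5.0


def quality_score(completeness: float, contamination: float) -> float:
    """completeness − 5 × contamination (may be negative)."""
    if not 0.0 <= completeness <= 100.0:
        raise InputError(f"completeness must be in [0, 100], got {completeness}")
    if contamination < 0.0:
        raise InputError(f"contamination must be >= 0, got {contamination}")
    return completeness - 5.0 * contamination


def require_quality(bin_id: str, qualities: Mapping[str, QualityRecord]) -> QualityRecord:
    record = qualities.get(bin_id)
    if record is None:
        raise InputError(f"bin {bin_id!r} has no quality record")
    return record


def filter_by_purity(
    bins: Iterable[SequenceBin],
    qualities: Mapping[str, QualityRecord],
    purity_threshold: float = 95.0,
) -> tuple[list[SequenceBin], list[tuple[str, str]]]:
    """Keep bins whose purity strictly exceeds the threshold.

    Returns (retained bins, rejection log of (bin_id, reason)).
    """
    if not 0.0 <= purity_threshold <= 100.0:
        raise InputError(f"purity threshold must be in [0, 100], got {purity_threshold}")
    retained: list[SequenceBin] = []
    rejected: list[tuple[str, str]] = []
    for b in bins:
        record = require_quality(b.bin_id, qualities)
        if record.purity > purity_threshold:
            retained.append(b)
        else:
            reason = (
                f"purity {record.purity:.4g} <= threshold {purity_threshold:.4g} "
                f"(contamination {record.contamination:.4g})"
            )
            rejected.append((b.bin_id, reason))
            logger.info("purity filter rejected %s: %s", b.bin_id, reason)
    return retained, rejected


def filter_by_length(bins: Iterable[SequenceBin], min_length: int = 200_000) -> list[SequenceBin]:
    """Keep bins with total length >= min_length (inclusive)."""
    if min_length < 0:
        raise InputError(f"min_length must be >= 0, got {min_length}")
    return [b for b in bins if b.total_length >= min_length]


def is_high_quality(q: QualityRecord) -> bool:
    """Strict high-quality gate: completeness > 90 and contamination < 5."""
    return q.completeness > HIGH_QUALITY_COMPLETENESS and q.contamination < HIGH_QUALITY_CONTAMINATION


def filter_by_completeness(
    bins: Iterable[SequenceBin],
    qualities: Mapping[str, QualityRecord],
    min_completeness: float = 50.0,
) -> list[SequenceBin]:
    """Final-output completeness gate, inclusive at the boundary."""
    if not 0.0 <= min_completeness <= 100.0:
        raise InputError(f"min_completeness must be in [0, 100], got {min_completeness}")
    return [b for b in bins if require_quality(b.bin_id, qualities).completeness >= min_completeness]
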