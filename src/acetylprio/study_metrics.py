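"""Small clinical-assay scores used alongside the transcriptomic screen.

Immunohistochemistry staining index (intensity 0-3 times proportion 0-4, the
usual immunoreactive-score convention; >= 6 is "high", <= 4 is "low" — no
product of these scales equals 5, so the two cutoffs are exhaustive),
xenograft tumour volume (length x width^2 / 2), and the 2^(-ddCt) relative
expression fold change from qPCR Ct values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from acetylprio.errors import DomainError


@dataclass(frozen=True)
class StainingScore:
    intensity: int
    proportion: int
    index: int
    category: str  # high | low | unclassified


def staining_index(intensity: int, proportion: int) -> StainingScore:
    """IHC staining index = intensity x proportion; >= 6 high, <= 4 low."""
    if intensity not in range(4):
        raise DomainError(f"intensity must be 0..3, got {intensity}")
    if proportion not in range(5):
        raise DomainError(f"proportion must be 0..4, got {proportion}")
    index = intensity * proportion
    if index >= 6:
        category = "high"
    elif index <= 4:
        category = "low"
    else:
        category = "unclassified"
    return StainingScore(intensity, proportion, index, category)


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Xenograft tumour volume in mm^3: length x width^2 / 2."""
    if length_mm < 0 or width_mm < 0:
        raise DomainError("length and width must be non-negative")
    if width_mm > length_mm:
        raise DomainError("width must not exceed length")
    return length_mm * width_mm**2 / 2.0


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^(-ddCt) method.

    ddCt = (Ct_target - Ct_reference)_sample - (Ct_target - Ct_reference)_calibrator.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(v):
            raise DomainError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return 2.0 ** (-ddct)
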