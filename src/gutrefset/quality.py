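"""Assembly quality score and filtration rules.

The composite quality score balances completeness, contamination and
assembly contiguity:

    score = completeness - 5 * contamination + 15 * log10(N50)

with completeness and contamination in percent (0-100) and N50 in base
pairs.  The same score ranks assemblies during per-individual
dereplication and picks cluster representatives.

Filtration keeps an assembly only if completeness > 70%, contamination
< 5% and strain heterogeneity < 5% — all strict inequalities, so a
value sitting exactly on a threshold is rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

COMPLETENESS_MIN = 70.0
CONTAMINATION_MAX = 5.0
HETEROGENEITY_MAX = 5.0


@dataclass(frozen=True)
class QualityMetrics:
    """Percent-scale quality estimates plus N50 for one assembly."""

    completeness: float
    contamination: float
    heterogeneity: float
    n50: int

    def __post_init__(self) -> None:
        for name in ("completeness", "contamination"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


def quality_score(m: QualityMetrics) -> float:
    """completeness - 5*contamination + 15*log10(n50)."""
    if m.n50 < 1:
        raise ValueError(f"n50 must be >= 1, got {m.n50}")
    return m.completeness - 5.0 * m.contamination + 15.0 * math.log10(m.n50)


def passes_filters(
    m: QualityMetrics,
    completeness_min: float = COMPLETENESS_MIN,
    contamination_max: float = CONTAMINATION_MAX,
    heterogeneity_max: float = HETEROGENEITY_MAX,
    allow_missing_heterogeneity: bool = False,
) -> tuple[bool, list[str]]:
    """Apply the strict quality thresholds; return (pass, failure reasons).

    Heterogeneity may be unavailable for isolate or long-read
    assemblies; a NaN value fails unless ``allow_missing_heterogeneity``
    is set, in which case only the other two rules apply.
    """
    reasons: list[str] = []
    if math.isnan(m.completeness) or not m.completeness > completeness_min:
        reasons.append(f"completeness <= {completeness_min:g}")
    if math.isnan(m.contamination) or not m.contamination < contamination_max:
        reasons.append(f"contamination >= {contamination_max:g}")
    if math.isnan(m.heterogeneity):
        if not allow_missing_heterogeneity:
            reasons.append("heterogeneity missing")
    elif not m.heterogeneity < heterogeneity_max:
        reasons.append(f"heterogeneity >= {heterogeneity_max:g}")
    return (len(reasons) == 0, reasons)
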