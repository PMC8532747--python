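"""Ordinal quality scale shared by every stage of the pipeline.

The four-level scale grades both single environmental variables (via the
age-conditioned weight bins) and the final rearing-condition label ARCf.
The integer value of each member is its *severity rank*: 0 for the best
condition, 3 for the worst, so comparisons like ``a <= b`` read as
"``a`` is at least as favourable as ``b``".
"""

from __future__ import annotations

from enum import IntEnum


class QualityClass(IntEnum):
    """Suitability grade of a rearing condition (or of one variable's bin)."""

    EXCELLENT = 0
    GOOD = 1
    MODERATE = 2
    INADEQUATE = 3

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``"Excellent"``."""
        return self.name.capitalize()

    @classmethod
    def from_label(cls, label: str) -> "QualityClass":
        """Parse a label such as ``"Good"`` (case-insensitive)."""
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown quality class {label!r}; expected one of {CLASS_LABELS}"
            ) from None


#: Canonical presentation order: best to worst severity.
CLASS_ORDER: tuple[QualityClass, ...] = tuple(QualityClass)
CLASS_LABELS: tuple[str, ...] = tuple(c.label for c in CLASS_ORDER)
N_CLASSES = len(CLASS_ORDER)
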