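"""Screening confusion counts and derived metrics (F1, enrichment factor)."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError


@dataclass(frozen=True)
class ScreenCounts:
    """Confusion counts from screening a labelled active/decoy library."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_active(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class ScreenMetrics:
    precision: float
    recall: float
    f1: float
    enrichment_factor: float
    normalized_f1: float | None = None


def compute_metrics(counts: ScreenCounts,
                    max_reference_f1: float | None = None) -> ScreenMetrics:
    """Precision, recall, F1 and enrichment factor from confusion counts.

    All zero-denominator cases are defined as 0 so that useless
    pharmacophores earn a reward of 0 rather than raising.  The enrichment
    factor is precision divided by the active fraction of the library; an
    unbiased random classifier therefore has EF = 1.  When
    ``max_reference_f1`` is given, ``normalized_f1 = f1 / max_reference_f1``
    (F1 relative to the best achievable from reference features).
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    if counts.n_active > 0 and counts.n_total > 0:
        ef = precision / (counts.n_active / counts.n_total)
    else:
        ef = 0.0
    norm = None
    if max_reference_f1 is not None:
        if max_reference_f1 <= 0:
            raise ContractError("normalization undefined: max reference F1 is 0")
        norm = f1 / max_reference_f1
    return ScreenMetrics(precision, recall, f1, ef, norm)
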