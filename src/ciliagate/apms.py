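"""AP-MS interactor filtering: TAP spectral-count rules, SILAC enrichment
gating, and the significance-A outlier statistic.

Tandem affinity purification (TAP) candidates are retained when identified
in at least 2 of 3 bait experiments with >= 2 peptides, peptide probability
> 80%, protein probability >= 95%, and seen in fewer than 15% of non-bait
control purifications (the 15%-or-more rule is inclusive per its wording).
SILAC candidates must be quantified by >= 2 peptides in >= 2 of 3
replicates and enriched >= 2-fold (2^median log2 H/L).  Significance A is
the robust-z outlier p-value of a log-ratio against the ratio population,
with the spread estimated from the 15.87/50/84.13 percentiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

__all__ = [
    "TapProteinRecord",
    "SilacProteinRecord",
    "FilterThresholds",
    "ComplexTableRow",
    "ND",
    "filter_tap",
    "rank_table",
    "silac_enrichment",
    "significance_a",
    "summarize_complex_table",
]

#: Marker for a TAP protein not detected by the SILAC quantification.
ND = "nd"


@dataclass(frozen=True)
class TapProteinRecord:
    """One protein's evidence across the TAP purification experiments."""

    symbol: str
    counts: tuple[int, ...]
    peptide_probability: float
    protein_probability: float
    control_frequency: float
    is_bait: bool = False
    name: str = ""

    def validate(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError(f"{self.symbol}: peptide counts must be >= 0")
        for attr in ("peptide_probability", "protein_probability", "control_frequency"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.symbol}: {attr} must be in [0, 1]")

    @property
    def avg_count(self) -> float:
        return float(np.mean(self.counts))


@dataclass(frozen=True)
class SilacProteinRecord:
    """One protein's SILAC quantification across replicates."""

    symbol: str
    log2_ratios: tuple[float, ...]
    peptides_quantified: tuple[int, ...]

    def validate(self) -> None:
        if len(self.log2_ratios) != len(self.peptides_quantified):
            raise ValueError(f"{self.symbol}: replicate arrays differ in length")
        if any(p < 0 for p in self.peptides_quantified):
            raise ValueError(f"{self.symbol}: peptide counts must be >= 0")


@dataclass(frozen=True)
class FilterThresholds:
    """Retention thresholds for TAP and SILAC filtering.

    Inclusivity follows the stated rules: peptide probability strictly
    > 0.80, protein probability >= 0.95 ("threshold was set to 95%"),
    control frequency >= 0.15 removes ("15% or more"), average count
    strictly > 1.5, SILAC enrichment >= 2-fold ("at least 2-fold").
    """

    min_experiments: int = 2
    total_experiments: int = 3
    min_peptides: int = 2
    peptide_prob: float = 0.80
    protein_prob: float = 0.95
    control_freq: float = 0.15
    min_avg_count: float = 1.5
    silac_fold: float = 2.0
    silac_min_peptides: int = 2
    silac_min_reps: int = 2

    def validate(self) -> None:
        if self.min_experiments > self.total_experiments:
            raise ValueError("min_experiments must be <= total_experiments")
        if min(
            self.min_experiments, self.min_peptides, self.silac_min_peptides,
            self.silac_min_reps,
        ) < 1 or min(
            self.peptide_prob, self.protein_prob, self.control_freq,
            self.min_avg_count, self.silac_fold,
        ) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class ComplexTableRow:
    """A row of the summary complex table (symbol, name, counts)."""

    symbol: str
    name: str
    avg_tap_count: float
    silac_enrichment: float | str  # numeric fold-change or the 'nd' marker

    @property
    def silac_detected(self) -> bool:
        return not (
            isinstance(self.silac_enrichment, str)
            and self.silac_enrichment == ND
        )


# --------------------------------------------------------------------------
# TAP filtering
# --------------------------------------------------------------------------

def filter_tap(
    records: list[TapProteinRecord],
    thresholds: FilterThresholds | None = None,
) -> list[str]:
    """Symbols retained as specific complex components.

    Retain iff (#experiments with count >= min_peptides) >= min_experiments
    AND peptide_probability > peptide_prob AND protein_probability >=
    protein_prob AND control_frequency < control_freq.  The rules are
    conjunctive, so their order is irrelevant.  The bait is always retained.
    """
    th = thresholds or FilterThresholds()
    th.validate()
    retained: list[str] = []
    for rec in records:
        rec.validate()
        if len(rec.counts) != th.total_experiments:
            raise ValueError(
                f"{rec.symbol}: {len(rec.counts)} experiments in record but "
                f"thresholds expect {th.total_experiments}"
            )
        if rec.is_bait:
            retained.append(rec.symbol)
            continue
        n_qualifying = sum(c >= th.min_peptides for c in rec.counts)
        if (
            n_qualifying >= th.min_experiments
            and rec.peptide_probability > th.peptide_prob
            and rec.protein_probability >= th.protein_prob
            and rec.control_frequency < th.control_freq
        ):
            retained.append(rec.symbol)
    return retained


def rank_table(
    records: list[TapProteinRecord],
    silac: dict[str, float | str] | None = None,
    thresholds: FilterThresholds | None = None,
) -> list[ComplexTableRow]:
    """Summary rows for retained records, sorted by average peptide count.

    Rows with average count > min_avg_count, sorted descending with
    alphabetical tie-break; ``silac`` optionally maps symbol -> fold change
    (or the 'nd' marker; missing symbols are marked 'nd').
    """
    if not records:
        raise ValueError("need >= 1 record")
    th = thresholds or FilterThresholds()
    silac = silac or {}
    rows = [
        ComplexTableRow(
            symbol=rec.symbol,
            name=rec.name,
            avg_tap_count=rec.avg_count,
            silac_enrichment=silac.get(rec.symbol, ND),
        )
        for rec in records
        if rec.avg_count > th.min_avg_count
    ]
    rows.sort(key=lambda r: (-r.avg_tap_count, r.symbol))
    return rows


# --------------------------------------------------------------------------
# SILAC enrichment
# --------------------------------------------------------------------------

def silac_enrichment(
    records: list[SilacProteinRecord],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[tuple[str, float]], list[str]]:
    """Enriched proteins with fold-changes, plus not-quantified symbols.

    A protein qualifies when >= silac_min_reps replicates have >=
    silac_min_peptides quantified peptides; its enrichment is
    2^(median log2 ratio over all replicates), retained iff >= silac_fold
    (inclusive).  Non-qualifying proteins are reported as not-quantified
    ('nd'), not an error.
    """
    th = thresholds or FilterThresholds()
    th.validate()
    enriched: list[tuple[str, float]] = []
    not_quantified: list[str] = []
    for rec in records:
        rec.validate()
        n_qual = sum(p >= th.silac_min_peptides for p in rec.peptides_quantified)
        if n_qual < th.silac_min_reps:
            not_quantified.append(rec.symbol)
            continue
        fold = float(2.0 ** np.median(rec.log2_ratios))
        if fold >= th.silac_fold:
            enriched.append((rec.symbol, fold))
    return enriched, not_quantified


def significance_a(log2_ratios: np.ndarray) -> np.ndarray:
    """Outlier p-value of each log-ratio against the ratio population.

    Robust z from the 15.87/50/84.13 percentiles of the distribution:
    z = (r - median) / (p84.13 - median) above the median, reflected with
    the lower spread below it; p = erfc(z / sqrt 2) / 2, giving p in
    (0, 0.5] on each tail with p = 0.5 exactly at the median.
    """
    r = np.asarray(log2_ratios, dtype=float)
    if r.size < 10:
        raise ValueError("need >= 10 ratios for stable percentiles")
    p_lo, med, p_hi = np.percentile(r, [15.87, 50.0, 84.13])
    if p_hi - med <= 0 or med - p_lo <= 0:
        raise ValueError("zero inter-percentile spread in ratio distribution")
    z = np.where(r >= med, (r - med) / (p_hi - med), (med - r) / (med - p_lo))
    return 0.5 * erfc(z / math.sqrt(2.0))


# --------------------------------------------------------------------------
# complex-table summary
# --------------------------------------------------------------------------

def summarize_complex_table(
    rows: list[ComplexTableRow], bait: str | None = None
) -> dict[str, float | int]:
    """Integer counts and extrema of the summary table.

    Returns n_total, n_silac_detected, n_silac_nd, max_count (the top,
    typically bait, average TAP count) and top_nonbait_count (the highest
    average count excluding the bait; the bait defaults to the row with the
    maximum count).
    """
    if not rows:
        return {
            "n_total": 0,
            "n_silac_detected": 0,
            "n_silac_nd": 0,
            "top_nonbait_count": 0.0,
            "max_count": 0.0,
        }
    counts = [r.avg_tap_count for r in rows]
    max_count = max(counts)
    if bait is None:
        bait = rows[int(np.argmax(counts))].symbol
    nonbait = [r.avg_tap_count for r in rows if r.symbol != bait]
    return {
        "n_total": len(rows),
        "n_silac_detected": sum(r.silac_detected for r in rows),
        "n_silac_nd": sum(not r.silac_detected for r in rows),
        "top_nonbait_count": max(nonbait) if nonbait else 0.0,
        "max_count": max_count,
    }
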