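"""Set comparison of search results and threshold-finding diagnostics.

Identification results from database (DB) searching and combined
database + spectral-library (DB + SL) searching are compared at the
spectrum level: PSMs found by both are "common", the rest are exclusive
to one side.  The frequency analysis tabulates, per feature-value bin,
what fraction of PSMs belong to the large-quantitation-error group — the
diagnostic used to pick filter cutoffs (a sharp frequency jump across a
feature value marks a usable threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .features import FEATURE_NAMES, FeatureVector
from .model import SpectrumKey

__all__ = [
    "SetComparison",
    "compare_sets",
    "FrequencyBin",
    "frequency_by_feature",
    "parse_bins",
    "ares_summary",
]


@dataclass(frozen=True)
class SetComparison:
    """Spectrum-level Venn partition of two search results."""

    common: frozenset[SpectrumKey]
    db_exclusive: frozenset[SpectrumKey]
    dbsl_exclusive: frozenset[SpectrumKey]


def compare_sets(
    db_keys: Set[SpectrumKey], dbsl_keys: Set[SpectrumKey]
) -> SetComparison:
    """Exact set algebra on spectrum keys."""
    db_keys = frozenset(db_keys)
    dbsl_keys = frozenset(dbsl_keys)
    return SetComparison(
        common=db_keys & dbsl_keys,
        db_exclusive=db_keys - dbsl_keys,
        dbsl_exclusive=dbsl_keys - db_keys,
    )


@dataclass(frozen=True)
class FrequencyBin:
    """Large-error frequency within one feature-value bin.

    ``frequency_pct`` is 100 * count_large / count_total, or ``None`` for
    an empty bin (undefined, not zero).
    """

    lower: float
    upper: float  # inclusive upper bound; +inf for open-ended
    count_large: int
    count_total: int

    @property
    def frequency_pct(self) -> Optional[float]:
        if self.count_total == 0:
            return None
        return 100.0 * self.count_large / self.count_total


def parse_bins(spec: str) -> list[tuple[float, float]]:
    """Parse a bin description like ``"1-24,25-"`` into [lo, hi] intervals.

    An absent upper bound means unbounded above.
    """
    bins = []
    for part in spec.split(","):
        lo_s, _, hi_s = part.strip().partition("-")
        lo = float(lo_s)
        hi = float(hi_s) if hi_s else math.inf
        bins.append((lo, hi))
    return bins


def frequency_by_feature(
    features: Mapping[SpectrumKey, FeatureVector],
    large_error: Set[SpectrumKey],
    feature: str,
    bins: Sequence[tuple[float, float]],
) -> list[FrequencyBin]:
    """Per-bin fraction of PSMs that carry large quantitation errors.

    Bins are closed intervals [lo, hi] and must not overlap; PSMs with a
    missing value of ``feature`` are not counted in any bin.
    """
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}")
    ordered = sorted(bins)
    for (lo1, hi1), (lo2, _) in zip(ordered, ordered[1:]):
        if lo2 <= hi1:
            raise ValueError(f"bins overlap: [{lo1}, {hi1}] and [{lo2}, ...]")
    unknown = large_error - set(features)
    if unknown:
        raise ValueError(f"{len(unknown)} large-error keys not in the feature map")

    out = []
    for lo, hi in bins:
        n_large = n_total = 0
        for key, fv in features.items():
            value = getattr(fv, feature)
            if value is None or not lo <= value <= hi:
                continue
            n_total += 1
            if key in large_error:
                n_large += 1
        out.append(FrequencyBin(lower=lo, upper=hi, count_large=n_large, count_total=n_total))
    return out


def ares_summary(ares: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) of an ARE distribution, by linear interpolation."""
    if len(ares) == 0:
        raise ValueError("need at least one ARE value")
    q1, med, q3 = np.percentile(np.asarray(ares, dtype=float), [25, 50, 75])
    return float(q1), float(med), float(q3)
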