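"""Reporter normalization, quantitation, and accuracy metrics.

Normalization equalizes the per-channel median reporter intensity across
all identified spectra, removing systematic channel loading differences.
Protein quantitation follows the SumPsmIntensity scheme: each channel's
intensities are summed over a protein's contributing PSMs before ratios
are formed.  Accuracy against known mixing ratios is scored by the
average relative error

    ARE = (1/n) * sum_i |x_i - y_i| / y_i

over the n observed/theoretical ratio pairs, and at the dataset level by
the area under the coverage-vs-ARE curve (the empirical CDF of PSM ARE
integrated over a capped error range; higher = more PSMs quantified
accurately).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .features import psm_ratios
from .model import ChannelDesign, Psm, SpectrumKey, check_channel_count

__all__ = [
    "normalize_reporters",
    "psm_are",
    "psm_ares",
    "eligible_for_eval",
    "coverage_auc",
    "ProteinQuant",
    "protein_quant_sum",
    "label_large_error",
]


def channel_medians(psms: Sequence[Psm], design: ChannelDesign) -> list[float]:
    """Median intensity of each channel over nonmissing values."""
    check_channel_count(psms, design)
    meds = []
    for c in range(design.n_channels):
        vals = [p.reporter_intensities[c] for p in psms if p.reporter_intensities[c] is not None]
        if not vals:
            raise ValueError(
                f"channel {design.channel_labels[c]!r} has no nonmissing intensities"
            )
        meds.append(float(np.median(vals)))
    return meds


def normalize_reporters(psms: Sequence[Psm], design: ChannelDesign) -> list[Psm]:
    """Scale each channel so all channel medians coincide.

    The common reference is the median of the per-channel medians, which
    keeps intensities near their original scale; ratios are invariant to
    this choice of reference.  Missing values stay missing.
    """
    meds = channel_medians(psms, design)
    reference = float(np.median(meds))
    scales = [reference / m for m in meds]
    out = []
    for p in psms:
        out.append(
            p.with_intensities(
                tuple(
                    None if v is None else v * scales[c]
                    for c, v in enumerate(p.reporter_intensities)
                )
            )
        )
    return out


def psm_are(observed: Sequence[float], theoretical: Sequence[float]) -> float:
    """Average relative error of an observed ratio vector vs the truth."""
    if len(observed) != len(theoretical):
        raise ValueError(
            f"length mismatch: {len(observed)} observed vs {len(theoretical)} theoretical"
        )
    if any(y <= 0 for y in theoretical):
        raise ValueError("theoretical ratios must be positive")
    return sum(abs(x - y) / y for x, y in zip(observed, theoretical)) / len(observed)


def eligible_for_eval(psm: Psm) -> bool:
    """A PSM enters accuracy evaluation only if it is quantifiable without
    ambiguity: not a shared peptide and no missing reporter channel."""
    return not psm.is_shared and not psm.has_missing_reporter


def psm_ares(
    psms: Sequence[Psm], design: ChannelDesign, only_eligible: bool = True
) -> Dict[SpectrumKey, float]:
    """ARE of each (eligible) PSM against the design's theoretical ratios."""
    out: Dict[SpectrumKey, float] = {}
    for p in psms:
        if only_eligible and not eligible_for_eval(p):
            continue
        ratios = psm_ratios(p, design)
        if ratios is None:
            continue
        out[p.key] = psm_are(ratios, design.theoretical_ratios)
    return out


def coverage_auc(ares: Sequence[float], max_are: float = 1.0) -> float:
    """Area under the coverage-vs-ARE curve, normalized to [0, 1].

    The coverage curve is the empirical CDF F(t) = fraction of PSMs with
    ARE <= t.  Its exact integral over [0, max_are] is
    (1/N) * sum_i max(0, max_are - a_i), which divided by max_are gives
    the AUC.  All-accurate data (every ARE 0) scores 1.
    """
    if len(ares) == 0:
        raise ValueError("need at least one ARE value")
    if max_are <= 0:
        raise ValueError("max_are must be positive")
    a = np.asarray(ares, dtype=float)
    if np.any(a < 0):
        raise ValueError("ARE values must be nonnegative")
    return float(np.mean(np.clip(max_are - a, 0.0, None)) / max_are)


@dataclass(frozen=True)
class ProteinQuant:
    """Summed-intensity quantitation of one protein."""

    accession: str
    channel_sums: tuple[float, ...]
    ratios: tuple[float, ...]
    are: float
    n_psms_used: int


def protein_quant_sum(
    psms: Sequence[Psm], design: ChannelDesign
) -> Dict[str, ProteinQuant]:
    """SumPsmIntensity protein quantitation over eligible PSMs.

    Channel intensities are summed per primary protein accession; ratios
    are then formed from the sums against the denominator channel and
    scored against the theoretical ratios.  Proteins with no eligible PSM
    are omitted.
    """
    check_channel_count(psms, design)
    groups: Dict[str, List[Psm]] = {}
    for p in psms:
        if eligible_for_eval(p):
            groups.setdefault(p.primary_accession, []).append(p)

    out: Dict[str, ProteinQuant] = {}
    for acc, members in groups.items():
        sums = [0.0] * design.n_channels
        for p in members:
            for c, v in enumerate(p.reporter_intensities):
                sums[c] += v
        denom = sums[design.denominator_index]
        if denom == 0:
            continue
        ratios = tuple(sums[i] / denom for i in design.numerator_indices)
        out[acc] = ProteinQuant(
            accession=acc,
            channel_sums=tuple(sums),
            ratios=ratios,
            are=psm_are(ratios, design.theoretical_ratios),
            n_psms_used=len(members),
        )
    return out


def label_large_error(
    psms_with_are: Iterable[Tuple[SpectrumKey, float]], fraction: float = 0.25
) -> Set[SpectrumKey]:
    """Keys of the top-ARE fraction of PSMs ("larger quantitation errors").

    Exactly ``ceil(fraction * N)`` keys are returned; ties at the cutoff
    are broken deterministically by ascending key order.
    """
    pairs = list(psms_with_are)
    if not pairs:
        raise ValueError("need at least one (key, ARE) pair")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    k = math.ceil(fraction * len(pairs))
    ranked = sorted(pairs, key=lambda kv: (-kv[1], kv[0]))
    return {key for key, _ in ranked[:k]}
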