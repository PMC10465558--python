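"""Spectral features used by the rule-based PSM filter.

Ten general features are computed for every PSM (charge, precursor mass,
peptide length, PTM count, PTM ratio, absolute mass difference, average
reporter intensity, PeptideProphet F-value, intra-protein ratio distance,
intra-peptide ratio distance), plus six features available only for
spectral-library (SpectraST) hits.  Features that cannot be computed —
missing reporter ions, absent library scores — are ``None``; the filter
bypasses conditions on missing features rather than triggering them.

The two ratio-distance features quantify how far a PSM's reporter-ratio
vector sits from its peers'::

    dist_j = sqrt( sum_i ((R_i^j - AvgRest_i) / Avg_i)^2 )

where, for ratio index i, ``AvgRest_i`` averages over the peer set without
PSM j and ``Avg_i`` over the peer set including j.  For the intra-protein
distance the peer set is every PSM of the protein; for the intra-peptide
distance it is every PSM of the same peptide sequence, except that all of
a protein's single-hit peptides (one PSM each) are merged into one
"pseudo-peptide" peer set so the statistic remains defined for them.
A PSM alone in its peer set has distance 0 by convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

from .model import ChannelDesign, Psm, SpectrumKey

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "psm_ratios",
    "avg_reporter_intensity",
    "iprotdist",
    "ipepdist",
    "count_ptms",
    "featurize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureVector:
    """All filterable features of one PSM; ``None`` marks a missing feature."""

    charge: int
    precursor_mass_da: float
    peptide_length: int
    n_ptm: int
    ptm_ratio: float
    abs_mass_diff_da: float
    avg_reporter_intensity: Optional[float]
    f_value: Optional[float]
    iprotdist: Optional[float]
    ipepdist: Optional[float]
    sl_precursor_mz_diff_abs: Optional[float] = None
    sl_dot: Optional[float] = None
    sl_delta: Optional[float] = None
    sl_n_hits: Optional[float] = None
    sl_hit_mean: Optional[float] = None
    sl_hit_std: Optional[float] = None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


FEATURE_NAMES: tuple[str, ...] = tuple(FeatureVector.__dataclass_fields__)


def psm_ratios(psm: Psm, design: ChannelDesign) -> Optional[tuple[float, ...]]:
    """Reporter-ion ratio vector: each numerator channel over the denominator.

    Returns ``None`` when any channel is missing or the denominator is 0,
    so that the missing state propagates to every ratio-based feature.
    """
    ints = psm.reporter_intensities
    if len(ints) != design.n_channels:
        raise ValueError(
            f"PSM {psm.key} has {len(ints)} channels, design has {design.n_channels}"
        )
    if any(v is None for v in ints):
        return None
    denom = ints[design.denominator_index]
    if denom == 0:
        return None
    return tuple(ints[i] / denom for i in design.numerator_indices)


def avg_reporter_intensity(psm: Psm) -> Optional[float]:
    """Arithmetic mean over all channels; ``None`` if any channel is missing."""
    ints = psm.reporter_intensities
    if any(v is None for v in ints):
        return None
    return sum(ints) / len(ints)


def _ratio_distance(
    target_ratios: Sequence[float],
    peer_ratios: Sequence[Sequence[float]],
) -> Optional[float]:
    """Shared kernel of the intra-protein / intra-peptide distances.

    ``peer_ratios`` includes the target's own vector.  Returns 0.0 when the
    target is the only peer, ``None`` when some Avg_i is 0 (undefined).
    """
    m = len(peer_ratios)
    if m <= 1:
        return 0.0
    n = len(target_ratios)
    total = 0.0
    for i in range(n):
        col = [r[i] for r in peer_ratios]
        avg = sum(col) / m
        if avg == 0:
            logger.warning("ratio distance undefined: Avg_%d is zero", i)
            return None
        avg_rest = (sum(col) - target_ratios[i]) / (m - 1)
        total += ((target_ratios[i] - avg_rest) / avg) ** 2
    return math.sqrt(total)


def _complete_peers(psms: Sequence[Psm], design: ChannelDesign) -> list[tuple[Psm, tuple[float, ...]]]:
    out = []
    for p in psms:
        r = psm_ratios(p, design)
        if r is not None:
            out.append((p, r))
    return out


def iprotdist(
    target: Psm, protein_psms: Sequence[Psm], design: ChannelDesign
) -> Optional[float]:
    """Distance of the target's ratio vector to all PSMs of its protein.

    ``protein_psms`` must contain the target.  PSMs with missing reporters
    cannot contribute ratio vectors and are excluded from the peer set; a
    target with missing reporters gets ``None`` (bypass).
    """
    target_ratios = psm_ratios(target, design)
    if target_ratios is None:
        return None
    peers = _complete_peers(protein_psms, design)
    return _ratio_distance(target_ratios, [r for _, r in peers])


def ipepdist(
    target: Psm, protein_psms: Sequence[Psm], design: ChannelDesign
) -> Optional[float]:
    """Distance of the target to the PSMs of the same peptide (or pseudo-peptide).

    If the target's peptide sequence has at least two PSMs in the protein,
    those are the peer set; otherwise the peer set is the merged
    pseudo-peptide: every PSM of the protein whose peptide is single-hit.
    """
    target_ratios = psm_ratios(target, design)
    if target_ratios is None:
        return None
    peers = _complete_peers(protein_psms, design)
    counts: Dict[str, int] = {}
    for p, _ in peers:
        counts[p.peptide] = counts.get(p.peptide, 0) + 1
    if counts.get(target.peptide, 0) >= 2:
        peer_ratios = [r for p, r in peers if p.peptide == target.peptide]
    else:
        # single-hit peptide: merge all of the protein's single-hit peptides
        peer_ratios = [r for p, r in peers if counts[p.peptide] == 1]
    return _ratio_distance(target_ratios, peer_ratios)


def count_ptms(psm: Psm) -> int:
    """Number of post-translational modifications, excluding label tags."""
    return sum(1 for m in psm.modifications if not m.is_label)


def featurize(
    psms: Sequence[Psm], design: ChannelDesign
) -> Dict[SpectrumKey, FeatureVector]:
    """Compute the full feature vector of every PSM.

    Ratio-distance peer groups are formed within the primary (first-listed)
    protein accession; reporter intensities are expected to be normalized
    already (features feed the filter that runs after normalization).
    """
    by_protein: Dict[str, list[Psm]] = {}
    for p in psms:
        by_protein.setdefault(p.primary_accession, []).append(p)

    out: Dict[SpectrumKey, FeatureVector] = {}
    for p in psms:
        group = by_protein[p.primary_accession]
        n_ptm = count_ptms(p)
        ss = p.spectrast_scores
        out[p.key] = FeatureVector(
            charge=p.assumed_charge,
            precursor_mass_da=p.precursor_neutral_mass_da,
            peptide_length=len(p.peptide),
            n_ptm=n_ptm,
            ptm_ratio=n_ptm / len(p.peptide),
            abs_mass_diff_da=abs(p.mass_diff_da),
            avg_reporter_intensity=avg_reporter_intensity(p),
            f_value=p.f_value,
            iprotdist=iprotdist(p, group, design),
            ipepdist=ipepdist(p, group, design),
            sl_precursor_mz_diff_abs=None if ss is None else ss.precursor_mz_diff_abs,
            sl_dot=None if ss is None else ss.dot_product,
            sl_delta=None if ss is None else ss.delta_score,
            sl_n_hits=None if ss is None else float(ss.n_hits),
            sl_hit_mean=None if ss is None else ss.hit_mean,
            sl_hit_std=None if ss is None else ss.hit_std,
        )
    return out


def features_to_table(features: Dict[SpectrumKey, FeatureVector]):
    """Feature map as a pandas DataFrame (one row per PSM) for audit export."""
    import pandas as pd

    rows = []
    for key, fv in features.items():
        row = {"run": key.run, "scan": key.scan, "charge_state": key.charge}
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


_INT_FEATURES = {"charge", "peptide_length", "n_ptm"}


def write_feature_table(features: Dict[SpectrumKey, FeatureVector], path) -> None:
    """Audit TSV: one row per PSM, one column per feature, empty = missing."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["run", "scan", "charge_state", *FEATURE_NAMES])
        for key, fv in features.items():
            row = [key.run, key.scan, key.charge]
            for name in FEATURE_NAMES:
                v = getattr(fv, name)
                row.append("" if v is None else repr(v) if isinstance(v, float) else v)
            writer.writerow(row)


def read_feature_table(path) -> Dict[SpectrumKey, FeatureVector]:
    """Read a feature TSV written by :func:`write_feature_table`."""
    import csv

    out: Dict[SpectrumKey, FeatureVector] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        idx = {c: i for i, c in enumerate(header)}
        for row in reader:
            key = SpectrumKey(row[idx["run"]], int(row[idx["scan"]]), int(row[idx["charge_state"]]))
            kwargs = {}
            for name in FEATURE_NAMES:
                cell = row[idx[name]]
                if cell == "":
                    kwargs[name] = None
                elif name in _INT_FEATURES:
                    kwargs[name] = int(cell)
                else:
                    kwargs[name] = float(cell)
            out[key] = FeatureVector(**kwargs)
    return out
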