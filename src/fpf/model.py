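"""Core data model: spectrum keys, PSMs, and the channel design.

A peptide-spectrum match (PSM) assigns one peptide sequence to one MS2
spectrum.  In isobaric-labeling experiments (TMT/iTRAQ) each PSM also
carries one reporter-ion intensity per multiplexed channel; relative
quantitation is done on ratios of those intensities against a designated
denominator channel.

Missing reporter intensities are represented as ``None`` — never as 0 —
because downstream filtering rules must bypass, not trigger on, features
that cannot be computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "SpectrumKey",
    "Modification",
    "SpectrastScores",
    "Psm",
    "ChannelDesign",
    "KNOWN_LABEL_MASSES",
]

#: Mass deltas (Da) of common isobaric / isotopic label reagents.  Used to
#: recognise label modifications when a file format carries no explicit flag.
KNOWN_LABEL_MASSES = (
    229.162932,  # TMT6/10/11-plex
    304.207146,  # TMTpro 16/18-plex
    144.102063,  # iTRAQ 4-plex
    304.205360,  # iTRAQ 8-plex
)


@dataclass(frozen=True, order=True)
class SpectrumKey:
    """Identity of one acquired spectrum query: (run basename, scan, charge).

    Charge is part of the key because TPP treats different assumed charge
    states of the same scan as distinct spectrum queries.
    """

    run: str
    scan: int
    charge: int

    def __post_init__(self) -> None:
        if self.scan <= 0:
            raise ValueError(f"scan number must be positive, got {self.scan}")
        if self.charge <= 0:
            raise ValueError(f"charge must be positive, got {self.charge}")

    def spectrum_name(self) -> str:
        """TPP-style spectrum attribute ``basename.scan.scan.charge``."""
        return f"{self.run}.{self.scan:05d}.{self.scan:05d}.{self.charge}"

    @classmethod
    def from_spectrum_name(cls, spectrum: str) -> "SpectrumKey":
        parts = spectrum.rsplit(".", 3)
        if len(parts) != 4:
            raise ValueError(f"cannot parse spectrum attribute {spectrum!r}")
        run, start, _end, charge = parts
        return cls(run=run, scan=int(start), charge=int(charge))


@dataclass(frozen=True)
class Modification:
    """One modification on a peptide.

    ``position`` is 1-based over residues; 0 marks the N-terminus and
    ``len(peptide) + 1`` the C-terminus.  ``is_label`` flags isobaric-label
    tags (TMT/iTRAQ), which are excluded from the PTM count feature.
    """

    position: int
    mass_delta: float
    is_label: bool = False

    @property
    def is_nterm(self) -> bool:
        return self.position == 0


@dataclass(frozen=True)
class SpectrastScores:
    """Search scores exclusive to SpectraST spectral-library hits."""

    precursor_mz_diff_abs: float
    dot_product: float
    delta_score: float
    n_hits: int
    hit_mean: float
    hit_std: float


@dataclass(frozen=True)
class ChannelDesign:
    """Reporter-channel layout and the theoretical ratio vector.

    ``theoretical_ratios`` has one entry per non-denominator channel, in
    channel order with the denominator removed; these are the y_i against
    which observed ratios x_i are scored by the average relative error.
    """

    channel_labels: tuple[str, ...]
    denominator_index: int
    theoretical_ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        object.__setattr__(self, "theoretical_ratios", tuple(float(r) for r in self.theoretical_ratios))
        if len(self.channel_labels) < 2:
            raise ValueError("need at least two channels")
        if not 0 <= self.denominator_index < len(self.channel_labels):
            raise ValueError("denominator_index out of range")
        if len(self.theoretical_ratios) != len(self.channel_labels) - 1:
            raise ValueError(
                f"expected {len(self.channel_labels) - 1} theoretical ratios, "
                f"got {len(self.theoretical_ratios)}"
            )
        if any(r <= 0 for r in self.theoretical_ratios):
            raise ValueError("theoretical ratios must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_ratios(self) -> int:
        return len(self.channel_labels) - 1

    @property
    def numerator_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_channels) if i != self.denominator_index)

    @classmethod
    def from_toml(cls, path) -> "ChannelDesign":
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        return cls(
            channel_labels=tuple(str(c) for c in doc["channels"]),
            denominator_index=int(doc.get("denominator_index", 0)),
            theoretical_ratios=tuple(doc["theoretical_ratios"]),
        )


@dataclass(frozen=True)
class Psm:
    """One peptide-spectrum match with identification and quantitation fields."""

    key: SpectrumKey
    peptide: str
    protein_accessions: tuple[str, ...]
    reporter_intensities: tuple[Optional[float], ...]
    modifications: tuple[Modification, ...] = ()
    is_shared: bool = False
    precursor_neutral_mass_da: float = 0.0
    theoretical_peptide_mass_da: float = 0.0
    mass_diff_da: float = 0.0
    iprophet_probability: float = 1.0
    f_value: Optional[float] = None
    spectrast_scores: Optional[SpectrastScores] = None
    provenance: frozenset[str] = frozenset({"DB"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein_accessions", tuple(self.protein_accessions))
        object.__setattr__(self, "modifications", tuple(self.modifications))
        object.__setattr__(
            self,
            "reporter_intensities",
            tuple(None if v is None else float(v) for v in self.reporter_intensities),
        )
        object.__setattr__(self, "provenance", frozenset(self.provenance))
        if not self.peptide:
            raise ValueError("peptide must be nonempty")
        if not self.protein_accessions:
            raise ValueError("need at least one protein accession")
        expected = self.precursor_neutral_mass_da - self.theoretical_peptide_mass_da
        if abs(self.mass_diff_da - expected) > 1e-6:
            raise ValueError(
                f"mass_diff_da {self.mass_diff_da} inconsistent with "
                f"observed-theoretical {expected}"
            )

    @property
    def assumed_charge(self) -> int:
        return self.key.charge

    @property
    def primary_accession(self) -> str:
        return self.protein_accessions[0]

    @property
    def has_missing_reporter(self) -> bool:
        return any(v is None for v in self.reporter_intensities)

    def with_intensities(self, intensities: Sequence[Optional[float]]) -> "Psm":
        return replace(self, reporter_intensities=tuple(intensities))


def check_channel_count(psms: Iterable[Psm], design: ChannelDesign) -> None:
    """Raise if any PSM's reporter vector does not match the design."""
    for psm in psms:
        if len(psm.reporter_intensities) != design.n_channels:
            raise ValueError(
                f"PSM {psm.key} carries {len(psm.reporter_intensities)} reporter "
                f"channels but the design defines {design.n_channels}"
            )
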