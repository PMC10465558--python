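"""Synthetic multi-channel PSM datasets with known ground truth.

The generator emulates the structure of an isobaric-labeling benchmark
mixture: proteins carrying several PSMs each, reporter intensities built
as (lognormal base abundance) x (channel factor from the theoretical
ratios) x (multiplicative lognormal noise), a controllable fraction of
"bad" PSMs whose ratio noise is inflated, and optional coupling of bad
status to the features a rule-based filter keys on (low reporter signal,
long peptide, high charge).  Shared peptides, missing reporter channels
and spectral-library score blocks are sprinkled in at configurable rates.

All randomness flows from one seeded generator in a fixed order, so the
same configuration always yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .model import ChannelDesign, Modification, Psm, SpectrastScores, SpectrumKey

__all__ = ["SynthConfig", "PsmTruth", "generate", "make_pepxml_fixture"]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

TMT_DELTA = 229.162932
OXIDATION_DELTA = 15.994915


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults model a six-plex equimolar mixture (all theoretical ratios 1,
    first channel as denominator) with 10% multiplicative reporter noise,
    a quarter of PSMs carrying 4x inflated noise, and bad status coupled
    to the filterable features.
    """

    seed: int = 0
    n_proteins: int = 150
    n_psms: Optional[int] = None  # exact total; None -> per-protein sampling
    psms_per_protein_mean: float = 8.0
    psms_per_protein_dispersion: float = 0.5
    n_channels: int = 6
    denominator_index: int = 0
    theoretical_ratios: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    base_intensity_log_mean: float = math.log(5e4)
    base_intensity_log_sd: float = 0.8
    low_intensity_log_mean: float = math.log(4e3)
    low_intensity_log_sd: float = 0.8
    ratio_noise_cv: float = 0.1
    frac_bad: float = 0.25
    bad_error_multiplier: float = 4.0
    frac_missing_reporter: float = 0.02
    frac_shared_peptides: float = 0.05
    frac_sl_exclusive: float = 0.7
    couple_low_intensity: bool = True
    couple_long_peptide: bool = True
    couple_high_charge: bool = True
    coupling_prob: float = 0.4
    run_name: str = "synthrun"

    def __post_init__(self) -> None:
        for name in (
            "frac_bad",
            "frac_missing_reporter",
            "frac_shared_peptides",
            "frac_sl_exclusive",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.theoretical_ratios) != self.n_channels - 1:
            raise ValueError("theoretical_ratios must have n_channels - 1 entries")
        if self.bad_error_multiplier < 1:
            raise ValueError("bad_error_multiplier must be >= 1")
        if self.frac_shared_peptides > 0 and self.n_proteins < 2:
            raise ValueError("shared peptides need at least two proteins")

    @property
    def design(self) -> ChannelDesign:
        return ChannelDesign(
            channel_labels=tuple(f"ch{i + 1:02d}" for i in range(self.n_channels)),
            denominator_index=self.denominator_index,
            theoretical_ratios=self.theoretical_ratios,
        )


@dataclass(frozen=True)
class PsmTruth:
    is_bad: bool
    true_ratios: Tuple[float, ...]


def _random_peptide(rng: np.random.Generator, length: int, taken: set) -> str:
    while True:
        seq = "".join(rng.choice(_AMINO_ACIDS, size=length))
        if seq not in taken:
            taken.add(seq)
            return seq


def _psm_counts(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    mean = config.psms_per_protein_mean
    disp = config.psms_per_protein_dispersion
    r = 1.0 / max(disp, 1e-9)
    if config.n_psms is not None:
        weights = rng.gamma(shape=r, scale=mean / r, size=config.n_proteins) + 1e-6
        return rng.multinomial(config.n_psms, weights / weights.sum())
    p = r / (r + mean)
    return np.maximum(rng.negative_binomial(r, p, size=config.n_proteins), 1)


def _label_mods(peptide: str) -> tuple[Modification, ...]:
    mods = [Modification(0, TMT_DELTA, True)]
    mods += [
        Modification(i + 1, TMT_DELTA, True) for i, aa in enumerate(peptide) if aa == "K"
    ]
    return tuple(mods)


def generate(config: SynthConfig) -> tuple[list[Psm], Dict[SpectrumKey, PsmTruth]]:
    """Draw one dataset: (PSM list, per-PSM ground truth)."""
    from .io import peptide_mass

    rng = np.random.default_rng(config.seed)
    design = config.design
    counts = _psm_counts(config, rng)
    factors = np.ones(config.n_channels)
    for idx, ratio in zip(design.numerator_indices, config.theoretical_ratios):
        factors[idx] = ratio

    taken_peptides: set = set()
    psms: list[Psm] = []
    truth: Dict[SpectrumKey, PsmTruth] = {}
    scan = 1000

    for prot_idx, n_psms in enumerate(counts):
        if n_psms == 0:
            continue
        accession = f"SYN{prot_idx:04d}"
        n_peptides = max(1, math.ceil(0.6 * n_psms))
        peptides = []
        for _ in range(n_peptides):
            length = int(rng.integers(8, 25))
            seq = _random_peptide(rng, length, taken_peptides)
            accessions = [accession]
            if rng.random() < config.frac_shared_peptides:
                other = int(rng.integers(config.n_proteins - 1))
                if other >= prot_idx:
                    other += 1
                accessions.append(f"SYN{other:04d}")
            peptides.append((seq, tuple(accessions)))

        for _ in range(int(n_psms)):
            is_bad = bool(rng.random() < config.frac_bad)
            seq, accessions = peptides[int(rng.integers(len(peptides)))]
            if is_bad and config.couple_long_peptide and rng.random() < config.coupling_prob:
                length = int(rng.integers(25, 41))
                seq = _random_peptide(rng, length, taken_peptides)
                accessions = (accession,)
            if is_bad and config.couple_high_charge and rng.random() < config.coupling_prob:
                charge = int(rng.integers(5, 7))
            else:
                charge = int(rng.choice([2, 3, 4], p=[0.5, 0.35, 0.15]))

            mods = list(_label_mods(seq))
            for i, aa in enumerate(seq):
                if aa == "M" and rng.random() < 0.2:
                    mods.append(Modification(i + 1, OXIDATION_DELTA, False))
            mods = tuple(mods)
            theoretical = peptide_mass(seq, mods)
            observed = theoretical + float(rng.normal(0, 0.002))

            if is_bad and config.couple_low_intensity and rng.random() < 0.5:
                base = float(
                    rng.lognormal(config.low_intensity_log_mean, config.low_intensity_log_sd)
                )
            else:
                base = float(
                    rng.lognormal(config.base_intensity_log_mean, config.base_intensity_log_sd)
                )
            cv = config.ratio_noise_cv * (config.bad_error_multiplier if is_bad else 1.0)
            sigma = math.sqrt(math.log(1.0 + cv * cv))
            noise = rng.lognormal(-0.5 * sigma * sigma, sigma, size=config.n_channels)
            intensities: list = [float(base * f * z) for f, z in zip(factors, noise)]
            if rng.random() < config.frac_missing_reporter:
                intensities[int(rng.integers(config.n_channels))] = None

            spectrast = None
            provenance = frozenset({"DB"})
            if rng.random() < config.frac_sl_exclusive:
                dot = float(rng.beta(8, 2))
                spectrast = SpectrastScores(
                    precursor_mz_diff_abs=abs(float(rng.normal(0, 0.01))),
                    dot_product=dot,
                    delta_score=float(rng.uniform(0.05, 0.5)),
                    n_hits=int(1 + rng.poisson(3)),
                    hit_mean=max(0.0, dot - float(rng.uniform(0, 0.2))),
                    hit_std=float(rng.uniform(0.01, 0.15)),
                )
                provenance = frozenset({"SL"})

            key = SpectrumKey(config.run_name, scan, charge)
            scan += 1
            psms.append(
                Psm(
                    key=key,
                    peptide=seq,
                    protein_accessions=accessions,
                    reporter_intensities=tuple(intensities),
                    modifications=mods,
                    is_shared=len(accessions) > 1,
                    precursor_neutral_mass_da=observed,
                    theoretical_peptide_mass_da=theoretical,
                    mass_diff_da=observed - theoretical,
                    iprophet_probability=float(rng.uniform(0.9, 1.0)),
                    f_value=float(rng.gamma(4, 0.5) + 0.2),
                    spectrast_scores=spectrast,
                    provenance=provenance,
                )
            )
            truth[key] = PsmTruth(is_bad=is_bad, true_ratios=config.theoretical_ratios)
    return psms, truth


# ---------------------------------------------------------------------------
# pepXML fixture writing


def make_pepxml_fixture(psms, path, design: ChannelDesign) -> None:
    """Write a minimal but schema-conformant iProphet-dialect pepXML file.

    The file round-trips through :func:`fpf.io.read_pepxml` with full field
    fidelity: Libra-style reporter blocks (missing channels written with
    absolute 0), SpectraST score elements, PeptideProphet fval parameters
    and iProphet probabilities.
    """
    from lxml import etree
    from pyteomics.mass import std_aa_mass

    from .io import HYDROGEN, PEPXML_NS, WATER

    def E(parent, tag, **attrs):
        el = etree.SubElement(parent, f"{{{PEPXML_NS}}}{tag}")
        for k, v in attrs.items():
            el.set(k, v if isinstance(v, str) else repr(v) if isinstance(v, float) else str(v))
        return el

    nsmap = {None: PEPXML_NS}
    root = etree.Element(f"{{{PEPXML_NS}}}msms_pipeline_analysis", nsmap=nsmap)
    root.set("date", "2000-01-01T00:00:00")
    root.set("summary_xml", str(path))
    E(root, "analysis_summary", analysis="interprophet", time="2000-01-01T00:00:00")
    libra_summary_parent = E(
        root, "analysis_summary", analysis="libra", time="2000-01-01T00:00:00"
    )
    libra_summary = E(
        libra_summary_parent,
        "libra_summary",
        mass_tolerance="0.2",
        centroiding_preference="2",
        normalization="0",
        output_type="0",
    )
    for c, label in enumerate(design.channel_labels):
        E(libra_summary, "fragment_masses", channel=c + 1, mz=f"{126.0 + c:.4f}")

    groups: dict = {}
    for p in psms:
        groups.setdefault((p.key.run, tuple(sorted(p.provenance))), []).append(p)

    engine_names = {"DB": "Comet", "SL": "SpectraST"}
    index = 1
    for (run, tags), members in sorted(groups.items()):
        run_summary = E(
            root,
            "msms_run_summary",
            base_name=run,
            raw_data_type="raw",
            raw_data=".mzML",
        )
        for search_id, tag in enumerate(tags, start=1):
            E(
                run_summary,
                "search_summary",
                base_name=run,
                search_engine=engine_names[tag],
                precursor_mass_type="monoisotopic",
                fragment_mass_type="monoisotopic",
                search_id=search_id,
            )
        for p in sorted(members, key=lambda q: q.key):
            sq = E(
                run_summary,
                "spectrum_query",
                spectrum=p.key.spectrum_name(),
                start_scan=p.key.scan,
                end_scan=p.key.scan,
                precursor_neutral_mass=p.precursor_neutral_mass_da,
                assumed_charge=p.key.charge,
                index=index,
            )
            index += 1
            sr = E(sq, "search_result")
            hit = E(
                sr,
                "search_hit",
                hit_rank="1",
                peptide=p.peptide,
                protein=p.protein_accessions[0],
                num_tot_proteins=len(p.protein_accessions),
                calc_neutral_pep_mass=p.theoretical_peptide_mass_da,
                massdiff=p.mass_diff_da,
            )
            for alt in p.protein_accessions[1:]:
                E(hit, "alternative_protein", protein=alt)
            residue_mods = [m for m in p.modifications if 0 < m.position <= len(p.peptide)]
            nterm = [m for m in p.modifications if m.position == 0]
            cterm = [m for m in p.modifications if m.position == len(p.peptide) + 1]
            if residue_mods or nterm or cterm:
                mi = E(hit, "modification_info")
                if nterm:
                    mi.set("mod_nterm_mass", repr(nterm[0].mass_delta + HYDROGEN))
                if cterm:
                    mi.set("mod_cterm_mass", repr(cterm[0].mass_delta + WATER - HYDROGEN))
                for m in sorted(residue_mods, key=lambda m: m.position):
                    E(
                        mi,
                        "mod_aminoacid_mass",
                        position=m.position,
                        mass=std_aa_mass[p.peptide[m.position - 1]] + m.mass_delta,
                    )
            ss = p.spectrast_scores
            if ss is not None:
                E(hit, "search_score", name="dot", value=ss.dot_product)
                E(hit, "search_score", name="delta", value=ss.delta_score)
                E(hit, "search_score", name="precursor_mz_diff", value=ss.precursor_mz_diff_abs)
                E(hit, "search_score", name="hits_num", value=ss.n_hits)
                E(hit, "search_score", name="hits_mean", value=ss.hit_mean)
                E(hit, "search_score", name="hits_stdev", value=ss.hit_std)
            if p.f_value is not None:
                ar = E(hit, "analysis_result", analysis="peptideprophet")
                ppr = E(ar, "peptideprophet_result", probability=p.iprophet_probability)
                sss = E(ppr, "search_score_summary")
                E(sss, "parameter", name="fval", value=p.f_value)
            ar = E(hit, "analysis_result", analysis="interprophet")
            E(ar, "interprophet_result", probability=p.iprophet_probability)
            ar = E(hit, "analysis_result", analysis="libra")
            lr = E(ar, "libra_result")
            for c, v in enumerate(p.reporter_intensities):
                E(
                    lr,
                    "intensity",
                    channel=c + 1,
                    target_mass=f"{126.0 + c:.4f}",
                    absolute=0.0 if v is None else v,
                    normalized="0",
                )
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
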