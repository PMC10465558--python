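"""pepXML (TPP/iProphet dialect) and canonical PSM-table I/O.

Reading collects one :class:`~fpf.model.Psm` per ``spectrum_query`` (rank-1
search hit only).  Reporter intensities are taken from Libra-style
``libra_result`` blocks inside the pepXML when present, or from a sidecar
TSV keyed by (run, scan, charge); an intensity that is absent or exactly 0
is an explicit missing value.  Writing a filtered file deletes the removed
``spectrum_query`` elements and leaves every other element untouched, so
the output stays consumable by downstream TPP tools (ProteinProphet,
Libra).

The canonical PSM table is a plain TSV holding every Psm field losslessly;
it is the interchange format used by the command-line tools and tests.
"""

from __future__ import annotations

import csv
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set

from lxml import etree

from .model import (
    KNOWN_LABEL_MASSES,
    ChannelDesign,
    Modification,
    Psm,
    SpectrastScores,
    SpectrumKey,
)

__all__ = [
    "read_pepxml",
    "write_filtered_pepxml",
    "read_psm_table",
    "write_psm_table",
    "read_reporter_sidecar",
    "PEPXML_NS",
]

PEPXML_NS = "http://regis-web.systemsbiology.net/pepXML"

# monoisotopic masses (Da)
HYDROGEN = 1.00782503207
WATER = 18.0105646863

#: SpectraST search_score names -> SpectrastScores fields
_SPECTRAST_SCORE_NAMES = {
    "precursor_mz_diff": "precursor_mz_diff_abs",
    "dot": "dot_product",
    "delta": "delta_score",
    "hits_num": "n_hits",
    "hits_mean": "hit_mean",
    "hits_stdev": "hit_std",
}


def _is_label_mass(delta: float, tol: float = 0.01) -> bool:
    return any(abs(delta - m) <= tol for m in KNOWN_LABEL_MASSES)


def _engine_tags(search_engine: str) -> set:
    return {"SL"} if "spectrast" in search_engine.lower() else {"DB"}


def peptide_mass(peptide: str, modifications: Sequence[Modification]) -> float:
    """Monoisotopic neutral mass of a (modified) peptide."""
    from pyteomics.mass import std_aa_mass

    return (
        sum(std_aa_mass[aa] for aa in peptide)
        + WATER
        + sum(m.mass_delta for m in modifications)
    )


def _parse_modifications(hit, peptide: str) -> tuple[Modification, ...]:
    from pyteomics.mass import std_aa_mass

    mods = []
    for mi in hit.iterfind("{*}modification_info"):
        nterm = mi.get("mod_nterm_mass")
        if nterm is not None:
            delta = float(nterm) - HYDROGEN
            mods.append(Modification(0, delta, _is_label_mass(delta)))
        cterm = mi.get("mod_cterm_mass")
        if cterm is not None:
            delta = float(cterm) - WATER + HYDROGEN  # OH terminus
            mods.append(Modification(len(peptide) + 1, delta, _is_label_mass(delta)))
        for ma in mi.iterfind("{*}mod_aminoacid_mass"):
            pos = int(ma.get("position"))
            delta = float(ma.get("mass")) - std_aa_mass[peptide[pos - 1]]
            mods.append(Modification(pos, delta, _is_label_mass(delta)))
    return tuple(mods)


def _parse_libra(hit, design: ChannelDesign, key: SpectrumKey):
    for ar in hit.iterfind("{*}analysis_result"):
        if ar.get("analysis") != "libra":
            continue
        lr = ar.find("{*}libra_result")
        if lr is None:
            continue
        intensities = lr.findall("{*}intensity")
        if len(intensities) != design.n_channels:
            raise ValueError(
                f"PSM {key}: libra_result has {len(intensities)} channels but the "
                f"design defines {design.n_channels}"
            )
        slots: list = [None] * design.n_channels
        for el in intensities:
            c = int(el.get("channel")) - 1
            if not 0 <= c < design.n_channels:
                raise ValueError(f"PSM {key}: libra channel {c + 1} out of range")
            value = float(el.get("absolute"))
            slots[c] = value if value > 0 else None
        return tuple(slots)
    return None


def _parse_scores(hit) -> dict:
    return {
        el.get("name"): el.get("value") for el in hit.iterfind("{*}search_score")
    }


def _parse_fval(hit, scores: dict) -> Optional[float]:
    if "fval" in scores:
        return float(scores["fval"])
    for ar in hit.iterfind("{*}analysis_result"):
        if ar.get("analysis") != "peptideprophet":
            continue
        for param in ar.iter("{*}parameter"):
            if param.get("name") == "fval":
                return float(param.get("value"))
    return None


def _parse_probability(hit) -> float:
    for ar in hit.iterfind("{*}analysis_result"):
        if ar.get("analysis") == "interprophet":
            res = ar.find("{*}interprophet_result")
            if res is not None:
                return float(res.get("probability"))
    for ar in hit.iterfind("{*}analysis_result"):
        if ar.get("analysis") == "peptideprophet":
            res = ar.find("{*}peptideprophet_result")
            if res is not None:
                return float(res.get("probability"))
    return 1.0


def read_pepxml(
    path,
    design: ChannelDesign,
    reporter_sidecar: Optional[Mapping[SpectrumKey, tuple]] = None,
) -> list[Psm]:
    """Read the rank-1 PSMs of an iProphet-dialect pepXML file.

    ``reporter_sidecar`` supplies per-channel intensities for files without
    embedded Libra blocks (map or TSV path; see
    :func:`read_reporter_sidecar`).
    """
    if isinstance(reporter_sidecar, (str, bytes)) or hasattr(reporter_sidecar, "__fspath__"):
        reporter_sidecar = read_reporter_sidecar(reporter_sidecar, design)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed pepXML in {path}: {exc}") from exc

    psms: list[Psm] = []
    for run_summary in tree.getroot().iter("{*}msms_run_summary"):
        tags: set = set()
        for ss in run_summary.iterfind("{*}search_summary"):
            tags |= _engine_tags(ss.get("search_engine", ""))
        if not tags:
            tags = {"DB"}
        for sq in run_summary.iterfind("{*}spectrum_query"):
            key = SpectrumKey(
                run=SpectrumKey.from_spectrum_name(sq.get("spectrum")).run,
                scan=int(sq.get("start_scan")),
                charge=int(sq.get("assumed_charge")),
            )
            hit = None
            for h in sq.iterfind("{*}search_result/{*}search_hit"):
                if int(h.get("hit_rank", "1")) == 1:
                    hit = h
                    break
            if hit is None:
                continue
            peptide = hit.get("peptide")
            accessions = [hit.get("protein")] + [
                ap.get("protein") for ap in hit.iterfind("{*}alternative_protein")
            ]
            mods = _parse_modifications(hit, peptide)
            scores = _parse_scores(hit)
            observed = float(sq.get("precursor_neutral_mass"))
            theoretical = float(hit.get("calc_neutral_pep_mass"))
            spectrast = None
            if "dot" in scores:
                spectrast = SpectrastScores(
                    precursor_mz_diff_abs=abs(float(scores.get("precursor_mz_diff", 0.0))),
                    dot_product=float(scores["dot"]),
                    delta_score=float(scores.get("delta", 0.0)),
                    n_hits=int(float(scores.get("hits_num", 0))),
                    hit_mean=float(scores.get("hits_mean", 0.0)),
                    hit_std=float(scores.get("hits_stdev", 0.0)),
                )
            intensities = _parse_libra(hit, design, key)
            if intensities is None and reporter_sidecar is not None:
                intensities = reporter_sidecar.get(key)
            if intensities is None:
                intensities = (None,) * design.n_channels
            psms.append(
                Psm(
                    key=key,
                    peptide=peptide,
                    protein_accessions=tuple(accessions),
                    reporter_intensities=intensities,
                    modifications=mods,
                    is_shared=len(accessions) > 1
                    or int(hit.get("num_tot_proteins", len(accessions))) > 1,
                    precursor_neutral_mass_da=observed,
                    theoretical_peptide_mass_da=theoretical,
                    mass_diff_da=observed - theoretical,
                    iprophet_probability=_parse_probability(hit),
                    f_value=_parse_fval(hit, scores),
                    spectrast_scores=spectrast,
                    provenance=frozenset(tags),
                )
            )
    return psms


def write_filtered_pepxml(source, removed: Set[SpectrumKey], dest) -> int:
    """Copy a pepXML file, deleting the spectrum_query elements in ``removed``.

    Everything else — headers, analysis summaries, retained queries — is
    preserved verbatim (apart from serialization whitespace).  Returns the
    number of deleted elements; raises if any key is absent from the source.
    """
    try:
        tree = etree.parse(str(source))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed pepXML in {source}: {exc}") from exc

    removed = set(removed)
    found: set = set()
    for sq in list(tree.getroot().iter("{*}spectrum_query")):
        key = SpectrumKey(
            run=SpectrumKey.from_spectrum_name(sq.get("spectrum")).run,
            scan=int(sq.get("start_scan")),
            charge=int(sq.get("assumed_charge")),
        )
        if key in removed:
            found.add(key)
            sq.getparent().remove(sq)
    missing = removed - found
    if missing:
        raise KeyError(
            f"{len(missing)} removal keys not present in {source}: "
            + ", ".join(str(k) for k in sorted(missing)[:5])
        )
    tree.write(str(dest), xml_declaration=True, encoding="UTF-8")
    return len(found)


# ---------------------------------------------------------------------------
# canonical PSM table (TSV)

_FIXED_COLUMNS = [
    "run",
    "scan",
    "charge",
    "peptide",
    "modifications",
    "proteins",
    "is_shared",
    "precursor_neutral_mass_da",
    "theoretical_peptide_mass_da",
    "mass_diff_da",
    "iprophet_probability",
    "f_value",
    "sl_precursor_mz_diff_abs",
    "sl_dot",
    "sl_delta",
    "sl_n_hits",
    "sl_hit_mean",
    "sl_hit_std",
    "provenance",
]

REPORTER_PREFIX = "reporter_"


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _encode_mods(mods: Sequence[Modification]) -> str:
    return ";".join(
        f"{m.position}:{m.mass_delta!r}:{'L' if m.is_label else 'P'}" for m in mods
    )


def _decode_mods(cell: str) -> tuple[Modification, ...]:
    if not cell:
        return ()
    out = []
    for part in cell.split(";"):
        pos, delta, kind = part.split(":")
        out.append(Modification(int(pos), float(delta), kind == "L"))
    return tuple(out)


def write_psm_table(psms: Sequence[Psm], path, design: ChannelDesign) -> None:
    """Write the canonical tab-separated PSM table (empty cell = missing)."""
    header = _FIXED_COLUMNS + [REPORTER_PREFIX + c for c in design.channel_labels]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for p in psms:
            ss = p.spectrast_scores
            row = [
                p.key.run,
                p.key.scan,
                p.key.charge,
                p.peptide,
                _encode_mods(p.modifications),
                ";".join(p.protein_accessions),
                int(p.is_shared),
                _fmt(p.precursor_neutral_mass_da),
                _fmt(p.theoretical_peptide_mass_da),
                _fmt(p.mass_diff_da),
                _fmt(p.iprophet_probability),
                _fmt(p.f_value),
                _fmt(None if ss is None else ss.precursor_mz_diff_abs),
                _fmt(None if ss is None else ss.dot_product),
                _fmt(None if ss is None else ss.delta_score),
                _fmt(None if ss is None else ss.n_hits),
                _fmt(None if ss is None else ss.hit_mean),
                _fmt(None if ss is None else ss.hit_std),
                ",".join(sorted(p.provenance)),
            ] + [_fmt(v) for v in p.reporter_intensities]
            writer.writerow(row)


def read_psm_table(path) -> list[Psm]:
    """Read the canonical PSM table written by :func:`write_psm_table`.

    Channel labels are taken from the ``reporter_*`` header columns.
    Unknown columns and duplicate spectrum keys are errors.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path} is empty (no header)") from None
        reporter_cols = [c for c in header if c.startswith(REPORTER_PREFIX)]
        unknown = [
            c for c in header if c not in _FIXED_COLUMNS and not c.startswith(REPORTER_PREFIX)
        ]
        if unknown:
            raise ValueError(f"unknown columns in {path}: {unknown}")
        missing_cols = [c for c in _FIXED_COLUMNS if c not in header]
        if missing_cols:
            raise ValueError(f"missing columns in {path}: {missing_cols}")
        idx = {c: i for i, c in enumerate(header)}

        psms: list[Psm] = []
        seen: set = set()
        for row in reader:
            cell = lambda c: row[idx[c]]
            key = SpectrumKey(cell("run"), int(cell("scan")), int(cell("charge")))
            if key in seen:
                raise ValueError(f"duplicate spectrum key {key} in {path}")
            seen.add(key)
            sl_dot = cell("sl_dot")
            spectrast = None
            if sl_dot != "":
                spectrast = SpectrastScores(
                    precursor_mz_diff_abs=float(cell("sl_precursor_mz_diff_abs")),
                    dot_product=float(sl_dot),
                    delta_score=float(cell("sl_delta")),
                    n_hits=int(cell("sl_n_hits")),
                    hit_mean=float(cell("sl_hit_mean")),
                    hit_std=float(cell("sl_hit_std")),
                )
            intensities = tuple(
                None if row[idx[c]] == "" else float(row[idx[c]]) for c in reporter_cols
            )
            psms.append(
                Psm(
                    key=key,
                    peptide=cell("peptide"),
                    protein_accessions=tuple(cell("proteins").split(";")),
                    reporter_intensities=intensities,
                    modifications=_decode_mods(cell("modifications")),
                    is_shared=bool(int(cell("is_shared"))),
                    precursor_neutral_mass_da=float(cell("precursor_neutral_mass_da")),
                    theoretical_peptide_mass_da=float(cell("theoretical_peptide_mass_da")),
                    mass_diff_da=float(cell("mass_diff_da")),
                    iprophet_probability=float(cell("iprophet_probability")),
                    f_value=None if cell("f_value") == "" else float(cell("f_value")),
                    spectrast_scores=spectrast,
                    provenance=frozenset(cell("provenance").split(",")),
                )
            )
    return psms


def read_reporter_sidecar(path, design: ChannelDesign) -> Dict[SpectrumKey, tuple]:
    """Read a sidecar intensity TSV: run, scan, charge, reporter_<label>...."""
    out: Dict[SpectrumKey, tuple] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        idx = {c: i for i, c in enumerate(header)}
        cols = [REPORTER_PREFIX + c for c in design.channel_labels]
        missing = [c for c in cols if c not in idx]
        if missing:
            raise ValueError(f"sidecar {path} lacks columns {missing}")
        for row in reader:
            key = SpectrumKey(row[idx["run"]], int(row[idx["scan"]]), int(row[idx["charge"]]))
            out[key] = tuple(
                None if row[idx[c]] == "" or float(row[idx[c]]) == 0 else float(row[idx[c]])
                for c in cols
            )
    return out
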