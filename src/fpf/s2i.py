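"""Precursor signal-to-interference (S2I) from MS1 survey scans.

When an isolation window co-isolates ions besides the targeted precursor,
the reporter signal of the MS2 scan is a blend of peptides and relative
ratios are compressed toward 1.  S2I quantifies precursor purity as

    S2I = (intensity of the precursor and its isotopic cluster in the
           isolation window) / (total ion intensity in the window)

measured on the MS1 scan nearest before the MS2 trigger.  A purity filter
removes PSMs with S2I below 0.7 before spectral-library construction, so
the library holds only reference spectra with clean reporter signal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .model import Psm, SpectrumKey

__all__ = ["Ms1Context", "compute_s2i", "s2i_filter", "contexts_from_mzml"]

logger = logging.getLogger(__name__)

#: Average mass gap between isotopologue peaks (Da).
ISOTOPE_SPACING_DA = 1.00335


@dataclass(frozen=True)
class Ms1Context:
    """Isolation-window parameters plus the MS1 peak list for one MS2 scan."""

    precursor_mz: float
    charge: int
    isolation_center_mz: float
    isolation_lower_offset: float
    isolation_upper_offset: float
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.charge <= 0:
            raise ValueError(f"charge must be positive, got {self.charge}")
        if self.isolation_lower_offset <= 0 or self.isolation_upper_offset <= 0:
            raise ValueError("isolation offsets must be positive")
        peaks = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        object.__setattr__(self, "peaks", peaks)


def compute_s2i(
    ctx: Ms1Context,
    ppm_tol: float = 10.0,
    n_isotopes: int = 4,
    isotope_spacing: float = ISOTOPE_SPACING_DA,
) -> float:
    """Fraction of in-window MS1 signal attributable to the precursor.

    Peaks within ``ppm_tol`` of ``precursor_mz + k * spacing / charge`` for
    k = 0..n_isotopes count as precursor signal; everything inside
    [center - lower, center + upper] counts toward the total.  Defined as
    0 for an empty window.
    """
    lo = ctx.isolation_center_mz - ctx.isolation_lower_offset
    hi = ctx.isolation_center_mz + ctx.isolation_upper_offset
    targets = [
        ctx.precursor_mz + k * isotope_spacing / ctx.charge
        for k in range(n_isotopes + 1)
    ]
    signal = total = 0.0
    for mz, inten in ctx.peaks:
        if not lo <= mz <= hi:
            continue
        total += inten
        if any(abs(mz - t) <= t * ppm_tol * 1e-6 for t in targets):
            signal += inten
    if total == 0:
        return 0.0
    return signal / total


def s2i_filter(
    psms: Sequence[Psm],
    contexts: Mapping[SpectrumKey, Ms1Context],
    threshold: float = 0.7,
    ppm_tol: float = 10.0,
    n_isotopes: int = 4,
) -> list[Psm]:
    """Keep PSMs with S2I >= threshold (strictly-below are removed).

    PSMs without an MS1 context cannot be scored and are retained with a
    warning rather than silently dropped.
    """
    retained = []
    for p in psms:
        ctx = contexts.get(p.key)
        if ctx is None:
            logger.warning("no MS1 context for %s; retained without S2I check", p.key)
            retained.append(p)
            continue
        if compute_s2i(ctx, ppm_tol=ppm_tol, n_isotopes=n_isotopes) >= threshold:
            retained.append(p)
    return retained


_SCAN_RE = re.compile(r"scan=(\d+)")


def _scan_number(spectrum_id: str, index: int) -> int:
    m = _SCAN_RE.search(spectrum_id)
    return int(m.group(1)) if m else index + 1


def _cv_params(element) -> Dict[str, str]:
    """accession -> value for the direct cvParam children of an element."""
    return {
        cv.get("accession"): cv.get("value")
        for cv in element.iterfind("{*}cvParam")
    }


def _decode_arrays(spectrum) -> tuple[tuple[float, float], ...]:
    """Decode the m/z and intensity binary arrays of one mzML spectrum."""
    import base64
    import struct
    import zlib

    mzs = intensities = None
    for bda in spectrum.iterfind("{*}binaryDataArrayList/{*}binaryDataArray"):
        params = _cv_params(bda)
        binary = bda.find("{*}binary")
        raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
        if "MS:1000574" in params:  # zlib compression
            raw = zlib.decompress(raw)
        fmt = "f" if "MS:1000521" in params else "d"  # 32- vs 64-bit float
        width = 4 if fmt == "f" else 8
        values = struct.unpack(f"<{len(raw) // width}{fmt}", raw)
        if "MS:1000514" in params:  # m/z array
            mzs = values
        elif "MS:1000515" in params:  # intensity array
            intensities = values
    if mzs is None or intensities is None:
        return ()
    return tuple(zip((float(m) for m in mzs), (float(i) for i in intensities)))


def contexts_from_mzml(
    path, default_half_window: float = 0.85
) -> Dict[int, Ms1Context]:
    """Build an Ms1Context for every MS2 scan in an mzML file, keyed by scan
    number.

    The peak list comes from the nearest preceding MS1 scan.  Isolation
    window center/offsets are read from the file when present; otherwise a
    symmetric +/- ``default_half_window`` Th window around the precursor
    m/z is assumed.  MS2 scans with no preceding MS1 or no selected-ion
    record are skipped with a warning.
    """
    from lxml import etree

    contexts: Dict[int, Ms1Context] = {}
    last_ms1: Optional[tuple[tuple[float, float], ...]] = None
    tree = etree.parse(str(path))
    for idx, spectrum in enumerate(tree.getroot().iter("{*}spectrum")):
        params = _cv_params(spectrum)
        level = int(params.get("MS:1000511", 0))  # ms level
        if level == 1:
            last_ms1 = _decode_arrays(spectrum)
            continue
        if level != 2:
            continue
        scan = _scan_number(spectrum.get("id", ""), idx)
        precursor = spectrum.find("{*}precursorList/{*}precursor")
        ion = None if precursor is None else precursor.find(
            "{*}selectedIonList/{*}selectedIon"
        )
        if ion is None:
            logger.warning("MS2 scan %d lacks precursor metadata; skipped", scan)
            continue
        if last_ms1 is None:
            logger.warning("MS2 scan %d has no preceding MS1 scan; skipped", scan)
            continue
        ion_params = _cv_params(ion)
        mz = float(ion_params["MS:1000744"])  # selected ion m/z
        charge = int(float(ion_params.get("MS:1000041", 1)))  # charge state
        window = precursor.find("{*}isolationWindow")
        win_params = {} if window is None else _cv_params(window)
        contexts[scan] = Ms1Context(
            precursor_mz=mz,
            charge=charge,
            isolation_center_mz=float(win_params.get("MS:1000827", mz)),
            isolation_lower_offset=float(win_params.get("MS:1000828", default_half_window)),
            isolation_upper_offset=float(win_params.get("MS:1000829", default_half_window)),
            peaks=last_ms1,
        )
    return contexts
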