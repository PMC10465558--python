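"""Test helpers: a minimal uncompressed mzML writer for S2I fixtures."""

import base64
import struct


def _b64(values):
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def _binary_array(values, accession, name, unit):
    data = _b64(values)
    return f"""
      <binaryDataArray encodedLength="{len(data)}">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
        <cvParam cvRef="MS" accession="{accession}" name="{name}" value="" unitName="{unit}"/>
        <binary>{data}</binary>
      </binaryDataArray>"""


def _spectrum_xml(index, scan, ms_level, mzs, intensities, precursor=None):
    precursor_xml = ""
    if precursor is not None:
        mz, charge, center, lower, upper = precursor
        window = ""
        if center is not None:
            window = f"""
          <isolationWindow>
            <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{center}"/>
            <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{lower}"/>
            <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{upper}"/>
          </isolationWindow>"""
        precursor_xml = f"""
      <precursorList count="1">
        <precursor>{window}
          <selectedIonList count="1">
            <selectedIon>
              <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{mz}"/>
              <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{charge}"/>
            </selectedIon>
          </selectedIonList>
        </precursor>
      </precursorList>"""
    kind = (
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        if ms_level == 1
        else '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
    )
    return f"""
    <spectrum index="{index}" id="controllerType=0 controllerNumber=1 scan={scan}" defaultArrayLength="{len(mzs)}">
      <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
      {kind}{precursor_xml}
      <binaryDataArrayList count="2">{_binary_array(mzs, "MS:1000514", "m/z array", "m/z")}{_binary_array(intensities, "MS:1000515", "intensity array", "number of detector counts")}
      </binaryDataArrayList>
    </spectrum>"""


def write_mzml(path, spectra):
    """Write a minimal uncompressed mzML file.

    ``spectra`` is a list of dicts with keys: scan, ms_level, mzs,
    intensities, and (MS2 only) precursor = (mz, charge, center, lower,
    upper); pass center=None to omit the isolation window.
    """
    body = "".join(
        _spectrum_xml(i, s["scan"], s["ms_level"], s["mzs"], s["intensities"], s.get("precursor"))
        for i, s in enumerate(spectra)
    )
    content = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="testrun">
    <spectrumList count="{len(spectra)}">{body}
    </spectrumList>
  </run>
</mzML>
"""
    with open(path, "w") as fh:
        fh.write(content)
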