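"""Readers and writers for the plain-text formats used across the package.

Formats
-------
Clinical table
    CSV with one header row, ``patient_id`` first column; an empty cell is
    a missing value.
Spectrum matrix
    CSV with first column ``sample_id`` and the remaining columns labelled
    by integer m/z bin.
Raw acquisition
    Either a long-format scan CSV (``scan_index,time_s,mz,intensity``) or
    an mzML file (MS1 scans).  The mzML reader and writer are implemented
    directly on lxml: the reader handles centroided MS1 spectra with
    uncompressed or zlib-compressed 32/64-bit float arrays, and the writer
    emits a minimal, schema-conformant mzML 1.1.0 document.
"""

from __future__ import annotations

import base64
import zlib
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree

from .preprocessing import RawAcquisition, Scan

# ---------------------------------------------------------------------------
# clinical table


def write_clinical_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_clinical_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# spectrum matrix


def write_spectrum_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a samples x integer-m/z-bin matrix; index holds sample IDs."""
    matrix.to_csv(path, index_label="sample_id", float_format="%.17g")


def read_spectrum_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, index_col=0, float_precision="round_trip")
    matrix.columns = [int(c) for c in matrix.columns]
    return matrix


# ---------------------------------------------------------------------------
# long-format scan CSV


def write_scan_csv(raw: RawAcquisition, path) -> None:
    """Write an acquisition as ``scan_index,time_s,mz,intensity`` rows."""
    frames = []
    for i, scan in enumerate(raw.scans):
        frames.append(
            pd.DataFrame(
                {
                    "scan_index": i,
                    "time_s": scan.time,
                    "mz": scan.mz,
                    "intensity": scan.intensity,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                 float_format="%.17g")


def read_scan_csv(path, metadata: dict | None = None) -> RawAcquisition:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"scan_index", "time_s", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"scan CSV must contain columns {sorted(required)}")
    scans = []
    for _, group in df.groupby("scan_index", sort=True):
        scans.append(
            Scan(
                time=float(group["time_s"].iloc[0]),
                mz=group["mz"].to_numpy(float),
                intensity=group["intensity"].to_numpy(float),
            )
        )
    return RawAcquisition(scans=scans, metadata=metadata or {})


# ---------------------------------------------------------------------------
# mzML

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={index}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{time}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        np.asarray(values, dtype="<f8").tobytes()
    ).decode("ascii")


def write_mzml(raw: RawAcquisition, path) -> None:
    """Write MS1 scans to a minimal mzML 1.1.0 document.

    Arrays are stored as uncompressed 64-bit floats; the output is readable
    by :func:`read_mzml` and by any conformant mzML reader.
    """
    run_id = escape(str(raw.metadata.get("sample_id", "run")))
    parts = [_MZML_HEADER.format(run_id=run_id, count=len(raw.scans))]
    for i, scan in enumerate(raw.scans):
        mz_b64 = _b64(scan.mz)
        int_b64 = _b64(scan.intensity)
        parts.append(
            _MZML_SPECTRUM.format(
                index=i,
                n=len(scan.mz),
                time=repr(float(scan.time)),
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                int_len=len(int_b64),
                int_b64=int_b64,
            )
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


_NS = "{http://psi.hupo.org/ms/mzml}"

# accessions understood by the array decoder
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"


def _cv_params(element) -> dict[str, str]:
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in element.iter(_NS + "cvParam")
    }


def _decode_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    binary = bda.find(_NS + "binary")
    raw = base64.b64decode((binary.text or "").encode("ascii"))
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _scan_time_seconds(spectrum_el) -> float:
    for scan in spectrum_el.iter(_NS + "scan"):
        for cv in scan.iter(_NS + "cvParam"):
            if cv.get("accession") == _ACC_SCAN_START:
                value = float(cv.get("value"))
                unit = (cv.get("unitName") or "second").lower()
                return value * 60.0 if unit.startswith("min") else value
    raise ValueError("spectrum has no scan start time")


def read_mzml(path, metadata: dict | None = None) -> RawAcquisition:
    """Read MS1 scans from an mzML file into a :class:`RawAcquisition`.

    Accepts uncompressed or zlib-compressed 32/64-bit float arrays, and
    both profile and centroid spectra (unit-mass binning downstream makes
    the distinction irrelevant).
    """
    tree = etree.parse(str(path))
    scans = []
    for spectrum_el in tree.iter(_NS + "spectrum"):
        params = _cv_params(spectrum_el)
        if int(params.get(_ACC_MS_LEVEL, "1")) != 1:
            continue
        mz = intensity = None
        for bda in spectrum_el.iter(_NS + "binaryDataArray"):
            arr_params = _cv_params(bda)
            if _ACC_MZ_ARRAY in arr_params:
                mz = _decode_array(bda)
            elif _ACC_INTENSITY_ARRAY in arr_params:
                intensity = _decode_array(bda)
        if mz is None or intensity is None:
            raise ValueError("spectrum lacks m/z or intensity array")
        scans.append(
            Scan(time=_scan_time_seconds(spectrum_el), mz=mz,
                 intensity=intensity)
        )
    scans.sort(key=lambda s: s.time)
    return RawAcquisition(scans=scans, metadata=metadata or {})
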