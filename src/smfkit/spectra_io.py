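"""Spectrum and table I/O plus acquisition quality-control statistics.

Supports two-column (m/z, intensity) TSV and mzML.  mzML support is a small
built-in reader/writer pair for the standard cvParam-annotated encoding
(64-bit little-endian floats, base64, optional zlib on read), verified by
bit-exact round trips.

QC statistics mirror standard fingerprinting practice: pairwise cosine
similarity of binned spectra (batch stability), percent coefficient of
variation across technical replicates, and relative standard deviation of
selected signals across QC acquisitions.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .containers import RawSpectrum

__all__ = [
    "read_spectrum", "write_spectrum", "read_spectra_dir",
    "cosine_similarity", "replicate_cv", "rsd", "average_replicates",
    "QCReport", "qc_report",
]


# ---------------------------------------------------------------------------
# reading / writing

def _read_tsv(path: Path) -> RawSpectrum:
    try:
        arr = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"format error in {path}: {exc}") from exc
    if arr.shape[1] != 2:
        raise ValueError(f"format error in {path}: expected 2 columns, got {arr.shape[1]}")
    mz, inten = arr[:, 0], arr[:, 1]
    if np.any(inten < 0):
        raise ValueError(f"validation error in {path}: negative intensity")
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    # merge exact duplicate m/z values by summing their intensities
    uniq, inverse = np.unique(mz, return_inverse=True)
    if len(uniq) < len(mz):
        inten = np.bincount(inverse, weights=inten)
        mz = uniq
    return RawSpectrum(mz, inten)


def _decode_mzml_array(elem, expected_len: int) -> np.ndarray:
    accs = {cv.get("accession") for cv in elem.iter() if cv.tag.endswith("cvParam")}
    data = None
    for child in elem.iter():
        if child.tag.endswith("binary"):
            data = base64.b64decode(child.text or "")
    if data is None:
        raise ValueError("mzML binaryDataArray without <binary> payload")
    if "MS:1000574" in accs:  # zlib compression
        data = zlib.decompress(data)
    dtype = "<f4" if "MS:1000521" in accs else "<f8"
    return np.frombuffer(data, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> RawSpectrum:
    """Minimal mzML reader: first spectrum's m/z + intensity arrays.

    Parses the standard cvParam-annotated binaryDataArray encoding
    (32/64-bit float, optional zlib) directly from the XML.
    """
    try:
        tree = ET.parse(path)
        mz = inten = None
        for elem in tree.iter():
            if not elem.tag.endswith("binaryDataArray"):
                continue
            accs = {cv.get("accession") for cv in elem.iter()
                    if cv.tag.endswith("cvParam")}
            spec_len = None
            for anc in tree.iter():
                if anc.tag.endswith("spectrum"):
                    spec_len = int(anc.get("defaultArrayLength", 0))
                    break
            arr = _decode_mzml_array(elem, spec_len or 0)
            if "MS:1000514" in accs:
                mz = arr
            elif "MS:1000515" in accs:
                inten = arr
            if mz is not None and inten is not None:
                break
        if mz is None or inten is None:
            raise ValueError("no m/z / intensity arrays in first spectrum")
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"format error in {path}: {exc}") from exc
    if np.any(inten < 0):
        raise ValueError(f"validation error in {path}: negative intensity")
    order = np.argsort(mz, kind="stable")
    return RawSpectrum(mz[order], inten[order])


def read_spectrum(path, fmt: str | None = None) -> RawSpectrum:
    """Read one spectrum from a two-column TSV or an mzML file.

    The m/z axis is sorted ascending if needed; exact duplicate m/z values
    are merged by summing intensities.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if path.suffix.lower() == ".mzml" else "tsv"
    if fmt.lower() == "mzml":
        return _read_mzml(path)
    if fmt.lower() in ("tsv", "txt"):
        return _read_tsv(path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


_MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="smfkit" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="smfkit"/>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="1" defaultDataProcessingRef="DP1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def write_spectrum(spectrum: RawSpectrum, path, fmt: str | None = None) -> None:
    """Write a spectrum as two-column TSV or single-scan mzML."""
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if path.suffix.lower() == ".mzml" else "tsv"
    if fmt.lower() in ("tsv", "txt"):
        np.savetxt(path, np.column_stack([spectrum.mz, spectrum.intensity]),
                   fmt="%.12g", delimiter="\t")
        return
    if fmt.lower() != "mzml":
        raise ValueError(f"unknown spectrum format {fmt!r}")
    mz_b64 = base64.b64encode(spectrum.mz.astype("<f8").tobytes()).decode()
    int_b64 = base64.b64encode(spectrum.intensity.astype("<f8").tobytes()).decode()
    xml = _MZML_TEMPLATE.format(
        run_id=escape(spectrum.sample_id or "run1"),
        n=len(spectrum), mz_b64=mz_b64, int_b64=int_b64,
        mz_len=len(mz_b64), int_len=len(int_b64),
    )
    path.write_text(xml)


def read_spectra_dir(directory, metadata: pd.DataFrame | None = None) -> list[RawSpectrum]:
    """Read every .tsv/.mzML spectrum in a directory, attaching metadata by file stem.

    The optional metadata table is indexed (or indexable) by
    ``<sample_id>_r<replicate>`` file stems with columns sample_id,
    replicate, batch, is_qc.
    """
    directory = Path(directory)
    meta = None
    if metadata is not None:
        meta = metadata.assign(
            stem=[f"{s}_r{r}" for s, r in zip(metadata["sample_id"], metadata["replicate"])]
        ).set_index("stem")
    spectra = []
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in (".tsv", ".txt", ".mzml"):
            continue
        spec = read_spectrum(path)
        if meta is not None and path.stem in meta.index:
            row = meta.loc[path.stem]
            spec.sample_id = str(row["sample_id"])
            spec.replicate = int(row["replicate"])
            spec.batch = str(row.get("batch", ""))
            spec.is_qc = bool(row.get("is_qc", False))
        else:
            spec.sample_id = path.stem
        spectra.append(spec)
    return spectra


# ---------------------------------------------------------------------------
# QC statistics

def cosine_similarity(a, b) -> float:
    """Cosine similarity of two spectra or intensity vectors on one grid.

    In [0, 1] for nonnegative inputs; 1 for identical (or positively scaled)
    nonzero spectra.  Raises on a zero vector, where the similarity is
    undefined.
    """
    va = a.intensity if isinstance(a, RawSpectrum) else np.asarray(a, dtype=float)
    vb = b.intensity if isinstance(b, RawSpectrum) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("spectra must share one grid; bin them first")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("undefined similarity: zero-intensity spectrum")
    return float(np.dot(va, vb) / (na * nb))


def replicate_cv(replicate_values: np.ndarray) -> np.ndarray:
    """Percent CV (100 * sd / mean, sample sd) per peak across replicates.

    ``replicate_values`` is replicates x peaks (a 1-D input is one peak).
    """
    arr = np.asarray(replicate_values, dtype=float)
    one_d = arr.ndim == 1
    if one_d:
        arr = arr.reshape(-1, 1)
    if arr.shape[0] < 2:
        raise ValueError("replicate CV requires >= 2 replicates")
    means = arr.mean(axis=0)
    if np.any(means == 0):
        raise ValueError("undefined CV: zero mean intensity")
    out = 100.0 * arr.std(axis=0, ddof=1) / means
    return float(out[0]) if one_d else out


#: RSD across QC acquisitions is the same statistic as replicate CV.
rsd = replicate_cv


def average_replicates(spectra_or_vectors, sample_ids=None):
    """Average technical replicates into one intensity vector per sample.

    Accepts either a list of :class:`RawSpectrum` (grouped by their
    ``sample_id``; all grids must match) or an array of vectors with a
    parallel ``sample_ids`` sequence.  Returns ``(sample_ids, matrix,
    replicate_counts)`` with samples in first-appearance order.
    """
    if sample_ids is None:
        spectra = list(spectra_or_vectors)
        if not spectra:
            raise ValueError("no spectra to average")
        grid = spectra[0].mz
        for s in spectra[1:]:
            if len(s.mz) != len(grid) or not np.allclose(s.mz, grid):
                raise ValueError("alignment required: spectra are on different grids")
        vectors = np.array([s.intensity for s in spectra])
        ids = [s.sample_id for s in spectra]
    else:
        vectors = np.asarray(spectra_or_vectors, dtype=float)
        ids = list(sample_ids)
    order = list(dict.fromkeys(ids))
    idx = {s: i for i, s in enumerate(order)}
    sums = np.zeros((len(order), vectors.shape[1]))
    counts = np.zeros(len(order), dtype=int)
    for sid, vec in zip(ids, vectors):
        sums[idx[sid]] += vec
        counts[idx[sid]] += 1
    return order, sums / counts[:, None], counts


@dataclass
class QCReport:
    """Batch-stability summary over QC acquisitions and replicates."""

    pairwise_similarity: np.ndarray  # condensed upper-triangle, QC spectra
    fraction_above_0p9: float
    replicate_cv: dict[str, np.ndarray] = field(default_factory=dict)  # sample -> CV% per peak
    rsd: np.ndarray = field(default_factory=lambda: np.empty(0))  # % per selected signal
    batch_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pairwise_similarity": self.pairwise_similarity.tolist(),
            "fraction_above_0p9": self.fraction_above_0p9,
            "replicate_cv": {k: v.tolist() for k, v in self.replicate_cv.items()},
            "rsd": self.rsd.tolist(),
            "batch_ids": self.batch_ids,
        }


def qc_report(spectra: list[RawSpectrum], bin_width: float = 0.05,
              mz_range: tuple[float, float] = (100.0, 600.0),
              feature_matrix=None, n_rsd_signals: int = 10) -> QCReport:
    """Compute the QC statistic suite for a cohort of raw spectra.

    Pairwise cosine similarities are taken between binned, baseline-corrected
    QC acquisitions (all spectra if none are flagged QC); replicate CV is
    computed per sample on the binned intensities of the strongest bins; RSD
    is computed on the top ``n_rsd_signals`` columns of the post-preprocessing
    feature matrix when one is supplied.
    """
    from .preprocess import PreprocessConfig, bin_spectrum, baseline_tophat

    cfg = PreprocessConfig(bin_width=bin_width, mz_range=mz_range)
    qcs = [s for s in spectra if s.is_qc] or list(spectra)
    binned = [baseline_tophat(bin_spectrum(s, cfg.bin_width, cfg.mz_range), cfg.element_width)
              for s in qcs]
    sims = []
    for i in range(len(binned)):
        for j in range(i + 1, len(binned)):
            sims.append(cosine_similarity(binned[i].intensity, binned[j].intensity))
    sims = np.array(sims)
    frac = float(np.mean(sims > 0.9)) if len(sims) else float("nan")

    cvs: dict[str, np.ndarray] = {}
    by_sample: dict[str, list[np.ndarray]] = {}
    for s in spectra:
        if not s.is_qc:
            bs = baseline_tophat(bin_spectrum(s, cfg.bin_width, cfg.mz_range), cfg.element_width)
            by_sample.setdefault(s.sample_id, []).append(bs.intensity)
    for sid, reps in by_sample.items():
        if len(reps) < 2:
            continue
        arr = np.array(reps)
        strongest = np.argsort(arr.mean(axis=0))[-4:]  # four reference peaks
        cvs[sid] = replicate_cv(arr[:, strongest])

    rsd_vals = np.empty(0)
    if feature_matrix is not None and feature_matrix.n_signals:
        top = np.argsort(feature_matrix.values.mean(axis=0))[-n_rsd_signals:]
        rsd_vals = rsd(feature_matrix.values[:, top])

    return QCReport(
        pairwise_similarity=sims,
        fraction_above_0p9=frac,
        replicate_cv=cvs,
        rsd=rsd_vals,
        batch_ids=sorted({s.batch for s in spectra if s.batch}),
    )
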