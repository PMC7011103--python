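"""Readers and writers for the pipeline's plain-text formats.

Feature tables are CSV (feature_id, mz, rt_min, then one intensity column
per sample). MS/MS spectra are accepted as MGF (PEPMASS and RTINSECONDS
honored) or as a minimal centroided mzML subset (MS2 scans only). A small
YAML run configuration carries tolerances and pipeline parameters; unknown
keys are rejected so typos cannot silently fall back to defaults.

The MGF and mzML codecs are implemented here with the standard library:
the usual proteomics parsers are not available in the supported runtime.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .annotate import MS1Feature, MsmsSpectrum

__all__ = [
    "FormatError",
    "RunConfig",
    "read_feature_table",
    "write_feature_table",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "write_mzml",
    "read_spectra",
]


class FormatError(ValueError):
    """A file did not conform to the documented schema."""


_FEATURE_REQUIRED = ["feature_id", "mz", "rt_min"]


def read_feature_table(path) -> list[MS1Feature]:
    """Read a feature CSV; malformed rows are reported with line numbers."""
    df = pd.read_csv(path, dtype={"feature_id": str})
    missing = [c for c in _FEATURE_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    sample_cols = [c for c in df.columns if c not in _FEATURE_REQUIRED]
    features = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = row._asdict()
        try:
            mz = float(rec["mz"])
            rt = float(rec["rt_min"])
            intensities = {s: float(rec[s]) for s in sample_cols}
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {pos}: non-numeric value ({exc})") from None
        features.append(
            MS1Feature(
                feature_id=str(rec["feature_id"]),
                mz=mz,
                rt=rt,
                intensities=intensities,
            )
        )
    return features


def write_feature_table(features: Sequence[MS1Feature], path) -> None:
    """Write features as CSV with a stable sample-column order."""
    sample_cols = sorted({s for f in features for s in f.intensities})
    rows = []
    for f in features:
        row = {"feature_id": f.feature_id, "mz": repr(f.mz), "rt_min": repr(f.rt)}
        row.update({s: repr(f.intensities.get(s, 0.0)) for s in sample_cols})
        rows.append(row)
    pd.DataFrame(rows, columns=_FEATURE_REQUIRED + sample_cols).to_csv(path, index=False)


def read_mgf(path) -> list[MsmsSpectrum]:
    """Parse an MGF peak list; RTINSECONDS is converted to minutes."""
    spectra = []
    block = None
    block_index = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                block_index += 1
                block = {"peaks": []}
                continue
            if line == "END IONS":
                if block is None:
                    raise FormatError(f"{path}: line {lineno}: END IONS without BEGIN IONS")
                try:
                    spectra.append(
                        MsmsSpectrum(
                            precursor_mz=block["pepmass"],
                            rt=block.get("rt_s", 0.0) / 60.0,
                            peaks=tuple(block["peaks"]),
                        )
                    )
                except KeyError as exc:
                    raise FormatError(
                        f"{path}: block {block_index}: missing {exc.args[0].upper()}"
                    ) from None
                block = None
                continue
            if block is None:
                continue  # headers outside blocks are ignored
            if "=" in line:
                key, _, value = line.partition("=")
                key = key.strip().upper()
                try:
                    if key == "PEPMASS":
                        block["pepmass"] = float(value.split()[0])
                    elif key == "RTINSECONDS":
                        block["rt_s"] = float(value)
                except ValueError:
                    raise FormatError(
                        f"{path}: block {block_index}: bad {key} value {value!r}"
                    ) from None
                continue
            parts = line.split()
            try:
                block["peaks"].append((float(parts[0]), float(parts[1])))
            except (IndexError, ValueError):
                raise FormatError(
                    f"{path}: block {block_index}: bad peak line {line!r}"
                ) from None
    if block is not None:
        raise FormatError(f"{path}: unterminated BEGIN IONS block {block_index}")
    return spectra


def write_mgf(spectra: Sequence[MsmsSpectrum], path) -> None:
    with open(path, "w") as fh:
        for i, spec in enumerate(spectra, start=1):
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE=spectrum_{i}\n")
            fh.write(f"PEPMASS={spec.precursor_mz!r}\n")
            fh.write(f"RTINSECONDS={spec.rt * 60.0!r}\n")
            for m, inten in spec.peaks:
                fh.write(f"{m!r} {inten!r}\n")
            fh.write("END IONS\n")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(elem) -> list[float]:
    dtype = "d"
    compressed = False
    data_text = ""
    for child in elem.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "f"
            elif acc == "MS:1000523":
                dtype = "d"
            elif acc == "MS:1000574":
                compressed = True
        elif tag == "binary" and child.text:
            data_text = child.text.strip()
    raw = base64.b64decode(data_text) if data_text else b""
    if compressed and raw:
        raw = zlib.decompress(raw)
    n = len(raw) // struct.calcsize(dtype)
    return list(struct.unpack(f"<{n}{dtype}", raw[: n * struct.calcsize(dtype)]))


def read_mzml(path) -> list[MsmsSpectrum]:
    """Read MS2 scans from a minimal centroided mzML file."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not well-formed XML ({exc})") from None
    spectra = []
    for idx, spectrum in enumerate(
        (e for e in tree.iter() if _local(e.tag) == "spectrum"), start=1
    ):
        ms_level = None
        precursor = None
        rt_min = 0.0
        mz_array: list[float] = []
        int_array: list[float] = []
        for elem in spectrum.iter():
            tag = _local(elem.tag)
            if tag == "cvParam":
                acc = elem.get("accession", "")
                if acc == "MS:1000511":
                    ms_level = int(elem.get("value", "0"))
                elif acc == "MS:1000016":
                    value = float(elem.get("value", "0"))
                    unit = elem.get("unitName", "minute")
                    rt_min = value / 60.0 if unit.lower() == "second" else value
                elif acc == "MS:1000744":
                    precursor = float(elem.get("value", "0"))
            elif tag == "binaryDataArray":
                accs = {
                    c.get("accession")
                    for c in elem.iter()
                    if _local(c.tag) == "cvParam"
                }
                values = _decode_binary(elem)
                if "MS:1000514" in accs:
                    mz_array = values
                elif "MS:1000515" in accs:
                    int_array = values
        if ms_level != 2:
            continue
        if precursor is None:
            raise FormatError(f"{path}: MS2 spectrum #{idx} lacks a selected-ion m/z")
        if len(mz_array) != len(int_array):
            raise FormatError(f"{path}: spectrum #{idx}: m/z and intensity arrays differ")
        spectra.append(
            MsmsSpectrum(
                precursor_mz=precursor,
                rt=rt_min,
                peaks=tuple(zip(mz_array, int_array)),
            )
        )
    return spectra


def write_mzml(spectra: Sequence[MsmsSpectrum], path) -> None:
    """Write a minimal MS2-only mzML (64-bit, uncompressed)."""

    def b64(values) -> str:
        return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()

    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        f'  <run id="run1"><spectrumList count="{len(spectra)}">',
    ]
    for i, spec in enumerate(spectra):
        mzs = [m for m, _ in spec.peaks]
        ints = [x for _, x in spec.peaks]
        lines += [
            f'    <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mzs)}">',
            '      <cvParam accession="MS:1000511" name="ms level" value="2"/>',
            "      <scanList><scan>",
            f'        <cvParam accession="MS:1000016" name="scan start time" value="{spec.rt * 60.0!r}" unitName="second"/>',
            "      </scan></scanList>",
            "      <precursorList><precursor><selectedIonList><selectedIon>",
            f'        <cvParam accession="MS:1000744" name="selected ion m/z" value="{spec.precursor_mz!r}"/>',
            "      </selectedIon></selectedIonList></precursor></precursorList>",
            '      <binaryDataArrayList count="2">',
            "        <binaryDataArray>",
            '          <cvParam accession="MS:1000523" name="64-bit float"/>',
            '          <cvParam accession="MS:1000576" name="no compression"/>',
            '          <cvParam accession="MS:1000514" name="m/z array"/>',
            f"          <binary>{b64(mzs)}</binary>",
            "        </binaryDataArray>",
            "        <binaryDataArray>",
            '          <cvParam accession="MS:1000523" name="64-bit float"/>',
            '          <cvParam accession="MS:1000576" name="no compression"/>',
            '          <cvParam accession="MS:1000515" name="intensity array"/>',
            f"          <binary>{b64(ints)}</binary>",
            "        </binaryDataArray>",
            "      </binaryDataArrayList>",
            "    </spectrum>",
        ]
    lines += ["  </spectrumList></run>", "</mzML>"]
    Path(path).write_text("\n".join(lines))


def read_spectra(path) -> list[MsmsSpectrum]:
    """Dispatch on extension: .mgf or .mzml/.xml."""
    suffix = Path(path).suffix.lower()
    if suffix == ".mgf":
        return read_mgf(path)
    if suffix in (".mzml", ".xml"):
        return read_mzml(path)
    raise FormatError(f"unsupported spectra format: {path}")


@dataclass
class RunConfig:
    """Pipeline parameters; defaults follow the documented workflow."""

    ms1_tol_ppm: float = 5.0
    ms2_tol_ppm: float = 10.0
    rt_window_min: float = 0.2
    mz_min: float = 100.0
    mz_max: float = 1600.0
    rt_min: float = 0.5
    rt_max: float = 16.0
    noise_threshold: float = 300.0
    min_samples_per_group: int = 3
    require_isotope_partner: bool = True
    eicc_width_ppm: float = 100.0
    noise_pct: float = 40.0
    smooth_points: float = 2.0
    cv_max: float = 25.0
    equal_var: bool = True
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("ms1_tol_ppm", "ms2_tol_ppm", "rt_window_min", "eicc_width_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
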