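"""File formats: jMRUI plain-text FIDs and a JSON dialect.

The jMRUI text dialect stores one or more FIDs with a key/value header
(``PointsInDataset``, ``SamplingInterval`` in ms, ``TransmitterFrequency`` in
Hz, ...) followed by two tab-separated columns of real/imaginary samples per
signal. TR/TE, the ppm reference and the ON/OFF/block tags — which the
original header has no slots for — travel in an ``AdditionalInfo`` line so
the round trip is lossless within float-text precision.

The JSON dialect mirrors the FID type directly and round-trips bit-exactly
(Python float repr is shortest-exact).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .core import FID, AcquisitionParams

__all__ = ["read_jmrui_text", "write_jmrui_text", "read_fid_json", "write_fid_json", "ParseError"]


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number where parsing failed."""

    def __init__(self, message: str, path, line: Optional[int] = None):
        loc = f"{path}" + (f":{line}" if line is not None else "")
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.line = line


def write_jmrui_text(fids: Sequence[FID], path: Union[str, Path]) -> None:
    """Write FIDs sharing one set of acquisition parameters to a jMRUI text file."""
    fids = list(fids)
    if not fids:
        raise ValueError("no FIDs to write")
    params = fids[0].params
    for f in fids:
        if f.params != params:
            raise ValueError("all FIDs in one jMRUI file must share acquisition parameters")
    labels = ",".join(f.label for f in fids)
    blocks = ",".join("" if f.block_index is None else str(f.block_index) for f in fids)
    lines = [
        "jMRUI Data Textfile",
        "",
        f"Filename: {Path(path).name}",
        "",
        f"PointsInDataset: {params.n_points}",
        f"DatasetsInFile: {len(fids)}",
        f"SamplingInterval: {params.dwell_s * 1e3!r}",
        "ZeroOrderPhase: 0",
        "BeginTime: 0",
        f"TransmitterFrequency: {params.f0_mhz * 1e6!r}",
        "MagneticField: 3",
        "TypeOfNucleus: 1H",
        f"AdditionalInfo: TR={params.tr_ms!r};TE={params.te_ms!r};"
        f"CenterPPM={params.center_ppm!r};Labels={labels};Blocks={blocks}",
        "",
        "Signal and FFT",
        "sig(real)\tsig(imag)",
    ]
    for i, fid in enumerate(fids, start=1):
        lines.append(f"Signal {i} out of {len(fids)} in file")
        for z in fid.samples:
            lines.append(f"{float(z.real)!r}\t{float(z.imag)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_additional_info(text: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for item in text.split(";"):
        if "=" in item:
            key, val = item.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def read_jmrui_text(path: Union[str, Path]) -> List[FID]:
    """Read all FIDs from a jMRUI text file written by :func:`write_jmrui_text`."""
    path = Path(path)
    raw = path.read_text().splitlines()
    header: Dict[str, str] = {}
    data_start = None
    for lineno, line in enumerate(raw, start=1):
        if line.strip().startswith("Signal and FFT") or line.strip().startswith("sig(real)"):
            data_start = lineno
            continue
        if data_start is None and ":" in line:
            key, val = line.split(":", 1)
            header[key.strip()] = val.strip()
    for required in ("PointsInDataset", "SamplingInterval", "TransmitterFrequency"):
        if required not in header:
            raise ParseError(f"missing required header key {required!r}", path)

    n_points = int(header["PointsInDataset"])
    dwell_ms = float(header["SamplingInterval"])
    f0_hz = float(header["TransmitterFrequency"])
    n_sets = int(header.get("DatasetsInFile", "1"))
    info = _parse_additional_info(header.get("AdditionalInfo", ""))
    params = AcquisitionParams(
        tr_ms=float(info.get("TR", 2000.0)),
        te_ms=float(info.get("TE", 68.0)),
        bandwidth_hz=1.0 / (dwell_ms * 1e-3),
        n_points=n_points,
        f0_mhz=f0_hz / 1e6,
        center_ppm=float(info.get("CenterPPM", 4.7)),
    )
    labels = info.get("Labels", "").split(",") if info.get("Labels") else []
    blocks = info.get("Blocks", "").split(",") if "Blocks" in info else []

    fids: List[FID] = []
    current: List[complex] = []
    signal_no = 0

    def _flush(lineno: int) -> None:
        nonlocal current, signal_no
        if signal_no == 0:
            return
        if len(current) != n_points:
            raise ParseError(
                f"signal {signal_no} has {len(current)} samples, expected {n_points} "
                "(truncated file?)",
                path,
                lineno,
            )
        label = labels[signal_no - 1] if signal_no <= len(labels) else "OFF"
        block: Optional[int] = None
        if signal_no <= len(blocks) and blocks[signal_no - 1] != "":
            block = int(blocks[signal_no - 1])
        fids.append(FID(samples=np.array(current), params=params, label=label or "OFF",
                        block_index=block))
        current = []

    in_data = False
    for lineno, line in enumerate(raw, start=1):
        stripped = line.strip()
        if stripped.startswith("Signal ") and " out of " in stripped:
            _flush(lineno)
            signal_no += 1
            in_data = True
            continue
        if not in_data or not stripped or stripped.startswith("sig("):
            continue
        parts = stripped.split()
        if len(parts) < 2:
            raise ParseError(f"expected two columns, got {stripped!r}", path, lineno)
        try:
            current.append(complex(float(parts[0]), float(parts[1])))
        except ValueError:
            raise ParseError(f"non-numeric sample {stripped!r}", path, lineno) from None
    _flush(len(raw))
    if len(fids) != n_sets:
        raise ParseError(
            f"header promises {n_sets} signals but file contains {len(fids)} "
            "(truncated file?)",
            path,
        )
    return fids


def write_fid_json(fids: Sequence[FID], path: Union[str, Path]) -> None:
    """Write FIDs to the package's JSON dialect (bit-exact round trip)."""
    fids = list(fids)
    if not fids:
        raise ValueError("no FIDs to write")
    params = fids[0].params
    doc = {
        "format": "gabaquant-fid",
        "version": 1,
        "params": {
            "tr_ms": params.tr_ms,
            "te_ms": params.te_ms,
            "bandwidth_hz": params.bandwidth_hz,
            "n_points": params.n_points,
            "f0_mhz": params.f0_mhz,
            "center_ppm": params.center_ppm,
        },
        "fids": [
            {
                "label": f.label,
                "block_index": f.block_index,
                "real": f.samples.real.tolist(),
                "imag": f.samples.imag.tolist(),
            }
            for f in fids
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_fid_json(path: Union[str, Path]) -> List[FID]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc.msg}", path, exc.lineno) from None
    if doc.get("format") != "gabaquant-fid":
        raise ParseError("not a gabaquant-fid JSON file", path)
    params = AcquisitionParams(**doc["params"])
    return [
        FID(
            samples=np.array(entry["real"]) + 1j * np.array(entry["imag"]),
            params=params,
            label=entry["label"],
            block_index=entry["block_index"],
        )
        for entry in doc["fids"]
    ]
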