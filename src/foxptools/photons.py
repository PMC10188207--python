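"""Time-tagged photon streams and their on-disk layouts.

A stream is three aligned arrays — macrotime (ns since acquisition start),
microtime (ns within the excitation period) and detection channel — plus
metadata.  Channels combine color and polarization: donor parallel (Dp),
donor perpendicular (Ds), acceptor parallel (Ap), acceptor perpendicular
(As).  Acceptor-excitation photons (for stoichiometry) are encoded PIE-style
in the second half of the microtime period.

Two documented layouts round-trip losslessly:

* TSV — commented ``# key\tvalue`` header, then columns
  ``macrotime_ns``, ``microtime_ns``, ``channel``;
* HDF5 — datasets ``/photons/{macrotime,microtime,channel}`` with metadata
  as attributes of ``/meta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

CHANNELS = ("Dp", "Ds", "Ap", "As")
CHANNEL_CODE = {label: i for i, label in enumerate(CHANNELS)}


class StreamSchemaError(ValueError):
    """Raised when a photon-stream file violates the documented layout."""


@dataclass
class PhotonStream:
    """Time-tagged photons with polarization/color channels."""

    macrotime_ns: np.ndarray
    microtime_ns: np.ndarray
    channel: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.macrotime_ns = np.asarray(self.macrotime_ns, dtype=np.float64)
        self.microtime_ns = np.asarray(self.microtime_ns, dtype=np.float64)
        self.channel = np.asarray(self.channel, dtype=np.int8)
        n = self.macrotime_ns.size
        if self.microtime_ns.size != n or self.channel.size != n:
            raise StreamSchemaError("photon arrays must have equal length")
        if n and np.any(np.diff(self.macrotime_ns) < 0):
            raise StreamSchemaError("macrotimes must be nondecreasing")
        if np.any(self.channel < 0) or np.any(self.channel >= len(CHANNELS)):
            raise StreamSchemaError("channel codes must index Dp/Ds/Ap/As")
        period = self.meta.get("excitation_period_ns")
        if period is not None and n and np.any(self.microtime_ns >= period):
            raise StreamSchemaError("microtime must be < excitation period")
        if n and np.any(self.microtime_ns < 0):
            raise StreamSchemaError("microtime must be non-negative")

    def __len__(self) -> int:
        return self.macrotime_ns.size

    @property
    def g_factor(self) -> float:
        return float(self.meta.get("g_factor", 1.0))

    @property
    def excitation_period_ns(self) -> float:
        return float(self.meta.get("excitation_period_ns", 50.0))

    def duration_ns(self) -> float:
        declared = self.meta.get("duration_ns")
        if declared is not None:
            return float(declared)
        return float(self.macrotime_ns[-1]) if len(self) else 0.0

    def select(self, mask: np.ndarray) -> "PhotonStream":
        return PhotonStream(
            macrotime_ns=self.macrotime_ns[mask],
            microtime_ns=self.microtime_ns[mask],
            channel=self.channel[mask],
            meta=dict(self.meta),
        )

    def channel_mask(self, labels) -> np.ndarray:
        codes = [CHANNEL_CODE[l] for l in labels]
        return np.isin(self.channel, codes)


def _encode_meta(meta: dict) -> dict:
    out = {}
    for key, value in meta.items():
        if isinstance(value, (dict, list, tuple)):
            out[key] = json.dumps(value)
        else:
            out[key] = value
    return out


def _decode_value(value):
    if isinstance(value, bytes):
        value = value.decode()
    if isinstance(value, str):
        try:
            return json.loads(value)
        except (json.JSONDecodeError, ValueError):
            return value
    if isinstance(value, np.generic):
        return value.item()
    return value


def write_stream(stream: PhotonStream, path, format: str | None = None) -> None:
    """Write a stream to TSV or HDF5 (format inferred from suffix)."""
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "tsv")
    if fmt == "tsv":
        lines = [f"# {k}\t{v}" for k, v in _encode_meta(stream.meta).items()]
        frame = pd.DataFrame(
            {
                "macrotime_ns": stream.macrotime_ns,
                "microtime_ns": stream.microtime_ns,
                "channel": [CHANNELS[c] for c in stream.channel],
            }
        )
        path.write_text(
            "\n".join(lines)
            + ("\n" if lines else "")
            + frame.to_csv(sep="\t", index=False, lineterminator="\n", float_format="%.17g")
        )
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            grp = fh.create_group("photons")
            grp.create_dataset("macrotime", data=stream.macrotime_ns)
            grp.create_dataset("microtime", data=stream.microtime_ns)
            grp.create_dataset("channel", data=stream.channel)
            meta = fh.create_group("meta")
            for key, value in _encode_meta(stream.meta).items():
                meta.attrs[key] = value
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_stream(path, format: str | None = None) -> PhotonStream:
    """Read a stream from TSV or HDF5, validating the documented schema."""
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "tsv")
    if fmt == "tsv":
        meta = {}
        header_lines = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                header_lines += 1
                key, _, value = line[1:].strip().partition("\t")
                meta[key.strip()] = _decode_value(value)
        frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        required = {"macrotime_ns", "microtime_ns", "channel"}
        missing = required - set(frame.columns)
        if missing:
            raise StreamSchemaError(
                f"{path}: missing columns {sorted(missing)} "
                f"(header ends at line {header_lines + 1})"
            )
        bad = ~frame["channel"].isin(CHANNELS)
        if bad.any():
            line_no = int(np.nonzero(bad.to_numpy())[0][0]) + header_lines + 2
            raise StreamSchemaError(
                f"{path}:{line_no}: unknown channel {frame['channel'][bad].iloc[0]!r}"
            )
        macro = frame["macrotime_ns"].to_numpy(dtype=np.float64)
        if macro.size and np.any(np.diff(macro) < 0):
            row = int(np.nonzero(np.diff(macro) < 0)[0][0])
            raise StreamSchemaError(
                f"{path}:{row + header_lines + 3}: macrotimes out of order"
            )
        return PhotonStream(
            macrotime_ns=macro,
            microtime_ns=frame["microtime_ns"].to_numpy(dtype=np.float64),
            channel=np.array(
                [CHANNEL_CODE[c] for c in frame["channel"]], dtype=np.int8
            ),
            meta=meta,
        )
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            if "photons" not in fh:
                raise StreamSchemaError(f"{path}: missing /photons group")
            grp = fh["photons"]
            for name in ("macrotime", "microtime", "channel"):
                if name not in grp:
                    raise StreamSchemaError(f"{path}: missing /photons/{name}")
            meta = {}
            if "meta" in fh:
                for key, value in fh["meta"].attrs.items():
                    meta[key] = _decode_value(value)
            macro = grp["macrotime"][:]
            if macro.size and np.any(np.diff(macro) < 0):
                raise StreamSchemaError(f"{path}: macrotimes out of order")
            return PhotonStream(
                macrotime_ns=macro,
                microtime_ns=grp["microtime"][:],
                channel=grp["channel"][:],
                meta=meta,
            )
    raise ValueError(f"unknown format {fmt!r}")
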