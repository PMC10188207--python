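"""Tabular containers for titration and unfolding experiments.

Both containers round-trip through TSV with a commented ``# key\tvalue``
header so that generator provenance (construct, seed, generating parameters)
travels with the data.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def _meta_header(meta: dict) -> str:
    lines = []
    for key, value in meta.items():
        if isinstance(value, (dict, list)):
            value = json.dumps(value)
        lines.append(f"# {key}\t{value}")
    return "\n".join(lines)


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "\t" in body:
                key, _, value = body.partition("\t")
                try:
                    value = json.loads(value)
                except (json.JSONDecodeError, ValueError):
                    pass
                meta[key.strip()] = value
    return meta


@dataclass
class TitrationCurve:
    """Concentration vs anisotropy pairs for a binding/dimerization assay."""

    conc_nm: np.ndarray
    signal: np.ndarray
    sd: np.ndarray | None = None
    construct: str = ""
    temperature_k: float = 310.15
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.conc_nm = np.asarray(self.conc_nm, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.conc_nm.shape != self.signal.shape:
            raise ValueError("conc_nm and signal must have identical shapes")
        if np.any(self.conc_nm < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return self.conc_nm.size

    def to_tsv(self, path) -> None:
        meta = {
            "construct": self.construct,
            "temperature_K": self.temperature_k,
            **self.meta,
        }
        frame = pd.DataFrame({"conc_nM": self.conc_nm, "signal": self.signal})
        if self.sd is not None:
            frame["sd"] = self.sd
        buf = io.StringIO()
        frame.to_csv(buf, sep="\t", index=False, lineterminator="\n", float_format="%.17g")
        Path(path).write_text(_meta_header(meta) + "\n" + buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "TitrationCurve":
        meta = _read_meta(path)
        frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        construct = str(meta.pop("construct", ""))
        temperature = float(meta.pop("temperature_K", 310.15))
        sd = frame["sd"].to_numpy() if "sd" in frame else None
        return cls(
            conc_nm=frame["conc_nM"].to_numpy(),
            signal=frame["signal"].to_numpy(),
            sd=sd,
            construct=construct,
            temperature_k=temperature,
            meta=meta,
        )


@dataclass
class UnfoldingCurve:
    """Denaturant molarity vs signal pairs for a chemical unfolding assay."""

    denaturant_m: np.ndarray
    signal: np.ndarray
    mechanism: str = "dimer2"
    p_total_nm: float | None = None
    sd: np.ndarray | None = None
    construct: str = ""
    temperature_k: float = 298.15
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.denaturant_m = np.asarray(self.denaturant_m, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.denaturant_m.shape != self.signal.shape:
            raise ValueError("denaturant_m and signal must have identical shapes")
        if self.mechanism.startswith("dimer") and not self.p_total_nm:
            raise ValueError("dimer mechanisms require p_total_nm")

    def __len__(self) -> int:
        return self.denaturant_m.size

    def to_tsv(self, path) -> None:
        meta = {
            "construct": self.construct,
            "mechanism": self.mechanism,
            "p_total_nM": self.p_total_nm,
            "temperature_K": self.temperature_k,
            **self.meta,
        }
        frame = pd.DataFrame(
            {"denaturant_M": self.denaturant_m, "signal": self.signal}
        )
        if self.sd is not None:
            frame["sd"] = self.sd
        buf = io.StringIO()
        frame.to_csv(buf, sep="\t", index=False, lineterminator="\n", float_format="%.17g")
        Path(path).write_text(_meta_header(meta) + "\n" + buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "UnfoldingCurve":
        meta = _read_meta(path)
        frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        p_total = meta.pop("p_total_nM", None)
        return cls(
            denaturant_m=frame["denaturant_M"].to_numpy(),
            signal=frame["signal"].to_numpy(),
            mechanism=str(meta.pop("mechanism", "dimer2")),
            p_total_nm=None if p_total in (None, "None", "") else float(p_total),
            sd=frame["sd"].to_numpy() if "sd" in frame else None,
            construct=str(meta.pop("construct", "")),
            temperature_k=float(meta.pop("temperature_K", 298.15)),
            meta=meta,
        )
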