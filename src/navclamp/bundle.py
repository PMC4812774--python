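"""Sweep-bundle container and HDF5 persistence.

A bundle holds everything recorded from one cell: the voltage protocols,
the main sweeps, their P/N subpulse families, the capacitance test pulse,
and provenance (recording metadata + simulator configuration).  On disk it
is an HDF5 file with embedded JSON metadata; traces are stored either as
float64 (lossless) or int16 with a declared scale quantum (pA per count).
A SHA-256 checksum over all stored trace bytes guards against truncation.

Format notes: sample indexing is 0-based; times are ms from sweep start;
all command potentials are junction-corrected mV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .protocols import RecordingMetadata, Sweep, VoltageProtocol
from .simulator import SimulatorConfig

__all__ = [
    "SweepBundle",
    "BundleIntegrityError",
    "write_bundle",
    "read_bundle",
    "results_to_dataframe",
    "write_results_csv",
]

SCHEMA_VERSION = 1


class BundleIntegrityError(Exception):
    """Raised when a bundle file fails schema or checksum validation."""


@dataclass
class SweepBundle:
    metadata: RecordingMetadata
    config: SimulatorConfig
    protocols: dict[str, VoltageProtocol]
    main_sweeps: dict[str, list[Sweep]]
    subpulse_sweeps: dict[str, list[list[Sweep]]]
    test_pulse: Sweep
    test_pulse_delta_mv: float

    def __post_init__(self):
        for name in self.main_sweeps:
            if name not in self.protocols:
                raise ValueError(f"sweeps reference unknown protocol {name!r}")


def _encode(traces: np.ndarray, storage: str, scale: float):
    if storage == "float":
        return traces.astype(np.float64)
    if storage == "int16":
        codes = np.round(traces / scale)
        if np.any(np.abs(codes) > 32767):
            raise ValueError("trace exceeds int16 range at the declared scale")
        return codes.astype(np.int16)
    raise ValueError("storage must be 'float' or 'int16'")


def _decode(data: np.ndarray, scale: float) -> np.ndarray:
    if data.dtype == np.int16:
        return data.astype(np.float64) * scale
    return np.asarray(data, dtype=np.float64)


def write_bundle(
    bundle: SweepBundle,
    path,
    storage: str = "float",
    int16_scale_pa: float = 0.5,
) -> None:
    """Serialize a bundle; float storage round-trips bit-exactly, int16
    storage is lossy only by the declared scale quantum (max error scale/2)."""
    digest = hashlib.sha256()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["storage"] = storage
        f.attrs["int16_scale_pa"] = int16_scale_pa
        f.attrs["metadata"] = json.dumps(dataclasses.asdict(bundle.metadata))
        f.attrs["config"] = json.dumps(dataclasses.asdict(bundle.config))
        f.attrs["test_pulse_delta_mv"] = bundle.test_pulse_delta_mv
        f.attrs["subpulse_convention"] = (
            "P/N subpulses: command deviation scaled by -1/N from a "
            "hyperpolarized subpulse holding level; scale stored per protocol"
        )
        pg = f.create_group("protocols")
        for name, proto in bundle.protocols.items():
            pg.attrs[name] = proto.to_json()
        tg = f.create_group("traces")
        for name, mains in bundle.main_sweeps.items():
            g = tg.create_group(name)
            cur = np.stack([s.current for s in mains])
            cmd = np.stack([s.command_voltage for s in mains])
            enc = _encode(cur, storage, int16_scale_pa)
            g.create_dataset("main_current", data=enc)
            g.create_dataset("main_command", data=cmd)
            digest.update(np.ascontiguousarray(enc).tobytes())
            subs = bundle.subpulse_sweeps.get(name, [])
            if subs:
                sub_cur = np.stack([[s.current for s in fam] for fam in subs])
                sub_cmd = np.stack([fam[0].command_voltage for fam in subs])
                enc_s = _encode(sub_cur, storage, int16_scale_pa)
                g.create_dataset("sub_current", data=enc_s)
                g.create_dataset("sub_command", data=sub_cmd)
                g.attrs["sub_scale"] = subs[0][0].subpulse_scale
                digest.update(np.ascontiguousarray(enc_s).tobytes())
        tp = tg.create_group("test_pulse")
        enc_tp = _encode(bundle.test_pulse.current[None, :], storage, int16_scale_pa)
        tp.create_dataset("current", data=enc_tp)
        tp.create_dataset("command", data=bundle.test_pulse.command_voltage)
        digest.update(np.ascontiguousarray(enc_tp).tobytes())
        f.attrs["sha256"] = digest.hexdigest()


def read_bundle(path) -> SweepBundle:
    """Load and validate a bundle; raises :class:`BundleIntegrityError` on
    schema mismatch, checksum failure or truncation (never a partial object)."""
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("schema_version", -1))
            if version != SCHEMA_VERSION:
                raise BundleIntegrityError(
                    f"unsupported bundle schema version {version}"
                )
            scale = float(f.attrs["int16_scale_pa"])
            meta_doc = json.loads(f.attrs["metadata"])
            cfg_doc = json.loads(f.attrs["config"])
            expected = f.attrs["sha256"]
            digest = hashlib.sha256()
            protocols = {
                name: VoltageProtocol.from_json(f["protocols"].attrs[name])
                for name in f["protocols"].attrs
            }
            main_sweeps: dict[str, list[Sweep]] = {}
            subpulse_sweeps: dict[str, list[list[Sweep]]] = {}
            tg = f["traces"]
            for name in protocols:
                if name not in tg:
                    continue
                g = tg[name]
                enc = g["main_current"][...]
                digest.update(np.ascontiguousarray(enc).tobytes())
                cur = _decode(enc, scale)
                cmd = g["main_command"][...]
                main_sweeps[name] = [
                    Sweep(cur[k], cmd[k], k) for k in range(cur.shape[0])
                ]
                if "sub_current" in g:
                    enc_s = g["sub_current"][...]
                    digest.update(np.ascontiguousarray(enc_s).tobytes())
                    sub_cur = _decode(enc_s, scale)
                    sub_cmd = g["sub_command"][...]
                    s_scale = float(g.attrs["sub_scale"])
                    subpulse_sweeps[name] = [
                        [
                            Sweep(sub_cur[k, j], sub_cmd[k], k, is_subpulse=True,
                                  subpulse_scale=s_scale)
                            for j in range(sub_cur.shape[1])
                        ]
                        for k in range(sub_cur.shape[0])
                    ]
            tp = tg["test_pulse"]
            enc_tp = tp["current"][...]
            digest.update(np.ascontiguousarray(enc_tp).tobytes())
            test_pulse = Sweep(_decode(enc_tp, scale)[0], tp["command"][...], 0)
            delta = float(f.attrs["test_pulse_delta_mv"])
            if digest.hexdigest() != expected:
                raise BundleIntegrityError("bundle checksum mismatch")
    except (OSError, KeyError) as exc:
        raise BundleIntegrityError(f"unreadable bundle file: {exc}") from exc
    return SweepBundle(
        metadata=RecordingMetadata(**meta_doc),
        config=SimulatorConfig(**cfg_doc),
        protocols=protocols,
        main_sweeps=main_sweeps,
        subpulse_sweeps=subpulse_sweeps,
        test_pulse=test_pulse,
        test_pulse_delta_mv=delta,
    )


def results_to_dataframe(cell_results) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in cell_results])


def write_results_csv(cell_results, path) -> None:
    # 6 significant digits keeps diffs stable across platforms
    results_to_dataframe(cell_results).to_csv(path, index=False, float_format="%.6g")
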