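"""DTOF container file format (HDF5) and tabular export.

Layout (format version 1.0)::

    /                  attrs: format_version
    /config            attrs: n_bins, bin_width_ps, rep_period_ns,
                              channel_width_nm, frame_time_s
                       dataset: channel_centers_nm
    /records/NNNNN     dataset: counts
                       attrs: role ('dtof' | 'irf'), wavelength_nm, rho_cm,
                              timestamp_s, acquisition_time_s, background

All records in one container share the binning; counts round-trip
integer-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .forward import DTOF, InstrumentConfig

__all__ = [
    "FORMAT_VERSION",
    "DTOFRecord",
    "ContainerError",
    "ContainerVersionError",
    "ContainerShapeError",
    "MissingIRFError",
    "write_container",
    "read_container",
    "records_to_frame",
]

FORMAT_VERSION = "1.0"


class ContainerError(RuntimeError):
    """Base class for container format violations."""


class ContainerVersionError(ContainerError):
    pass


class ContainerShapeError(ContainerError):
    pass


class MissingIRFError(ContainerError):
    pass


@dataclass
class DTOFRecord:
    dtof: DTOF
    role: str = "dtof"              # 'dtof' | 'irf'
    timestamp: float = 0.0          # s

    def __post_init__(self):
        if self.role not in ("dtof", "irf"):
            raise ValueError("role must be 'dtof' or 'irf'")


def write_container(path, records, config: InstrumentConfig) -> None:
    """Write records to an HDF5 container, enforcing shared binning."""
    records = list(records)
    if not records:
        raise ContainerShapeError("no records to write")
    n_bins = records[0].dtof.n_bins
    bw = records[0].dtof.bin_width
    for r in records:
        if r.dtof.n_bins != n_bins or r.dtof.bin_width != bw:
            raise ContainerShapeError("all records must share n_bins and bin_width")
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        g = f.create_group("config")
        g.attrs["n_bins"] = config.n_bins
        g.attrs["bin_width_ps"] = config.bin_width
        g.attrs["rep_period_ns"] = config.rep_period
        g.attrs["channel_width_nm"] = config.channel_width
        g.attrs["frame_time_s"] = config.frame_time
        g.create_dataset("channel_centers_nm", data=np.asarray(config.channel_centers))
        recs = f.create_group("records")
        for i, r in enumerate(records):
            d = recs.create_dataset(f"{i:05d}", data=np.asarray(r.dtof.counts))
            d.attrs["role"] = r.role
            d.attrs["wavelength_nm"] = r.dtof.channel_wavelength
            d.attrs["rho_cm"] = r.dtof.rho
            d.attrs["timestamp_s"] = r.timestamp
            d.attrs["acquisition_time_s"] = r.dtof.acquisition_time
            d.attrs["background"] = r.dtof.background_level


def read_container(path, *, require_irf: bool = False):
    """Read a container back as (records, InstrumentConfig)."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ContainerVersionError(f"unsupported format version {version!r}")
        g = f["config"]
        config = InstrumentConfig(
            n_bins=int(g.attrs["n_bins"]),
            bin_width=float(g.attrs["bin_width_ps"]),
            rep_period=float(g.attrs["rep_period_ns"]),
            channel_centers=tuple(np.asarray(g["channel_centers_nm"])),
            channel_width=float(g.attrs["channel_width_nm"]),
            frame_time=float(g.attrs["frame_time_s"]),
        )
        records = []
        for name in sorted(f["records"]):
            d = f["records"][name]
            counts = np.asarray(d)
            if counts.size != config.n_bins:
                raise ContainerShapeError("record length does not match config")
            records.append(
                DTOFRecord(
                    dtof=DTOF(
                        counts=counts,
                        bin_width=config.bin_width,
                        channel_wavelength=float(d.attrs["wavelength_nm"]),
                        rho=float(d.attrs["rho_cm"]),
                        acquisition_time=float(d.attrs["acquisition_time_s"]),
                        background_level=float(d.attrs["background"]),
                    ),
                    role=str(d.attrs["role"]),
                    timestamp=float(d.attrs["timestamp_s"]),
                )
            )
    if require_irf and not any(r.role == "irf" for r in records):
        raise MissingIRFError("container holds no IRF record")
    return records, config


def records_to_frame(records) -> pd.DataFrame:
    """Tidy per-record metadata table (without the counts arrays)."""
    return pd.DataFrame(
        [
            {
                "role": r.role,
                "wavelength_nm": r.dtof.channel_wavelength,
                "rho_cm": r.dtof.rho,
                "timestamp_s": r.timestamp,
                "acquisition_time_s": r.dtof.acquisition_time,
                "total_counts": float(np.sum(r.dtof.counts)),
            }
            for r in records
        ]
    )
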