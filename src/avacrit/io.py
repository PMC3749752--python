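"""Plain-text file formats for every intermediate of the pipeline.

All tabular outputs are CSV (diffable in tests); parameters and results are
YAML/JSON structured text.  Metadata that a bare CSV cannot carry (bin width,
matrix shape, index conventions) travels in ``#``-prefixed comment lines
before the header, or in a YAML sidecar for signal matrices.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .avalanche import BinnedRaster, SignalMatrix
from .dg import DGParams
from .fss import FSSResult
from .patterns import PatternDistribution
from .thermo import ThermoCurve

__all__ = [
    "read_signal_matrix", "write_signal_matrix",
    "read_raster_csv", "write_raster_csv",
    "read_pattern_distribution", "write_pattern_distribution",
    "read_dg_params", "write_dg_params",
    "read_curves_csv", "write_curves_csv",
    "write_fss_result", "read_fss_result",
]

PathLike = Union[str, Path]


# -- signal matrices --------------------------------------------------------

def read_signal_matrix(path: PathLike, sidecar_path: PathLike) -> SignalMatrix:
    """Read a channels x samples delimited-text matrix plus its YAML sidecar.

    The sidecar must carry ``sampling_rate`` (Hz) and may carry
    ``channel_coords`` (per-channel [x, y] in mm).
    """
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh) or {}
    if "sampling_rate" not in meta:
        raise ValueError(f"sidecar {sidecar_path} is missing sampling_rate")
    coords = meta.get("channel_coords")
    if coords is not None:
        coords = np.asarray(coords, dtype=float)
        if len(coords) != values.shape[0]:
            raise ValueError("sidecar coordinate count does not match channel count")
    return SignalMatrix(values, float(meta["sampling_rate"]), coords)


def write_signal_matrix(signal: SignalMatrix, path: PathLike,
                        sidecar_path: PathLike) -> None:
    np.savetxt(path, signal.values, delimiter=",")
    meta = {"sampling_rate": float(signal.sampling_rate)}
    if signal.channel_coords is not None:
        meta["channel_coords"] = signal.channel_coords.tolist()
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh)


# -- event rasters ----------------------------------------------------------

def write_raster_csv(raster: BinnedRaster, path: PathLike) -> None:
    """Occupied (channel, bin) pairs, 0-based, with shape metadata in comments."""
    ch, b = np.nonzero(raster.occupancy)
    with open(path, "w") as fh:
        fh.write(f"# bin_width_ms={raster.bin_width_ms}\n")
        fh.write(f"# n_channels={raster.n_channels}\n")
        fh.write(f"# n_bins={raster.n_bins}\n")
        fh.write("channel,bin\n")
        for c, k in zip(ch, b):
            fh.write(f"{c},{k}\n")


def read_raster_csv(path: PathLike) -> BinnedRaster:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = float(value)
    for key in ("bin_width_ms", "n_channels", "n_bins"):
        if key not in meta:
            raise ValueError(f"raster CSV {path} is missing '# {key}=' metadata")
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != ["channel", "bin"]:
        raise ValueError("raster CSV must have header 'channel,bin'")
    occ = np.zeros((int(meta["n_channels"]), int(meta["n_bins"])), dtype=bool)
    if len(df):
        occ[df["channel"].to_numpy(), df["bin"].to_numpy()] = True
    return BinnedRaster(occ, meta["bin_width_ms"])


# -- pattern distributions --------------------------------------------------

def write_pattern_distribution(dist: PatternDistribution, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# pattern_index bit j set <=> channel j active; "
                 "channel 0 = least significant bit; index 0 = quiescent state\n")
        fh.write(f"# n_units={dist.n_units}\n")
        fh.write("pattern_index,probability\n")
        for i, p in enumerate(dist.probabilities):
            fh.write(f"{i},{float(p)!r}\n")


def read_pattern_distribution(path: PathLike) -> PatternDistribution:
    n_units = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "n_units=" in line:
                n_units = int(line.split("n_units=")[1])
    if n_units is None:
        raise ValueError(f"{path} is missing '# n_units=' metadata")
    df = pd.read_csv(path, comment="#")
    probs = np.zeros(2**n_units)
    probs[df["pattern_index"].to_numpy()] = df["probability"].to_numpy()
    return PatternDistribution(probs, n_units)


# -- DG parameters ----------------------------------------------------------

def write_dg_params(params: DGParams, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"delta": params.delta.tolist(),
                        "Lambda": params.Lambda.tolist()}, fh)


def read_dg_params(path: PathLike) -> DGParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return DGParams(np.asarray(data["delta"]), np.asarray(data["Lambda"]))


# -- thermodynamic curves ---------------------------------------------------

def write_curves_csv(curves: list[ThermoCurve], path: PathLike) -> None:
    rows = []
    for c in curves:
        for T, v in zip(c.T_grid, c.values):
            rows.append((c.quantity, c.system_size, T, v))
    pd.DataFrame(rows, columns=["quantity", "n", "T", "value"]).to_csv(
        path, index=False)


def read_curves_csv(path: PathLike) -> list[ThermoCurve]:
    df = pd.read_csv(path)
    curves = []
    for (quantity, n), grp in df.groupby(["quantity", "n"], sort=True):
        grp = grp.sort_values("T")
        curves.append(ThermoCurve(str(quantity), int(n),
                                  grp["T"].to_numpy(), grp["value"].to_numpy()))
    return curves


# -- FSS results ------------------------------------------------------------

def write_fss_result(result: FSSResult, path: PathLike) -> None:
    payload = {
        "quantity": result.quantity,
        "t_c": result.T_c,
        "nu_d": result.nu_d,
        "exponent": result.quantity_exponent,
        "gc": result.gc,
        "starts": result.optimizer_trace,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_fss_result(path: PathLike) -> FSSResult:
    with open(path) as fh:
        data = json.load(fh)
    return FSSResult(data["t_c"], data["nu_d"], data["exponent"],
                     data["gc"], data["quantity"], data["starts"])
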