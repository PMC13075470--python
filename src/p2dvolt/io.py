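"""File formats, run manifests and synthetic fixture voltammograms.

CSV dialect for voltammograms: header columns ``time_s, potential_V,
j_total_A_m2, j_mediated_A_m2, j_direct_A_m2, direction`` (plus an optional
``c_surface`` column), one row per sample, '.' decimal separator.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParameters
from .simulate import Voltammogram

__all__ = [
    "RunManifest",
    "write_voltammogram_csv",
    "read_voltammogram_csv",
    "write_history_csv",
    "write_json_summary",
    "make_fixture_voltammogram",
]

_REQUIRED_COLUMNS = ["time_s", "potential_V", "j_total_A_m2",
                     "j_mediated_A_m2", "j_direct_A_m2", "direction"]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run deterministically."""

    command: str
    parameters: dict
    nx: int
    nr: int
    rel_tol: float
    seed: int | None
    package_version: str
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    wall_time_s: float = 0.0
    platform: str = field(default_factory=platform.platform)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def read(cls, path) -> "RunManifest":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        raw.pop("platform", None)
        m = cls(**{k: v for k, v in raw.items() if k != "platform"})
        return m


def write_voltammogram_csv(vgram: Voltammogram, path) -> None:
    df = vgram.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")


def read_voltammogram_csv(path, kind: str | None = None,
                          scan_rate: float | None = None) -> Voltammogram:
    """Read a voltammogram in the package CSV dialect.

    Malformed rows raise a :class:`ValueError` naming the first bad line.
    ``kind``/``scan_rate`` override the values inferred from the trace
    (kind defaults to "synthetic" for external files).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse voltammogram CSV {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in _REQUIRED_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric value in column "
                             f"{col!r} at line {line}")
        if df[col].isna().any():
            line = int(np.nonzero(df[col].isna().to_numpy())[0][0]) + 2
            raise ValueError(f"{path}: missing value in column {col!r} "
                             f"at line {line}")
    t = df["time_s"].to_numpy(float)
    E = df["potential_V"].to_numpy(float)
    if scan_rate is None and len(t) > 1:
        dE = np.abs(np.diff(E)) / np.maximum(np.diff(t), 1e-300)
        scan_rate = float(np.median(dE)) if np.all(np.diff(t) > 0) else None
    return Voltammogram(
        t=t, E=E,
        j_total=df["j_total_A_m2"].to_numpy(float),
        j_mediated=df["j_mediated_A_m2"].to_numpy(float),
        j_direct=df["j_direct_A_m2"].to_numpy(float),
        direction=df["direction"].to_numpy(int),
        kind=kind or "synthetic", scan_rate=scan_rate,
        c_surface=(df["c_surface"].to_numpy(float)
                   if "c_surface" in df.columns else None))


def write_history_csv(history, prefix) -> list:
    """Multi-table CSV bundle: grids plus per-snapshot field tables."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    meta = pd.DataFrame({"time_s": history.times, "potential_V": history.E,
                         "direction": history.direction})
    for name, nodes, mat in (("C_e", history.x_nodes, history.C_e),
                             ("C_s", history.r_nodes, history.C_s),
                             ("theta", history.r_nodes, history.theta)):
        df = pd.DataFrame(mat, columns=[f"{v:.8e}" for v in nodes])
        df.insert(0, "time_s", history.times)
        path = prefix.with_name(prefix.name + f"_{name}.csv")
        df.to_csv(path, index=False, float_format="%.8g")
        paths.append(path)
    path = prefix.with_name(prefix.name + "_snapshots.csv")
    meta.to_csv(path, index=False, float_format="%.8g")
    paths.append(path)
    return paths


def write_json_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True,
                                     default=_json_default) + "\n",
                          encoding="utf-8")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def file_sha1(path) -> str:
    return hashlib.sha1(Path(path).read_bytes()).hexdigest()


def make_fixture_voltammogram(kind: str, seed: int = 0,
                              params: ModelParameters | None = None,
                              path=None) -> Voltammogram:
    """Small synthetic voltammograms with known ground truth.

    * ``ideal-bv``: exact cathodic Butler-Volmer samples with rate scale
      ``k0_bare`` (Tafel analysis recovers alpha and k0_bare exactly);
    * ``noisy-peak``: Gaussian-bump cathodic peak with known vertex at
      (-0.5 V, -1.0 A m^-2) plus seeded noise;
    * ``flat``: zero-current trace (peak search must fail).
    """
    if params is None:
        from .params import default_parameters

        params = default_parameters()
    rng = np.random.default_rng(seed)
    E = np.arange(0.2, -1.2, -0.001)
    t = (0.2 - E) / 0.05
    direction = np.ones(E.size, dtype=int)
    zeros = np.zeros_like(E)
    if kind == "ideal-bv":
        eta = E - params.E_eq
        j = -(params.n_electrons * params.F * params.k0_bare * params.C_bulk
              * np.exp(-params.alpha * params.f_thermal * eta))
        vgram = Voltammogram(t=t, E=E, j_total=j, j_mediated=zeros,
                             j_direct=j, direction=direction, kind="bare",
                             scan_rate=0.05,
                             c_surface=np.ones_like(E))
    elif kind == "noisy-peak":
        j = -np.exp(-((E + 0.5) ** 2) / (2 * 0.1 ** 2))
        j = j + rng.normal(0.0, 0.01, size=j.shape)
        vgram = Voltammogram(t=t, E=E, j_total=j, j_mediated=j,
                             j_direct=zeros, direction=direction,
                             kind="synthetic", scan_rate=0.05)
    elif kind == "flat":
        vgram = Voltammogram(t=t, E=E, j_total=zeros, j_mediated=zeros,
                             j_direct=zeros, direction=direction,
                             kind="synthetic", scan_rate=0.05)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if path is not None:
        write_voltammogram_csv(vgram, path)
    return vgram
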