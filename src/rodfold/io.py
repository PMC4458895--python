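"""File formats and provenance.

CSV dialect: comma-separated, '.' decimal, UTF-8, header row mandatory;
lengths in nm.  Movies are 16-bit TIFF stacks.  Every writer can leave a
JSON provenance sidecar (tool version, seed, config hash) so a run can
be reproduced from its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .afm import ForceExtensionTrace
from .thermo import DenaturationCurve

TRACE_COLUMNS = ("time_s", "extension_nm", "force_pN")
CURVE_COLUMNS = ("denaturant_M", "signal")
CHEVRON_COLUMNS = ("denaturant_M", "kobs_s")


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, seed: int | None, config: dict) -> None:
    """JSON sidecar (<path>.meta.json) recording how a file was made."""
    from . import __version__
    meta = {"tool": "rodfold", "version": __version__, "seed": seed,
            "config": config, "config_hash": config_hash(config)}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2,
                                                         default=str))


def write_trace_csv(path, trace: ForceExtensionTrace,
                    seed: int | None = None) -> None:
    df = pd.DataFrame({"time_s": trace.time,
                       "extension_nm": trace.extension,
                       "force_pN": trace.force})
    df.to_csv(path, index=False)
    write_provenance(path, seed, {"speed_nm_s": trace.speed,
                                  **trace.meta})


def read_trace_csv(path, speed: float = np.nan) -> ForceExtensionTrace:
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    ext = df["extension_nm"].to_numpy(float)
    if np.any(np.diff(ext) < -1e-9):
        raise ValueError(f"{path}: extension_nm must be non-decreasing")
    return ForceExtensionTrace(df["time_s"].to_numpy(float), ext,
                               df["force_pN"].to_numpy(float), speed)


def write_curve_csv(path, curve: DenaturationCurve,
                    seed: int | None = None) -> None:
    pd.DataFrame({"denaturant_M": curve.denaturant,
                  "signal": curve.signal}).to_csv(path, index=False)
    write_provenance(path, seed, {"construct": curve.construct})


def read_curve_csv(path, construct: str = "") -> DenaturationCurve:
    df = pd.read_csv(path)
    _require_columns(df, CURVE_COLUMNS, path)
    return DenaturationCurve(df["denaturant_M"].to_numpy(float),
                             df["signal"].to_numpy(float), construct)


def read_chevron_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CHEVRON_COLUMNS, path)
    return df


def write_movie(path, stack: np.ndarray, seed: int | None = None,
                config: dict | None = None) -> None:
    """16-bit TIFF stack (counts clipped to the uint16 range)."""
    data = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    write_provenance(path, seed, config or {})


def read_movie(path, min_frames: int = 15) -> np.ndarray:
    stack = tifffile.imread(path).astype(float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] < min_frames:
        raise ValueError(
            f"{path}: SHRImP needs >= {min_frames} frames, stack has "
            f"{stack.shape[0]}")
    return stack


def write_chain_pdb(path, chain) -> None:
    """Minimal CA-style bead records of a bead chain."""
    lines = []
    for i, (x, y, z) in enumerate(chain.coords, start=1):
        # PDB columns are in Angstrom
        lines.append(
            f"ATOM  {i % 100000:5d}  CA  GLY A{i % 10000:4d}    "
            f"{10 * x:8.3f}{10 * y:8.3f}{10 * z:8.3f}  1.00  0.00           C")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_chain_xyz(path, chain) -> None:
    lines = [str(chain.n_beads), "bead chain (nm)"]
    for x, y, z in chain.coords:
        lines.append(f"C {x:.4f} {y:.4f} {z:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_profile_dat(path, profile) -> None:
    """3-column scattering profile: s (nm^-1), I(s), sigma placeholder."""
    arr = np.column_stack([profile.s, profile.intensity,
                           np.zeros_like(profile.s)])
    np.savetxt(path, arr, header="s_nm^-1 I sigma", comments="# ")
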