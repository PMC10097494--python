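"""On-disk formats: amplitude-matrix CSV, four-frame CSV+JSON container,
configuration loading and provenance headers.

Matrices are stored as hand-inspectable CSV with a header row/column of
1-based electrode numbers; an empty cell means the condition was not
recorded.  Frame sets are stored as one long-format CSV (condition, frame
label, sample index, µV) plus a JSON sidecar holding acquisition
parameters.  Floats are written with 17 significant digits so write→read
round-trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .matrix import ECAPMatrix
from .waveforms import ECAPFrameSet

__version__ = "0.1.0"

_FLOAT_FMT = "%.17g"


def provenance_line(config: dict | None = None) -> str:
    """Provenance comment: tool version plus a hash of the active config."""
    digest = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# speedcap v{__version__} config:{digest}"


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_matrix(path, M: ECAPMatrix, config: dict | None = None) -> Path:
    """Write an amplitude matrix as CSV (+ JSON sidecar when meta present)."""
    path = Path(path)
    n = M.n_electrodes
    ids = [str(e) for e in range(1, n + 1)]
    with open(path, "w") as fh:
        fh.write(provenance_line(config) + "\n")
        fh.write("," + ",".join(ids) + "\n")
        for i in range(n):
            cells = [
                (_FLOAT_FMT % M.values[i, j]) if M.recorded_mask[i, j] else ""
                for j in range(n)
            ]
            fh.write(ids[i] + "," + ",".join(cells) + "\n")
    if M.meta:
        _meta_path(path).write_text(json.dumps(M.meta, indent=2, default=str))
    return path


def read_matrix(path) -> ECAPMatrix:
    """Read an amplitude-matrix CSV written by :func:`write_matrix`.

    Raises
    ------
    FormatError
        On an empty file, ragged rows, non-numeric cells, duplicate or
        inconsistent electrode ids, or negative amplitudes — with the
        offending row/column named.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    header = lines[0].split(",")
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        raise FormatError(f"{path}: duplicate electrode ids in header")
    n = len(col_ids)
    if len(lines) - 1 != n:
        raise FormatError(f"{path}: {len(lines) - 1} data rows for {n} columns")
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    seen_rows = set()
    for i, ln in enumerate(lines[1:]):
        parts = ln.split(",")
        if len(parts) != n + 1:
            raise FormatError(f"{path}: row {i + 2} has {len(parts) - 1} cells, expected {n}")
        row_id = parts[0]
        if row_id in seen_rows:
            raise FormatError(f"{path}: duplicate electrode id {row_id!r} at row {i + 2}")
        seen_rows.add(row_id)
        for j, cell in enumerate(parts[1:]):
            if cell.strip() == "":
                continue
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row id {row_id}, column id {col_ids[j]}: {cell!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path}: negative amplitude {v} at probe {row_id}, masker {col_ids[j]}"
                )
            values[i, j] = v
            mask[i, j] = True
    meta_file = _meta_path(path)
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    return ECAPMatrix(values, mask, meta)


def write_frames(path, framesets: list[ECAPFrameSet], config: dict | None = None) -> Path:
    """Write frame sets as long-format CSV plus a JSON parameter sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_line(config) + "\n")
        fh.write("condition_id,probe,masker,frame_label,sample_index,microvolts\n")
        for fs in framesets:
            for lab in "ABCD":
                trace = fs.frames[lab]
                for k in range(trace.size):
                    fh.write(
                        f"{fs.condition_id},{fs.probe_electrode},{fs.masker_electrode},"
                        f"{lab},{k},{_FLOAT_FMT % trace[k]}\n"
                    )
    sidecar = {
        fs.condition_id: {
            "sample_rate": fs.sample_rate,
            "n_sweeps": fs.n_sweeps,
            "gain_db": fs.gain_db,
            "delay_us": fs.delay_us,
            "probe_level_cu": fs.probe_level_cu,
        }
        for fs in framesets
    }
    _meta_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_frames(path) -> list[ECAPFrameSet]:
    """Read a frame container written by :func:`write_frames`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse frame CSV ({exc})") from exc
    required = {"condition_id", "probe", "masker", "frame_label", "sample_index", "microvolts"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    meta_file = _meta_path(path)
    sidecar = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    out = []
    for cid, grp in df.groupby("condition_id", sort=True):
        frames = {}
        for lab, g in grp.groupby("frame_label"):
            g = g.sort_values("sample_index")
            if not np.array_equal(g["sample_index"].to_numpy(), np.arange(len(g))):
                raise FormatError(f"{path}: condition {cid} frame {lab}: non-contiguous samples")
            frames[lab] = g["microvolts"].to_numpy(dtype=float)
        params = sidecar.get(str(cid), {})
        out.append(
            ECAPFrameSet(
                probe_electrode=int(grp["probe"].iloc[0]),
                masker_electrode=int(grp["masker"].iloc[0]),
                frames=frames,
                **params,
            )
        )
    if not out:
        raise FormatError(f"{path}: no frame data")
    return out


def dataclass_from_mapping(cls, mapping: dict, source: str = "config"):
    """Instantiate a (data)class from a mapping, rejecting unknown keys."""
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ParameterError(f"{source}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")
    return cls(**mapping)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    import yaml

    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top-level config must be a mapping")
    return data
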