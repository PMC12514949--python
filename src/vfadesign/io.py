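"""Readers and writers for schemes, parameter sets, datasets and matrices.

All files are plain text: schemes and datasets are comma-separated tables
with a mandatory header row, parameter sets are JSON.  Every written file
carries a provenance header in ``#``-prefixed comment lines (package
version, seed, content hash) and round-trips bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import numpy as np

from .exceptions import SchemeParseError
from .fisher import FIMResult
from .kinetics import Dataset, FlipAngleScheme, KineticParameters

__all__ = [
    "read_params",
    "write_params",
    "read_scheme",
    "write_scheme",
    "read_dataset",
    "write_dataset",
    "write_fim",
    "write_results",
]

_GRID_RTOL = 1e-6


def _content_hash(payload: str) -> str:
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(seed: Optional[int], payload: str, extra: Optional[Dict] = None) -> str:
    from . import __version__

    lines = [f"# vfadesign: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append(f"# content-hash: {_content_hash(payload)}")
    return "\n".join(lines) + "\n"


def _read_table(path: Union[str, Path], expected_header: list) -> list:
    """Read a '#'-commented CSV, returning (line_number, fields) rows."""
    path = Path(path)
    if not path.exists():
        raise SchemeParseError(f"{path}: no such file")
    rows = []
    header = None
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(",")]
        if header is None:
            header = fields
            if header != expected_header:
                raise SchemeParseError(
                    f"{path}:{ln}: expected header {','.join(expected_header)}, "
                    f"got {','.join(header)}"
                )
            continue
        if len(fields) != len(expected_header):
            raise SchemeParseError(
                f"{path}:{ln}: expected {len(expected_header)} fields, got {len(fields)}"
            )
        rows.append((ln, fields))
    if header is None:
        raise SchemeParseError(f"{path}: missing header row")
    return rows


def write_params(
    params: KineticParameters, path: Union[str, Path], seed: Optional[int] = None
) -> Path:
    """Write a parameter set as JSON (keys k, R1S, R1P, S0, P0, B1S)."""
    path = Path(path)
    doc = {n: getattr(params, n) for n in ("k", "R1S", "R1P", "S0", "P0", "B1S")}
    payload = json.dumps(doc, indent=2, sort_keys=True)
    meta = {
        "_provenance": {
            "vfadesign": __import__("vfadesign").__version__,
            "seed": seed,
            "content-hash": _content_hash(payload),
        }
    }
    doc.update(meta)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_params(path: Union[str, Path]) -> KineticParameters:
    path = Path(path)
    if not path.exists():
        raise SchemeParseError(f"{path}: no such file")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemeParseError(f"{path}: invalid JSON ({e})") from e
    try:
        kwargs = {n: float(doc[n]) for n in ("k", "R1S", "R1P", "S0", "P0")}
    except KeyError as e:
        raise SchemeParseError(f"{path}: missing parameter key {e}") from e
    kwargs["B1S"] = float(doc.get("B1S", 1.0))
    return KineticParameters(**kwargs)


def write_scheme(
    scheme: FlipAngleScheme, path: Union[str, Path], seed: Optional[int] = None
) -> Path:
    """Write a scheme as CSV with columns index, time_s, flip_deg."""
    path = Path(path)
    lines = ["index,time_s,flip_deg"]
    for i, (t, a) in enumerate(zip(scheme.times, scheme.angles_deg)):
        lines.append(f"{i},{t:.6g},{a:.4f}")
    payload = "\n".join(lines) + "\n"
    path.write_text(_provenance(seed, payload, {"tr_s": f"{scheme.tr:.6g}"}) + payload)
    return path


def read_scheme(path: Union[str, Path]) -> FlipAngleScheme:
    """Read and validate a scheme CSV (uniform TR grid, angles in [0, 90])."""
    rows = _read_table(path, ["index", "time_s", "flip_deg"])
    times, angles = [], []
    for ln, (idx, t, a) in rows:
        try:
            times.append(float(t))
            angles.append(float(a))
            int(idx)
        except ValueError as e:
            raise SchemeParseError(f"{path}:{ln}: malformed row ({e})") from e
        if not (0.0 <= angles[-1] <= 90.0):
            raise SchemeParseError(
                f"{path}:{ln}: flip angle {angles[-1]} outside [0, 90] degrees"
            )
    if not times:
        raise SchemeParseError(f"{path}: empty scheme")
    times = np.asarray(times)
    if times.size == 1:
        tr = 1.0  # a single excitation has no grid; TR is immaterial
    else:
        dt = np.diff(times)
        tr = float(dt[0])
        if tr <= 0 or not np.allclose(dt, tr, rtol=_GRID_RTOL, atol=0.0):
            raise SchemeParseError(
                f"{path}: sampling instants are not a uniform TR grid"
            )
    return FlipAngleScheme(np.asarray(angles), tr)


def write_dataset(
    dataset: Dataset, path: Union[str, Path], seed: Optional[int] = None
) -> Path:
    """Write a dataset as CSV (time_s, substrate, product, flip_deg, included).

    sigma and the normalization divisor go into the provenance header so the
    file round-trips to an identical Dataset.
    """
    if dataset.scheme is None:
        raise ValueError("dataset needs an attached scheme to be written")
    path = Path(path)
    scheme = dataset.scheme
    lines = ["time_s,substrate,product,flip_deg,included"]
    for t in range(scheme.n_excitations):
        lines.append(
            f"{scheme.times[t]:.6g},{dataset.signals[0, t]:.10e},"
            f"{dataset.signals[1, t]:.10e},{scheme.angles_deg[t]:.4f},"
            f"{int(dataset.included[t])}"
        )
    payload = "\n".join(lines) + "\n"
    extra = {
        "sigma": f"{dataset.sigma:.10e}",
        "normalization": f"{dataset.normalization:.10e}",
        "tr_s": f"{scheme.tr:.6g}",
    }
    path.write_text(_provenance(seed, payload, extra) + payload)
    return path


def read_dataset(path: Union[str, Path]) -> Dataset:
    path = Path(path)
    meta = {}
    for raw in path.read_text().splitlines() if path.exists() else []:
        if raw.startswith("#") and ":" in raw:
            key, _, val = raw.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    rows = _read_table(path, ["time_s", "substrate", "product", "flip_deg", "included"])
    times, sub, prod, ang, inc = [], [], [], [], []
    for ln, fields in rows:
        try:
            times.append(float(fields[0]))
            sub.append(float(fields[1]))
            prod.append(float(fields[2]))
            ang.append(float(fields[3]))
            inc.append(bool(int(fields[4])))
        except ValueError as e:
            raise SchemeParseError(f"{path}:{ln}: malformed row ({e})") from e
    times = np.asarray(times)
    tr = float(times[1] - times[0]) if times.size > 1 else float(meta.get("tr_s", 1.0))
    scheme = FlipAngleScheme(np.asarray(ang), tr)
    try:
        sigma = float(meta["sigma"])
        normalization = float(meta["normalization"])
    except KeyError as e:
        raise SchemeParseError(f"{path}: provenance header lacks {e}") from e
    return Dataset(
        signals=np.vstack([sub, prod]),
        sigma=sigma,
        normalization=normalization,
        included=np.asarray(inc, bool),
        scheme=scheme,
    )


def write_fim(fimres: FIMResult, path: Union[str, Path], seed: Optional[int] = None) -> Path:
    """Write a FIM (or any matrix result) as CSV with a parameter header row."""
    path = Path(path)
    lines = ["," + ",".join(fimres.order)]
    for name, row in zip(fimres.order, fimres.matrix):
        lines.append(name + "," + ",".join(f"{v:.10e}" for v in row))
    payload = "\n".join(lines) + "\n"
    extra = {"condition": f"{fimres.condition:.6g}", "invertible": fimres.invertible}
    path.write_text(_provenance(seed, payload, extra) + payload)
    return path


def write_results(
    objects: Mapping[str, object], out_dir: Union[str, Path], seed: Optional[int] = None
) -> Dict[str, Path]:
    """Write a named collection of result objects with deterministic filenames.

    Dispatches on type: schemes -> ``<name>.scheme.csv``, datasets ->
    ``<name>.data.csv``, parameter sets -> ``<name>.params.json``, FIMs ->
    ``<name>.fim.csv``.
    """
    out = Path(out_dir)
    if not out.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {out}")
    paths: Dict[str, Path] = {}
    for name, obj in objects.items():
        if isinstance(obj, FlipAngleScheme):
            paths[name] = write_scheme(obj, out / f"{name}.scheme.csv", seed)
        elif isinstance(obj, Dataset):
            paths[name] = write_dataset(obj, out / f"{name}.data.csv", seed)
        elif isinstance(obj, KineticParameters):
            paths[name] = write_params(obj, out / f"{name}.params.json", seed)
        elif isinstance(obj, FIMResult):
            paths[name] = write_fim(obj, out / f"{name}.fim.csv", seed)
        else:
            raise TypeError(f"don't know how to write {type(obj).__name__} ({name})")
    return paths
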