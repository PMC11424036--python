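"""Configuration, delimited-text I/O, and run orchestration.

File dialects
-------------
Time series: delimited text (comma or tab, auto-detected), rows = time
points, columns = channels, optional single header row of channel names.
Connectivity matrices: delimited text with a header row and an index column
of channel names; entry (row i, column j) is the measure from channel j to
channel i.  Frequency curves: long format with columns
(source, target, theta_rad[, freq_hz], value).  Floats are written with 17
significant digits so a write/read round trip is exact.

A measure run fits ONE model and derives every requested measure, matrix
and curve from it, so comparisons between measures are internally
consistent; the run directory receives a machine-readable manifest (config
echo, package version, seeds, model diagnostics) sufficient to replay the
run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from .measures import _MEASURE_DISPATCH, all_pairs, dtf
from .spectral import DEFAULT_GRID_SIZE, hz_band_to_theta
from .var_ss import check_assumptions, fit_var, select_order, var_to_ss

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "write_matrix",
    "read_matrix",
    "write_curves",
    "run_measure",
]

logger = logging.getLogger(__name__)

_KNOWN_METHODS = tuple(sorted(_MEASURE_DISPATCH)) + ("dtf",)


@dataclass
class RunConfig:
    """Validated settings for a measure run."""

    order: int | None = 1
    order_criterion: str = "BIC"
    order_max: int = 8
    n_grid: int = DEFAULT_GRID_SIZE
    methods: tuple[str, ...] = ("gcm", "cgcm-std", "cgcm-sent", "cgcm-jent")
    mode: str = "conditional-on-rest"
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"lowband": (0.0, float(np.pi) / 2.0)}
    )
    tr: float | None = None
    seed: int = 0
    out_dir: str = "megc-run"

    def __post_init__(self) -> None:
        if self.order is not None and self.order < 1:
            raise ValueError("model order must be >= 1")
        if self.n_grid < 2:
            raise ValueError("frequency grid needs at least 2 points")
        if self.mode not in ("conditional-on-rest", "pairwise"):
            raise ValueError("mode must be 'conditional-on-rest' or 'pairwise'")
        for m in self.methods:
            if m not in _KNOWN_METHODS:
                raise ValueError(f"unknown method '{m}'; choose from {_KNOWN_METHODS}")
        for name, (lo, hi) in self.bands.items():
            if not (0.0 <= lo < hi <= np.pi + 1e-12):
                raise ValueError(f"band '{name}' must satisfy 0 <= lo < hi <= pi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "bands" in raw:
            bands = {}
            for name, spec in raw["bands"].items():
                if isinstance(spec, dict):  # physical units: {hz: [lo, hi]}
                    lo, hi = spec["hz"]
                    tr = raw.get("tr")
                    if tr is None:
                        raise ValueError(f"band '{name}' given in Hz but no tr set")
                    bands[name] = hz_band_to_theta(lo, hi, tr)
                else:
                    bands[name] = (float(spec[0]), float(spec[1]))
            raw["bands"] = bands
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = {k: [float(v[0]), float(v[1])] for k, v in self.bands.items()}
        d["methods"] = list(self.methods)
        return d


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_timeseries(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a (time, channels) matrix; returns (data, channel_names).

    Header row auto-detection: if the first row contains any non-numeric
    token it is treated as channel names.  Ragged rows raise with the
    offending line number.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    first = lines[0].split(delim)

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in first)
    names = [t.strip() for t in first] if has_header else []
    start = 1 if has_header else 0
    width = len(lines[start].split(delim))
    rows = []
    for k, ln in enumerate(lines[start:], start=start + 1):
        toks = ln.split(delim)
        if len(toks) != width:
            raise ValueError(f"{path}: ragged row at line {k} ({len(toks)} != {width} fields)")
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric value at line {k}") from exc
    data = np.asarray(rows)
    if has_header and len(names) != data.shape[1]:
        raise ValueError(f"{path}: header has {len(names)} names for {data.shape[1]} columns")
    if not names:
        names = [f"c{i}" for i in range(data.shape[1])]
    return data, names


def write_timeseries(path: str | Path, data: np.ndarray, names=None, delim: str = "\t") -> None:
    data = np.asarray(data)
    names = list(names) if names else [f"c{i}" for i in range(data.shape[1])]
    with open(path, "w") as fh:
        fh.write(delim.join(names) + "\n")
        for row in data:
            fh.write(delim.join(f"{v:.17g}" for v in row) + "\n")


def write_matrix(path: str | Path, mat: np.ndarray, names=None, delim: str = "\t") -> None:
    """Connectivity matrix with header row/column of channel names."""
    mat = np.asarray(mat)
    names = list(names) if names else [f"c{i}" for i in range(mat.shape[1])]
    with open(path, "w") as fh:
        fh.write(delim.join([""] + names) + "\n")
        for name, row in zip(names, mat):
            fh.write(delim.join([name] + [f"{v:.17g}" for v in row]) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    delim = _sniff_delimiter(lines[0])
    names = [t.strip() for t in lines[0].split(delim)[1:]]
    rows = [[float(t) for t in ln.split(delim)[1:]] for ln in lines[1:]]
    return np.asarray(rows), names


def write_curves(
    path: str | Path,
    records: list[tuple[str, str, np.ndarray, np.ndarray]],
    tr: float | None = None,
    delim: str = "\t",
) -> None:
    """Long-format frequency curves: (source, target, grid, values) records."""
    with open(path, "w") as fh:
        cols = ["source", "target", "theta_rad"] + (["freq_hz"] if tr else []) + ["value"]
        fh.write(delim.join(cols) + "\n")
        for src, tgt, grid, vals in records:
            for th, v in zip(grid, vals):
                row = [src, tgt, f"{th:.17g}"]
                if tr:
                    row.append(f"{th / (2.0 * np.pi * tr):.17g}")
                row.append(f"{v:.17g}")
                fh.write(delim.join(row) + "\n")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_measure(config: RunConfig, data: np.ndarray, names=None) -> dict:
    """Fit one model and compute every requested measure from it.

    Writes connectivity matrices (time-domain and per-band) and a manifest
    into ``config.out_dir``; returns a dict of the in-memory results.
    """
    t_start = time.time()
    data = np.asarray(data, dtype=float)
    T, n = data.shape
    names = list(names) if names else [f"c{i}" for i in range(n)]
    if n < 2:
        raise ValueError("need at least two channels")
    if config.mode == "conditional-on-rest" and n < 3:
        conditional = [m for m in config.methods if m.startswith("cgcm")]
        if conditional:
            raise ValueError(
                f"conditional measures {conditional} need at least 3 channels "
                f"(got {n}); use mode='pairwise'"
            )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    order = config.order
    if order is None:
        order = select_order(data, config.order_max, config.order_criterion)
        logger.info("selected order p=%d by %s", order, config.order_criterion)
    model = fit_var(data, order, channel_names=names)
    ss = var_to_ss(model)
    report = check_assumptions(ss)
    logger.info("model radii: %s", report.radii)

    results: dict = {"order": order, "diagnostics": report.radii, "matrices": {}}
    for method in config.methods:
        t0 = time.time()
        if method == "dtf":
            theta, curves = dtf(ss, config.n_grid)
            tmat = curves.mean(axis=0)
            write_matrix(out_dir / "dtf_time.tsv", tmat, names)
            results["matrices"]["dtf"] = {"time": tmat}
            continue
        mats = {}
        tmat, bmat = all_pairs(ss, method=method, mode=config.mode, n_grid=config.n_grid)
        mats["time"] = tmat
        write_matrix(out_dir / f"{method}_time.tsv", tmat, names)
        for bname, band in config.bands.items():
            _, bmat = all_pairs(ss, method=method, mode=config.mode, band=band, n_grid=config.n_grid)
            mats[bname] = bmat
            write_matrix(out_dir / f"{method}_{bname}.tsv", bmat, names)
        results["matrices"][method] = mats
        logger.info("method %s done in %.2fs", method, time.time() - t0)

    manifest = {
        "package": "megc",
        "version": _version,
        "config": config.to_dict(),
        "n_timepoints": T,
        "n_channels": n,
        "channel_names": names,
        "order": order,
        "diagnostics": {k: float(v) for k, v in report.radii.items()},
        "elapsed_s": time.time() - t_start,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
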