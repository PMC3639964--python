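"""Readers and writers for capture histories, reports and run manifests.

Two capture-history dialects are supported:

* CSV — header row ``id,occ1,...,occK`` with 0/1 cells, one individual per
  row, occasions 1-based;
* MARK-style ``.inp`` — one line per history: K digits, whitespace, a
  positive integer frequency and a terminating semicolon (``10110 3;``).
  Frequencies expand to repeated rows on read.  Lines beginning ``/*`` are
  comments and are ignored.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .gof import GOFReport
from .inference import FitResult
from .scenarios import CaptureHistoryMatrix

__all__ = [
    "ParseError",
    "read_capture_histories",
    "write_capture_histories",
    "write_true_p_sidecar",
    "fit_result_to_csv",
    "gof_report_to_csv",
    "gof_report_to_json",
    "write_manifest",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed capture-history file; message carries the line number."""


def _first_from_matrix(det: np.ndarray, source: str) -> np.ndarray:
    if det.size == 0 or det.shape[1] == 0:
        raise ParseError(f"{source}: zero-length histories")
    any_seen = det.any(axis=1)
    if not any_seen.all():
        bad = int(np.flatnonzero(~any_seen)[0])
        raise ParseError(f"{source}: history {bad + 1} contains no detection")
    return det.argmax(axis=1)


def read_capture_histories(path: PathLike, format: Optional[str] = None) -> CaptureHistoryMatrix:
    """Read capture histories from ``path``; ``format`` is ``csv`` or ``inp``
    (inferred from the suffix when omitted)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "inp":
        return _read_inp(path)
    raise ValueError(f"unknown capture-history format {fmt!r}; expected 'csv' or 'inp'")


def _read_csv(path: Path) -> CaptureHistoryMatrix:
    df = pd.read_csv(path)
    occ_cols = [c for c in df.columns if c.lower().startswith("occ")]
    if not occ_cols:
        raise ParseError(f"{path}: no occasion columns (expected occ1..occK)")
    det = df[occ_cols].to_numpy()
    if not np.isin(det, (0, 1)).all():
        bad = int(np.flatnonzero(~np.isin(det, (0, 1)).all(axis=1))[0])
        raise ParseError(f"{path}: non-binary value in data row {bad + 1}")
    det = det.astype(np.int8)
    return CaptureHistoryMatrix(detections=det, first_capture=_first_from_matrix(det, str(path)))


def _read_inp(path: Path) -> CaptureHistoryMatrix:
    rows: list[list[int]] = []
    width: Optional[int] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("/*"):
                continue
            if not line.endswith(";"):
                raise ParseError(f"{path}:{lineno}: missing terminating ';'")
            body = line[:-1].split()
            if len(body) == 1:
                digits, freq_s = body[0], "1"
            elif len(body) == 2:
                digits, freq_s = body
            else:
                raise ParseError(f"{path}:{lineno}: expected 'history frequency;'")
            if not set(digits) <= {"0", "1"}:
                raise ParseError(f"{path}:{lineno}: non-binary symbol in history {digits!r}")
            if width is None:
                width = len(digits)
            elif len(digits) != width:
                raise ParseError(
                    f"{path}:{lineno}: ragged history length {len(digits)} (expected {width})"
                )
            try:
                freq = int(freq_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad frequency {freq_s!r}") from None
            if freq < 1:
                raise ParseError(f"{path}:{lineno}: frequency must be >= 1")
            rows.extend([[int(c) for c in digits]] * freq)
    if not rows:
        raise ParseError(f"{path}: no capture histories found")
    det = np.asarray(rows, dtype=np.int8)
    return CaptureHistoryMatrix(detections=det, first_capture=_first_from_matrix(det, str(path)))


def write_capture_histories(
    data: CaptureHistoryMatrix, path: PathLike, format: Optional[str] = None
) -> None:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        k = data.n_occasions
        df = pd.DataFrame(data.detections, columns=[f"occ{t + 1}" for t in range(k)])
        df.insert(0, "id", np.arange(1, data.n_individuals + 1))
        df.to_csv(path, index=False)
    elif fmt == "inp":
        with open(path, "w") as fh:
            for row in data.detections:
                fh.write("".join(str(int(v)) for v in row) + " 1;\n")
    else:
        raise ValueError(f"unknown capture-history format {fmt!r}")


def write_true_p_sidecar(data: CaptureHistoryMatrix, path: PathLike) -> None:
    """Sidecar CSV with the generating per-individual detection probability
    (and group label for two-group data); simulated data only."""
    if data.true_p is None:
        raise ValueError("dataset carries no generating detection probabilities")
    df = pd.DataFrame(
        {"id": np.arange(1, data.n_individuals + 1), "true_p": data.true_p}
    )
    if data.true_group is not None:
        df["true_group"] = data.true_group
    df.to_csv(path, index=False)


def fit_result_to_csv(fit: FitResult, path: PathLike) -> None:
    """Flat CSV: parameter, mean, sd, q2.5, q50, q97.5, rhat."""
    fit.params.to_csv(path, index_label="parameter")


def gof_report_to_csv(report: GOFReport, path: PathLike) -> None:
    rows = [c.as_dict() for c in report.components.values()]
    rows.append(
        dict(component="OVERALL", chi2=report.chi2, df=report.df, p=report.p,
             z=None, p_z=None, n_tables=None, degenerate=report.degenerate)
    )
    pd.DataFrame(rows).to_csv(path, index=False)


def gof_report_to_json(report: GOFReport, path: PathLike) -> None:
    payload = {
        "components": {k: c.as_dict() for k, c in report.components.items()},
        "overall": dict(chi2=report.chi2, df=report.df, p=report.p,
                        c_hat=report.c_hat, degenerate=report.degenerate),
        "marray": {
            "releases": report.marray.releases.tolist(),
            "m": report.marray.m.tolist(),
            "never_recaptured": report.marray.never_recaptured.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_manifest(path: PathLike, seed, config: dict, extra: Optional[dict] = None) -> dict:
    """Write a JSON run manifest (seed, config and its hash, package version)
    sufficient to reproduce the artifact."""
    from . import __version__

    canonical = json.dumps(config, sort_keys=True, default=_json_default)
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "package": "cjshet",
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default))
    return manifest
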