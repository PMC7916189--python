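"""On-disk formats: frame files, spectra matrices, feature tables, classifiers.

Frames and spectra are stored as delimited-text matrices next to a JSON
metadata sidecar (``<path>.json``) that carries the sampling parameters,
per-frame d.c. levels and timestamps, plus the configuration hash and seed
of the producing run when available.  The formats are defined by this
package; round trips are lossless (values are written with 17 significant
digits, enough to reproduce IEEE doubles exactly).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import LinearClassifier
from .errors import FrameIOError, GridMismatchError
from .spectral import PhotocurrentFrame, PowerSpectrum

__all__ = [
    "write_frames",
    "read_frames",
    "write_spectra",
    "read_spectra",
    "write_features",
    "read_features",
    "save_classifier",
    "load_classifier",
]

_FMT = "%.17g"


def _sidecar_path(path: str) -> str:
    return path + ".json"


def _write_sidecar(path: str, payload: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        json.dump(payload, fh, indent=1)


def _read_sidecar(path: str) -> dict:
    sc = _sidecar_path(path)
    if not os.path.exists(sc):
        raise FrameIOError(f"missing metadata sidecar {sc!r}")
    with open(sc) as fh:
        return json.load(fh)


def write_frames(
    frames: Sequence[PhotocurrentFrame], path: str, meta: dict | None = None
) -> None:
    """Write frames as a text matrix (one row per frame: iac1 then iac2).

    The sidecar records fs, frame length, channel layout, per-frame d.c.
    levels and start times, and any extra `meta` (e.g. gain, device id,
    config hash, seed).
    """
    frames = list(frames)
    if not frames:
        raise FrameIOError("no frames to write")
    n = len(frames[0])
    fs = frames[0].fs
    for i, fr in enumerate(frames):
        if len(fr) != n or fr.fs != fs:
            raise FrameIOError(f"frame {i}: inconsistent length or sampling rate")
    mat = np.vstack([np.concatenate([fr.iac1, fr.iac2]) for fr in frames])
    np.savetxt(path, mat, fmt=_FMT, delimiter="\t")
    _write_sidecar(
        path,
        {
            "format": "ldflow-frames",
            "fs": fs,
            "n_samples": n,
            "n_frames": len(frames),
            "channels": ["iac1", "iac2"],
            "idc": [fr.idc for fr in frames],
            "t0": [fr.t0 for fr in frames],
            **(meta or {}),
        },
    )


def read_frames(path: str) -> list[PhotocurrentFrame]:
    """Read a frame file written by :func:`write_frames`."""
    meta = _read_sidecar(path)
    if meta.get("format") != "ldflow-frames":
        raise FrameIOError(f"{path!r}: sidecar does not describe a frame file")
    n = int(meta["n_samples"])
    frames: list[PhotocurrentFrame] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            row = np.array(line.split("\t"), dtype=float)
            if len(row) != 2 * n:
                raise FrameIOError(
                    f"{path!r}: frame {i} has {len(row)} values, expected {2 * n}"
                )
            frames.append(
                PhotocurrentFrame(
                    iac1=row[:n],
                    iac2=row[n:],
                    idc=float(meta["idc"][i]),
                    fs=float(meta["fs"]),
                    t0=float(meta["t0"][i]),
                )
            )
    if len(frames) != int(meta["n_frames"]):
        raise FrameIOError(
            f"{path!r}: truncated at frame {len(frames)} of {meta['n_frames']}"
        )
    return frames


def write_spectra(
    spectra: Sequence[PowerSpectrum], path: str, meta: dict | None = None
) -> None:
    """Write a spectra series as an ``n_frames x n_bins`` text matrix."""
    spectra = list(spectra)
    if not spectra:
        raise FrameIOError("no spectra to write")
    f = spectra[0].f
    for i, s in enumerate(spectra):
        if len(s.f) != len(f) or not np.array_equal(s.f, f):
            raise GridMismatchError(f"spectrum {i} is not on the shared grid")
    mat = np.vstack([s.S for s in spectra])
    np.savetxt(path, mat, fmt=_FMT, delimiter="\t")
    _write_sidecar(
        path,
        {
            "format": "ldflow-spectra",
            "f": f.tolist(),
            "df": spectra[0].df,
            "n_frames": len(spectra),
            "n_bins": len(f),
            "idc": [s.idc for s in spectra],
            "t0": [s.t0 for s in spectra],
            **(meta or {}),
        },
    )


def read_spectra(path: str) -> list[PowerSpectrum]:
    """Read a spectra file written by :func:`write_spectra`."""
    meta = _read_sidecar(path)
    if meta.get("format") != "ldflow-spectra":
        raise FrameIOError(f"{path!r}: sidecar does not describe a spectra file")
    mat = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    n_frames, n_bins = int(meta["n_frames"]), int(meta["n_bins"])
    if mat.shape != (n_frames, n_bins):
        raise FrameIOError(
            f"{path!r}: matrix shape {mat.shape} does not match sidecar "
            f"({n_frames}, {n_bins})"
        )
    f = np.asarray(meta["f"], dtype=float)
    return [
        PowerSpectrum(
            f=f, S=mat[i], idc=float(meta["idc"][i]), t0=float(meta["t0"][i])
        )
        for i in range(n_frames)
    ]


def write_features(table: pd.DataFrame, path: str, meta: dict | None = None) -> None:
    """Feature table as tab-delimited text with a ``#``-prefixed metadata line."""
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + json.dumps(meta) + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_features(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def save_classifier(clf: LinearClassifier, path: str) -> None:
    """Serialise a linear classifier (intercept, ordered coefficients) as JSON."""
    with open(path, "w") as fh:
        json.dump(asdict(clf), fh, indent=1)


def load_classifier(path: str) -> LinearClassifier:
    with open(path) as fh:
        d = json.load(fh)
    return LinearClassifier(
        intercept=d["intercept"],
        coefficients=dict(d["coefficients"]),
        positive_label=d.get("positive_label"),
        provenance=d.get("provenance", "fitted"),
        meta=d.get("meta", {}),
    )
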