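"""Readers and writers for the plain-text formats the pipeline exchanges:
TSV peak lists and profile spectra, PSM/quant tables, JSON ground truth,
and mzML input via pyteomics when available."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .intact import ProfileSpectrum

__all__ = [
    "write_spectra_tsv",
    "read_spectra_tsv",
    "read_mzml",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
]


def write_spectra_tsv(spectra: list[ProfileSpectrum], path) -> None:
    """Profile spectra as a long-format TSV (scan, mz, intensity).

    Zero-intensity points are dropped to keep files small; the m/z window
    and resolving power ride along as header comments.
    """
    path = Path(path)
    with path.open("w") as fh:
        first = spectra[0]
        fh.write(f"# mz_window={first.mz_window[0]},{first.mz_window[1]}\n")
        fh.write(f"# resolving_power={first.resolving_power}\n")
        fh.write("scan\tmz\tintensity\n")
        for spec in spectra:
            keep = spec.intensity > 0
            for mz, inten in zip(spec.mz[keep], spec.intensity[keep]):
                fh.write(f"{spec.scan_index}\t{mz:.6f}\t{inten:.6g}\n")


def read_spectra_tsv(path) -> list[ProfileSpectrum]:
    path = Path(path)
    window, rp = (625.0, 925.0), 60000.0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "mz_window":
                lo, hi = val.split(",")
                window = (float(lo), float(hi))
            elif key.strip() == "resolving_power":
                rp = float(val)
    df = pd.read_csv(path, sep="\t", comment="#")
    spectra = []
    for scan, grp in df.groupby("scan"):
        grp = grp.sort_values("mz")
        spectra.append(
            ProfileSpectrum(
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                scan_index=int(scan),
                mz_window=window,
                resolving_power=rp,
            )
        )
    return spectra


def read_mzml(path, resolving_power: float = 60000.0) -> list[ProfileSpectrum]:
    """MS1 profile spectra from an mzML file (requires pyteomics.mzml)."""
    from pyteomics import mzml

    spectra = []
    with mzml.read(str(path)) as reader:
        for i, scan in enumerate(reader):
            if scan.get("ms level", 1) != 1:
                continue
            mz = np.asarray(scan["m/z array"], dtype=float)
            inten = np.asarray(scan["intensity array"], dtype=float)
            spectra.append(
                ProfileSpectrum(
                    mz=mz, intensity=inten, scan_index=i,
                    mz_window=(float(mz.min()), float(mz.max())),
                    resolving_power=resolving_power,
                )
            )
    return spectra


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def read_json(path):
    with Path(path).open() as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
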