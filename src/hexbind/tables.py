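"""Plain-text table I/O: λ-series, umbrella windows, PMF profiles and
titration curves.

Formats
-------
λ-series: TSV/CSV with header ``lambda, dudl_mean[, dudl_sem]``.
Umbrella windows: one file per window; ``# center = <x>`` and
``# spring_k = <k>`` header comments followed by one sample per line
(a single ``samples`` column header is tolerated).
PMF: two-column TSV ``coordinate, free_energy_kcal_mol``.
Titration: CSV with columns ``concentration_mM, delta_a[, replicate_id]``.
"""

from __future__ import annotations

import glob
import os

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE
from .free_energy import (
    LambdaSeries,
    PMFProfile,
    UmbrellaWindow,
    UmbrellaWindowSet,
)
from .titration import TitrationSeries

__all__ = [
    "read_lambda_series",
    "write_lambda_series",
    "read_umbrella_windows",
    "write_umbrella_window",
    "write_pmf",
    "read_titration_csv",
    "write_titration_csv",
]


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    sep = None  # sniff comma vs whitespace
    return pd.read_csv(path, sep=sep, comment="#", engine="python")


def read_lambda_series(path: str | os.PathLike) -> LambdaSeries:
    df = _read_table(path)
    cols = {c.lower().strip(): c for c in df.columns}
    lam = df[cols["lambda"]].to_numpy(float)
    mean = df[cols["dudl_mean"]].to_numpy(float)
    sem = (
        df[cols["dudl_sem"]].to_numpy(float)
        if "dudl_sem" in cols
        else np.zeros_like(mean)
    )
    return LambdaSeries(lambdas=lam, dudl_mean=mean, dudl_sem=sem)


def write_lambda_series(series: LambdaSeries, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "lambda": series.lambdas,
            "dudl_mean": series.dudl_mean,
            "dudl_sem": series.dudl_sem,
        }
    ).to_csv(path, sep="\t", index=False)


def write_umbrella_window(window: UmbrellaWindow, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# center = {window.center!r}\n")
        fh.write(f"# spring_k = {window.spring_k!r}\n")
        fh.write("samples\n")
        np.savetxt(fh, window.samples, fmt="%.8g")


def _parse_window_file(path: str) -> UmbrellaWindow:
    center = spring_k = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, val = (t.strip() for t in body.split("=", 1))
                    if key == "center":
                        center = float(val)
                    elif key == "spring_k":
                        spring_k = float(val)
    if center is None or spring_k is None:
        raise ValueError(f"{path}: missing '# center =' / '# spring_k =' headers")
    df = _read_table(path)
    samples = df[df.columns[0]].to_numpy(float)
    return UmbrellaWindow(center=center, spring_k=spring_k, samples=samples)


def read_umbrella_windows(
    source: str | os.PathLike | list,
    temperature: float = DEFAULT_TEMPERATURE,
) -> UmbrellaWindowSet:
    """Load a window set from a directory (all ``*.tsv``/``*.dat`` files),
    a glob, or an explicit list of paths."""
    if isinstance(source, (list, tuple)):
        paths = [os.fspath(p) for p in source]
    else:
        source = os.fspath(source)
        if os.path.isdir(source):
            paths = sorted(
                glob.glob(os.path.join(source, "*.tsv"))
                + glob.glob(os.path.join(source, "*.dat"))
            )
        else:
            paths = sorted(glob.glob(source))
    if not paths:
        raise FileNotFoundError(f"no umbrella window files under {source!r}")
    windows = [_parse_window_file(p) for p in paths]
    windows.sort(key=lambda w: w.center)
    return UmbrellaWindowSet(windows=windows, temperature=temperature)


def write_pmf(profile: PMFProfile, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "coordinate": profile.bin_centers,
            "free_energy_kcal_mol": profile.free_energy,
        }
    ).to_csv(path, sep="\t", index=False)


def read_titration_csv(path: str | os.PathLike) -> list[TitrationSeries]:
    """One TitrationSeries per replicate_id (0 if the column is absent)."""
    df = pd.read_csv(path, comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    if "replicate_id" in cols:
        groups = df.groupby(df[cols["replicate_id"]])
    else:
        groups = [(0, df)]
    out = []
    for rid, g in groups:
        out.append(
            TitrationSeries(
                concentrations=g[cols["concentration_mm"]].to_numpy(float),
                delta_a=g[cols["delta_a"]].to_numpy(float),
                replicate_id=int(rid),
            )
        )
    return out


def write_titration_csv(
    series_list: list[TitrationSeries], path: str | os.PathLike
) -> None:
    frames = [
        pd.DataFrame(
            {
                "concentration_mM": s.concentrations,
                "delta_a": s.delta_a,
                "replicate_id": s.replicate_id,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
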