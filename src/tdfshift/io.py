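"""Plain-text readers and writers for decays, spectra and run manifests.

Decay files are two-column ASCII (channel index, counts) with metadata in
``# key: value`` header comments (channel width, wavelength, alignment
channel); spectra are two-column CSV (wavelength_nm, intensity); run
manifests are JSON with input hashes, seed and settings so a pipeline run
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import DecayCurve
from .tres import Spectrum

__all__ = [
    "read_decay_file",
    "write_decay_file",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_manifest",
    "sha256_file",
]


def write_decay_file(decay: DecayCurve, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# channel_width_ns: {decay.channel_width!r}"]
    if decay.wavelength is not None:
        lines.append(f"# wavelength_nm: {decay.wavelength!r}")
    lines.append(f"# t0_channel: {decay.t0_channel}")
    for k, c in enumerate(decay.counts):
        lines.append(f"{k}\t{int(round(c))}")
    path.write_text("\n".join(lines) + "\n")


def read_decay_file(path: str | Path) -> DecayCurve:
    """Parse one two-column decay file; malformed lines are reported by number."""
    path = Path(path)
    meta: dict[str, float] = {}
    channels: list[int] = []
    counts: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line.lstrip("#").partition(":")
                try:
                    meta[key.strip()] = float(value.strip())
                except ValueError:
                    pass  # free-form comment
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'channel counts', got {raw!r}")
        try:
            ch, ct = int(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric entry in {raw!r}") from exc
        if ct < 0:
            raise ValueError(f"{path}:{lineno}: negative count {ct}")
        channels.append(ch)
        counts.append(ct)
    if "channel_width_ns" not in meta:
        raise ValueError(f"{path}: missing required metadata field 'channel_width_ns'")
    if not counts:
        raise ValueError(f"{path}: no data rows (header-only file)")
    if channels != list(range(len(channels))):
        raise ValueError(f"{path}: channel indices must run 0..n-1 without gaps")
    return DecayCurve(
        counts=np.asarray(counts),
        channel_width=meta["channel_width_ns"],
        wavelength=meta.get("wavelength_nm"),
        t0_channel=int(meta.get("t0_channel", 0)),
    )


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength, "intensity": spectrum.intensity}
    ).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, intensity)")
    wl, inten = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    order = np.argsort(wl)
    return Spectrum(wavelength=wl[order], intensity=inten[order])


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path, inputs: dict[str, str | Path], seed: int | None, settings: dict
) -> dict:
    """Write a machine-readable run manifest (input hashes, seed, settings)."""
    manifest = {
        "inputs": {name: sha256_file(p) for name, p in inputs.items()},
        "seed": seed,
        "settings": settings,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
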