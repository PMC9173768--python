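"""Plain-text I/O: spectrum CSVs, library bundles, descriptor files.

Spectrum CSV contract: two columns ``wavenumber_cm-1,intensity`` with a
header row, UTF-8.  A fingerprint library is a directory of one CSV per
basis spectrum plus a ``manifest.json`` naming the grid, the molecules
and the fingerprint families.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .coexistence import FingerprintDescriptor
from .errors import ConfigError
from .spectra import FingerprintLibrary, RamanSpectrum, SpectralGrid

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "save_library",
    "load_library",
    "read_descriptors",
]

_WAVENUMBER_COL = "wavenumber_cm-1"
_INTENSITY_COL = "intensity"


def read_spectrum_csv(path: str | Path, label: str | None = None) -> RamanSpectrum:
    df = pd.read_csv(path)
    if _WAVENUMBER_COL not in df.columns or _INTENSITY_COL not in df.columns:
        raise ConfigError(
            f"{path}: expected columns '{_WAVENUMBER_COL}' and '{_INTENSITY_COL}'"
        )
    return RamanSpectrum(
        df[_WAVENUMBER_COL].to_numpy(float),
        df[_INTENSITY_COL].to_numpy(float),
        label=label if label is not None else Path(path).stem,
    )


def write_spectrum_csv(spectrum: RamanSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {_WAVENUMBER_COL: spectrum.wavenumbers, _INTENSITY_COL: spectrum.intensities}
    ).to_csv(path, index=False)


def save_library(library: FingerprintLibrary, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "grid": {
            "lo": library.grid.lo,
            "hi": library.grid.hi,
            "n_points": library.grid.n_points,
        },
        "molecules": ["A", "B"],
        "fingerprints": library.fingerprint_names,
        "seed": library.seed,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for name, spec in library.all_spectra().items():
        write_spectrum_csv(spec, d / f"{name}.csv")


def load_library(directory: str | Path) -> FingerprintLibrary:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    grid = SpectralGrid(**manifest["grid"])
    mol_a, mol_b = manifest["molecules"]
    return FingerprintLibrary(
        grid=grid,
        molecule_A=read_spectrum_csv(d / f"{mol_a}.csv", label=mol_a),
        molecule_B=read_spectrum_csv(d / f"{mol_b}.csv", label=mol_b),
        fingerprints={
            n: read_spectrum_csv(d / f"{n}.csv", label=n)
            for n in manifest["fingerprints"]
        },
        seed=int(manifest.get("seed", 0)),
    )


def read_descriptors(path: str | Path) -> list[FingerprintDescriptor]:
    """Read fingerprint descriptors from YAML (list of mappings with
    keys name, delta, pair_energy, segments)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Sequence):
        raise ConfigError(f"{path}: expected a list of descriptor mappings")
    out = []
    for entry in raw:
        out.append(
            FingerprintDescriptor(
                name=entry["name"],
                delta=entry.get("delta"),
                pair_energy=entry.get("pair_energy", {}),
                segments=int(entry.get("segments", 1)),
            )
        )
    return out
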