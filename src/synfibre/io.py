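"""File formats and run configuration.

SAXS curves travel as 3-column ASCII ``.dat`` (q [1/Å], I, sigma; ``#``
comments preserved on round trip); micrographs as TIFF or PNG grayscale;
tables as CSV; populations and manifests as JSON.  The shared YAML config
holds parameter overrides for every pipeline stage; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .emquant import Micrograph, Polarity
from .saxs import SAXSCurve


class ParseError(ValueError):
    pass


def read_saxs_dat(path) -> SAXSCurve:
    """Read a 2- or 3-column ASCII scattering file; comments start with '#'."""
    q, i, s = [], [], []
    comments = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                comments.append(stripped.lstrip("#").strip())
                continue
            parts = stripped.split()
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns")
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise ParseError(f"{path}:{lineno}: inconsistent column count")
            q.append(values[0])
            i.append(values[1])
            if n_cols == 3:
                s.append(values[2])
    if not q:
        raise ParseError(f"{path}: no data rows")
    curve = SAXSCurve(np.array(q), np.array(i), np.array(s) if s else None)
    curve.comments = comments  # type: ignore[attr-defined]
    return curve


def write_saxs_dat(curve: SAXSCurve, path, comments=None) -> None:
    comments = comments if comments is not None else getattr(curve, "comments", [])
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        if curve.sigma is not None:
            for q, i, s in zip(curve.q, curve.I, curve.sigma):
                fh.write(f"{q:.6g} {i:.6g} {s:.6g}\n")
        else:
            for q, i in zip(curve.q, curve.I):
                fh.write(f"{q:.6g} {i:.6g}\n")


def read_micrograph(path, pixel_size: float, polarity=Polarity.DARK_RIDGES) -> Micrograph:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        from PIL import Image

        pixels = np.asarray(Image.open(path).convert("F"))
    return Micrograph(np.asarray(pixels, dtype=float), pixel_size, polarity)


def write_micrograph(image: Micrograph, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.pixels.astype(np.float32))
    else:
        from PIL import Image

        arr = image.pixels
        lo, hi = float(arr.min()), float(arr.max())
        scaled = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)
        Image.fromarray((scaled * 65535).astype(np.uint16)).save(path)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "assembly": {
        "initial_length": 20.0,
        "increment": 15.0,
        "lattice_translation": 156.0,
        "lateral_spacing": 5.0,
        "ten_nm_fibre_nominal": 10.0,
        "bundle_max": 40.0,
    },
    "mass_model": {
        "cross_section_side": 100.0,
        "solvent_fraction": 0.5,
        "protein_density": 1.33,
    },
    "saxs": {
        "qRg_limit": 1.3,
        "qRc_limit": 1.3,
        "dmax_min": 10.0,
        "dmax_max": 85.0,
        "dmax_step": 2.5,
    },
    "em": {
        "pixel_size": 0.5,
        "sigma": 2.0,
        "high_thresh": 0.3,
        "low_thresh": 0.1,
        "min_length_px": 20.0,
        "bg_scale": 40.0,
        "band_small": 2.0,
        "band_large": 40.0,
        "bin_nm": 0.5,
        "k_populations": 2,
        "polarity": "dark",
    },
    "noise": {"relative_sd": 0.02, "floor_sd": 1e-4},
}


def _merge_checked(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in overrides.items():
        if key not in defaults:
            raise KeyError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {path}{key} must be a mapping")
            out[key] = _merge_checked(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Defaults, overridden by the YAML file at ``path`` (unknown keys rejected)."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    if not isinstance(overrides, dict):
        raise ValueError("config file must contain a mapping")
    return _merge_checked(DEFAULT_CONFIG, overrides)


def write_manifest(path, subcommand: str, config: dict, outputs) -> None:
    """Machine-readable record sufficient to re-run a pipeline stage."""
    from . import __version__

    manifest = {
        "tool": "synfibre",
        "version": __version__,
        "subcommand": subcommand,
        "seed": config.get("seed"),
        "config": config,
        "outputs": [str(p) for p in outputs],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
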