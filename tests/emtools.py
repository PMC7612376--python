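"""Helpers for building noise-free synthetic fibre images in tests."""

import numpy as np
import pandas as pd

from synfibre import emquant, simulate


def straight_fibre_truth(length_px, width_px, angle_deg, shape=(512, 512), centre=None):
    """Ground-truth table for one straight fibre through the image centre."""
    h, w = shape
    cx, cy = centre if centre is not None else (w / 2.0, h / 2.0)
    theta = np.radians(angle_deg)
    d = np.array([np.cos(theta), np.sin(theta)])
    t = np.linspace(-length_px / 2.0, length_px / 2.0, 65)
    poly = np.array([cx, cy]) + t[:, None] * d
    return pd.DataFrame(
        [
            {
                "id": 0,
                "label": "test",
                "width_nm": width_px * 0.5,
                "width_px": float(width_px),
                "length_nm": length_px * 0.5,
                "polyline": poly,
            }
        ]
    )


def render_fibres(truth, shape=(512, 512), psf_sigma=1.0, pixel_size=0.5):
    """Noise-free bright-ridge micrograph from a truth table."""
    recipe = simulate.MicrographRecipe(
        shape=shape, pixel_size=pixel_size, psf_sigma_px=psf_sigma
    )
    layer = simulate.render_micrograph(truth, recipe)
    return emquant.Micrograph(layer, pixel_size, emquant.Polarity.BRIGHT_RIDGES)


def detect_calibrated(image, width_px):
    """Ridge detection with the documented synthetic-calibration parameters."""
    sigma = max(1.0, width_px / (2.0 * np.sqrt(3.0)))
    return emquant.detect_ridges(
        image, sigma=sigma, high_thresh=0.12, low_thresh=0.05,
        min_length=0.75 * width_px,
    )
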