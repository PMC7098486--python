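"""Mitophagic-flux quantification (Keima blots and red-only image signal)
and PRM absolute quantification with heavy reference peptides.

Flux from immunoblots is the background-corrected ratio of the
lysosome-resistant processed reporter band to the post-import band; flux
from two-channel images follows the red-minus-green masking procedure and
its bookkeeping equation (mask area x percent area x 0.01 x mean masked
intensity), with somata below 30% of the cohort's mean expression
excluded.  PRM abundance converts light/heavy chromatographic area ratios
and the spiked heavy amount into fmol per microgram of mitochondria, and
stoichiometries between proteins carry first-order propagated errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FluxMeasurement",
    "keima_ratio",
    "red_only_signal",
    "expression_filter",
    "normalize_to_untreated",
    "prm_abundance",
    "stoichiometry",
]

EXPRESSION_FILTER_FRACTION = 0.30


@dataclass
class FluxMeasurement:
    """Band intensities for one lane of a flux-reporter immunoblot."""

    sample: str
    post_import_intensity: float
    processed_intensity: float
    background: float = 0.0

    def __post_init__(self):
        if min(self.post_import_intensity, self.processed_intensity, self.background) < 0:
            raise ValueError("intensities must be non-negative")
        if self.background > min(self.post_import_intensity, self.processed_intensity):
            raise ValueError("background cannot exceed the band intensities")


def keima_ratio(measurement: FluxMeasurement) -> float:
    """Processed-to-unprocessed reporter ratio from quantitative blotting.

    ``(processed - background) / (post_import - background)``; the
    post-import band must rise above background.  The ratio is invariant to
    uniform intensity scaling of the lane.
    """
    denom = measurement.post_import_intensity - measurement.background
    if denom <= 0:
        raise ValueError("post-import band must exceed background")
    return (measurement.processed_intensity - measurement.background) / denom


def red_only_signal(
    red: np.ndarray,
    green: np.ndarray,
    pixel_size: float = 1.0,
) -> float:
    """Red-only (mitolysosome) signal for one soma image pair.

    Step 1: red minus green, clipped at zero; step 2: binary mask of the
    positive pixels; step 3: mask area x percent area x 0.01 x mean masked
    intensity.  Percent area is the masked fraction of the field in percent
    units (hence the x0.01).  An empty mask yields 0.  The value is
    homogeneous of degree 1 in punctum intensity.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape:
        raise ValueError("channel arrays must have the same shape")
    diff = np.clip(red - green, 0.0, None)
    mask = diff > 0
    n_mask = int(mask.sum())
    if n_mask == 0:
        return 0.0
    area = n_mask * pixel_size**2
    percent_area = 100.0 * n_mask / mask.size
    mean_intensity = float(diff[mask].mean())
    return area * percent_area * 0.01 * mean_intensity


def expression_filter(
    image_pairs: list[dict],
    min_fraction: float = EXPRESSION_FILTER_FRACTION,
) -> tuple[list[dict], list[str]]:
    """Exclude somata expressing below ``min_fraction`` of the cohort mean.

    Mean dual-channel (red+green) intensity per soma is compared against
    the cohort average; the default 30% rule removes low-expressing cells
    before flux quantification.  Returns (retained pairs, excluded ids).
    """
    if not image_pairs:
        raise ValueError("at least one image pair is required")
    levels = np.array(
        [0.5 * (p["red"].mean() + p["green"].mean()) for p in image_pairs]
    )
    cohort_mean = levels.mean()
    keep = levels >= min_fraction * cohort_mean
    retained = [p for p, k in zip(image_pairs, keep) if k]
    excluded = [p.get("soma_id", str(i)) for i, (p, k) in enumerate(zip(image_pairs, keep)) if not k]
    return retained, excluded


def normalize_to_untreated(values: pd.Series, untreated_values: pd.Series) -> pd.Series:
    """Per-value division by the untreated-condition mean."""
    denom = float(np.asarray(untreated_values, dtype=float).mean())
    if denom <= 0:
        raise ValueError("untreated mean must be positive")
    return values / denom


def prm_abundance(peptides: pd.DataFrame) -> tuple[float, float]:
    """Protein abundance (fmol per ug of mitochondria) from PRM peptides.

    Per peptide, ``fmol = spike_fmol * light_area / heavy_area``; the
    protein value is the mean across its peptides divided by the input
    amount, with the SEM across peptides.  Requires >= 1 quantified peptide
    with positive heavy area.
    """
    if len(peptides) < 1:
        raise ValueError("at least one quantified peptide is required")
    if (peptides["heavy_area"] <= 0).any():
        raise ValueError("heavy areas must be positive for quantified peptides")
    fmol = (
        peptides["spike_fmol"] * peptides["light_area"] / peptides["heavy_area"]
    ) / peptides["input_ug"]
    mean = float(fmol.mean())
    sem = float(fmol.std(ddof=1) / math.sqrt(len(fmol))) if len(fmol) > 1 else 0.0
    return mean, sem


def stoichiometry(
    abundance_a: tuple[float, float], abundance_b: tuple[float, float]
) -> tuple[float, float]:
    """Molar ratio A/B of two protein abundances with first-order error
    propagation from the peptide SEMs."""
    (a, sa), (b, sb) = abundance_a, abundance_b
    if b <= 0:
        raise ValueError("denominator abundance must be positive")
    ratio = a / b
    if a == 0:
        return 0.0, sa / b
    err = abs(ratio) * math.sqrt((sa / a) ** 2 + (sb / b) ** 2)
    return ratio, err
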