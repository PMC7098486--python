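"""TMT-MS3 reporter-ion quantification: PSM filtering, reporter matching,
rollup to protein/site matrices, and the normalizations used for
multiplexed proteome / diGLY / phospho layers.

Quality filters follow the MS3 pipeline conventions: PSMs are excluded when
isolation specificity is below 0.7, when the summed reporter
signal-to-noise is below 150, or when no MS3 scan was acquired (values at
the thresholds are retained — the exclusions are strict "less than"
rules).  Features are quantified by summing reporter S/N across matching
PSMs; channels are then scaled to equal total loading, modification sites
are normalized to their protein's relative abundance profile when the
protein was quantified, and time courses are expressed relative to the
untreated channels of each genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .simulate import PlexDesign

__all__ = [
    "ASCORE_LOCALIZED",
    "REPORTER_TOLERANCE_DA",
    "load_reporter_masses",
    "filter_psms",
    "match_reporter_centroids",
    "rollup",
    "normalize_equal_loading",
    "normalize_site_to_protein",
    "relative_to_untreated",
    "sn_columns",
]

#: AScore at or above which a modification site counts as localized
#: (13 corresponds to 95% confidence)
ASCORE_LOCALIZED = 13.0
#: reporter-ion centroid integration tolerance, Da
REPORTER_TOLERANCE_DA = 0.003

MIN_ISOLATION_SPECIFICITY = 0.7
MIN_SUMMED_SN = 150.0


def load_reporter_masses(plex: int = 11) -> pd.Series:
    """Expected TMT reporter-ion m/z per channel for a 10- or 11-plex."""
    if plex not in (10, 11):
        raise ValueError("plex must be 10 or 11")
    with resources.files("ubquant.data").joinpath("tmt_reporters.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"channel": str})
    df = df[df["plex"].astype(str).str.split(",").apply(lambda v: str(plex) in v)]
    return pd.Series(df["reporter_mz"].values, index=df["channel"].values)


def sn_columns(df: pd.DataFrame) -> list[str]:
    """Reporter S/N columns of a PSM table (``sn_<channel>``)."""
    return [c for c in df.columns if c.startswith("sn_")]


def filter_psms(psms: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the quantification quality filters and return an audit.

    Retains PSMs with isolation specificity >= 0.7 AND summed S/N >= 150
    AND an MS3 scan.  The audit counts, per rule, how many PSMs violate it
    (a PSM violating several rules is counted under each).
    """
    low_spec = psms["isolation_specificity"] < MIN_ISOLATION_SPECIFICITY
    low_sn = psms["summed_sn"] < MIN_SUMMED_SN
    no_ms3 = ~psms["has_ms3"].astype(bool)
    excluded = low_spec | low_sn | no_ms3
    audit = {
        "low_specificity": int(low_spec.sum()),
        "low_sn": int(low_sn.sum()),
        "no_ms3": int(no_ms3.sum()),
        "excluded_total": int(excluded.sum()),
        "retained": int((~excluded).sum()),
    }
    return psms.loc[~excluded].copy(), audit


def match_reporter_centroids(
    peaks: np.ndarray | list[tuple[float, float]],
    reference_masses: pd.Series,
    tolerance: float = REPORTER_TOLERANCE_DA,
) -> pd.Series:
    """Per channel, the S/N of the closest centroid within the tolerance.

    ``peaks`` is an (n, 2) array of (m/z, S/N) centroids from an MS3 scan;
    channels with no centroid within ``tolerance`` Da read 0.
    """
    peaks = np.asarray(peaks, dtype=float).reshape(-1, 2)
    out = {}
    for channel, ref in reference_masses.items():
        if peaks.size == 0:
            out[channel] = 0.0
            continue
        d = np.abs(peaks[:, 0] - ref)
        j = int(np.argmin(d))
        out[channel] = float(peaks[j, 1]) if d[j] <= tolerance else 0.0
    return pd.Series(out)


def _feature_key(level: str):
    if level == "protein":
        return ["protein"]
    if level == "site":
        return ["protein", "site", "mod_type"]
    raise ValueError("level must be 'protein' or 'site'")


def _assign_shared_peptides(psms: pd.DataFrame) -> pd.DataFrame:
    """Resolve peptides listing multiple proteins (';'-separated) by simple
    parsimony: the protein with the most quantified PSMs wins, ties broken
    alphabetically."""
    if not psms["protein"].astype(str).str.contains(";").any():
        return psms
    psms = psms.copy()
    counts: dict[str, int] = {}
    for entry in psms["protein"]:
        for p in str(entry).split(";"):
            counts[p] = counts.get(p, 0) + 1
    psms["protein"] = [
        max(str(entry).split(";"), key=lambda p: (counts.get(p, 0), p))
        if ";" in str(entry)
        else entry
        for entry in psms["protein"]
    ]
    return psms


def rollup(psms: pd.DataFrame, level: str = "site") -> pd.DataFrame:
    """Sum reporter S/N across matching PSMs into a feature x channel matrix.

    ``level='protein'`` keys rows by protein; ``level='site'`` keys rows by
    (protein, residue position, modification type) and keeps only PSMs with
    a localized site (AScore >= 13).  The returned matrix records its layer
    provenance in ``.attrs``.
    """
    cols = sn_columns(psms)
    if not cols:
        raise ValueError("PSM table has no reporter S/N columns (sn_*)")
    psms = _assign_shared_peptides(psms)
    if level == "site":
        psms = psms[psms["mod_type"] != "none"]
        psms = psms[psms["ascore"].fillna(0.0) >= ASCORE_LOCALIZED]
    matrix = psms.groupby(_feature_key(level))[cols].sum(min_count=1)
    matrix.attrs["level"] = level
    matrix.attrs["normalization"] = []
    return matrix


def normalize_equal_loading(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each channel so all column sums equal the mean column sum.

    Implements equal-protein-loading normalization; missing values are
    excluded from the sums.  Column sums afterwards agree to better than
    1e-6 relative.
    """
    if matrix.shape[0] < 1:
        raise ValueError("matrix must have at least one feature")
    sums = matrix.sum(axis=0, skipna=True)
    if (sums <= 0).any():
        raise ValueError("every channel must have positive total signal")
    target = sums.mean()
    out = matrix * (target / sums)
    out.attrs = dict(matrix.attrs)
    out.attrs["normalization"] = list(matrix.attrs.get("normalization", [])) + [
        "equal_loading"
    ]
    return out


def normalize_site_to_protein(
    site_matrix: pd.DataFrame, protein_matrix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize site rows by their protein's relative abundance profile.

    The protein profile is its channel vector divided by its own mean, so a
    protein flat across channels leaves the site unchanged.  Sites whose
    protein was not quantified pass through untouched and are flagged
    ``unnormalized`` (the open/filled marker distinction on volcano plots).
    A zero protein channel turns that site channel into a missing value.
    """
    if list(site_matrix.columns) != list(protein_matrix.columns):
        raise ValueError("site and protein matrices must be column-aligned")
    out = site_matrix.copy()
    flags = pd.Series("normalized", index=site_matrix.index, dtype=object)
    prot_index = protein_matrix.index
    for key in site_matrix.index:
        protein = key[0] if isinstance(key, tuple) else key
        if protein not in prot_index:
            flags.loc[[key]] = "unnormalized"
            continue
        prof = protein_matrix.loc[protein].astype(float)
        mean = prof.mean(skipna=True)
        if not np.isfinite(mean) or mean <= 0:
            flags.loc[[key]] = "unnormalized"
            continue
        rel = prof / mean
        rel = rel.where(rel > 0)  # zero protein channel -> missing site value
        out.loc[[key]] = (site_matrix.loc[[key]].astype(float) / rel).values
    out.attrs = dict(site_matrix.attrs)
    out.attrs["normalization"] = list(site_matrix.attrs.get("normalization", [])) + [
        "site_to_protein"
    ]
    return out, flags


def relative_to_untreated(matrix: pd.DataFrame, design: PlexDesign) -> pd.DataFrame:
    """Express each channel relative to the mean of its genotype's untreated
    channels (time-course normalization applied separately per genotype)."""
    genotypes = {c.genotype for c in design.channels.values()}
    scale = {}
    for geno in genotypes:
        ut = [f"sn_{ch}" for ch in design.group(genotype=geno, treatment="UT")]
        ut = [c for c in ut if c in matrix.columns]
        geno_cols = [
            f"sn_{ch}" for ch in design.group(genotype=geno)
            if f"sn_{ch}" in matrix.columns
        ]
        if geno_cols and not ut:
            raise ValueError(f"genotype {geno!r} has no untreated channels")
        for col in geno_cols:
            scale[col] = matrix[ut].mean(axis=1, skipna=True)
    out = matrix.copy().astype(float)
    for col, denom in scale.items():
        out[col] = matrix[col] / denom
    out.attrs = dict(matrix.attrs)
    out.attrs["normalization"] = list(matrix.attrs.get("normalization", [])) + [
        "relative_to_untreated"
    ]
    return out
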