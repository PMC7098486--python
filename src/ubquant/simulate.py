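"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: profile-mode
intact-mass spectra of Ub^dGG proteoform mixtures, multiplexed TMT PSM
tables with planted depolarization/USP30 effects, flux-reporter immunoblot
and two-channel image data, and PRM light/heavy peak areas.  Each generator
takes an explicit seed and emits a ground-truth record alongside the data,
so recovery can be tested end to end.

Noise models: additive Gaussian noise (a configurable fraction of the base
peak) for profile spectra; multiplicative log-normal noise for TMT reporter
channels, blot bands, and PRM areas — the standard error structure of these
measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import UbProteoform, mz_for_charge, ub_dgg_candidates
from .intact import ProfileSpectrum

__all__ = [
    "ProteoformMixture",
    "SpectrumSimParams",
    "gen_intact_spectra",
    "PlexDesign",
    "ChannelCondition",
    "EffectModel",
    "gen_tmt_experiment",
    "gen_flux_blots",
    "gen_flux_images",
    "gen_prm_areas",
    "HELA_1H_MIXTURE",
    "INEURON_6H_MIXTURE",
    "eleven_plex_parkin",
    "ten_plex_usp30",
]


# ---------------------------------------------------------------------------
# intact-mass spectra
# ---------------------------------------------------------------------------

@dataclass
class ProteoformMixture:
    """Mapping UbProteoform -> relative fraction (non-negative, sums to 1)."""

    fractions: dict[UbProteoform, float]

    def __post_init__(self):
        vals = np.array(list(self.fractions.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    def items(self):
        return self.fractions.items()


def _mixture(phospho_and_unmod: dict[tuple[int, bool], float]) -> ProteoformMixture:
    return ProteoformMixture(
        {UbProteoform(n, p): f for (n, p), f in phospho_and_unmod.items()}
    )


# Depolarized-HeLa (1 h) composition: the phosphorylated species carry the
# published relative abundances (12%, 1.42%, 0.05% for 0/1/2 branches); the
# unphosphorylated complement is a realistic fill summing to 1.
HELA_1H_MIXTURE = _mixture({
    (0, False): 0.6863,
    (1, False): 0.14,
    (2, False): 0.035,
    (3, False): 0.004,
    (0, True): 0.12,
    (1, True): 0.0142,
    (2, True): 0.0005,
    (3, True): 0.0,
})

# Depolarized-iNeuron (6 h) composition: phospho species at 5.5% and 0.27%
# for 0/1 branches, with trace 2-branch signal.
INEURON_6H_MIXTURE = _mixture({
    (0, False): 0.8449,
    (1, False): 0.08,
    (2, False): 0.015,
    (3, False): 0.002,
    (0, True): 0.055,
    (1, True): 0.0027,
    (2, True): 0.0004,
    (3, True): 0.0,
})


@dataclass
class SpectrumSimParams:
    """Acquisition and simulation parameters for intact-mass spectra."""

    mz_window: tuple[float, float] = (625.0, 925.0)
    resolving_power: float = 60000.0  # at m/z 200, ~1/sqrt(m/z) scaling
    charge_mean: float = 12.0
    charge_sigma: float = 1.2
    max_charge: int = 17
    n_scans: int = 5
    elution_sigma_scans: float = 1.0
    total_intensity: float = 1.0e6
    noise_level: float = 0.0  # Gaussian sd as a fraction of the base peak
    grid_step: float | None = None  # default: finest FWHM / 5
    n_isotope_peaks: int = 45
    seed: int = 0

    def __post_init__(self):
        if self.mz_window[0] >= self.mz_window[1]:
            raise ValueError("mz window low must be below high")
        if self.resolving_power <= 0:
            raise ValueError("resolving power must be positive")

    def sigma_at(self, mz: float) -> float:
        r = self.resolving_power * math.sqrt(200.0 / mz)
        return (mz / r) / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def gen_intact_spectra(
    mixture: ProteoformMixture, params: SpectrumSimParams
) -> tuple[list[ProfileSpectrum], dict]:
    """Render profile spectra of a proteoform mixture with ground truth.

    For each scan, every proteoform's isotopic cluster is rendered as
    Gaussian profiles at each charge state whose envelope falls inside the
    m/z window, scaled by mixture fraction x normalized charge-envelope
    weight x Gaussian elution weight.  Total rendered area per species
    equals fraction x total_intensity (noise off), so XIC integration can
    be checked in closed form.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.mz_window
    step = params.grid_step
    if step is None:
        step = params.sigma_at(lo) * 2.3548 / 5.0
    grid = np.arange(lo, hi + step, step)
    scans = [np.zeros_like(grid) for _ in range(params.n_scans)]

    centers = (params.n_scans - 1) / 2.0
    elut = np.exp(
        -0.5 * ((np.arange(params.n_scans) - centers) / params.elution_sigma_scans) ** 2
    )
    elut = elut / elut.sum()

    truth_species = []
    warnings_list = []
    for proteoform, fraction in mixture.items():
        dist = proteoform.isotope_distribution(params.n_isotope_peaks)
        mono = proteoform.monoisotopic_mass
        usable = []
        for z in range(1, params.max_charge + 1):
            mzs = (dist.masses + z * 1.007276466) / z
            if mzs.min() >= lo and mzs.max() <= hi:
                w = math.exp(-0.5 * ((z - params.charge_mean) / params.charge_sigma) ** 2)
                usable.append((z, w, mzs))
        record = {
            "proteoform": proteoform.label,
            "n_branches": proteoform.n_digly_branches,
            "phosphorylated": proteoform.phosphorylated,
            "monoisotopic_mass": mono,
            "fraction": fraction,
            "total_area": fraction * params.total_intensity,
            "charges": [z for z, _, _ in usable],
        }
        truth_species.append(record)
        if fraction > 0 and not usable:
            warnings_list.append(
                f"{proteoform.label}: no charge state inside the m/z window; "
                "species is not deconvolvable"
            )
            continue
        if fraction == 0 or not usable:
            continue
        wsum = sum(w for _, w, _ in usable)
        for z, w, mzs in usable:
            for k in range(len(dist)):
                ab = dist.abundances[k]
                if ab < 1e-7:
                    continue
                for s in range(params.n_scans):
                    area = fraction * params.total_intensity * (w / wsum) * elut[s] * ab
                    mu = mzs[k]
                    sig = params.sigma_at(mu)
                    j0 = np.searchsorted(grid, mu - 6 * sig)
                    j1 = np.searchsorted(grid, mu + 6 * sig)
                    x = grid[j0:j1]
                    scans[s][j0:j1] += (
                        area / (sig * math.sqrt(2.0 * math.pi))
                    ) * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    spectra = []
    for s, y in enumerate(scans):
        if params.noise_level > 0:
            y = y + rng.normal(0.0, params.noise_level * y.max(), size=y.size)
            y = np.clip(y, 0.0, None)
        spectra.append(
            ProfileSpectrum(
                mz=grid.copy(), intensity=y, scan_index=s,
                mz_window=params.mz_window,
                resolving_power=params.resolving_power,
            )
        )
    truth = {
        "species": truth_species,
        "elution_weights": elut.tolist(),
        "grid_step": float(step),
        "seed": params.seed,
        "warnings": warnings_list,
    }
    return spectra, truth


# ---------------------------------------------------------------------------
# TMT plex experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelCondition:
    genotype: str
    treatment: str  # "UT" or "AO"
    timepoint_h: float
    replicate: int


@dataclass
class PlexDesign:
    """Per-channel experimental conditions for a 10- or 11-plex."""

    channels: dict[str, ChannelCondition]

    def __post_init__(self):
        if len(self.channels) not in (10, 11):
            raise ValueError("plex size must be 10 or 11")
        conds = {}
        for name, c in self.channels.items():
            key = (c.genotype, c.treatment, c.timepoint_h, c.replicate)
            if key in conds:
                raise ValueError(f"duplicate channel condition {key}")
            conds[key] = name

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def group(self, genotype=None, treatment=None, timepoint_h=None) -> list[str]:
        out = []
        for name, c in self.channels.items():
            if genotype is not None and c.genotype != genotype:
                continue
            if treatment is not None and c.treatment != treatment:
                continue
            if timepoint_h is not None and c.timepoint_h != timepoint_h:
                continue
            out.append(name)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"channel": name, "genotype": c.genotype, "treatment": c.treatment,
                 "timepoint_h": c.timepoint_h, "replicate": c.replicate}
                for name, c in self.channels.items()
            ]
        )


_TMT11 = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
          "130C", "131N", "131C"]


def eleven_plex_parkin() -> PlexDesign:
    """11-plex WT/S65A-Parkin depolarization layout (untreated, 2 h, 6 h).

    WT untreated and 6 h are triplicates so the primary untreated-vs-6 h
    contrast has n=3 per arm; WT 2 h is a duplicate and S65A 6 h a
    triplicate.
    """
    conds = (
        [("WT", "UT", 0.0, r) for r in (1, 2, 3)]
        + [("WT", "AO", 2.0, r) for r in (1, 2)]
        + [("WT", "AO", 6.0, r) for r in (1, 2, 3)]
        + [("S65A", "AO", 6.0, r) for r in (1, 2, 3)]
    )
    return PlexDesign(
        {ch: ChannelCondition(*c) for ch, c in zip(_TMT11, conds)}
    )


def ten_plex_usp30() -> PlexDesign:
    """10-plex WT / USP30-null time course (0, 1, 2, 3, 4 h depolarization)."""
    conds = []
    for geno in ("WT", "USP30KO"):
        conds.append((geno, "UT", 0.0, 1))
        for t in (1.0, 2.0, 3.0, 4.0):
            conds.append((geno, "AO", t, 1))
    return PlexDesign(
        {ch: ChannelCondition(*c) for ch, c in zip(_TMT11[:10], conds)}
    )


@dataclass
class EffectModel:
    """Planted effect structure and noise model for a TMT layer.

    ``planted_effects`` maps a feature index to a dict of
    (genotype, treatment, timepoint) -> log2 effect relative to that
    feature's basal mean; unlisted features are null.  ``attenuation``
    scales planted log2 effects in the named genotype (e.g. the reduced
    ubiquitylation signature of S65A-Parkin).
    """

    noise_sigma_log2: float = 0.25
    psm_count_lambda: float = 1.5  # PSMs per feature = 1 + Poisson(lambda)
    planted_effects: dict[int, dict[tuple[str, str, float], float]] = field(
        default_factory=dict
    )
    attenuated_genotype: str | None = None
    attenuation: float = 1.0  # multiplies planted log2 effects, in [0, 1]
    frac_low_specificity: float = 0.05
    frac_low_sn: float = 0.05
    frac_no_ms3: float = 0.02
    frac_poor_localization: float = 0.02
    base_intensity_range: tuple[float, float] = (200.0, 5000.0)

    def __post_init__(self):
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must be in [0, 1]")
        if self.noise_sigma_log2 < 0:
            raise ValueError("noise sigma must be >= 0")


def gen_tmt_experiment(
    design: PlexDesign,
    effects: EffectModel,
    n_features: int,
    seed: int = 0,
    layer: str = "diGLY",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a PSM-level TMT table for one quantification layer.

    Returns ``(psm_table, truth)``.  The PSM table carries peptide, protein,
    modification type and site, AScore, isolation specificity, summed
    reporter S/N, an MS3 flag, and per-channel reporter S/N columns
    (``sn_<channel>``).  Planted effects shift channel means before noise.
    The truth table lists each feature's class, per-channel expected
    relative level, and per-filter violation counts are included in
    ``truth.attrs['filter_violations']``.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    channels = design.channel_names
    conds = [design.channels[ch] for ch in channels]

    mod_type = {"proteome": "none", "diGLY": "diGLY", "phospho": "phospho"}[layer]
    rows = []
    truth_rows = []
    violations = {"low_specificity": 0, "low_sn": 0, "no_ms3": 0,
                  "poor_localization": 0}
    lo_b, hi_b = effects.base_intensity_range
    for i in range(n_features):
        protein = f"PROT{i // 3 + 1:04d}" if layer != "proteome" else f"PROT{i + 1:04d}"
        # sites are distinct within a protein so features never merge at rollup
        site = 0 if mod_type == "none" else int(5 + 37 * (i % 3) + i // 3 % 37)
        peptide = f"PEP{layer[:2].upper()}{i:05d}K"
        eff = effects.planted_effects.get(i, {})
        log2_by_channel = []
        for c in conds:
            e = eff.get((c.genotype, c.treatment, c.timepoint_h), 0.0)
            if effects.attenuated_genotype and c.genotype == effects.attenuated_genotype:
                e *= effects.attenuation
            log2_by_channel.append(e)
        log2_by_channel = np.array(log2_by_channel)
        base = math.exp(rng.uniform(math.log(lo_b), math.log(hi_b)))
        channel_means = base * np.power(2.0, log2_by_channel)

        n_psms = 1 + int(rng.poisson(effects.psm_count_lambda))
        for j in range(n_psms):
            # the feature set emulates *quantified* peptides: every feature
            # keeps at least one clean PSM, and filter-violating PSMs are
            # contamination on top of that
            if j == 0:
                low_spec = low_sn = no_ms3 = poor_loc = False
            else:
                low_spec = rng.random() < effects.frac_low_specificity
                low_sn = rng.random() < effects.frac_low_sn
                no_ms3 = rng.random() < effects.frac_no_ms3
                poor_loc = (mod_type != "none"
                            and rng.random() < effects.frac_poor_localization)
            violations["low_specificity"] += low_spec
            violations["low_sn"] += low_sn
            violations["no_ms3"] += no_ms3
            violations["poor_localization"] += poor_loc
            spec = (rng.uniform(0.30, 0.699) if low_spec
                    else rng.uniform(0.75, 1.0))
            if effects.noise_sigma_log2 > 0:
                noise = rng.lognormal(
                    0.0, effects.noise_sigma_log2 * math.log(2.0), size=len(channels)
                )
            else:
                noise = np.ones(len(channels))
            profile = channel_means * noise
            total = (rng.uniform(20.0, 149.0) if low_sn
                     else math.exp(rng.uniform(math.log(160.0), math.log(8000.0))))
            sn = profile / profile.sum() * total
            ascore = (rng.uniform(0.0, 12.9) if poor_loc
                      else rng.uniform(15.0, 1000.0))
            row = {
                "peptide": peptide + str(j), "protein": protein,
                "mod_type": mod_type, "site": site,
                "ascore": float(ascore) if mod_type != "none" else np.nan,
                "isolation_specificity": float(spec),
                "summed_sn": float(sn.sum()),
                "has_ms3": not no_ms3,
            }
            for ch, v in zip(channels, sn):
                row[f"sn_{ch}"] = float(v)
            rows.append(row)
        truth_rows.append(
            {"feature": i, "protein": protein, "site": site, "mod_type": mod_type,
             "is_planted": i in effects.planted_effects, "n_psms": n_psms,
             **{f"log2_{ch}": e for ch, e in zip(channels, log2_by_channel)}}
        )
    psm_table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["filter_violations"] = violations
    truth.attrs["seed"] = seed
    truth.attrs["layer"] = layer
    return psm_table, truth


# ---------------------------------------------------------------------------
# flux reporters
# ---------------------------------------------------------------------------

def gen_flux_blots(
    conditions: list[dict],
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    background: float = 50.0,
    post_import_level: float = 5000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate quantitative-immunoblot band intensities for Keima reporters.

    ``conditions`` rows need ``genotype``, ``treatment``, ``time_h`` and the
    ground-truth ``true_ratio`` of processed to unprocessed (post-import)
    reporter.  Band intensities are drawn log-normally around the true
    levels on top of a shared background.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            noise = rng.lognormal(0.0, noise_cv, size=2) if noise_cv > 0 else np.ones(2)
            post = background + post_import_level * noise[0]
            processed = background + post_import_level * cond["true_ratio"] * noise[1]
            rows.append(
                {"genotype": cond["genotype"], "treatment": cond["treatment"],
                 "time_h": cond["time_h"], "replicate": rep,
                 "post_import_intensity": float(post),
                 "processed_intensity": float(processed),
                 "background": float(background)}
            )
    truth = pd.DataFrame(conditions)
    truth.attrs["seed"] = seed
    return pd.DataFrame(rows), truth


def gen_flux_images(
    n_somata: int = 10,
    shape: tuple[int, int] = (96, 96),
    soma_intensity: float = 400.0,
    n_puncta: int = 3,
    punctum_radius: int = 3,
    punctum_intensity: float = 800.0,
    low_expression_fraction: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[dict], dict]:
    """Two-channel (red=mCherry, green=GFP) soma images with red-only puncta.

    Each soma is a filled disk present in both channels; mitophagic puncta
    are red-only disks.  A configurable fraction of somata is rendered at
    10% expression to exercise the expression filter.  Ground truth records
    per-soma punctum pixel counts and the closed-form red-only signal.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    images = []
    truth_rows = []
    n_low = int(round(low_expression_fraction * n_somata))
    for i in range(n_somata):
        level = 0.10 if i < n_low else 1.0
        cy, cx, r = h // 2, w // 2, min(h, w) // 3
        soma = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r
        green = np.where(soma, soma_intensity * level, 0.0)
        red = green.copy()
        punct_px = 0
        for _ in range(n_puncta):
            py = int(rng.integers(cy - r // 2, cy + r // 2))
            px = int(rng.integers(cx - r // 2, cx + r // 2))
            punct = ((yy - py) ** 2 + (xx - px) ** 2) <= punctum_radius ** 2
            red = np.where(punct, green + punctum_intensity * level, red)
            punct_px = int(np.count_nonzero(red - green > 0))
        if noise_sd > 0:
            green = np.clip(green + rng.normal(0, noise_sd, shape), 0, None)
            red = np.clip(red + rng.normal(0, noise_sd, shape), 0, None)
        images.append({"soma_id": f"soma{i:02d}", "red": red, "green": green})
        truth_rows.append(
            {"soma_id": f"soma{i:02d}", "expression_level": level,
             "punctum_pixels": punct_px,
             "punctum_intensity": punctum_intensity * level}
        )
    truth = {"somata": truth_rows, "n_low_expression": n_low, "seed": seed}
    return images, truth


# ---------------------------------------------------------------------------
# PRM
# ---------------------------------------------------------------------------

def gen_prm_areas(
    proteins: dict[str, float],
    peptides_per_protein: dict[str, int],
    spike_fmol: float = 50.0,
    input_ug: float = 1.0,
    noise_cv: float = 0.0,
    heavy_area_scale: float = 1.0e6,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Light/heavy PRM peak-area pairs for heavy-reference quantification.

    ``proteins`` maps protein -> true abundance (fmol per ug of
    mitochondria).  The light/heavy area ratio encodes
    ``true_fmol_in_sample / spike_fmol`` with optional multiplicative
    log-normal noise.
    """
    if spike_fmol <= 0:
        raise ValueError("spike_fmol must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for protein, fmol_per_ug in proteins.items():
        n_pep = peptides_per_protein.get(protein, 2)
        for j in range(1, n_pep + 1):
            heavy = heavy_area_scale * rng.uniform(0.5, 2.0)
            ratio = fmol_per_ug * input_ug / spike_fmol
            if noise_cv > 0:
                ratio *= rng.lognormal(0.0, noise_cv)
            rows.append(
                {"protein": protein, "peptide": f"{protein}_pep{j}",
                 "spike_fmol": spike_fmol, "light_area": float(heavy * ratio),
                 "heavy_area": float(heavy), "input_ug": input_ug}
            )
    truth = {"fmol_per_ug": dict(proteins), "spike_fmol": spike_fmol,
             "input_ug": input_ug, "seed": seed}
    return pd.DataFrame(rows), truth
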