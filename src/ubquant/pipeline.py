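"""End-to-end orchestration: simulate inputs, run the quantification
stages, and check computed values against an expectations table.

A run is described by a :class:`RunConfig` (YAML or dict): which stages to
execute, where to write outputs, a global seed, and per-stage parameter
blocks.  Stages run in dependency order, write their tables as TSV/JSON,
and contribute a summary to the :class:`RunReport`; identical (config,
seed) pairs produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ubio
from .chem import UbProteoform, ub_dgg_candidates
from .flux import FluxMeasurement, keima_ratio, prm_abundance, stoichiometry
from .intact import DeconvParams, UB_MASS_RANGE, deconvolve_run
from .simulate import (
    EffectModel,
    HELA_1H_MIXTURE,
    INEURON_6H_MIXTURE,
    ProteoformMixture,
    SpectrumSimParams,
    eleven_plex_parkin,
    gen_flux_blots,
    gen_intact_spectra,
    gen_prm_areas,
    gen_tmt_experiment,
    ten_plex_usp30,
)
from .stats import StatsParams, diff_test
from .tmt import (
    filter_psms,
    normalize_equal_loading,
    normalize_site_to_protein,
    rollup,
)

__all__ = ["RunConfig", "RunReport", "StageError", "run_pipeline", "check_acceptance"]

_MIXTURES = {"hela_1h": HELA_1H_MIXTURE, "ineuron_6h": INEURON_6H_MIXTURE}
_DESIGNS = {"parkin_11plex": eleven_plex_parkin, "usp30_10plex": ten_plex_usp30}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    stages: list[str]
    outdir: str = "pipeline_out"
    seed: int = 0
    intact: dict = field(default_factory=dict)
    tmt: dict = field(default_factory=dict)
    flux: dict = field(default_factory=dict)
    prm: dict = field(default_factory=dict)

    KNOWN_STAGES = ("intact", "tmt", "flux", "prm")

    def __post_init__(self):
        unknown = set(self.stages) - set(self.KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(
            {"stages": self.stages, "seed": self.seed, "intact": self.intact,
             "tmt": self.tmt, "flux": self.flux, "prm": self.prm},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def value(self, path: str):
        """Dotted-path lookup into the stage summaries."""
        node = self.stages
        for part in path.split("."):
            node = node[part]
        return node


def _stage_intact(cfg: dict, seed: int, outdir: Path) -> dict:
    mixture_cfg = cfg.get("mixture", "hela_1h")
    if isinstance(mixture_cfg, str):
        mixture = _MIXTURES[mixture_cfg]
        mixture_name = mixture_cfg
    else:
        mixture = ProteoformMixture(
            {UbProteoform(int(n), bool(p)): float(f)
             for (n, p), f in mixture_cfg.items()}
        )
        mixture_name = "custom"
    sim = SpectrumSimParams(
        noise_level=float(cfg.get("noise_level", 0.0)),
        n_scans=int(cfg.get("n_scans", 5)),
        seed=seed,
    )
    spectra, truth = gen_intact_spectra(mixture, sim)
    ubio.write_spectra_tsv(spectra, outdir / "intact_spectra.tsv")
    ubio.write_json(truth, outdir / "intact_truth.json")
    params = DeconvParams(mass_range=UB_MASS_RANGE)
    _, result = deconvolve_run(spectra, params, ub_dgg_candidates())
    frame = result.to_frame()
    ubio.write_table(frame, outdir / "proteoform_fractions.tsv")
    percents = {
        row.proteoform: 100.0 * row.relative_abundance
        for row in frame.itertuples(index=False)
    }
    return {
        "mixture": mixture_name,
        "unassigned_fraction": result.unassigned_fraction,
        "percent": percents,
    }


def _stage_tmt(cfg: dict, seed: int, outdir: Path) -> dict:
    design = _DESIGNS[cfg.get("design", "parkin_11plex")]()
    n_features = int(cfg.get("n_features", 2400))
    n_planted = int(cfg.get("n_planted", 134))
    effect_range = cfg.get("effect_range", (1.0, 3.0))
    rng = np.random.default_rng(seed)
    planted_idx = rng.choice(n_features, size=n_planted, replace=False)
    treated = [
        (c.genotype, c.treatment, c.timepoint_h)
        for c in design.channels.values()
        if c.genotype == "WT" and c.treatment == "AO"
    ]
    planted = {
        int(i): {cond: float(rng.uniform(*effect_range)) for cond in set(treated)}
        for i in planted_idx
    }
    effects = EffectModel(
        noise_sigma_log2=float(cfg.get("noise_sigma_log2", 0.25)),
        planted_effects=planted,
    )
    digly_psms, digly_truth = gen_tmt_experiment(
        design, effects, n_features, seed=seed + 1, layer="diGLY"
    )
    prot_psms, _ = gen_tmt_experiment(
        design, EffectModel(noise_sigma_log2=effects.noise_sigma_log2),
        max(n_features // 3, 10), seed=seed + 2, layer="proteome",
    )
    digly_kept, audit = filter_psms(digly_psms)
    prot_kept, _ = filter_psms(prot_psms)
    site_mat = normalize_equal_loading(rollup(digly_kept, level="site"))
    prot_mat = normalize_equal_loading(rollup(prot_kept, level="protein"))
    site_norm, flags = normalize_site_to_protein(site_mat, prot_mat)
    ubio.write_table(site_norm.reset_index(), outdir / "digly_site_matrix.tsv")
    ubio.write_table(prot_mat.reset_index(), outdir / "protein_matrix.tsv")
    ubio.write_table(digly_truth, outdir / "digly_truth.tsv")

    stats_cfg = cfg.get("stats", {})
    params = StatsParams(
        s0=float(stats_cfg.get("s0", 1.0)),
        fdr_level=float(stats_cfg.get("fdr_level", 0.01)),
        n_permutations=int(stats_cfg.get("n_permutations", 250)),
        seed=seed + 3,
    )
    cols_a = [f"sn_{ch}" for ch in design.group("WT", "AO", 6.0)]
    cols_b = [f"sn_{ch}" for ch in design.group("WT", "UT")]
    result = diff_test(site_norm, cols_a, cols_b, params)
    ubio.write_table(result.reset_index(), outdir / "digly_diff_results.tsv")

    hits = result[result["significant"] & (result["direction"] == "up")]
    planted_keys = set()
    feature_of = {}
    for row in digly_truth.itertuples(index=False):
        key = (row.protein, row.site, row.mod_type)
        feature_of[key] = row.feature
        if row.is_planted:
            planted_keys.add(key)
    hit_keys = set(hits.index)
    n_recovered = len(hit_keys & planted_keys)
    false_hits = len(hit_keys - planted_keys)
    return {
        "audit": audit,
        "n_features_tested": int(result["d"].notna().sum()),
        "n_planted": n_planted,
        "n_significant_up": int(len(hit_keys)),
        "n_recovered": int(n_recovered),
        "recall": n_recovered / n_planted if n_planted else np.nan,
        "false_discovery_proportion": false_hits / max(len(hit_keys), 1),
    }


def _stage_flux(cfg: dict, seed: int, outdir: Path) -> dict:
    trajectory = cfg.get(
        "trajectory",
        [{"genotype": "WT", "treatment": "UT", "time_h": 0.0, "true_ratio": 0.3},
         {"genotype": "WT", "treatment": "AO", "time_h": 4.0, "true_ratio": 0.4},
         {"genotype": "WT", "treatment": "AO", "time_h": 12.0, "true_ratio": 0.5}],
    )
    blots, truth = gen_flux_blots(
        trajectory, noise_cv=float(cfg.get("noise_cv", 0.02)), seed=seed
    )
    ubio.write_table(blots, outdir / "flux_blots.tsv")
    ratios = blots.assign(
        ratio=[
            keima_ratio(FluxMeasurement(
                sample=f"{r.genotype}-{r.time_h}h-{r.replicate}",
                post_import_intensity=r.post_import_intensity,
                processed_intensity=r.processed_intensity,
                background=r.background,
            ))
            for r in blots.itertuples(index=False)
        ]
    )
    summary = (
        ratios.groupby(["genotype", "treatment", "time_h"])["ratio"]
        .mean()
        .reset_index()
    )
    ubio.write_table(summary, outdir / "flux_ratios.tsv")
    return {
        "ratio_by_time": {
            f"{r.genotype}_{r.time_h:g}h": float(r.ratio)
            for r in summary.itertuples(index=False)
        }
    }


def _stage_prm(cfg: dict, seed: int, outdir: Path) -> dict:
    proteins = cfg.get(
        "proteins", {"TOMM20": 10.0, "TOMM70": 8.0, "USP30": 3.0}
    )
    peptides = cfg.get(
        "peptides_per_protein", {"TOMM20": 2, "TOMM70": 6, "USP30": 2}
    )
    table, truth = gen_prm_areas(
        proteins, peptides, noise_cv=float(cfg.get("noise_cv", 0.03)), seed=seed
    )
    ubio.write_table(table, outdir / "prm_areas.tsv")
    abundances = {
        protein: prm_abundance(grp) for protein, grp in table.groupby("protein")
    }
    ratios = {}
    if "USP30" in abundances:
        for ref in ("TOMM20", "TOMM70"):
            if ref in abundances:
                r, e = stoichiometry(abundances["USP30"], abundances[ref])
                ratios[f"USP30_to_{ref}"] = {"ratio": r, "error": e}
    return {
        "fmol_per_ug": {p: {"mean": m, "sem": s} for p, (m, s) in abundances.items()},
        "stoichiometry": ratios,
    }


_STAGE_FUNCS = {
    "intact": _stage_intact,
    "tmt": _stage_tmt,
    "flux": _stage_flux,
    "prm": _stage_prm,
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the selected stages in dependency order.

    Every stage writes its tables under ``config.outdir`` and contributes a
    summary; a stage failure halts the run with a :class:`StageError`
    naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.digest(), seed=config.seed)
    for stage in config.KNOWN_STAGES:
        if stage not in config.stages:
            continue
        cfg = getattr(config, stage)
        try:
            report.stages[stage] = _STAGE_FUNCS[stage](cfg, config.seed, outdir)
        except Exception as exc:  # noqa: BLE001 - structured stage error
            raise StageError(stage, exc) from exc
    ubio.write_json(
        {"config_hash": report.config_hash, "seed": report.seed,
         "stages": report.stages},
        outdir / "run_report.json",
    )
    return report


def check_acceptance(report: RunReport, targets: list[dict]) -> tuple[pd.DataFrame, bool]:
    """Compare report values against an expectations table.

    Each target needs ``id``, ``path`` (dotted lookup into the report),
    ``expected`` and ``tolerance``.  Returns the pass/fail table and an
    overall flag (an empty target list passes trivially).
    """
    rows = []
    for t in targets:
        try:
            value = float(report.value(t["path"]))
            ok = abs(value - float(t["expected"])) <= float(t["tolerance"])
        except KeyError:
            value, ok = np.nan, False
        rows.append(
            {"id": t["id"], "value": value, "expected": t["expected"],
             "tolerance": t["tolerance"], "passed": bool(ok)}
        )
    table = pd.DataFrame(rows)
    return table, bool(table["passed"].all()) if len(table) else True
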