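"""diGLY ubiquitylome quantification with permutation-FDR statistics.

Simulates an 11-plex TMT-MS3 diGLY experiment (WT and S65A-Parkin, with
and without depolarization) in which 134 of 2,400 ubiquitylation sites are
planted with elevated abundance after 6 h of depolarization (log2 >= 1).
The pipeline filters PSMs, rolls up to sites, applies equal-loading and
site-to-protein normalization, then calls significance with a moderated
Welch test (S0 = 1) and SAM-style permutation FDR at 1%.
"""

from ubquant.pipeline import RunConfig, run_pipeline

cfg = RunConfig(stages=["tmt"], outdir="example_out", seed=17)
summary = run_pipeline(cfg).stages["tmt"]

print(f"PSMs retained after quality filters: {summary['audit']['retained']}")
print(f"  excluded: {summary['audit']['excluded_total']} "
      f"(specificity<0.7: {summary['audit']['low_specificity']}, "
      f"S/N<150: {summary['audit']['low_sn']}, "
      f"no MS3: {summary['audit']['no_ms3']})")
print(f"features tested: {summary['n_features_tested']}")
print(f"planted elevated sites: {summary['n_planted']}")
print(f"significant (up, FDR 1%): {summary['n_significant_up']}")
print(f"recall of planted sites: {summary['recall']:.1%}")
print(f"observed false-discovery proportion: "
      f"{summary['false_discovery_proportion']:.1%}")
print("High recall with an FDP at or below the nominal level shows the")
print("permutation FDR is calibrated on realistic reporter-ion noise.")
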