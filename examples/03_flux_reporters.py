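"""Mitophagic-flux quantification from Keima blots and two-channel images.

Simulates quantitative-immunoblot bands for the processed (lysosome
resistant) and post-import forms of a matrix-targeted Keima reporter over
a depolarization time course (basal flux ratio ~0.3 rising to ~0.5), and a
cohort of mCherry-GFP soma images with red-only mitolysosome puncta,
including low-expressing cells removed by the 30% expression filter.
"""

import numpy as np

from ubquant.flux import (
    FluxMeasurement,
    expression_filter,
    keima_ratio,
    red_only_signal,
)
from ubquant.simulate import gen_flux_blots, gen_flux_images

conditions = [
    {"genotype": "WT", "treatment": "UT", "time_h": 0.0, "true_ratio": 0.3},
    {"genotype": "WT", "treatment": "AO", "time_h": 4.0, "true_ratio": 0.4},
    {"genotype": "WT", "treatment": "AO", "time_h": 12.0, "true_ratio": 0.5},
]
blots, _ = gen_flux_blots(conditions, n_replicates=3, noise_cv=0.02, seed=2)
print("Keima processed/unprocessed ratio (mean of 3 replicates):")
for t, grp in blots.groupby("time_h"):
    ratios = [
        keima_ratio(FluxMeasurement("s", r.post_import_intensity,
                                    r.processed_intensity, r.background))
        for r in grp.itertuples(index=False)
    ]
    print(f"  {t:>5.1f} h  ratio = {np.mean(ratios):.3f}")
print("The rise from ~0.3 to ~0.5 is the depolarization-induced flux.")

images, truth = gen_flux_images(n_somata=10, low_expression_fraction=0.2, seed=3)
retained, excluded = expression_filter(images)
print(f"\nsomata imaged: {len(images)}, excluded by 30% expression rule: "
      f"{len(excluded)} ({', '.join(excluded)})")
signals = [red_only_signal(p["red"], p["green"]) for p in retained]
print(f"red-only signal per retained soma (area x %area x 0.01 x mean): "
      f"{np.mean(signals):.1f} +/- {np.std(signals):.1f}")
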