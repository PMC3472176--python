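"""Published reference estimates used in worked examples and cross-checks.

``REFERENCE_ESTIMATES`` holds REML variance components reported for six
production and fitness traits in a genotyped Nordic Holstein bull population
(5217 progeny-tested bulls, 44,012 informative SNP after QC): the pedigree
animal model (model 1), the genomic model (model 2), the joint genomic +
residual polygenic model (model 3), and the per-chromosome genomic variance
summed over 29 single-chromosome analyses (model 4). The summary functions
in :mod:`gvarpart.partition` reproduce the headline ratios from these
components — e.g. the average genomic share of total genetic variance and
the model-3 / model-1 total-variance ratios.
"""

import pandas as pd

REFERENCE_ESTIMATES = pd.DataFrame(
    [
        # trait,      m1_sigma_a2, m1_vr, m2_sigma_g2, m2_vr, m3_sigma_g2, m3_sigma_a2, m3_vr, m4_sum_sigma_c2
        ("milk",      138.24, 0.92, 134.18, 0.88, 119.49, 20.87, 0.93, 115.3),
        ("fat",       113.10, 0.91, 109.33, 0.87,  93.61, 22.36, 0.94,  90.5),
        ("protein",   143.16, 0.97, 132.99, 0.88, 106.67, 34.26, 0.96, 103.0),
        ("fertility", 151.74, 0.78, 142.42, 0.74, 110.38, 40.10, 0.78, 106.5),
        ("health",    141.57, 0.65, 136.70, 0.63, 101.84, 42.60, 0.66,  98.4),
        ("mastitis",   99.19, 0.82,  97.30, 0.79,  81.77, 23.67, 0.85,  79.0),
    ],
    columns=["trait", "m1_sigma_a2", "m1_vr", "m2_sigma_g2", "m2_vr",
             "m3_sigma_g2", "m3_sigma_a2", "m3_vr", "m4_sum_sigma_c2"],
).set_index("trait")

#: Traits conventionally grouped as production vs fitness.
PRODUCTION_TRAITS = ["milk", "fat", "protein"]
FITNESS_TRAITS = ["fertility", "health", "mastitis"]
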