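"""Bundled example data.

:func:`nine_phenotype_counts` returns the per-trait replication counts of a
published nine-phenotype comparison of earlier (non-biobank) GWAS against
later UK Biobank GWAS of the same traits: for each trait, the number of SNVs
reaching genome-wide significance (P < 5e-8) in the discovery GWAS and the
number of those that replicated (significant and direction-congruent in the
UK Biobank GWAS).  These counts exercise the rate and pooling stages without
any raw summary statistics ("pre-called counts" mode).
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # trait, type, total sample size, discovery-significant SNVs, replicated
    ("Asthma", "binary", 225_309, 889, 494),
    ("Systolic blood pressure", "quantitative", 430_797, 110, 107),
    ("Eczema", "binary", 330_142, 640, 337),
    ("Body mass index", "quantitative", 613_900, 1835, 1756),
    ("Waist circumference", "quantitative", 618_033, 937, 827),
    ("Hip circumference", "quantitative", 598_925, 1083, 1043),
    ("Coronary artery disease", "binary", 387_786, 159, 149),
    ("Resting heart rate", "quantitative", 447_198, 549, 547),
    ("Diastolic blood pressure", "quantitative", 430_806, 87, 83),
]


def nine_phenotype_counts() -> pd.DataFrame:
    """Per-trait replication counts (columns: trait_name, trait_type,
    total_sample_size, n_significant, k_replicated)."""
    return pd.DataFrame(
        _ROWS,
        columns=["trait_name", "trait_type", "total_sample_size", "n_significant", "k_replicated"],
    )
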