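import numpy as np
import pandas as pd
import pytest

import gwasrep as g


def write_tsv(path, rows: dict) -> str:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return str(path)


@pytest.fixture
def sumstats_rows():
    """Three well-formed summary-statistics rows in default column names."""
    return {
        "SNP": ["rs1", "rs2", "rs3"],
        "A1": ["A", "C", "G"],
        "A2": ["G", "T", "T"],
        "BETA": [0.10, -0.05, 0.02],
        "SE": [0.01, 0.02, 0.015],
        "P": [1e-9, 0.012, 0.18],
        "EAF": [0.3, 0.45, 0.12],
        "INFO": [0.98, 0.91, 0.99],
        "N": [50000, 50000, 50000],
    }


@pytest.fixture(scope="session")
def sim_harmonized():
    """One mid-sized simulated pair, harmonized, with calls and ground truth."""
    cfg = g.SimConfig(
        n_snvs=20_000,
        frac_null=0.9,
        tau=0.05,
        n_discovery=20_000,
        n_replication=40_000,
        p_allele_swap=0.3,
        p_missing_rsid=0.05,
        seed=20240917,
    )
    pair, truth = g.simulate_pair(cfg)
    harm = g.harmonize_pair(pair)
    calls = g.call_replication(harm.table)
    return {"config": cfg, "pair": pair, "truth": truth, "harm": harm, "calls": calls}


@pytest.fixture(scope="session")
def nine_trait_estimates():
    """Per-trait RateEstimates built from the bundled nine-phenotype counts."""
    counts = g.nine_phenotype_counts()
    ests = [
        g.rate_from_counts(int(r.k_replicated), int(r.n_significant), r.trait_name)
        for r in counts.itertuples()
    ]
    return counts, ests


def brute_force_auc(y, scores) -> float:
    """Exhaustive pair-counting AUC oracle: (concordant + ties/2) / pairs."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = conc = ties = 0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                conc += 1
            elif a == b:
                ties += 1
    return (conc + 0.5 * ties) / total
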