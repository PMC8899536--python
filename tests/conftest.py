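import pandas as pd
import pytest

import esterscreen as es


@pytest.fixture
def small_counts() -> pd.DataFrame:
    """Hand-sized count table with one clear up, one clear down, nulls."""
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC", "gD", "gE"],
            "count_group1": [300, 10, 100, 0, 55],
            "count_group2": [100, 300, 100, 40, 50],
        }
    )


@pytest.fixture
def small_annotations() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC", "gD", "gE"],
            "kegg_ko": ["K16815", "K16815", "NA", "NA", "NA"],
            "go_terms": ["GO:0016042", "GO:0016787", "GO:0008150", "GO:0016787", ""],
            "annotation_label": ["Lipase", "Lipase", "", "Esterase", ""],
        }
    )


@pytest.fixture
def recovery_sim():
    """Simulation tuned so the pipeline should recover the shortlist exactly:
    planted folds >= 4 and expected counts >= 50 in deep libraries."""
    cfg = es.SimConfig(
        n_genes=24319,
        n1=1_000_000,
        n2=1_000_000,
        de_fraction=0.05,
        fold_min=4.0,
        fold_max=10.0,
        planted_candidates=23,
        seed=20210820,
    )
    return es.simulate_counts(cfg)
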