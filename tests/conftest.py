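import numpy as np
import pandas as pd
import pytest

import metaboratio as mr


@pytest.fixture(scope="session")
def default_panel():
    """One synthetic panel at generator defaults, carried through the pipeline."""
    cfg = mr.SyntheticConfig(seed=11)
    abundance, meta, truth = mr.generate_panel(cfg)
    return cfg, abundance, meta, truth


@pytest.fixture(scope="session")
def corrected_panel(default_panel):
    """Log10 + RUV-III (k=9) + replicate aggregation of the default panel."""
    cfg, abundance, meta, truth = default_panel
    logged = mr.log10_transform(abundance)
    design = mr.build_replicate_design(meta, logged.sample_ids)
    model = mr.ruv3_correct(logged, design, k=9)
    aggregated = mr.aggregate_replicates(model.corrected, meta)
    return cfg, meta, truth, model, aggregated


@pytest.fixture(scope="session")
def ratio_panel(corrected_panel):
    """Unscaled and z-scored ratio matrices for the default panel."""
    cfg, meta, truth, model, aggregated = corrected_panel
    feats = mr.build_ratio_features(cfg.pathway_set, aggregated.metabolite_ids)
    ratios = mr.compute_ratio_matrix(aggregated, feats)
    scaled = mr.zscore_features(ratios)
    return cfg, truth, ratios, scaled


def make_abundance(values, sample_ids=None, metabolite_ids=None, scale="raw"):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    metabolite_ids = metabolite_ids or [f"m{j}" for j in range(values.shape[1])]
    return mr.AbundanceMatrix(
        pd.DataFrame(values, index=sample_ids, columns=metabolite_ids), scale=scale
    )
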