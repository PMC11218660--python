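"""Shared fixtures: a small end-to-end simulated REF/ALT study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cardmpra import sim, quantify, active


@pytest.fixture(scope="session")
def study():
    """A compact simulated REF/ALT assay with effects planted on active
    reference regions, carried through FPM normalization and active calls."""
    cfg = sim.SimConfig(seed=42, n_regions=120, active_fraction=0.3,
                        activity_log2fc_range=(1.0, 2.0),
                        variant_effect_fraction=0.0)
    genome, regions = sim.simulate_genome(cfg)
    pair_ids = [f"pair_{r}" for r in regions["region_id"]]
    truth = sim.assign_truth(regions, cfg, pair_ids=pair_ids)
    for i, r in enumerate(sorted(truth.active_regions())):
        truth.pair_effect[f"pair_{r}"] = 1.5 if i % 2 == 0 else -1.5
    designs = pd.DataFrame({
        "design_id": np.concatenate([regions["region_id"] + "_REF",
                                     regions["region_id"] + "_ALT"]),
        "region_id": np.tile(regions["region_id"], 2),
        "pair_id": np.tile(pair_ids, 2),
        "role": ["REF"] * len(regions) + ["ALT"] * len(regions),
    })
    counts = sim.simulate_counts(designs, truth, cfg)
    fpm = quantify.normalize_fpm(counts)
    keep = quantify.filter_coverage(fpm)
    activity = quantify.activity_scores(fpm, keep)
    calls = active.call_active(counts, keep=keep)
    pair_table = pd.DataFrame({
        "pair_id": pair_ids,
        "ref_id": regions["region_id"] + "_REF",
        "alt_id": regions["region_id"] + "_ALT",
    })
    return {
        "config": cfg, "genome": genome, "regions": regions, "truth": truth,
        "designs": designs, "counts": counts, "fpm": fpm, "keep": keep,
        "activity": activity, "calls": calls, "pairs": pair_table,
    }
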