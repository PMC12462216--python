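import numpy as np
import pandas as pd
import pytest

from nigraspace.io import CountMatrix
from nigraspace.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def two_group_null():
    """2000-gene two-group null dataset (12 vs 12 ROIs, no planted effects)."""
    cfg = SimulationConfig(
        n_genes=2000, groups=("HC", "PD"), n_subjects_per_group=2,
        rois_per_subject=6, frac_de=0.0, unwanted_sigma=0.0, seed=101,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def two_group_planted():
    """Two-group dataset with 10% planted DE at |log2FC| = 2."""
    cfg = SimulationConfig(
        n_genes=2000, groups=("HC", "PD"), n_subjects_per_group=2,
        rois_per_subject=6, frac_de=0.1, effect_log2fc=2.0,
        unwanted_sigma=0.0, seed=202,
    )
    return generate_dataset(cfg)


@pytest.fixture
def tiny_counts():
    """Hand-sized count matrix for algebraic checks."""
    df = pd.DataFrame(
        {"R1": [10, 20, 5, 0], "R2": [20, 40, 10, 0], "R3": [12, 18, 6, 1]},
        index=["GA", "GB", "GC", "GD"],
    )
    return CountMatrix(df)


@pytest.fixture
def meta_for(request):
    def build(counts, groups=("HC", "PD"), quadrants=("DM", "DL", "VM", "VL"), nuclei=200):
        rois = counts.rois
        rows = []
        for i, r in enumerate(rois):
            g = groups[i % len(groups)]
            rows.append(
                {
                    "roi_id": r, "subject_id": f"{g}1", "group": g,
                    "quadrant": quadrants[i % len(quadrants)],
                    "slide_id": f"slide_{g}1", "nuclei_count": nuclei,
                }
            )
        return pd.DataFrame(rows)

    return build
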