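import numpy as np
import pytest

import attnmod as am


@pytest.fixture(scope="session")
def observer():
    return am.ObserverModel()


@pytest.fixture(scope="session")
def small_session():
    """Two short endogenous runs: enough trials for every condition."""
    return am.generate_session("endogenous", n_runs=2, trials_per_run=40, seed=7)


@pytest.fixture(scope="session")
def noiseless_run(small_session):
    gt = am.make_ground_truth("endogenous", "increasing", "flat")
    run = am.simulate_attention_run(
        small_session.runs[0], small_session, gt, am.NoiseParams(0, 0, 0), seed=3,
        n_voxels_per_roi=4, responsive_frac=1.0, voxel_gain_sd=0.0,
    )
    return run, gt


@pytest.fixture(scope="session")
def amplitude_table_flat():
    """Synthetic condition-amplitude table with a known flat validity effect."""
    import pandas as pd

    rng = np.random.default_rng(11)
    rows = []
    for p in [f"P{i}" for i in range(1, 6)]:
        bump = rng.normal(0, 0.02)
        for roi in am.ROIS:
            for attention in ("endogenous", "exogenous"):
                for epoch in ("pre", "post"):
                    for lat in ("contralateral", "ipsilateral"):
                        for validity in ("valid", "invalid"):
                            beta = 0.5 if lat == "contralateral" else 0.25
                            if lat == "contralateral" and validity == "valid":
                                beta += 0.2
                            beta += rng.normal(0, 0.01)  # keep error strata non-degenerate
                            rows.append(
                                {
                                    "participant": p,
                                    "roi": roi,
                                    "attention_type": attention,
                                    "cue_epoch": epoch,
                                    "laterality": lat,
                                    "validity": validity,
                                    "beta_psc": beta + bump,
                                }
                            )
    return pd.DataFrame(rows)
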