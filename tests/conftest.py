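import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import itnuse as iu

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def make_households(rows):
    """Build a household table from (household_id, weight, members, residence, month) tuples."""
    return pd.DataFrame(
        [
            {
                "survey_id": "T1",
                "household_id": hid,
                "cluster_id": "c1",
                "stratum_id": res,
                "weight": w,
                "n_defacto_members": m,
                "residence": res,
                "interview_year": 2015,
                "interview_month": month,
                "survey_type": "DHS",
            }
            for hid, w, m, res, month in rows
        ]
    )


def make_nets(rows):
    """Build a net table from (household_id, net_index, is_itn, used, codes) tuples."""
    return pd.DataFrame(
        {
            "survey_id": "T1",
            "household_id": [r[0] for r in rows],
            "net_index": [r[1] for r in rows],
            "is_itn": pd.array([r[2] for r in rows], dtype="boolean"),
            "age_months": pd.array([12] * len(rows), dtype="Int64"),
            "used_last_night": pd.array([r[3] for r in rows], dtype="boolean"),
            "n_users": pd.array(
                [2 if r[3] else 0 for r in rows], dtype="Int64"
            ),
            "raw_reason_codes": [r[4] for r in rows],
        }
    )


@pytest.fixture(scope="session")
def default_codebook():
    return iu.load_codebook()


@pytest.fixture(scope="session")
def small_survey():
    """A modest survey reused by structural tests (about 1,500 nets)."""
    cfg = iu.SynthConfig(
        survey_id="SMALL", seed=42, n_clusters=40, households_per_cluster=20
    )
    return cfg, iu.generate_survey(cfg)


def effective_n(weights: np.ndarray) -> float:
    """Kish effective sample size for a weighted proportion."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


def binomial_se_pct(p_pct: float, n: float) -> float:
    p = p_pct / 100.0
    return 100.0 * np.sqrt(p * (1 - p) / n)
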