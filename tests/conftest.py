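"""Shared fixtures.

The session-scoped synthetic corpus mirrors the study conditions used
throughout: three classes (normal / ST-elevation ischemia / infarction),
20 records per class of 3 minutes each, two leads at 250 Hz, default noise,
all seeded. Feature extraction over it is the expensive step, so it is
computed once per session and reused by the separation, classification and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cwdetect import FeatureTable, generate_corpus
from cwdetect.config import PipelineConfig
from cwdetect.pipeline import compute_features

CORPUS_SEED = 42
CORPUS_CONDITIONS = {"normal": 20, "ischemia_st_elev": 20, "infarction": 20}
CORPUS_MINUTES = 3
CORPUS_LEADS = 2


@pytest.fixture(scope="session")
def corpus_records():
    return generate_corpus(
        CORPUS_CONDITIONS, minutes=CORPUS_MINUTES, n_leads=CORPUS_LEADS, seed=CORPUS_SEED
    )


@pytest.fixture(scope="session")
def corpus_features(corpus_records) -> FeatureTable:
    return compute_features(corpus_records, PipelineConfig())


def split_by_record(table: FeatureTable, test_fraction: float, seed: int):
    """Record-stratified train/test split (segments never straddle)."""
    data = table.data
    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    recs = data.groupby("record_id")["label"].first()
    for label in sorted(recs.unique()):
        ids = sorted(recs[recs == label].index)
        n_test = max(1, int(round(test_fraction * len(ids))))
        test_ids.extend(rng.choice(ids, n_test, replace=False))
    train = FeatureTable(data[~data["record_id"].isin(test_ids)])
    test = FeatureTable(data[data["record_id"].isin(test_ids)])
    return train, test


def blob_table(
    centers: dict[str, tuple[float, float]],
    n_per_class: int,
    spread: float = 1.0,
    seed: int = 0,
    lead: str = "I",
) -> FeatureTable:
    """Gaussian-blob feature table for classifier unit tests (one row per record)."""
    rng = np.random.default_rng(seed)
    rows = []
    for label in sorted(centers):
        cx, cy = centers[label]
        pts = rng.normal([cx, cy], spread, size=(n_per_class, 2))
        pts = np.abs(pts)  # feature invariant: non-negative powers
        for i, (p_st, p_pr) in enumerate(pts):
            rows.append(
                {
                    "record_id": f"{label}-{i:03d}",
                    "segment_index": 0,
                    "lead_name": lead,
                    "p_st": p_st,
                    "p_pr": p_pr,
                    "label": label,
                }
            )
    return FeatureTable(pd.DataFrame(rows))
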