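import numpy as np
import pandas as pd
import pytest

from cartx.matrix import ExpressionMatrix, FeatureAnnotation, SampleMetadata
from cartx.simulate import ScenarioConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests (read-only)."""
    config = ScenarioConfig()
    counts, mirna_counts, annotation, metadata, truth = generate_cohort(config)
    return {
        "config": config,
        "counts": counts,
        "mirna_counts": mirna_counts,
        "annotation": annotation,
        "metadata": metadata,
        "truth": truth,
    }


@pytest.fixture
def toy_annotation():
    def build(feature_ids, lengths=None, biotypes=None, flags=None, marker_of=None):
        n = len(feature_ids)
        table = pd.DataFrame(
            {
                "symbol": feature_ids,
                "biotype": biotypes or ["coding"] * n,
                "length_bp": lengths or [1000] * n,
                "flags": flags or [""] * n,
                "marker_of": marker_of or [""] * n,
            },
            index=pd.Index(feature_ids, name="feature_id"),
        )
        return FeatureAnnotation(table)

    return build


@pytest.fixture
def toy_matrix():
    def build(values, feature_ids=None, sample_ids=None, unit="raw_count"):
        values = np.asarray(values, dtype=float)
        feature_ids = feature_ids or [f"g{i + 1}" for i in range(values.shape[0])]
        sample_ids = sample_ids or [f"s{j + 1}" for j in range(values.shape[1])]
        return ExpressionMatrix(
            pd.DataFrame(values, index=feature_ids, columns=sample_ids), unit
        )

    return build


@pytest.fixture
def toy_metadata():
    def build(patients, timepoints=("D0", "D14"), remission=None):
        rows = []
        for i, p in enumerate(patients):
            for t in timepoints:
                rows.append(
                    {
                        "sample_id": f"{p}-{t}",
                        "patient": p,
                        "timepoint": t,
                        "remission": (remission or ["R"] * len(patients))[i],
                    }
                )
        return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))

    return build
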