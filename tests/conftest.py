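import pandas as pd
import pytest

from solitude.pipeline import TranscriptFeaturizer, build_feature_table
from solitude.simulate import cohort_scores_frame


@pytest.fixture(scope="session")
def featurizer() -> TranscriptFeaturizer:
    return TranscriptFeaturizer().fit()


@pytest.fixture(scope="session")
def cohort_table(featurizer):
    """Build (FeatureTable, raw feature frame) for a synthetic cohort."""

    def build(cohort):
        frame = featurizer.transform([p.transcript for p in cohort])
        table = build_feature_table(frame, cohort_scores_frame(cohort))
        return table, frame

    return build
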