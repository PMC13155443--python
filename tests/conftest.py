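import numpy as np
import pytest

from mislabel import (
    ClassVocabulary,
    ImageDataset,
    OracleClassifier,
    inject_mislabels,
    make_stand_in_dataset,
)


@pytest.fixture(scope="session")
def small_dataset() -> ImageDataset:
    """4-class, 80-image separable set with true labels."""
    return make_stand_in_dataset(n_classes=4, per_class=20, seed=0)


@pytest.fixture(scope="session")
def noisy_dataset(small_dataset):
    """small_dataset with 8 injected flips plus the ground-truth record."""
    return inject_mislabels(small_dataset, count=8, seed=1)


@pytest.fixture()
def oracle_ensemble(noisy_dataset):
    """Five perfect-confidence oracles bound to the noisy dataset."""
    noisy, _ = noisy_dataset
    return [OracleClassifier.from_dataset(noisy) for _ in range(5)]


@pytest.fixture(scope="session")
def vocab3() -> ClassVocabulary:
    return ClassVocabulary(("double", "empty", "single"))


def random_records(rng, n_samples, m, K, confident=False):
    """Synthetic prediction records for vote-logic tests."""
    from mislabel.filtering import PredictionRecord

    records = []
    for q in range(n_samples):
        for j in range(m):
            raw = rng.dirichlet(np.ones(K) * (0.3 if confident else 1.0))
            pred = int(np.argmax(raw))
            records.append(
                PredictionRecord(
                    index=q,
                    classifier_id=j,
                    proba=raw,
                    predicted=pred,
                    top_p=float(raw[pred]),
                    round_id=0,
                )
            )
    return records
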