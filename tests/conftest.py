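import numpy as np
import pytest

from metasample import CorpusConfig, StudyRecord, generate_corpus


def make_record(study_id="S1", **overrides) -> StudyRecord:
    base = dict(
        study_id=study_id,
        year=2018,
        sample_country="M01",
        n_patients=40,
        n_controls=40,
        accuracy=0.8,
        cv_scheme="kfold",
    )
    base.update(overrides)
    return StudyRecord(**base)


@pytest.fixture(scope="session")
def small_corpus():
    """A 300-study synthetic corpus shared across read-only tests."""
    return generate_corpus(CorpusConfig(seed=101, n_studies=300))


@pytest.fixture()
def evidence_csv(tmp_path, small_corpus):
    from metasample import write_evidence_table

    path = tmp_path / "evidence.csv"
    write_evidence_table(small_corpus.evidence, path)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
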