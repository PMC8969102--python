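import numpy as np
import pytest

import demfusion as dm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tone_440():
    """2 s pure 440 Hz sine at 16 kHz."""
    sr = 16_000
    t = np.arange(2 * sr) / sr
    return dm.Waveform(0.5 * np.sin(2 * np.pi * 440.0 * t), sr)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """24-subject strong-signal corpus with short recordings, generated once."""
    out = tmp_path_factory.mktemp("corpus")
    spec = dm.CorpusSpec(n_subjects=24, ad_fraction=0.5, seed=7, duration_s=6.0)
    subjects, csv_path = dm.generate_corpus(spec, out)
    return subjects, csv_path


@pytest.fixture(scope="session")
def tiny_bundle():
    return dm.build_tiny_encoders(d=32, N=64, T=17, seed=0)


@pytest.fixture(scope="session")
def small_samples(small_corpus, tiny_bundle):
    subjects, _ = small_corpus
    return dm.prepare_dataset(subjects, tiny_bundle)


CHA_FIXTURE = """@UTF8
@Begin
@Languages:\teng
@Participants:\tPAR Participant, INV Investigator
@ID:\teng|test|S001|||||Participant|||
*INV:\tcan you tell me about the picture ?
*PAR:\tthe boy [/] the boy falls .
%mor:\tdet|the n|boy det|the n|boy v|fall-3S .
*PAR:\t<the mother> [//] mother is washing (.) dishes &=laughs .
@End
"""


@pytest.fixture()
def cha_file(tmp_path):
    p = tmp_path / "S001.cha"
    p.write_text(CHA_FIXTURE)
    return p
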