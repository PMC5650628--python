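import numpy as np
import pytest
from hypothesis import settings

from seqcca.simulate import eeg_preset, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def eeg_dataset():
    """One synthetic subject, default EEG-like conditions, 4 runs x 12 trials."""
    cfg = eeg_preset(n_subjects=1, n_runs=4, trials_per_run=12, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def trained_model(eeg_dataset):
    from seqcca import train_filter_model

    return train_filter_model(eeg_dataset.trials)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Cheap 4-object design for evaluation-scheme tests (high SNR)."""
    cfg = eeg_preset(
        n_objects=4,
        n_reps=3,
        n_channels=8,
        trials_per_run=4,
        n_runs=3,
        n_subjects=1,
        snr=1.2,
        seed=13,
    )
    return simulate_dataset(cfg)


def write_edf(path, data, fs, annotations=(), phys_range=1000.0):
    """Minimal EDF+C writer (synthetic fixture only): int16, 1 s records,
    optional EDF+ annotations packed into the first record."""
    data = np.asarray(data, dtype=float)
    n, c = data.shape
    fs = int(fs)
    n_rec = int(np.ceil(n / fs))
    pad = n_rec * fs - n
    if pad:
        data = np.vstack([data, np.zeros((pad, c))])
    dig = np.clip(np.round(data / phys_range * 32767), -32768, 32767).astype("<i2")
    ann_ns = 640
    ns = c + 1
    hdr = b"0       "
    hdr += b" " * 80 + b" " * 80
    hdr += b"01.01.24" + b"00.00.00"
    hdr += f"{256 * (ns + 1):<8d}".encode()
    hdr += b"EDF+C" + b" " * 39
    hdr += f"{n_rec:<8d}".encode() + b"1       "
    hdr += f"{ns:<4d}".encode()

    def fld(vals, w):
        return "".join(str(v)[:w].ljust(w) for v in vals).encode()

    labels = [f"ch{i}" for i in range(c)] + ["EDF Annotations"]
    hdr += fld(labels, 16)
    hdr += fld([""] * ns, 80)
    hdr += fld(["uV"] * c + [""], 8)
    hdr += fld([-phys_range] * c + [-1], 8)
    hdr += fld([phys_range] * c + [1], 8)
    hdr += fld([-32768] * ns, 8)
    hdr += fld([32767] * ns, 8)
    hdr += fld([""] * ns, 80)
    hdr += fld([fs] * c + [ann_ns], 8)
    hdr += fld([""] * ns, 32)
    assert len(hdr) == 256 * (ns + 1)
    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            f.write(dig[r * fs : (r + 1) * fs].T.tobytes())
            tal = f"+{r}\x14\x14\x00".encode()
            if r == 0:
                for onset, dur, desc in annotations:
                    tal += f"+{onset:.4f}\x15{dur:.3f}\x14{desc}\x14\x00".encode()
            assert len(tal) <= 2 * ann_ns
            f.write(tal + b"\x00" * (2 * ann_ns - len(tal)))


@pytest.fixture
def edf_writer():
    return write_edf
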