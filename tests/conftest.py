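import struct

import numpy as np
import pandas as pd
import pytest

from eegad.features import BiomarkerTable
from eegad.io import EegRecord
from eegad.montage import MONTAGE_19
from eegad.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort with the default disease effects."""
    spec = CohortSpec(n_ad=10, n_nold=10, duration=20.0,
                      channels=MONTAGE_19[7:13], seed=11)
    records, truth = generate_cohort(spec)
    return spec, records, truth


@pytest.fixture()
def sine_record():
    fs = 128.0
    t = np.arange(int(fs * 10)) / fs
    data = np.vstack([np.sin(2 * np.pi * 10 * t),
                      np.sin(2 * np.pi * 5 * t)])
    return EegRecord("sine", "UNKNOWN", fs, ["O1", "O2"], data)


def make_table(n_per_group: int, n_noise: int, n_signal: int, shift: float,
               seed: int) -> BiomarkerTable:
    """Gaussian biomarker table with `n_signal` group-shifted columns.

    Columns are valid feature ids so panel machinery can address them.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    cols = []
    from eegad.montage import iter_feature_ids

    ids = list(iter_feature_ids(list(MONTAGE_19)))
    assert n_noise + n_signal <= len(ids)
    X = rng.normal(size=(n, n_noise + n_signal))
    groups = ["AD"] * n_per_group + ["NOLD"] * n_per_group
    for j in range(n_signal):
        X[:n_per_group, j] += shift
    cols = [f.column for f in ids[: n_noise + n_signal]]
    # put signal columns first in the id list for easy reference
    values = pd.DataFrame(X, columns=cols,
                          index=[f"s{i:03d}" for i in range(n)])
    return BiomarkerTable(values, pd.Series(groups, index=values.index))


def write_minimal_edf(path, data_uv: np.ndarray, fs: int,
                      labels: list[str]) -> None:
    """Write a minimal uncalibrated-free EDF file (one data record).

    Enough of the format for round-trip testing of the reader: 16-bit
    samples, physical range chosen around the data.
    """
    n_ch, n_samp = data_uv.shape
    dur = n_samp / fs
    phys_min, phys_max = -500.0, 500.0
    dig_min, dig_max = -32768, 32767
    header = bytearray()
    header += f"{0:<8}".encode()                       # version
    header += f"{'synthetic subject':<80}".encode()
    header += f"{'synthetic recording':<80}".encode()
    header += f"{'01.01.20':<8}".encode()
    header += f"{'00.00.00':<8}".encode()
    header += f"{256 + 256 * n_ch:<8}".encode()        # header bytes
    header += b" " * 44
    header += f"{1:<8}".encode()                       # n data records
    header += f"{dur:<8.3f}".encode()[:8]              # record duration
    header += f"{n_ch:<4}".encode()
    for lab in labels:
        header += f"{lab:<16}".encode()
    for _ in labels:
        header += f"{'':<80}".encode()                 # transducer
    for _ in labels:
        header += f"{'uV':<8}".encode()
    for _ in labels:
        header += f"{phys_min:<8.1f}".encode()[:8]
    for _ in labels:
        header += f"{phys_max:<8.1f}".encode()[:8]
    for _ in labels:
        header += f"{dig_min:<8}".encode()
    for _ in labels:
        header += f"{dig_max:<8}".encode()
    for _ in labels:
        header += f"{'':<80}".encode()                 # prefiltering
    for _ in labels:
        header += f"{n_samp:<8}".encode()
    for _ in labels:
        header += b" " * 32
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for ch in range(n_ch):
            dig = np.clip((data_uv[ch] - phys_min) * scale + dig_min,
                          dig_min, dig_max).astype("<i2")
            fh.write(struct.pack(f"<{n_samp}h", *dig))
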