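"""Shared fixtures: tiny synthetic cohorts and a minimal EDF writer."""

import struct

import numpy as np
import pytest

from endeeg.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort: 8 subjects/class, 6 channels, 2 windows each."""
    return SyntheticSpec(
        n_per_class=8, n_channels=6, duration=32.0,
        informative_channels=frozenset({0, 1}), effect_size=4.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


def write_minimal_edf(path, channel_names, data_uv, fs):
    """Write a single-record EDF file with int16 samples in microvolts.

    ``data_uv`` is channels x samples of integer-valued microvolt
    amplitudes in [-32768, 32767]; physical = digital (gain 1 uV/count).
    """
    n_sig = len(channel_names)
    n_samp = data_uv.shape[1]
    header_bytes = 256 + 256 * n_sig

    def pad(text, width):
        return text.ljust(width)[:width].encode("ascii")

    hdr = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate 01-JAN-2020 X X X", 80),
        pad("01.01.20", 8),
        pad("00.00.00", 8),
        pad(str(header_bytes), 8),
        pad("", 44),
        pad("1", 8),                    # one data record
        pad(str(n_samp / fs), 8),       # record duration in seconds
        pad(str(n_sig), 4),
    ])
    for field, width in [
        (channel_names, 16), (["" for _ in channel_names], 80),
        (["uV"] * n_sig, 8), (["-32768"] * n_sig, 8), (["32767"] * n_sig, 8),
        (["-32768"] * n_sig, 8), (["32767"] * n_sig, 8),
        (["" for _ in channel_names], 80), ([str(n_samp)] * n_sig, 8),
        (["" for _ in channel_names], 32),
    ]:
        hdr += b"".join(pad(str(v), width) for v in field)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for row in data_uv.astype(np.int16):
            fh.write(struct.pack(f"<{n_samp}h", *row))
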