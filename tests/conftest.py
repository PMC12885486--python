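"""Shared fixtures: tiny recordings and level series built in memory."""

from datetime import datetime
from zoneinfo import ZoneInfo

import numpy as np
import pytest

from tremorindex.decomposition import ElevationSeries, LevelSeries
from tremorindex.e4_io import RawAccelRecording

UTC = ZoneInfo("UTC")


def epoch(*args) -> float:
    """Unix epoch of a UTC wall-clock datetime given as datetime args."""
    return datetime(*args, tzinfo=UTC).timestamp()


@pytest.fixture
def rng():
    return np.random.default_rng(20230501)


@pytest.fixture
def make_recording():
    """Factory for gap-free recordings with constant axes."""

    def _make(duration_s, fs=32.0, start_epoch=0.0, az=0.5, hand="T",
              gaps=None):
        n = int(round(duration_s * fs))
        z = np.full(n, az, dtype=float)
        return RawAccelRecording(
            start_epoch=start_epoch, fs=fs,
            ax=np.zeros(n), ay=np.zeros(n), az=z,
            hand_label=hand, gaps=gaps or [],
        )

    return _make


@pytest.fixture
def make_level():
    """Factory for LevelSeries with all-valid samples."""

    def _make(values, fs_f=8.0, f=3, start_epoch=0.0, valid=None, gaps=None):
        values = np.asarray(values, dtype=float)
        v = np.ones(len(values), dtype=bool) if valid is None else valid
        return LevelSeries(
            f=f, fs_f=fs_f, start_epoch=start_epoch, values=values,
            valid=v, band=(fs_f / 4, fs_f / 2), gaps=gaps or [],
        )

    return _make


@pytest.fixture
def sine_elevation():
    """Factory for a pure-sinusoid elevation series at 32 Hz."""

    def _make(freq, amp, duration_s=1200.0, fs=32.0, start_epoch=-150.0,
              phase=0.0):
        t = np.arange(int(duration_s * fs)) / fs + start_epoch
        return ElevationSeries(
            theta=amp * np.sin(2 * np.pi * freq * t + phase),
            fs=fs, start_epoch=start_epoch,
        )

    return _make
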