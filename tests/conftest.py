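"""Shared fixtures: low-rate templates, synthetic recordings, an EDF writer.

Engine tests run at reduced sampling rates (64-256 Hz) where the behavior
is identical sample-for-sample in structure but segments carry far fewer
windows; the monotonicity suite uses the study rate of 512 Hz.
"""

import numpy as np
import pytest

from bei import EngineConfig, SynthSpec, default_template, gen_background


@pytest.fixture(scope="session")
def cfg():
    return EngineConfig()


@pytest.fixture(scope="session")
def tpl128():
    return default_template(128.0)


@pytest.fixture(scope="session")
def tpl64():
    return default_template(64.0)


@pytest.fixture(scope="session")
def tpl512():
    return default_template(512.0)


@pytest.fixture()
def quiet_background128():
    """Low-amplitude 10 s background segment at 128 Hz (seeded)."""
    spec = SynthSpec(duration_s=10, fs=128.0, rms_uv=5, embed_rate=0,
                     artifact_rate=0, seed=1)
    return gen_background(spec)


def blink_pulse(fs: float, amplitude: float) -> np.ndarray:
    """Biphasic half-second transient used to fabricate artifact windows."""
    n = int(round(0.5 * fs))
    t = np.arange(n) / fs
    pulse = np.sin(2 * np.pi * 2.0 * t) * np.hanning(n)
    return amplitude * pulse / np.abs(pulse).max()


def write_minimal_edf(path, sig, fs, label="Fpz"):
    """Hand-write a minimal single-channel 16-bit EDF file (test fixture).

    One data record per second, physical range spanning the signal. This
    is a fixture generator, not a parser: reading goes through the package.
    """
    sig = np.asarray(sig, dtype=float)
    fs = int(fs)
    nrec = int(np.ceil(sig.size / fs))
    sig = np.concatenate([sig, np.zeros(nrec * fs - sig.size)])
    pmin, pmax = float(sig.min()), float(sig.max())
    if pmax == pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    dig = np.round((sig - pmin) / (pmax - pmin) * (dmax - dmin) + dmin).astype("<i2")
    hdr = b"0".ljust(8)
    hdr += b"X X X X".ljust(80)
    hdr += b"Startdate 01-JAN-2020 X X X".ljust(80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(512).encode().ljust(8)          # header bytes: 256 + 256*nsignals
    hdr += b"".ljust(44)
    hdr += str(nrec).encode().ljust(8)
    hdr += b"1".ljust(8)                       # record duration, s
    hdr += b"1".ljust(4)                       # number of signals
    hdr += label.encode().ljust(16)
    hdr += b"".ljust(80)                       # transducer
    hdr += b"uV".ljust(8)
    hdr += f"{pmin:.8g}".encode()[:8].ljust(8)
    hdr += f"{pmax:.8g}".encode()[:8].ljust(8)
    hdr += str(dmin).encode().ljust(8)
    hdr += str(dmax).encode().ljust(8)
    hdr += b"".ljust(80)                       # prefiltering
    hdr += str(fs).encode().ljust(8)
    hdr += b"".ljust(32)
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(dig.tobytes())
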