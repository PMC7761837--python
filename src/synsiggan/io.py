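"""Signal containers, synthetic fixture generation, and file I/O.

The native on-disk format is a plain CSV with a one-line metadata header
(``# record_id=..,fs=..,type=..``) and one sample per line; annotations live
in a parallel ``<stem>.ann.csv`` with ``index,label`` columns.  WFDB records
(.hea/.dat/.atr, signal formats 16 and 212) and EDF files are read-only.

The fixture generator emulates the morphology of the four physiological
signal families this package targets:

* **ECG** — quasi-periodic beats built from a sum-of-Gaussians P-QRS-T
  template with per-beat R-R variability, i.e. a spiky, sharply localised
  QRS complex riding on smooth low-frequency waves.
* **PPG** — smooth periodic pulses (systolic peak plus dicrotic bump).
* **EEG / EMG** — band-limited stochastic processes, realised as white noise
  shaped by a 4th-order Butterworth band-pass (EEG 1–30 Hz, EMG 20–150 Hz,
  clipped below the Nyquist rate).

Additive white Gaussian noise is scaled so the realised SNR equals the
requested value exactly; the clean template and the noise draw come from
independent child streams of the seed, so the clean signal of a spec is
identical whether or not noise is requested.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "SignalType", "SignalRecord", "FixtureSpec",
    "generate_fixture", "generate_fixture_pair",
    "read_record", "write_record", "map_wfdb_symbol",
    "WFDB_SYMBOL_TO_CLASS", "RecordFormatError",
]


class SignalType(str, Enum):
    ECG = "ECG"
    EEG = "EEG"
    EMG = "EMG"
    PPG = "PPG"
    OTHER = "OTHER"


class RecordFormatError(ValueError):
    """A file does not parse under the named standard."""


@dataclass
class SignalRecord:
    """A sampled 1-D physiological signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude values (arbitrary units, e.g. mV). Finite and non-empty.
    fs : float
        Sampling rate in Hz, > 0.
    signal_type : SignalType
    annotations : list of (sample_index, label)
        0-based indices, strictly within ``[0, len(samples))`` and
        non-decreasing; labels are free strings (e.g. the 17-class ECG
        beat vocabulary).
    record_id : str
    """

    samples: np.ndarray
    fs: float
    signal_type: SignalType = SignalType.OTHER
    annotations: list[tuple[int, str]] = field(default_factory=list)
    record_id: str = "record"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite-valued")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.signal_type = SignalType(self.signal_type)
        prev = -1
        n = self.samples.size
        for idx, label in self.annotations:
            if not (0 <= idx < n):
                raise ValueError(f"annotation index {idx} outside [0, {n})")
            if idx < prev:
                raise ValueError("annotation indices must be non-decreasing")
            prev = idx

    def __len__(self):
        return self.samples.size


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic ground-truth corpus (one record)."""

    signal_type: SignalType
    n_segments: int = 10
    segment_length_range: tuple[int, int] = (324, 396)
    fs: float = 360.0
    noise_snr_db: float = 10.0
    class_labels: tuple[str, ...] = ("NB",)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "signal_type", SignalType(self.signal_type))
        lo, hi = self.segment_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid segment_length_range {self.segment_length_range}")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not self.class_labels:
            raise ValueError("class_labels must be non-empty")


# --- clean waveform templates ------------------------------------------------

# ECG beat as 5 Gaussian bumps (P, Q, R, S, T): (center, width, amplitude)
# in units of the beat period.
_ECG_BUMPS = (
    (0.18, 0.035, 0.12),   # P
    (0.44, 0.012, -0.20),  # Q
    (0.47, 0.010, 1.00),   # R
    (0.50, 0.012, -0.25),  # S
    (0.72, 0.060, 0.35),   # T
)

# PPG pulse: systolic peak + dicrotic bump.
_PPG_BUMPS = (
    (0.30, 0.110, 1.00),
    (0.62, 0.140, 0.45),
)


def _bump_template(length, bumps, scale):
    phase = np.arange(length) / length
    y = np.zeros(length)
    for center, width, amp in bumps:
        y += amp * scale * np.exp(-0.5 * ((phase - center) / width) ** 2)
    return y


def _bandlimited_noise(rng, length, fs, band):
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        raise ValueError(f"band {band} invalid at fs={fs}")
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # pad so the zero-phase filter's edge transients stay out of the segment
    pad = int(4 * fs / lo)
    white = rng.standard_normal(length + 2 * pad)
    return sosfiltfilt(sos, white)[pad:pad + length]


def _clean_segment(rng, sig_type, length, fs, class_index):
    # class identity shifts amplitudes deterministically so that distinct
    # labels carry distinct morphology
    scale = 1.0 + 0.25 * class_index
    if sig_type is SignalType.ECG:
        return _bump_template(length, _ECG_BUMPS, scale)
    if sig_type is SignalType.PPG:
        return _bump_template(length, _PPG_BUMPS, scale)
    if sig_type is SignalType.EEG:
        return scale * _bandlimited_noise(rng, length, fs, (1.0, 30.0))
    if sig_type is SignalType.EMG:
        return scale * _bandlimited_noise(rng, length, fs, (20.0, 150.0))
    return scale * _bandlimited_noise(rng, length, fs, (1.0, 40.0))


def generate_fixture_pair(spec: FixtureSpec) -> tuple[SignalRecord, SignalRecord]:
    """Generate (noisy, clean) records from one spec.

    The clean record is the noise-free concatenation of per-segment
    templates; the noisy record adds white Gaussian noise rescaled so that
    ``10*log10(sum(clean**2)/sum(noise**2))`` equals ``spec.noise_snr_db``
    exactly.  Segment lengths are drawn uniformly from
    ``segment_length_range`` (the source of beat-to-beat R-R variability),
    labels cycle through ``class_labels``, and one annotation marks each
    segment start.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_clean, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    lo, hi = spec.segment_length_range

    pieces, annotations, pos = [], [], 0
    for k in range(spec.n_segments):
        length = int(rng_clean.integers(lo, hi + 1))
        label = spec.class_labels[k % len(spec.class_labels)]
        class_index = spec.class_labels.index(label)
        pieces.append(_clean_segment(rng_clean, spec.signal_type, length,
                                     spec.fs, class_index))
        annotations.append((pos, label))
        pos += length

    clean = np.concatenate(pieces)
    noisy = clean.copy()
    if math.isfinite(spec.noise_snr_db):
        noise = rng_noise.standard_normal(clean.size)
        target_noise_energy = float(np.sum(clean ** 2)) / 10 ** (spec.noise_snr_db / 10)
        noise *= math.sqrt(target_noise_energy / float(np.sum(noise ** 2)))
        noisy = clean + noise

    rid = f"fixture-{spec.signal_type.value}-{spec.seed}"
    make = lambda x, suffix: SignalRecord(
        x, spec.fs, spec.signal_type, list(annotations), rid + suffix)
    return make(noisy, ""), make(clean, "-clean")


def generate_fixture(spec: FixtureSpec) -> SignalRecord:
    """Generate the noisy synthetic record described by ``spec``."""
    noisy, _ = generate_fixture_pair(spec)
    return noisy


# --- native CSV format -------------------------------------------------------

def _ann_path(path: Path) -> Path:
    return path.with_name(path.stem + ".ann.csv")


def write_record(record: SignalRecord, path, format: str = "CSV") -> None:
    """Write a record in the native CSV format (lossless round trip).

    Samples are printed with ``%.17g`` so reading the file back reproduces
    every float bit-exactly.  Annotations go to ``<stem>.ann.csv`` when
    present.
    """
    if format.upper() != "CSV":
        raise ValueError(f"unsupported write format: {format}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# record_id={record.record_id},fs={record.fs!r},"
                 f"type={record.signal_type.value}\n")
        for v in record.samples:
            fh.write(f"{v:.17g}\n")
    if record.annotations:
        with open(_ann_path(path), "w") as fh:
            fh.write("index,label\n")
            for idx, label in record.annotations:
                fh.write(f"{idx},{label}\n")


def _read_csv_record(path: Path) -> SignalRecord:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise RecordFormatError(f"{path}: missing '# key=value' header line")
        meta = {}
        for part in header.lstrip("#").strip().split(","):
            if "=" in part:
                key, val = part.split("=", 1)
                meta[key.strip()] = val.strip()
        try:
            fs = float(meta["fs"])
        except (KeyError, ValueError) as exc:
            raise RecordFormatError(f"{path}: bad or missing fs in header") from exc
        try:
            samples = np.array([float(line) for line in fh if line.strip()])
        except ValueError as exc:
            raise RecordFormatError(f"{path}: non-numeric sample line") from exc
    annotations = []
    ann = _ann_path(path)
    if ann.exists():
        with open(ann) as fh:
            fh.readline()  # header
            for line in fh:
                line = line.strip()
                if line:
                    idx, label = line.split(",", 1)
                    annotations.append((int(idx), label))
    return SignalRecord(samples, fs,
                        SignalType(meta.get("type", "OTHER")),
                        annotations, meta.get("record_id", path.stem))


# --- WFDB (.hea/.dat/.atr) ---------------------------------------------------

# MIT annotation codes (the .atr numeric codes) -> display symbols.
_WFDB_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}

# Beat/annotation symbols -> the 17-class ECG vocabulary; anything else
# maps to "UB" (unclassifiable).
WFDB_SYMBOL_TO_CLASS = {
    "N": "NB", "+": "RC", "R": "RBBB", "L": "LBBB", "E": "VEB", "A": "APB",
    "V": "PVC", "j": "NEB", "a": "AAPB", "F": "FVNB", "f": "FPNB",
    "!": "VFW", '"': "CA", "/": "PB", "x": "NCPW", "~": "CSQ", "Q": "UB",
}


def map_wfdb_symbol(symbol: str) -> str:
    """Map a WFDB annotation symbol onto the 17-class ECG vocabulary."""
    return WFDB_SYMBOL_TO_CLASS.get(symbol, "UB")


def _read_wfdb_header(hea: Path):
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise RecordFormatError(f"{hea}: empty header")
    head = lines[0].split()
    if len(head) < 2:
        raise RecordFormatError(f"{hea}: malformed record line")
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    if n_sig < 1:
        raise RecordFormatError(f"{hea}: zero signals")
    signals = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0]
        gain, baseline = 200.0, None
        if len(tok) > 2:
            gstr = tok[2].split("/")[0]
            if "(" in gstr:
                gstr, bstr = gstr.split("(")
                baseline = int(bstr.rstrip(")"))
            gain = float(gstr) if gstr else 200.0
            if gain == 0:
                gain = 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        signals.append({"file": fname, "fmt": int(fmt), "gain": gain,
                        "baseline": baseline})
    return name, n_sig, fs, n_samp, signals


def _decode_dat(raw: bytes, fmt: int, n_sig: int) -> np.ndarray:
    """Decode a WFDB .dat payload to an (n_samples, n_sig) int array."""
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2")
        usable = (flat.size // n_sig) * n_sig
        return flat[:usable].reshape(-1, n_sig).astype(np.int64)
    if fmt == 212:
        # 2 samples packed into 3 bytes, 12 bits each, sign-extended
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int64)
        s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        pairs = np.stack([s1, s2], axis=1).reshape(-1)
        pairs = np.where(pairs > 2047, pairs - 4096, pairs)
        usable = (pairs.size // n_sig) * n_sig
        return pairs[:usable].reshape(-1, n_sig)
    raise RecordFormatError(f"unsupported WFDB signal format {fmt}")


def _read_wfdb_annotations(atr: Path) -> list[tuple[int, str]]:
    """Parse a MIT-format annotation file into (sample_index, class label)."""
    raw = atr.read_bytes()
    out, time, i = [], 0, 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if code == 0 and delta == 0:      # EOF
            break
        if code == 59:                    # SKIP: 4-byte time follows
            if i + 3 >= len(raw):
                raise RecordFormatError(f"{atr}: truncated SKIP")
            time += struct.unpack("<i", bytes([raw[i + 2], raw[i + 3],
                                               raw[i], raw[i + 1]]))[0]
            i += 4
        elif code == 63:                  # AUX: `delta` info bytes, even-padded
            i += delta + (delta & 1)
        elif code in (60, 61, 62):        # NUM / SUB / CHN modifiers
            continue
        else:
            time += delta
            symbol = _WFDB_CODE_TO_SYMBOL.get(code, "Q")
            out.append((time, map_wfdb_symbol(symbol)))
    return out


def _read_wfdb_record(path: Path, channel: int) -> SignalRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    name, n_sig, fs, n_samp, signals = _read_wfdb_header(hea)
    if not (0 <= channel < n_sig):
        raise ValueError(f"channel {channel} outside 0..{n_sig - 1}")
    sig = signals[channel]
    dat = hea.parent / sig["file"]
    if not dat.exists():
        raise FileNotFoundError(dat)
    adc = _decode_dat(dat.read_bytes(), sig["fmt"], n_sig)
    if n_samp:
        adc = adc[:n_samp]
    physical = (adc[:, channel] - sig["baseline"]) / sig["gain"]
    annotations = []
    atr = hea.with_suffix(".atr")
    if atr.exists():
        annotations = [(t, lab) for t, lab in _read_wfdb_annotations(atr)
                       if 0 <= t < physical.size]
    return SignalRecord(physical, fs, SignalType.ECG, annotations, name)


# --- EDF ---------------------------------------------------------------------

def _read_edf_record(path: Path, channel: int) -> SignalRecord:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the 'mne' package "
                          "(install synsiggan[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if len(raw.ch_names) == 0:
        raise RecordFormatError(f"{path}: zero channels")
    if not (0 <= channel < len(raw.ch_names)):
        raise ValueError(f"channel {channel} outside 0..{len(raw.ch_names) - 1}")
    data = raw.get_data(picks=[channel])[0]
    return SignalRecord(data, float(raw.info["sfreq"]), SignalType.OTHER,
                        [], path.stem)


def read_record(path, format: str = "CSV", channel: int = 0) -> SignalRecord:
    """Read a record from CSV (native), WFDB, or EDF.

    Multi-channel formats expose ``channel`` and default to channel 0.
    WFDB beat annotations are mapped onto the 17-class ECG vocabulary
    (unknown symbols become ``"UB"``); EDF reading recovers samples and
    sampling rate only.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt == "CSV":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_csv_record(path)
    if fmt == "WFDB":
        return _read_wfdb_record(path, channel)
    if fmt == "EDF":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_edf_record(path, channel)
    raise ValueError(f"unknown format: {format}")
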