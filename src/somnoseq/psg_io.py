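"""PSG signal and hypnogram I/O plus staging preprocessing.

Reading EDF/EDF+ goes through :mod:`mne`; writing (used by the
synthetic cohort generator, which must emit files the reader can
ingest) uses a minimal self-contained EDF writer (16-bit samples,
1-second records).  Hypnograms travel as plain text, one uppercase
stage token per line, with an optional ``epoch_index,stage`` CSV
variant.

Preprocessing mirrors the staging pipeline's contract: select the
3-derivation montage, downsample 200 -> 100 Hz with a zero-phase
anti-alias FIR, trim unscored recording margins, and cut the signal
into the 30-s epoch grid.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .stages import (
    EPOCH_SECONDS,
    REQUIRED_DERIVATIONS,
    UNSCORED,
    Hypnogram,
    PsgRecording,
    SignalChannel,
    parse_stage_token,
)

logger = logging.getLogger(__name__)


class ChannelNotFoundError(KeyError):
    pass


class HypnogramParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Channel-label matching
# ---------------------------------------------------------------------------

#: Extra labels accepted for each canonical derivation; matching is
#: case-insensitive and ignores a leading signal-type prefix, so
#: "EOG E1-M2" and "e1-m2" both resolve to "E1-M2".
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "F4-M1": ("EEG F4-M1", "F4M1", "F4-A1"),
    "E1-M2": ("EOG E1-M2", "E1M2", "E1-A2", "LOC-M2"),
    "Chin1-Chin2": ("EMG Chin1-Chin2", "CHIN1-CHIN2", "CHIN EMG", "EMG CHIN"),
}

_TYPE_PREFIXES = ("EEG ", "EOG ", "EMG ")


def _normalize_label(label: str) -> str:
    s = label.strip().upper()
    for p in _TYPE_PREFIXES:
        if s.startswith(p):
            s = s[len(p):]
    return s


def match_channel(
    available: list[str],
    derivation: str,
    aliases: dict[str, tuple[str, ...]] | None = None,
) -> str:
    """Resolve a canonical derivation to one of the labels present in a file."""
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    wanted = {_normalize_label(derivation)}
    wanted.update(_normalize_label(a) for a in aliases.get(derivation, ()))
    for lab in available:
        if _normalize_label(lab) in wanted:
            return lab
    raise ChannelNotFoundError(
        f"derivation {derivation!r} not found; file has {available}")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def read_edf(
    path: str | Path,
    required_derivations: tuple[str, ...] = REQUIRED_DERIVATIONS,
    aliases: dict[str, tuple[str, ...]] | None = None,
    metadata: dict | None = None,
) -> PsgRecording:
    """Read an EDF/EDF+ file and return the requested montage in microvolts."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    labels = list(raw.ch_names)
    logger.info("read %s: channels=%s sfreq=%g Hz n=%d",
                path.name, labels, sfreq, raw.n_times)
    channels: dict[str, SignalChannel] = {}
    for deriv in required_derivations:
        lab = match_channel(labels, deriv, aliases)
        data = raw.get_data(picks=[lab])[0] * 1e6  # mne holds volts
        channels[deriv] = SignalChannel(deriv, sfreq, data)
    return PsgRecording(id=path.stem, channels=channels, metadata=metadata or {})


def _pad_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r}")
    return b.ljust(width)


def write_edf(recording: PsgRecording, path: str | Path) -> None:
    """Write a recording as EDF (16-bit, 1-s data records, physical unit uV).

    The recording duration must be a whole number of seconds and the
    sampling rate a whole number of samples per second.
    """
    path = Path(path)
    rate = recording.sampling_rate_hz
    spr = int(round(rate))  # samples per 1-s record
    if abs(spr - rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_samples = recording.n_samples
    if n_samples % spr != 0:
        raise ValueError("EDF writer requires a whole number of seconds of signal")
    n_records = n_samples // spr
    derivs = list(recording.channels)
    ns = len(derivs)

    phys_ranges = []
    digitized = []
    for d in derivs:
        x = recording.channels[d].samples
        pmax = float(max(np.max(np.abs(x)), 1e-6)) * (1.0 + 1e-9)
        pmin = -pmax
        scale = (32767 - (-32768)) / (pmax - pmin)
        dig = np.round((x - pmin) * scale + (-32768)).astype("<i2")
        phys_ranges.append((pmin, pmax))
        digitized.append(dig)

    def num(x: float, width: int = 8) -> bytes:
        s = f"{x:.6g}"
        if len(s) > width:
            s = f"{x:.{max(width - 7, 0)}e}"
        return _pad_field(s, width)

    with open(path, "wb") as f:
        f.write(_pad_field("0", 8))
        f.write(_pad_field(recording.id[:80], 80))
        f.write(_pad_field("synthetic PSG", 80))
        f.write(_pad_field("01.01.00", 8))
        f.write(_pad_field("00.00.00", 8))
        f.write(_pad_field(str(256 * (ns + 1)), 8))
        f.write(_pad_field("", 44))
        f.write(_pad_field(str(n_records), 8))
        f.write(_pad_field("1", 8))
        f.write(_pad_field(str(ns), 4))
        for d in derivs:
            f.write(_pad_field(d[:16], 16))
        for _ in derivs:
            f.write(_pad_field("", 80))
        for _ in derivs:
            f.write(_pad_field("uV", 8))
        for pmin, _ in phys_ranges:
            f.write(num(pmin))
        for _, pmax in phys_ranges:
            f.write(num(pmax))
        for _ in derivs:
            f.write(_pad_field("-32768", 8))
        for _ in derivs:
            f.write(_pad_field("32767", 8))
        for _ in derivs:
            f.write(_pad_field("", 80))
        for _ in derivs:
            f.write(_pad_field(str(spr), 8))
        for _ in derivs:
            f.write(_pad_field("", 32))
        for r in range(n_records):
            for dig in digitized:
                f.write(dig[r * spr:(r + 1) * spr].tobytes())
    logger.info("wrote %s: %d channels x %d s at %d Hz", path.name, ns, n_records, spr)


def edf_quantization_step(recording: PsgRecording) -> dict[str, float]:
    """Physical value of one digital step for each channel as written by
    :func:`write_edf` (bounds the round-trip error)."""
    out = {}
    for d, ch in recording.channels.items():
        pmax = float(max(np.max(np.abs(ch.samples)), 1e-6)) * (1.0 + 1e-9)
        out[d] = 2 * pmax / 65535
    return out


# ---------------------------------------------------------------------------
# Hypnogram text formats
# ---------------------------------------------------------------------------


def read_hypnogram_codes(path: str | Path) -> np.ndarray:
    """Read stage codes from text, allowing the UNSCORED sentinel.

    Accepts one token per line ("W", "N1", ..., "R", "?"/"UNSCORED"),
    blank lines ignored; or the CSV variant with an
    ``epoch_index,stage`` header.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    codes: list[int] = []
    csv_mode = bool(lines) and lines[0].strip().lower().replace(" ", "") == "epoch_index,stage"
    for i, line in enumerate(lines[1:] if csv_mode else lines,
                             start=2 if csv_mode else 1):
        tok = line.strip()
        if not tok:
            continue
        if csv_mode:
            parts = tok.split(",")
            if len(parts) != 2:
                raise HypnogramParseError(f"{path.name}:{i}: expected 'index,stage'")
            tok = parts[1]
        try:
            codes.append(parse_stage_token(tok))
        except ValueError as e:
            raise HypnogramParseError(f"{path.name}:{i}: {e}") from None
    if not codes:
        raise HypnogramParseError(f"{path.name}: no stage labels found")
    logger.info("read %s: %d epochs", path.name, len(codes))
    return np.asarray(codes, dtype=np.int64)


def read_hypnogram(path: str | Path, source_id: str | None = None) -> Hypnogram:
    """Read a fully scored hypnogram (UNSCORED tokens are rejected)."""
    codes = read_hypnogram_codes(path)
    if (codes == UNSCORED).any():
        raise HypnogramParseError(
            f"{Path(path).name}: contains UNSCORED epochs; "
            "use read_hypnogram_codes + trim_to_scored")
    return Hypnogram(codes, source_id=source_id or Path(path).stem)


def write_hypnogram(h: Hypnogram, path: str | Path, csv: bool = False) -> None:
    path = Path(path)
    if csv:
        lines = ["epoch_index,stage"] + [
            f"{i},{s}" for i, s in enumerate(h.stages)]
    else:
        lines = [str(s) for s in h.stages]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def downsample(channel: SignalChannel, target_rate: float,
               numtaps: int = 129) -> SignalChannel:
    """Integer-factor decimation behind a zero-phase anti-alias FIR low-pass.

    The cutoff sits at 0.8x the target Nyquist; applied forward-backward
    (zero phase) so stage-defining waveforms are not phase-shifted.
    """
    ratio = channel.sampling_rate_hz / target_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"downsampling ratio {channel.sampling_rate_hz}/{target_rate} "
            "is not an integer")
    if q == 1:
        return SignalChannel(channel.derivation, float(target_rate),
                             channel.samples.copy())
    cutoff = 0.8 * (target_rate / 2.0)
    taps = sps.firwin(numtaps, cutoff, fs=channel.sampling_rate_hz)
    filtered = sps.filtfilt(taps, [1.0], channel.samples)
    return SignalChannel(channel.derivation, float(target_rate), filtered[::q])


def downsample_recording(recording: PsgRecording, target_rate: float) -> PsgRecording:
    return PsgRecording(
        id=recording.id,
        channels={d: downsample(c, target_rate) for d, c in recording.channels.items()},
        metadata=dict(recording.metadata),
    )


def trim_to_scored(
    recording: PsgRecording,
    codes: np.ndarray | Hypnogram,
    source_id: str = "",
) -> tuple[PsgRecording, Hypnogram]:
    """Drop unscored recording margins so signal and hypnogram align exactly.

    ``codes`` may carry the UNSCORED sentinel only as a contiguous
    prefix and/or suffix; an interior unscored epoch is an error.
    """
    if isinstance(codes, Hypnogram):
        arr = codes.codes
        source_id = source_id or codes.source_id
    else:
        arr = np.asarray(codes, dtype=np.int64)
    scored = np.flatnonzero(arr != UNSCORED)
    if len(scored) == 0:
        raise ValueError("hypnogram has no scored epochs")
    first, last = int(scored[0]), int(scored[-1])
    if (arr[first:last + 1] == UNSCORED).any():
        raise ValueError("UNSCORED epochs must be contiguous recording margins, "
                         "not interior gaps")
    rate = recording.sampling_rate_hz
    spe = int(round(EPOCH_SECONDS * rate))
    lo, hi = first * spe, (last + 1) * spe
    if hi > recording.n_samples:
        raise ValueError("hypnogram extends past the end of the signal")
    if first == 0 and hi == recording.n_samples and last == len(arr) - 1:
        return recording, Hypnogram(arr, source_id=source_id)
    channels = {
        d: SignalChannel(d, rate, c.samples[lo:hi])
        for d, c in recording.channels.items()
    }
    trimmed = PsgRecording(id=recording.id, channels=channels,
                           metadata=dict(recording.metadata))
    logger.info("trimmed %s to scored span: epochs [%d, %d]",
                recording.id, first, last)
    return trimmed, Hypnogram(arr[first:last + 1], source_id=source_id)


def epochize(recording: PsgRecording,
             order: tuple[str, ...] = REQUIRED_DERIVATIONS) -> np.ndarray:
    """Cut a trimmed recording into the 30-s epoch grid.

    Returns an array of shape (n_epochs, n_channels, 30*rate); a
    trailing remainder shorter than one epoch is dropped.
    """
    rate = recording.sampling_rate_hz
    spe = int(round(EPOCH_SECONDS * rate))
    n_epochs = recording.n_samples // spe
    if n_epochs < 1:
        raise ValueError(
            f"recording {recording.id} shorter than one 30-s epoch")
    x = recording.channel_matrix(order)[:n_epochs * spe]  # (n, c)
    return np.transpose(x.reshape(n_epochs, spe, len(order)), (0, 2, 1))
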