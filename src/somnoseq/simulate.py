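"""Synthetic stage-labelled PSG cohorts.

The study data this package targets (overnight pediatric PSG with
manual AASM scoring) is access-restricted, so every downstream stage is
exercised on simulated recordings instead.  Three generators compose:

* a 5-state Markov chain over stages whose stationary distribution is
  calibrated to the stage composition of the reference pediatric cohort
  (see :data:`PEDIATRIC_COMPOSITION`), with configurable mean bout
  lengths driving the dynamics;
* a per-stage signal synthesizer producing the 3-channel montage
  (frontal EEG, EOG, chin EMG) as mixtures of band-limited noise with
  AASM-style stage signatures (delta-dominant high-amplitude N3,
  spindle bursts in N2, REM muscle atonia, slow vs. rapid eye
  movements);
* an imperfect-scorer model that relabels a ground-truth hypnogram
  through a diagonally dominant confusion kernel, for rater-agreement
  analyses.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .stages import (
    N_STAGES,
    REQUIRED_DERIVATIONS,
    STAGE_NAMES,
    Hypnogram,
    PsgRecording,
    SignalChannel,
    Stage,
)

# ---------------------------------------------------------------------------
# Reference cohort composition (calibration target for the stage dynamics)
# ---------------------------------------------------------------------------

#: Per-stage 30-s epoch counts and printed percentages of the reference
#: pediatric cohort, whole dataset and by recruitment group.  The whole-
#: dataset counts define the default stationary target of the hypnogram
#: simulator.
PEDIATRIC_COMPOSITION = {
    "whole": {
        "counts": {"W": 8469, "N1": 3724, "N2": 28880, "N3": 54786, "R": 22917},
        "percentages": {"W": 7.1, "N1": 3.1, "N2": 24.3, "N3": 46.1, "R": 19.3},
        "total": 118776,
    },
    "SDB": {
        "counts": {"W": 4455, "N1": 1657, "N2": 14170, "N3": 28055, "R": 11649},
        "percentages": {"W": 7.4, "N1": 2.8, "N2": 23.6, "N3": 46.8, "R": 19.4},
        "total": 59986,
    },
    "control": {
        "counts": {"W": 4014, "N1": 2067, "N2": 14710, "N3": 26731, "R": 11268},
        "percentages": {"W": 6.8, "N1": 3.5, "N2": 25.0, "N3": 45.5, "R": 19.2},
        "total": 58790,
    },
}


def default_stage_proportions() -> np.ndarray:
    """Whole-dataset stage proportions (exact count fractions, ordinal order)."""
    c = PEDIATRIC_COMPOSITION["whole"]["counts"]
    v = np.array([c[s] for s in STAGE_NAMES], dtype=float)
    return v / v.sum()


#: Default mean bout lengths in epochs (W, N1, N2, N3, R).  The reference
#: tables give composition only, not dynamics; these produce hypnograms
#: with plausible bout structure (brief N1, long consolidated N3/R).
DEFAULT_MEAN_BOUTS = np.array([4.0, 2.0, 10.0, 20.0, 15.0])


def derive_seed(master_seed: int, index: int) -> int:
    """Per-item seed from a master seed via a splitmix64-style mix."""
    mask = 0xFFFFFFFFFFFFFFFF
    z = (master_seed + (index + 1) * 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z = z ^ (z >> 31)
    return z % 2**31


# ---------------------------------------------------------------------------
# Stage-transition model
# ---------------------------------------------------------------------------


@dataclass
class StageTransitionModel:
    """Row-stochastic 5x5 next-epoch transition matrix + initial distribution."""

    transition: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (N_STAGES, N_STAGES):
            raise ValueError("transition matrix must be 5x5")
        if (self.transition < 0).any() or (self.initial < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (direct solve)."""
    P = np.asarray(transition, dtype=float)
    n = P.shape[0]
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


class CalibrationError(ValueError):
    pass


def calibrate_transition_model(
    target_proportions: np.ndarray | None = None,
    mean_bout_epochs: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> StageTransitionModel:
    """Build a transition model with a prescribed stationary distribution.

    Self-transitions are fixed by the mean bout lengths,
    ``p_ii = 1 - 1/m_i`` (geometric bout durations), so the exit flow
    from stage i under the target pi is ``f_i = pi_i / m_i``.  Exits are
    distributed over destination stages proportionally to a weight
    vector, which is iterated (a one-sided Sinkhorn scaling) until the
    inflow of every stage balances its outflow; flow balance with the
    fixed diagonal makes the target exactly stationary.
    """
    pi = default_stage_proportions() if target_proportions is None else np.asarray(
        target_proportions, dtype=float)
    m = DEFAULT_MEAN_BOUTS if mean_bout_epochs is None else np.asarray(
        mean_bout_epochs, dtype=float)
    if pi.shape != (N_STAGES,) or m.shape != (N_STAGES,):
        raise ValueError("target proportions and bout lengths must have length 5")
    if not np.isclose(pi.sum(), 1.0, atol=1e-9):
        raise CalibrationError("target proportions must sum to 1")
    if (pi <= 0).any():
        raise CalibrationError("target proportions must be strictly positive")
    if (m < 1).any():
        raise CalibrationError(
            "mean bout length < 1 epoch requires negative self-transition mass")

    p_self = 1.0 - 1.0 / m
    f = pi / m                       # exit flow out of each stage
    w = f / f.sum()                  # destination weights, iterated to balance
    for _ in range(max_iter):
        denom = w.sum() - w          # row-wise normalizer excluding self
        Q = w[None, :] / denom[:, None]
        np.fill_diagonal(Q, 0.0)
        inflow = ((1.0 - p_self) * pi) @ Q
        if np.max(np.abs(inflow - f)) < tol * max(f.max(), 1e-30):
            break
        w = w * f / inflow
        w = w / w.sum()
    else:
        raise CalibrationError("flow-balance iteration did not converge")

    P = np.diag(p_self) + (1.0 - p_self)[:, None] * Q
    P = P / P.sum(axis=1, keepdims=True)   # tidy rounding at 1e-16 level
    return StageTransitionModel(transition=P, initial=pi / pi.sum())


def simulate_hypnogram(n_epochs: int, model: StageTransitionModel, seed: int,
                       source_id: str = "truth") -> Hypnogram:
    """Sample a stage sequence from the Markov model; deterministic per seed."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n_epochs)
    cum_init = np.cumsum(model.initial)
    cum_rows = np.cumsum(model.transition, axis=1)
    codes = np.empty(n_epochs, dtype=np.int64)
    codes[0] = np.searchsorted(cum_init, u[0] * cum_init[-1], side="right")
    for t in range(1, n_epochs):
        row = cum_rows[codes[t - 1]]
        codes[t] = np.searchsorted(row, u[t] * row[-1], side="right")
    np.clip(codes, 0, N_STAGES - 1, out=codes)
    return Hypnogram(codes, source_id=source_id)


# ---------------------------------------------------------------------------
# Stage signal signatures
# ---------------------------------------------------------------------------

#: EEG frequency bands in Hz: delta, theta, alpha, beta.
EEG_BANDS = ((0.5, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 30.0))
BAND_NAMES = ("delta", "theta", "alpha", "beta")


@dataclass
class StageSignature:
    """Per-stage signal parameters.

    band_weights are relative EEG power fractions over
    (delta, theta, alpha, beta) and must sum to 1.  RMS values are in
    microvolts; event rates in events/min.
    """

    band_weights: tuple[float, float, float, float]
    eeg_rms: float
    emg_rms: float
    eog_event_rate: float
    eog_event_type: str  # "slow", "rapid", or "none"
    spindle_rate: float = 0.0  # 11-16 Hz bursts, N2 only


@dataclass
class StageSignalSpec:
    """Full cohort signal specification: one signature per stage plus globals."""

    signatures: dict[int, StageSignature] = field(default_factory=lambda: dict(_DEFAULT_SIGNATURES))
    noise_floor_rms: float = 2.0       # broadband floor on every channel, uV
    eeg_crosstalk_into_eog: float = 0.4
    spindle_freq_hz: float = 13.0
    spindle_duration_s: float = 1.0
    spindle_amp_uv: float = 25.0
    eog_event_amp_uv: float = 120.0

    def __post_init__(self) -> None:
        for code, sig in self.signatures.items():
            w = np.asarray(sig.band_weights, dtype=float)
            if not np.isclose(w.sum(), 1.0, atol=1e-9):
                raise ValueError(f"band weights for {Stage(code).name} must sum to 1")
        emg = {c: s.emg_rms for c, s in self.signatures.items()}
        if not all(emg[int(Stage.R)] < v for c, v in emg.items() if c != int(Stage.R)):
            raise ValueError("REM atonia violated: R EMG tone must be the minimum")
        n3_delta = self.signatures[int(Stage.N3)].band_weights[0]
        all_w = [w for s in self.signatures.values() for w in s.band_weights]
        if n3_delta < max(all_w):
            raise ValueError("N3 delta weight must be the maximum stage-band weight")


# Defaults encode the textbook stage signatures at clearly separable
# margins: alpha-dominant low-voltage W, theta-dominant N1, spindle-rich
# N2, high-amplitude delta-dominant N3, and theta-dominant R with muscle
# atonia and rapid eye movements.
_DEFAULT_SIGNATURES = {
    int(Stage.W):  StageSignature((0.15, 0.15, 0.45, 0.25), eeg_rms=30.0, emg_rms=15.0,
                                  eog_event_rate=4.0, eog_event_type="slow"),
    int(Stage.N1): StageSignature((0.25, 0.50, 0.15, 0.10), eeg_rms=35.0, emg_rms=8.0,
                                  eog_event_rate=3.0, eog_event_type="slow"),
    int(Stage.N2): StageSignature((0.45, 0.30, 0.15, 0.10), eeg_rms=50.0, emg_rms=6.0,
                                  eog_event_rate=0.0, eog_event_type="none",
                                  spindle_rate=3.0),
    int(Stage.N3): StageSignature((0.75, 0.13, 0.07, 0.05), eeg_rms=80.0, emg_rms=5.0,
                                  eog_event_rate=0.0, eog_event_type="none"),
    int(Stage.R):  StageSignature((0.30, 0.45, 0.15, 0.10), eeg_rms=35.0, emg_rms=1.5,
                                  eog_event_rate=8.0, eog_event_type="rapid"),
}


def _unit_rms_band_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                         rate: float) -> np.ndarray:
    lo, hi = band
    nyq = rate / 2.0
    sos = sps.butter(4, [lo / nyq, min(hi / nyq, 0.999)], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


def synthesize_recording(
    hypnogram: Hypnogram,
    spec: StageSignalSpec | None = None,
    rate: float = 200.0,
    seed: int = 0,
    rec_id: str = "synthetic",
    metadata: dict | None = None,
) -> PsgRecording:
    """Render a 3-channel recording whose epochs carry their stage's signature.

    Band-limited noise carriers are generated once for the whole
    recording and mixed per epoch with stage-dependent gains, so the
    signal is continuous within a band; epoch boundaries switch only
    the mixing gains (plus stage-specific transients: N2 spindles and
    EOG events).
    """
    if rate not in (100.0, 200.0, 100, 200):
        raise ValueError("supported sampling rates: 100 or 200 Hz")
    spec = spec or StageSignalSpec()
    rng = np.random.default_rng(seed)
    spe = int(round(hypnogram.epoch_duration_s * rate))  # samples per epoch
    n_epochs = len(hypnogram)
    n = n_epochs * spe
    codes = hypnogram.codes

    for c in np.unique(codes):
        if int(c) not in spec.signatures:
            raise KeyError(f"no signal signature for stage code {int(c)}")

    # ---- EEG: per-band carriers mixed with per-epoch stage gains
    carriers = np.stack(
        [_unit_rms_band_noise(rng, n, b, rate) for b in EEG_BANDS], axis=0)
    sig_amp = np.array([[spec.signatures[int(c)].eeg_rms *
                         np.sqrt(spec.signatures[int(c)].band_weights[b])
                         for b in range(4)] for c in codes])  # (n_epochs, 4)
    gains = np.repeat(sig_amp, spe, axis=0).T                  # (4, n)
    eeg = (carriers * gains).sum(axis=0)

    # N2 spindle bursts: Hann-windowed sinusoid packets
    spindle_len = int(spec.spindle_duration_s * rate)
    window = np.hanning(spindle_len)
    t_burst = np.arange(spindle_len) / rate
    for e in np.flatnonzero(codes == int(Stage.N2)):
        lam = spec.signatures[int(Stage.N2)].spindle_rate * hypnogram.epoch_duration_s / 60.0
        for _ in range(rng.poisson(lam)):
            start = e * spe + rng.integers(0, spe - spindle_len)
            phase = rng.uniform(0, 2 * np.pi)
            burst = spec.spindle_amp_uv * window * np.sin(
                2 * np.pi * spec.spindle_freq_hz * t_burst + phase)
            eeg[start:start + spindle_len] += burst

    # ---- EMG: broadband tone with per-epoch stage RMS
    emg_carrier = _unit_rms_band_noise(rng, n, (10.0, min(45.0, rate / 2 - 5)), rate)
    emg_gain = np.repeat(
        np.array([spec.signatures[int(c)].emg_rms for c in codes]), spe)
    emg = emg_carrier * emg_gain

    # ---- EOG: attenuated EEG crosstalk + slow drift + stage-typed events
    slow = _unit_rms_band_noise(rng, n, (0.2, 1.5), rate)
    eog = spec.eeg_crosstalk_into_eog * eeg + 8.0 * slow
    for e in range(n_epochs):
        sig = spec.signatures[int(codes[e])]
        if sig.eog_event_type == "none" or sig.eog_event_rate <= 0:
            continue
        lam = sig.eog_event_rate * hypnogram.epoch_duration_s / 60.0
        dur = 1.5 if sig.eog_event_type == "slow" else 0.3
        ev_len = int(dur * rate)
        shape = np.sin(np.pi * np.arange(ev_len) / ev_len)  # half-sine deflection
        for _ in range(rng.poisson(lam)):
            start = e * spe + rng.integers(0, spe - ev_len)
            sign = rng.choice((-1.0, 1.0))
            eog[start:start + ev_len] += sign * spec.eog_event_amp_uv * shape

    floor = spec.noise_floor_rms
    eeg = eeg + floor * rng.standard_normal(n)
    eog = eog + floor * rng.standard_normal(n)
    emg = emg + floor * rng.standard_normal(n)

    channels = {
        "F4-M1": SignalChannel("F4-M1", float(rate), eeg),
        "E1-M2": SignalChannel("E1-M2", float(rate), eog),
        "Chin1-Chin2": SignalChannel("Chin1-Chin2", float(rate), emg),
    }
    return PsgRecording(id=rec_id, channels=channels, metadata=metadata or {})


# ---------------------------------------------------------------------------
# Imperfect scorers
# ---------------------------------------------------------------------------


@dataclass
class ScorerErrorModel:
    """Row-stochastic kernel: probability a scorer relabels true stage i as j."""

    kernel: np.ndarray

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.shape != (N_STAGES, N_STAGES):
            raise ValueError("kernel must be 5x5")
        if (self.kernel < 0).any():
            raise ValueError("kernel entries must be non-negative")
        if not np.allclose(self.kernel.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("kernel rows must sum to 1")
        off = self.kernel - np.diag(np.diag(self.kernel))
        if (np.diag(self.kernel) <= off.max(axis=1)).any():
            raise ValueError("kernel must be diagonally dominant")


#: Default scorer kernel: 85% of epochs kept, errors concentrated on the
#: stages human scorers actually confuse (N1 with N2 and W; N3 with N2).
DEFAULT_SCORER_KERNEL = np.array([
    [0.850, 0.100, 0.030, 0.010, 0.010],   # W
    [0.060, 0.850, 0.070, 0.005, 0.015],   # N1
    [0.010, 0.060, 0.850, 0.070, 0.010],   # N2
    [0.005, 0.005, 0.130, 0.850, 0.010],   # N3
    [0.020, 0.060, 0.060, 0.010, 0.850],   # R
])


def default_scorer_model() -> ScorerErrorModel:
    return ScorerErrorModel(DEFAULT_SCORER_KERNEL.copy())


def simulate_scorer(truth: Hypnogram, error_model: ScorerErrorModel, seed: int,
                    source_id: str = "scorer") -> Hypnogram:
    """Relabel each epoch independently through the confusion kernel."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(error_model.kernel, axis=1)
    u = rng.random(len(truth))
    rows = cum[truth.codes]
    codes = (u[:, None] * rows[:, -1:] > rows).sum(axis=1)
    np.clip(codes, 0, N_STAGES - 1, out=codes)
    return Hypnogram(codes, source_id=source_id)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_AHI_CYCLE = (0.3, 0.8, 1.0, 2.4)  # events/h, straddles the OSA threshold of 1


def generate_cohort(
    n_recordings: int,
    epochs_per_recording: int,
    seed: int,
    rate: float = 200.0,
    spec: StageSignalSpec | None = None,
    transition_model: StageTransitionModel | None = None,
) -> list[tuple[PsgRecording, Hypnogram]]:
    """Generate a labelled cohort with alternating group flags.

    Per-recording seeds derive deterministically from the master seed
    (splitmix-style), so a cohort is reproducible and extensible:
    recording k is identical whether n_recordings is 8 or 80.
    """
    if n_recordings < 1:
        raise ValueError("n_recordings must be >= 1")
    model = transition_model or calibrate_transition_model()
    out = []
    for i in range(n_recordings):
        rec_seed = derive_seed(seed, i)
        truth = simulate_hypnogram(epochs_per_recording, model, rec_seed,
                                   source_id="reference")
        meta = {
            "group": "SDB" if i % 2 == 0 else "control",
            "ahi": _AHI_CYCLE[i % len(_AHI_CYCLE)],
            "sex": "M" if i % 3 else "F",
            "age": 10 + (i % 4),
            "seed": rec_seed,
        }
        rec = synthesize_recording(truth, spec=spec, rate=rate,
                                   seed=rec_seed + 1, rec_id=f"synt{i:03d}",
                                   metadata=meta)
        out.append((rec, truth))
    return out
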