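"""Synthetic single-subject fNIRS sound-localization sessions.

Emulates the block-design experiment the analysis chain expects: after a
10-s preparation period, 100 trials (5 source azimuths x 2 levels x 10
repetitions, seeded-random order) of 10-s stimulation followed by 10-s
rest, sampled at 13.3 Hz over the 20-channel bilateral montage.

Per trial, every channel of an affected ROI receives
``amplitude * h(t - onset - latency)`` where ``h`` is a canonical
double-gamma hemodynamic impulse response convolved with the 10-s stimulus
boxcar and normalised to unit peak, so ``amplitude`` is the peak oxy-Hb
excursion in mM*mm.  On top of the evoked signal each channel carries:

* a cardiac sinusoid (frequency drawn once per session inside 1-1.5 Hz),
* a respiratory sinusoid (0.2-0.5 Hz),
* a slow sinusoidal baseline drift (< 0.03 Hz),
* white sensor noise, and
* a global systemic component added identically to all channels (removed
  exactly by common-average-reference filtering).

Physiological frequencies are drawn once per session (quasi-stationary
rhythms), phases per channel.  Trial-to-trial amplitude variability is a
multiplicative Gaussian jitter.

The behavioral half of the session is drawn from a per-location confusion
model; the ``lateral_confusion`` preset sends all errors at +/-90 deg to
the adjacent +/-60 deg speaker, the pattern normal-hearing listeners show
on this task.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core import BehavioralSession, Event, Recording, ValidationError
from .io import write_behavioral, write_recording
from .probe import ROI_CHANNELS, load_probe_map

__all__ = [
    "HrfKernel",
    "NoiseConfig",
    "SimulationConfig",
    "simulate_session",
    "make_fixture_suite",
    "null_effect",
    "lateral_effect",
    "high_snr_effect",
    "intensity_effect",
    "perfect_confusion",
    "lateral_confusion",
]

#: loudspeaker index of each active source azimuth
_LOC_TO_SPEAKER = {-90: 1, -30: 3, 0: 4, 30: 5, 90: 7}


@dataclass(frozen=True)
class HrfKernel:
    """Canonical double-gamma hemodynamic impulse response."""

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    ratio: float = 1.0 / 6.0
    duration_s: float = 32.0

    def impulse(self, fs_hz: float) -> np.ndarray:
        """Sampled impulse response, peak-normalised to 1."""
        from scipy.stats import gamma

        t = np.arange(0, self.duration_s, 1.0 / fs_hz)
        # shape a, scale 1: mode at a-1 -> a = peak + 1
        pos = gamma.pdf(t, self.peak_s + 1.0)
        neg = gamma.pdf(t, self.undershoot_s + 1.0)
        h = pos - self.ratio * neg
        peak = h.max()
        if peak <= 0:
            raise ValidationError("HRF kernel must integrate to a positive response")
        return h / peak

    def block_response(self, fs_hz: float, stim_s: float = 10.0) -> np.ndarray:
        """Impulse response convolved with a stim_s boxcar, unit peak."""
        h = self.impulse(fs_hz)
        box = np.ones(int(round(stim_s * fs_hz)))
        r = np.convolve(h, box)
        return r / r.max()


@dataclass(frozen=True)
class NoiseConfig:
    """Amplitudes (mM*mm) and frequency bands (Hz) of the noise model."""

    cardiac_band: tuple[float, float] = (1.0, 1.5)
    cardiac_amp: float = 0.04
    resp_band: tuple[float, float] = (0.2, 0.5)
    resp_amp: float = 0.03
    drift_band: tuple[float, float] = (0.005, 0.03)
    drift_amp: float = 0.08
    white_sd: float = 0.035
    global_amp: float = 0.05

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "resp_amp", "drift_amp", "white_sd", "global_amp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one subject session deterministically."""

    seed: int = 0
    n_reps: int = 10
    fs_hz: float = 13.3
    stim_s: float = 10.0
    rest_s: float = 10.0
    prep_s: float = 10.0
    #: (roi_id, location_deg, intensity_db) -> (peak amplitude mM*mm, latency s)
    effect: dict[tuple[int, int, int], tuple[float, float]] = field(default_factory=dict)
    noise: NoiseConfig = NoiseConfig()
    hrf: HrfKernel = HrfKernel()
    #: fractional sd of per-trial multiplicative amplitude jitter
    trial_jitter_sd: float = 0.25
    #: location_deg -> {response_speaker: probability}
    confusion: dict[int, dict[int, float]] = field(default_factory=dict)
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        for key, (amp, lat) in self.effect.items():
            if amp < 0:
                raise ValidationError(f"effect amplitude for {key} must be >= 0")
        for loc, probs in self.confusion.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"confusion probabilities for {loc} deg sum to {total}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ValidationError(f"negative confusion probability for {loc} deg")
            if any(not 1 <= spk <= 7 for spk in probs):
                raise ValidationError(f"confusion responses for {loc} deg outside speakers 1-7")


# ---------------------------------------------------------------------------
# effect / confusion presets

_AUDITORY_L = (4, 5)        # left STG / auditory association
_AUDITORY_R = (9, 10)       # right STG / auditory association
_WERNICKE_L, _WERNICKE_R = 2, 7
_DLPFC = (3, 8)

#: committed study-conditions calibration of the lateral-vs-front preset
_LATERAL_BASE_AMP = 0.020        # evoked auditory response, every location
_LATERAL_BASE_LAT_S = 1.0        # response latency for front/near-front sources
_LATERAL_CONTRA_BOOST = 0.006    # extra contralateral STG/BA40 drive, lateral sources
_LATERAL_DLPFC_AMP = 0.016       # bilateral dlPFC response, lateral sources only
_LATERAL_CONTRA_DELAY_S = 0.35   # contralateral latency shift for lateral sources
_LATERAL_IPSI_DELAY_M90_S = 2.0  # ipsilateral latency shift, -90 deg
_LATERAL_IPSI_DELAY_P90_S = 2.4  # ipsilateral latency shift, +90 deg (peaks later)


def null_effect() -> dict[tuple[int, int, int], tuple[float, float]]:
    """No condition-dependent response at all (noise-only sessions)."""
    return {}


def lateral_effect(scale: float = 1.0) -> dict[tuple[int, int, int], tuple[float, float]]:
    """Condition effects mimicking lateral-vs-front phenomenology.

    Every location evokes a baseline bilateral auditory response.  Lateral
    sources additionally drive the contralateral STG/supramarginal ROIs
    (amplitude boost, small latency shift: a steeper contralateral rise
    relative to the delayed ipsilateral response) and bilateral dlPFC, and
    the ipsilateral response to +90 deg peaks later than to -90 deg.
    Front and +/-30 deg sources share an identical pattern, and 48/58 dB
    are identical (no level effect).  ``scale`` multiplies amplitudes only.
    """
    eff: dict[tuple[int, int, int], tuple[float, float]] = {}
    lat0 = _LATERAL_BASE_LAT_S
    for db in (48, 58):
        for loc in (-90, -30, 0, 30, 90):
            for roi in _AUDITORY_L + _AUDITORY_R:
                eff[(roi, loc, db)] = (_LATERAL_BASE_AMP * scale, lat0)
        # contralateral hemisphere: amplitude boost, slight delay
        for roi in (*_AUDITORY_R, _WERNICKE_R):
            amp = eff.get((roi, -90, db), (0.0, lat0))[0]
            eff[(roi, -90, db)] = (amp + _LATERAL_CONTRA_BOOST * scale,
                                   lat0 + _LATERAL_CONTRA_DELAY_S)
        for roi in (*_AUDITORY_L, _WERNICKE_L):
            amp = eff.get((roi, 90, db), (0.0, lat0))[0]
            eff[(roi, 90, db)] = (amp + _LATERAL_CONTRA_BOOST * scale,
                                  lat0 + _LATERAL_CONTRA_DELAY_S)
        # ipsilateral hemisphere: delayed rise; +90 peaks later than -90
        for roi in _AUDITORY_L:
            amp, _ = eff[(roi, -90, db)]
            eff[(roi, -90, db)] = (amp, lat0 + _LATERAL_IPSI_DELAY_M90_S)
        for roi in _AUDITORY_R:
            amp, _ = eff[(roi, 90, db)]
            eff[(roi, 90, db)] = (amp, lat0 + _LATERAL_IPSI_DELAY_P90_S)
        for roi in _DLPFC:
            for loc in (-90, 90):
                eff[(roi, loc, db)] = (_LATERAL_DLPFC_AMP * scale, lat0)
    return eff


def high_snr_effect() -> dict[tuple[int, int, int], tuple[float, float]]:
    """Strongly separable lateral-vs-front pattern (near-noiseless decoding)."""
    return lateral_effect(scale=10.0)


def intensity_effect(
    roi_id: int = 4, amplitude: float = 0.05
) -> dict[tuple[int, int, int], tuple[float, float]]:
    """A pure sound-level effect in one ROI: 58 dB evokes, 48 dB does not."""
    return {(roi_id, loc, 58): (amplitude, 0.0) for loc in (-90, -30, 0, 30, 90)}


def perfect_confusion() -> dict[int, dict[int, float]]:
    """Every trial answered with the target speaker."""
    return {loc: {spk: 1.0} for loc, spk in _LOC_TO_SPEAKER.items()}


def lateral_confusion(p_error: float = 0.3) -> dict[int, dict[int, float]]:
    """Errors only at +/-90 deg, always toward the adjacent +/-60 speaker."""
    conf = perfect_confusion()
    conf[-90] = {1: 1.0 - p_error, 2: p_error}
    conf[90] = {7: 1.0 - p_error, 6: p_error}
    return conf


# ---------------------------------------------------------------------------
# generator


def _band_sinusoid(rng, band, n_ch, t, amp):
    """Per-channel sinusoids: one session frequency, random phase per channel."""
    f = rng.uniform(*band)
    phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    return amp * np.sin(2 * np.pi * f * t[None, :] + phases[:, None])


def simulate_session(
    cfg: SimulationConfig,
) -> tuple[Recording, BehavioralSession, list[Event]]:
    """Generate one complete subject session.

    Returns ``(recording, behavioral_session, schedule)``; the schedule is
    the ground-truth condition sequence (identical to ``recording.events``).
    Identical configs (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    probe = load_probe_map()
    n_ch = probe.n_channels
    fs = cfg.fs_hz

    conditions = [
        (loc, db)
        for loc in (-90, -30, 0, 30, 90)
        for db in (48, 58)
        for _ in range(cfg.n_reps)
    ]
    order = rng.permutation(len(conditions))
    schedule = [conditions[i] for i in order]
    n_trials = len(schedule)

    block_s = cfg.stim_s + cfg.rest_s
    total_s = cfg.prep_s + n_trials * block_s
    n_samples = int(round(total_s * fs))
    t = np.arange(n_samples) / fs

    events = [
        Event(
            onset_s=cfg.prep_s + i * block_s,
            location_deg=loc,
            intensity_db=db,
            duration_s=cfg.stim_s,
        )
        for i, (loc, db) in enumerate(schedule)
    ]

    data = np.zeros((n_ch, n_samples))

    # --- evoked responses -------------------------------------------------
    if cfg.effect:
        response = cfg.hrf.block_response(fs, cfg.stim_s)
        gains = (
            1.0 + rng.normal(0.0, cfg.trial_jitter_sd, size=(n_trials, 10))
            if cfg.trial_jitter_sd > 0
            else np.ones((n_trials, 10))
        )
        for i, ev in enumerate(events):
            for roi_id in range(1, 11):
                key = (roi_id, ev.location_deg, ev.intensity_db)
                if key not in cfg.effect:
                    continue
                amp, lat = cfg.effect[key]
                if amp == 0:
                    continue
                start = int(round((ev.onset_s + lat) * fs))
                stop = min(start + response.size, n_samples)
                if start >= n_samples:
                    continue
                seg = amp * gains[i, roi_id - 1] * response[: stop - start]
                for ch in ROI_CHANNELS[roi_id]:
                    data[ch - 1, start:stop] += seg
    else:
        # keep the random stream aligned whether or not effects are present
        if cfg.trial_jitter_sd > 0:
            rng.normal(0.0, cfg.trial_jitter_sd, size=(n_trials, 10))

    # --- noise ------------------------------------------------------------
    nz = cfg.noise
    if nz.cardiac_amp > 0:
        data += _band_sinusoid(rng, nz.cardiac_band, n_ch, t, nz.cardiac_amp)
    if nz.resp_amp > 0:
        data += _band_sinusoid(rng, nz.resp_band, n_ch, t, nz.resp_amp)
    if nz.drift_amp > 0:
        data += _band_sinusoid(rng, nz.drift_band, n_ch, t, nz.drift_amp)
    if nz.white_sd > 0:
        data += rng.normal(0.0, nz.white_sd, size=data.shape)
    if nz.global_amp > 0:
        raw = rng.normal(size=n_samples)
        sos = sps.butter(2, 0.1, btype="lowpass", fs=fs, output="sos")
        g = sps.sosfiltfilt(sos, raw)
        sd = g.std()
        if sd > 0:
            g = g / sd * nz.global_amp
        data += g[None, :]

    rec = Recording(
        data=data,
        fs_hz=fs,
        chromophore="oxy",
        channels=list(probe.channels),
        events=events,
        subject_id=cfg.subject_id,
    )

    # --- behavioral responses ---------------------------------------------
    confusion = cfg.confusion or perfect_confusion()
    trials = []
    for loc, db in schedule:
        target = _LOC_TO_SPEAKER[loc]
        probs = confusion.get(loc, {target: 1.0})
        speakers = sorted(probs)
        p = np.array([probs[s] for s in speakers])
        resp = int(rng.choice(speakers, p=p))
        trials.append((target, resp, db))
    beh = BehavioralSession(trials=trials, subject_id=cfg.subject_id)

    return rec, beh, events


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write a small battery of sessions for tests and documentation.

    Three sessions are produced: ``null`` (no condition effect),
    ``high_snr`` (strong lateral-vs-front effect, decodable near 100%) and
    ``intensity`` (a level effect in ROI 4 only), plus a JSON manifest.
    Regeneration with the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suites = {
        "null": null_effect(),
        "high_snr": high_snr_effect(),
        "intensity": intensity_effect(),
    }
    paths: list[Path] = []
    manifest: dict[str, dict] = {}
    for i, (name, effect) in enumerate(suites.items()):
        cfg = SimulationConfig(
            seed=seed + i,
            effect=effect,
            confusion=lateral_confusion() if name == "high_snr" else perfect_confusion(),
            subject_id=name,
        )
        rec, beh, schedule = simulate_session(cfg)
        stem = out / name
        write_recording(rec, stem)
        write_behavioral(beh, stem.with_suffix(".responses.tsv"))
        session_files = [
            stem.with_suffix(".data.tsv"),
            stem.with_suffix(".meta.yaml"),
            stem.with_suffix(".events.tsv"),
            stem.with_suffix(".responses.tsv"),
        ]
        paths.extend(session_files)
        manifest[name] = {
            "seed": seed + i,
            "n_trials": len(schedule),
            "files": [p.name for p in session_files],
        }
    man = out / "manifest.json"
    man.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths.append(man)
    return paths
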