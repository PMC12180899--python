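"""Synthetic pupil and BOLD cohorts with known ground truth.

These generators emulate the structure of the empirical recordings the
analysis pipelines expect — per-trial pupil traces with blink dropouts,
slow drift and a switch-locked dilation whose amplitude depends on switch
latency; and parcel-level BOLD time series with a low-rank set of
HRF-convolved event components plus modular correlation structure — while
exposing every planted parameter, so recovery can be checked end to end.

Both generators are pure functions of (spec, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .fmri import ParcelDataset, canonical_hrf

__all__ = [
    "PupilSimSpec",
    "BoldSimSpec",
    "PupilCohort",
    "BoldTruth",
    "gen_pupil_cohort",
    "gen_bold_cohort",
    "dilation_kernel",
]


@dataclass
class PupilSimSpec:
    """Generator settings for the synthetic pupillometry cohort.

    The dilation amplitude on each trial follows
    ``a = a0 + b * (switch_index - switch_mode)`` with ``b < 0``
    mimicking the empirical pattern (earlier switches evoke larger
    dilations).  Amplitudes are stated in units of the analysis
    pipeline's evoked-peak measure (max of the cleaned, filtered,
    per-set z-scored trace in the switch image's response window):
    ``amplitude_gain`` is an internal injection gain calibrated so that
    under the default drift/noise levels one planted amplitude unit
    produces one unit of measured peak, compensating for the per-set
    z-scoring and the overlap of neighbouring dilations.
    """

    n_subjects: int = 35
    n_sets: int = 20
    images_per_set: int = 15
    fs: float = 1000.0
    image_duration_ms: float = 750.0
    iti_ms: float = 2000.0
    switch_mode: float = 9.0
    switch_sd: float = 1.5
    switch_clip: tuple[int, int] = (4, 14)
    kernel_peak_ms: float = 900.0
    kernel_shape: float = 2.5
    envelope: tuple[float, ...] = (0.15, 0.35, 0.65, 1.0, 0.5, 0.2, 0.05)
    a0: float = 1.0
    a0_subject_sd: float = 0.1
    b: float = -0.2
    amplitude_gain: float = 0.70
    drift_amplitude: float = 0.7
    drift_freq_hz: tuple[float, float] = (0.01, 0.04)
    noise_sd: float = 1.0
    blink_rate_hz: float = 0.1
    blink_duration_ms: tuple[float, float] = (150.0, 50.0)  # mean, sd
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fs, self.image_duration_ms, self.iti_ms) <= 0:
            raise ValueError("rates and durations must be positive")
        if not (1 <= self.switch_clip[0] < self.switch_clip[1] <= self.images_per_set):
            raise ValueError("switch clip range outside the image set")
        set_ms = self.images_per_set * (self.image_duration_ms + self.iti_ms)
        if self.kernel_peak_ms * 4 > set_ms:
            raise ValueError("dilation kernel longer than a picture set")

    @property
    def image_period_ms(self) -> float:
        return self.image_duration_ms + self.iti_ms

    @property
    def set_duration_ms(self) -> float:
        return self.images_per_set * self.image_period_ms


@dataclass
class PupilCohort:
    """Synthetic cohort: raw traces, annotations and planted truth."""

    traces: dict  # subject -> 1-D array (concatenated sets)
    annotations: pd.DataFrame  # subject, set_id, image_index, onset_ms, is_switch
    truth: pd.DataFrame  # per trial: subject, set_id, switch_index, amplitude
    spec: PupilSimSpec


def dilation_kernel(spec: PupilSimSpec) -> np.ndarray:
    """Gamma-shaped dilation kernel, unit peak, ~3x peak-latency support."""
    scale = spec.kernel_peak_ms / (spec.kernel_shape - 1.0)
    t = np.arange(0.0, spec.kernel_peak_ms * 4, 1000.0 / spec.fs)
    k = stats.gamma.pdf(t, spec.kernel_shape, scale=scale)
    return k / k.max()


def gen_pupil_cohort(spec: Optional[PupilSimSpec] = None, seed: Optional[int] = None) -> PupilCohort:
    """Generate per-subject pupil traces with planted switch-locked dilations.

    Each trial (picture set) is baseline + slow sinusoidal drift + the
    switch-locked dilation complex (the envelope spreads sub-peak
    dilations over the three images flanking the switch) + white noise +
    blink dropouts (samples set to 0 for the pipeline's cleaner to
    find).
    """
    spec = spec or PupilSimSpec()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    kernel = dilation_kernel(spec)
    n_set = round(spec.set_duration_ms * spec.fs / 1000.0)
    period = round(spec.image_period_ms * spec.fs / 1000.0)
    delta_range = np.arange(-3, 4)

    traces = {}
    ann_rows = []
    truth_rows = []
    for subj in range(spec.n_subjects):
        a0_s = spec.a0 + spec.a0_subject_sd * rng.standard_normal()
        parts = []
        for s in range(spec.n_sets):
            sw = int(
                np.clip(
                    round(rng.normal(spec.switch_mode, spec.switch_sd)),
                    *spec.switch_clip,
                )
            )
            amp = a0_s + spec.b * (sw - spec.switch_mode)
            x = np.zeros(n_set)
            # slow drift
            f = rng.uniform(*spec.drift_freq_hz)
            phase = rng.uniform(0, 2 * np.pi)
            tt = np.arange(n_set) / spec.fs
            x += spec.drift_amplitude * np.sin(2 * np.pi * f * tt + phase)
            # switch-locked dilation complex
            for w, d in zip(spec.envelope, delta_range):
                img = sw + d
                if not 1 <= img <= spec.images_per_set:
                    continue
                onset = (img - 1) * period
                seg = min(len(kernel), n_set - onset)
                x[onset : onset + seg] += spec.amplitude_gain * amp * w * kernel[:seg]
            x += spec.noise_sd * rng.standard_normal(n_set)
            x += 5.0  # arbitrary positive baseline (a.u.)
            # blinks: dropout to zero
            n_blinks = rng.poisson(spec.blink_rate_hz * spec.set_duration_ms / 1000.0)
            for _ in range(n_blinks):
                start = rng.integers(0, n_set)
                dur = max(
                    1,
                    int(rng.normal(*spec.blink_duration_ms) * spec.fs / 1000.0),
                )
                x[start : start + dur] = 0.0
            parts.append(x)
            set_start_ms = s * spec.set_duration_ms
            for img in range(1, spec.images_per_set + 1):
                ann_rows.append(
                    {
                        "subject": subj,
                        "set_id": s,
                        "image_index": img,
                        "onset_ms": set_start_ms + (img - 1) * spec.image_period_ms,
                        "is_switch": img == sw,
                    }
                )
            truth_rows.append(
                {"subject": subj, "set_id": s, "switch_index": sw, "amplitude": amp}
            )
        traces[subj] = np.concatenate(parts)
    return PupilCohort(
        traces, pd.DataFrame(ann_rows), pd.DataFrame(truth_rows), spec
    )


# --------------------------------------------------------------------------
# BOLD cohort
# --------------------------------------------------------------------------


@dataclass
class BoldSimSpec:
    """Generator settings for the synthetic parcel-level BOLD cohort.

    Three orthonormal spatial maps carry planted signal components: a
    smooth background fluctuation, a switch-locked component whose
    event amplitudes follow ``switch_profile`` over Delta = -3..+3, and
    a set-onset component; the event components are convolved with the
    canonical HRF.  The three time courses are mutually near-orthogonal
    so the components are identifiable by PCA.  ``variance_shares`` are
    the approximate fractions of total variance assigned to the three
    components; the rest is modular noise (3 planted modules with
    within-module shared signal) plus independent AR(1) noise.
    """

    n_subjects: int = 17
    n_regions: int = 375
    tr_s: float = 2.0
    n_sets: int = 20
    images_per_set: int = 15
    n_isi: int = 8  # jittered fixation gaps per set
    isi_options_s: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    switch_mode: float = 9.0
    switch_sd: float = 1.5
    switch_clip: tuple[int, int] = (4, 14)
    switch_profile: tuple[float, ...] = (0.0, 0.2, 0.5, 1.0, 0.5, 0.2, 0.0)
    variance_shares: tuple[float, float, float] = (0.12, 0.08, 0.05)
    n_modules: int = 3
    module_signal_sd: float = 0.6
    ar1_phi: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.variance_shares) >= 1.0:
            raise ValueError("variance shares must sum to < 1")
        if len(self.switch_profile) != 7:
            raise ValueError("switch profile covers Delta -3..+3 (7 values)")


@dataclass
class BoldTruth:
    """Planted ground truth of the synthetic BOLD cohort."""

    maps: np.ndarray  # (n_regions, 3) orthonormal spatial maps
    module_labels: np.ndarray  # (n_regions,)
    switch_profile: np.ndarray  # (7,)
    switch_component: int  # column of `maps` carrying the switch signal
    component_amplitudes: np.ndarray


def _ar1(rng: np.random.Generator, n: int, phi: float, size: int) -> np.ndarray:
    """(size, n) AR(1) series with unit innovation SD."""
    x = np.empty((size, n))
    x[:, 0] = rng.standard_normal(size) / np.sqrt(max(1e-9, 1 - phi**2))
    eps = rng.standard_normal((size, n))
    for t in range(1, n):
        x[:, t] = phi * x[:, t - 1] + eps[:, t]
    return x


def gen_bold_cohort(
    spec: Optional[BoldSimSpec] = None, seed: Optional[int] = None
) -> tuple[ParcelDataset, BoldTruth]:
    """Generate a ParcelDataset with planted components and modules."""
    spec = spec or BoldSimSpec()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    hrf = canonical_hrf(spec.tr_s)

    maps = np.linalg.qr(rng.standard_normal((spec.n_regions, 3)))[0][:, :3]
    module_labels = rng.integers(0, spec.n_modules, spec.n_regions)
    profile = np.asarray(spec.switch_profile, dtype=float)

    data = []
    ev_rows = []
    for subj in range(spec.n_subjects):
        # event schedule: images are 1 TR; jittered fixation gaps between them
        onsets = []
        sets = []
        images = []
        switches = {}
        t = 0.0
        for s in range(spec.n_sets):
            gap_positions = set(
                rng.choice(spec.images_per_set - 1, size=spec.n_isi, replace=False)
            )
            sw = int(
                np.clip(
                    round(rng.normal(spec.switch_mode, spec.switch_sd)),
                    *spec.switch_clip,
                )
            )
            switches[s] = sw
            for img in range(1, spec.images_per_set + 1):
                onsets.append(t)
                sets.append(s)
                images.append(img)
                t += spec.tr_s
                if (img - 1) in gap_positions:
                    t += float(rng.choice(spec.isi_options_s))
            t += 2.0 * spec.tr_s  # end-of-set screen
        n_vol = int(np.ceil(t / spec.tr_s)) + len(hrf)
        # component time courses: smooth background + two event trains
        trains = np.zeros((n_vol, 3))
        for onset, s, img in zip(onsets, sets, images):
            vol = int(round(onset / spec.tr_s))
            delta = img - switches[s]
            if -3 <= delta <= 3:
                trains[vol, 1] += profile[delta + 3]  # switch-locked
            if img == 1:
                trains[vol, 2] += 1.0  # set onset
        tcs = np.stack(
            [np.convolve(trains[:, k], hrf)[:n_vol] for k in range(3)], axis=1
        )
        # background: heavily smoothed noise, uncorrelated with the events
        bg = np.convolve(
            rng.standard_normal(n_vol), np.hanning(25) / np.hanning(25).sum(), "same"
        )
        tcs[:, 0] = bg
        sd = tcs.std(axis=0)
        tcs = (tcs - tcs.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

        shares = np.asarray(spec.variance_shares)
        noise_var = spec.noise_sd**2 + spec.module_signal_sd**2
        resid_share = 1.0 - shares.sum()
        if noise_var > 0:
            amps = np.sqrt(shares / resid_share * spec.n_regions * noise_var)
        else:  # noise-free: only the relative component scales matter
            amps = np.sqrt(shares)

        mod_sig = _ar1(rng, n_vol, spec.ar1_phi, spec.n_modules) * spec.module_signal_sd
        noise = _ar1(rng, n_vol, spec.ar1_phi, spec.n_regions) * spec.noise_sd
        mat = (maps * amps) @ tcs.T + mod_sig[module_labels] + noise
        data.append(mat)
        for onset, s, img in zip(onsets, sets, images):
            ev_rows.append(
                {
                    "subject": subj,
                    "set_id": s,
                    "image_index": img,
                    "onset_s": onset,
                    "is_switch": img == switches[s],
                }
            )
    events = pd.DataFrame(ev_rows)
    dataset = ParcelDataset(data, events, tr_s=spec.tr_s)
    truth = BoldTruth(
        maps=maps,
        module_labels=module_labels,
        switch_profile=profile,
        switch_component=1,
        component_amplitudes=amps,
    )
    return dataset, truth
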