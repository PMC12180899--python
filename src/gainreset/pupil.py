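"""Pupillometry preprocessing and switch-locked statistics.

Pupil-diameter traces (1 kHz) are cleaned of blinks/artefacts by linear
interpolation, low-pass filtered (second-order 2.5 Hz Butterworth,
applied forward-backward so switch-locked peaks are not delayed), and
z-scored within each 15-image picture set.  The per-image response is
then summarised, locked to the reported perceptual switch, and two group
statistics are computed: a one-sample t-test on the pre-switch rise of
the evoked response, and a two-level linear model relating the evoked
peak to the switch latency (per-subject slopes, then a one-tailed group
t-test that the mean slope is negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "CleanResult",
    "EvokedPositions",
    "clean_trace",
    "lowpass",
    "normalise_per_set",
    "image_values",
    "evoked_lock",
    "preswitch_test",
    "latency_model",
    "preprocess",
]

# evoked curve positions: first image, Delta -3..+3, last image
EVOKED_POSITIONS = ["first", -3, -2, -1, 0, 1, 2, 3, "last"]
PRESWITCH_POSITIONS = [-3, -2, -1]


@dataclass
class CleanResult:
    trace: np.ndarray
    mask: np.ndarray  # True where interpolated
    valid: bool  # False when too much of the trace was masked
    span_lengths: np.ndarray  # lengths of interpolated spans (samples)


@dataclass
class EvokedPositions:
    """Evoked values at the nine switch-locked positions per subject."""

    subjects: list
    values: np.ndarray  # (n_subjects, 9); nan where a position is missing

    @property
    def group_mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)


def clean_trace(
    trace: np.ndarray,
    mask: Optional[np.ndarray] = None,
    velocity_threshold: float = 10.0,
    max_masked_fraction: float = 0.4,
) -> CleanResult:
    """Remove blinks/artefacts and linearly interpolate across them.

    Samples are masked when flagged explicitly, non-positive (blink
    dropout), or when the absolute sample-to-sample velocity exceeds
    ``velocity_threshold`` (artefact spikes).  Masked spans are replaced
    by linear interpolation between the surrounding valid samples; a
    trace with more than ``max_masked_fraction`` masked is flagged
    invalid.
    """
    x = np.asarray(trace, dtype=float).copy()
    bad = np.zeros(len(x), dtype=bool) if mask is None else np.asarray(mask, bool).copy()
    bad |= ~np.isfinite(x)
    bad |= x <= 0
    vel = np.abs(np.diff(x, prepend=x[0]))
    bad |= vel > velocity_threshold
    valid = bad.mean() <= max_masked_fraction
    if not valid:
        warnings.warn(
            f"{bad.mean():.0%} of samples masked (> {max_masked_fraction:.0%}); "
            "trace flagged invalid",
            stacklevel=2,
        )
    spans = []
    if bad.any() and not bad.all():
        good_idx = np.where(~bad)[0]
        x[bad] = np.interp(np.where(bad)[0], good_idx, x[good_idx])
        # span bookkeeping
        edges = np.diff(bad.astype(int))
        starts = np.where(edges == 1)[0] + 1
        ends = np.where(edges == -1)[0] + 1
        if bad[0]:
            starts = np.insert(starts, 0, 0)
        if bad[-1]:
            ends = np.append(ends, len(bad))
        spans = (ends - starts).tolist()
    return CleanResult(x, bad, valid, np.asarray(spans, dtype=int))


def lowpass(
    trace: np.ndarray, fs: float = 1000.0, fc: float = 2.5, order: int = 2
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward)."""
    if fc >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = signal.butter(order, fc, fs=fs)
    return signal.filtfilt(b, a, np.asarray(trace, dtype=float))


def normalise_per_set(
    trace: np.ndarray, set_bounds: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, list[int]]:
    """Z-score the trace within each picture-set segment.

    ``set_bounds`` holds (start, stop) sample indices per set.  Returns
    the normalised trace and the indices of zero-variance sets (left
    untouched and flagged).
    """
    out = np.asarray(trace, dtype=float).copy()
    flagged = []
    for i, (lo, hi) in enumerate(set_bounds):
        seg = out[lo:hi]
        sd = seg.std()
        if sd == 0:
            flagged.append(i)
            continue
        out[lo:hi] = (seg - seg.mean()) / sd
    if flagged:
        warnings.warn(f"zero-variance sets excluded from normalisation: {flagged}", stacklevel=2)
    return out, flagged


def set_bounds_from_annotations(
    annotations: pd.DataFrame, n_samples: int, fs: float = 1000.0
) -> list[tuple[int, int]]:
    """(start, stop) sample indices per set, assuming contiguous sets."""
    starts = (
        annotations.groupby("set_id")["onset_ms"].min().sort_values() * fs / 1000.0
    ).astype(int)
    bounds = []
    vals = starts.tolist()
    for i, s in enumerate(vals):
        stop = vals[i + 1] if i + 1 < len(vals) else n_samples
        bounds.append((s, stop))
    return bounds


def image_values(
    trace: np.ndarray,
    annotations: pd.DataFrame,
    fs: float = 1000.0,
    window_ms: float = 1250.0,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Per-image scalar response: mean (or max) of the trace in a window
    starting at each image onset (default 750 ms presentation + 500 ms)."""
    rows = []
    n = len(trace)
    for _, row in annotations.iterrows():
        lo = int(round(row["onset_ms"] * fs / 1000.0))
        hi = min(n, lo + int(round(window_ms * fs / 1000.0)))
        if lo >= n:
            continue
        seg = trace[lo:hi]
        val = float(seg.max() if statistic == "max" else seg.mean())
        rows.append(
            {
                "set_id": row["set_id"],
                "image_index": int(row["image_index"]),
                "is_switch": bool(row["is_switch"]),
                "value": val,
            }
        )
    return pd.DataFrame(rows)


def evoked_lock(
    per_subject_values: dict,
    n_images: int = 15,
) -> EvokedPositions:
    """Switch-locked evoked curves per subject, aligned on Delta = 0.

    ``per_subject_values`` maps subject id to an image_values frame.
    Within each set the nine positions (first image, Delta -3..+3, last
    image) are extracted; sets without a reported switch are excluded
    (counted via a warning); positions are averaged across sets per
    subject.
    """
    subjects = list(per_subject_values)
    curves = np.full((len(subjects), len(EVOKED_POSITIONS)), np.nan)
    n_skipped = 0
    for si, subj in enumerate(subjects):
        vals = per_subject_values[subj]
        acc = np.zeros(len(EVOKED_POSITIONS))
        cnt = np.zeros(len(EVOKED_POSITIONS))
        for set_id, grp in vals.groupby("set_id"):
            sw = grp.loc[grp["is_switch"], "image_index"]
            if len(sw) == 0:
                n_skipped += 1
                continue
            s = int(sw.iloc[0])
            by_img = grp.set_index("image_index")["value"]
            for pi, pos in enumerate(EVOKED_POSITIONS):
                if pos == "first":
                    img = 1
                elif pos == "last":
                    img = n_images
                else:
                    img = s + pos
                if img in by_img.index:
                    acc[pi] += by_img.loc[img]
                    cnt[pi] += 1
        with np.errstate(invalid="ignore"):
            curves[si] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    if n_skipped:
        warnings.warn(f"{n_skipped} set(s) without a reported switch excluded", stacklevel=2)
    return EvokedPositions(subjects, curves)


def _one_sample_t(values: np.ndarray, alternative: str) -> tuple[float, float]:
    """One-sample t-test against 0, well-defined for degenerate input.

    A zero-variance sample with zero mean carries no evidence either
    way: t = 0 and the one-tailed p is 0.5.
    """
    values = np.asarray(values, dtype=float)
    if values.std(ddof=1) == 0:
        if values.mean() == 0:
            return 0.0, 0.5
        sign = np.sign(values.mean())
        hit = (sign > 0) == (alternative == "greater")
        return float(sign * np.inf), 0.0 if hit else 1.0
    t, p = stats.ttest_1samp(values, 0.0, alternative=alternative)
    return float(t), float(p)


def preswitch_test(evoked: EvokedPositions) -> dict:
    """One-tailed group test of the pre-switch pupil rise.

    Per subject, the mean of the three pre-switch positions
    (Delta -3..-1) minus the first-image baseline; a one-sample t-test
    asks whether this rise exceeds zero at the group level.
    """
    vals = evoked.values
    if vals.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    pre_idx = [EVOKED_POSITIONS.index(p) for p in PRESWITCH_POSITIONS]
    base_idx = EVOKED_POSITIONS.index("first")
    rise = np.nanmean(vals[:, pre_idx], axis=1) - vals[:, base_idx]
    rise = rise[np.isfinite(rise)]
    t, p = _one_sample_t(rise, alternative="greater")
    sd = rise.std(ddof=1)
    return {
        "mean_rise": float(rise.mean()),
        "t": float(t),
        "p": float(p),
        "df": len(rise) - 1,
        "cohen_d": float(rise.mean() / sd) if sd > 0 else np.nan,
        "n_subjects": len(rise),
    }


def latency_model(
    trials: pd.DataFrame,
    median_window: int = 2,
    min_trials: int = 3,
) -> dict:
    """Two-level model of evoked peak pupil on switch latency.

    ``trials`` has one row per (subject, set) with columns
    (subject, switch_index, peak).  Trials outside ``median_window``
    images of the grand median switch index are excluded (controls
    impulsive/late responses and thin extremes).  Level 1 fits a
    per-subject OLS slope of peak on switch index; level 2 is a
    one-tailed t-test that the mean slope is negative.
    """
    med = float(trials["switch_index"].median())
    keep = trials[np.abs(trials["switch_index"] - med) <= median_window]
    slopes = []
    excluded = []
    for subj, grp in keep.groupby("subject"):
        if len(grp) < min_trials or grp["switch_index"].nunique() < 2:
            excluded.append(subj)
            continue
        slope = np.polyfit(grp["switch_index"], grp["peak"], 1)[0]
        slopes.append(slope)
    if excluded:
        warnings.warn(
            f"{len(excluded)} subject(s) excluded (<{min_trials} qualifying trials)",
            stacklevel=2,
        )
    slopes = np.asarray(slopes)
    # clamp floating-point residue from exactly-constant fits
    slopes[np.abs(slopes) < 1e-12] = 0.0
    if len(slopes) < 3:
        raise ValueError("fewer than 3 subjects with enough qualifying trials")
    t, p = _one_sample_t(slopes, alternative="less")
    return {
        "mean_slope": float(slopes.mean()),
        "sd_slope": float(slopes.std(ddof=1)),
        "t": float(t),
        "p": float(p),
        "df": len(slopes) - 1,
        "n_subjects": len(slopes),
        "median_switch": med,
        "fraction_kept": float(len(keep) / len(trials)),
    }


def preprocess(
    trace: np.ndarray,
    annotations: pd.DataFrame,
    fs: float = 1000.0,
    mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, CleanResult]:
    """Clean, filter and per-set normalise one subject's trace."""
    cleaned = clean_trace(trace, mask)
    filtered = lowpass(cleaned.trace, fs=fs)
    bounds = set_bounds_from_annotations(annotations, len(filtered), fs)
    normalised, _ = normalise_per_set(filtered, bounds)
    return normalised, cleaned
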