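"""Functional cleaning chain for parcellated block-design BOLD.

Implements the motion-based censoring and nuisance-removal sequence used for
task fMRI before any network or shape-graph analysis:

1. framewise displacement (FD) from the six rigid-body motion parameters,
2. a censor mask from an FD threshold, dilated one frame back and two forward,
3. per-run nuisance regression (intercept + linear trend + 6 motion
   parameters) with betas estimated on non-censored frames only,
4. linear interpolation across censored frames,
5. zero-phase Butterworth band-pass (0.009-0.08 Hz by default),
6. removal of censored frames,
7. aggregation of parcels into large-scale network means.

All steps operate per run; censoring dilation and filtering never cross run
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

#: Canonical 7-network labels (Yeo-style ordering), used everywhere a network
#: axis appears.
NETWORKS = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default")

#: Rotation-to-displacement radius (mm) for the FD computation
#: (rotations are projected onto a sphere of this radius).
FD_ROTATION_RADIUS_MM = 50.0


@dataclass
class ParcelTimeSeries:
    """Frames x parcels BOLD matrix with run structure and a network map.

    Parameters
    ----------
    data:
        ``(n_frames, n_parcels)`` float array, arbitrary BOLD units.
    tr_seconds:
        Repetition time.
    run_boundaries:
        Monotone frame offsets ``[0, n1, n1+n2, ..., n_frames]`` partitioning
        the timeline into runs.
    parcel_ids:
        One id per column.
    parcel_to_network:
        Mapping parcel id -> network label (one of :data:`NETWORKS`).
    """

    data: np.ndarray
    tr_seconds: float
    run_boundaries: Sequence[int]
    parcel_ids: Sequence[str]
    parcel_to_network: Mapping[str, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (frames x parcels)")
        rb = list(self.run_boundaries)
        if rb[0] != 0 or rb[-1] != self.data.shape[0] or any(np.diff(rb) <= 0):
            raise ValueError(
                f"run_boundaries {rb} do not partition {self.data.shape[0]} frames"
            )
        if len(self.parcel_ids) != self.data.shape[1]:
            raise ValueError("parcel_ids length does not match column count")
        missing = [p for p in self.parcel_ids if p not in self.parcel_to_network]
        if missing:
            raise ValueError(f"parcels without a network assignment: {missing[:5]}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.run_boundaries) - 1

    def run_slices(self) -> list[slice]:
        rb = list(self.run_boundaries)
        return [slice(rb[i], rb[i + 1]) for i in range(len(rb) - 1)]


@dataclass
class CensorMask:
    """Per-frame censoring flags (True = censored) plus provenance."""

    flags: np.ndarray
    threshold_mm: float
    back: int
    forward: int

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_censored(self) -> int:
        return int(self.flags.sum())


@dataclass
class CleanSeries:
    """Cleaned matrix restricted to retained frames.

    ``retained_indices`` index into the original (pre-censoring) timeline;
    ``labels``, when present, is the *full* original per-frame label table, so
    downstream stages can align retained rows via ``retained_indices``.
    """

    data: np.ndarray
    retained_indices: np.ndarray
    tr_seconds: float
    run_boundaries: Sequence[int]
    parcel_ids: Sequence[str]
    parcel_to_network: Mapping[str, str]
    labels: pd.DataFrame | None = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def retained_labels(self) -> pd.DataFrame:
        if self.labels is None:
            raise ValueError("no labels attached to this CleanSeries")
        return self.labels.iloc[self.retained_indices].reset_index(drop=True)


def compute_fd(motion: np.ndarray) -> np.ndarray:
    """Framewise displacement for one run of 6-column motion parameters.

    ``FD_t = sum |d translation| + R * sum |d rotation|`` with
    ``R = 50 mm``; the first frame of the run is assigned FD 0.  Columns are
    three translations (mm) then three rotations (radians).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (n_frames, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters contain non-finite values")
    diffs = np.abs(np.diff(motion, axis=0))
    fd = diffs[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def compute_fd_runs(motion_runs: Sequence[np.ndarray]) -> np.ndarray:
    """FD for a list of per-run motion arrays, concatenated in run order."""
    return np.concatenate([compute_fd(m) for m in motion_runs])


def build_censor_mask(
    fd: np.ndarray,
    run_boundaries: Sequence[int],
    threshold: float = 0.2,
    back: int = 1,
    forward: int = 2,
) -> CensorMask:
    """Flag frames with FD above ``threshold`` plus a dilation window.

    Each supra-threshold frame also censors ``back`` frames before it and
    ``forward`` frames after it, clipped at run boundaries (the dilation never
    leaks into an adjacent run).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if back < 0 or forward < 0:
        raise ValueError("dilation widths must be non-negative")
    fd = np.asarray(fd, dtype=float)
    flags = np.zeros(fd.shape[0], dtype=bool)
    rb = list(run_boundaries)
    for start, stop in zip(rb[:-1], rb[1:]):
        hits = np.nonzero(fd[start:stop] > threshold)[0]
        for h in hits:
            lo = max(0, h - back)
            hi = min(stop - start, h + forward + 1)
            flags[start + lo : start + hi] = True
    return CensorMask(flags=flags, threshold_mm=threshold, back=back, forward=forward)


def _interpolate_censored(x: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Linearly interpolate censored rows of ``x`` (frames x parcels).

    Censored frames before the first / after the last kept frame take the
    nearest kept value (constant extrapolation), matching ``np.interp``.
    """
    out = x.copy()
    cens = ~keep
    if not cens.any():
        return out
    t = np.arange(x.shape[0])
    tk = t[keep]
    tc = t[cens]
    # vectorised piecewise-linear interpolation across parcels
    pos = np.searchsorted(tk, tc)
    lo = np.clip(pos - 1, 0, len(tk) - 1)
    hi = np.clip(pos, 0, len(tk) - 1)
    denom = (tk[hi] - tk[lo]).astype(float)
    w = np.where(denom > 0, (tc - tk[lo]) / np.where(denom == 0, 1, denom), 0.0)
    out[cens] = (1 - w)[:, None] * x[keep][lo] + w[:, None] * x[keep][hi]
    return out


def clean_timeseries(
    ts: ParcelTimeSeries,
    motion_runs: Sequence[np.ndarray],
    mask: CensorMask,
    band: tuple[float, float] = (0.009, 0.08),
    labels: pd.DataFrame | None = None,
    filter_order: int = 4,
) -> CleanSeries:
    """Nuisance-regress, interpolate, band-pass and censor a parcel series.

    Per run: one OLS against ``[1, t, motion(6)]`` with betas estimated on
    non-censored frames only (this performs demeaning, linear detrending and
    motion regression in a single projection); residuals are computed for all
    frames, censored frames are linearly interpolated, the band-pass is a
    zero-phase Butterworth of the given order applied forward-backward, and
    finally censored frames are dropped.
    """
    if mask.flags.shape[0] != ts.n_frames:
        raise ValueError("censor mask is not aligned with the time series")
    if len(motion_runs) != ts.n_runs:
        raise ValueError(f"expected {ts.n_runs} motion arrays, got {len(motion_runs)}")
    nyquist = 0.5 / ts.tr_seconds
    lo, hi = band
    if not (0 < lo < hi < nyquist):
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist ({nyquist})")
    if labels is not None and len(labels) != ts.n_frames:
        raise ValueError("labels are not aligned with the time series")

    b, a = signal.butter(filter_order, [lo, hi], btype="bandpass", fs=1.0 / ts.tr_seconds)
    cleaned = np.empty_like(ts.data)
    for run_idx, sl in enumerate(ts.run_slices()):
        x = ts.data[sl]
        mot = np.asarray(motion_runs[run_idx], dtype=float)
        if mot.shape != (x.shape[0], 6):
            raise ValueError(
                f"run {run_idx}: motion shape {mot.shape} does not match {x.shape[0]} frames"
            )
        keep = ~mask.flags[sl]
        n = x.shape[0]
        design = np.column_stack([np.ones(n), np.linspace(-1, 1, n), mot])
        if keep.sum() <= design.shape[1]:
            raise ValueError(
                f"run {run_idx}: only {int(keep.sum())} retained frames, "
                "too few to estimate nuisance betas"
            )
        beta, *_ = np.linalg.lstsq(design[keep], x[keep], rcond=None)
        resid = x - design @ beta
        resid = _interpolate_censored(resid, keep)
        cleaned[sl] = signal.filtfilt(b, a, resid, axis=0)

    retained = np.nonzero(~mask.flags)[0]
    return CleanSeries(
        data=cleaned[retained],
        retained_indices=retained,
        tr_seconds=ts.tr_seconds,
        run_boundaries=ts.run_boundaries,
        parcel_ids=ts.parcel_ids,
        parcel_to_network=ts.parcel_to_network,
        labels=labels,
    )


def aggregate_networks(clean: CleanSeries, networks: Sequence[str] = NETWORKS) -> pd.DataFrame:
    """Unweighted mean of member parcels per network, per retained frame."""
    cols = {}
    ids = np.asarray(clean.parcel_ids)
    assigned = np.array([clean.parcel_to_network[p] for p in ids])
    unknown = set(assigned) - set(networks)
    if unknown:
        raise ValueError(f"parcels mapped to unknown networks: {sorted(unknown)}")
    for net in networks:
        members = assigned == net
        if not members.any():
            raise ValueError(f"network {net!r} has no member parcels")
        cols[net] = clean.data[:, members].mean(axis=1)
    return pd.DataFrame(cols, columns=list(networks))
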