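"""Synthetic BOLD time series with known ground-truth condition amplitudes.

Generates the two run types the analysis needs:

* event-related attention runs — every stimulus-responsive voxel carries a
  sum of condition-amplitude x HRF responses at the trial onsets from the
  session design, on a baseline of 100 with low-frequency drift and AR(1)
  noise on top;
* block-design localizer runs — 16 cycles of 17.5 s (8.75 s gratings on /
  8.75 s off, 280 s of cycling at TR 1.75 s), used downstream to select
  stimulus-responsive voxels.

Amplitudes are expressed in percent signal change (PSC) about the baseline.
Laterality is built in: a left-side cue drives right-hemisphere voxels
(contralateral) harder than left-hemisphere ones.  The valid-minus-invalid
contralateral difference per ROI follows a *modulation profile* over the
hierarchy rank (1-6): "increasing" (scales linearly with rank), "flat"
(constant positive) or "null" (zero) — the three regimes whose combinations
distinguish the attention systems under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .trial_design import (
    ROIS, HEMISPHERES, HIERARCHY_RANK, SessionDesign, TrialEvent, DEFAULT_TR,
)

MODULATION_PROFILES = ("increasing", "flat", "null")

#: The 8 task conditions plus cue-only, blank and the eye-movement nuisance
#: class; names double as GLM regressor names.
TASK_CONDITIONS = tuple(
    f"{side}_{validity}_{epoch}"
    for side in ("left", "right")
    for validity in ("valid", "invalid")
    for epoch in ("pre", "post")
)
ALL_CONDITIONS = TASK_CONDITIONS + ("cue_only_left", "cue_only_right", "blank")
GLM_REGRESSORS = ALL_CONDITIONS + ("eye_movement",)


def hrf(time_grid: np.ndarray, peak_shape: float = 6.0, undershoot_shape: float = 16.0,
        dispersion: float = 1.0, undershoot_ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    Zero at t = 0, peaks near 5 s, followed by a negative undershoot whose
    area is 1/``undershoot_ratio`` of the positive lobe (before
    normalization), so the total integral stays positive.
    """
    t = np.asarray(time_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative (causal kernel)")
    h = (
        gamma_dist.pdf(t, peak_shape, scale=dispersion)
        - gamma_dist.pdf(t, undershoot_shape, scale=dispersion) / undershoot_ratio
    )
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF parameterization")
    return h / peak


def convolve_onsets(
    onsets: np.ndarray,
    frame_times: np.ndarray,
    *,
    dt: float = 0.05,
    hrf_kwargs: dict | None = None,
) -> np.ndarray:
    """HRF-convolved unit-impulse regressor sampled at ``frame_times``.

    Events are modeled as impulses on a ``dt``-resolution grid; an isolated
    event of weight 1 therefore evokes a response whose peak is 1, so that a
    GLM beta on this regressor reads directly in the amplitude units of the
    simulator (PSC).  The same routine builds both the simulated signal and
    the design-matrix columns.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    t_end = frame_times.max() + 32.0
    n_hi = int(np.ceil(t_end / dt)) + 1
    train = np.zeros(n_hi)
    for onset in np.atleast_1d(onsets):
        k = int(round(onset / dt))
        if 0 <= k < n_hi:
            train[k] += 1.0
    kernel = hrf(np.arange(0.0, 32.0, dt), **(hrf_kwargs or {}))
    sig = np.convolve(train, kernel)[:n_hi]
    idx = np.round(frame_times / dt).astype(int)
    return sig[idx]


def convolve_boxcar(
    frame_times: np.ndarray,
    on_intervals: list[tuple[float, float]],
    *,
    dt: float = 0.05,
    hrf_kwargs: dict | None = None,
) -> np.ndarray:
    """HRF-convolved boxcar, normalized so a sustained block plateaus near 1."""
    frame_times = np.asarray(frame_times, dtype=float)
    t_end = frame_times.max() + 32.0
    n_hi = int(np.ceil(t_end / dt)) + 1
    train = np.zeros(n_hi)
    hi_t = np.arange(n_hi) * dt
    for a, b in on_intervals:
        train[(hi_t >= a) & (hi_t < b)] = 1.0
    kernel = hrf(np.arange(0.0, 32.0, dt), **(hrf_kwargs or {}))
    kernel = kernel / kernel.sum()  # unit-gain for sustained input
    sig = np.convolve(train, kernel)[:n_hi]
    idx = np.round(frame_times / dt).astype(int)
    return sig[idx]


@dataclass
class NoiseParams:
    """Additive noise of the simulator, all in PSC units.

    ``drift_amplitude`` is the peak-to-peak scale of the per-voxel linear
    drift over a run; ``ar_coef`` and ``white_sd`` parameterize AR(1) noise
    with marginal standard deviation ``white_sd``.
    """

    drift_amplitude: float = 1.0
    ar_coef: float = 0.3
    white_sd: float = 0.5

    def is_zero(self) -> bool:
        return self.drift_amplitude == 0 and self.white_sd == 0


@dataclass
class GroundTruthEffects:
    """True condition amplitudes (PSC) per ROI x hemisphere for one session type."""

    attention_type: str
    profiles: dict  # {"pre": profile, "post": profile}
    amplitudes: dict  # {(roi, hemisphere, condition): PSC}
    eye_movement_amp: float
    params: dict = field(default_factory=dict)

    def amplitude(self, roi: str, hemisphere: str, condition: str) -> float:
        if condition == "eye_movement":
            return self.eye_movement_amp
        return self.amplitudes[(roi, hemisphere, condition)]

    def contra_validity_difference(self, roi: str, epoch: str) -> float:
        """Ground-truth contralateral valid - invalid difference for an ROI/epoch."""
        # left-cue conditions drive the right hemisphere contralaterally
        v = self.amplitudes[(roi, "right", f"left_valid_{epoch}")]
        i = self.amplitudes[(roi, "right", f"left_invalid_{epoch}")]
        return v - i

    def to_json(self, path) -> None:
        payload = {
            "attention_type": self.attention_type,
            "profiles": self.profiles,
            "eye_movement_amp": self.eye_movement_amp,
            "params": self.params,
            "amplitudes": {"|".join(k): v for k, v in self.amplitudes.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruthEffects":
        with open(path) as fh:
            payload = json.load(fh)
        amplitudes = {tuple(k.split("|")): v for k, v in payload.pop("amplitudes").items()}
        return cls(amplitudes=amplitudes, **payload)


def _profile_delta(profile: str, rank: int, slope: float, flat_level: float) -> float:
    if profile == "increasing":
        return slope * rank
    if profile == "flat":
        return flat_level
    if profile == "null":
        return 0.0
    raise ValueError(f"unknown modulation profile {profile!r}")


def make_ground_truth(
    attention_type: str,
    profile_pre: str,
    profile_post: str,
    *,
    base_contra: float = 0.8,
    base_ipsi: float = 0.4,
    slope: float = 0.05,
    flat_level: float = 0.15,
    cue_only_amp: float = 0.3,
    blank_amp: float = 0.1,
    eye_movement_amp: float = 0.5,
) -> GroundTruthEffects:
    """Build ground-truth amplitudes implementing a modulation profile per epoch.

    The contralateral valid/invalid amplitudes straddle ``base_contra`` by
    +/- delta/2 where delta follows the profile over hierarchy rank;
    ipsilateral responses carry no validity effect.  Cue-only responses are
    lateralized (weaker ipsilaterally); blank trials model response-cue
    activity only.
    """
    amplitudes: dict[tuple[str, str, str], float] = {}
    for roi in ROIS:
        rank = HIERARCHY_RANK[roi]
        deltas = {
            "pre": _profile_delta(profile_pre, rank, slope, flat_level),
            "post": _profile_delta(profile_post, rank, slope, flat_level),
        }
        for hemi in HEMISPHERES:
            for side in ("left", "right"):
                contra = (side == "left") == (hemi == "right")
                for epoch in ("pre", "post"):
                    for validity in ("valid", "invalid"):
                        if contra:
                            amp = base_contra + (0.5 if validity == "valid" else -0.5) * deltas[epoch]
                        else:
                            amp = base_ipsi
                        amplitudes[(roi, hemi, f"{side}_{validity}_{epoch}")] = amp
                amplitudes[(roi, hemi, f"cue_only_{side}")] = (
                    cue_only_amp if contra else cue_only_amp / 2.0
                )
            amplitudes[(roi, hemi, "blank")] = blank_amp
    gt = GroundTruthEffects(
        attention_type=attention_type,
        profiles={"pre": profile_pre, "post": profile_post},
        amplitudes=amplitudes,
        eye_movement_amp=eye_movement_amp,
        params={
            "base_contra": base_contra, "base_ipsi": base_ipsi, "slope": slope,
            "flat_level": flat_level, "cue_only_amp": cue_only_amp,
            "blank_amp": blank_amp,
        },
    )
    _check_profiles(gt)
    return gt


def _check_profiles(gt: GroundTruthEffects) -> None:
    for epoch, profile in gt.profiles.items():
        diffs = [gt.contra_validity_difference(roi, epoch) for roi in ROIS]
        if profile == "increasing" and not np.all(np.diff(diffs) > 0):
            raise ValueError("'increasing' profile is not strictly increasing in rank")
        if profile == "flat" and not (
            np.allclose(diffs, diffs[0]) and diffs[0] > 0
        ):
            raise ValueError("'flat' profile must be constant positive")
        if profile == "null" and not np.allclose(diffs, 0.0):
            raise ValueError("'null' profile must have zero differences")


@dataclass
class VoxelTimeSeries:
    """A run's voxel x timepoint matrix with acquisition metadata.

    ``units`` is "raw" for simulator output (baseline ~100) and "psc" after
    preprocessing.  ``voxel_meta`` has one row per voxel: roi, hemisphere,
    responsive (ground-truth stimulus-responsive flag).
    """

    data: np.ndarray
    tr: float
    run_id: str
    n_discard: int
    voxel_meta: pd.DataFrame
    units: str = "raw"
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.shape[0] != len(self.voxel_meta):
            raise ValueError("voxel_meta must have one row per voxel")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr


def _make_voxel_meta(n_voxels_per_roi: int, responsive_frac: float) -> pd.DataFrame:
    n_resp = int(round(responsive_frac * n_voxels_per_roi))
    rows = []
    for roi in ROIS:
        for hemi in HEMISPHERES:
            for v in range(n_voxels_per_roi):
                rows.append({"roi": roi, "hemisphere": hemi, "responsive": v < n_resp})
    return pd.DataFrame(rows)


def _noise_matrix(
    n_voxels: int, n_t: int, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    out = np.zeros((n_voxels, n_t))
    if noise.drift_amplitude > 0:
        slopes = rng.uniform(-1.0, 1.0, size=n_voxels) * noise.drift_amplitude
        ramp = np.linspace(-0.5, 0.5, n_t)
        out += slopes[:, None] * ramp[None, :]
    if noise.white_sd > 0:
        rho = noise.ar_coef
        innov_sd = noise.white_sd * np.sqrt(max(1.0 - rho**2, 1e-12))
        e = rng.standard_normal((n_voxels, n_t))
        ar = np.empty_like(e)
        ar[:, 0] = e[:, 0] * noise.white_sd
        for t in range(1, n_t):
            ar[:, t] = rho * ar[:, t - 1] + innov_sd * e[:, t]
        out += ar
    return out


def simulate_attention_run(
    run_trials: list[TrialEvent],
    session: SessionDesign,
    ground_truth: GroundTruthEffects,
    noise: NoiseParams,
    seed: int,
    *,
    run_id: str = "run-01",
    n_voxels_per_roi: int = 100,
    responsive_frac: float = 0.8,
    voxel_gain_sd: float = 0.1,
    baseline: float = 100.0,
    hrf_kwargs: dict | None = None,
) -> VoxelTimeSeries:
    """Simulate one event-related attention run.

    Each stimulus-responsive voxel carries, in PSC, the sum over conditions of
    (per-voxel gain x ROI ground-truth amplitude) x HRF responses at that
    condition's trial onsets, plus drift and AR(1) noise; the series is then
    expressed on a raw baseline of 100.  Non-responsive voxels carry noise
    only.  Excluded (fixation-break) trials evoke the distinct eye-movement
    response class, matching how the GLM models them.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    meta = _make_voxel_meta(n_voxels_per_roi, responsive_frac)
    frame_times = np.arange(session.n_volumes) * session.tr
    last_offset = max(max(t.onsets.values()) for t in run_trials)
    if last_offset > frame_times[-1] + session.tr:
        raise ValueError("run duration shorter than the trial timeline it must contain")

    # condition -> onsets for this run
    onsets_by_cond: dict[str, list[float]] = {}
    for t in run_trials:
        onsets_by_cond.setdefault(t.condition_label(), []).append(t.onset)
    regressors = {
        cond: convolve_onsets(np.asarray(ons), frame_times, hrf_kwargs=hrf_kwargs)
        for cond, ons in onsets_by_cond.items()
    }

    n_vox = len(meta)
    gains = 1.0 + voxel_gain_sd * rng.standard_normal(n_vox)
    signal = np.zeros((n_vox, len(frame_times)))
    for (roi, hemi), idx in meta.groupby(["roi", "hemisphere"], sort=False).groups.items():
        idx = np.asarray(idx)
        resp_idx = idx[meta.loc[idx, "responsive"].to_numpy()]
        if resp_idx.size == 0:
            continue
        roi_signal = np.zeros(len(frame_times))
        for cond, reg in regressors.items():
            roi_signal += ground_truth.amplitude(roi, hemi, cond) * reg
        signal[resp_idx] = gains[resp_idx, None] * roi_signal[None, :]

    psc = signal + _noise_matrix(n_vox, len(frame_times), noise, rng)
    data = baseline * (1.0 + psc / 100.0)
    return VoxelTimeSeries(
        data=data, tr=session.tr, run_id=run_id, n_discard=8, voxel_meta=meta,
    )


@dataclass
class LocalizerParams:
    """Block-alternation localizer: ``n_cycles`` cycles of ``cycle_s`` seconds."""

    n_cycles: int = 16
    cycle_s: float = 17.5
    tr: float = DEFAULT_TR
    n_leadin: int = 8           # dummy volumes discarded in preprocessing
    amplitude: float = 1.0      # PSC of responsive voxels
    lag_s: float = 5.0          # hemodynamic lag of the response fundamental
    n_voxels_per_roi: int = 100
    responsive_frac: float = 0.8
    voxel_gain_sd: float = 0.1
    baseline: float = 100.0

    @property
    def cycling_duration(self) -> float:
        return self.n_cycles * self.cycle_s

    @property
    def n_volumes(self) -> int:
        n_cycle_vols = int(round(self.cycling_duration / self.tr))
        return self.n_leadin + n_cycle_vols

    @property
    def stimulus_frequency(self) -> float:
        return 1.0 / self.cycle_s


def simulate_localizer_run(
    params: LocalizerParams,
    noise: NoiseParams,
    seed: int,
    *,
    run_id: str = "localizer-01",
) -> VoxelTimeSeries:
    """Simulate one block-design localizer run.

    Cycling starts after ``n_leadin`` dummy volumes so that, once those are
    discarded, the remaining series spans exactly ``n_cycles`` cycles (280 s,
    160 volumes at the defaults) and the stimulus frequency is a harmonic of
    the series length.

    Responsive voxels carry the *fundamental* of the hemodynamic block
    response — a raised cosine at the cycle frequency, delayed by ``lag_s``
    — which is the component the downstream sinusoid fit estimates; at a
    ~5 s lag on a 17.5 s cycle the response phase falls inside (0, pi).
    Non-responsive voxels carry drift and noise only.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    meta = _make_voxel_meta(params.n_voxels_per_roi, params.responsive_frac)
    n_t = params.n_volumes
    frame_times = np.arange(n_t) * params.tr
    t0 = params.n_leadin * params.tr
    f = params.stimulus_frequency
    block = 0.5 * (1.0 + np.cos(2.0 * np.pi * f * (frame_times - t0 - params.lag_s)))

    n_vox = len(meta)
    gains = 1.0 + params.voxel_gain_sd * rng.standard_normal(n_vox)
    responsive = meta["responsive"].to_numpy()
    psc = np.zeros((n_vox, n_t))
    psc[responsive] = params.amplitude * gains[responsive, None] * block[None, :]
    psc += _noise_matrix(n_vox, n_t, noise, rng)
    data = params.baseline * (1.0 + psc / 100.0)
    return VoxelTimeSeries(
        data=data, tr=params.tr, run_id=run_id, n_discard=params.n_leadin,
        voxel_meta=meta,
    )


def to_psc(data: np.ndarray, baseline: np.ndarray | float) -> np.ndarray:
    """Express raw signal as percent change about ``baseline``."""
    return 100.0 * (data - np.asarray(baseline)) / np.asarray(baseline)


def from_psc(psc: np.ndarray, baseline: np.ndarray | float) -> np.ndarray:
    """Invert :func:`to_psc` (round-trip identity)."""
    return np.asarray(baseline) * (1.0 + psc / 100.0)
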