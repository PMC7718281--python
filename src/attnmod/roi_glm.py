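"""Preprocessing, ROI averaging and the 12-regressor event-related GLM.

Preprocessing per run: discard the first 8 volumes (steady-state
magnetization), convert to percent signal change about the voxel baseline,
remove the per-voxel linear trend, and high-pass filter below 0.01 Hz via
projection on a discrete-cosine (DCT) drift basis.

The event-related model has twelve task regressors: the 8 combinations of
cue side (left/right) x validity (valid/invalid) x cue epoch (pre/post),
left and right cue-only, blank, and eye-movement (blink / broken-fixation
trials).  Optionally, incorrect stimulus trials load on a separate nuisance
column so the 8 condition betas reflect correct trials only.  Amplitudes are
ordinary-least-squares betas on the voxel-averaged ROI time course,
concatenated across runs with per-run intercepts.

The drift/high-pass projection applied to the data is applied identically to
the design-matrix columns (Frisch-Waugh-Lovell), so filtering introduces no
bias in the condition betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bold_synth import GLM_REGRESSORS, VoxelTimeSeries, convolve_onsets
from .localizer_fit import VoxelSelection
from .trial_design import ROIS, HEMISPHERES, SessionDesign, TrialEvent

DEFAULT_HIGHPASS_HZ = 0.01
DEFAULT_N_DISCARD = 8
MIN_RUN_LENGTH = 16


def dct_drift_basis(n_t: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Unit-norm DCT-II drift columns with frequency below ``cutoff_hz``.

    Column ``j`` has frequency j / (2 * n_t * tr); the constant and linear
    trend are handled separately, so columns start at j = 1.
    """
    n_drift = int(np.floor(2.0 * n_t * tr * cutoff_hz))
    t = np.arange(n_t)
    cols = [np.cos(np.pi * j * (2 * t + 1) / (2 * n_t)) for j in range(1, n_drift + 1)]
    if not cols:
        return np.empty((n_t, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0, keepdims=True)


def _nuisance_projector(n_t: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Residual-forming matrix for [constant, linear trend, DCT drifts]."""
    t = np.arange(n_t)
    cols = [np.ones(n_t), t - t.mean()]
    drift = dct_drift_basis(n_t, tr, cutoff_hz)
    basis = np.column_stack([np.column_stack(cols), drift])
    q, _ = np.linalg.qr(basis)
    return np.eye(n_t) - q @ q.T


def preprocess_run(
    ts: VoxelTimeSeries,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    n_discard: int | None = None,
    *,
    baseline: str | float = "mean",
) -> VoxelTimeSeries:
    """Discard lead-in volumes, convert to PSC, detrend and high-pass filter.

    ``baseline`` is "mean" (per-voxel temporal mean, the standard choice) or
    an explicit raw value.  The filter settings are recorded on the returned
    object so the GLM can apply the identical projection to its regressors.
    """
    start = ts.n_discard if n_discard is None else n_discard
    if ts.n_timepoints - start < MIN_RUN_LENGTH:
        raise ValueError(
            f"run {ts.run_id}: {ts.n_timepoints} volumes leave fewer than "
            f"{MIN_RUN_LENGTH} after discarding {start}"
        )
    cropped = ts.data[:, start:]
    if baseline == "mean":
        base = cropped.mean(axis=1, keepdims=True)
    else:
        base = float(baseline)
    psc = 100.0 * (cropped - base) / base
    proj = _nuisance_projector(psc.shape[1], ts.tr, highpass_hz)
    clean = psc @ proj.T
    return VoxelTimeSeries(
        data=clean,
        tr=ts.tr,
        run_id=ts.run_id,
        n_discard=0,
        voxel_meta=ts.voxel_meta.copy(),
        units="psc",
        preprocessing={
            "highpass_hz": highpass_hz,
            "n_discard": start,
            "baseline": baseline,
            "detrended": True,
        },
    )


def average_roi_timecourse(
    ts: VoxelTimeSeries,
    selection: VoxelSelection | None,
    roi: str,
    hemisphere: str,
) -> np.ndarray:
    """Unweighted mean time course over the selected voxels of one ROI/hemisphere.

    Falls back (with a warning) to all voxels of the ROI when the localizer
    selection retained none.  Raises if the ROI is absent altogether.
    """
    meta = ts.voxel_meta
    roi_mask = (meta["roi"] == roi) & (meta["hemisphere"] == hemisphere)
    if not roi_mask.any():
        raise ValueError(f"ROI {roi}/{hemisphere} absent from the data")
    if selection is not None:
        idx = selection.indices(roi, hemisphere)
        if idx.size == 0:
            warnings.warn(
                f"no selected voxels for {roi}/{hemisphere}; averaging all "
                f"{int(roi_mask.sum())} ROI voxels instead",
                stacklevel=2,
            )
            idx = np.flatnonzero(roi_mask.to_numpy())
    else:
        idx = np.flatnonzero(roi_mask.to_numpy())
    return ts.data[idx].mean(axis=0)


@dataclass
class DesignMatrix:
    """Concatenated-run design: task regressors, nuisance columns, run labels."""

    matrix: np.ndarray
    names: list[str]
    task_names: list[str]
    run_index: np.ndarray
    empty_columns: list[str] = field(default_factory=list)

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def build_design_matrix(
    session: SessionDesign,
    runs: list[list[TrialEvent]] | None = None,
    *,
    correct_only: bool = False,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    n_discard: int = DEFAULT_N_DISCARD,
    hrf_kwargs: dict | None = None,
) -> DesignMatrix:
    """Build the 12-regressor event-related design across a session's runs.

    Each trial loads an impulse (at its first event) on its condition
    regressor; excluded trials load only on ``eye_movement``; with
    ``correct_only`` incorrect stimulus trials move to an ``incorrect``
    nuisance column.  Columns are HRF-convolved, sampled on the post-discard
    volume grid, filtered with the same nuisance projection used in
    preprocessing, and concatenated across runs; per-run intercepts are
    appended.  Task conditions absent from the session yield all-zero columns
    which are flagged in ``empty_columns``.
    """
    runs = session.runs if runs is None else runs
    n_run_t = session.n_volumes - n_discard
    frame_times = (np.arange(n_run_t) + n_discard) * session.tr
    proj = _nuisance_projector(n_run_t, session.tr, highpass_hz)

    task_names = list(GLM_REGRESSORS) + (["incorrect"] if correct_only else [])
    blocks = []
    run_index = []
    for r, trials in enumerate(runs):
        onsets: dict[str, list[float]] = {name: [] for name in task_names}
        for t in trials:
            name = t.condition_label()
            if (
                correct_only
                and name != "eye_movement"
                and t.is_stimulus_trial
                and t.correct is False
            ):
                name = "incorrect"
            if t.onset in onsets[name]:
                warnings.warn(
                    f"run {r}: duplicate onset {t.onset} in regressor {name}; merged",
                    stacklevel=2,
                )
                continue
            onsets[name].append(t.onset)
        cols = []
        for name in task_names:
            if onsets[name]:
                col = convolve_onsets(
                    np.asarray(onsets[name]), frame_times, hrf_kwargs=hrf_kwargs
                )
            else:
                col = np.zeros(n_run_t)
            cols.append(col)
        block = proj @ np.column_stack(cols)
        blocks.append(block)
        run_index.extend([r] * n_run_t)

    task = np.vstack(blocks)
    run_index = np.asarray(run_index)
    n_runs = len(runs)
    intercepts = np.zeros((task.shape[0], n_runs))
    for r in range(n_runs):
        intercepts[run_index == r, r] = 1.0
    matrix = np.hstack([task, intercepts])
    names = task_names + [f"run_{r + 1}_intercept" for r in range(n_runs)]
    empty = [
        name for j, name in enumerate(task_names)
        if not np.any(np.abs(task[:, j]) > 0)
    ]
    return DesignMatrix(
        matrix=matrix, names=names, task_names=task_names,
        run_index=run_index, empty_columns=empty,
    )


@dataclass
class GLMFit:
    betas: dict[str, float]
    se: dict[str, float]
    sigma2: float
    df_resid: int
    dropped: list[str]


def estimate_amplitudes(roi_timecourse: np.ndarray, design: DesignMatrix) -> GLMFit:
    """OLS betas (PSC) for every regressor, with standard errors.

    All-zero (flagged) columns are dropped before fitting; any remaining rank
    deficiency is rejected with the offending columns named.
    """
    y = np.asarray(roi_timecourse, dtype=float)
    keep = [i for i, n in enumerate(design.names) if n not in design.empty_columns]
    X = design.matrix[:, keep]
    names = [design.names[i] for i in keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient (columns: {bad})")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid / df) if df > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    return GLMFit(
        betas=dict(zip(names, beta)),
        se=dict(zip(names, se)),
        sigma2=sigma2,
        df_resid=df,
        dropped=list(design.empty_columns),
    )


def _laterality(cue_side: str, hemisphere: str) -> str:
    """A left-side cue drives the right hemisphere contralaterally."""
    return "contralateral" if (cue_side == "left") == (hemisphere == "right") else "ipsilateral"


def recode_laterality(table: pd.DataFrame) -> pd.DataFrame:
    """Add/refresh the contra/ipsilateral label from cue side and hemisphere.

    Pure relabeling: applying it twice is the identity.
    """
    out = table.copy()
    out["laterality"] = [
        _laterality(s, h) for s, h in zip(out["cue_side"], out["hemisphere"])
    ]
    return out


def condition_amplitude_table(
    participant: str,
    session: SessionDesign,
    preprocessed_runs: list[VoxelTimeSeries],
    selection: VoxelSelection | None,
    *,
    correct_only: bool = True,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    n_discard: int = DEFAULT_N_DISCARD,
    hrf_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Estimate per-condition amplitudes for every ROI x hemisphere of a session.

    Returns the long-format amplitude table (one row per ROI, hemisphere and
    task condition) with cue-side conditions recoded to contra/ipsilateral.
    """
    design = build_design_matrix(
        session, runs=session.runs[: len(preprocessed_runs)],
        correct_only=correct_only, highpass_hz=highpass_hz,
        n_discard=n_discard, hrf_kwargs=hrf_kwargs,
    )
    rows = []
    for roi in ROIS:
        for hemi in HEMISPHERES:
            y = np.concatenate(
                [average_roi_timecourse(run, selection, roi, hemi)
                 for run in preprocessed_runs]
            )
            fit = estimate_amplitudes(y, design)
            for side in ("left", "right"):
                for validity in ("valid", "invalid"):
                    for epoch in ("pre", "post"):
                        name = f"{side}_{validity}_{epoch}"
                        if name not in fit.betas:
                            continue
                        rows.append(
                            {
                                "participant": participant,
                                "roi": roi,
                                "hemisphere": hemi,
                                "cue_side": side,
                                "attention_type": session.attention_type,
                                "cue_epoch": epoch,
                                "validity": validity,
                                "beta_psc": fit.betas[name],
                                "se": fit.se[name],
                            }
                        )
    return recode_laterality(pd.DataFrame(rows))
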