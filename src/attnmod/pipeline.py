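"""End-to-end orchestration: configuration, stage running, file I/O.

The pipeline chains the stages: simulate sessions and behavior -> simulate
BOLD (localizer + attention runs) -> localizer voxel selection -> preprocess
+ event-related GLM -> AMI -> group statistics.  Every stage is driven by a
single :class:`PipelineConfig` whose defaults carry the analysis constants
(0.01 Hz high-pass, 8 discarded volumes, coherence > 0.2, AMI constant 0.2)
and whose seeds make every run bit-reproducible.

Interchange formats are standard: 4-D NIfTI volumes with the TR in the
header for runs, a 3-D integer label NIfTI for the ROI atlas, BIDS-dialect
TSV event files, UTF-8 CSV tables, and JSON for configuration, ground truth
and statistics.  Output tables carry a provenance header (config hash and
seed) as ``#``-prefixed comment lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import attn_stats, behavior, bold_synth, localizer_fit, roi_glm, trial_design
from .behavior import ObserverModel
from .bold_synth import (
    GroundTruthEffects, LocalizerParams, NoiseParams, VoxelTimeSeries,
    make_ground_truth,
)
from .trial_design import ATTENTION_TYPES, ROIS, HEMISPHERES

logger = logging.getLogger(__name__)

#: Default modulation profiles: the study-motivated four-regime pattern.
DEFAULT_PROFILES = {
    "endogenous": {"pre": "increasing", "post": "flat"},
    "exogenous": {"pre": "flat", "post": "null"},
}


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the analysis defaults baked in."""

    # cohort / design
    n_participants: int = 5
    attention_types: tuple = ATTENTION_TYPES
    n_runs: int = 14
    trials_per_run: int = 40
    n_localizer_runs: int = 6
    tr: float = trial_design.DEFAULT_TR

    # observer
    observer_sigma_deg: float = 1.5
    validity_effect: float = 0.6
    lapse_rate: float = 0.01
    exclusion_rate: float = 0.13
    staircase_trials: int = 400
    target_accuracy: float = 0.794

    # ground truth / effect sizes
    profiles: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_PROFILES)))
    base_contra: float = 0.8
    base_ipsi: float = 0.4
    profile_slope: float = 0.05
    profile_flat_level: float = 0.15

    # between-participant heterogeneity (log-normal factors)
    participant_modulation_sd: float = 0.2
    participant_gain_sd: float = 0.1
    participant_sigma_sd: float = 0.15

    # voxels / noise
    n_voxels_per_roi: int = 100
    responsive_frac: float = 0.8
    voxel_gain_sd: float = 0.1
    drift_amplitude: float = 1.0
    ar_coef: float = 0.3
    white_sd: float = 0.5
    localizer_amplitude: float = 1.0

    # analysis thresholds (the study defaults)
    highpass_hz: float = 0.01
    n_discard: int = 8
    coherence_min: float = 0.2
    phase_window: tuple = (0.0, float(np.pi))
    ami_constant: float = 0.2
    correct_only: bool = True

    # stage toggles
    run_behavior: bool = True
    run_imaging: bool = True

    seed: int = 0

    def noise(self) -> NoiseParams:
        return NoiseParams(
            drift_amplitude=self.drift_amplitude,
            ar_coef=self.ar_coef,
            white_sd=self.white_sd,
        )

    def observer(self) -> ObserverModel:
        return ObserverModel(
            sigma_deg=self.observer_sigma_deg,
            validity_effect=self.validity_effect,
            lapse_rate=self.lapse_rate,
            exclusion_rate=self.exclusion_rate,
        )

    def ground_truth(
        self, attention_type: str,
        *, modulation_factor: float = 1.0, gain_factor: float = 1.0,
    ) -> GroundTruthEffects:
        """Ground truth for one session, optionally scaled per participant.

        ``modulation_factor`` scales the attentional effect sizes (slope and
        flat level), ``gain_factor`` the overall responsiveness; a "null"
        profile stays null under any scaling.
        """
        prof = self.profiles[attention_type]
        return make_ground_truth(
            attention_type, prof["pre"], prof["post"],
            base_contra=self.base_contra * gain_factor,
            base_ipsi=self.base_ipsi * gain_factor,
            slope=self.profile_slope * modulation_factor,
            flat_level=self.profile_flat_level * modulation_factor,
        )

    def localizer_params(self) -> LocalizerParams:
        return LocalizerParams(
            tr=self.tr, n_leadin=self.n_discard,
            amplitude=self.localizer_amplitude,
            n_voxels_per_roi=self.n_voxels_per_roi,
            responsive_frac=self.responsive_frac,
            voxel_gain_sd=self.voxel_gain_sd,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["attention_types"] = list(self.attention_types)
        d["phase_window"] = list(self.phase_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "attention_types" in d:
            d["attention_types"] = tuple(d["attention_types"])
        if "phase_window" in d:
            d["phase_window"] = tuple(d["phase_window"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def demo_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale configuration: full design logic at reduced problem size."""
    return PipelineConfig(
        n_runs=2,
        n_localizer_runs=2,
        n_voxels_per_roi=12,
        staircase_trials=200,
        white_sd=0.3,
        seed=seed,
    )


def _derived_seed(base: int, *indices: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(("-".join(map(str, (base, *indices)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# NIfTI / atlas I/O
# ---------------------------------------------------------------------------

ROI_LABELS = {
    (roi, hemi): 1 + i * len(HEMISPHERES) + j
    for i, roi in enumerate(ROIS)
    for j, hemi in enumerate(HEMISPHERES)
}
LABEL_TO_ROI = {v: k for k, v in ROI_LABELS.items()}


def write_run_nifti(ts: VoxelTimeSeries, path: str | Path) -> None:
    """Write a run as 4-D NIfTI (voxels laid out along x), TR in the header."""
    vol = ts.data[:, None, None, :].astype(np.float32)
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, ts.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_atlas_nifti(voxel_meta: pd.DataFrame, path: str | Path) -> None:
    labels = np.array(
        [ROI_LABELS[(r, h)] for r, h in zip(voxel_meta["roi"], voxel_meta["hemisphere"])],
        dtype=np.int16,
    )
    img = nib.Nifti1Image(labels[:, None, None], affine=np.eye(4))
    nib.save(img, str(path))


def read_run_nifti(
    path: str | Path, atlas_path: str | Path, *,
    run_id: str | None = None, n_discard: int = roi_glm.DEFAULT_N_DISCARD,
) -> VoxelTimeSeries:
    """Read a 4-D run plus ROI atlas back into a :class:`VoxelTimeSeries`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float).reshape(img.shape[0], -1, img.shape[-1])
    data = data.reshape(img.shape[0], img.shape[-1])
    tr = float(img.header.get_zooms()[3])
    labels = np.asarray(nib.load(str(atlas_path)).dataobj).reshape(-1).astype(int)
    meta = pd.DataFrame(
        [
            {"roi": LABEL_TO_ROI[l][0], "hemisphere": LABEL_TO_ROI[l][1], "responsive": False}
            if l in LABEL_TO_ROI
            else {"roi": "background", "hemisphere": "none", "responsive": False}
            for l in labels
        ]
    )
    return VoxelTimeSeries(
        data=data, tr=tr, run_id=run_id or Path(path).stem,
        n_discard=n_discard, voxel_meta=meta,
    )


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict) -> None:
    """CSV with ``#``-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in provenance.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Amplitude-table import (e.g. externally deposited condition data)
# ---------------------------------------------------------------------------

REQUIRED_AMPLITUDE_COLUMNS = (
    "participant", "roi", "attention_type", "cue_epoch", "validity",
    "laterality", "beta_psc",
)


def import_amplitude_table(
    path: str | Path, column_mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Load and validate an externally supplied condition-amplitude table.

    ``column_mapping`` renames source columns to the internal schema
    (participant, roi, attention_type, cue_epoch, validity, laterality,
    beta_psc).  Tables carrying ``hemisphere`` and ``cue_side`` instead of
    ``laterality`` are recoded with the cue-side rule (left cue ->
    right hemisphere contralateral).  Missing columns, unknown ROIs and
    incomplete cells are enumerated in the error.
    """
    df = pd.read_csv(path, comment="#")
    if column_mapping:
        df = df.rename(columns=column_mapping)
    if "laterality" not in df.columns and {"hemisphere", "cue_side"} <= set(df.columns):
        df = roi_glm.recode_laterality(df)
    missing_cols = [c for c in REQUIRED_AMPLITUDE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"amplitude table missing columns: {missing_cols}")
    unknown_rois = sorted(set(df["roi"]) - set(ROIS))
    if unknown_rois:
        raise ValueError(f"unknown ROIs in amplitude table: {unknown_rois}")
    missing_rois = sorted(set(ROIS) - set(df["roi"]))
    if missing_rois:
        raise ValueError(f"amplitude table missing ROIs: {missing_rois}")
    # every participant needs every (roi, attention, epoch, validity, laterality) cell
    cells = df.groupby(
        ["participant", "roi", "attention_type", "cue_epoch", "validity", "laterality"]
    ).size()
    systems = sorted(df["attention_type"].unique())
    expected = [
        (p, r, a, e, v, l)
        for p in sorted(df["participant"].unique())
        for r in ROIS
        for a in systems
        for e in ("pre", "post")
        for v in ("valid", "invalid")
        for l in ("contralateral", "ipsilateral")
    ]
    absent = [c for c in expected if c not in cells.index]
    if absent:
        raise ValueError(
            f"amplitude table is missing {len(absent)} cells, e.g. {absent[:5]}"
        )
    return df


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    behavior_summary: pd.DataFrame | None = None
    behavior_anova: pd.DataFrame | None = None
    tradeoff_check: pd.DataFrame | None = None
    selection_reports: pd.DataFrame | None = None
    amplitude_table: pd.DataFrame | None = None
    ami: pd.DataFrame | None = None
    ami_vs_one: attn_stats.OneSampleResult | None = None
    per_roi_tests: pd.DataFrame | None = None
    hierarchy: dict | None = None
    laterality: dict | None = None
    mixed_models: dict | None = None
    sensitivity: pd.DataFrame | None = None

    def provenance(self) -> dict:
        return {"config_hash": self.config.digest(), "seed": self.config.seed}


def simulate_participant(
    config: PipelineConfig, participant_idx: int
) -> dict:
    """Simulate one participant: staircase, sessions, behavior, BOLD runs.

    Participants differ by seeded log-normal factors on their attentional
    modulation strength, overall BOLD responsiveness and psychophysical
    sigma, giving the cohort realistic between-participant variance.
    """
    p_rng = np.random.default_rng(_derived_seed(config.seed, participant_idx, 999))
    modulation_factor = float(np.exp(config.participant_modulation_sd * p_rng.standard_normal()))
    gain_factor = float(np.exp(config.participant_gain_sd * p_rng.standard_normal()))
    sigma_factor = float(np.exp(config.participant_sigma_sd * p_rng.standard_normal()))
    observer = config.observer()
    observer.sigma_deg *= sigma_factor
    out: dict = {"participant": f"P{participant_idx + 1:02d}", "sessions": {}}
    for a_idx, attention in enumerate(config.attention_types):
        stair = behavior.run_staircase(
            observer,
            target_accuracy=config.target_accuracy,
            n_trials=config.staircase_trials,
            seed=_derived_seed(config.seed, participant_idx, a_idx, 0),
        )
        session = trial_design.generate_session(
            attention, config.n_runs, config.trials_per_run,
            seed=_derived_seed(config.seed, participant_idx, a_idx, 1),
            tr=config.tr,
        )
        session = behavior.simulate_responses(
            session, observer, stair.threshold_tilt,
            seed=_derived_seed(config.seed, participant_idx, a_idx, 2),
        )
        entry: dict = {"session": session, "staircase": stair}
        if config.run_imaging:
            gt = config.ground_truth(
                attention, modulation_factor=modulation_factor, gain_factor=gain_factor
            )
            noise = config.noise()
            loc_params = config.localizer_params()
            entry["ground_truth"] = gt
            entry["localizer_runs"] = [
                bold_synth.simulate_localizer_run(
                    loc_params, noise,
                    seed=_derived_seed(config.seed, participant_idx, a_idx, 10 + r),
                    run_id=f"localizer-{r + 1:02d}",
                )
                for r in range(config.n_localizer_runs)
            ]
            entry["attention_runs"] = [
                bold_synth.simulate_attention_run(
                    session.runs[r], session, gt, noise,
                    seed=_derived_seed(config.seed, participant_idx, a_idx, 100 + r),
                    run_id=f"run-{r + 1:02d}",
                    n_voxels_per_roi=config.n_voxels_per_roi,
                    responsive_frac=config.responsive_frac,
                    voxel_gain_sd=config.voxel_gain_sd,
                )
                for r in range(config.n_runs)
            ]
        out["sessions"][attention] = entry
    return out


def analyze_participant(config: PipelineConfig, sim: dict) -> dict:
    """Localizer selection + GLM amplitudes for one simulated participant."""
    participant = sim["participant"]
    out: dict = {"participant": participant, "amplitudes": [], "selection": []}
    for attention, entry in sim["sessions"].items():
        selection = localizer_fit.localizer_selection(
            entry["localizer_runs"],
            config.localizer_params().stimulus_frequency,
            phase_window=tuple(config.phase_window),
            coherence_min=config.coherence_min,
        )
        report = selection.roi_report()
        report.insert(0, "participant", participant)
        report.insert(1, "attention_type", attention)
        out["selection"].append(report)
        session = entry["session"]
        preprocessed = [
            roi_glm.preprocess_run(
                run, highpass_hz=config.highpass_hz, n_discard=config.n_discard
            )
            for run in entry["attention_runs"]
        ]
        table = roi_glm.condition_amplitude_table(
            participant, session, preprocessed, selection,
            correct_only=config.correct_only,
            highpass_hz=config.highpass_hz, n_discard=config.n_discard,
        )
        out["amplitudes"].append(table)
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and collect every result table.

    Stage failures surface with the stage name and the offending input in
    the exception chain.
    """
    result = PipelineResult(config=config)
    sims = []
    for p in range(config.n_participants):
        try:
            sims.append(simulate_participant(config, p))
        except Exception as err:  # pragma: no cover - defensive reporting
            raise RuntimeError(f"stage 'simulate' failed for participant {p + 1}") from err

    if config.run_behavior:
        sessions = {
            sim["participant"]: [e["session"] for e in sim["sessions"].values()]
            for sim in sims
        }
        result.behavior_summary = behavior.summarize_behavior(sessions)
        result.behavior_anova = behavior.behavior_anova(result.behavior_summary)
        result.tradeoff_check = behavior.check_speed_accuracy_tradeoff(
            result.behavior_summary
        )

    if config.run_imaging:
        analyses = []
        for sim in sims:
            try:
                analyses.append(analyze_participant(config, sim))
            except Exception as err:
                raise RuntimeError(
                    f"stage 'glm' failed for participant {sim['participant']}"
                ) from err
        result.selection_reports = pd.concat(
            [r for a in analyses for r in a["selection"]], ignore_index=True
        )
        result.amplitude_table = pd.concat(
            [t for a in analyses for t in a["amplitudes"]], ignore_index=True
        )
        try:
            result.ami = attn_stats.ami_table(
                result.amplitude_table, constant=config.ami_constant
            )
            result.ami_vs_one = attn_stats.ami_vs_one_test(result.ami)
            result.per_roi_tests = attn_stats.per_roi_validity_tests(result.ami)
            result.hierarchy = attn_stats.hierarchy_regressions(result.ami)
            result.laterality = {
                a: attn_stats.laterality_anova(result.amplitude_table, a)
                for a in config.attention_types
            }
            result.mixed_models = {
                epoch: attn_stats.fit_mixed_model(result.ami, epoch)
                for epoch in ("pre", "post")
            }
            result.sensitivity = attn_stats.ami_sensitivity(
                result.amplitude_table,
                constants=[config.ami_constant / 2, config.ami_constant,
                           config.ami_constant * 2],
            )
        except Exception as err:
            raise RuntimeError("stage 'stats' failed") from err
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write every result table with a provenance header; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = result.provenance()
    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame | None) -> None:
        if df is None:
            return
        p = out_dir / f"{name}.csv"
        write_table(df, p, prov)
        paths[name] = p

    _write("behavior_summary", result.behavior_summary)
    _write("behavior_anova", result.behavior_anova)
    _write("speed_accuracy_check", result.tradeoff_check)
    _write("selection_report", result.selection_reports)
    _write("amplitude_table", result.amplitude_table)
    _write("ami", result.ami)
    _write("per_roi_tests", result.per_roi_tests)
    _write("ami_sensitivity", result.sensitivity)
    if result.laterality is not None:
        for attention, table in result.laterality.items():
            _write(f"laterality_anova_{attention}", table)

    stats_payload: dict = {"provenance": prov}
    if result.ami_vs_one is not None:
        r = result.ami_vs_one
        stats_payload["ami_vs_one"] = {
            "t": r.t, "df": r.df, "p": r.p, "cohens_d": r.cohens_d,
            "mean": r.mean, "degenerate": r.degenerate,
        }
    if result.hierarchy is not None:
        stats_payload["hierarchy_regressions"] = {
            f"{a}_{e}": {
                "slope": h.slope, "intercept": h.intercept, "F": h.F,
                "df": list(h.df), "p": h.p, "r2": h.r2,
            }
            for (a, e), h in result.hierarchy.items()
        }
    if result.mixed_models is not None:
        stats_payload["mixed_models"] = {
            epoch: {
                "estimates": m.estimates, "se": m.se, "t": m.tvalues,
                "t_p": m.t_pvalues, "df_t": m.df_t, "lrt_p": m.lrt_p,
                "converged": m.converged, "singular": m.singular,
                "random_structure": m.random_structure,
            }
            for epoch, m in result.mixed_models.items()
        }
    stats_path = out_dir / "statistics.json"
    stats_path.write_text(json.dumps(stats_payload, indent=2, default=float))
    paths["statistics"] = stats_path
    config_path = out_dir / "config.json"
    result.config.to_json(config_path)
    paths["config"] = config_path
    return paths
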