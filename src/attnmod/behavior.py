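"""Simulated 2-AFC observer, staircase titration, and behavioral metrics.

The observer discriminates whether a target grating is tilted clockwise or
counterclockwise of vertical.  Accuracy follows a cumulative-Gaussian
psychometric function of tilt whose sensitivity is scaled down on invalid
trials (attention withdrawn from the probed location), with a small lapse
rate.  Task difficulty is titrated with an n-down-1-up staircase to ~80%
correct on valid trials, mirroring how the task difficulty was equated across
attention conditions in the study this package reproduces.

Sensitivity is summarized per condition as d' = z(H) - z(F) where clockwise
responses to clockwise targets count as hits and clockwise responses to
counterclockwise targets as false alarms; extreme proportions are clipped to
1/(2N) and 1 - 1/(2N).  Median reaction time is the secondary measure; RTs are
drawn from a shifted log-normal per validity level.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.anova import AnovaRM

from .trial_design import SessionDesign, TrialEvent


@dataclass
class ObserverModel:
    """Stochastic 2-AFC observer with validity-dependent sensitivity.

    Parameters
    ----------
    sigma_deg:
        Tilt (degrees) at which valid-trial accuracy reaches ~84%
        (one standard deviation of the cumulative-Gaussian psychometric).
    validity_effect:
        Multiplicative sensitivity factor applied on invalid trials; < 1
        means attention at the probed location improves discriminability.
    lapse_rate:
        Stimulus-independent error probability (splits equally between
        responses), in [0, 0.1].
    rt_params:
        Per-validity shifted log-normal RT parameters
        ``(shift_s, median_s, sigma_log)``.
    exclusion_rate:
        Probability a trial is flagged as a fixation break and excluded.
    """

    sigma_deg: float = 1.5
    validity_effect: float = 0.6
    lapse_rate: float = 0.01
    rt_params: dict = field(
        default_factory=lambda: {
            "valid": (0.25, 0.20, 0.25),
            "invalid": (0.25, 0.28, 0.25),
        }
    )
    exclusion_rate: float = 0.13

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if not (0.0 < self.validity_effect <= 1.0):
            raise ValueError("validity_effect must lie in (0, 1]")
        if self.sigma_deg <= 0:
            raise ValueError("sigma_deg must be positive")

    def accuracy(self, tilt: float, valid: bool = True) -> float:
        """Expected probability correct at a given |tilt|."""
        if tilt < 0:
            raise ValueError("tilt must be non-negative")
        sens = 1.0 if valid else self.validity_effect
        p_true = norm.cdf(tilt * sens / self.sigma_deg)
        return self.lapse_rate / 2.0 + (1.0 - self.lapse_rate) * p_true

    def threshold_tilt(self, target_accuracy: float, valid: bool = True) -> float:
        """Tilt at which expected accuracy equals ``target_accuracy`` (closed form)."""
        ceiling = 1.0 - self.lapse_rate / 2.0
        if not (0.5 < target_accuracy < ceiling):
            raise ValueError(
                f"target accuracy {target_accuracy} unreachable (ceiling {ceiling:.3f})"
            )
        p_true = (target_accuracy - self.lapse_rate / 2.0) / (1.0 - self.lapse_rate)
        sens = 1.0 if valid else self.validity_effect
        return norm.ppf(p_true) * self.sigma_deg / sens


def simulate_responses(
    session: SessionDesign,
    observer: ObserverModel,
    tilt: float,
    seed: int,
) -> SessionDesign:
    """Fill correctness, responses, RTs and exclusion flags for a session.

    Stimulus trials receive orientation responses from the psychometric model;
    cue-only and blank trials receive the third-key response (always correct).
    Returns a deep copy; the input design is untouched.
    """
    if tilt < 0:
        raise ValueError("tilt must be non-negative")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(session)
    for trial in out.all_trials():
        trial.excluded = bool(rng.random() < observer.exclusion_rate)
        if not trial.is_stimulus_trial:
            trial.correct = True
            trial.rt = None
            continue
        valid = trial.validity == "valid"
        trial.stim_orientation = int(rng.choice((-1, 1)))
        p = observer.accuracy(tilt, valid=valid)
        trial.correct = bool(rng.random() < p)
        trial.response = trial.stim_orientation if trial.correct else -trial.stim_orientation
        shift, median, sig = observer.rt_params["valid" if valid else "invalid"]
        trial.rt = float(shift + median * np.exp(sig * rng.standard_normal()))
    return out


@dataclass
class StaircaseResult:
    threshold_tilt: float
    trace: np.ndarray           # tilt presented on each trial
    trace_correct: np.ndarray   # per-trial correctness during titration
    reversal_tilts: np.ndarray
    converged: bool
    n_down: int
    message: str = ""


def run_staircase(
    observer: ObserverModel,
    target_accuracy: float = 0.794,
    n_trials: int = 400,
    seed: int = 0,
    *,
    start_tilt: float = 4.0,
    initial_step: float = 0.20,
    min_step: float = 0.0125,
) -> StaircaseResult:
    """Titrate tilt with an n-down-1-up staircase on valid trials.

    ``n`` is derived from the target accuracy (p_target^n = 1/2); the default
    0.794 gives the classic 3-down-1-up rule converging near 79.4% correct,
    i.e. the ~80% level the task was titrated to.  Steps are multiplicative
    (``initial_step`` in log10 units) and halve after every two reversals
    until ``min_step``.  The returned threshold is the geometric mean of the
    presented tilts after a burn-in of a quarter of the trials — averaging
    the whole stationary trace rather than reversal tilts alone, which
    lowers both the bias and the variance of the estimate; the reversal
    tilts are returned for inspection.

    Non-convergence (accuracy ceiling below target, or too few reversals) is
    reported via ``converged`` and ``message`` rather than silently accepted.
    """
    if not (0.5 < target_accuracy < 1.0):
        raise ValueError("target_accuracy must lie in (0.5, 1)")
    if n_trials < 100:
        raise ValueError("n_trials must be at least 100")
    n_down = max(1, int(round(np.log(0.5) / np.log(target_accuracy))))
    rng = np.random.default_rng(seed)

    ceiling = 1.0 - observer.lapse_rate / 2.0
    ceiling_ok = ceiling > target_accuracy

    log_tilt = np.log10(start_tilt)
    step = initial_step
    streak = 0
    last_direction = 0
    trace = np.empty(n_trials)
    trace_correct = np.empty(n_trials, dtype=bool)
    reversal_tilts: list[float] = []
    for i in range(n_trials):
        tilt = 10.0 ** log_tilt
        trace[i] = tilt
        correct = rng.random() < observer.accuracy(tilt, valid=True)
        trace_correct[i] = correct
        direction = 0
        if correct:
            streak += 1
            if streak >= n_down:
                direction = -1
                streak = 0
        else:
            streak = 0
            direction = +1
        if direction != 0:
            if last_direction != 0 and direction != last_direction:
                reversal_tilts.append(tilt)
                if len(reversal_tilts) % 2 == 0:
                    step = max(step / 2.0, min_step)
            last_direction = direction
            log_tilt += direction * step

    if not ceiling_ok:
        return StaircaseResult(
            threshold_tilt=float(trace[-1]), trace=trace, trace_correct=trace_correct,
            reversal_tilts=np.asarray(reversal_tilts), converged=False, n_down=n_down,
            message=f"accuracy ceiling {ceiling:.3f} below target {target_accuracy:.3f}",
        )
    if len(reversal_tilts) < 8:
        return StaircaseResult(
            threshold_tilt=float(trace[-1]), trace=trace, trace_correct=trace_correct,
            reversal_tilts=np.asarray(reversal_tilts), converged=False, n_down=n_down,
            message=f"only {len(reversal_tilts)} reversals; staircase still moving",
        )
    burn_in = n_trials // 4
    threshold = float(np.exp(np.mean(np.log(trace[burn_in:]))))
    return StaircaseResult(
        threshold_tilt=threshold, trace=trace, trace_correct=trace_correct,
        reversal_tilts=np.asarray(reversal_tilts), converged=True, n_down=n_down,
    )


def d_prime(n_hit: int, n_signal: int, n_fa: int, n_noise: int) -> float:
    """d' = z(H) - z(F) with extreme rates clipped to 1/(2N), 1 - 1/(2N)."""
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("need at least one signal and one noise trial")
    h = min(max(n_hit / n_signal, 1.0 / (2 * n_signal)), 1.0 - 1.0 / (2 * n_signal))
    f = min(max(n_fa / n_noise, 1.0 / (2 * n_noise)), 1.0 - 1.0 / (2 * n_noise))
    return float(norm.ppf(h) - norm.ppf(f))


def _trials_frame(sessions: dict[str, list[SessionDesign]]) -> pd.DataFrame:
    rows = []
    for participant, sess_list in sessions.items():
        for sess in sess_list:
            for t in sess.all_trials():
                rows.append(
                    {
                        "participant": participant,
                        "attention_type": sess.attention_type,
                        "trial_type": t.trial_type,
                        "cue_epoch": t.cue_epoch,
                        "validity": t.validity,
                        "correct": t.correct,
                        "response": t.response,
                        "stim_orientation": t.stim_orientation,
                        "rt": t.rt,
                        "excluded": t.excluded,
                    }
                )
    return pd.DataFrame(rows)


def summarize_behavior(sessions: dict[str, list[SessionDesign]]) -> pd.DataFrame:
    """Per-participant d' and median RT for each attention x epoch x validity cell.

    Excluded trials and cue-only/blank trials are removed first.  Raises with
    the offending cell named if any cell is empty after exclusions.
    """
    df = _trials_frame(sessions)
    df = df[(~df["excluded"]) & df["trial_type"].isin(["pre_cue", "post_cue"])]
    if df["correct"].isna().any():
        raise ValueError("sessions contain unsimulated trials (correct is undefined)")
    rows = []
    for participant in sorted(sessions):
        sub_p = df[df["participant"] == participant]
        for attention in sorted(sub_p["attention_type"].unique()):
            for epoch in ("pre", "post"):
                for validity in ("valid", "invalid"):
                    cell = sub_p[
                        (sub_p["attention_type"] == attention)
                        & (sub_p["cue_epoch"] == epoch)
                        & (sub_p["validity"] == validity)
                    ]
                    if len(cell) == 0:
                        raise ValueError(
                            f"empty cell after exclusions: participant={participant}, "
                            f"attention_type={attention}, cue_epoch={epoch}, validity={validity}"
                        )
                    signal = cell[cell["stim_orientation"] == 1]
                    noise = cell[cell["stim_orientation"] == -1]
                    dp = d_prime(
                        int((signal["response"] == 1).sum()), len(signal),
                        int((noise["response"] == 1).sum()), len(noise),
                    )
                    rows.append(
                        {
                            "participant": participant,
                            "attention_type": attention,
                            "cue_epoch": epoch,
                            "validity": validity,
                            "d_prime": dp,
                            "median_rt_s": float(cell["rt"].median()),
                            "n_trials": len(cell),
                        }
                    )
    return pd.DataFrame(rows)


def behavior_anova(summary: pd.DataFrame, dv: str = "d_prime") -> pd.DataFrame:
    """Three-way repeated-measures ANOVA (attention x validity x epoch).

    Expects the per-participant table from :func:`summarize_behavior`; returns
    a tidy table of F, degrees of freedom and p per effect.
    """
    participants = summary["participant"].unique()
    if len(participants) < 2:
        raise ValueError("repeated-measures ANOVA requires at least 2 participants")
    cells = summary.groupby(
        ["participant", "attention_type", "cue_epoch", "validity"]
    )[dv].mean().reset_index()
    expected = 2 * 2 * 2
    for p in participants:
        got = len(cells[cells["participant"] == p])
        if got != expected:
            have = set(
                map(tuple, cells[cells["participant"] == p]
                    [["attention_type", "cue_epoch", "validity"]].values)
            )
            full = {
                (a, e, v)
                for a in cells["attention_type"].unique()
                for e in ("pre", "post")
                for v in ("valid", "invalid")
            }
            missing = sorted(full - have)
            raise ValueError(f"incomplete design for participant {p}: missing {missing}")
    res = AnovaRM(
        cells, depvar=dv, subject="participant",
        within=["attention_type", "cue_epoch", "validity"],
    ).fit()
    table = res.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df_num", "Den DF": "df_den", "Pr > F": "p"}
    )
    table.index.name = "effect"
    return table.reset_index()


def check_speed_accuracy_tradeoff(summary: pd.DataFrame) -> pd.DataFrame:
    """Sign check that valid trials are both faster and more accurate.

    Mirrors the qualitative no-speed-accuracy-trade-off argument: per
    attention type and epoch, the group-mean valid cell should have higher d'
    and lower median RT than the invalid cell.
    """
    g = summary.groupby(["attention_type", "cue_epoch", "validity"])[
        ["d_prime", "median_rt_s"]
    ].mean()
    rows = []
    for (attention, epoch) in {(a, e) for a, e, _ in g.index}:
        valid = g.loc[(attention, epoch, "valid")]
        invalid = g.loc[(attention, epoch, "invalid")]
        rows.append(
            {
                "attention_type": attention,
                "cue_epoch": epoch,
                "valid_more_accurate": bool(valid["d_prime"] > invalid["d_prime"]),
                "valid_faster": bool(valid["median_rt_s"] < invalid["median_rt_s"]),
            }
        )
    return pd.DataFrame(rows).sort_values(["attention_type", "cue_epoch"]).reset_index(drop=True)
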