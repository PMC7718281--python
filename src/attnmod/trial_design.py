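"""Randomized trial sequences and event timelines for covert-attention sessions.

A session belongs to one attention system — *endogenous* (voluntary, cued by an
informative central cue) or *exogenous* (involuntary, cued by an uninformative
peripheral cue) — and mixes four trial types: pre-cue trials (cue before the
grating stimuli), post-cue trials (cue after the stimuli), cue-only trials and
blank trials.  The latter two exist so that the event-related GLM can model the
visual response evoked by the cue itself and by the response cue.

Timing (seconds) follows the study design this package reproduces: the cue is
shown for 67 ms, the gratings for 50 ms, and the cue–stimulus ISI is 50 ms for
exogenous and 250 ms for endogenous sessions, giving cue→stimulus SOAs of
117 ms and 317 ms.  A response cue (800 ms) ends every trial; total trial
duration is 1.7 s (exogenous) or 1.9 s (endogenous).  Post-cue trials present
the same events in reversed order with identical durations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

ATTENTION_TYPES = ("endogenous", "exogenous")
TRIAL_TYPES = ("pre_cue", "post_cue", "cue_only", "blank")

#: Trial-type mixture, fixed by the session design.
TRIAL_TYPE_PROPORTIONS = {"pre_cue": 0.40, "post_cue": 0.40, "cue_only": 0.10, "blank": 0.10}

#: Cue validity: the informative endogenous cue is 75% valid, the
#: uninformative exogenous cue 50%.
VALIDITY_RATE = {"endogenous": 0.75, "exogenous": 0.50}

# Event durations (s)
CUE_DURATION = 0.067
STIM_DURATION = 0.050
RESPONSE_CUE_DURATION = 0.800
ISI = {"endogenous": 0.250, "exogenous": 0.050}
TRIAL_DURATION = {"endogenous": 1.900, "exogenous": 1.700}

DEFAULT_TR = 1.75
#: Lead-in fixation before the first trial; its 8 volumes are the ones later
#: discarded while longitudinal magnetization reaches steady state.
DEFAULT_LEADIN = 14.0
#: Tail fixation so the hemodynamic response of late trials is sampled.
DEFAULT_TAIL = 21.0

#: Retinotopic regions of interest, ordered by their rank in the visual hierarchy.
ROIS = ("V1", "V2", "V3", "V3A", "hV4", "LO1")
HIERARCHY_RANK = {roi: i + 1 for i, roi in enumerate(ROIS)}
HEMISPHERES = ("left", "right")


@dataclass
class TrialEvent:
    """One trial of a session: type, cueing, timing and (after simulation) behavior."""

    trial_index: int
    trial_type: str
    attention_type: str
    cue_side: str               # left / right / none
    response_cue_side: str      # left / right / none
    validity: str               # valid / invalid / n/a
    onsets: dict[str, float] = field(default_factory=dict)
    correct: bool | None = None
    response: int | None = None          # +1 reported clockwise, -1 counterclockwise
    stim_orientation: int | None = None  # +1 target clockwise, -1 counterclockwise
    rt: float | None = None
    excluded: bool = False               # fixation break / blink proxy

    @property
    def is_stimulus_trial(self) -> bool:
        return self.trial_type in ("pre_cue", "post_cue")

    @property
    def cue_epoch(self) -> str | None:
        """'pre' or 'post' for stimulus trials, else ``None``."""
        if self.trial_type == "pre_cue":
            return "pre"
        if self.trial_type == "post_cue":
            return "post"
        return None

    @property
    def onset(self) -> float:
        """Trial onset: time of the first event, seconds from run start."""
        return min(self.onsets.values())

    def condition_label(self) -> str:
        """Regressor name this trial loads on in the event-related GLM.

        Excluded (fixation-break) trials always load on ``eye_movement``.
        """
        if self.excluded:
            return "eye_movement"
        if self.trial_type == "blank":
            return "blank"
        if self.trial_type == "cue_only":
            return f"cue_only_{self.cue_side}"
        return f"{self.cue_side}_{self.validity}_{self.cue_epoch}"


def trial_timeline(trial_type: str, attention_type: str) -> dict[str, float]:
    """Event onsets (s, relative to trial start) for one trial.

    Pre-cue order is cue → stimulus; post-cue trials swap the two intervals
    keeping every duration identical, so the response-cue window is unchanged.
    """
    if attention_type not in ATTENTION_TYPES:
        raise ValueError(f"unknown attention_type {attention_type!r}")
    if trial_type not in TRIAL_TYPES:
        raise ValueError(f"unknown trial_type {trial_type!r}")
    isi = ISI[attention_type]
    total = TRIAL_DURATION[attention_type]
    resp_on = total - RESPONSE_CUE_DURATION
    onsets: dict[str, float] = {}
    if trial_type == "pre_cue":
        onsets["cue_on"] = 0.0
        onsets["cue_off"] = CUE_DURATION
        onsets["stim_on"] = CUE_DURATION + isi
        onsets["stim_off"] = CUE_DURATION + isi + STIM_DURATION
    elif trial_type == "post_cue":
        onsets["stim_on"] = 0.0
        onsets["stim_off"] = STIM_DURATION
        onsets["cue_on"] = STIM_DURATION + isi
        onsets["cue_off"] = STIM_DURATION + isi + CUE_DURATION
    elif trial_type == "cue_only":
        onsets["cue_on"] = 0.0
        onsets["cue_off"] = CUE_DURATION
    onsets["response_cue_on"] = resp_on
    onsets["response_cue_off"] = total
    return onsets


@dataclass
class SessionDesign:
    """A full session: ``n_runs`` runs of counterbalanced, shuffled trials."""

    attention_type: str
    n_runs: int
    trials_per_run: int
    validity_rate: float
    seed: int
    tr: float = DEFAULT_TR
    leadin: float = DEFAULT_LEADIN
    tail: float = DEFAULT_TAIL
    iti: float = 0.0
    runs: list[list[TrialEvent]] = field(default_factory=list)

    @property
    def trial_period(self) -> float:
        return TRIAL_DURATION[self.attention_type] + self.iti

    @property
    def run_duration(self) -> float:
        return self.leadin + self.trials_per_run * self.trial_period + self.tail

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_duration / self.tr))

    def all_trials(self) -> list[TrialEvent]:
        return [t for run in self.runs for t in run]

    def events_dataframe(self, run: int) -> pd.DataFrame:
        rows = []
        for t in self.runs[run]:
            rows.append(
                {
                    "onset": round(t.onset, 4),
                    "duration": TRIAL_DURATION[self.attention_type],
                    "trial_type": t.trial_type,
                    "cue_side": t.cue_side,
                    "response_cue_side": t.response_cue_side,
                    "validity": t.validity,
                    "correct": "n/a" if t.correct is None else int(t.correct),
                    "excluded": int(t.excluded),
                }
            )
        return pd.DataFrame(rows)

    def write_events(self, out_dir: str | Path) -> list[Path]:
        """Write one BIDS-events-dialect TSV per run plus a design sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for r in range(self.n_runs):
            p = out_dir / f"{self.attention_type}_run-{r + 1:02d}_events.tsv"
            self.events_dataframe(r).to_csv(p, sep="\t", index=False)
            paths.append(p)
        sidecar = {
            "attention_type": self.attention_type,
            "n_runs": self.n_runs,
            "trials_per_run": self.trials_per_run,
            "validity_rate": self.validity_rate,
            "seed": self.seed,
            "tr": self.tr,
            "leadin": self.leadin,
            "tail": self.tail,
            "iti": self.iti,
            "trial_duration": TRIAL_DURATION[self.attention_type],
            "run_duration": self.run_duration,
            "n_volumes": self.n_volumes,
        }
        with open(out_dir / f"{self.attention_type}_design.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        return paths


def _default_iti(attention_type: str, tr: float, min_iti: float = 1.0) -> float:
    """Fixed ITI making the trial period an integer multiple of TR.

    With TR = 1.75 s this yields a 3.5 s period for both attention types
    (ITI 1.6 s endogenous, 1.8 s exogenous), so event onsets stay locked to
    the volume grid and the GLM onsets are exactly known.
    """
    dur = TRIAL_DURATION[attention_type]
    n = int(np.ceil((dur + min_iti) / tr))
    return n * tr - dur


def _balanced_block(attention_type: str, n: int, rng: np.random.Generator) -> list[dict]:
    """Exact-count trial specs for a block of ``n`` trials (n divisible by 20)."""
    validity_rate = VALIDITY_RATE[attention_type]
    specs: list[dict] = []
    for ttype in ("pre_cue", "post_cue"):
        n_type = int(round(TRIAL_TYPE_PROPORTIONS[ttype] * n))
        n_valid = int(round(validity_rate * n_type))
        for validity, count in (("valid", n_valid), ("invalid", n_type - n_valid)):
            # response cue left on exactly half of each (type, validity) group
            half = count // 2
            for i in range(count):
                resp = "left" if i < half else "right"
                if validity == "valid":
                    cue = resp
                else:
                    cue = "right" if resp == "left" else "left"
                specs.append(
                    {"trial_type": ttype, "validity": validity,
                     "cue_side": cue, "response_cue_side": resp}
                )
    n_cue_only = int(round(TRIAL_TYPE_PROPORTIONS["cue_only"] * n))
    for i in range(n_cue_only):
        specs.append(
            {"trial_type": "cue_only", "validity": "n/a",
             "cue_side": "left" if i < n_cue_only // 2 else "right",
             "response_cue_side": "none"}
        )
    n_blank = n - len(specs)
    for _ in range(n_blank):
        specs.append(
            {"trial_type": "blank", "validity": "n/a",
             "cue_side": "none", "response_cue_side": "none"}
        )
    rng.shuffle(specs)
    return specs


def generate_session(
    attention_type: str,
    n_runs: int = 14,
    trials_per_run: int = 40,
    seed: int = 0,
    *,
    balance: str = "session",
    iti: float | None = None,
    tr: float = DEFAULT_TR,
    leadin: float = DEFAULT_LEADIN,
    tail: float = DEFAULT_TAIL,
) -> SessionDesign:
    """Generate a counterbalanced, seeded session of attention-task runs.

    Trial-type counts (40% pre-cue, 40% post-cue, 10% cue-only, 10% blank) and
    validity counts are exact at the ``balance`` level ("session" or "run");
    the order is a seeded permutation.

    Parameters
    ----------
    trials_per_run:
        Must be divisible by 20 so the stated proportions are realizable
        exactly.
    iti:
        Inter-trial fixation interval.  Default locks the trial period to an
        integer number of TRs (see :func:`_default_iti`).
    """
    if attention_type not in ATTENTION_TYPES:
        raise ValueError(f"unknown attention_type {attention_type!r}")
    if trials_per_run % 20 != 0 or trials_per_run <= 0:
        raise ValueError("trials_per_run must be a positive multiple of 20")
    if balance not in ("session", "run"):
        raise ValueError("balance must be 'session' or 'run'")
    rng = np.random.default_rng(seed)
    if iti is None:
        iti = _default_iti(attention_type, tr)

    if balance == "session":
        specs = _balanced_block(attention_type, n_runs * trials_per_run, rng)
    else:
        specs = []
        for _ in range(n_runs):
            specs.extend(_balanced_block(attention_type, trials_per_run, rng))

    design = SessionDesign(
        attention_type=attention_type,
        n_runs=n_runs,
        trials_per_run=trials_per_run,
        validity_rate=VALIDITY_RATE[attention_type],
        seed=seed,
        tr=tr,
        leadin=leadin,
        tail=tail,
        iti=iti,
    )
    period = design.trial_period
    idx = 0
    for _ in range(n_runs):
        run_trials: list[TrialEvent] = []
        for k in range(trials_per_run):
            spec = specs[idx]
            rel = trial_timeline(spec["trial_type"], attention_type)
            t0 = leadin + k * period
            run_trials.append(
                TrialEvent(
                    trial_index=idx,
                    trial_type=spec["trial_type"],
                    attention_type=attention_type,
                    cue_side=spec["cue_side"],
                    response_cue_side=spec["response_cue_side"],
                    validity=spec["validity"],
                    onsets={name: t0 + t for name, t in rel.items()},
                )
            )
            idx += 1
        design.runs.append(run_trials)
    return design


def read_events(path: str | Path, attention_type: str, *,
                tr: float = DEFAULT_TR) -> list[TrialEvent]:
    """Read one run's event TSV back into :class:`TrialEvent` objects."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)  # 'n/a' is a category
    trials = []
    for i, row in df.iterrows():
        rel = trial_timeline(row["trial_type"], attention_type)
        rel0 = min(rel.values())  # file 'onset' is the first event of the trial
        correct = None if str(row["correct"]) in ("n/a", "nan") else bool(int(row["correct"]))
        trials.append(
            TrialEvent(
                trial_index=int(i),
                trial_type=row["trial_type"],
                attention_type=attention_type,
                cue_side=row["cue_side"],
                response_cue_side=row["response_cue_side"],
                validity=row["validity"],
                onsets={name: float(row["onset"]) + t - rel0 for name, t in rel.items()},
                correct=correct,
                excluded=bool(int(row["excluded"])),
            )
        )
    return trials
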