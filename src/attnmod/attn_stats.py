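"""Attentional Modulation Index (AMI) and group-level inference.

The AMI for one participant, ROI, attention system and cue epoch is

    AMI = (Vc + c) / mean(Vc + c, Ic + c, Vi + c, Ii + c)

where Vc/Ic are the contralateral valid/invalid response amplitudes, Vi/Ii
the ipsilateral ("distractor") ones, and c a fixed constant (default 0.2)
added to every condition so all values are positive.  AMI = 1 means no
attentional modulation; the index is recomputed for several constants to show
the qualitative pattern does not depend on the choice.

Group inference covers: the laterality ANOVA (contralateral > ipsilateral),
the one-sample test of AMI against 1, per-ROI one-tailed valid > invalid
t-tests, the hierarchy regression of the group-mean valid-invalid difference
on ROI rank (V1=1 ... LO1=6), and linear mixed models of the difference on
rank x attention system with by-participant random intercepts and slopes,
with likelihood-ratio p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import mixedlm
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .trial_design import ROIS, HIERARCHY_RANK

logger = logging.getLogger(__name__)

DEFAULT_AMI_CONSTANT = 0.2
NUMERATOR_CONDITIONS = ("Vc", "Ic", "Vi", "Ii")


# ---------------------------------------------------------------------------
# AMI
# ---------------------------------------------------------------------------

def compute_ami(
    vc, ic, vi, ii,
    constant: float = DEFAULT_AMI_CONSTANT,
    numerator: str = "Vc",
):
    """AMI with a common additive constant; vectorized over array inputs.

    ``numerator`` picks which offset amplitude forms the numerator (default
    the valid-contralateral response).  The offset denominator mean must be
    positive — if it is not, raise with the advice to use a larger constant,
    which is the reason the offset exists.
    """
    if numerator not in NUMERATOR_CONDITIONS:
        raise ValueError(f"numerator must be one of {NUMERATOR_CONDITIONS}")
    if constant < 0:
        raise ValueError("constant must be non-negative")
    offset = {
        "Vc": np.asarray(vc, dtype=float) + constant,
        "Ic": np.asarray(ic, dtype=float) + constant,
        "Vi": np.asarray(vi, dtype=float) + constant,
        "Ii": np.asarray(ii, dtype=float) + constant,
    }
    denom = np.mean([offset[k] for k in NUMERATOR_CONDITIONS], axis=0)
    if np.any(denom <= 0):
        raise ValueError(
            "offset denominator mean is non-positive; raise the constant so "
            "all offset condition values are positive"
        )
    out = offset[numerator] / denom
    return float(out) if np.ndim(out) == 0 else out


def ami_table(
    amplitudes: pd.DataFrame,
    constant: float = DEFAULT_AMI_CONSTANT,
    *,
    ipsi_epoch_specific: bool = False,
) -> pd.DataFrame:
    """AMI per participant x ROI x attention system x cue epoch.

    ``amplitudes`` is the long condition-amplitude table (columns participant,
    roi, laterality, attention_type, cue_epoch, validity, beta_psc; extra
    columns such as hemisphere are averaged over).  Vc/Ic are epoch-specific
    contralateral amplitudes.  By default the ipsilateral terms average the
    pre- and post-cue epochs, matching their role as the distractor-stimulus
    reference; ``ipsi_epoch_specific`` switches to fully epoch-specific
    ipsilateral terms.

    Returns one row per cell with Vc, Ic, Vi, Ii, the AMI with valid and with
    invalid numerator, and their difference ``ami_diff``.
    """
    cell = (
        amplitudes.groupby(
            ["participant", "roi", "attention_type", "cue_epoch", "laterality", "validity"]
        )["beta_psc"].mean()
    )
    ipsi_avg = (
        amplitudes[amplitudes["laterality"] == "ipsilateral"]
        .groupby(["participant", "roi", "attention_type", "validity"])["beta_psc"]
        .mean()
    )
    rows = []
    for (participant, roi, attention), _ in amplitudes.groupby(
        ["participant", "roi", "attention_type"], sort=True
    ):
        for epoch in ("pre", "post"):
            vc = cell[(participant, roi, attention, epoch, "contralateral", "valid")]
            ic = cell[(participant, roi, attention, epoch, "contralateral", "invalid")]
            if ipsi_epoch_specific:
                vi = cell[(participant, roi, attention, epoch, "ipsilateral", "valid")]
                ii = cell[(participant, roi, attention, epoch, "ipsilateral", "invalid")]
            else:
                vi = ipsi_avg[(participant, roi, attention, "valid")]
                ii = ipsi_avg[(participant, roi, attention, "invalid")]
            ami_valid = compute_ami(vc, ic, vi, ii, constant, numerator="Vc")
            ami_invalid = compute_ami(vc, ic, vi, ii, constant, numerator="Ic")
            rows.append(
                {
                    "participant": participant,
                    "roi": roi,
                    "hierarchy_rank": HIERARCHY_RANK[roi],
                    "attention_type": attention,
                    "cue_epoch": epoch,
                    "Vc": vc, "Ic": ic, "Vi": vi, "Ii": ii,
                    "ami_valid": ami_valid,
                    "ami_invalid": ami_invalid,
                    "ami_diff": ami_valid - ami_invalid,
                    "constant_used": constant,
                }
            )
    return pd.DataFrame(rows)


def ami_sensitivity(
    amplitudes: pd.DataFrame,
    constants: list[float] = (0.1, 0.2, 0.4),
    **ami_kwargs,
) -> pd.DataFrame:
    """Recompute the AMI and hierarchy regressions for several constants.

    Returns one row per constant and condition with the regression slope
    sign and significance, plus whether the set of significant conditions is
    identical across all constants (``pattern_invariant``).
    """
    records = []
    patterns = []
    for c in constants:
        table = ami_table(amplitudes, constant=c, **ami_kwargs)
        regs = hierarchy_regressions(table)
        sig = frozenset(k for k, r in regs.items() if r.p < 0.05)
        patterns.append(sig)
        for (attention, epoch), r in regs.items():
            records.append(
                {
                    "constant": c,
                    "attention_type": attention,
                    "cue_epoch": epoch,
                    "slope": r.slope,
                    "slope_sign": int(np.sign(r.slope)),
                    "p": r.p,
                    "significant": r.p < 0.05,
                }
            )
    out = pd.DataFrame(records)
    out["pattern_invariant"] = len(set(patterns)) == 1
    return out


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def laterality_anova(amplitudes: pd.DataFrame, attention_type: str) -> pd.DataFrame:
    """Repeated-measures ANOVA: laterality x validity x ROI, one attention system.

    Reports all effects; the ones of scientific interest are the laterality
    main effect (contralateral > ipsilateral) and the laterality x validity
    interaction.
    """
    sub = amplitudes[amplitudes["attention_type"] == attention_type]
    if len(sub) == 0:
        raise ValueError(f"no rows for attention_type {attention_type!r}")
    cells = (
        sub.groupby(["participant", "laterality", "validity", "roi"])["beta_psc"]
        .mean().reset_index()
    )
    counts = cells.groupby("participant").size()
    expected = 2 * 2 * len(ROIS)
    bad = counts[counts != expected]
    if len(bad):
        raise ValueError(
            f"incomplete laterality design for participants {list(bad.index)}: "
            f"expected {expected} cells, got {bad.to_dict()}"
        )
    res = AnovaRM(
        cells, depvar="beta_psc", subject="participant",
        within=["laterality", "validity", "roi"],
    ).fit()
    table = res.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df_num", "Den DF": "df_den", "Pr > F": "p"}
    )
    table.index.name = "effect"
    return table.reset_index()


@dataclass
class OneSampleResult:
    t: float
    df: int
    p: float
    cohens_d: float
    mean: float
    participant_means: pd.Series
    degenerate: bool = False


def ami_vs_one_test(ami: pd.DataFrame, value: str = "ami_valid") -> OneSampleResult:
    """One-sample t-test of participant-mean AMI against 1 (two-sided).

    Each participant contributes one mean over all conditions and ROIs;
    Cohen's d is (mean - 1) / SD of the participant means.  A zero-variance
    set of means is reported as degenerate rather than producing infinities.
    """
    means = ami.groupby("participant")[value].mean()
    n = len(means)
    if n < 2:
        raise ValueError("need at least 2 participants")
    sd = means.std(ddof=1)
    if sd == 0:
        return OneSampleResult(
            t=np.nan, df=n - 1, p=np.nan, cohens_d=np.nan,
            mean=float(means.mean()), participant_means=means, degenerate=True,
        )
    t, p = stats.ttest_1samp(means, popmean=1.0)
    d = (means.mean() - 1.0) / sd
    return OneSampleResult(
        t=float(t), df=n - 1, p=float(p), cohens_d=float(d),
        mean=float(means.mean()), participant_means=means,
    )


def per_roi_validity_tests(
    ami: pd.DataFrame, *, correction: str | None = None
) -> pd.DataFrame:
    """Paired one-tailed t-tests (valid > invalid AMI) per ROI and condition.

    No multiple-comparison correction by default; ``correction="holm"``
    adjusts p-values within each attention system x epoch family.
    """
    rows = []
    for (attention, epoch, roi), sub in ami.groupby(
        ["attention_type", "cue_epoch", "roi"], sort=True
    ):
        sub = sub.sort_values("participant")
        if sub["participant"].duplicated().any():
            raise ValueError(
                f"unpaired data: duplicate participants in cell "
                f"({attention}, {epoch}, {roi})"
            )
        diff = sub["ami_valid"].to_numpy() - sub["ami_invalid"].to_numpy()
        if np.std(diff, ddof=1) == 0:
            # degenerate paired differences: t pinned by the sign of the mean
            t = 0.0 if diff.mean() == 0 else np.sign(diff.mean()) * np.inf
            p = {0.0: 0.5, np.inf: 0.0, -np.inf: 1.0}[t]
        else:
            t, p = stats.ttest_rel(
                sub["ami_valid"], sub["ami_invalid"], alternative="greater"
            )
        rows.append(
            {
                "attention_type": attention,
                "cue_epoch": epoch,
                "roi": roi,
                "hierarchy_rank": HIERARCHY_RANK[roi],
                "n": len(sub),
                "t": float(t),
                "df": len(sub) - 1,
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["attention_type", "cue_epoch", "hierarchy_rank"]
    ).reset_index(drop=True)
    if correction == "holm":
        out["p_corrected"] = np.nan
        for _, idx in out.groupby(["attention_type", "cue_epoch"]).groups.items():
            out.loc[idx, "p_corrected"] = multipletests(
                out.loc[idx, "p"], method="holm"
            )[1]
    elif correction is not None:
        raise ValueError("correction must be None or 'holm'")
    return out


# ---------------------------------------------------------------------------
# Hierarchy regression
# ---------------------------------------------------------------------------

@dataclass
class HierarchyRegressionResult:
    """Simple regression of the group-mean valid-invalid difference on ROI rank."""

    condition: tuple[str, str]      # (attention_type, cue_epoch)
    slope: float
    intercept: float
    F: float
    df: tuple[int, int]
    p: float
    r2: float


def hierarchy_regression(
    ami: pd.DataFrame,
    attention_type: str,
    cue_epoch: str,
    value: str = "ami_diff",
) -> HierarchyRegressionResult:
    """OLS line of the group-mean difference on hierarchy rank (one per ROI).

    With 6 ROIs the slope F-test has (1, 4) degrees of freedom.
    """
    sub = ami[(ami["attention_type"] == attention_type) & (ami["cue_epoch"] == cue_epoch)]
    points = sub.groupby("hierarchy_rank")[value].mean()
    n = len(points)
    if n < 3:
        raise ValueError(f"hierarchy regression needs >= 3 ROIs, got {n}")
    x = points.index.to_numpy(dtype=float)
    y = points.to_numpy(dtype=float)
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - fitted) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df = (1, n - 2)
    if ss_res == 0:
        F = np.inf if ss_tot > 0 else 0.0
        p = 0.0 if ss_tot > 0 else 1.0
    else:
        F = (ss_tot - ss_res) / (ss_res / df[1])
        p = float(stats.f.sf(F, *df))
    return HierarchyRegressionResult(
        condition=(attention_type, cue_epoch), slope=slope, intercept=intercept,
        F=float(F), df=df, p=p, r2=float(r2),
    )


def hierarchy_regressions(
    ami: pd.DataFrame, value: str = "ami_diff"
) -> dict[tuple[str, str], HierarchyRegressionResult]:
    """One hierarchy regression per attention system x cue epoch present."""
    out = {}
    for attention in sorted(ami["attention_type"].unique()):
        for epoch in ("pre", "post"):
            if ((ami["attention_type"] == attention) & (ami["cue_epoch"] == epoch)).any():
                out[(attention, epoch)] = hierarchy_regression(ami, attention, epoch, value)
    return out


def validity_difference_anova(ami: pd.DataFrame) -> pd.DataFrame:
    """Three-way RM ANOVA of the valid-invalid difference: attention x epoch x ROI."""
    cells = (
        ami.groupby(["participant", "attention_type", "cue_epoch", "roi"])["ami_diff"]
        .mean().reset_index()
    )
    res = AnovaRM(
        cells, depvar="ami_diff", subject="participant",
        within=["attention_type", "cue_epoch", "roi"],
    ).fit()
    table = res.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df_num", "Den DF": "df_den", "Pr > F": "p"}
    )
    table.index.name = "effect"
    return table.reset_index()


# ---------------------------------------------------------------------------
# Linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """ML mixed-model fit of the valid-invalid difference for one cue epoch.

    Fixed effects: intercept, ROI rank, attention contrast (+1/2 endogenous,
    -1/2 exogenous) and their interaction.  t statistics use the
    observations-minus-fixed-effects df convention (56 for 5 participants x
    6 ROIs x 2 systems).  ``lrt_p`` holds likelihood-ratio p-values from
    nested-model comparisons.
    """

    cue_epoch: str
    estimates: dict[str, float]
    se: dict[str, float]
    tvalues: dict[str, float]
    t_pvalues: dict[str, float]
    df_t: int
    lrt_p: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    random_structure: str = "intercept+slopes"
    loglik: float = np.nan
    singular: bool = False


_FIXED_TERMS = {
    "intercept": "Intercept",
    "rank": "rank",
    "attention": "attn",
    "rank_x_attention": "rank:attn",
}


def _fit_ml(formula: str, df: pd.DataFrame, random_structure: str):
    if random_structure == "fixed_only":
        # degenerate limit (zero random variance): plain ML regression
        from statsmodels.formula.api import ols

        return ols(formula, df).fit()
    kwargs = {"groups": "participant", "re_formula": "1"}
    if random_structure == "intercept+slopes":
        kwargs["vc_formula"] = {"rank": "0 + rank", "attn": "0 + attn"}
    model = mixedlm(formula, df, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        return model.fit(reml=False, method="lbfgs", maxiter=500)


def fit_mixed_model(
    ami: pd.DataFrame,
    cue_epoch: str,
    value: str = "ami_diff",
    *,
    random_structure: str = "intercept+slopes",
) -> MixedModelResult:
    """Mixed model of the valid-invalid difference on rank x attention system.

    Maximum-likelihood fit with by-participant random intercepts and
    independent random slopes for rank and attention (no random interaction).
    P-values for each fixed term come from likelihood-ratio tests against the
    model without that term.  If the full random structure fails to converge
    the model falls back to random intercepts only, and the fallback is
    logged and recorded on the result; a singular (zero-variance) random
    structure is reported via ``singular``.
    """
    sub = ami[ami["cue_epoch"] == cue_epoch].copy()
    systems = sorted(sub["attention_type"].unique())
    if len(systems) != 2:
        raise ValueError(f"need both attention systems, got {systems}")
    per_participant = sub.groupby("participant").size()
    if (per_participant != 2 * len(ROIS)).any():
        raise ValueError(
            f"each participant needs {2 * len(ROIS)} observations "
            f"(2 systems x {len(ROIS)} ROIs): {per_participant.to_dict()}"
        )
    df = pd.DataFrame(
        {
            "participant": sub["participant"],
            "y": sub[value].astype(float),
            "rank": sub["hierarchy_rank"].astype(float),
            # +1/2 endogenous, -1/2 exogenous: the intercept is the grand mean
            "attn": np.where(sub["attention_type"] == "endogenous", 0.5, -0.5),
        }
    )

    full_formula = "y ~ rank * attn"
    fallbacks = {"intercept+slopes": ["intercept+slopes", "intercept", "fixed_only"],
                 "intercept": ["intercept", "fixed_only"],
                 "fixed_only": ["fixed_only"]}[random_structure]
    full = None
    for structure in fallbacks:
        try:
            candidate = _fit_ml(full_formula, df, structure)
        except Exception:
            candidate = None
        if candidate is not None and bool(getattr(candidate, "converged", True)):
            full = candidate
            break
        logger.warning(
            "mixed model (%s) failed to converge for %s-cue; simplifying the "
            "random structure", structure, cue_epoch,
        )
    if full is None:  # pragma: no cover - fixed_only cannot fail on valid input
        raise RuntimeError(f"no mixed-model structure converged for {cue_epoch}-cue")

    # LRT per fixed term against the nested model without it
    reduced_formulas = {
        "rank_x_attention": "y ~ rank + attn",
        "rank": "y ~ attn + rank:attn",
        "attention": "y ~ rank + rank:attn",
        "intercept": "y ~ 0 + rank * attn",
    }
    lrt_p = {}
    for term, formula in reduced_formulas.items():
        try:
            reduced = _fit_ml(formula, df, structure)
            lr = 2.0 * (full.llf - reduced.llf)
            lrt_p[term] = float(stats.chi2.sf(max(lr, 0.0), df=1))
        except Exception:  # pragma: no cover - degenerate reduced fit
            lrt_p[term] = np.nan

    n_fixed = 4
    df_t = len(df) - n_fixed
    estimates, se, tvals, t_p = {}, {}, {}, {}
    for term, key in _FIXED_TERMS.items():
        est = float(full.params[key])
        s = float(full.bse[key])
        estimates[term] = est
        se[term] = s
        tvals[term] = est / s if s > 0 else np.nan
        t_p[term] = (
            float(2.0 * stats.t.sf(abs(tvals[term]), df_t)) if s > 0 else np.nan
        )

    cov_re = getattr(full, "cov_re", None)
    re_var = float(np.diag(cov_re).sum()) if cov_re is not None and np.size(cov_re) else 0.0
    vcomp = getattr(full, "vcomp", None)
    vc_var = float(np.sum(vcomp)) if vcomp is not None else 0.0
    singular = bool(re_var + vc_var < 1e-10) or structure == "fixed_only"
    if singular:
        logger.warning(
            "mixed model for %s-cue has a singular random structure "
            "(all random variances ~ 0)", cue_epoch,
        )
    return MixedModelResult(
        cue_epoch=cue_epoch,
        estimates=estimates, se=se, tvalues=tvals, t_pvalues=t_p, df_t=df_t,
        lrt_p=lrt_p, converged=bool(getattr(full, "converged", True)),
        random_structure=structure,
        loglik=float(full.llf), singular=singular,
    )
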