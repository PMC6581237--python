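"""Group-level analyses: population rhythmicity, phase summaries, overall
level changes, and the circadian- vs behaviour-influenced classification.

All fits here are mixed-effects cosinor models (random mesor per subject,
ML). Rhythm detection runs per condition on relative clock time; the
classification stage refits each commonly rhythmic metabolite on pooled
both-condition data twice — once against circadian time (hours after the
melatonin phase) and once against behavioural time (hours after lights-off) —
and labels the metabolite by whichever significant model has the lower BIC.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import circstats
from .cosinor import CosinorFit, bh_adjust, fit_cosinor_mixed, lrt_condition_effect
from .io_preprocess import ConcentrationMatrix

_FIT_COLUMNS = ["mesor", "beta_cos", "beta_sin", "amplitude", "phase_h",
                "loglik", "bic", "n_obs", "p_rhythm", "residual_sd",
                "random_mesor_sd", "converged"]


class MissingTimeAxisError(ValueError):
    """The requested time axis is absent or unavailable for some samples."""


def _fit_to_row(fit: CosinorFit) -> dict:
    return {c: getattr(fit, c) for c in _FIT_COLUMNS}


def _mixed_fits(values: pd.DataFrame, times: np.ndarray, subjects: np.ndarray) -> pd.DataFrame:
    rows = []
    for met in values.index:
        y = values.loc[met].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_cosinor_mixed(times, y, subjects)
        row = _fit_to_row(fit)
        row["metabolite_id"] = met
        rows.append(row)
    df = pd.DataFrame(rows).set_index("metabolite_id")
    # failed fits propagate as non-rhythmic
    bad = ~df["converged"] | df["p_rhythm"].isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} mixed fit(s) failed; treated as non-rhythmic",
                      RuntimeWarning)
        df.loc[bad, "p_rhythm"] = 1.0
    return df


def run_group_rhythmicity(
    samples: pd.DataFrame,
    matrix: ConcentrationMatrix,
    condition: str,
    time_axis: str = "relative_time_h",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Mixed-effects cosinor rhythm detection for one condition.

    Returns one row per metabolite with the fit fields plus ``q_rhythm``
    (BH across metabolites within the condition) and ``rhythmic``
    (``q_rhythm < fdr``).
    """
    sel = samples["condition"] == condition
    if not sel.any():
        raise ValueError(f"no samples in condition {condition!r}")
    sub = samples.loc[sel]
    if time_axis not in sub.columns or sub[time_axis].isna().any():
        raise MissingTimeAxisError(f"time axis {time_axis!r} unavailable for some samples")
    values = matrix.values[sub["sample_id"]]
    df = _mixed_fits(values, sub[time_axis].to_numpy(float), sub["subject_id"].to_numpy())
    df["q_rhythm"] = bh_adjust(df["p_rhythm"].to_numpy())
    df["rhythmic"] = df["q_rhythm"] < fdr
    df["condition"] = condition
    return df


def rhythmic_count_curve(fits: pd.DataFrame, cutoffs=None) -> pd.DataFrame:
    """Number of metabolites with q below each cutoff (monotone in cutoff)."""
    if cutoffs is None:
        cutoffs = np.linspace(0.0, 1.0, 101)
    q = fits["q_rhythm"].to_numpy()
    return pd.DataFrame({
        "cutoff": cutoffs,
        "n_rhythmic": [int(np.sum(q < c)) if c > 0 else 0 for c in cutoffs],
    })


def overlap_test(fits_a: pd.DataFrame, fits_b: pd.DataFrame) -> dict:
    """Hypergeometric test for the overlap of the two conditions' rhythmic sets."""
    set_a = set(fits_a.index[fits_a["rhythmic"]])
    set_b = set(fits_b.index[fits_b["rhythmic"]])
    universe = fits_a.index.union(fits_b.index)
    inter = set_a & set_b
    p = circstats.hypergeometric_overlap(len(set_a), len(set_b), len(inter), len(universe))
    return {
        "n_a": len(set_a), "n_b": len(set_b),
        "n_overlap": len(inter), "n_universe": len(universe),
        "overlap": sorted(inter), "p": p,
    }


def classify_circadian_behavioural(
    samples: pd.DataFrame,
    matrix: ConcentrationMatrix,
    rhythmic_both: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Model selection between a circadian and a behavioural driver.

    For each metabolite rhythmic in both conditions, the mixed cosinor is fit
    on pooled both-condition data twice: with time measured from the melatonin
    phase (circadian model) and from lights-off (behavioural model); each
    model shares a single (b, c) pair across conditions. LRT p-values are BH
    corrected across metabolites separately within each model family. Labels:

    * ``circadian``   — q_circadian < alpha and BIC_circadian < BIC_behavioural
    * ``behavioural`` — q_behavioural < alpha and BIC_behavioural < BIC_circadian
    * ``neither``     — otherwise.
    """
    if samples["circadian_time_h"].isna().any():
        raise MissingTimeAxisError(
            "circadian time requires a melatonin phase for every subject; "
            "refusing to classify without it"
        )
    rhythmic_both = [m for m in rhythmic_both]
    if not rhythmic_both:
        return pd.DataFrame(columns=["label", "p_circadian", "p_behavioural",
                                     "q_circadian", "q_behavioural",
                                     "bic_circadian", "bic_behavioural"])
    values = matrix.values.loc[rhythmic_both, samples["sample_id"]]
    subjects = samples["subject_id"].to_numpy()
    fits = {}
    for name, axis in (("circadian", "circadian_time_h"),
                       ("behavioural", "behavioural_time_h")):
        fits[name] = _mixed_fits(values, samples[axis].to_numpy(float), subjects)
        fits[name]["q"] = bh_adjust(fits[name]["p_rhythm"].to_numpy())

    out = pd.DataFrame(index=pd.Index(rhythmic_both, name="metabolite_id"))
    for name in ("circadian", "behavioural"):
        out[f"p_{name}"] = fits[name]["p_rhythm"]
        out[f"q_{name}"] = fits[name]["q"]
        out[f"bic_{name}"] = fits[name]["bic"]
        out[f"amplitude_{name}"] = fits[name]["amplitude"]
        out[f"phase_{name}_h"] = fits[name]["phase_h"]
    circ = (out["q_circadian"] < alpha) & (out["bic_circadian"] < out["bic_behavioural"])
    behav = (out["q_behavioural"] < alpha) & (out["bic_behavioural"] < out["bic_circadian"])
    out["label"] = np.select([circ, behav], ["circadian", "behavioural"], default="neither")
    return out


def run_level_change(
    samples: pd.DataFrame,
    matrix: ConcentrationMatrix,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Differential overall level between conditions, per metabolite.

    Mixed model ``log2 value ~ condition + (1 | subject)`` fit by ML; the
    condition effect (night shift minus baseline, log2 units) is tested by a
    chi-square(1) LRT and BH-corrected across metabolites. ``direction`` is
    ``up``/``down`` only at ``q < fdr``.
    """
    conds = np.sort(samples["condition"].unique())
    if conds.size != 2:
        raise ValueError("level-change analysis needs both conditions")
    subjects = samples["subject_id"].to_numpy()
    cond = samples["condition"].to_numpy()
    values = matrix.values[samples["sample_id"]]
    rows = []
    for met in values.index:
        y = values.loc[met].to_numpy(float)
        keep = np.isfinite(y)
        effect, p = lrt_condition_effect(y[keep], cond[keep], subjects[keep])
        rows.append({"metabolite_id": met, "condition_effect": effect, "p": p})
    df = pd.DataFrame(rows).set_index("metabolite_id")
    df["q"] = bh_adjust(df["p"].to_numpy())
    sig = df["q"] < fdr
    df["direction"] = np.select(
        [sig & (df["condition_effect"] > 0), sig & (df["condition_effect"] < 0)],
        ["up", "down"], default="unchanged",
    )
    return df


def summarize_phase_distribution(fits: pd.DataFrame, n_mc: int = 10_000,
                                 seed: int = 0) -> dict:
    """Rao spacing uniformity test on the acrophases of the rhythmic set."""
    phases = fits.loc[fits["rhythmic"], "phase_h"].dropna().to_numpy()
    if phases.size < 4:
        raise circstats.InsufficientDataError(
            f"need >= 4 rhythmic metabolites, got {phases.size}")
    u, p = circstats.rao_spacing_test(phases, n_mc=n_mc, seed=seed)
    return {"rao_U": u, "p": p, "phases_h": phases.tolist()}


def group_phase_shifts(fits_base: pd.DataFrame, fits_shift: pd.DataFrame,
                       metabolites: list[str]) -> pd.DataFrame:
    """Per-metabolite group-level phase shift (baseline minus night shift,
    wrapped to [-12, 12); negative = delay)."""
    rows = []
    for met in metabolites:
        rec = circstats.phase_difference(
            fits_base.loc[met, "phase_h"], fits_shift.loc[met, "phase_h"],
            metabolite_id=met, subject_id="group")
        rows.append({"metabolite_id": met, "delta_phi_h": rec.delta_phi_h,
                     "direction": rec.direction})
    return pd.DataFrame(rows).set_index("metabolite_id")


def group_phase_shift_summary(delta_phi_h, alpha: float = 0.05) -> dict:
    """Rayleigh test on a set of phase shifts; circular mean/SD are reported
    only when the mean direction is significant."""
    d = np.asarray(delta_phi_h, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 3:
        raise circstats.InsufficientDataError("need >= 3 defined phase shifts")
    r_bar, p = circstats.rayleigh_test(d)
    out = {"n": int(d.size), "r_bar": r_bar, "p": p,
           "mean_shift_h": None, "circ_sd_h": None}
    if p < alpha:
        mean_h, _, sd_h, _ = circstats.circ_mean_resultant(d)
        out["mean_shift_h"] = float(circstats.wrap_difference(mean_h))
        out["circ_sd_h"] = sd_h
    return out


def compare_amplitudes(fits_base: pd.DataFrame, fits_shift: pd.DataFrame,
                       metabolites: list[str]) -> dict:
    """Paired Wilcoxon signed-rank test on fitted amplitudes across conditions
    (exact distribution for n <= 25, normal approximation above)."""
    a = fits_base.loc[metabolites, "amplitude"].to_numpy(float)
    b = fits_shift.loc[metabolites, "amplitude"].to_numpy(float)
    method = "exact" if len(metabolites) <= 25 else "approx"
    if np.allclose(a, b):
        return {"statistic": float("nan"), "p": 1.0,
                "median_base": float(np.median(a)), "median_shift": float(np.median(b))}
    res = stats.wilcoxon(a, b, method=method)
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "median_base": float(np.median(a)), "median_shift": float(np.median(b))}
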