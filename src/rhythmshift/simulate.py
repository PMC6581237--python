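"""Synthetic night-shift metabolomics datasets with known ground truth.

The generator emulates the design of a within-subject simulated night-shift
study: 9 subjects sampled every 2 h over 24 h in each of two conditions
(baseline and a schedule in which lights-off is delayed by 10 h), ~130
metabolites across 7 chemical classes, and three generative regimes:

* **behavioural** — the rhythm's phase is locked to the sleep/fasting
  schedule: in the shifted condition it moves with lights-off, scaled by a
  per-subject adaptation fraction (1 = fully shifted, 0 = not shifted).
* **circadian** — the phase is locked to the subject's melatonin phase,
  which does not move between conditions, so the rhythm stays put.
* **arrhythmic** — amplitude zero.

Log2 concentrations are mesor + subject random intercept + cosine + Gaussian
noise (i.e. lognormal concentrations). Optional below-LOD censoring flags the
lowest generated concentrations of each metabolite, and a small fraction of
samples can be dropped completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import ConcentrationMatrix, compute_time_axes

_CLASS_CYCLE = (
    "acylcarnitine",
    "amino_acid",
    "biogenic_amine",
    "lysophospholipid",
    "organic_acid",
    "phosphatidylcholine",
    "sphingolipid",
)


@dataclass
class SimulationConfig:
    """Design and distributional parameters of a simulated study.

    Defaults mirror the target study: 9 subjects, 2-h sampling over 24 h
    (13 nominal timepoints including both endpoints), a 10-h behavioural
    delay, 130 metabolites (30 behaviour-driven, 10 circadian-driven, 90
    arrhythmic), and a handful of completely-at-random missing samples so
    that ~229 of the nominal 234 samples survive.
    """

    n_subjects: int = 9
    timepoints_h: tuple = tuple(float(t) for t in range(0, 25, 2))
    behavioural_delay_h: float = 10.0
    n_behavioural: int = 30
    n_circadian: int = 10
    n_arrhythmic: int = 90
    amplitude_range: tuple = (0.2, 1.0)     # log2 units
    mesor_range: tuple = (2.0, 8.0)         # log2 uM
    subject_mesor_sd: float = 0.5           # log2 units
    residual_sd: float = 0.25               # log2 units
    adaptation_fraction: tuple | None = None  # per subject; None -> all 1.0
    lod_quantile: float = 0.01
    missing_rate: float = 0.021             # ~5 of 234 samples
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or len(self.timepoints_h) < 1:
            raise ValueError("need at least one subject and one timepoint")
        if min(self.subject_mesor_sd, self.residual_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(np.diff(self.timepoints_h) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.adaptation_fraction is not None and \
                len(self.adaptation_fraction) != self.n_subjects:
            raise ValueError("adaptation_fraction must have one entry per subject")

    @property
    def n_metabolites(self) -> int:
        return self.n_behavioural + self.n_circadian + self.n_arrhythmic


@dataclass
class GroundTruth:
    """Generative parameters: one row per metabolite and one per subject.

    ``metabolites`` columns: metabolite_id, regime, metabolite_class, mesor,
    amplitude, phase_baseline_h, phase_nightshift_h (phases on the relative
    clock-time axis, per the average subject). ``subjects`` columns:
    subject_id, adaptation_fraction, true_shift_h (negative = delay).
    """

    metabolites: pd.DataFrame
    subjects: pd.DataFrame


def simulate_dataset(config: SimulationConfig):
    """Generate ``(samples, matrix, truth)`` for one simulated study.

    Bit-reproducible for a fixed ``config.seed``. Sampling clock times follow
    each subject's habitual schedule so that the relative-time grid equals
    ``config.timepoints_h`` in both conditions; lights-off is delayed by
    ``behavioural_delay_h`` in the night-shift condition while the melatonin
    phase stays fixed, which is what makes the two regimes separable.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_sub = cfg.n_subjects
    adapt = (np.ones(n_sub) if cfg.adaptation_fraction is None
             else np.asarray(cfg.adaptation_fraction, dtype=float))

    subjects = [f"S{i+1:02d}" for i in range(n_sub)]
    sleep_onset = np.mod(23.0 + rng.normal(0.0, 0.75, n_sub), 24.0)
    melatonin = np.mod(sleep_onset - 2.0 + rng.normal(0.0, 0.5, n_sub), 24.0)

    rows = []
    for i, sid in enumerate(subjects):
        for cond in ("baseline", "nightshift"):
            lights_off = sleep_onset[i] if cond == "baseline" \
                else np.mod(sleep_onset[i] + cfg.behavioural_delay_h, 24.0)
            for j, t_rel in enumerate(cfg.timepoints_h):
                rows.append({
                    "sample_id": f"{sid}_{cond}_{j:02d}",
                    "subject_id": sid,
                    "condition": cond,
                    "clock_time_h": np.mod(sleep_onset[i] + t_rel, 24.0),
                    "t_rel_unwrapped": t_rel,
                    "habitual_sleep_onset_h": sleep_onset[i],
                    "lights_off_h": lights_off,
                    "melatonin_phase_h": melatonin[i],
                })
    samples = pd.DataFrame(rows)

    regimes = (["behavioural"] * cfg.n_behavioural
               + ["circadian"] * cfg.n_circadian
               + ["arrhythmic"] * cfg.n_arrhythmic)
    n_met = cfg.n_metabolites
    met_ids = [f"M{k+1:03d}" for k in range(n_met)]
    classes = [_CLASS_CYCLE[k % len(_CLASS_CYCLE)] for k in range(n_met)]
    mesors = rng.uniform(*cfg.mesor_range, n_met)
    amps = np.where(np.array(regimes) == "arrhythmic", 0.0,
                    rng.uniform(*cfg.amplitude_range, n_met))
    phases = rng.uniform(0.0, 24.0, n_met)  # on the driving axis

    subj_int = rng.normal(0.0, cfg.subject_mesor_sd, (n_met, n_sub))
    sub_idx = samples["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    is_night = (samples["condition"] == "nightshift").to_numpy()
    t_rel = samples["t_rel_unwrapped"].to_numpy()

    # effective phase on the relative-time axis, per sample, per metabolite
    omega = 2.0 * np.pi / 24.0
    values = np.empty((n_met, len(samples)))
    mel_offset = np.mod(sleep_onset - melatonin, 24.0)  # circadian lag per subject
    for k in range(n_met):
        if regimes[k] == "behavioural":
            # baseline: locked to lights-off == sleep onset; nightshift: moves
            # with the delay, scaled by each subject's adaptation fraction
            shift = np.where(is_night, cfg.behavioural_delay_h * adapt[sub_idx], 0.0)
            eff_phase = phases[k] + shift
        elif regimes[k] == "circadian":
            # locked to melatonin: cos peaks at circadian time phases[k] in
            # both conditions (circadian_time = t_rel + mel_offset per subject)
            eff_phase = phases[k] - mel_offset[sub_idx]
        else:
            eff_phase = 0.0
        signal = amps[k] * np.cos(omega * (t_rel - eff_phase))
        values[k] = (mesors[k] + subj_int[k, sub_idx] + signal
                     + rng.normal(0.0, cfg.residual_sd, len(samples)))

    flags = np.zeros_like(values, dtype=bool)
    if cfg.lod_quantile > 0:
        lod = np.quantile(values, cfg.lod_quantile, axis=1, keepdims=True)
        flags = values < lod

    if cfg.missing_rate > 0:
        n_drop = int(round(cfg.missing_rate * len(samples)))
        drop = rng.choice(len(samples), size=n_drop, replace=False)
        keep = np.setdiff1d(np.arange(len(samples)), drop)
        samples = samples.iloc[keep].reset_index(drop=True)
        values = values[:, keep]
        flags = flags[:, keep]

    samples = compute_time_axes(samples.drop(columns=["t_rel_unwrapped"]))
    matrix = ConcentrationMatrix(
        values=pd.DataFrame(values, index=met_ids, columns=samples["sample_id"]),
        metabolite_class=pd.Series(classes, index=met_ids, name="metabolite_class"),
        lod_flags=pd.DataFrame(flags, index=met_ids, columns=samples["sample_id"]),
    )

    phase_base = np.empty(n_met)
    phase_night = np.empty(n_met)
    for k in range(n_met):
        if regimes[k] == "behavioural":
            phase_base[k] = np.mod(phases[k], 24.0)
            phase_night[k] = np.mod(phases[k] + cfg.behavioural_delay_h * adapt.mean(), 24.0)
        elif regimes[k] == "circadian":
            base = phases[k] - mel_offset.mean()
            phase_base[k] = phase_night[k] = np.mod(base, 24.0)
        else:
            phase_base[k] = phase_night[k] = np.nan
    truth = GroundTruth(
        metabolites=pd.DataFrame({
            "metabolite_id": met_ids,
            "regime": regimes,
            "metabolite_class": classes,
            "mesor": mesors,
            "amplitude": amps,
            "phase_baseline_h": phase_base,
            "phase_nightshift_h": phase_night,
        }),
        subjects=pd.DataFrame({
            "subject_id": subjects,
            "adaptation_fraction": adapt,
            "true_shift_h": -cfg.behavioural_delay_h * adapt,
        }),
    )
    return samples, matrix, truth


def simulate_null_dataset(config: SimulationConfig):
    """All-arrhythmic variant of :func:`simulate_dataset` (every amplitude 0),
    for type-I-error calibration of the rhythm tests."""
    from dataclasses import replace
    cfg = replace(config,
                  n_behavioural=0, n_circadian=0,
                  n_arrhythmic=config.n_metabolites)
    return simulate_dataset(cfg)


def write_dataset(samples: pd.DataFrame, matrix: ConcentrationMatrix,
                  outdir, truth: GroundTruth | None = None,
                  linear_scale: bool = True) -> dict:
    """Write the three-table TSV layout that :func:`..io_preprocess.load_dataset`
    reads (concentrations in linear uM by default), plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "samples.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "concentrations": outdir / "concentrations.tsv",
    }
    derived = ["relative_time_h", "behavioural_time_h", "circadian_time_h"]
    samples.drop(columns=derived, errors="ignore") \
        .to_csv(paths["samples"], sep="\t", index=False)
    matrix.metabolite_class.rename("metabolite_class").rename_axis("metabolite_id") \
        .reset_index().to_csv(paths["metabolites"], sep="\t", index=False)
    long = matrix.values.rename_axis("metabolite_id").reset_index() \
        .melt(id_vars="metabolite_id", var_name="sample_id", value_name="value")
    flags_long = matrix.lod_flags.rename_axis("metabolite_id").reset_index() \
        .melt(id_vars="metabolite_id", var_name="sample_id", value_name="below_lod")
    long["below_lod"] = flags_long["below_lod"]
    if linear_scale:
        long["value"] = 2.0 ** long["value"]
    long.to_csv(paths["concentrations"], sep="\t", index=False)
    if truth is not None:
        paths["truth_metabolites"] = outdir / "truth_metabolites.tsv"
        paths["truth_subjects"] = outdir / "truth_subjects.tsv"
        truth.metabolites.to_csv(paths["truth_metabolites"], sep="\t", index=False)
        truth.subjects.to_csv(paths["truth_subjects"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
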