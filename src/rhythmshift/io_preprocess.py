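"""Loading, validation and preprocessing of metabolomics study tables.

Three delimited text tables (TSV or CSV, header row) describe a study:

* **samples** — one row per plasma sample: ``sample_id``, ``subject_id``,
  ``condition`` (``baseline`` or ``nightshift``), ``clock_time_h``,
  ``habitual_sleep_onset_h``, ``lights_off_h`` (per subject per condition)
  and optionally ``melatonin_phase_h`` (per subject).
* **metabolites** — ``metabolite_id`` and ``metabolite_class``.
* **concentrations** — long format ``metabolite_id, sample_id, value``
  with an optional ``below_lod`` flag column; a wide matrix (metabolite rows,
  sample columns) is also accepted.

Concentrations are micromolar; they are log2-transformed on load unless
``already_log2`` is set. Values censored at the limit of detection (LOD) are
distinct from missing-at-random values: censored cells are imputed at 50% of
the metabolite's lowest detected concentration, missing cells stay missing
and are dropped row-wise by each fit downstream.

Each sample carries three time coordinates, all reduced modulo 24:

* relative time     = clock time - habitual sleep onset,
* behavioural time  = clock time - lights-off (per condition),
* circadian time    = clock time - melatonin phase (when available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("baseline", "nightshift")

METABOLITE_CLASSES = (
    "acylcarnitine",
    "amino_acid",
    "biogenic_amine",
    "lysophospholipid",
    "organic_acid",
    "phosphatidylcholine",
    "sphingolipid",
    "other",
)

SAMPLE_COLUMNS = (
    "sample_id",
    "subject_id",
    "condition",
    "clock_time_h",
    "habitual_sleep_onset_h",
    "lights_off_h",
)

TIME_AXES = ("relative_time_h", "behavioural_time_h", "circadian_time_h")


class SchemaError(ValueError):
    """A required column is missing or a value violates its domain."""


class DuplicationError(ValueError):
    """The same (metabolite, sample) cell appears more than once."""


@dataclass
class ConcentrationMatrix:
    """Metabolites x samples log2 concentrations with class and LOD metadata.

    ``values`` may contain NaN (missing-at-random); ``lod_flags`` marks cells
    that were below the LOD *before* imputation.
    """

    values: pd.DataFrame            # index metabolite_id, columns sample_id
    metabolite_class: pd.Series     # index metabolite_id
    lod_flags: pd.DataFrame         # bool, same shape as values
    filter_report: dict = field(default_factory=dict)

    @property
    def metabolites(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            self.values.copy(), self.metabolite_class.copy(),
            self.lod_flags.copy(), dict(self.filter_report),
        )


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def _require(df: pd.DataFrame, cols, table: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required column(s): {missing}")


def compute_time_axes(samples: pd.DataFrame) -> pd.DataFrame:
    """Add the three time coordinates (mod 24) to a sample table.

    ``circadian_time_h`` is NaN when the subject's melatonin phase is absent;
    downstream classification refuses to run on such samples rather than
    silently substituting another axis.
    """
    out = samples.copy()
    clock = out["clock_time_h"].astype(float)

    def _wrap(x):
        w = np.mod(x, 24.0)
        return np.where(w >= 24.0, 0.0, w)  # float guard at the boundary

    out["relative_time_h"] = _wrap(clock - out["habitual_sleep_onset_h"].astype(float))
    out["behavioural_time_h"] = _wrap(clock - out["lights_off_h"].astype(float))
    if "melatonin_phase_h" in out.columns:
        out["circadian_time_h"] = _wrap(clock - out["melatonin_phase_h"].astype(float))
    else:
        out["circadian_time_h"] = np.nan
    return out


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    _require(samples, SAMPLE_COLUMNS, "samples")
    bad = set(samples["condition"]) - set(CONDITIONS)
    if bad:
        raise SchemaError(f"unknown condition value(s) {sorted(bad)}; expected {CONDITIONS}")
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise DuplicationError(f"duplicate sample_id(s): {dups}")
    counts = samples.groupby(["subject_id", "condition"])["clock_time_h"].nunique()
    thin = counts[counts < 3]
    if len(thin):
        raise SchemaError(
            "each (subject, condition) needs >= 3 distinct sampling times; "
            f"violated by {thin.index.tolist()}"
        )
    return samples


def _concentrations_to_long(conc: pd.DataFrame) -> pd.DataFrame:
    if {"metabolite_id", "sample_id", "value"}.issubset(conc.columns):
        long = conc.copy()
    else:
        # wide matrix: first column names metabolites, remaining columns samples
        idcol = conc.columns[0]
        long = conc.melt(id_vars=[idcol], var_name="sample_id", value_name="value")
        long = long.rename(columns={idcol: "metabolite_id"})
    if "below_lod" not in long.columns:
        long["below_lod"] = False
    long["below_lod"] = long["below_lod"].fillna(False).astype(bool)
    return long


def load_dataset(
    samples_path,
    metabolites_path,
    concentrations_path,
    already_log2: bool = False,
):
    """Read and cross-validate the three study tables.

    Returns ``(samples, matrix)``: the annotated sample table with time axes
    computed, and a :class:`ConcentrationMatrix` of log2 values (transform
    skipped when ``already_log2``). Duplicate measurements of the same
    (metabolite, sample) cell raise; duplicate sampling times within a
    (subject, condition, clock time) are tolerated as distinct samples.
    """
    samples = validate_samples(_read_table(samples_path))
    metabolites = _read_table(metabolites_path)
    _require(metabolites, ("metabolite_id", "metabolite_class"), "metabolites")
    bad_cls = set(metabolites["metabolite_class"]) - set(METABOLITE_CLASSES)
    if bad_cls:
        raise SchemaError(
            f"unknown metabolite class(es) {sorted(bad_cls)}; expected {METABOLITE_CLASSES}"
        )
    long = _concentrations_to_long(_read_table(concentrations_path))

    if long.duplicated(["metabolite_id", "sample_id"]).any():
        dups = long.loc[long.duplicated(["metabolite_id", "sample_id"]),
                        ["metabolite_id", "sample_id"]]
        raise DuplicationError(f"duplicate (metabolite, sample) cells: {dups.values.tolist()}")

    unknown_samples = set(long["sample_id"]) - set(samples["sample_id"])
    if unknown_samples:
        raise SchemaError(f"concentration rows reference unknown sample_id(s): "
                          f"{sorted(unknown_samples)[:5]}")
    unknown_mets = set(long["metabolite_id"]) - set(metabolites["metabolite_id"])
    if unknown_mets:
        raise SchemaError(f"concentration rows reference unknown metabolite_id(s): "
                          f"{sorted(unknown_mets)[:5]}")

    values = long.pivot(index="metabolite_id", columns="sample_id", values="value")
    flags = (
        long.pivot(index="metabolite_id", columns="sample_id", values="below_lod")
        .reindex(index=values.index, columns=values.columns)
        .fillna(False)
        .astype(bool)
    )
    # keep sample ordering of the annotation table
    values = values.reindex(columns=pd.Index(samples["sample_id"]))
    flags = flags.reindex(columns=values.columns, fill_value=False)
    if not already_log2:
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.log2(values.where(values > 0))
    classes = metabolites.set_index("metabolite_id")["metabolite_class"].reindex(values.index)
    samples = compute_time_axes(samples)
    return samples, ConcentrationMatrix(values, classes, flags)


def filter_lod(matrix: ConcentrationMatrix, max_below_frac: float = 0.10) -> ConcentrationMatrix:
    """Apply LOD-based filtering and censored-value imputation.

    Metabolites whose below-LOD fraction (among non-missing measurements)
    exceeds ``max_below_frac`` are removed — equivalently, a metabolite is
    retained when it is above the LOD in at least ``1 - max_below_frac`` of
    its samples. Remaining below-LOD cells are imputed at half the
    metabolite's minimum detected concentration, i.e. ``min(log2 value) - 1``
    on the log2 scale. The returned matrix's ``filter_report`` lists removed
    metabolites and per-metabolite imputation counts; the operation is
    idempotent.
    """
    values = matrix.values.copy()
    flags = matrix.lod_flags.copy()
    observed = values.notna()
    n_obs = observed.sum(axis=1)
    below = (flags & observed).sum(axis=1)
    frac = below / n_obs.replace(0, np.nan)
    all_below = (n_obs > 0) & (below == n_obs)
    drop = (frac > max_below_frac) | frac.isna() | all_below
    if all_below.any():
        warnings.warn(
            f"metabolite(s) entirely below LOD removed: {list(values.index[all_below])}",
            RuntimeWarning,
        )
    removed = list(values.index[drop])
    keep_idx = values.index[~drop]
    values = values.loc[keep_idx]
    flags = flags.loc[keep_idx]

    imputed_counts = {}
    for met in keep_idx:
        mask = flags.loc[met] & values.loc[met].notna()
        n_below = int(mask.sum())
        if n_below == 0:
            continue
        detected = values.loc[met, ~flags.loc[met]]
        detected = detected.dropna()
        if detected.empty:  # unreachable given the all-below removal above
            continue
        values.loc[met, mask[mask].index] = float(detected.min()) - 1.0
        imputed_counts[met] = n_below

    report = {
        "removed": removed,
        "n_removed": len(removed),
        "n_retained": int(len(keep_idx)),
        "imputed": imputed_counts,
        "max_below_frac": max_below_frac,
    }
    # flags keep recording pre-imputation censoring; re-running the filter
    # recomputes identical fractions and identical imputed values (idempotent)
    return ConcentrationMatrix(values, matrix.metabolite_class.loc[keep_idx],
                               flags, report)


def write_matrix_tsv(matrix: ConcentrationMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t")
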