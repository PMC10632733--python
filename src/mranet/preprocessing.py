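"""Normalization of raw phosphoprotein quantifications into fold changes.

Two modalities feed the response matrix:

* Luminex bead-based multiplex assays (median fluorescence intensities,
  MFI).  Each analyte's MFI is first normalized by the mean MFI of that
  analyte across all samples of the same biological replicate, then
  expressed as fold change over the mean of the DMSO-treated controls of
  that replicate.
* Quantitative immunoblots.  Band intensities are first divided by the
  lane's total protein stain (TPS) to correct loading, then by the mean
  of that quantity across all samples on the same gel (gels may carry
  both cell lines' samples for the same treatments), and finally turned
  into fold change relative to the mean over the DMSO controls of all
  replicates.

Inputs are long-format tables with columns ``sample_id``, ``replicate``,
``treatment``, ``analyte``, ``value`` (plus ``gel`` and ``tps`` for
blots).  Exclusions of discordant (replicate, analyte) combinations are
explicit configuration — a diagnostic of replicate correlations is
available in :func:`mranet.data.replicate_correlations`, but data are
never removed automatically.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ResponseDataset
from .structure import condition

CONTROL_LABEL = "DMSO"

LUMINEX_COLUMNS = ("replicate", "treatment", "analyte", "value")
BLOT_COLUMNS = LUMINEX_COLUMNS + ("gel", "tps")


class PreprocessingError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PreprocessingError(f"{what} table lacks columns {missing}")


def normalize_luminex(raw: pd.DataFrame, control_label: str = CONTROL_LABEL) -> pd.DataFrame:
    """Two-step Luminex normalization to fold changes.

    ``fc = (MFI / mean MFI of the analyte over the replicate's samples)
    / (mean of that normalized value over the replicate's DMSO controls)``.
    The DMSO controls of each (replicate, analyte) average to exactly 1.
    """
    _check_columns(raw, LUMINEX_COLUMNS, "Luminex")
    df = raw.copy()
    if (df["value"] < 0).any():
        raise PreprocessingError("negative intensities")
    rep_mean = df.groupby(["replicate", "analyte"])["value"].transform("mean")
    if (rep_mean == 0).any():
        raise PreprocessingError("replicate with zero mean intensity for an analyte")
    df["normalized"] = df["value"] / rep_mean
    ctrl = df[df["treatment"] == control_label]
    if ctrl.empty:
        raise PreprocessingError("no control samples found")
    ctrl_mean = ctrl.groupby(["replicate", "analyte"])["normalized"].mean()
    missing = set(map(tuple, df[["replicate", "analyte"]].drop_duplicates().to_numpy())) \
        - set(ctrl_mean.index)
    if missing:
        raise PreprocessingError(f"replicates without DMSO control: {sorted(missing)}")
    df["fold_change"] = df["normalized"] / df.set_index(["replicate", "analyte"]).index.map(ctrl_mean)
    return df.drop(columns=["normalized"])


def normalize_blots(raw: pd.DataFrame, control_label: str = CONTROL_LABEL) -> pd.DataFrame:
    """Three-step immunoblot normalization to fold changes.

    ``fc = ((band / TPS) / mean(band / TPS over the gel's samples))
    / (mean of that quantity over the DMSO controls of all replicates)``.
    Loading correction first, cross-gel scaling second, and a fold change
    against the pooled controls last — so the pooled DMSO mean is 1.
    """
    _check_columns(raw, BLOT_COLUMNS, "immunoblot")
    df = raw.copy()
    if (df["tps"] <= 0).any():
        raise PreprocessingError("zero or negative total protein stain")
    df["signal"] = df["value"] / df["tps"]
    gel_mean = df.groupby(["gel", "analyte"])["signal"].transform("mean")
    if (gel_mean == 0).any():
        raise PreprocessingError("gel with zero mean signal for an analyte")
    df["normalized"] = df["signal"] / gel_mean
    ctrl = df[df["treatment"] == control_label]
    if ctrl.empty:
        raise PreprocessingError("no control samples found")
    ctrl_mean = ctrl.groupby("analyte")["normalized"].mean()
    df["fold_change"] = df["normalized"] / df["analyte"].map(ctrl_mean)
    return df.drop(columns=["signal", "normalized"])


def _treatment_to_condition(label: str, control_label: str) -> tuple[str, ...]:
    if label == control_label:
        return condition()
    return condition(label.split("+"))


def assemble_dataset(fc_tables: Sequence[pd.DataFrame] | pd.DataFrame,
                     exclusions: Iterable[tuple[int, str]] = (),
                     control_label: str = CONTROL_LABEL,
                     cell_line: str = "",
                     condition_map: Mapping[str, tuple[str, ...]] | None = None,
                     ) -> ResponseDataset:
    """Merge normalized fold-change tables into one response dataset.

    Treatment labels become conditions (``"A+B"`` is the combination of
    agents A and B; override with ``condition_map``).  ``exclusions`` are
    (replicate, analyte) pairs whose cells are marked missing, not zero.
    Conflicting duplicate (condition, analyte, replicate) entries raise.
    """
    if isinstance(fc_tables, pd.DataFrame):
        fc_tables = [fc_tables]
    frames = []
    for t in fc_tables:
        _check_columns(t, ("replicate", "treatment", "analyte", "fold_change"), "fold-change")
        frames.append(t[["replicate", "treatment", "analyte", "fold_change"]])
    df = pd.concat(frames, ignore_index=True)

    def to_cond(label: str) -> tuple[str, ...]:
        if condition_map is not None and label in condition_map:
            return tuple(condition_map[label])
        return _treatment_to_condition(label, control_label)

    df["condition"] = df["treatment"].map(to_cond)
    dup = df.groupby(["condition", "analyte", "replicate"])["fold_change"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()[:3]
        raise PreprocessingError(f"conflicting duplicate entries, e.g. {bad}")
    df = df.drop_duplicates(["condition", "analyte", "replicate"])

    conditions = list(dict.fromkeys(df["condition"]))
    if condition() not in conditions:
        raise PreprocessingError("no vehicle-control condition after assembly")
    conditions = [condition()] + [c for c in conditions if c != condition()]
    analytes = list(dict.fromkeys(df["analyte"]))
    replicates = sorted(df["replicate"].unique())
    c_idx = {c: i for i, c in enumerate(conditions)}
    a_idx = {a: j for j, a in enumerate(analytes)}
    r_idx = {r: k for k, r in enumerate(replicates)}

    values = np.full((len(conditions), len(analytes), len(replicates)), np.nan)
    for row in df.itertuples(index=False):
        values[c_idx[row.condition], a_idx[row.analyte], r_idx[row.replicate]] = row.fold_change
    for rep, analyte in exclusions:
        if rep in r_idx and analyte in a_idx:
            values[:, a_idx[analyte], r_idx[rep]] = np.nan
    return ResponseDataset(conditions, analytes, values, cell_line=cell_line)
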