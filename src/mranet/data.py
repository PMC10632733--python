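"""Perturbation-response datasets.

A :class:`ResponseDataset` holds the global response matrix of one cell
line: for every treatment condition and phospho-readout, the fold change
relative to vehicle control, with replicate structure.  Values are stored
as linear fold changes (as deposited on disk); all modeling happens on the
log2 scale, with per-cell measurement errors estimated from the replicate
spread of the log2 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_SIGMA_MIN = 0.1  # log2 units; floor on the standard error of a cell


class DatasetError(ValueError):
    """Raised for malformed response datasets."""


@dataclass
class ResponseDataset:
    """Fold-change responses of one cell line to a perturbation design.

    Parameters
    ----------
    conditions
        Treatment conditions as sorted tuples of active agent ids; the empty
        tuple is the vehicle control and must be present.
    readouts
        Measured node identifiers.
    values
        Array ``(n_conditions, n_readouts, n_replicates)`` of linear fold
        changes; ``nan`` marks missing measurements.
    cell_line
        Label, e.g. ``"XX"`` or ``"XO"``.
    sigma
        Optional known measurement errors on the log2 scale, shape
        ``(n_conditions, n_readouts)``.  When absent, errors are estimated
        from the replicate spread via :func:`estimate_errors`.
    """

    conditions: list[tuple[str, ...]]
    readouts: list[str]
    values: np.ndarray
    cell_line: str = ""
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DatasetError("values must be (conditions, readouts, replicates)")
        n_c, n_r, _ = self.values.shape
        if n_c != len(self.conditions) or n_r != len(self.readouts):
            raise DatasetError("values shape does not match conditions/readouts")
        if len(set(self.conditions)) != len(self.conditions):
            raise DatasetError("duplicate treatment conditions")
        if () not in self.conditions:
            raise DatasetError("vehicle control (empty condition) missing")
        if np.nanmin(self.values, initial=np.inf) <= 0:
            raise DatasetError("fold changes must be strictly positive")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != (n_c, n_r):
                raise DatasetError("sigma shape does not match (conditions, readouts)")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    @property
    def control_index(self) -> int:
        return self.conditions.index(())

    @property
    def treatment_indices(self) -> np.ndarray:
        """Indices of non-control conditions, in dataset order."""
        ctrl = self.control_index
        return np.array([i for i in range(len(self.conditions)) if i != ctrl])

    def log2_values(self) -> np.ndarray:
        return np.log2(self.values)

    def log2_mean(self) -> np.ndarray:
        """Replicate mean of log2 fold changes; nan where all replicates miss."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.log2_values(), axis=2)

    def n_observed(self) -> int:
        """Number of non-missing (treatment condition, readout) data points."""
        mean = self.log2_mean()[self.treatment_indices]
        return int(np.isfinite(mean).sum())

    def errors(self, sigma_min: float = DEFAULT_SIGMA_MIN) -> np.ndarray:
        """Measurement errors: the attached sigma if known, else estimated."""
        if self.sigma is not None:
            return self.sigma
        return estimate_errors(self, sigma_min)


def estimate_errors(dataset: ResponseDataset, sigma_min: float = DEFAULT_SIGMA_MIN) -> np.ndarray:
    """Standard error of the replicate-mean log2 fold change per cell.

    ``sigma(c, a) = max(sd(log2 replicates) / sqrt(n_rep), sigma_min)``;
    cells with fewer than two replicates get ``sigma_min``.  Cells with no
    observation at all are left ``nan`` (they carry no data).
    """
    if sigma_min <= 0:
        raise DatasetError("sigma_min must be positive")
    import warnings

    log2 = dataset.log2_values()
    n = np.isfinite(log2).sum(axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(log2, axis=2, ddof=1)
        sigma = np.where(n >= 2, np.maximum(sd / np.sqrt(np.maximum(n, 1)), sigma_min), sigma_min)
    sigma = np.where(n == 0, np.nan, sigma)
    return sigma


def replicate_correlations(dataset: ResponseDataset) -> dict[str, np.ndarray]:
    """Pairwise Pearson correlation of replicates per readout (diagnostic).

    Returns a map readout -> (n_rep, n_rep) correlation matrix computed on
    log2 fold changes across conditions.  Purely informational: the study
    excluded discordant replicate/analyte combinations by inspection, and
    exclusions here are configuration, never automatic.
    """
    log2 = dataset.log2_values()
    out: dict[str, np.ndarray] = {}
    for j, readout in enumerate(dataset.readouts):
        block = log2[:, j, :]  # conditions x replicates
        n_rep = block.shape[1]
        corr = np.full((n_rep, n_rep), np.nan)
        for a in range(n_rep):
            for b in range(n_rep):
                ok = np.isfinite(block[:, a]) & np.isfinite(block[:, b])
                if ok.sum() >= 3:
                    corr[a, b] = np.corrcoef(block[ok, a], block[ok, b])[0, 1]
        out[readout] = corr
    return out


def from_replicate_values(
    conditions: Sequence[tuple[str, ...]],
    readouts: Sequence[str],
    values: np.ndarray,
    **kwargs,
) -> ResponseDataset:
    """Convenience constructor validating shapes."""
    return ResponseDataset(list(conditions), list(readouts), np.asarray(values, float), **kwargs)
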