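"""Synthetic viability plates and expression panels with known ground truth.

Two generators make every downstream stage testable without external data:

* :func:`generate_dose_response` emulates a resazurin-style fluorescence
  plate: viability follows a Hill curve
  ``v(c) = 1 / (1 + (c / ic50)^h)`` and each well reads
  ``blank + (control - blank) * v(c) * (1 + eps)`` with multiplicative
  Gaussian noise ``eps ~ N(0, noise_cv)``. Vehicle-control wells take
  ``v = 1`` and blank wells carry only the background signal. Negative draws
  are clamped at zero fluorescence and counted.

* :func:`generate_panel` emulates an NCI-style panel: a per-cell-line
  log10(IC50) response ``z ~ N(response_mean, response_sd)`` plus a gene
  expression matrix in which a planted minority of genes is linearly coupled
  to the response. A planted positive gene is
  ``x = r * z_std + sqrt(1 - r^2) * eps`` with ``z_std`` the
  population-standardised response, so its population Pearson correlation
  with the response is exactly ``+r`` (negative genes use ``-r``); null genes
  are iid standard normal. Expression values are emitted already normalised
  (z-scale), the scale on which correlation ranking operates.

Both generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseResponseDataset
from .exceptions import ValidationError

__all__ = [
    "PlateSimConfig",
    "PanelSimConfig",
    "PanelGroundTruth",
    "default_doses",
    "generate_dose_response",
    "generate_panel",
    "generate_grouped_panel",
]


def default_doses(n: int = 8, low: float = 0.1, high: float = 300.0) -> np.ndarray:
    """Geometric dose ladder in uM (default 8 doses spanning 0.1-300)."""
    return np.geomspace(low, high, n)


@dataclass(frozen=True)
class PlateSimConfig:
    """Conditions for one simulated viability plate.

    Defaults mirror a routine cytotoxicity run: 8 geometric doses of
    0.1-300 uM, six replicates, 5% well-to-well CV, and a fluorescence window
    of 2000 (blank) to 50000 (untreated control) arbitrary units.
    """

    true_ic50: float = 10.0          # uM
    hill_slope: float = 1.0
    concentrations: tuple = tuple(default_doses())  # uM, strictly increasing
    n_replicates: int = 6
    control_signal: float = 50000.0  # fluorescence a.u.
    blank_signal: float = 2000.0     # fluorescence a.u.
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if not (np.isfinite(self.true_ic50) and self.true_ic50 > 0):
            raise ValidationError(f"true_ic50: must be > 0, got {self.true_ic50}")
        if not (np.isfinite(self.hill_slope) and self.hill_slope > 0):
            raise ValidationError(f"hill_slope: must be > 0, got {self.hill_slope}")
        if c.size < 2 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValidationError(
                "concentrations: must be positive and strictly increasing")
        if self.n_replicates < 1:
            raise ValidationError(f"n_replicates: must be >= 1, got {self.n_replicates}")
        if self.noise_cv < 0:
            raise ValidationError(f"noise_cv: must be >= 0, got {self.noise_cv}")
        if not self.control_signal > self.blank_signal:
            raise ValidationError(
                f"control_signal: must exceed blank_signal "
                f"({self.control_signal} <= {self.blank_signal})")


@dataclass(frozen=True)
class PanelSimConfig:
    """Conditions for one simulated expression panel.

    Defaults are the study conditions downstream stages are validated under:
    a 47-cell-line panel carrying 2000 null genes and 20 + 20 genes planted
    at population correlation +/-0.7 with a log10(IC50) response of mean 1.5
    and SD 0.4 (IC50s spanning roughly 8-120 uM).
    """

    n_cell_lines: int = 47
    n_null_genes: int = 2000
    n_pos_genes: int = 20
    n_neg_genes: int = 20
    target_r: float = 0.7
    response_mean: float = 1.5   # log10(uM)
    response_sd: float = 0.4     # log10(uM)
    seed: int = 0
    drug: str = "simdrug"

    def __post_init__(self) -> None:
        if self.n_cell_lines < 4:
            raise ValidationError(f"n_cell_lines: must be >= 4, got {self.n_cell_lines}")
        if min(self.n_null_genes, self.n_pos_genes, self.n_neg_genes) < 0:
            raise ValidationError("gene counts: must be >= 0")
        if self.n_null_genes + self.n_pos_genes + self.n_neg_genes < 1:
            raise ValidationError("gene counts: panel needs at least one gene")
        if not (0.0 < self.target_r < 1.0):
            raise ValidationError(
                f"target_r: must be strictly between 0 and 1, got {self.target_r}")
        if not (np.isfinite(self.response_sd) and self.response_sd > 0):
            raise ValidationError(
                f"response_sd: must be > 0 (correlation undefined otherwise), "
                f"got {self.response_sd}")


@dataclass(frozen=True)
class PanelGroundTruth:
    """Which simulated genes were planted, and the true response vector."""

    planted_pos: frozenset
    planted_neg: frozenset
    true_response: pd.Series = field(compare=False)

    def gene_class(self, gene_id: str) -> str:
        if gene_id in self.planted_pos:
            return "pos"
        if gene_id in self.planted_neg:
            return "neg"
        return "null"


def generate_dose_response(config: PlateSimConfig,
                           cell_line: str = "SIM-1") -> DoseResponseDataset:
    """Simulate one plate for one cell line under ``config``."""
    rng = np.random.default_rng(config.seed)
    c = np.asarray(config.concentrations, dtype=float)
    v = 1.0 / (1.0 + (c / config.true_ic50) ** config.hill_slope)
    span = config.control_signal - config.blank_signal

    def noisy(signal_over_blank: np.ndarray, shape) -> np.ndarray:
        eps = rng.normal(0.0, config.noise_cv, size=shape)
        return config.blank_signal + signal_over_blank * (1.0 + eps)

    treated = noisy(span * v[:, None], (c.size, config.n_replicates))
    controls = noisy(np.float64(span), config.n_replicates)
    # blank wells: background only, same multiplicative noise on the signal
    blanks = config.blank_signal * (1.0 + rng.normal(0.0, config.noise_cv,
                                                     config.n_replicates))
    total_clamped = 0
    for arr in (treated, controls, blanks):
        total_clamped += int(np.count_nonzero(arr < 0))
        np.clip(arr, 0.0, None, out=arr)
    return DoseResponseDataset(cell_line=cell_line, doses=c, treated=treated,
                               controls=controls, blanks=blanks,
                               n_clamped=total_clamped)


def _gene_ids(n: int, width: int = 5) -> list:
    return [f"gene_{i:0{width}d}" for i in range(1, n + 1)]


def generate_panel(config: PanelSimConfig):
    """Simulate an expression panel, its drug-response vector and ground truth.

    Returns ``(panel, response, truth)`` where ``panel`` is a genes x
    cell-lines :class:`pandas.DataFrame`, ``response`` a per-cell-line
    log10(IC50) :class:`pandas.Series` named after the drug, and ``truth``
    records the planted gene sets.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cell_lines
    cells = [f"CL{i:03d}" for i in range(1, n + 1)]

    z = rng.normal(config.response_mean, config.response_sd, n)
    z_std = (z - config.response_mean) / config.response_sd  # population scale

    r = config.target_r
    mix = np.sqrt(1.0 - r * r)
    pos = r * z_std + mix * rng.standard_normal((config.n_pos_genes, n))
    neg = -r * z_std + mix * rng.standard_normal((config.n_neg_genes, n))
    null = rng.standard_normal((config.n_null_genes, n))

    values = np.vstack([pos, neg, null])
    genes = _gene_ids(values.shape[0])
    n_pos, n_neg = config.n_pos_genes, config.n_neg_genes
    panel = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                         columns=cells)
    response = pd.Series(z, index=cells, name=config.drug)
    truth = PanelGroundTruth(
        planted_pos=frozenset(genes[:n_pos]),
        planted_neg=frozenset(genes[n_pos:n_pos + n_neg]),
        true_response=response.copy(),
    )
    return panel, response, truth


def generate_grouped_panel(n_cell_lines: int = 47, n_genes: int = 40,
                           n_groups: int = 4, shift: float = 6.0,
                           noise_sd: float = 1.0, seed: int = 0):
    """Panel with planted cell-line groups (for validating cluster recovery).

    Cell lines are split as evenly as possible into ``n_groups`` groups; each
    group has its own Gaussian gene-expression centroid with component SD
    ``shift``, and wells add iid noise of SD ``noise_sd``. With
    ``shift >> noise_sd`` the groups are unambiguous.

    Returns ``(panel, labels)`` with ``labels`` a cell-line -> group Series.
    """
    if n_groups < 1 or n_groups > n_cell_lines:
        raise ValidationError("n_groups: must be in [1, n_cell_lines]")
    rng = np.random.default_rng(seed)
    cells = [f"CL{i:03d}" for i in range(1, n_cell_lines + 1)]
    group_of = np.arange(n_cell_lines) % n_groups
    centroids = rng.normal(0.0, shift, (n_groups, n_genes))
    values = centroids[group_of] + rng.normal(0.0, noise_sd,
                                              (n_cell_lines, n_genes))
    panel = pd.DataFrame(values.T, index=pd.Index(_gene_ids(n_genes),
                                                  name="gene_id"),
                         columns=cells)
    labels = pd.Series(group_of, index=cells, name="group")
    return panel, labels
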