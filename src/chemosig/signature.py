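"""Correlation ranking of gene expression against drug response.

Every gene in a genes x cell-lines panel is scored by the Pearson
product-moment correlation ``r`` between its expression row and the panel's
log10(IC50) vector, using pairwise-complete observations. The signature is
then the top-k positively correlating genes with ``r >= r_min`` and the
top-k negatively correlating genes with ``r <= -r_min`` — two separate
rank-ordered lists, mirroring how such drug-sensitivity signatures are
conventionally tabulated.

Genes with fewer than three usable observations or zero expression variance
cannot carry a correlation and are excluded (counted and logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .defaults import K_SIGNATURE, R_MIN
from .exceptions import DataError, ValidationError

__all__ = [
    "SignatureSelection",
    "align_panel",
    "correlate_genes",
    "select_signature",
]

logger = logging.getLogger(__name__)

MIN_SHARED_CELL_LINES = 4
MIN_OBS_PER_GENE = 3


def align_panel(panel: pd.DataFrame, response: pd.Series,
                min_shared: int = MIN_SHARED_CELL_LINES):
    """Restrict panel and response to their shared cell lines.

    The canonical cell-line order is the response order (so every downstream
    artifact — dendrogram, partition, contingency table — is cross-referable
    to the response file). Unmatched identifiers on either side are logged.
    """
    panel_cells = set(panel.columns)
    shared = [c for c in response.index if c in panel_cells]
    if len(shared) < min_shared:
        raise DataError(
            f"only {len(shared)} cell lines shared between panel and response "
            f"(need >= {min_shared})")
    dropped_panel = sorted(panel_cells - set(shared))
    dropped_response = sorted(set(response.index) - set(shared))
    for name, dropped in (("panel", dropped_panel),
                          ("response", dropped_response)):
        if dropped:
            logger.warning("align_panel: %d unmatched %s cell line(s): %s",
                           len(dropped), name, ", ".join(dropped))
    return panel.loc[:, shared], response.loc[shared]


def correlate_genes(panel: pd.DataFrame, response: pd.Series) -> pd.DataFrame:
    """Per-gene Pearson r against the response, pairwise-complete.

    Returns a DataFrame indexed by gene_id with columns ``r`` and ``n_used``,
    in panel row order. Excluded genes (zero variance or n_used < 3) are
    absent; their ids are recorded in ``result.attrs["excluded_gene_ids"]``.
    """
    if list(panel.columns) != list(response.index):
        panel, response = align_panel(panel, response)
    X = panel.to_numpy(dtype=float)
    y = response.to_numpy(dtype=float)
    mask = np.isfinite(X) & np.isfinite(y)[None, :]
    n_used = mask.sum(axis=1)

    Xm = np.where(mask, X, 0.0)
    Ym = np.where(mask, y[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        safe_n = np.maximum(n_used, 1)
        mx = Xm.sum(axis=1) / safe_n
        my = Ym.sum(axis=1) / safe_n
        dx = np.where(mask, X - mx[:, None], 0.0)
        dy = np.where(mask, y[None, :] - my[:, None], 0.0)
        sxx = (dx * dx).sum(axis=1)
        syy = (dy * dy).sum(axis=1)
        sxy = (dx * dy).sum(axis=1)
        r = sxy / np.sqrt(sxx * syy)

    valid = (n_used >= MIN_OBS_PER_GENE) & (sxx > 0) & (syy > 0)
    excluded = panel.index[~valid]
    if len(excluded) == len(panel.index):
        raise DataError("all genes excluded (zero variance or too few "
                        "pairwise-complete observations)")
    if len(excluded):
        logger.warning("correlate_genes: excluded %d gene(s) with zero "
                       "variance or < %d observations", len(excluded),
                       MIN_OBS_PER_GENE)
    records = pd.DataFrame(
        {"r": np.clip(r[valid], -1.0, 1.0), "n_used": n_used[valid]},
        index=panel.index[valid])
    records.index.name = "gene_id"
    records.attrs["n_excluded"] = int(len(excluded))
    records.attrs["excluded_gene_ids"] = list(excluded)
    return records


@dataclass
class SignatureSelection:
    """Rank-ordered positively / negatively correlating gene lists.

    ``top_positive`` is sorted by descending r (all r >= r_min),
    ``top_negative`` by ascending r (all r <= -r_min); ties broken by
    gene_id. Each holds columns ``r``, ``n_used`` and ``rank`` (1-based).
    """

    top_positive: pd.DataFrame
    top_negative: pd.DataFrame
    k: int = K_SIGNATURE
    r_min: float = R_MIN
    warnings: list = field(default_factory=list)

    @property
    def gene_ids(self) -> list:
        """Signature gene ids, positive list first."""
        return list(self.top_positive.index) + list(self.top_negative.index)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: gene_id, r, direction (pos/neg), rank."""
        parts = []
        for direction, df in (("pos", self.top_positive),
                              ("neg", self.top_negative)):
            part = df.reset_index()[["gene_id", "r"]]
            part["direction"] = direction
            part["rank"] = np.arange(1, len(part) + 1)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def select_signature(records: pd.DataFrame, k: int = K_SIGNATURE,
                     r_min: float = R_MIN) -> SignatureSelection:
    """Select the top-k genes per direction passing the |r| threshold."""
    if k <= 0:
        raise ValidationError(f"k: must be a positive count, got {k}")
    if not (0.0 <= r_min < 1.0):
        raise ValidationError(f"r_min: must be in [0, 1), got {r_min}")
    if records.empty:
        raise DataError("records: no gene correlations to select from")

    work = records.reset_index()
    pos = (work[work["r"] >= r_min]
           .sort_values(["r", "gene_id"], ascending=[False, True])
           .head(k).set_index("gene_id"))
    neg = (work[work["r"] <= -r_min]
           .sort_values(["r", "gene_id"], ascending=[True, True])
           .head(k).set_index("gene_id"))
    for df in (pos, neg):
        df["rank"] = np.arange(1, len(df) + 1)

    warnings = []
    for name, df in (("positive", pos), ("negative", neg)):
        if len(df) < k:
            msg = (f"only {len(df)} {name} gene(s) pass |r| >= {r_min} "
                   f"(requested {k})")
            warnings.append(msg)
            logger.warning("select_signature: %s", msg)
    return SignatureSelection(top_positive=pos, top_negative=neg, k=k,
                              r_min=r_min, warnings=warnings)
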