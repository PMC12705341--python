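"""Tertiary lymphoid structure (TLS) quantification.

Two complementary read-outs:

- an expression-based TLS signature score — the per-sample mean of
  gene-wise z-scores over a user-supplied TLS marker gene set,
- a spatial count of TLS from multiplex-immunofluorescence cell tables: a
  TLS is an aggregate of more than 100 CD20+ CD45+ PanCK- B cells
  surrounded by CD20- CD45+ PanCK- immune cells, and the per-sample
  enrichment is the count normalised by the valid stained tissue area
  (TLS per mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN

__all__ = [
    "SpatialCellTable",
    "TLSResult",
    "tls_signature_score",
    "detect_tls",
    "compare_tls_density",
]


@dataclass
class SpatialCellTable:
    """Cell coordinates (µm) with CD20/CD45/PanCK phenotype flags.

    ``valid_area`` is the valid stained tissue area in mm², supplied as a
    precomputed input from upstream image quality control.
    """

    cells: pd.DataFrame  # columns x_um, y_um, cd20, cd45, panck (0/1)
    valid_area: float

    def __post_init__(self) -> None:
        required = {"x_um", "y_um", "cd20", "cd45", "panck"}
        if not required.issubset(self.cells.columns):
            raise ValueError(f"cell table needs columns {sorted(required)}")
        if not np.isfinite(self.cells[["x_um", "y_um"]].to_numpy()).all():
            raise ValueError("coordinates must be finite")
        if self.valid_area <= 0:
            raise ValueError("valid_area must be positive (mm^2)")


@dataclass
class TLSResult:
    """Detected TLS count, density and per-structure detail."""

    n_tls: int
    density: float  # TLS per mm^2
    structures: list[dict] = field(default_factory=list)


def tls_signature_score(expression: pd.DataFrame, tls_genes) -> pd.Series:
    """Mean gene-wise z-score of the TLS marker genes, per sample.

    ``expression`` is the normalised-log matrix (genes x samples). Each
    signature gene is z-scored across samples (genes with zero variance
    contribute 0) and the per-sample average over the signature is
    returned. Missing signature genes are ignored; an entirely absent
    signature is an error.
    """
    present = [g for g in tls_genes if g in expression.index]
    if not present:
        raise ValueError("none of the signature genes are present")
    x = expression.loc[present].to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.divide(x - mu, sd, out=np.zeros_like(x), where=sd > 0)
    return pd.Series(z.mean(axis=0), index=expression.columns, name="tls_score")


def detect_tls(
    table: SpatialCellTable,
    cluster_radius: float = 30.0,
    min_cells: int = 101,
    ring_radius: float = 50.0,
    min_ring_fraction: float = 0.5,
    min_neighbors: int = 5,
    n_angular_bins: int = 36,
) -> TLSResult:
    """Count TLS in a spatial cell table.

    B-cell-phenotype cells (CD20+ CD45+ PanCK-) are clustered with DBSCAN
    (eps = ``cluster_radius`` µm). A cluster is a TLS when it has at least
    ``min_cells`` members (default 101, i.e. strictly more than 100 cells)
    and its surrounding annulus — width ``ring_radius`` µm beyond the
    cluster's 95th-percentile radius — has ring-phenotype cells
    (CD20- CD45+ PanCK-) covering at least ``min_ring_fraction`` of its
    angular extent. Density is the count divided by the valid area.
    """
    cells = table.cells
    is_b = (cells.cd20 == 1) & (cells.cd45 == 1) & (cells.panck == 0)
    is_ring = (cells.cd20 == 0) & (cells.cd45 == 1) & (cells.panck == 0)
    b_xy = cells.loc[is_b, ["x_um", "y_um"]].to_numpy(float)
    ring_xy = cells.loc[is_ring, ["x_um", "y_um"]].to_numpy(float)

    structures: list[dict] = []
    if len(b_xy) >= min_neighbors:
        labels = DBSCAN(eps=cluster_radius, min_samples=min_neighbors).fit_predict(b_xy)
        for lab in np.unique(labels):
            if lab < 0:
                continue
            members = b_xy[labels == lab]
            if len(members) < min_cells:
                continue
            centroid = members.mean(axis=0)
            dist = np.linalg.norm(members - centroid, axis=1)
            r_cluster = float(np.quantile(dist, 0.95))
            coverage = 0.0
            if len(ring_xy):
                delta = ring_xy - centroid
                rd = np.linalg.norm(delta, axis=1)
                in_ring = (rd > r_cluster) & (rd <= r_cluster + ring_radius)
                if in_ring.any():
                    ang = np.arctan2(delta[in_ring, 1], delta[in_ring, 0])
                    bins = np.floor((ang + np.pi) / (2 * np.pi) * n_angular_bins)
                    bins = np.clip(bins.astype(int), 0, n_angular_bins - 1)
                    coverage = np.unique(bins).size / n_angular_bins
            if coverage >= min_ring_fraction:
                structures.append(
                    {
                        "n_cells": int(len(members)),
                        "centroid": (float(centroid[0]), float(centroid[1])),
                        "radius_um": r_cluster,
                        "ring_coverage": float(coverage),
                    }
                )

    n = len(structures)
    return TLSResult(n_tls=n, density=n / table.valid_area, structures=structures)


def compare_tls_density(densities, labels) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test on per-sample TLS densities."""
    y = np.asarray(labels)
    d = np.asarray(densities, float)
    g1, g0 = d[y == 1], d[y == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("need at least 2 samples per group")
    res = stats.ttest_ind(g1, g0)
    return float(res.statistic), float(res.pvalue)
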