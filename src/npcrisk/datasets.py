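"""Cohort data containers and plain-text I/O.

A :class:`CohortDataset` bundles everything the pipeline needs for one
cohort: the raw count matrix (genes x samples), its normalised-log
transform, the binary metastasis labels, and optional clinical and
survival tables indexed by sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortDataset"]


@dataclass
class CohortDataset:
    """One cohort's expression matrix with labels and clinical annotations.

    Parameters
    ----------
    counts : pandas.DataFrame
        Raw nonnegative integer counts, genes as rows, samples as columns.
    labels : pandas.Series
        Binary metastasis status per sample (1 = MET, 0 = non-MET), indexed
        like ``counts.columns``.
    clinical : pandas.DataFrame, optional
        Per-sample covariate table (e.g. ``relapse``, ``bmi_ge_23``,
        ``ebv_ge_4000``, ``tnm_eq_4``) indexed by sample.
    survival : pandas.DataFrame, optional
        Columns ``time`` (months) and ``event`` (binary), indexed by sample.
    name : str
        Cohort identifier used in reports.

    Notes
    -----
    ``normalised_log`` is the expression scale used throughout the risk
    models: counts are library-normalised by median-of-ratios size factors
    and transformed as ``log10(normalised count + 1)``. It is computed
    lazily on first access and cached.
    """

    counts: pd.DataFrame
    labels: pd.Series
    clinical: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None
    name: str = "cohort"
    _normalised_log: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.counts.columns)
        if self.labels.isna().any():
            raise ValueError("every sample needs a nonmissing MET/non-MET label")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def normalised_log(self) -> pd.DataFrame:
        if self._normalised_log is None:
            from npcrisk.screening import normalise

            self._normalised_log = normalise(self.counts)
        return self._normalised_log

    def expression(self, genes) -> pd.DataFrame:
        """Normalised-log expression for a gene subset (genes x samples)."""
        missing = [g for g in genes if g not in self.counts.index]
        if missing:
            raise KeyError(f"genes absent from cohort {self.name!r}: {missing[:5]}")
        return self.normalised_log.loc[list(genes)]

    # ------------------------------------------------------------------ I/O

    def to_dir(self, path: str | Path) -> None:
        """Write counts TSV, clinical CSV and survival CSV under ``path``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(path / "counts.tsv", sep="\t")
        self.labels.rename("met").to_csv(path / "labels.csv")
        if self.clinical is not None:
            self.clinical.to_csv(path / "clinical.csv")
        if self.survival is not None:
            self.survival.to_csv(path / "survival.csv")

    @classmethod
    def from_dir(cls, path: str | Path, name: str | None = None) -> "CohortDataset":
        path = Path(path)
        counts = pd.read_csv(path / "counts.tsv", sep="\t", index_col=0)
        labels = pd.read_csv(path / "labels.csv", index_col=0)["met"]
        clinical = survival = None
        if (path / "clinical.csv").exists():
            clinical = pd.read_csv(path / "clinical.csv", index_col=0)
        if (path / "survival.csv").exists():
            survival = pd.read_csv(path / "survival.csv", index_col=0)
        return cls(counts, labels, clinical, survival, name=name or path.name)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into ``{set name: [genes]}``."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
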