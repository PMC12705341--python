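"""Synthetic multi-cohort data with known ground truth.

The generator emulates the structure of the study this pipeline targets:
three bulk RNA-seq cohorts of pre-treatment NPC biopsies — two training
cohorts (77 samples with 39 MET / 38 non-MET; 30 with 13/17) and one
testing cohort (70 with 23/47) — with negative-binomial counts, planted
differentially expressed marker genes (15 up / 14 down in MET), gene-wise
multiplicative cohort effects standing in for site/batch differences,
binary clinical covariates whose odds shift with outcome, and exponential
survival times whose log-hazard is linear in a latent per-sample risk.

It also produces known-proportion bulk mixtures for validating the
deconvolution module and spatial cell maps with planted tertiary lymphoid
structures (TLS) for validating the spatial counter. Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from npcrisk.datasets import CohortDataset

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohorts",
    "simulate_mixtures",
    "simulate_spatial_map",
]

#: baseline log-odds of each binary clinical indicator among non-MET samples
_BASE_LOGODDS = {
    "bmi_ge_23": 0.0,
    "ebv_ge_4000": -0.6,
    "tnm_eq_4": -1.1,
    "relapse": -0.8,
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the multi-cohort generator.

    Defaults reproduce the target study's design: cohort sizes
    (39/38, 13/17, 23/47), 15 up- and 14 down-regulated marker genes at
    |log2FC| = 1 (comfortably above the 0.5 screening threshold),
    negative-binomial dispersion 0.1, and gene-wise cohort effects of
    SD 0.3 on the log2 scale.
    """

    n_genes: int = 2000
    cohort_sizes: list[tuple[int, int]] = field(
        default_factory=lambda: [(39, 38), (13, 17), (23, 47)]
    )
    n_de_genes_up: int = 15
    n_de_genes_down: int = 14
    de_log2fc: float = 1.0
    nb_dispersion: float = 0.1
    cohort_effect_sd: float = 0.3
    library_size_range: tuple[float, float] = (5e5, 1.5e6)
    clinical_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {
            "bmi_ge_23": -1.0,
            "ebv_ge_4000": 1.2,
            "tnm_eq_4": 1.5,
            "relapse": 1.0,
        }
    )
    survival_baseline_hazard: float = 0.01  # events per month
    survival_score_loghazard: float = 1.2
    censor_window: float = 120.0  # months
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or any(
            n <= 0 for pair in self.cohort_sizes for n in pair
        ):
            raise ValueError("all sample and gene counts must be positive")
        if self.n_de_genes_up + self.n_de_genes_down > self.n_genes:
            raise ValueError("planted DE genes exceed the gene count")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.cohort_effect_sd < 0:
            raise ValueError("cohort_effect_sd must be >= 0")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must satisfy 0 < min <= max")


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    de_gene_signs: dict[str, int] = field(default_factory=dict)
    true_risk: dict[str, np.ndarray] = field(default_factory=dict)
    mixture_proportions: np.ndarray | None = None
    n_tls: int | None = None

    def __post_init__(self) -> None:
        if any(s not in (-1, 1) for s in self.de_gene_signs.values()):
            raise ValueError("DE gene signs must be +1 or -1")


def simulate_cohorts(config: SimulationConfig) -> tuple[list[CohortDataset], GroundTruth]:
    """Draw the multi-cohort expression / clinical / survival data.

    Counts for gene g, sample s in cohort c are negative-binomial with
    mean ``base_g * 2^(sign_g * de_log2fc * MET_s) * 2^(N(0, cohort_sd))
    * library_factor_s`` and variance ``mu + mu^2 * dispersion``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_de = config.n_de_genes_up + config.n_de_genes_down
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    signs = np.concatenate(
        [np.ones(config.n_de_genes_up), -np.ones(config.n_de_genes_down)]
    ).astype(int)
    de_signs = {genes[i]: int(s) for i, s in zip(de_idx, signs)}
    sign_vec = np.zeros(config.n_genes)
    sign_vec[de_idx] = signs

    # per-gene baseline mean expression (log-normal, heavy-tailed like real data)
    base = rng.lognormal(mean=np.log(60.0), sigma=1.2, size=config.n_genes)

    truth = GroundTruth(de_gene_signs=de_signs)
    cohorts: list[CohortDataset] = []
    r = 1.0 / config.nb_dispersion  # NB size parameter

    for c, (n_met, n_non) in enumerate(config.cohort_sizes):
        n = n_met + n_non
        labels = np.concatenate([np.ones(n_met), np.zeros(n_non)]).astype(int)
        sample_ids = [f"C{c + 1}S{j:03d}" for j in range(n)]

        cohort_fc = 2.0 ** rng.normal(0.0, config.cohort_effect_sd, config.n_genes)
        lib = rng.uniform(*config.library_size_range, size=n)
        lib_factor = lib / base.sum()

        mu = (
            base[:, None]
            * cohort_fc[:, None]
            * 2.0 ** (sign_vec[:, None] * config.de_log2fc * labels[None, :])
            * lib_factor[None, :]
        )
        counts = rng.negative_binomial(r, r / (r + mu))

        clinical = {}
        for cov, effect in config.clinical_effect_sizes.items():
            logodds = _BASE_LOGODDS.get(cov, 0.0) + effect * labels
            p = 1.0 / (1.0 + np.exp(-logodds))
            clinical[cov] = rng.binomial(1, p)
        clinical_df = pd.DataFrame(clinical, index=sample_ids)

        # latent risk on the calibrated-score scale: non-MET ~ 0, MET ~ 1
        risk = labels + rng.normal(0.0, 0.25, size=n)
        hazard = config.survival_baseline_hazard * np.exp(
            config.survival_score_loghazard * (risk - 0.5)
        )
        t_event = rng.exponential(1.0 / hazard)
        t_censor = rng.uniform(0.0, config.censor_window, size=n)
        survival_df = pd.DataFrame(
            {
                "time": np.minimum(t_event, t_censor),
                "event": (t_event <= t_censor).astype(int),
            },
            index=sample_ids,
        )

        name = f"cohort{c + 1}"
        truth.true_risk[name] = risk
        cohorts.append(
            CohortDataset(
                counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
                labels=pd.Series(labels, index=sample_ids, name="met"),
                clinical=clinical_df,
                survival=survival_df,
                name=name,
            )
        )

    return cohorts, truth


def simulate_mixtures(
    reference,
    proportions,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Known-proportion bulk profiles from a deconvolution reference.

    Each bulk profile is the proportion-weighted sum of the reference mean
    profiles plus Gaussian noise with per-gene SD
    ``noise_sd * sqrt(sum_j P_j * var_ij)``; at ``noise_sd = 0`` the
    mixture is exactly linear in the proportions.

    Returns a genes x mixtures array.
    """
    P = np.atleast_2d(np.asarray(proportions, float))
    if P.shape[1] != reference.n_types:
        raise ValueError("proportion dimension does not match reference cell types")
    if (P < -1e-12).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each proportion vector must lie on the simplex")
    rng = np.random.default_rng(seed)
    mean = reference.mean_expr.to_numpy(float)  # genes x types
    var = reference.var_expr.to_numpy(float)
    bulk = mean @ P.T
    if noise_sd > 0:
        bulk = bulk + rng.normal(0.0, 1.0, bulk.shape) * noise_sd * np.sqrt(var @ P.T)
    return bulk


def simulate_spatial_map(
    n_tls: int,
    cells_per_tls: int = 150,
    ring_width: float = 50.0,
    background_density: float = 500.0,
    area: float = 4.0,
    seed: int | None = None,
    cluster_sd: float = 30.0,
    ring_cells_per_tls: int | None = None,
):
    """Spatial cell map with planted TLS clusters.

    Each TLS is a Gaussian cluster (SD ``cluster_sd`` µm) of
    CD20+ CD45+ PanCK- B cells surrounded by an annulus (width
    ``ring_width`` µm) of CD20- CD45+ PanCK- cells; background cells
    (mostly PanCK+ tumour) are scattered uniformly over a square tissue of
    ``area`` mm². Centres are kept at least 4x the effective cluster
    radius apart.

    Returns ``(SpatialCellTable, GroundTruth)``.
    """
    from npcrisk.tls import SpatialCellTable

    if n_tls < 0 or area <= 0:
        raise ValueError("need n_tls >= 0 and area > 0")
    rng = np.random.default_rng(seed)
    side = np.sqrt(area) * 1000.0  # µm
    r_eff = 3.0 * cluster_sd
    margin = r_eff + ring_width

    centres: list[np.ndarray] = []
    attempts = 0
    while len(centres) < n_tls:
        attempts += 1
        if attempts > 2000 * max(n_tls, 1):
            raise ValueError(
                f"cannot pack {n_tls} TLS of radius {r_eff:.0f} um into {area} mm^2"
            )
        cand = rng.uniform(margin, side - margin, size=2)
        if all(np.linalg.norm(cand - c) >= 4.0 * r_eff for c in centres):
            centres.append(cand)

    rows = []
    n_ring = ring_cells_per_tls if ring_cells_per_tls is not None else cells_per_tls
    r_core = 2.0 * cluster_sd  # aggregates are compact: truncate at 2 SD
    for centre in centres:
        placed = 0
        while placed < cells_per_tls:
            draw = rng.normal(centre, cluster_sd, size=(cells_per_tls, 2))
            keep = draw[np.linalg.norm(draw - centre, axis=1) <= r_core]
            for x, y in keep[: cells_per_tls - placed]:
                rows.append((x, y, 1, 1, 0))
            placed += min(len(keep), cells_per_tls - placed)
        theta = rng.uniform(0, 2 * np.pi, n_ring)
        rad = rng.uniform(r_core, r_core + ring_width, n_ring)
        for t, rr in zip(theta, rad):
            rows.append((centre[0] + rr * np.cos(t), centre[1] + rr * np.sin(t), 0, 1, 0))

    n_bg = rng.poisson(background_density * area)
    xy = rng.uniform(0, side, size=(n_bg, 2))
    # background composition: PanCK+ tumour, lone CD45+ cells, sparse B cells
    kinds = rng.choice(3, size=n_bg, p=[0.73, 0.25, 0.02])
    pheno = {0: (0, 0, 1), 1: (0, 1, 0), 2: (1, 1, 0)}
    for (x, y), k in zip(xy, kinds):
        rows.append((x, y, *pheno[k]))

    cells = pd.DataFrame(rows, columns=["x_um", "y_um", "cd20", "cd45", "panck"])
    table = SpatialCellTable(cells=cells, valid_area=area)
    return table, GroundTruth(n_tls=n_tls)
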