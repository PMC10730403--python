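"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* ``simulate_sc_experiment`` — gene-wise negative-binomial counts per cell
  type x condition with cell-specific size factors, planted multi-cell-type
  up-regulated programs (the iron-response analogue) and a senescence-like
  subpopulation; mitochondrial and ribosomal genes are flagged by symbol
  prefix so QC behaves as on real data.
* ``simulate_patient_cohort`` — per-patient double-positive cell counts under
  a beta-binomial with additive study effects on the logit scale.
* ``simulate_multiecho_phantom`` — mono-exponential multi-echo decay volumes
  with additive Gaussian noise and concentric cortex/medulla ROIs.

Every generator is a pure function of (config, seed): the seed inside the
config fully determines the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .io_formats import CellAnnotation, CountMatrix
from .relaxometry import EchoSeries, ROIMask

__all__ = [
    "PlantedProgram",
    "ScSimConfig",
    "CohortSimConfig",
    "PhantomConfig",
    "GroundTruth",
    "simulate_sc_experiment",
    "simulate_patient_cohort",
    "simulate_multiecho_phantom",
]


@dataclass
class PlantedProgram:
    """A gene program up-shifted by ``log2fc`` in the given cell types and
    conditions."""

    genes: list[str]
    log2fc: float
    cell_types: list[str]
    conditions: list[str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc):
            raise ValueError("log2fc must be finite")


def _default_programs() -> list[PlantedProgram]:
    # Emulates the iron-exposure design: a consensus program induced in 6 of
    # the 10 major cell types two days post-exposure, and a minor program
    # confined to 2 cell types (below the consensus support rule).
    consensus = PlantedProgram(
        genes=[f"Ias{i:03d}" for i in range(1, 61)],
        log2fc=1.5,
        cell_types=[f"celltype{i:02d}" for i in range(1, 7)],
        conditions=["iron_d2"],
    )
    minor = PlantedProgram(
        genes=[f"Min{i:03d}" for i in range(1, 31)],
        log2fc=1.5,
        cell_types=["celltype01", "celltype02"],
        conditions=["iron_d2"],
    )
    return [consensus, minor]


@dataclass
class ScSimConfig:
    n_cell_types: int = 10
    cells_per_type_per_condition: int = 150
    n_genes: int = 1000
    conditions: tuple[str, ...] = ("control", "iron_d2")
    nb_dispersion: float = 0.3
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    planted_programs: list[PlantedProgram] = field(default_factory=_default_programs)
    senescence_genes: list[str] = field(
        default_factory=lambda: [f"Sen{i:03d}" for i in range(1, 21)]
    )
    senescence_log2fc: float = 2.0
    senescence_fraction: float = 0.10
    senescence_conditions: tuple[str, ...] = ("iron_d2",)
    mito_gene_fraction: float = 0.03
    mito_beta: tuple[float, float] = (2.0, 30.0)  # per-cell mito-content Beta
    ribo_gene_fraction: float = 0.05
    libsize_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cell_types, self.cells_per_type_per_condition, self.n_genes) <= 0:
            raise ValueError("dimensions must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.senescence_fraction <= 1:
            raise ValueError("senescence_fraction must be in [0, 1]")
        planted = [g for p in self.planted_programs for g in p.genes]
        overlap = set(planted) & set(self.senescence_genes)
        if len(set(planted)) != len(planted) or overlap:
            raise ValueError("planted gene lists must be disjoint")

    @property
    def cell_types(self) -> list[str]:
        return [f"celltype{i:02d}" for i in range(1, self.n_cell_types + 1)]


@dataclass
class CohortSimConfig:
    n_patients_per_condition: int = 20
    cells_per_patient: tuple[int, int] = (300, 800)
    conditions: tuple[str, ...] = ("control", "fibrotic")
    study_labels: tuple[str, ...] = ("study1", "study2", "study3")
    study_effects: tuple[float, ...] = (0.0, 0.3, -0.3)  # logit scale
    baseline_logit: float = -2.2  # ~10% double-positive at baseline
    condition_effect: float = 1.0
    rho: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("overdispersion rho must be in [0, 1)")
        if len(self.study_effects) != len(self.study_labels):
            raise ValueError("one study effect per study label")
        if self.n_patients_per_condition <= 0:
            raise ValueError("need at least one patient per condition")
        lo, hi = self.cells_per_patient
        if not 0 < lo <= hi:
            raise ValueError("cells_per_patient must be a positive (low, high) range")


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, ...] = (32, 32, 32)
    # concentric layout: medulla core inside a cortex shell, background 0
    cortex_radius: float = 0.45  # fraction of the in-plane half-width
    medulla_radius: float = 0.25
    r2star_by_region: dict = field(
        default_factory=lambda: {"cortex": 40.0, "medulla": 20.0}
    )
    s0_by_region: dict = field(
        default_factory=lambda: {"cortex": 1000.0, "medulla": 1000.0}
    )
    te_ms: tuple[float, ...] = tuple(np.linspace(3.5, 48.5, 10))
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms)
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("TE must be positive and strictly increasing")
        if any(v < 0 for v in self.r2star_by_region.values()):
            raise ValueError("R2* must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside each simulated dataset.

    Only the fields relevant to the emitting generator are populated.
    """

    de_truth: pd.DataFrame | None = None  # gene x cell_type x condition log2fc
    senescent_cell_ids: list[str] | None = None
    cohort: pd.DataFrame | None = None  # per patient: true mean fraction
    cohort_params: dict | None = None
    r2star_field: np.ndarray | None = None
    s0_field: np.ndarray | None = None
    config: dict | None = None

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"config": self.config}
        if self.de_truth is not None:
            self.de_truth.to_csv(out / "de_truth.csv", index=False)
        if self.senescent_cell_ids is not None:
            meta["senescent_cell_ids"] = list(self.senescent_cell_ids)
        if self.cohort is not None:
            self.cohort.to_csv(out / "cohort_truth.csv", index=False)
        if self.cohort_params is not None:
            meta["cohort_params"] = self.cohort_params
        if self.r2star_field is not None:
            np.savez(
                out / "phantom_truth.npz",
                r2star=self.r2star_field,
                s0=self.s0_field,
            )
        (out / "ground_truth.json").write_text(json.dumps(meta, indent=2, default=str))

    @classmethod
    def load(cls, out_dir: str | Path) -> "GroundTruth":
        out = Path(out_dir)
        meta = json.loads((out / "ground_truth.json").read_text())
        gt = cls(config=meta.get("config"))
        gt.senescent_cell_ids = meta.get("senescent_cell_ids")
        gt.cohort_params = meta.get("cohort_params")
        if (out / "de_truth.csv").exists():
            gt.de_truth = pd.read_csv(out / "de_truth.csv")
        if (out / "cohort_truth.csv").exists():
            gt.cohort = pd.read_csv(out / "cohort_truth.csv")
        if (out / "phantom_truth.npz").exists():
            data = np.load(out / "phantom_truth.npz")
            gt.r2star_field = data["r2star"]
            gt.s0_field = data["s0"]
        return gt


# ---------------------------------------------------------------------------
# Single-cell experiment


def _gene_names(config: ScSimConfig) -> list[str]:
    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    n_ribo = int(round(config.ribo_gene_fraction * config.n_genes))
    planted = [g for p in config.planted_programs for g in p.genes]
    named = planted + list(config.senescence_genes)
    n_background = config.n_genes - n_mito - n_ribo - len(named)
    if n_background < 0:
        raise ValueError("n_genes too small for the configured programs")
    names = (
        named
        + [f"G{i:05d}" for i in range(1, n_background + 1)]
        + [f"mt-S{i:02d}" for i in range(1, n_mito + 1)]
        + [f"Rps{i:02d}" if i % 2 else f"Rpl{i:02d}" for i in range(1, n_ribo + 1)]
    )
    return names


def simulate_sc_experiment(
    config: ScSimConfig | None = None,
) -> tuple[CountMatrix, CellAnnotation, GroundTruth]:
    """Draw a single-cell count matrix with planted programs.

    Counts are gene-wise negative-binomial (Gamma-Poisson) with log-normal
    baseline means, cell-specific log-normal size factors, and log-mean
    shifts of ``log2fc`` for planted (gene, cell type, condition) triples.
    Mitochondrial content per cell follows the configured Beta; ribosomal
    genes share the baseline model and exist so QC has something to drop.
    """
    config = config or ScSimConfig()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    cell_types = config.cell_types
    n_cells = (
        config.n_cell_types
        * len(config.conditions)
        * config.cells_per_type_per_condition
    )

    ct_labels = np.repeat(
        np.tile(cell_types, len(config.conditions)),
        config.cells_per_type_per_condition,
    )
    cond_labels = np.repeat(
        list(config.conditions),
        config.n_cell_types * config.cells_per_type_per_condition,
    )
    cell_ids = [f"cell{i:06d}" for i in range(1, n_cells + 1)]

    base_mean = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, size=len(genes)
    )
    size_factor = rng.lognormal(0.0, config.libsize_log_sd, size=n_cells)

    gene_index = {g: i for i, g in enumerate(genes)}
    fold = np.ones((len(genes), n_cells))
    truth_rows = []
    for prog in config.planted_programs:
        g_idx = [gene_index[g] for g in prog.genes]
        cell_mask = np.isin(ct_labels, prog.cell_types) & np.isin(
            cond_labels, prog.conditions
        )
        fold[np.ix_(g_idx, np.flatnonzero(cell_mask))] *= 2.0**prog.log2fc
        for g in prog.genes:
            for ct in prog.cell_types:
                for cond in prog.conditions:
                    truth_rows.append(
                        {"gene": g, "cell_type": ct, "condition": cond,
                         "true_log2fc": prog.log2fc}
                    )

    # senescence-like subpopulation within the affected conditions
    sen_pool = np.flatnonzero(np.isin(cond_labels, config.senescence_conditions))
    n_sen = int(round(config.senescence_fraction * sen_pool.size))
    sen_cells = np.sort(rng.choice(sen_pool, size=n_sen, replace=False))
    sen_idx = [gene_index[g] for g in config.senescence_genes]
    if n_sen:
        fold[np.ix_(sen_idx, sen_cells)] *= 2.0**config.senescence_log2fc

    mu = base_mean[:, None] * size_factor[None, :] * fold

    # rescale mitochondrial genes to hit the drawn per-cell mito fraction
    mito_mask = np.array([g.startswith("mt-") for g in genes])
    if mito_mask.any():
        target = rng.beta(*config.mito_beta, size=n_cells)
        non_mito_total = mu[~mito_mask].sum(axis=0)
        mito_total = mu[mito_mask].sum(axis=0)
        scale = np.where(
            mito_total > 0, target / (1 - target) * non_mito_total / mito_total, 1.0
        )
        mu[mito_mask] *= scale[None, :]

    r = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(np.int64)

    matrix = CountMatrix(sp.csr_matrix(counts), genes, cell_ids)
    annot = CellAnnotation(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "cell_type_level1": ct_labels,
                "condition": cond_labels,
                "donor_id": ["mouse1"] * n_cells,
                "study_id": ["simulated"] * n_cells,
            }
        )
    )
    truth = GroundTruth(
        de_truth=pd.DataFrame(
            truth_rows, columns=["gene", "cell_type", "condition", "true_log2fc"]
        ),
        senescent_cell_ids=[cell_ids[i] for i in sen_cells],
        config=_jsonable(config),
    )
    return matrix, annot, truth


# ---------------------------------------------------------------------------
# Patient cohort


def simulate_patient_cohort(
    config: CohortSimConfig | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-patient double-positive counts under a beta-binomial.

    Each patient's success probability p is Beta-distributed with mean
    ``logit^-1(b0 + b_cond * cond + b_study)`` and overdispersion rho
    (rho = 0 degenerates to p = mean); y ~ Binomial(n, p).
    """
    config = config or CohortSimConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    truth_rows = []
    patient = 0
    lo, hi = config.cells_per_patient
    for cond_idx, cond in enumerate(config.conditions):
        for i in range(config.n_patients_per_condition):
            study_i = patient % len(config.study_labels)
            eta = (
                config.baseline_logit
                + config.condition_effect * (1 if cond_idx > 0 else 0)
                + config.study_effects[study_i]
            )
            mu = float(expit(eta))
            if config.rho > 0:
                a = mu * (1 - config.rho) / config.rho
                b = (1 - mu) * (1 - config.rho) / config.rho
                p = float(rng.beta(a, b))
            else:
                p = mu
            n = int(rng.integers(lo, hi + 1))
            y = int(rng.binomial(n, p))
            patient += 1
            donor = f"donor{patient:04d}"
            rows.append(
                {
                    "donor_id": donor,
                    "n_cells": n,
                    "n_double_pos": y,
                    "condition": cond,
                    "study_id": config.study_labels[study_i],
                }
            )
            truth_rows.append({"donor_id": donor, "true_mean": mu, "true_p": p})
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        cohort=pd.DataFrame(truth_rows),
        cohort_params={
            "baseline_logit": config.baseline_logit,
            "condition_effect": config.condition_effect,
            "study_effects": list(config.study_effects),
            "rho": config.rho,
        },
        config=_jsonable(config),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Multi-echo phantom


def _region_fields(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    shape = config.grid_shape
    nx, ny = shape[0], shape[1]
    xx, yy = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), indexing="ij"
    )
    radius = np.sqrt(xx**2 + yy**2)
    plane = np.zeros((nx, ny), dtype=np.int16)
    plane[radius <= 2 * config.cortex_radius] = 1  # cortex shell
    plane[radius <= 2 * config.medulla_radius] = 2  # medulla core
    labels = np.broadcast_to(
        plane.reshape(nx, ny, *([1] * (len(shape) - 2))), shape
    ).copy()
    r2 = np.zeros(shape)
    s0 = np.zeros(shape)
    r2[labels == 1] = config.r2star_by_region["cortex"]
    r2[labels == 2] = config.r2star_by_region["medulla"]
    s0[labels == 1] = config.s0_by_region["cortex"]
    s0[labels == 2] = config.s0_by_region["medulla"]
    return labels, r2, s0


def simulate_multiecho_phantom(
    config: PhantomConfig | None = None,
) -> tuple[EchoSeries, ROIMask, GroundTruth]:
    """Mono-exponential decay volumes: S(v, TE) = S0(v) exp(-R2*(v) TE) plus
    additive noise (none when sigma = 0)."""
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed)
    labels, r2star, s0 = _region_fields(config)
    te_s = np.asarray(config.te_ms) / 1000.0
    clean = s0[None] * np.exp(-r2star[None] * te_s.reshape(-1, *([1] * labels.ndim)))
    if config.noise_sigma > 0:
        if config.noise_model == "rician":
            re = clean + rng.normal(0, config.noise_sigma, clean.shape)
            im = rng.normal(0, config.noise_sigma, clean.shape)
            signal = np.sqrt(re**2 + im**2)
        else:
            signal = clean + rng.normal(0, config.noise_sigma, clean.shape)
    else:
        signal = clean
    series = EchoSeries(te_ms=np.asarray(config.te_ms), signal=signal)
    mask = ROIMask(labels=labels, label_names={1: "cortex", 2: "medulla"})
    truth = GroundTruth(r2star_field=r2star, s0_field=s0, config=_jsonable(config))
    return series, mask, truth


def _jsonable(config) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=lambda o: list(o) if hasattr(o, "__iter__") else str(o)))
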