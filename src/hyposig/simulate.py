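"""Synthetic cell-line and tumor-cohort generators with known ground truth.

Both generators work on the log2 scale and exponentiate at the end, so
downstream normalization and fold-change logic see realistic, strictly
positive signal values.  Generation is a pure function of the seed.

Cell-line model
---------------
Each probeset has a log-normal baseline.  A planted subset of
"hypoxia-responsive" probesets shifts between the paired normoxic and
hypoxic samples of each cell line: the per-line log2 shift is
``sign_j * effect_log2 + N(0, line_sd^2)``, with independent residual
log2 noise everywhere.  Non-planted probesets have zero expected shift.

Tumor-cohort model
------------------
A latent hypoxia indicator H ~ Bernoulli(hypoxia_fraction) shifts the
signature probesets upward by ``signature_shift_log2`` for H=1 and
leaves a weaker genome-wide footprint on the remaining probesets
(per-probeset signed shift with sd ``background_shift_sd``), reflecting
the broad transcriptional difference between hypoxic and non-hypoxic
tumors.  Survival times are exponential with hazard
``baseline_hazard * true_hr^H * exp(beta^T x)`` for binary covariates x
(MYCN amplification, INSS stage 4, age >= 1 year), with independent
exponential censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, PairedDesign
from .signature import Signature

__all__ = [
    "CellLineSimConfig",
    "CohortSimConfig",
    "simulate_cell_line_pairs",
    "simulate_tumor_cohort",
]


@dataclass
class CellLineSimConfig:
    n_lines: int = 11
    n_probesets: int = 2000
    n_responsive: int = 50
    effect_log2: float = 1.5
    line_sd: float = 0.3
    noise_sd: float = 0.5
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    up_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if not (0 <= self.n_responsive <= self.n_probesets):
            raise ValueError("n_responsive must be in [0, n_probesets]")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be >= 0")
        for name in ("line_sd", "noise_sd", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd == 0 and self.baseline_log2_sd == 0:
            raise ValueError("need some noise or baseline variation")


def simulate_cell_line_pairs(
    cfg: CellLineSimConfig,
) -> tuple[ExpressionMatrix, PairedDesign, set[str]]:
    """Paired normoxic/hypoxic profiles with a planted responsive subset.

    Returns the linear-scale matrix, the paired design, and the set of
    planted probeset ids.
    """
    rng = np.random.default_rng(cfg.seed)
    p, L = cfg.n_probesets, cfg.n_lines
    probesets = [f"PS{i:05d}" for i in range(p)]
    lines = [f"L{i + 1:02d}" for i in range(L)]
    planted_idx = rng.choice(p, size=cfg.n_responsive, replace=False)
    signs = np.ones(cfg.n_responsive) if cfg.up_only else rng.choice([-1.0, 1.0], size=cfg.n_responsive)

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=p)
    # per (planted probeset, line) log2 shift under hypoxia
    shift = np.zeros((p, L))
    shift[planted_idx, :] = (
        signs[:, None] * cfg.effect_log2 + rng.normal(0.0, cfg.line_sd, size=(cfg.n_responsive, L))
    )

    cols: dict[str, np.ndarray] = {}
    entries = []
    for li, line in enumerate(lines):
        nox = baseline + rng.normal(0.0, cfg.noise_sd, size=p)
        hyp = baseline + shift[:, li] + rng.normal(0.0, cfg.noise_sd, size=p)
        cols[f"{line}_N"] = nox
        cols[f"{line}_H"] = hyp
        entries.append((line, f"{line}_N", f"{line}_H"))

    log2_df = pd.DataFrame(cols, index=probesets)
    E = ExpressionMatrix(np.exp2(log2_df), scale="linear")
    design = PairedDesign(entries)
    truth = {probesets[i] for i in planted_idx}
    return E, design, truth


@dataclass
class CohortSimConfig:
    signature: Signature
    n_patients: int = 88
    n_probesets: int = 1000
    hypoxia_fraction: float = 0.24
    signature_shift_log2: float = 1.5
    background_shift_sd: float = 0.5
    noise_sd: float = 1.0
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    true_hr: float = 4.0
    baseline_hazard: float = 0.10
    censor_rate: float = 0.05
    covariate_prevalences: dict = field(
        default_factory=lambda: {"mycn": 0.182, "stage4": 0.455, "age_ge1": 0.716}
    )
    covariate_log_hrs: dict = field(default_factory=dict)
    round_decimals: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.signature) == 0:
            raise ValueError("signature must be non-empty")
        if not (0 < self.hypoxia_fraction < 1):
            raise ValueError("hypoxia_fraction must be in (0, 1)")
        if not np.isfinite(self.true_hr) or self.true_hr <= 0:
            raise ValueError("true_hr must be a finite positive number")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        for v in self.covariate_prevalences.values():
            if not (0 <= v <= 1):
                raise ValueError("covariate prevalences must be in [0, 1]")
        if len(self.signature) > self.n_probesets:
            raise ValueError("n_probesets must cover the signature")


# INSS non-stage-4 composition (stages 1, 2, 3, 4S)
_NON4_STAGES = np.array(["1", "2", "3", "4S"])
_NON4_PROBS = np.array([8, 15, 13, 12], dtype=float) / 48.0


def simulate_tumor_cohort(
    cfg: CohortSimConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, np.ndarray]:
    """Tumor expression + clinical table driven by a latent hypoxia status.

    Returns the linear-scale matrix (probesets x patients), the clinical
    table, and the ground-truth hypoxia indicator H (1 = hypoxic-high).
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_patients, cfg.n_probesets
    sig_ids = list(cfg.signature.probesets)
    bg_ids = [f"BG{i:05d}" for i in range(p - len(sig_ids))]
    probesets = sig_ids + bg_ids
    patients = [f"P{i + 1:03d}" for i in range(n)]

    H = (rng.random(n) < cfg.hypoxia_fraction).astype(int)

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=p)
    shift = np.empty(p)
    shift[: len(sig_ids)] = cfg.signature_shift_log2
    shift[len(sig_ids):] = rng.normal(0.0, cfg.background_shift_sd, size=len(bg_ids))

    log2 = (
        baseline[:, None]
        + shift[:, None] * H[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(p, n))
    )
    E = ExpressionMatrix(pd.DataFrame(np.exp2(log2), index=probesets, columns=patients), "linear")

    prev = cfg.covariate_prevalences
    mycn = (rng.random(n) < prev.get("mycn", 0.0)).astype(int)
    stage4 = (rng.random(n) < prev.get("stage4", 0.0)).astype(int)
    age_ge1 = (rng.random(n) < prev.get("age_ge1", 0.0)).astype(int)
    inss = np.where(stage4 == 1, "4", rng.choice(_NON4_STAGES, size=n, p=_NON4_PROBS))

    log_hr = np.log(cfg.true_hr) * H
    for name, x in (("mycn", mycn), ("stage4", stage4), ("age_ge1", age_ge1)):
        log_hr = log_hr + cfg.covariate_log_hrs.get(name, 0.0) * x
    hazard = cfg.baseline_hazard * np.exp(log_hr)
    T = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        C = rng.exponential(1.0 / cfg.censor_rate, size=n)
    else:
        C = np.full(n, np.inf)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    if cfg.round_decimals is not None:
        time = np.maximum(np.round(time, cfg.round_decimals), 10.0 ** -cfg.round_decimals)

    clin = ClinicalTable(
        pd.DataFrame(
            {
                "time": time,
                "event": event,
                "mycn": np.where(mycn == 1, "amplified", "normal"),
                "inss": inss,
                "age_group": np.where(age_ge1 == 1, "ge1", "lt1"),
            },
            index=pd.Index(patients, name="id"),
        )
    )
    return E, clin, H
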