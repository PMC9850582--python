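"""Synthetic two-phenotype cohorts with planted ferroptosis structure.

The generator emulates the statistical skeleton of a transplant-biopsy
expression study: a case group (TCMR-like) in which a planted fraction of
panel *driver* genes is shifted up and a planted fraction of *suppressor*
genes is shifted down on the log2 scale, against Gaussian residual noise
and a block of unshifted background genes. Survival times are exponential
with a hazard that rises multiplicatively with the latent case axis, so the
same structure that drives diagnosis also drives prognosis.

Each gene g has baseline b_g ~ N(baseline_mean, 1); sample s of group
c(s) in {case, control} observes

    x[g, s] = b_g + shift_g * 1[c(s) = case] + N(0, sigma^2)

with shift_g = +delta_driver for planted drivers, -delta_suppressor for
planted suppressors and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import ExpressionMatrix, FerroptosisGeneSet, PhenotypeTable


@dataclass
class CohortConfig:
    """Knobs of the cohort generator; defaults define the reference study
    conditions used throughout the test-suite."""

    n_case: int = 40
    n_control: int = 40
    n_driver: int = 60
    n_suppressor: int = 60
    n_marker: int = 30
    n_background: int = 500
    delta_driver: float = 1.0
    delta_suppressor: float = 1.0
    planted_fraction: float = 0.5
    sigma: float = 0.7
    baseline_mean: float = 6.0
    hazard_ratio_per_sd: float = 2.0
    censor_rate: float = 0.5
    horizon: float = 1095.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_driver", "n_suppressor",
                     "n_marker", "n_background"):
            if getattr(self, name) <= 0 and name != "n_background" and name != "n_marker":
                raise ValidationError(f"{name} must be positive")
        if self.n_marker < 0 or self.n_background < 0:
            raise ValidationError("gene counts must be non-negative")
        if not (0.0 < self.planted_fraction <= 1.0):
            raise ValidationError("planted_fraction must lie in (0, 1]")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValidationError("censor_rate must lie in [0, 1)")
        if self.hazard_ratio_per_sd <= 0:
            raise ValidationError("hazard_ratio_per_sd must be positive")
        if self.horizon <= 0:
            raise ValidationError("horizon must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortTruth:
    """Ground truth recorded alongside a generated cohort, sufficient to
    compute signature-recovery metrics without re-derivation."""

    planted_drivers: list[str]
    planted_suppressors: list[str]
    case_ids: list[str]
    control_ids: list[str]
    latent_scores: "pd.Series"  # standardized, indexed by sample_id

    def to_dict(self) -> dict:
        return {
            "planted_drivers": self.planted_drivers,
            "planted_suppressors": self.planted_suppressors,
            "case_ids": self.case_ids,
            "control_ids": self.control_ids,
            "latent_scores": {k: float(v) for k, v in self.latent_scores.items()},
        }


def generate_gene_universe(config: CohortConfig) -> tuple[FerroptosisGeneSet, list[str]]:
    """Deterministic symbol universe: a driver/suppressor/marker panel plus
    background symbols disjoint from the panel."""
    if config.n_driver <= 0 or config.n_suppressor <= 0:
        raise ValidationError("panel must contain driver and suppressor genes")
    entries = (
        [(f"DRV{i:04d}", "driver") for i in range(config.n_driver)]
        + [(f"SUP{i:04d}", "suppressor") for i in range(config.n_suppressor)]
        + [(f"MRK{i:04d}", "marker") for i in range(config.n_marker)]
    )
    background = [f"BGD{i:04d}" for i in range(config.n_background)]
    return FerroptosisGeneSet(entries), background


def _planted_subset(rng: np.random.Generator, symbols: Sequence[str],
                    fraction: float) -> list[str]:
    k = max(1, int(round(fraction * len(symbols))))
    chosen = rng.choice(len(symbols), size=k, replace=False)
    return [symbols[i] for i in sorted(chosen)]


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, PhenotypeTable, CohortTruth]:
    """Draw one cohort; byte-identical across calls with the same config."""
    rng = np.random.default_rng(config.seed)
    panel, background = generate_gene_universe(config)
    genes = panel.symbols + background
    case_ids = [f"CASE{i:03d}" for i in range(config.n_case)]
    control_ids = [f"CTRL{i:03d}" for i in range(config.n_control)]
    samples = case_ids + control_ids
    is_case = np.array([1] * config.n_case + [0] * config.n_control)

    planted_drivers = _planted_subset(rng, panel.symbols_in("driver"),
                                      config.planted_fraction)
    planted_suppressors = _planted_subset(rng, panel.symbols_in("suppressor"),
                                          config.planted_fraction)
    shift = pd.Series(0.0, index=genes)
    shift[planted_drivers] = config.delta_driver
    shift[planted_suppressors] = -config.delta_suppressor

    baseline = rng.normal(config.baseline_mean, 1.0, size=len(genes))
    noise = rng.normal(0.0, config.sigma, size=(len(genes), len(samples)))
    values = baseline[:, None] + np.outer(shift.to_numpy(), is_case) + noise

    matrix = ExpressionMatrix(genes, samples, values)
    phenotypes = PhenotypeTable(pd.DataFrame({
        "sample_id": samples,
        "diagnosis": ["TCMR"] * config.n_case + ["non_rejection"] * config.n_control,
    }))

    frame = matrix.to_frame()
    raw_latent = (frame.loc[planted_drivers].mean(axis=0)
                  - frame.loc[planted_suppressors].mean(axis=0))
    latent = (raw_latent - raw_latent.mean()) / raw_latent.std(ddof=0)
    truth = CohortTruth(planted_drivers, planted_suppressors,
                        case_ids, control_ids, latent)
    return matrix, phenotypes, truth


def attach_survival(
    phenotypes: PhenotypeTable,
    latent_scores: pd.Series,
    config: CohortConfig,
) -> PhenotypeTable:
    """Add exponential event times whose hazard scales as
    ``hazard_ratio_per_sd ** z`` in the standardized latent score ``z``.

    The baseline hazard is ``log(2) / horizon`` (median survival at the
    horizon for an average sample); censoring is an independent exponential
    clock calibrated so a ``z = 0`` sample is censored with probability
    ``censor_rate``. ``censor_rate = 0`` disables censoring entirely.
    """
    missing = [s for s in phenotypes.sample_ids if s not in latent_scores.index]
    if missing:
        raise ValidationError(f"missing latent score for sample(s) {missing[:5]}")
    z = latent_scores.loc[phenotypes.sample_ids].to_numpy(dtype=float)
    # spawn an independent stream so expression and survival draws never interleave
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    h0 = np.log(2.0) / config.horizon
    hazard = h0 * config.hazard_ratio_per_sd ** z
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        mu = h0 * config.censor_rate / (1.0 - config.censor_rate)
        censor_time = rng.exponential(1.0 / mu, size=len(z))
    else:
        censor_time = np.full(len(z), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    frame = phenotypes.data.copy()
    frame["time"] = time
    frame["event"] = event
    return PhenotypeTable(frame)


def generate_survival_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, PhenotypeTable, CohortTruth]:
    """Convenience: cohort with survival columns attached from its own truth."""
    matrix, phenotypes, truth = generate_cohort(config)
    phenotypes = attach_survival(phenotypes, truth.latent_scores, config)
    return matrix, phenotypes, truth
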