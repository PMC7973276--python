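"""Seeded synthetic cohort generator.

Emulates the statistical structure of a small tumor immune-profiling
cohort: log-normal TPM values with optional per-group shifts on the log
scale, correlated gene blocks drawn through a Gaussian copula,
compositional immune cell percentages whose subset sum lands near a
configured total-immune infiltration (~15-20%), and per-group
exponential survival with censoring. Everything is reproducible from a
single seed.

The copula's target rho is a Spearman target: the latent Pearson
correlation is set to 2 sin(pi rho / 6), so the rank correlation of the
generated values matches the request regardless of the marginal
transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import (
    CELL_SUBSETS,
    AnalyteKind,
    Cohort,
    SampleRecord,
    SurvivalValue,
    load_reference_analytes,
)

__all__ = [
    "AnalyteSpec",
    "SurvivalSpec",
    "SynthConfig",
    "generate_cohort",
    "study_shaped_fixture",
    "ground_truth",
]

#: Group sizes of the study design this generator emulates.
DEFAULT_GROUP_SIZES = {"long": 11, "intermediate": 7, "short": 8}

#: Per-group exponential hazards (1/months) chosen so group median
#: survival matches the discovery cohort's printed PFS medians
#: (76 / 24 / 6 months), and censoring fractions mirroring its pattern
#: (long mostly censored, short mostly events).
DEFAULT_HAZARDS = {"long": np.log(2) / 76, "intermediate": np.log(2) / 24,
                   "short": np.log(2) / 6}
DEFAULT_CENSOR_PROB = {"long": 0.7, "intermediate": 0.2, "short": 0.05}

_GROUP_PREFIX = {"long": "L", "intermediate": "I", "short": "S"}


@dataclass(frozen=True)
class AnalyteSpec:
    """Marginal model for one analyte.

    For ``gene_tpm`` analytes ``loc`` is the natural log of the typical
    TPM; for ``cell_percent`` it is a logit-scale location of the
    subset's share of a reference 30% infiltration ceiling. ``sd`` is
    the latent normal scale and ``group_effect`` an additive per-group
    shift on the latent scale. ``corr_block`` names an optional copula
    block.
    """

    name: str
    kind: AnalyteKind
    loc: float
    sd: float = 0.6
    group_effect: Mapping[str, float] = field(default_factory=dict)
    corr_block: str | None = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive for {self.name!r}")


@dataclass(frozen=True)
class SurvivalSpec:
    hazard: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    censor_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CENSOR_PROB))
    horizon: float = 100.0  # months; times beyond it are censored there
    os_extra_mean: float = 12.0  # mean extra months from progression to death


@dataclass(frozen=True)
class SynthConfig:
    analytes: tuple[AnalyteSpec, ...]
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    block_rho: Mapping[str, float] = field(default_factory=dict)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    total_immune_mean: float = 17.5  # percent; subset sums land near here
    total_immune_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for block, rho in self.block_rho.items():
            if not abs(rho) < 1:
                raise ValueError(f"block {block!r} rho must satisfy |rho| < 1")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for {g!r}")


def _latent_correlation(analytes: Sequence[AnalyteSpec],
                        block_rho: Mapping[str, float]) -> np.ndarray:
    """Equicorrelated within blocks; latent Pearson from Spearman target."""
    k = len(analytes)
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            bi, bj = analytes[i].corr_block, analytes[j].corr_block
            if bi is not None and bi == bj:
                rho_s = block_rho.get(bi, 0.0)
                corr[i, j] = corr[j, i] = 2.0 * np.sin(np.pi * rho_s / 6.0)
    return corr


def generate_cohort(config: SynthConfig) -> Cohort:
    """Draw one cohort from the configured generative model."""
    rng = np.random.default_rng(config.seed)
    analytes = list(config.analytes)
    names = [a.name for a in analytes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate analyte names in config")
    corr = _latent_correlation(analytes, config.block_rho)
    chol = np.linalg.cholesky(corr)
    cell_idx = [i for i, a in enumerate(analytes) if a.kind == "cell_percent"]

    rows, records = [], []
    for group in ("long", "intermediate", "short"):
        n_g = config.group_sizes.get(group, 0)
        for s in range(n_g):
            sid = f"{_GROUP_PREFIX[group]}{s + 1:02d}"
            z = chol @ rng.standard_normal(len(analytes))
            latent = np.array(
                [a.loc + a.group_effect.get(group, 0.0) + a.sd * z[i]
                 for i, a in enumerate(analytes)]
            )
            values = np.empty(len(analytes))
            for i, a in enumerate(analytes):
                if a.kind == "gene_tpm":
                    values[i] = np.exp(latent[i])
            if cell_idx:
                raw = expit(latent[cell_idx])
                total = float(np.clip(
                    rng.normal(config.total_immune_mean, config.total_immune_sd),
                    1.0, 60.0))
                shares = raw / raw.sum()
                values[cell_idx] = shares * total
            surv = config.survival
            h = surv.hazard[group]
            pfs_t = rng.exponential(1.0 / h)
            pfs_cens = bool(rng.random() < surv.censor_prob[group])
            if pfs_t > surv.horizon:
                pfs_t, pfs_cens = surv.horizon, True
            os_t = pfs_t + rng.exponential(surv.os_extra_mean)
            os_cens = pfs_cens
            if os_t > surv.horizon:
                os_t, os_cens = surv.horizon, True
            rows.append(values)
            records.append(SampleRecord(
                sample_id=sid,
                group=group,
                pfs=SurvivalValue(round(pfs_t, 1), censored=pfs_cens),
                os=SurvivalValue(round(os_t, 1), censored=os_cens),
            ))
    matrix = pd.DataFrame(rows, index=[r.sample_id for r in records],
                          columns=names)
    matrix.index.name = "sample_id"
    kinds = {a.name: a.kind for a in analytes}
    return Cohort(records, matrix, kinds)


def ground_truth(config: SynthConfig) -> dict:
    """Planted parameters of a config, for test harnesses."""
    return {
        "seed": config.seed,
        "group_sizes": dict(config.group_sizes),
        "block_rho": dict(config.block_rho),
        "hazard": {g: float(h) for g, h in config.survival.hazard.items()},
        "censor_prob": dict(config.survival.censor_prob),
        "effects": {
            a.name: dict(a.group_effect)
            for a in config.analytes if a.group_effect
        },
    }


# -- study-shaped fixture ------------------------------------------------------

#: Reference ceiling (percent) used to express cell-subset medians as
#: logit-scale fractions.
_CELL_CEILING = 30.0
_MIN_CELL_MEDIAN = 0.05


def study_shaped_fixture(seed: int = 0, log_sd: float = 0.6,
                         corr_rho: float = 0.89) -> SynthConfig:
    """Config whose 40 analytes and group medians track the published
    discovery-cohort summary table.

    Gene log-locations are set to ln(long-group median) with the
    short-group shift ln(median_short / median_long) (intermediate gets
    half the shift); cell subsets use the analogous logit-scale
    locations. The ICOS-CTLA4 pair forms a correlated block at the
    given Spearman rho.
    """
    ref = load_reference_analytes()
    specs = []
    for _, row in ref.iterrows():
        name, kind = str(row["analyte"]), str(row["kind"])
        m_long = max(float(row["median_long"]), _MIN_CELL_MEDIAN)
        m_short = max(float(row["median_short"]), _MIN_CELL_MEDIAN)
        if kind == "gene_tpm":
            loc = float(np.log(m_long))
            shift = float(np.log(m_short / m_long))
        else:
            loc = float(logit(m_long / _CELL_CEILING))
            shift = float(logit(m_short / _CELL_CEILING) - loc)
        specs.append(AnalyteSpec(
            name=name,
            kind="gene_tpm" if kind == "gene_tpm" else "cell_percent",
            loc=loc,
            sd=log_sd,
            group_effect={"short": shift, "intermediate": shift / 2.0},
            corr_block="icos_ctla4" if name in ("ICOS", "CTLA4") else None,
        ))
    assert [s.name for s in specs if s.kind == "cell_percent"] == list(CELL_SUBSETS)
    return SynthConfig(
        analytes=tuple(specs),
        block_rho={"icos_ctla4": corr_rho},
        seed=seed,
    )
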