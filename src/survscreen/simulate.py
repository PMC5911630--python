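"""Synthetic cohorts, paired tumor/normal expression, and promoter
sequences with the statistical structure the screen assumes.

The cohort generator emulates a gastric-cancer microarray survival
cohort: log-normal marker expression, exponential event times whose
hazard is multiplied by ``exp(log HR)`` for patients above the cohort
median of each prognostic gene, independent exponential random
censoring, and administrative censoring at a 60-month horizon (5-year
overall survival).  Clinical subgroup labels (stage, histology, HER2
status, treatment arm) are drawn from configurable category proportions.

The true-hazard covariate is deliberately the median-split indicator --
the same dichotomization the screen analyses -- so parameter-recovery
experiments measure estimation error, not model misspecification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "PairedConfig",
    "simulate_cohort",
    "simulate_paired_expression",
    "simulate_promoter",
    "DEFAULT_SUBGROUP_SCHEME",
    "IUPAC_CODES",
]

#: category proportions per clinical label.  HER2 and treatment-arm
#: proportions follow the cohort sizes of the gastric meta-cohort the
#: screen emulates (HER2- 532/876, HER2+ 344/876; surgery 380/876,
#: 5FU+surgery 153/876, remainder unresected/other); stage and Lauren
#: histology proportions are field-typical values.
DEFAULT_SUBGROUP_SCHEME: dict[str, dict[str, float]] = {
    "stage": {"1": 0.15, "2": 0.25, "3": 0.40, "4": 0.20},
    "histology": {"intestinal": 0.55, "diffuse": 0.45},
    "her2": {"neg": 532 / 876, "pos": 344 / 876},
    "treatment": {"surgery": 380 / 876, "5fu_surgery": 153 / 876, "other": 343 / 876},
}

CLINICAL_COLUMNS = ("sample_id", "time_months", "event", "stage", "histology", "her2", "treatment")


def _check_positive(name: str, value) -> None:
    if not (value > 0):
        raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic survival cohort.

    ``log_hr_by_gene`` gives each gene's true log hazard ratio for the
    high-expression (above cohort median) group; genes absent from the
    map are null.  ``baseline_hazard`` is in events/month for a patient
    below the median of every prognostic gene.  ``censor_horizon`` is
    the administrative cut (months); ``random_censor_rate`` adds
    independent exponential dropout (events/month, 0 disables it).
    """

    n_patients: int = 876
    n_genes: int = 10
    baseline_hazard: float = 0.015
    log_hr_by_gene: dict[str, float] = field(default_factory=dict)
    censor_horizon: float = 60.0
    random_censor_rate: float = 0.005
    subgroup_scheme: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUBGROUP_SCHEME.items()}
    )
    expression_meanlog: float = 6.0
    expression_sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients > 0):
            raise ValueError(f"n_patients must be a positive integer, got {self.n_patients!r}")
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes > 0):
            raise ValueError(f"n_genes must be a positive integer, got {self.n_genes!r}")
        _check_positive("baseline_hazard", self.baseline_hazard)
        _check_positive("censor_horizon", self.censor_horizon)
        if self.random_censor_rate < 0:
            raise ValueError(
                f"random_censor_rate must be >= 0, got {self.random_censor_rate!r}"
            )
        for label, props in self.subgroup_scheme.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"subgroup_scheme[{label!r}] proportions sum to {total}, expected 1"
                )
            if any(p < 0 for p in props.values()):
                raise ValueError(f"subgroup_scheme[{label!r}] has a negative proportion")

    @property
    def gene_names(self) -> list[str]:
        """Named prognostic genes first, padded with null genes G1, G2, ...
        up to ``n_genes`` columns."""
        names = list(self.log_hr_by_gene)
        i = 1
        while len(names) < self.n_genes:
            candidate = f"G{i}"
            if candidate not in names:
                names.append(candidate)
            i += 1
        return names


@dataclass
class PairedConfig:
    """Matched tumor/normal expression pairs with a common per-pair
    baseline, a tumor log-fold shift, and independent measurement noise."""

    n_pairs: int = 34
    log_fold_change: float = 0.0
    noise_sd: float = 0.5
    base_mean: float = 8.0
    base_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError(f"n_pairs must be at least 2, got {self.n_pairs!r}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd!r}")


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw one cohort table: clinical columns plus one column per gene.

    Event times are exponential with hazard ``baseline_hazard * exp(sum
    of log HRs over genes whose expression exceeds the cohort median)``;
    observed time is the minimum of event time, random censoring time
    and the administrative horizon, and the event flag is 1 only when
    the event time attains that minimum.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    genes = config.gene_names

    expr = rng.lognormal(config.expression_meanlog, config.expression_sdlog, size=(n, len(genes)))
    log_relative_hazard = np.zeros(n)
    for j, gene in enumerate(genes):
        log_hr = config.log_hr_by_gene.get(gene, 0.0)
        if log_hr != 0.0:
            high = expr[:, j] > np.median(expr[:, j])
            log_relative_hazard += log_hr * high
    hazard = config.baseline_hazard * np.exp(log_relative_hazard)

    event_time = rng.exponential(1.0 / hazard)
    if config.random_censor_rate > 0:
        censor_time = rng.exponential(1.0 / config.random_censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    bound = np.minimum(censor_time, config.censor_horizon)
    observed = np.minimum(event_time, bound)
    event = event_time <= bound

    data = {
        "sample_id": [f"S{i + 1:05d}" for i in range(n)],
        "time_months": observed,
        "event": event.astype(int),
    }
    for label in ("stage", "histology", "her2", "treatment"):
        scheme = config.subgroup_scheme.get(label)
        if scheme is None:
            data[label] = ["na"] * n
        else:
            cats = list(scheme)
            probs = np.array([scheme[c] for c in cats])
            data[label] = rng.choice(cats, size=n, p=probs / probs.sum())
    cohort = pd.DataFrame(data)
    for j, gene in enumerate(genes):
        cohort[gene] = expr[:, j]
    return cohort


def simulate_paired_expression(config: PairedConfig) -> pd.DataFrame:
    """Matched normal/tumor table: ``normal = base + noise``,
    ``tumor = base + log_fold_change + noise``, independent noise draws."""
    rng = np.random.default_rng(config.seed)
    base = rng.normal(config.base_mean, config.base_sd, size=config.n_pairs)
    normal = base + rng.normal(0.0, config.noise_sd, size=config.n_pairs)
    tumor = base + config.log_fold_change + rng.normal(0.0, config.noise_sd, size=config.n_pairs)
    return pd.DataFrame(
        {
            "pair_id": [f"P{i + 1:04d}" for i in range(config.n_pairs)],
            "normal": normal,
            "tumor": tumor,
        }
    )


IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}


def _validate_iupac(motif: str) -> str:
    motif = motif.upper()
    for ch in motif:
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC nucleotide code {ch!r} in motif {motif!r}")
    return motif


def simulate_promoter(
    length: int, motif: str, n_planted: int, seed: int
) -> tuple[str, list[int]]:
    """Uniform ACGT background with non-overlapping planted motif copies.

    One concrete realization of the IUPAC ``motif`` (degenerate
    positions resolved once, uniformly) is written at ``n_planted``
    non-overlapping positions chosen uniformly among all valid
    placements.  Returns ``(sequence, sorted planted positions)``; the
    background may by chance contain additional matches.
    """
    motif = _validate_iupac(motif)
    m = len(motif)
    if n_planted < 0:
        raise ValueError("n_planted must be >= 0")
    if n_planted * m > length:
        raise ValueError(
            f"cannot plant {n_planted} copies of a {m}-mer in {length} bases"
        )
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=length)
    realization = "".join(
        rng.choice(list(IUPAC_CODES[ch].replace("N", "") or "ACGT")) for ch in motif
    )
    positions: list[int] = []
    if n_planted > 0:
        # uniform non-overlapping placement via the gap bijection:
        # combinations c_1 < ... < c_k map to starts c_i + i*(m-1)
        slots = length - n_planted * m + n_planted
        chosen = np.sort(rng.choice(slots, size=n_planted, replace=False))
        positions = [int(c + i * (m - 1)) for i, c in enumerate(chosen)]
        for pos in positions:
            seq[pos : pos + m] = list(realization)
    return "".join(seq), positions
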