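"""Deterministic cost and duration model for qPCR validation experiments.

Two chemistries are modelled:

* **TaqMan** — three target genes plus a reference multiplexed per well,
  each reaction in triplicate, so the 3-plex and the 3 replicates cancel and
  the plate count is ``floor(n_genes * n_samples / 96)``.  Per-gene probes
  cost $250 each.
* **SYBrGreen** — no multiplexing (one gene well plus one reference well per
  gene-sample pair, in triplicate), so six times the wells:
  ``floor(n_genes * n_samples * 3 * 2 / 96)`` plates.  No probe cost.

Each plate costs $154 in consumables (mastermix + plate).  A technician paid
$40,000/year runs 4 plates/day, 22 days/month, i.e. 1,056 plates/year;
duration in years is plates / 1056 and personnel cost is salary times the
exact fractional duration.  The floor on the plate count is kept as stated —
a partially filled final plate is absorbed rather than rounded up — because
that is the arithmetic the published budget figures follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CostParameters",
    "CostEstimate",
    "SavingsReport",
    "taqman_plates",
    "sybrgreen_plates",
    "qpcr_cost",
    "validation_savings",
]

TECHNOLOGIES = ("taqman", "sybrgreen")


@dataclass(frozen=True)
class CostParameters:
    """Unit costs and throughput assumptions, all overridable."""

    probe_cost_usd: float = 250.0  # per TaqMan probe (one per gene)
    mastermix_usd_per_plate: float = 150.0
    plate_usd: float = 4.0
    salary_usd_per_year: float = 40_000.0
    plates_per_day: float = 4.0
    working_days_per_month: float = 22.0
    months_per_year: float = 12.0
    wells_per_plate: int = 96
    replicates: int = 3
    taqman_multiplex: int = 3  # genes per well, excluding the reference
    sybr_wells_per_gene_sample: int = 2  # gene well + reference well

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"cost parameter {name} must be positive, got {value}")

    @property
    def plate_consumable_usd(self) -> float:
        return self.mastermix_usd_per_plate + self.plate_usd

    @property
    def plates_per_year(self) -> float:
        return self.plates_per_day * self.working_days_per_month * self.months_per_year


DEFAULT_PARAMS = CostParameters()


@dataclass(frozen=True)
class CostEstimate:
    technology: str
    n_genes: int
    n_samples: int
    n_plates: int
    time_years: float
    cost_usd: float
    components: dict[str, float] = field(default_factory=dict)


def taqman_plates(n_genes: int, n_samples: int, params: CostParameters = DEFAULT_PARAMS) -> int:
    """Plate count for TaqMan: floor(n_genes * n_samples / wells_per_plate).

    The multiplexing factor and the replicate count cancel when, as in the
    defaults, both equal 3.
    """
    _check_counts(n_genes, n_samples)
    wells = n_genes / params.taqman_multiplex * n_samples * params.replicates
    return math.floor(wells / params.wells_per_plate)


def sybrgreen_plates(n_genes: int, n_samples: int, params: CostParameters = DEFAULT_PARAMS) -> int:
    """Plate count for SYBrGreen: floor(n_genes * n_samples * replicates * 2 / wells)."""
    _check_counts(n_genes, n_samples)
    wells = n_genes * n_samples * params.replicates * params.sybr_wells_per_gene_sample
    return math.floor(wells / params.wells_per_plate)


def _check_counts(n_genes, n_samples) -> None:
    if n_genes < 0 or n_samples < 0:
        raise ValueError(f"counts must be nonnegative, got genes={n_genes}, samples={n_samples}")


def qpcr_cost(
    technology: str,
    n_genes: int,
    n_samples: int,
    params: CostParameters = DEFAULT_PARAMS,
) -> CostEstimate:
    """Itemized cost and duration of validating n_genes on n_samples.

    Components are primer (TaqMan only), reagent (plate consumables) and
    personnel (salary times the exact fractional years of bench time).
    """
    tech = technology.lower()
    if tech not in TECHNOLOGIES:
        raise ValueError(f"unknown technology {technology!r}; expected one of {TECHNOLOGIES}")
    if tech == "taqman":
        plates = taqman_plates(n_genes, n_samples, params)
        primer = params.probe_cost_usd * n_genes
    else:
        plates = sybrgreen_plates(n_genes, n_samples, params)
        primer = 0.0
    time_years = plates / params.plates_per_year
    components = {
        "primer": primer,
        "reagent": params.plate_consumable_usd * plates,
        "personnel": params.salary_usd_per_year * time_years,
    }
    return CostEstimate(
        technology=tech,
        n_genes=int(n_genes),
        n_samples=int(n_samples),
        n_plates=plates,
        time_years=time_years,
        cost_usd=sum(components.values()),
        components=components,
    )


@dataclass(frozen=True)
class SavingsReport:
    manual: CostEstimate
    statistical: CostEstimate
    validation_fraction: float

    @property
    def cost_saved_usd(self) -> float:
        return self.manual.cost_usd - self.statistical.cost_usd

    @property
    def time_saved_years(self) -> float:
        return self.manual.time_years - self.statistical.time_years


def validation_savings(
    n_de_genes: int,
    n_samples: int,
    validation_n: int,
    technology: str = "taqman",
    params: CostParameters = DEFAULT_PARAMS,
) -> SavingsReport:
    """Compare validating every significant gene against a statistical subsample.

    ``validation_n`` is the design sample size (how many genes the
    statistical-validation strategy confirms); the fraction reported is
    validation_n / n_de_genes.
    """
    if validation_n > n_de_genes:
        raise ValueError(
            f"validation_n ({validation_n}) cannot exceed the list size ({n_de_genes})"
        )
    manual = qpcr_cost(technology, n_de_genes, n_samples, params)
    statistical = qpcr_cost(technology, validation_n, n_samples, params)
    return SavingsReport(manual, statistical, validation_n / n_de_genes)
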