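"""Seeded synthetic chemical inventories, plus the published top-10 score table.

No public dataset accompanies the ranking method — the original evaluation
inventory (62 substances controlled under the Korean occupational safety
act, all with CMR toxicity) was never deposited. This module generates
statistically comparable stand-in inventories: per-indicator hazard class
draws with configurable weights, log-uniform handling volumes and measured
exposures (the banding cut-points are logarithmic, so log-uniform draws
populate every band), log-uniform worker/workplace counts, and a
liquid-vs-solid state mix. Everything is driven by one integer seed;
identical spec + seed reproduces the inventory bit for bit.

:func:`table5_fixture` returns the published top-10 normalized score rows,
the one piece of real data the source prints, for regression tests of the
ranking arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exposure import DustForm, ExposureProfile, PhysicalForm
from .hazard import VALID_CLASSES, HazardClass, HazardIndicator, HazardProfile
from .records import ChemicalRecord, format_cas

__all__ = ["InventorySpec", "generate_inventory", "table5_fixture"]

#: Exposure fields that the ``missingness`` setting can blank out.
MISSABLE_FIELDS = (
    "handling_volume_tpy",
    "circulation_tpy",
    "worker_count",
    "workplace_count",
    "form",
    "measured_exposure",
)


def _uniform_weights() -> dict[HazardIndicator, dict[HazardClass, float]]:
    return {
        ind: {cls: 1.0 / len(valid) for cls in sorted(valid, key=lambda c: c.value)}
        for ind, valid in VALID_CLASSES.items()
    }


@dataclass(frozen=True)
class InventorySpec:
    """Generation parameters for one synthetic inventory.

    Defaults emulate the evaluation conditions of the original study where
    stated (62 chemicals) and span every scoring band where not: volumes
    over 10^-2..10^4 t/y, counts over 1..1000, measured exposures over
    10^-2..10^3 ppm (liquid/gas) and 10^-3..10^2 mg/m³ (solid), 70%
    liquids/gases, hazard classes uniform over each indicator's valid
    labels, and no missing fields.
    """

    n_chemicals: int = 62
    seed: int = 0
    hazard_class_weights: Mapping[HazardIndicator, Mapping[HazardClass, float]] = field(
        default_factory=_uniform_weights
    )
    volume_log_range: tuple[float, float] = (-2.0, 4.0)
    count_range: tuple[int, int] = (1, 1000)
    state_mix: float = 0.7
    measured_log_range_liquid: tuple[float, float] = (-2.0, 3.0)
    measured_log_range_solid: tuple[float, float] = (-3.0, 2.0)
    boiling_point_range: tuple[float, float] = (20.0, 300.0)
    missingness: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be positive")
        if not 0.0 <= self.state_mix <= 1.0:
            raise ValueError(f"state_mix must be a probability, got {self.state_mix}")
        for fname, p in self.missingness.items():
            if fname not in MISSABLE_FIELDS:
                raise ValueError(f"unknown missingness field {fname!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness[{fname!r}] must be in [0,1], got {p}")
        for ind in HazardIndicator:
            if ind not in self.hazard_class_weights:
                raise ValueError(f"hazard_class_weights missing {ind.name}")
            w = self.hazard_class_weights[ind]
            for cls in w:
                if cls not in VALID_CLASSES[ind]:
                    raise ValueError(
                        f"weight given for invalid class {cls.value!r} of {ind.name}"
                    )
            total = sum(w.values())
            if total <= 0 or any(v < 0 for v in w.values()):
                raise ValueError(f"weights for {ind.name} must be non-negative, sum > 0")
        for lo, hi in (
            self.volume_log_range,
            self.measured_log_range_liquid,
            self.measured_log_range_solid,
            self.boiling_point_range,
        ):
            if hi < lo:
                raise ValueError(f"range ({lo}, {hi}) is inverted")
        if self.count_range[0] < 0 or self.count_range[1] < self.count_range[0]:
            raise ValueError(f"bad count_range {self.count_range}")


def _draw_class(
    rng: np.random.Generator, weights: Mapping[HazardClass, float]
) -> HazardClass:
    classes = sorted(weights, key=lambda c: c.value)  # stable draw order
    probs = np.array([weights[c] for c in classes], dtype=float)
    probs /= probs.sum()
    return classes[rng.choice(len(classes), p=probs)]


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10.0 ** rng.uniform(lo, hi))


def generate_inventory(spec: InventorySpec) -> list[ChemicalRecord]:
    """Generate ``spec.n_chemicals`` synthetic records, reproducibly by seed.

    Synthetic CAS identifiers carry a valid check digit; names are
    ``SYN-0001`` etc. Missingness is applied per field as independent
    Bernoulli draws.
    """
    rng = np.random.default_rng(spec.seed)
    miss = {f: float(spec.missingness.get(f, 0.0)) for f in MISSABLE_FIELDS}
    lo_n, hi_n = spec.count_range
    log_lo_n, log_hi_n = np.log10(max(lo_n, 1)), np.log10(max(hi_n, 1))

    records: list[ChemicalRecord] = []
    seen_cas: set[str] = set()
    for i in range(spec.n_chemicals):
        profile = HazardProfile(
            {
                ind: _draw_class(rng, spec.hazard_class_weights[ind])
                for ind in HazardIndicator
            }
        )

        def present(fname: str) -> bool:
            return rng.random() >= miss[fname]

        volume = (
            _log_uniform(rng, *spec.volume_log_range)
            if present("handling_volume_tpy")
            else None
        )
        circulation = (
            _log_uniform(rng, *spec.volume_log_range)
            if present("circulation_tpy")
            else None
        )
        workers = (
            int(round(10.0 ** rng.uniform(log_lo_n, log_hi_n)))
            if present("worker_count")
            else None
        )
        workplaces = (
            int(round(10.0 ** rng.uniform(log_lo_n, log_hi_n)))
            if present("workplace_count")
            else None
        )

        is_liquid = rng.random() < spec.state_mix
        if present("form"):
            if is_liquid:
                form = PhysicalForm(
                    "liquid_gas",
                    boiling_point_C=float(rng.uniform(*spec.boiling_point_range)),
                )
            else:
                form = PhysicalForm(
                    "solid", dust_form=list(DustForm)[rng.integers(0, len(DustForm))]
                )
        else:
            form = None

        if form is not None and present("measured_exposure"):
            rng_range = (
                spec.measured_log_range_liquid
                if form.state == "liquid_gas"
                else spec.measured_log_range_solid
            )
            measured = _log_uniform(rng, *rng_range)
        else:
            measured = None

        while True:  # CAS base is 6 random digits; retry the rare collision
            base = "".join(str(d) for d in rng.integers(0, 10, size=6))
            cas = format_cas(base)
            if cas not in seen_cas:
                seen_cas.add(cas)
                break

        records.append(
            ChemicalRecord(
                name=f"SYN-{i + 1:04d}",
                cas=cas,
                hazard=profile,
                exposure=ExposureProfile(
                    handling_volume_tpy=volume,
                    circulation_tpy=circulation,
                    worker_count=workers,
                    workplace_count=workplaces,
                    form=form,
                    measured_exposure=measured,
                ),
            )
        )
    return records


# Published top-10 rows: (name, CAS, normalized hazard score, normalized
# exposure score, printed total score). The printed totals were computed
# from unrounded normalized scores, so a 2-dp product can differ in the
# last digit.
_TABLE5_ROWS = [
    ("Styrene", "100-42-5", 6.98, 9.60, 67.05),
    ("Acrylamide", "79-06-1", 8.89, 6.80, 60.44),
    ("Acrylonitrile", "107-13-1", 8.41, 6.80, 57.21),
    ("Cyclohexanone", "108-94-1", 6.35, 7.60, 48.25),
    ("Ethyleneimine", "151-56-4", 10.00, 4.80, 48.00),
    ("Stoddard solvents", "8052-41-3", 5.08, 9.20, 46.73),
    ("Dimethyl sulfate", "77-78-1", 6.98, 6.40, 44.70),
    ("Perchloroethylene", "127-18-4", 4.92, 8.80, 43.30),
    ("Dimethylformamide", "68-12-2", 4.60, 9.20, 42.35),
    ("Ethyl acrylate", "140-88-3", 5.56, 7.20, 40.00),
]


def table5_fixture() -> pd.DataFrame:
    """The published top-10 ranked chemicals with their printed scores.

    Columns: ``name``, ``cas``, ``hazard_score``, ``exposure_score``,
    ``total_score`` — normalized scores as printed, in printed rank order.
    """
    return pd.DataFrame(
        _TABLE5_ROWS,
        columns=["name", "cas", "hazard_score", "exposure_score", "total_score"],
    )
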