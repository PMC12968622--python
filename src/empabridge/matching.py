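"""Exposure-matching dose rationale.

Paediatric dose selection proceeds by requiring the distribution of child
steady-state exposure (AUC, Cmax) to fall inside an adult reference window:
at least 70% of the exposure of a normal-weight adult on the 10 mg heart-
failure dose (efficacy floor) and at most 130% of the exposure of an adult
receiving the maximum recommended 25 mg dose (safety cap).  Ratios are
formed between independently simulated child and adult virtual subjects,
so the ratio distribution reflects inter-individual variability in both
populations.  The minimum admissible body weight for a fixed tablet
strength is the smallest weight on the evaluation grid whose median ratios
satisfy both criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import draw_individual_parameters
from .model import steady_state_metrics_batch
from .params import PopulationSpec, ValidationError

__all__ = [
    "MatchingCriteria",
    "RatioSummary",
    "ratio_distribution",
    "evaluate_weight_bands",
    "min_admissible_weight",
    "bands_to_frame",
]

_QUANTS = {"q05": 0.05, "q25": 0.25, "median": 0.5, "q75": 0.75, "q95": 0.95}


def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass(frozen=True)
class MatchingCriteria:
    """Exposure-matching acceptance window.

    efficacy_floor: minimum median child/adult AUC ratio against the
    efficacy reference (adult on 10 mg).  safety_cap: maximum median child/
    adult AUC and Cmax ratio against the safety reference (adult on 25 mg).
    The safety reference defaults to a 50 kg adult (the lightest plausible
    adult, i.e. the conservative comparator); the efficacy reference to a
    70 kg normal-weight adult.
    """

    efficacy_floor: float = 0.70
    safety_cap: float = 1.30
    safety_ref_weight: float = 50.0
    safety_ref_dose: float = 25.0
    efficacy_ref_weight: float = 70.0
    efficacy_ref_dose: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.efficacy_floor < 1 < self.safety_cap):
            raise ValidationError(
                f"need 0 < efficacy_floor < 1 < safety_cap, got "
                f"{self.efficacy_floor}, {self.safety_cap}"
            )

    @property
    def adult_ref_weights(self) -> tuple:
        return (self.safety_ref_weight, self.efficacy_ref_weight)


@dataclass(frozen=True)
class RatioSummary:
    """Quantile summary of a child/adult exposure-ratio distribution."""

    metric: str
    median: float
    q25: float
    q75: float
    q05: float
    q95: float

    def __post_init__(self) -> None:
        if not (self.q05 <= self.q25 <= self.median <= self.q75 <= self.q95):
            raise ValidationError(f"quantiles out of order for {self.metric}")


def _summaries(child: dict, adult: dict) -> dict:
    out = {}
    for name, key in (("AUC", "auc"), ("Cmax", "cmax"), ("Css", "css")):
        ratio = child[key] / adult[key]
        qs = {k: float(np.quantile(ratio, q)) for k, q in _QUANTS.items()}
        out[name] = RatioSummary(metric=name, **qs)
    return out


def _draw_metrics(weight: float, dose_mg: float, population: PopulationSpec, n: int, rng) -> dict:
    theta = draw_individual_parameters(population.reference, np.full(n, float(weight)), population, rng)
    return steady_state_metrics_batch(theta, dose_mg)


def ratio_distribution(
    child_weight: float,
    child_dose: float,
    adult_weight: float,
    adult_dose: float,
    population: PopulationSpec,
    n_pairs: int = 10_000,
    seed=None,
) -> dict:
    """Quantile summaries of per-pair child/adult steady-state exposure
    ratios (AUC, Cmax, Css), from ``n_pairs`` independent child and adult
    virtual subjects."""
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    child_rng, adult_rng = [np.random.default_rng(s) for s in _seed_seq(seed).spawn(2)]
    child = _draw_metrics(child_weight, child_dose, population, n_pairs, child_rng)
    adult = _draw_metrics(adult_weight, adult_dose, population, n_pairs, adult_rng)
    return _summaries(child, adult)


@dataclass(frozen=True)
class WeightBandResult:
    """Exposure-ratio summaries and pass/fail flags for one (weight, dose)."""

    weight: float
    dose_mg: float
    efficacy: dict    # metric -> RatioSummary vs the efficacy reference
    safety: dict      # metric -> RatioSummary vs the safety reference
    pass_efficacy: bool
    pass_safety: bool
    adult_safety_q95: dict  # metric -> 95th pct of the adult safety reference


def evaluate_weight_bands(
    weights,
    doses,
    criteria: MatchingCriteria,
    population: PopulationSpec,
    n: int = 10_000,
    seed=None,
) -> list[WeightBandResult]:
    """Evaluate the exposure-matching criteria over a weight grid.

    For each weight and dose, the efficacy flag requires the median AUC
    ratio against the efficacy reference to be at or above the floor; the
    safety flag requires the median AUC *and* Cmax ratios against the
    safety reference to be at or below the cap.
    """
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    if weights.size == 0:
        raise ValidationError("weight grid must be non-empty")
    seq = _seed_seq(seed)
    ref_seed, cell_seed = seq.spawn(2)
    saf_rng, eff_rng = [np.random.default_rng(s) for s in ref_seed.spawn(2)]
    safety_ref = _draw_metrics(criteria.safety_ref_weight, criteria.safety_ref_dose, population, n, saf_rng)
    efficacy_ref = _draw_metrics(criteria.efficacy_ref_weight, criteria.efficacy_ref_dose, population, n, eff_rng)
    safety_q95 = {m: float(np.quantile(safety_ref[k], 0.95)) for m, k in (("AUC", "auc"), ("Cmax", "cmax"), ("Css", "css"))}

    results = []
    cell_rngs = iter(np.random.default_rng(s) for s in cell_seed.spawn(weights.size * doses.size))
    for w in weights:
        for d in doses:
            child = _draw_metrics(w, d, population, n, next(cell_rngs))
            eff = _summaries(child, efficacy_ref)
            saf = _summaries(child, safety_ref)
            results.append(
                WeightBandResult(
                    weight=float(w),
                    dose_mg=float(d),
                    efficacy=eff,
                    safety=saf,
                    pass_efficacy=eff["AUC"].median >= criteria.efficacy_floor,
                    pass_safety=(saf["AUC"].median <= criteria.safety_cap)
                    and (saf["Cmax"].median <= criteria.safety_cap),
                    adult_safety_q95=safety_q95,
                )
            )
    return results


def min_admissible_weight(
    grid,
    dose: float,
    criteria: MatchingCriteria,
    population: PopulationSpec,
    n: int = 10_000,
    seed=None,
):
    """Smallest grid weight passing both exposure-matching criteria at the
    given dose, or ``None`` if no grid weight is admissible."""
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("weight grid must be sorted ascending")
    bands = evaluate_weight_bands(grid, [dose], criteria, population, n=n, seed=seed)
    for band in bands:
        if band.pass_efficacy and band.pass_safety:
            return band.weight
    return None


def bands_to_frame(results: list[WeightBandResult]) -> pd.DataFrame:
    """Tidy table of weight-band results: one row per (weight, dose, metric,
    reference), with quantiles and pass flags."""
    rows = []
    for r in results:
        for ref_name, summaries in (("efficacy", r.efficacy), ("safety", r.safety)):
            for metric, s in summaries.items():
                rows.append(
                    {
                        "weight_kg": r.weight,
                        "dose_mg": r.dose_mg,
                        "reference": ref_name,
                        "metric": metric,
                        "median": s.median,
                        "q25": s.q25,
                        "q75": s.q75,
                        "q05": s.q05,
                        "q95": s.q95,
                        "pass_efficacy": r.pass_efficacy,
                        "pass_safety": r.pass_safety,
                    }
                )
    return pd.DataFrame(rows)
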