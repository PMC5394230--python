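"""Synthetic survey-data generator with exact ground truth.

Amounts are derived from target area-treatment totals
(``amount = AT * rate * area``) rather than sampled directly, so at zero
noise the pipeline must recover the configured per-crop AT trend, hazard
quotients, and contribution shares exactly.  Multiplicative log-normal
noise (mean 1) can be layered on amounts.  Each table draws from its own
pseudo-random stream split from the master seed, keyed by crop position,
so adding a crop does not perturb other tables' draws.
"""

from __future__ import annotations

import json
import math
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from herbtrends.errors import ConfigurationError
from herbtrends.normalize import IngredientMapping, write_mapping_table
from herbtrends.survey_io import (
    CropAreaRecord,
    ToxicityProfile,
    UseRecord,
    write_area_table,
    write_toxicity_table,
    write_use_table,
)

_SALT_NAMES = (
    "isopropylamine salt",
    "potassium salt",
    "dimethylamine salt",
    "ammonium salt",
    "diammonium salt",
    "sodium salt",
    "choline salt",
    "diethanolamine salt",
    "2-ethylhexyl ester",
    "butoxyethyl ester",
    "triisopropanolamine salt",
    "monoethanolamine salt",
)


@dataclass(frozen=True)
class CropPlan:
    """Ground-truth plan for one crop's surveyed series."""

    name: str
    years: tuple[int, ...]
    n_ais: int
    n_labels_per_ai: int = 1
    at_baseline: float = 1.0
    at_slope: float = 0.0
    area_ha: float = 1.0e6
    dominance_weights: tuple[float, ...] | None = None

    def weights(self) -> tuple[float, ...]:
        if self.dominance_weights is not None:
            return self.dominance_weights
        return tuple([1.0 / self.n_ais] * self.n_ais)

    def target_total(self, year: int) -> float:
        return self.at_baseline + self.at_slope * (year - self.years[0])


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    crops: tuple[CropPlan, ...]
    noel_range: tuple[float, float] = (0.03, 20000.0)
    ld50_range: tuple[float, float] = (112.0, 9000.0)
    censor_prob: float = 0.2
    censor_bound: float = 5000.0
    rate_range: tuple[float, float] = (0.05, 5.0)
    noise_sd: float = 0.0

    def validate(self) -> None:
        if not self.crops:
            raise ConfigurationError("at least one crop plan required")
        names = [c.name for c in self.crops]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate crop names: {names}")
        for lo, hi, label in (
            (*self.noel_range, "noel_range"),
            (*self.ld50_range, "ld50_range"),
            (*self.rate_range, "rate_range"),
        ):
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{label} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        if not 0.0 <= self.censor_prob <= 1.0:
            raise ConfigurationError(f"censor_prob must be in [0, 1], got {self.censor_prob}")
        if not self.censor_bound > 0:
            raise ConfigurationError(f"censor_bound must be > 0, got {self.censor_bound}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for plan in self.crops:
            if plan.n_ais < 1:
                raise ConfigurationError(f"{plan.name}: n_ais must be >= 1")
            if plan.n_labels_per_ai < 1:
                raise ConfigurationError(f"{plan.name}: n_labels_per_ai must be >= 1")
            if not plan.area_ha > 0:
                raise ConfigurationError(f"{plan.name}: area_ha must be > 0")
            if not plan.years or any(b <= a for a, b in zip(plan.years, plan.years[1:])):
                raise ConfigurationError(f"{plan.name}: years must be non-empty and strictly increasing")
            w = plan.weights()
            if len(w) != plan.n_ais or any(x < 0 for x in w) or not math.isclose(sum(w), 1.0, rel_tol=1e-9):
                raise ConfigurationError(f"{plan.name}: dominance_weights must be {plan.n_ais} non-negative values summing to 1")
            for year in plan.years:
                if plan.target_total(year) < 0:
                    raise ConfigurationError(f"{plan.name}: target AT total negative in {year}")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    use_records: list[UseRecord]
    toxicity: list[ToxicityProfile]
    areas: list[CropAreaRecord]
    mappings: list[IngredientMapping]
    truth: dict = field(default_factory=dict)


def generate_salt_labels(ai: str, k: int, seed: int) -> list[str]:
    """Return ``k`` distinct formulation labels that all stand for ``ai``.

    ``k == 1`` returns the ai name itself; larger ``k`` appends distinct
    salt/ester suffixes chosen deterministically from ``seed``.
    """
    if k < 1:
        raise ConfigurationError(f"salt multiplicity must be >= 1, got {k}")
    if k == 1:
        return [ai]
    rng = np.random.default_rng(seed)
    suffixes = [_SALT_NAMES[i] for i in rng.permutation(len(_SALT_NAMES))]
    while len(suffixes) < k:
        suffixes.append(f"formulation {len(suffixes) + 1}")
    return [f"{ai}, {suffix}" for suffix in suffixes[:k]]


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Generate use/toxicity/area tables plus an exact ground-truth record."""
    config.validate()

    use_records: list[UseRecord] = []
    toxicity: list[ToxicityProfile] = []
    areas: list[CropAreaRecord] = []
    mappings: list[IngredientMapping] = []
    truth: dict = {"at_series": {}, "per_ai_weights": {}, "toxicity": {}, "hq": {}, "shares": {}}

    for ci, plan in enumerate(config.crops):
        tox_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0, ci)))
        use_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, ci)))

        ais = [f"{plan.name} ai {i + 1:02d}" for i in range(plan.n_ais)]
        weights = plan.weights()

        noels = _log_uniform(tox_rng, *config.noel_range, plan.n_ais)
        ld50s = _log_uniform(tox_rng, *config.ld50_range, plan.n_ais)
        censored = tox_rng.random(plan.n_ais) < config.censor_prob
        ld50s = np.where(censored, config.censor_bound, ld50s)
        for ai, noel, ld50, cens in zip(ais, noels, ld50s, censored):
            toxicity.append(ToxicityProfile(ai=ai, acute_ld50=float(ld50), acute_censored=bool(cens), chronic_noel=float(noel)))
            truth["toxicity"][ai] = {"chronic_noel": float(noel), "acute_ld50": float(ld50), "censored": bool(cens)}

        rates = _log_uniform(use_rng, *config.rate_range, plan.n_ais)
        label_sets = []
        for ai in ais:
            label_seed = int(use_rng.integers(0, 2**31))
            labels = generate_salt_labels(ai, plan.n_labels_per_ai, label_seed)
            label_sets.append(labels)
            for label in labels:
                mappings.append(IngredientMapping(label=label, ai=ai))

        truth["per_ai_weights"][plan.name] = dict(zip(ais, map(float, weights)))
        truth["at_series"][plan.name] = []
        truth["hq"][plan.name] = {"chronic": [], "acute": []}
        truth["shares"][plan.name] = {"chronic": {}, "acute": {}}

        for year in plan.years:
            areas.append(CropAreaRecord(crop=plan.name, year=year, planted_area=plan.area_ha))
            total_at = plan.target_total(year)
            truth["at_series"][plan.name].append([int(year), float(total_at)])

            partial = {"chronic": [], "acute": []}
            for ai, w, rate, labels in zip(ais, weights, rates, label_sets):
                at_i = w * total_at
                amount = at_i * rate * plan.area_ha
                amount_mg_ha = at_i * rate * 1e6
                partial["chronic"].append(amount_mg_ha / truth["toxicity"][ai]["chronic_noel"])
                partial["acute"].append(amount_mg_ha / truth["toxicity"][ai]["acute_ld50"])
                if config.noise_sd > 0:
                    # mean-one multiplicative noise keeps slope estimates unbiased
                    z = use_rng.standard_normal()
                    amount *= math.exp(config.noise_sd * z - config.noise_sd**2 / 2)
                fractions = use_rng.dirichlet(np.ones(len(labels))) if len(labels) > 1 else np.array([1.0])
                for label, frac in zip(labels, fractions):
                    use_records.append(
                        UseRecord(crop=plan.name, year=year, ingredient_label=label, amount_applied=float(amount * frac), avg_rate=float(rate))
                    )

            for endpoint in ("chronic", "acute"):
                hq = float(sum(partial[endpoint]))
                truth["hq"][plan.name][endpoint].append([int(year), hq])
                truth["shares"][plan.name][endpoint][str(year)] = {
                    ai: (100.0 * p / hq if hq > 0 else 0.0) for ai, p in zip(ais, partial[endpoint])
                }

    return SyntheticDataset(config=config, use_records=use_records, toxicity=toxicity, areas=areas, mappings=mappings, truth=truth)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the tables survey_io reads, plus ground truth and a run config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "use": out / "use.csv",
        "toxicity": out / "toxicity.csv",
        "area": out / "area.csv",
        "mapping": out / "mapping.csv",
        "ground_truth": out / "ground_truth.json",
        "run_config": out / "run.yaml",
    }
    write_use_table(dataset.use_records, paths["use"])
    write_toxicity_table(dataset.toxicity, paths["toxicity"])
    write_area_table(dataset.areas, paths["area"])
    write_mapping_table(dataset.mappings, paths["mapping"])
    with paths["ground_truth"].open("w", encoding="utf-8") as handle:
        json.dump(dataset.truth, handle, indent=1, sort_keys=True)
    crops = [plan.name for plan in dataset.config.crops]
    years = [min(p.years[0] for p in dataset.config.crops), max(p.years[-1] for p in dataset.config.crops)]
    run_cfg = {
        "inputs": {k: str(paths[k]) for k in ("use", "toxicity", "area", "mapping")},
        "columns": {
            "use": {"crop": "crop", "year": "year", "ingredient": "ingredient", "amount": "amount_kg", "rate": "rate_kg_ha"},
            "area": {"crop": "crop", "year": "year", "area": "area_ha"},
        },
        "units": {"use": {"mass": "kg", "area": "ha"}, "area": {"area": "ha"}},
        "crops": crops,
        "years": years,
        "out_dir": str(out / "results"),
    }
    with paths["run_config"].open("w", encoding="utf-8") as handle:
        yaml.safe_dump(run_cfg, handle, sort_keys=True)
    return paths


def load_sim_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML."""
    with Path(path).open(encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "crops" not in raw or "seed" not in raw:
        raise ConfigurationError(f"{path}: simulation config needs 'seed' and 'crops'")
    plans = []
    for entry in raw["crops"]:
        try:
            plans.append(
                CropPlan(
                    name=entry["name"],
                    years=tuple(int(y) for y in entry["years"]),
                    n_ais=int(entry["n_ais"]),
                    n_labels_per_ai=int(entry.get("n_labels_per_ai", 1)),
                    at_baseline=float(entry.get("at_baseline", 1.0)),
                    at_slope=float(entry.get("at_slope", 0.0)),
                    area_ha=float(entry.get("area_ha", 1.0e6)),
                    dominance_weights=tuple(float(w) for w in entry["dominance_weights"]) if "dominance_weights" in entry else None,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"{path}: bad crop plan entry {entry!r}: {exc}") from exc
    config = SimulationConfig(
        seed=int(raw["seed"]),
        crops=tuple(plans),
        noel_range=tuple(raw.get("noel_range", (0.03, 20000.0))),  # type: ignore[arg-type]
        ld50_range=tuple(raw.get("ld50_range", (112.0, 9000.0))),  # type: ignore[arg-type]
        censor_prob=float(raw.get("censor_prob", 0.2)),
        censor_bound=float(raw.get("censor_bound", 5000.0)),
        rate_range=tuple(raw.get("rate_range", (0.05, 5.0))),  # type: ignore[arg-type]
        noise_sd=float(raw.get("noise_sd", 0.0)),
    )
    config.validate()
    return config


def demo_config(seed: int, noise_sd: float = 0.0) -> SimulationConfig:
    """Six-crop configuration mirroring the survey structure under study.

    Slopes span 0.05-0.09 area-treatments per year; rice is surveyed
    only six times in the 25-year window.
    """
    span = tuple(range(1990, 2016))
    return SimulationConfig(
        seed=seed,
        crops=(
            CropPlan("maize", span, n_ais=8, n_labels_per_ai=2, at_baseline=2.0, at_slope=0.05,
                     dominance_weights=(0.5, 0.2, 0.1, 0.05, 0.05, 0.04, 0.03, 0.03)),
            CropPlan("soybean", span, n_ais=6, n_labels_per_ai=3, at_baseline=1.5, at_slope=0.0),
            CropPlan("cotton", span, n_ais=6, n_labels_per_ai=1, at_baseline=1.8, at_slope=0.05),
            CropPlan("rice", (1990, 1995, 2000, 2006, 2010, 2013), n_ais=4, n_labels_per_ai=1,
                     at_baseline=2.5, at_slope=0.07, dominance_weights=(0.85, 0.05, 0.05, 0.05)),
            CropPlan("spring wheat", span, n_ais=5, n_labels_per_ai=2, at_baseline=1.2, at_slope=0.09),
            CropPlan("winter wheat", span, n_ais=5, n_labels_per_ai=1, at_baseline=0.8, at_slope=0.06),
        ),
        noise_sd=noise_sd,
    )
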