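"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of (config, seed): identical inputs give
bit-identical outputs.  Outputs use the domain types and table schemas of
:mod:`emtscreen.io`; concentrations are emitted in nM end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import four_pl
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    PlateLayout,
    WellRecord,
    WellRole,
)
from .screen import HitThresholds, classify_compound

__all__ = [
    "ConfigError",
    "ScreenSimConfig",
    "DoseResponseCurve",
    "DoseResponseSimConfig",
    "PanelSimConfig",
    "gen_screen_plates",
    "gen_dose_response",
    "gen_growth_curves",
    "gen_panel_expression",
    "make_screen_effects",
]


class ConfigError(ValueError):
    """A simulation config violates its invariants."""


# ---------------------------------------------------------------------------
# screen plates


@dataclass
class ScreenSimConfig:
    """Screen simulation: 96-well plates, two channels, per-field counts.

    ``compound_effects`` maps compound_id -> (g, r): the true surviving
    fraction of the green and red channel at the single screening dose.
    Per plate, column 1 holds vehicle wells, column 12 the positive
    control (suppresses the red channel only), columns 2-11 hold 80
    compound wells filled row-major across as many plates as needed.
    """

    compound_effects: Mapping[str, tuple[float, float]]
    n_vehicle: int = 8
    n_positive: int = 8
    fields_per_well: int = 13
    baseline_per_field: float = 300.0
    noise: str = "poisson"  # "poisson" | "negative_binomial"
    dispersion: float = 0.1  # NB only: var = mu + dispersion * mu^2
    positive_red_survival: float = 0.05
    screen_dose_nM: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cid, (g, r) in self.compound_effects.items():
            if not (0.0 <= g <= 1.0 and 0.0 <= r <= 1.0):
                raise ConfigError(
                    f"compound {cid}: viability fractions ({g}, {r}) outside [0, 1]"
                )
        if self.baseline_per_field <= 0:
            raise ConfigError("baseline_per_field must be > 0")
        if not (0.0 <= self.positive_red_survival <= 1.0):
            raise ConfigError("positive_red_survival outside [0, 1]")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ConfigError(f"unknown noise model {self.noise!r}")
        if not (1 <= self.n_vehicle <= 8 and 0 <= self.n_positive <= 8):
            raise ConfigError("control well counts must fit in one column")


_ROWS = "ABCDEFGH"
_COMPOUND_COLS = range(2, 12)


def _screen_layouts(cfg: ScreenSimConfig) -> list[PlateLayout]:
    compounds = list(cfg.compound_effects)
    per_plate = len(_ROWS) * len(_COMPOUND_COLS)
    n_plates = math.ceil(len(compounds) / per_plate)
    layouts = []
    k = 0
    for p in range(n_plates):
        wells: dict[str, WellRole] = {}
        for i, row in enumerate(_ROWS):
            wells[f"{row}01"] = (
                WellRole("vehicle") if i < cfg.n_vehicle else WellRole("empty")
            )
            wells[f"{row}12"] = (
                WellRole(
                    "positive_control",
                    concentration=350.0,
                    concentration_unit="ug/ml",
                )
                if i < cfg.n_positive
                else WellRole("empty")
            )
        for row in _ROWS:
            for col in _COMPOUND_COLS:
                if k < len(compounds):
                    wells[f"{row}{col:02d}"] = WellRole(
                        "compound",
                        compound_id=compounds[k],
                        concentration=cfg.screen_dose_nM,
                    )
                    k += 1
                else:
                    wells[f"{row}{col:02d}"] = WellRole("empty")
        layouts.append(PlateLayout(f"P{p + 1:03d}", wells))
    return layouts


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, cfg: ScreenSimConfig
) -> np.ndarray:
    if cfg.noise == "poisson":
        return rng.poisson(mean)
    n = 1.0 / cfg.dispersion
    p = n / (n + np.maximum(mean, 1e-12))
    return rng.negative_binomial(n, p)


def gen_screen_plates(
    cfg: ScreenSimConfig,
    thresholds: HitThresholds = HitThresholds(),
) -> tuple[list[WellRecord], list[PlateLayout], pd.DataFrame]:
    """Simulate a single-dose screen.

    Per-field counts are drawn with expectation
    baseline_per_field * true surviving fraction of the well's channel
    (vehicle: 1.0 both channels; positive control: 1.0 green,
    ``positive_red_survival`` red).  The truth table records each
    compound's planted class under the hit rules applied to its exact
    (g, r), independent of any noise realization.
    """
    rng = np.random.default_rng(cfg.seed)
    layouts = _screen_layouts(cfg)
    records: list[WellRecord] = []
    for layout in layouts:
        for well in sorted(layout.wells):
            role = layout.wells[well]
            if role.kind == "empty":
                continue
            if role.kind == "vehicle":
                fracs = (1.0, 1.0)
            elif role.kind == "positive_control":
                fracs = (1.0, cfg.positive_red_survival)
            else:
                fracs = cfg.compound_effects[role.compound_id]
            for channel, frac in zip(("green", "red"), fracs):
                mean = np.full(cfg.fields_per_well, cfg.baseline_per_field * frac)
                counts = _draw_counts(rng, mean, cfg)
                records.extend(
                    WellRecord(layout.plate_id, well, channel, f + 1, int(c))
                    for f, c in enumerate(counts)
                )
    truth_rows = []
    for cid, (g, r) in cfg.compound_effects.items():
        planted_class, _ = classify_compound(g, r, thresholds)
        truth_rows.append(
            {"compound_id": cid, "true_g": g, "true_r": r, "true_class": planted_class}
        )
    truth = pd.DataFrame(truth_rows)
    return records, layouts, truth


def make_screen_effects(
    n_compounds: int,
    n_emt: int = 0,
    n_epi: int = 0,
    n_pan: int = 0,
    emt_effect: tuple[float, float] = (0.9, 0.2),
    epi_effect: tuple[float, float] = (0.3, 0.95),
    pan_effect: tuple[float, float] = (0.2, 0.2),
    inactive_jitter: float = 0.03,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Build a compound-effect table with planted selective profiles.

    Planted compounds are interleaved deterministically across the compound
    list; the inactive background sits near (1, 1) with a small jitter.
    """
    if n_emt + n_epi + n_pan > n_compounds:
        raise ConfigError("more planted compounds than compounds")
    rng = np.random.default_rng(seed)
    ids = [f"CPD{i + 1:05d}" for i in range(n_compounds)]
    planted = (
        [emt_effect] * n_emt + [epi_effect] * n_epi + [pan_effect] * n_pan
    )
    slots = np.linspace(0, n_compounds - 1, num=len(planted), dtype=int) if planted else []
    effects: dict[str, tuple[float, float]] = {}
    planted_at = dict(zip(slots, planted))
    for i, cid in enumerate(ids):
        if i in planted_at:
            effects[cid] = planted_at[i]
        else:
            g, r = 1.0 + inactive_jitter * rng.standard_normal(2)
            effects[cid] = (float(np.clip(g, 0.0, 1.0)), float(np.clip(r, 0.0, 1.0)))
    return effects


# ---------------------------------------------------------------------------
# dose-response tables


@dataclass(frozen=True)
class DoseResponseCurve:
    """True 4PL parameters for one (compound, cell line)."""

    compound_id: str
    cell_line: str
    bottom: float = 0.0
    top: float = 1.0
    hill: float = 1.0
    ec50_nM: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bottom < self.top):
            raise ConfigError("need 0 <= bottom < top")
        if self.hill <= 0 or self.ec50_nM <= 0:
            raise ConfigError("hill and ec50 must be > 0")


@dataclass
class DoseResponseSimConfig:
    curves: Sequence[DoseResponseCurve]
    top_dose_nM: float = 10000.0
    dilution_factor: float = 3.0
    n_points: int = 9
    replicates: int = 3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1.0:
            raise ConfigError("dilution factor must be > 1")
        if self.top_dose_nM <= 0 or self.n_points < 2 or self.replicates < 1:
            raise ConfigError("invalid dilution series")
        if self.noise_sd < 0:
            raise ConfigError("noise SD must be >= 0")

    @property
    def concentrations_nM(self) -> np.ndarray:
        return self.top_dose_nM / self.dilution_factor ** np.arange(self.n_points)


def gen_dose_response(
    cfg: DoseResponseSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate normalized-viability dose-response tables.

    viability = 4PL(conc; truth) + Normal(0, noise_sd), truncated at 0.
    Returns (viability table, truth table); concentrations in nM.
    """
    rng = np.random.default_rng(cfg.seed)
    conc = cfg.concentrations_nM
    rows = []
    for curve in cfg.curves:
        clean = four_pl(conc, curve.bottom, curve.top, curve.hill, curve.ec50_nM)
        for rep in range(1, cfg.replicates + 1):
            noisy = np.maximum(
                clean + cfg.noise_sd * rng.standard_normal(len(conc)), 0.0
            )
            for c, v in zip(conc, noisy):
                rows.append(
                    {
                        "compound_id": curve.compound_id,
                        "cell_line": curve.cell_line,
                        "conc_nM": float(c),
                        "replicate": rep,
                        "viability": float(v),
                    }
                )
    truth = pd.DataFrame(
        [
            {
                "compound_id": c.compound_id,
                "cell_line": c.cell_line,
                "bottom": c.bottom,
                "top": c.top,
                "hill": c.hill,
                "ec50_nM": c.ec50_nM,
            }
            for c in cfg.curves
        ]
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# growth curves


def gen_growth_curves(
    doubling_times_h: Mapping[str, float],
    timepoints_h: Sequence[float],
    x0: float = 50_000.0,
    treatment_rate_factor: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential growth curves with multiplicative lognormal noise.

    One control and (when ``treatment_rate_factor != 1``) one treated
    condition per line; the treated growth rate is the control rate times
    the factor.  Counts are real-valued expectations when ``noise_cv`` is 0.
    """
    for line, dt in doubling_times_h.items():
        if dt <= 0:
            raise ConfigError(f"{line}: doubling time must be > 0")
    if any(t < 0 for t in timepoints_h):
        raise ConfigError("negative timepoint")
    if x0 <= 0:
        raise ConfigError("inoculum must be > 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    conditions = (
        [("control", 1.0)]
        if treatment_rate_factor == 1.0
        else [("control", 1.0), ("treated", treatment_rate_factor)]
    )
    rows = []
    for line in sorted(doubling_times_h):
        rate = 1.0 / doubling_times_h[line]  # doublings per hour
        for condition, factor in conditions:
            for t in timepoints_h:
                count = x0 * 2.0 ** (rate * factor * t)
                if sigma > 0:
                    count *= math.exp(
                        rng.normal(-0.5 * sigma**2, sigma)
                    )  # mean-preserving
                rows.append(
                    {
                        "cell_line": line,
                        "condition": condition,
                        "time_h": float(t),
                        "count": float(count),
                        "x0": float(x0),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# panel expression


@dataclass
class PanelSimConfig:
    n_sensitive: int = 13
    n_resistant: int = 11
    n_genes: int = 1000
    enriched_set_size: int = 50
    enriched_set_name: str = "PLANTED_UP_IN_SENSITIVE"
    effect_size: float = 2.0  # mean shift in sensitive group, units of noise SD
    noise_sd: float = 1.0
    n_decoy_sets: int = 15
    decoy_size: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensitive < 2 or self.n_resistant < 2:
            raise ConfigError("need >= 2 samples per class")
        if self.enriched_set_size > self.n_genes:
            raise ConfigError("enriched set larger than gene universe")
        if self.effect_size < 0:
            raise ConfigError("effect size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise SD must be > 0")
        if self.decoy_size > self.n_genes - self.enriched_set_size:
            raise ConfigError("decoy sets larger than background gene pool")


def gen_panel_expression(
    cfg: PanelSimConfig,
) -> tuple[ExpressionMatrix, GeneSetCollection]:
    """Expression matrix with one gene set up-shifted in the sensitive group.

    Background genes are iid Normal(0, noise_sd) in every sample; the
    designated set's genes get + effect_size * noise_sd added in sensitive
    samples.  Decoy sets are drawn from the background genes.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    samples = [f"SENS{i + 1:02d}" for i in range(cfg.n_sensitive)] + [
        f"RES{i + 1:02d}" for i in range(cfg.n_resistant)
    ]
    phenotype = {
        s: ("sensitive" if s.startswith("SENS") else "resistant") for s in samples
    }
    values = cfg.noise_sd * rng.standard_normal((cfg.n_genes, len(samples)))
    enriched_idx = rng.choice(cfg.n_genes, size=cfg.enriched_set_size, replace=False)
    values[np.ix_(enriched_idx, np.arange(cfg.n_sensitive))] += (
        cfg.effect_size * cfg.noise_sd
    )
    background = np.setdiff1d(np.arange(cfg.n_genes), enriched_idx)
    sets = {cfg.enriched_set_name: sorted(genes[i] for i in enriched_idx)}
    for d in range(cfg.n_decoy_sets):
        decoy_idx = rng.choice(background, size=cfg.decoy_size, replace=False)
        sets[f"DECOY{d + 1:03d}"] = sorted(genes[i] for i in decoy_idx)
    expr = ExpressionMatrix(
        genes=genes, samples=samples, values=values, phenotype=phenotype
    )
    return expr, GeneSetCollection(sets, name="simulated")
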