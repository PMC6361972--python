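"""Plate normalization, assay-quality statistics and selectivity hit calling.

Normalization is per plate: each well's per-channel total (sum over imaged
fields) is divided by the mean total of the vehicle wells of the same plate,
so vehicle wells average exactly 1.0 per channel by construction.

Hit calling applies three-criterion rule sets to the normalized green and
red viabilities and their ratio R/G = red_norm / green_norm:

* selective against the red (EMT-like) line:
  green >= g_min, red <= r_max, R/G <= ratio_max;
* selective against the green (epithelial) line:
  green <= g_max, red >= r_min, R/G >= ratio_min;
* cytotoxic to both: green <= pan_max and red <= pan_max;
* otherwise inactive.

Quality statistics use the conventional control-separation formulas
S/N = (mu_n - mu_p) / sd_n, S/B = mu_n / mu_p and
Z' = 1 - 3 (sd_p + sd_n) / (mu_n - mu_p), with sample (n-1) standard
deviations.  The default QC channel is red because the positive control
(hygromycin) acts on the hygromycin-sensitive red line only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import PlateLayout, WellRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationError",
    "QCError",
    "HitThresholds",
    "NormalizedWell",
    "QCStats",
    "HitCall",
    "well_totals",
    "normalize_plate",
    "compute_qc",
    "compute_qc_screen",
    "aggregate_compounds",
    "call_hits",
]


class NormalizationError(ValueError):
    """Vehicle-well mean is zero for a channel; normalization impossible."""


class QCError(ValueError):
    """Not enough control wells to compute quality statistics."""


@dataclass(frozen=True)
class HitThresholds:
    """Hit-calling thresholds (defaults from the screen's published rules)."""

    g_min: float = 0.55      # red-selective rule (a): green survives
    r_max: float = 0.41      # red-selective rule (b): red killed
    ratio_max: float = 0.65  # red-selective rule (c)
    g_max: float = 0.41      # green-selective rule (a): green killed
    r_min: float = 0.46      # green-selective rule (b): red survives
    ratio_min: float = 1.80  # green-selective rule (c)
    pan_max: float = 0.41    # both channels at or below -> pan-cytotoxic


@dataclass(frozen=True)
class NormalizedWell:
    plate_id: str
    well: str
    kind: str
    compound_id: str | None
    green_norm: float
    red_norm: float

    def __post_init__(self) -> None:
        if self.green_norm < 0 or self.red_norm < 0:
            raise ValueError("normalized viabilities must be >= 0")

    @property
    def ratio_rg(self) -> float | None:
        """red_norm / green_norm; undefined (None) when green_norm == 0."""
        if self.green_norm == 0:
            return None
        return self.red_norm / self.green_norm


@dataclass(frozen=True)
class QCStats:
    plate_id: str
    channel: str
    mu_n: float
    mu_p: float
    sd_n: float
    sd_p: float
    z_prime: float
    s_over_n: float
    s_over_b: float
    n_negative: int
    n_positive: int


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    green_norm: float
    red_norm: float
    ratio_rg: float | None
    hit_class: str  # emt_selective | epithelial_selective | pan_cytotoxic | inactive
    criteria: dict = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str = ""


def well_totals(
    records: Iterable[WellRecord],
) -> dict[tuple[str, str, str], int]:
    """Sum field counts into per-(plate, well, channel) totals."""
    totals: dict[tuple[str, str, str], int] = {}
    for r in records:
        key = (r.plate_id, r.well, r.channel)
        totals[key] = totals.get(key, 0) + r.count
    return totals


def normalize_plate(
    records: Iterable[WellRecord], layout: PlateLayout
) -> list[NormalizedWell]:
    """Normalize per-well totals to the vehicle-well mean of the plate."""
    totals = well_totals(r for r in records if r.plate_id == layout.plate_id)
    vehicle_wells = layout.wells_of_kind("vehicle")
    if not vehicle_wells:
        raise NormalizationError(
            f"plate {layout.plate_id}: no vehicle wells in layout"
        )
    vehicle_mean = {}
    for channel in ("green", "red"):
        values = [totals.get((layout.plate_id, w, channel), 0) for w in vehicle_wells]
        mean = float(np.mean(values))
        if mean == 0:
            raise NormalizationError(
                f"plate {layout.plate_id}, channel {channel}: "
                "vehicle-well mean is zero"
            )
        vehicle_mean[channel] = mean

    wells_present = sorted({(r.plate_id, r.well) for r in records
                            if r.plate_id == layout.plate_id})
    out = []
    for plate_id, well in wells_present:
        role = layout.wells.get(well)
        if role is None or role.kind == "empty":
            continue
        out.append(
            NormalizedWell(
                plate_id=plate_id,
                well=well,
                kind=role.kind,
                compound_id=role.compound_id,
                green_norm=totals.get((plate_id, well, "green"), 0)
                / vehicle_mean["green"],
                red_norm=totals.get((plate_id, well, "red"), 0)
                / vehicle_mean["red"],
            )
        )
    return out


def _channel_value(w: NormalizedWell, channel: str) -> float:
    return w.green_norm if channel == "green" else w.red_norm


def compute_qc(
    normalized: Sequence[NormalizedWell],
    channel: str = "red",
    plate_id: str | None = None,
) -> QCStats:
    """Compute Z', S/N and S/B from the control wells of one plate.

    Negative controls are vehicle wells, positive controls are
    positive-control wells.  Requires >= 2 of each.  Degenerate cases are
    reported as NaN (mu_n == mu_p: Z' and S/N undefined; mu_p == 0: S/B
    undefined) rather than raised.
    """
    if channel not in ("green", "red"):
        raise ValueError(f"unknown channel {channel!r}")
    if channel == "green":
        logger.warning(
            "QC on the green channel: the assay design has no green-acting "
            "positive control; interpret with caution"
        )
    wells = [w for w in normalized if plate_id is None or w.plate_id == plate_id]
    neg = [_channel_value(w, channel) for w in wells if w.kind == "vehicle"]
    pos = [_channel_value(w, channel) for w in wells if w.kind == "positive_control"]
    if len(neg) < 2 or len(pos) < 2:
        raise QCError(
            f"need >= 2 negative and >= 2 positive control wells, "
            f"got {len(neg)} and {len(pos)}"
        )
    mu_n, mu_p = float(np.mean(neg)), float(np.mean(pos))
    sd_n = float(np.std(neg, ddof=1))
    sd_p = float(np.std(pos, ddof=1))
    window = mu_n - mu_p
    if window == 0:
        z_prime = math.nan
        s_over_n = math.nan
    else:
        z_prime = 1.0 - 3.0 * (sd_p + sd_n) / window
        s_over_n = window / sd_n if sd_n > 0 else math.inf
    s_over_b = mu_n / mu_p if mu_p != 0 else math.nan
    pid = plate_id if plate_id is not None else (
        wells[0].plate_id if len({w.plate_id for w in wells}) == 1 else "screen"
    )
    return QCStats(
        plate_id=pid,
        channel=channel,
        mu_n=mu_n,
        mu_p=mu_p,
        sd_n=sd_n,
        sd_p=sd_p,
        z_prime=z_prime,
        s_over_n=s_over_n,
        s_over_b=s_over_b,
        n_negative=len(neg),
        n_positive=len(pos),
    )


def compute_qc_screen(
    normalized: Sequence[NormalizedWell], channel: str = "red"
) -> tuple[list[QCStats], QCStats]:
    """Per-plate QC plus the across-plate average of each statistic."""
    plate_ids = sorted({w.plate_id for w in normalized})
    per_plate = [compute_qc(normalized, channel, plate_id=p) for p in plate_ids]

    def avg(attr: str) -> float:
        return float(np.mean([getattr(s, attr) for s in per_plate]))

    average = QCStats(
        plate_id="screen-average",
        channel=channel,
        mu_n=avg("mu_n"),
        mu_p=avg("mu_p"),
        sd_n=avg("sd_n"),
        sd_p=avg("sd_p"),
        z_prime=avg("z_prime"),
        s_over_n=avg("s_over_n"),
        s_over_b=avg("s_over_b"),
        n_negative=sum(s.n_negative for s in per_plate),
        n_positive=sum(s.n_positive for s in per_plate),
    )
    return per_plate, average


def aggregate_compounds(
    normalized: Iterable[NormalizedWell],
) -> dict[str, tuple[float, float]]:
    """Mean (green_norm, red_norm) per compound across replicate wells."""
    acc: dict[str, list[tuple[float, float]]] = {}
    for w in normalized:
        if w.kind == "compound" and w.compound_id is not None:
            acc.setdefault(w.compound_id, []).append((w.green_norm, w.red_norm))
    return {
        c: (
            float(np.mean([g for g, _ in vals])),
            float(np.mean([r for _, r in vals])),
        )
        for c, vals in acc.items()
    }


def classify_compound(
    green_norm: float, red_norm: float, thresholds: HitThresholds
) -> tuple[str, dict]:
    """Apply the three-criterion rule sets to one compound's (g, r)."""
    t = thresholds
    ratio = red_norm / green_norm if green_norm > 0 else None
    criteria = {
        "emt_a": green_norm >= t.g_min,
        "emt_b": red_norm <= t.r_max,
        "emt_c": ratio is not None and ratio <= t.ratio_max,
        "epi_a": green_norm <= t.g_max,
        "epi_b": red_norm >= t.r_min,
        "epi_c": ratio is not None and ratio >= t.ratio_min,
    }
    if ratio is None:
        # green completely killed: ratio undefined, only the pan check applies
        if red_norm <= t.pan_max:
            return "pan_cytotoxic", criteria
        return "inactive", criteria
    if criteria["emt_a"] and criteria["emt_b"] and criteria["emt_c"]:
        return "emt_selective", criteria
    if criteria["epi_a"] and criteria["epi_b"] and criteria["epi_c"]:
        return "epithelial_selective", criteria
    if green_norm <= t.pan_max and red_norm <= t.pan_max:
        return "pan_cytotoxic", criteria
    return "inactive", criteria


def call_hits(
    per_compound: Mapping[str, tuple[float, float]],
    thresholds: HitThresholds = HitThresholds(),
    exclusions: Mapping[str, str] | None = None,
) -> list[HitCall]:
    """Classify every compound; excluded compounds keep their data-derived
    class but are flagged for removal from reported hit lists.

    ``exclusions`` maps compound_id -> reason text (e.g. "auto-fluorescent");
    it is an input annotation, never computed here.
    """
    exclusions = exclusions or {}
    calls = []
    for compound_id in sorted(per_compound):
        g, r = per_compound[compound_id]
        hit_class, criteria = classify_compound(g, r, thresholds)
        calls.append(
            HitCall(
                compound_id=compound_id,
                green_norm=g,
                red_norm=r,
                ratio_rg=r / g if g > 0 else None,
                hit_class=hit_class,
                criteria=criteria,
                excluded=compound_id in exclusions,
                exclusion_reason=exclusions.get(compound_id, ""),
            )
        )
    return calls


def hit_list(calls: Iterable[HitCall], hit_class: str) -> list[str]:
    """Reported hit list for one class: excluded compounds removed."""
    return sorted(
        c.compound_id for c in calls if c.hit_class == hit_class and not c.excluded
    )
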