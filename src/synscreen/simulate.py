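"""Synthetic data generators with planted ground truth.

Three generators emulate the three kinds of input the pipeline consumes:

* a single-dose combination screen of a compound library against two
  ferroptosis inducers (erastin-like "E" and RSL3-like "R") in 96-well
  plates, with planted synergistic compounds;
* single-agent and constant-ratio combination dose-response series drawn
  from the median-effect model;
* subcutaneous xenograft growth measured by calipers every few days, with
  treatment-specific exponential growth rates.

Each generator returns its data table together with a separate ground-truth
artifact.  Truth is never consumed by any pipeline stage; it exists only so
that recovery tests can compare pipeline output against what was planted.

Screen generative model
-----------------------
Each compound c has a single-agent effect fa_c drawn uniformly from a
configured range.  Non-hit combinations follow Bliss independence,
``fa_comb = fa_c + fa_i - fa_c * fa_i``; planted hits additionally receive an
additive Bliss-excess boost delta (clamped so fa stays <= 1).  Under this
model the true Synergy Index has the closed form ``SI = 1 - fa_c`` for
non-hits and ``SI = 1 - fa_c + delta / fa_i`` for unclamped hits, which makes
planted truth analytically checkable.

Raw plate signal is emitted on an absorbance-like scale::

    signal = (1 - fa_true) * (vehicle - blank) + blank + N(0, noise_sd)

truncated from below at ``0.5 * blank`` (a plate reader never reports signal
far under the medium-only background).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .median_effect import DoseResponseSeries

__all__ = [
    "ScreenSimConfig",
    "MedianEffectParams",
    "XenoSimConfig",
    "ScreenTruth",
    "ComboDesign",
    "simulate_screen",
    "simulate_dose_response",
    "simulate_combo_matrix",
    "simulate_xenograft",
    "bliss_combination",
]

#: fixed longest/shortest caliper aspect ratio used when emitting diameters
CALIPER_ASPECT = 1.25

#: dose metadata attached to screen arms (uM); values are annotation only,
#: the screen is a single-dose design and no stage computes on them
SCREEN_DOSES = {"cpd": 10.0, "E": 10.0, "R": 1.0}


def bliss_combination(fa_1: float, fa_2: float):
    """Bliss-independence combined effect 1 - (1-fa_1)(1-fa_2)."""
    return fa_1 + fa_2 - fa_1 * fa_2


@dataclass(frozen=True)
class ScreenSimConfig:
    """Configuration of the simulated combination screen.

    Defaults reproduce the reference screen: a 303-compound library against
    two inducers each killing 30% alone, 10 planted synergistic compounds
    boosted delta = 0.35 above Bliss, triplicate wells, and additive plate
    noise of 0.02 on a vehicle-minus-blank signal span of ~1.
    """

    n_compounds: int = 303
    hit_indices: frozenset[int] = frozenset(range(10))
    fa_cpd_range: tuple[float, float] = (0.0, 0.4)
    fa_inducer: Mapping[str, float] = None  # default {"E": 0.3, "R": 0.3}
    bliss_excess_hits: float = 0.35
    noise_sd: float = 0.02
    n_replicates: int = 3
    seed: int = 0
    vehicle_signal: float = 1.0
    blank_signal: float = 0.05
    n_control_wells: int = 4

    def __post_init__(self):
        if self.fa_inducer is None:
            object.__setattr__(self, "fa_inducer", {"E": 0.3, "R": 0.3})
        object.__setattr__(self, "hit_indices", frozenset(self.hit_indices))
        self.validate()

    def validate(self) -> None:
        if self.n_compounds < 1:
            raise ConfigError("n_compounds must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        lo, hi = self.fa_cpd_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("fa_cpd_range must be an interval within [0, 1]")
        for label, fa in self.fa_inducer.items():
            if not 0.0 < fa < 1.0:
                raise ConfigError(
                    f"fa_inducer[{label!r}]={fa} must lie in (0, 1): "
                    "it is the Synergy Index denominator"
                )
        if self.bliss_excess_hits < 0:
            raise ConfigError("bliss_excess_hits (delta) must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.hit_indices and max(self.hit_indices) >= self.n_compounds:
            raise ConfigError("hit_indices out of range")
        if min(self.hit_indices, default=0) < 0:
            raise ConfigError("hit_indices must be nonnegative")
        if self.vehicle_signal <= self.blank_signal:
            raise ConfigError("vehicle_signal must exceed blank_signal")


@dataclass(frozen=True)
class ScreenTruth:
    """Ground truth emitted alongside a simulated screen.

    ``compounds`` has one row per compound: true fa_cpd, fa_comb per inducer,
    SI per inducer, and the is_hit flag (the hit rule applied to true
    values).  ``fa_inducer`` maps inducer label to its true single-agent
    effect.  Pipeline stages must never read this object.
    """

    compounds: pd.DataFrame
    fa_inducer: dict[str, float]


@dataclass(frozen=True)
class MedianEffectParams:
    """True parameters of a median-effect dose-response: fa = 1/(1+(Dm/D)^m)."""

    Dm: float
    m: float

    def __post_init__(self):
        if self.Dm <= 0:
            raise ConfigError(f"Dm={self.Dm} must be > 0")
        if self.m <= 0:
            raise ConfigError(f"m={self.m} must be > 0")

    def fa(self, dose):
        """Noiseless fraction affected at the given dose(s)."""
        dose = np.asarray(dose, dtype=float)
        if np.any(dose <= 0):
            raise ConfigError("doses must be strictly positive (log-domain model)")
        return 1.0 / (1.0 + (self.Dm / dose) ** self.m)


@dataclass(frozen=True)
class XenoSimConfig:
    """Configuration of the simulated xenograft study.

    Each group grows exponentially, V(t) = v0 * exp(g t), from a common
    starting volume of ~100 mm^3 (the randomization threshold), with caliper
    measurements every ``measurement_interval`` days up to ``horizon``.
    """

    groups: Sequence[tuple[str, float]] = (("vehicle", 0.10), ("combo", 0.02))
    v0: float = 100.0
    measurement_interval: int = 4
    horizon: int = 28
    caliper_noise_sd: float = 0.3
    n_animals: int = 6
    seed: int = 0
    control: str | None = None  # defaults to the first group label

    def __post_init__(self):
        if not self.groups:
            raise ConfigError("at least one group required")
        for label, g in self.groups:
            if not np.isfinite(g):
                raise ConfigError(f"growth rate for {label!r} not finite")
        if self.v0 <= 0:
            raise ConfigError("v0 must be > 0")
        if self.measurement_interval < 1 or self.horizon < 0:
            raise ConfigError("measurement schedule invalid")
        if self.caliper_noise_sd < 0 or self.n_animals < 1:
            raise ConfigError("noise/animal count invalid")
        if self.control is None:
            object.__setattr__(self, "control", self.groups[0][0])
        elif self.control not in {lab for lab, _ in self.groups}:
            raise ConfigError(f"control group {self.control!r} not in groups")


def _well_labels(n: int) -> list[str]:
    """Standard 96-well labels A01..H12, extended row-wise beyond 96 plates'
    worth if a logical plate overflows."""
    labels = []
    rows = string.ascii_uppercase
    i = 0
    while len(labels) < n:
        row, col = divmod(i, 12)
        labels.append(f"{rows[row % 26]}{col + 1:02d}")
        i += 1
    return labels


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate the combination screen; return (wells table, truth).

    The wells table has columns plate, well, compound_id, arm, dose,
    replicate, signal.  Arms: vehicle, blank, cpd, inducer_E, inducer_R,
    combo_E, combo_R (one inducer_*/combo_* pair per configured inducer).
    Compounds are packed onto 96-well plates, each plate carrying its own
    vehicle, blank and inducer-alone wells so normalization is plate-local.

    Raises
    ------
    ConfigError
        If any planted hit's expected Synergy Index is not > 1 for every
        inducer (delta too small relative to the drawn fa_cpd): the planted
        truth would be unusable for recovery testing.
    """
    rng = np.random.default_rng(config.seed)
    inducers = dict(config.fa_inducer)
    lo, hi = config.fa_cpd_range
    fa_cpd = rng.uniform(lo, hi, size=config.n_compounds)

    # --- truth ------------------------------------------------------------
    truth_rows = []
    for c in range(config.n_compounds):
        is_planted = c in config.hit_indices
        row = {"compound_id": f"CPD{c:04d}", "fa_cpd": fa_cpd[c]}
        for lab, fa_i in inducers.items():
            fa_comb = bliss_combination(fa_cpd[c], fa_i)
            if is_planted:
                fa_comb = min(1.0, fa_comb + config.bliss_excess_hits)
            si = (fa_comb - fa_cpd[c]) / fa_i
            row[f"fa_comb_{lab}"] = fa_comb
            row[f"si_{lab}"] = si
            if is_planted and si <= 1.0:
                raise ConfigError(
                    f"planted hit {row['compound_id']} has expected "
                    f"SI_{lab}={si:.3f} <= 1; increase bliss_excess_hits"
                )
        row["is_hit"] = is_planted and all(
            row[f"si_{lab}"] > 1.0 and row[f"fa_comb_{lab}"] >= 0.5
            for lab in inducers
        )
        truth_rows.append(row)
    truth = ScreenTruth(
        compounds=pd.DataFrame(truth_rows), fa_inducer=dict(inducers)
    )

    # --- plate packing ----------------------------------------------------
    r = config.n_replicates
    wells_per_cpd = (1 + len(inducers)) * r  # cpd + one combo per inducer
    controls = 2 * config.n_control_wells + len(inducers) * r
    capacity = max(1, (96 - controls) // wells_per_cpd)

    span = config.vehicle_signal - config.blank_signal
    floor = 0.5 * config.blank_signal

    def emit(rows, plate, well, compound_id, arm, dose, replicate, fa_true):
        mean = (1.0 - fa_true) * span + config.blank_signal
        noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
        rows.append(
            (plate, well, compound_id, arm, dose, replicate,
             max(mean + noise, floor))
        )

    rows: list[tuple] = []
    for p_start in range(0, config.n_compounds, capacity):
        plate_cpds = range(p_start, min(p_start + capacity, config.n_compounds))
        plate_id = f"P{p_start // capacity + 1:03d}"
        n_wells = (
            2 * config.n_control_wells
            + len(inducers) * r
            + len(plate_cpds) * wells_per_cpd
        )
        wells = iter(_well_labels(n_wells))
        for k in range(config.n_control_wells):
            emit(rows, plate_id, next(wells), "", "vehicle", np.nan, k + 1, 0.0)
        for k in range(config.n_control_wells):
            # blanks are medium-only: fa_true = 1 puts the mean at blank_signal
            emit(rows, plate_id, next(wells), "", "blank", np.nan, k + 1, 1.0)
        for lab, fa_i in inducers.items():
            for k in range(r):
                emit(rows, plate_id, next(wells), "", f"inducer_{lab}",
                     SCREEN_DOSES.get(lab, np.nan), k + 1, fa_i)
        for c in plate_cpds:
            cid = f"CPD{c:04d}"
            t = truth.compounds.iloc[c]
            for k in range(r):
                emit(rows, plate_id, next(wells), cid, "cpd",
                     SCREEN_DOSES["cpd"], k + 1, fa_cpd[c])
            for lab in inducers:
                for k in range(r):
                    emit(rows, plate_id, next(wells), cid, f"combo_{lab}",
                         SCREEN_DOSES["cpd"], k + 1, t[f"fa_comb_{lab}"])

    wells_df = pd.DataFrame(
        rows,
        columns=["plate", "well", "compound_id", "arm", "dose",
                 "replicate", "signal"],
    )
    return wells_df, truth


def simulate_dose_response(
    params: MedianEffectParams,
    doses: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    drug_id: str = "drug",
) -> DoseResponseSeries:
    """Draw a dose-response series from the median-effect model.

    fa(D) = 1/(1 + (Dm/D)^m) plus additive Gaussian noise, clipped to [0, 1].
    With noise_sd = 0 the emitted values equal the model exactly (no clipping
    artifact).
    """
    doses = np.asarray(doses, dtype=float)
    fa = params.fa(doses)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fa = np.clip(fa + rng.normal(0.0, noise_sd, size=fa.shape), 0.0, 1.0)
    return DoseResponseSeries(drug_id, doses, fa)


@dataclass(frozen=True)
class ComboDesign:
    """A simulated constant-ratio combination experiment.

    ``combo`` is the mixture treated as one agent on total dose; ``drug_a``
    and ``drug_b`` are the component single-agent series.  ``params_combo``
    records the true combination parameters; ``dm_ref`` is the
    Loewe-additive reference Dm for the ratio (so potency_shift =
    params_combo.Dm / dm_ref).
    """

    combo: DoseResponseSeries
    drug_a: DoseResponseSeries
    drug_b: DoseResponseSeries
    ratio: tuple[float, float]
    dm_ref: float
    params_a: MedianEffectParams
    params_b: MedianEffectParams
    params_combo: MedianEffectParams


def _design_doses(Dm: float, n: int) -> np.ndarray:
    """Geometric dose ladder centred on Dm (two-fold steps), the standard
    constant-ratio design."""
    k = np.arange(n) - (n - 1) / 2.0
    return Dm * 2.0 ** k


def simulate_combo_matrix(
    params_a: MedianEffectParams,
    params_b: MedianEffectParams,
    ratio: tuple[float, float] = (0.5, 0.5),
    potency_shift: float = 1.0,
    total_doses: int | Sequence[float] = 8,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ComboDesign:
    """Simulate a constant-ratio two-drug combination plus its components.

    The mixture at total dose D (split d1 = ratio[0]*D, d2 = ratio[1]*D)
    follows the median-effect model with ``Dm_combo = potency_shift * Dm_ref``
    where Dm_ref is the Loewe-additive reference dose for that ratio,
    ``1 / (ratio[0]/Dm_a + ratio[1]/Dm_b)`` (for identical components this is
    just Dm).  potency_shift < 1 encodes synergy (the mixture is more potent
    than additivity predicts), and the downstream Combination Index equals
    potency_shift when the component slopes agree.

    The combination slope is the ratio-weighted mean of the component slopes;
    when the slopes agree the emitted curve is exactly the Loewe-additive
    reference scaled by potency_shift.
    """
    r1, r2 = float(ratio[0]), float(ratio[1])
    if r1 <= 0 or r2 <= 0 or abs(r1 + r2 - 1.0) > 1e-9:
        raise ConfigError("ratio must be two positive fractions summing to 1")
    if potency_shift <= 0:
        raise ConfigError(f"potency_shift={potency_shift} must be > 0")
    dm_ref = 1.0 / (r1 / params_a.Dm + r2 / params_b.Dm)
    m_combo = r1 * params_a.m + r2 * params_b.m
    params_combo = MedianEffectParams(Dm=potency_shift * dm_ref, m=m_combo)

    seeds = np.random.SeedSequence(seed).spawn(3)

    def series(params, drug_id, ss):
        if isinstance(total_doses, int):
            doses = _design_doses(params.Dm, total_doses)
        else:
            doses = np.asarray(total_doses, dtype=float)
        return simulate_dose_response(
            params, doses, noise_sd=noise_sd,
            seed=ss.generate_state(1)[0], drug_id=drug_id,
        )

    return ComboDesign(
        combo=series(params_combo, "combo", seeds[0]),
        drug_a=series(params_a, "drug_a", seeds[1]),
        drug_b=series(params_b, "drug_b", seeds[2]),
        ratio=(r1, r2),
        dm_ref=dm_ref,
        params_a=params_a,
        params_b=params_b,
        params_combo=params_combo,
    )


def true_tgi(g_control: float, g_treated: float, v0: float, horizon: float) -> float:
    """Closed-form TGI of noiseless exponential growth at the horizon."""
    vc = v0 * np.exp(g_control * horizon)
    vt = v0 * np.exp(g_treated * horizon)
    return (vc - vt) / (vc - v0) * 100.0


def simulate_xenograft(config: XenoSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate caliper trajectories; return (trajectories, truth).

    Each animal's volume grows as V(t) = v0 * exp(g t); volumes are emitted
    as caliper pairs (L, S) with a fixed aspect ratio L/S = 1.25 solving
    L * S^2 / 2 = V, plus Gaussian caliper noise on each diameter.  Diameters
    are re-ordered after noise so L >= S and floored at 0.1 mm so volumes
    stay positive.

    Truth has one row per non-control group with the noiseless group TGI at
    the horizon (identical growth rates within a group make the group median
    equal any member).
    """
    rng = np.random.default_rng(config.seed)
    days = np.arange(0, config.horizon + 1, config.measurement_interval)
    if days[-1] != config.horizon:
        days = np.append(days, config.horizon)
    rows = []
    animal_no = 0
    for label, g in config.groups:
        for _ in range(config.n_animals):
            animal_no += 1
            aid = f"M{animal_no:03d}"
            for day in days:
                v = config.v0 * np.exp(g * day)
                s = (2.0 * v / CALIPER_ASPECT) ** (1.0 / 3.0)
                l = CALIPER_ASPECT * s
                if config.caliper_noise_sd > 0:
                    l += rng.normal(0.0, config.caliper_noise_sd)
                    s += rng.normal(0.0, config.caliper_noise_sd)
                l, s = max(l, s, 0.1), max(min(l, s), 0.1)
                rows.append((aid, label, int(day), l, s))
    traj = pd.DataFrame(rows, columns=["animal_id", "group", "day", "L_mm", "S_mm"])

    g_control = dict(config.groups)[config.control]
    truth = pd.DataFrame(
        [
            {
                "group": label,
                "growth_rate": g,
                "true_tgi": true_tgi(g_control, g, config.v0, config.horizon),
            }
            for label, g in config.groups
            if label != config.control
        ]
    )
    return traj, truth
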