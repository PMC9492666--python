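"""Viability normalization: raw well signal -> fraction affected (fa).

Viability is expressed relative to vehicle-treated wells after subtracting the
medium-only blank, both plate-local::

    viability = (signal - blank_mean) / (vehicle_mean - blank_mean)
    fa        = 1 - viability, clamped to [0, 1]

Clamping happens per replicate, before averaging, so the replicate sd stays
meaningful and fa never leaves [0, 1].  Vehicle and blank statistics use the
mean.  Each plate is normalized against its own controls; replicate fa values
for the same condition are then pooled across plates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NormalizationError, PlateRejectedError

__all__ = ["FaRecord", "compute_fa", "normalize_plate"]

logger = logging.getLogger(__name__)

#: minimum number of vehicle (and, when required, blank) wells per plate
MIN_CONTROL_WELLS = 2


@dataclass(frozen=True)
class FaRecord:
    """Fraction affected for one condition (compound, arm, dose)."""

    compound_id: str
    arm: str
    dose: float
    fa: float
    n: int
    sd: float


def _per_replicate_fa(treated, vehicle_mean: float, blank_mean: float) -> np.ndarray:
    viability = (np.asarray(treated, dtype=float) - blank_mean) / (
        vehicle_mean - blank_mean
    )
    return np.clip(1.0 - viability, 0.0, 1.0)


def compute_fa(
    treated_signals: Sequence[float],
    vehicle_signals: Sequence[float],
    blank_signals: Sequence[float] | None = None,
    compound_id: str = "",
    arm: str = "",
    dose: float = float("nan"),
) -> FaRecord:
    """Fraction affected of one condition from raw replicate signals.

    ``blank_signals`` may be omitted (blank taken as 0), covering assays run
    without a medium-only background well.

    Raises
    ------
    NormalizationError
        If the vehicle mean does not exceed the blank mean (failed plate) or
        no treated replicate is given.
    """
    treated = np.asarray(treated_signals, dtype=float)
    if treated.size == 0:
        raise NormalizationError("no treated replicates")
    vehicle_mean = float(np.mean(vehicle_signals))
    blank_mean = 0.0 if blank_signals is None else float(np.mean(blank_signals))
    if vehicle_mean <= blank_mean:
        raise NormalizationError(
            f"vehicle mean {vehicle_mean:.4g} <= blank mean {blank_mean:.4g}: "
            "normalization impossible"
        )
    fa = _per_replicate_fa(treated, vehicle_mean, blank_mean)
    sd = float(np.std(fa, ddof=1)) if fa.size > 1 else 0.0
    return FaRecord(
        compound_id=compound_id,
        arm=arm,
        dose=dose,
        fa=float(np.mean(fa)),
        n=int(fa.size),
        sd=sd,
    )


def normalize_plate(
    wells: pd.DataFrame,
    vehicle_arm: str = "vehicle",
    blank_arm: str = "blank",
    require_blank: bool = True,
) -> pd.DataFrame:
    """Normalize a wells table to an fa table.

    Expects columns plate, compound_id, arm, dose, replicate, signal.  Each
    plate is normalized against its own vehicle/blank means; plates missing
    the required controls (or whose vehicle mean does not exceed the blank
    mean) are rejected with a logged reason.  Per-replicate fa values are
    pooled across plates and summarized per (compound_id, arm, dose).

    With ``require_blank=False`` a plate without blank wells is normalized
    against a blank of 0.

    Returns a DataFrame with columns compound_id, arm, dose, fa, n, sd.
    """
    frames = []
    n_rejected = 0
    for plate_id, plate in wells.groupby("plate", sort=True):
        veh = plate.loc[plate["arm"] == vehicle_arm, "signal"]
        blank = plate.loc[plate["arm"] == blank_arm, "signal"]
        try:
            if len(veh) < MIN_CONTROL_WELLS:
                raise PlateRejectedError(
                    f"plate {plate_id}: {len(veh)} vehicle wells "
                    f"(need >= {MIN_CONTROL_WELLS})"
                )
            if len(blank) < MIN_CONTROL_WELLS:
                if require_blank:
                    raise PlateRejectedError(
                        f"plate {plate_id}: {len(blank)} blank wells "
                        f"(need >= {MIN_CONTROL_WELLS})"
                    )
                blank_mean = 0.0
            else:
                blank_mean = float(blank.mean())
            vehicle_mean = float(veh.mean())
            if vehicle_mean <= blank_mean:
                raise NormalizationError(
                    f"plate {plate_id}: vehicle mean {vehicle_mean:.4g} <= "
                    f"blank mean {blank_mean:.4g}"
                )
        except NormalizationError as exc:
            logger.warning("rejecting plate: %s", exc)
            n_rejected += 1
            continue
        treated = plate[~plate["arm"].isin([vehicle_arm, blank_arm])].copy()
        treated["fa_rep"] = _per_replicate_fa(
            treated["signal"].to_numpy(), vehicle_mean, blank_mean
        )
        frames.append(treated)
    if not frames:
        raise NormalizationError(
            f"no normalizable plates ({n_rejected} rejected)"
        )
    pooled = pd.concat(frames, ignore_index=True)
    pooled["compound_id"] = pooled["compound_id"].fillna("")
    grouped = pooled.groupby(["compound_id", "arm", "dose"], dropna=False)[
        "fa_rep"
    ]
    out = grouped.agg(fa="mean", n="size", sd="std").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["n"] = out["n"].astype(int)
    logger.info(
        "normalized %d conditions from %d wells (%d plates rejected)",
        len(out), len(wells), n_rejected,
    )
    return out[["compound_id", "arm", "dose", "fa", "n", "sd"]]
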