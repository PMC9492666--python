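"""Caliper-based tumor volumes and tumor growth inhibition (TGI).

Tumor volume from two perpendicular caliper diameters (longest L, shortest
S, both mm)::

    V = L * S**2 / 2        [mm^3]

Tumor growth inhibition compares group-median volumes::

    TGI (%) = (Vc - Vt) / (Vc - V0) * 100

with Vc and Vt the median volumes of the control and treated groups at the
end of the study and V0 the control median at the start.  TGI = 100% means
complete stasis at baseline, 0% no effect; values above 100 (regression) and
below 0 (treated outgrew control) are legal and reported as-is.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import MeasurementOrderError, UndefinedTGIError

__all__ = ["tumor_volume", "tgi", "tgi_from_trajectories"]

logger = logging.getLogger(__name__)


def tumor_volume(L, S, auto_correct: bool = False):
    """Tumor volume V = L * S^2 / 2 (mm^3) from caliper diameters (mm).

    Accepts scalars or arrays.  If S > L the diameters were recorded in the
    wrong order; with ``auto_correct=True`` they are swapped, otherwise a
    MeasurementOrderError is raised.
    """
    L = np.asarray(L, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(S <= 0) or np.any(L <= 0):
        raise ValueError("diameters must be positive")
    swapped = S > L
    if np.any(swapped):
        if not auto_correct:
            raise MeasurementOrderError(
                "shortest diameter exceeds longest; pass auto_correct=True "
                "to swap"
            )
        L, S = np.maximum(L, S), np.minimum(L, S)
    v = L * S**2 / 2.0
    return float(v) if v.ndim == 0 else v


def tgi(Vc: float, Vt: float, V0: float) -> float:
    """TGI (%) = (Vc - Vt) / (Vc - V0) * 100.

    Raises
    ------
    UndefinedTGIError
        If Vc <= V0: the control group did not grow, so inhibition relative
        to control growth is undefined.
    """
    if Vc <= V0:
        raise UndefinedTGIError(
            f"control did not grow (Vc={Vc:.4g} <= V0={V0:.4g}): TGI undefined"
        )
    return (Vc - Vt) / (Vc - V0) * 100.0


def _volume_at(animal: pd.DataFrame, day: int) -> tuple[float, bool]:
    """Volume at ``day``, or last observation carried forward.

    Returns (volume, carried) where carried flags an LOCF substitution.
    """
    upto = animal[animal["day"] <= day]
    if upto.empty:
        return np.nan, False
    last = upto.iloc[-1]
    return float(last["volume"]), bool(last["day"] != day)


def tgi_from_trajectories(
    trajectories: pd.DataFrame,
    control_group: str,
    endpoint_day: int | None = None,
    baseline_day: int | None = None,
    per_group_baseline: bool = False,
    auto_correct: bool = False,
) -> pd.DataFrame:
    """TGI per treated group from a caliper trajectory table.

    Expects columns animal_id, group, day, L_mm, S_mm.  Volumes are computed
    from the diameters; group medians are taken at the endpoint (default:
    the last day measured in every group) and at baseline (default: the
    first day present, i.e. the first treatment day).  Animals without an
    endpoint measurement contribute their last observation carried forward
    (counted and logged).

    V0 is the control group's baseline median; ``per_group_baseline=True``
    uses each treated group's own baseline median instead.

    Returns a DataFrame with columns group, Vc, Vt, V0, n, n_locf,
    tgi_percent.
    """
    df = trajectories.copy()
    df["volume"] = tumor_volume(
        df["L_mm"].to_numpy(), df["S_mm"].to_numpy(), auto_correct=auto_correct
    )
    df = df.sort_values(["animal_id", "day"])
    groups = df["group"].unique()
    if control_group not in groups:
        raise UndefinedTGIError(f"control group {control_group!r} not present")
    if baseline_day is None:
        baseline_day = int(df["day"].min())
    if endpoint_day is None:
        endpoint_day = int(df.groupby("group")["day"].max().min())

    def group_median_at(label: str, day: int) -> tuple[float, int, int]:
        sub = df[df["group"] == label]
        vols, n_locf = [], 0
        for _, animal in sub.groupby("animal_id"):
            v, carried = _volume_at(animal, day)
            if not np.isnan(v):
                vols.append(v)
                n_locf += int(carried)
        if not vols:
            return np.nan, 0, 0
        return float(np.median(vols)), len(vols), n_locf

    vc, n_control, locf_c = group_median_at(control_group, endpoint_day)
    if n_control == 0:
        raise UndefinedTGIError("control group has no usable measurements")
    v0_control, _, _ = group_median_at(control_group, baseline_day)
    if locf_c:
        logger.info("control group: %d last-observation-carried-forward", locf_c)

    rows = []
    for label in groups:
        if label == control_group:
            continue
        vt, n, n_locf = group_median_at(label, endpoint_day)
        if n == 0:
            logger.warning("group %r empty at endpoint; skipped", label)
            continue
        if n_locf:
            logger.info("group %r: %d last-observation-carried-forward",
                        label, n_locf)
        if per_group_baseline:
            v0, _, _ = group_median_at(label, baseline_day)
        else:
            v0 = v0_control
        rows.append(
            {
                "group": label,
                "Vc": vc,
                "Vt": vt,
                "V0": v0,
                "n": n,
                "n_locf": n_locf,
                "tgi_percent": tgi(vc, vt, v0),
            }
        )
    return pd.DataFrame(rows)
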