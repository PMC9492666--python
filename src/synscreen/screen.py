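"""Synergy Index screening and hit calling.

The screen treats every library compound against each ferroptosis inducer and
scores the pair with the Synergy Index::

    SI = (Fa_comb - Fa_cpd) / Fa_inducer

where Fa_comb is the fraction affected of the combination, Fa_cpd of the
compound alone and Fa_inducer of the inducer alone.  SI > 1 indicates
synergism, SI < 1 antagonism.  A compound is a hit when the combination with
each inducer kills at least half the cells (fa_comb >= 0.5, inclusive) and
the SI against each inducer exceeds 1 (strict).

SI is computed on replicate-mean fa values; an SI standard deviation is
propagated from the replicate dispersions in quadrature and reported for
description only (no test is attached to it).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ScreenError, UndefinedSIError

__all__ = ["synergy_index", "score_screen", "call_hits", "combine_screens",
           "volcano_table"]

logger = logging.getLogger(__name__)

#: minimum inducer-alone effect for the SI ratio to be meaningful
DEFAULT_EPSILON = 0.01

#: "at least 50% death" hit criterion on the combination arm
DEFAULT_DEATH_THRESHOLD = 0.5


def synergy_index(
    fa_comb: float,
    fa_cpd: float,
    fa_inducer: float,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Synergy Index (fa_comb - fa_cpd) / fa_inducer.

    May be negative (combination weaker than the compound alone).

    Raises
    ------
    UndefinedSIError
        If the inducer-alone effect is below ``epsilon``: the ratio is
        numerically meaningless when the inducer kills (almost) nothing.
        Callers must report such pairs as missing, never as 0.
    """
    for name, v in (("fa_comb", fa_comb), ("fa_cpd", fa_cpd),
                    ("fa_inducer", fa_inducer)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if fa_inducer < epsilon:
        raise UndefinedSIError(
            f"fa_inducer={fa_inducer:.4g} < epsilon={epsilon}: SI undefined"
        )
    return (fa_comb - fa_cpd) / fa_inducer


def _lookup_inducer(fa_table: pd.DataFrame, label: str) -> tuple[float, float]:
    rec = fa_table[
        (fa_table["arm"] == f"inducer_{label}")
        & (fa_table["compound_id"].fillna("") == "")
    ]
    if rec.empty:
        raise ScreenError(
            f"no inducer-alone record for inducer {label!r}: the SI "
            "denominator is undefined for every compound"
        )
    return float(rec["fa"].iloc[0]), float(rec["sd"].iloc[0])


def score_screen(
    fa_table: pd.DataFrame,
    inducers: Sequence[str] = ("E", "R"),
    epsilon: float = DEFAULT_EPSILON,
    death_threshold: float = DEFAULT_DEATH_THRESHOLD,
) -> pd.DataFrame:
    """Score every compound of an fa table against each inducer.

    Expects the fa table produced by normalization, with arms ``cpd``,
    ``inducer_<X>`` and ``combo_<X>`` for each inducer label.  Returns one
    row per compound with fa values, both SI values (NaN where an arm is
    missing or the SI is undefined), the propagated SI sd, the hit flag and
    a rank (best first: largest min SI, ties broken by mean combination fa
    descending, then compound_id).
    """
    fa_ind = {lab: _lookup_inducer(fa_table, lab) for lab in inducers}
    cpds = fa_table[fa_table["compound_id"].fillna("") != ""]
    by_cpd_arm = cpds.set_index(["compound_id", "arm"])[["fa", "sd", "n"]]

    rows = []
    for cid in sorted(cpds["compound_id"].unique()):
        row: dict = {"compound_id": cid}
        try:
            cpd_rec = by_cpd_arm.loc[(cid, "cpd")]
            row["fa_cpd"] = float(cpd_rec["fa"])
            cpd_sd = float(cpd_rec["sd"])
        except KeyError:
            row["fa_cpd"] = np.nan
            cpd_sd = np.nan
        for lab in inducers:
            fa_i, _ = fa_ind[lab]
            row[f"fa_inducer_{lab}"] = fa_i
            try:
                comb_rec = by_cpd_arm.loc[(cid, f"combo_{lab}")]
                fa_comb = float(comb_rec["fa"])
                comb_sd = float(comb_rec["sd"])
            except KeyError:
                fa_comb, comb_sd = np.nan, np.nan
            row[f"fa_comb_{lab}"] = fa_comb
            if math.isnan(fa_comb) or math.isnan(row["fa_cpd"]) or fa_i < epsilon:
                row[f"si_{lab}"] = np.nan
                row[f"si_sd_{lab}"] = np.nan
            else:
                row[f"si_{lab}"] = synergy_index(
                    fa_comb, row["fa_cpd"], fa_i, epsilon=epsilon
                )
                row[f"si_sd_{lab}"] = math.sqrt(comb_sd**2 + cpd_sd**2) / fa_i
        rows.append(row)
    results = pd.DataFrame(rows)

    si_cols = [f"si_{lab}" for lab in inducers]
    comb_cols = [f"fa_comb_{lab}" for lab in inducers]
    results["is_hit"] = call_hits_mask(results, inducers, death_threshold)
    results["_min_si"] = results[si_cols].min(axis=1)
    results["_mean_comb"] = results[comb_cols].mean(axis=1)
    results = results.sort_values(
        ["_min_si", "_mean_comb", "compound_id"],
        ascending=[False, False, True],
        na_position="last",
    ).reset_index(drop=True)
    results["rank"] = np.arange(1, len(results) + 1)
    return results.drop(columns=["_min_si", "_mean_comb"])


def call_hits_mask(
    results: pd.DataFrame,
    inducers: Sequence[str] = ("E", "R"),
    death_threshold: float = DEFAULT_DEATH_THRESHOLD,
) -> pd.Series:
    """Boolean hit mask: every combination arm kills >= threshold (inclusive)
    and every SI > 1 (strict).  Missing values never qualify."""
    mask = pd.Series(True, index=results.index)
    for lab in inducers:
        si = results[f"si_{lab}"]
        comb = results[f"fa_comb_{lab}"]
        mask &= si.notna() & (si > 1.0)
        mask &= comb.notna() & (comb >= death_threshold)
    return mask


def call_hits(
    results: pd.DataFrame,
    death_threshold: float = DEFAULT_DEATH_THRESHOLD,
    inducers: Sequence[str] = ("E", "R"),
) -> pd.DataFrame:
    """Subset of screen results passing the hit rule, re-flagged."""
    out = results.copy()
    out["is_hit"] = call_hits_mask(out, inducers, death_threshold)
    return out[out["is_hit"]].reset_index(drop=True)


def combine_screens(
    results_per_line: Sequence[pd.DataFrame],
    rule: str = "intersection",
    inducers: Sequence[str] = ("E", "R"),
) -> pd.DataFrame:
    """Combine hit calls across cell lines.

    ``rule='intersection'`` (default) keeps compounds that are hits in every
    line; ``'union'`` keeps compounds that are hits in any line.  Returns the
    first line's rows for the retained compounds.
    """
    if rule not in {"intersection", "union"}:
        raise ScreenError(f"unknown combination rule {rule!r}")
    hit_sets = [
        set(r.loc[r["is_hit"], "compound_id"]) for r in results_per_line
    ]
    kept = set.intersection(*hit_sets) if rule == "intersection" else set.union(*hit_sets)
    first = results_per_line[0]
    return first[first["compound_id"].isin(kept)].reset_index(drop=True)


def volcano_table(
    results: pd.DataFrame, inducers: Sequence[str] = ("E", "R")
) -> pd.DataFrame:
    """Per-compound SI coordinates for a volcano-style scatter export."""
    cols = ["compound_id"] + [f"si_{lab}" for lab in inducers] + ["is_hit"]
    return results[cols].copy()
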