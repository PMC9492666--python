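"""Chou-Talalay mass-action analysis.

The median-effect equation relates the fraction of cells affected (fa) to dose
D through two parameters, the median-effect dose Dm (the dose producing
fa = 0.5, i.e. the model's IC50) and the sigmoidicity m::

    fa / fu = (D / Dm) ** m,          fu = 1 - fa

Taking log10 of both sides linearizes the model: the "median-effect plot" of
y = log10(fa/fu) against x = log10(D) is a straight line with slope m and
x-intercept log10(Dm).  Fitting is ordinary least squares on that plot, the
method's canonical linearization; no nonlinear refinement is applied, so a fit
is an exact, reproducible function of the retained points.

For a two-drug combination administered at a constant dose ratio the mixture
is treated as a third agent on total dose, and the Combination Index at effect
level fa is the mutually exclusive two-term form::

    CI(fa) = d1 / Dx1 + d2 / Dx2

where (d1, d2) split the combination dose achieving fa according to the ratio
and Dx1, Dx2 are the single-agent doses achieving the same fa.  CI < 1 is
synergism, CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ModelViolationError, UndefinedDoseError

__all__ = [
    "DoseResponseSeries",
    "MedianEffectFit",
    "CIResult",
    "fit_median_effect",
    "dose_for_fa",
    "combination_index",
    "ic50",
    "ic50_fold_shift",
    "resistance_factor",
]

#: fa values outside this open interval are unrepresentable in log-odds and
#: are excluded from the fit (configurable per call).
DEFAULT_FA_BOUNDS = (0.005, 0.995)

#: |CI - 1| below this is classified as additivity.
ADDITIVITY_TOL = 1e-9


@dataclass(frozen=True)
class DoseResponseSeries:
    """A single-agent (or constant-ratio combination) dose-response series."""

    drug_id: str
    doses: np.ndarray
    fa: np.ndarray

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        fa = np.asarray(self.fa, dtype=float)
        if doses.shape != fa.shape:
            raise ValueError("doses and fa must have the same length")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "fa", fa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"drug_id": self.drug_id, "dose": self.doses, "fa": self.fa}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, drug_id: str | None = None) -> "DoseResponseSeries":
        if drug_id is not None:
            df = df[df["drug_id"] == drug_id]
        else:
            ids = df["drug_id"].unique()
            if len(ids) != 1:
                raise ValueError(
                    f"frame holds {len(ids)} drug_ids; pass drug_id explicitly"
                )
            drug_id = ids[0]
        return cls(str(drug_id), df["dose"].to_numpy(), df["fa"].to_numpy())


@dataclass(frozen=True)
class MedianEffectFit:
    """Result of a median-effect plot fit.

    Attributes
    ----------
    Dm : median-effect dose (same units as the input doses); the model IC50.
    m : sigmoidicity (slope of the median-effect plot), > 0 for valid data.
    r : Pearson correlation of the linearized points; |r| close to 1 means the
        mass-action model describes the series well.
    n_used : points retained after the fa filter.
    n_excluded : points dropped because fa fell outside the filter bounds.
    """

    drug_id: str
    Dm: float
    m: float
    r: float
    n_used: int
    n_excluded: int = 0


@dataclass(frozen=True)
class CIResult:
    """Combination Index at one effect level."""

    fa: float
    D_total: float
    d1: float
    d2: float
    Dx1: float
    Dx2: float
    ci: float
    classification: str


def fit_median_effect(
    series: DoseResponseSeries,
    fa_bounds: tuple[float, float] = DEFAULT_FA_BOUNDS,
) -> MedianEffectFit:
    """Fit the median-effect model by OLS on the log-log median-effect plot.

    Points with fa outside the open interval ``fa_bounds`` are excluded (the
    log-odds transform is undefined at 0 and 1) and counted in ``n_excluded``.

    Raises
    ------
    FitError
        Fewer than 3 usable points remain after filtering.
    ModelViolationError
        The fitted slope is <= 0 (non-monotone or inverted data).
    """
    f_lo, f_hi = fa_bounds
    mask = (series.fa > f_lo) & (series.fa < f_hi)
    n_used = int(mask.sum())
    n_excluded = int(len(series.fa) - n_used)
    if n_used < 3:
        raise FitError(
            f"{series.drug_id}: only {n_used} points with fa in "
            f"({f_lo}, {f_hi}); need >= 3"
        )
    d = series.doses[mask]
    fa = series.fa[mask]
    x = np.log10(d)
    y = np.log10(fa / (1.0 - fa))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ModelViolationError(
            f"{series.drug_id}: median-effect slope {m:.4g} <= 0"
        )
    Dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(
        drug_id=series.drug_id,
        Dm=Dm,
        m=m,
        r=float(res.rvalue),
        n_used=n_used,
        n_excluded=n_excluded,
    )


def dose_for_fa(fit: MedianEffectFit, fa: float) -> float:
    """Invert the median-effect equation: Dx = Dm * (fa/(1-fa))**(1/m)."""
    if not 0.0 < fa < 1.0:
        raise UndefinedDoseError(
            f"fa={fa} has no finite dose under the median-effect model"
        )
    return fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def ic50(fit: MedianEffectFit) -> float:
    """The model IC50, which is Dm by definition (fa = 0.5 at D = Dm)."""
    return fit.Dm


def ic50_fold_shift(fit_alone: MedianEffectFit, fit_with_sensitizer: MedianEffectFit) -> float:
    """IC50(alone) / IC50(with sensitizer); > 1 means sensitization."""
    return ic50(fit_alone) / ic50(fit_with_sensitizer)


def resistance_factor(
    fit_tolerant: MedianEffectFit,
    fit_parental: MedianEffectFit,
    threshold: float = 10.0,
) -> tuple[float, bool]:
    """IC50 ratio of a drug-tolerant line over its parental line.

    A line is called resistant when the ratio reaches ``threshold`` (default
    10-fold, the conventional endpoint for tolerance selection); the boundary
    is inclusive.
    """
    ratio = ic50(fit_tolerant) / ic50(fit_parental)
    return ratio, bool(ratio >= threshold)


def _classify(ci: float) -> str:
    if abs(ci - 1.0) <= ADDITIVITY_TOL:
        return "additivity"
    return "synergism" if ci < 1.0 else "antagonism"


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    ratio: tuple[float, float] = (0.5, 0.5),
    fa_levels: Sequence[float] = (0.5, 0.75, 0.9),
) -> list[CIResult]:
    """Combination Index at each requested effect level.

    ``ratio`` gives the dose fractions (summing to 1) of drugs a and b within
    the combination's total dose; the combination must have been fitted as a
    single agent on total dose (constant-ratio design).
    """
    r1, r2 = float(ratio[0]), float(ratio[1])
    if r1 <= 0 or r2 <= 0:
        raise ValueError("ratio fractions must be positive")
    if abs(r1 + r2 - 1.0) > 1e-9:
        raise ValueError(f"ratio fractions must sum to 1 (got {r1 + r2})")
    out: list[CIResult] = []
    for fa in fa_levels:
        D_total = dose_for_fa(fit_combo, fa)
        d1, d2 = r1 * D_total, r2 * D_total
        Dx1 = dose_for_fa(fit_a, fa)
        Dx2 = dose_for_fa(fit_b, fa)
        ci = d1 / Dx1 + d2 / Dx2
        out.append(
            CIResult(
                fa=float(fa),
                D_total=D_total,
                d1=d1,
                d2=d2,
                Dx1=Dx1,
                Dx2=Dx2,
                ci=ci,
                classification=_classify(ci),
            )
        )
    return out


def ci_table(results: Sequence[CIResult]) -> pd.DataFrame:
    """Tabulate CIResults (fa, d1, d2, Dx1, Dx2, CI, class)."""
    return pd.DataFrame(
        {
            "fa": [r.fa for r in results],
            "D_total": [r.D_total for r in results],
            "d1": [r.d1 for r in results],
            "d2": [r.d2 for r in results],
            "Dx1": [r.Dx1 for r in results],
            "Dx2": [r.Dx2 for r in results],
            "CI": [r.ci for r in results],
            "class": [r.classification for r in results],
        }
    )


def fit_table(fits: Sequence[MedianEffectFit]) -> pd.DataFrame:
    """Tabulate fits (drug_id, Dm, m, r, n_used)."""
    return pd.DataFrame(
        {
            "drug_id": [f.drug_id for f in fits],
            "Dm": [f.Dm for f in fits],
            "m": [f.m for f in fits],
            "r": [f.r for f in fits],
            "n_used": [f.n_used for f in fits],
        }
    )
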