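"""Melting temperature of short probes under FISH hybridization conditions.

The workhorse is the empirical GC/length closed form (Marmur–Doty family)
with logarithmic monovalent-salt correction and a linear formamide
depression:

    Tm = base + salt·log10([Na+]) + gc·(%GC) − num/L − fa·(%formamide)

with default coefficients (81.5, 16.6, 0.41, 675, 0.65) — the standard
formula used for FISH oligo design.  Hybridization buffers are expressed in
SSC folds; 1×SSC is 0.15 M NaCl + 0.015 M trisodium citrate, i.e. 0.195 M
Na+ counting the three citrate sodiums (use ``na_per_ssc_fold=0.165`` for
the NaCl-only convention).

For a degenerate probe pool the Tm varies only through GC content, and the
closed form is monotone in GC, so the pool's Tm range is attained at the
minimum- and maximum-GC expansions (:func:`tm_range`).

Because published probe tables rarely disclose the exact Tm engine used,
:func:`calibrate_model` fits the free coefficients to a table of printed Tm
values and reports the residual error instead of assuming the defaults
reproduce the printed numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .iupac_seq import DegenerateSeq, _as_seq

__all__ = [
    "SSC_NA_PER_FOLD",
    "HybridizationConditions",
    "TmModel",
    "MARMUR_DOTY_FISH",
    "TmRange",
    "CalibrationResult",
    "tm_fixed",
    "tm_range",
    "calibrate_model",
]

#: mol/L of monovalent cation per SSC fold (NaCl + trisodium citrate).
SSC_NA_PER_FOLD = 0.195

#: Minimum probe length for which the empirical closed form is used.
MIN_FORMULA_LENGTH = 14


@dataclass(frozen=True)
class HybridizationConditions:
    """Hybridization buffer: SSC fold and formamide percentage.

    Attributes
    ----------
    ssc_fold:
        Buffer concentration in SSC folds (2.0 = 2×SSC).  Must be > 0 for
        the logarithmic salt term.
    formamide_pct:
        Formamide, percent v/v in [0, 100].
    na_per_ssc_fold:
        Monovalent cation molarity contributed per SSC fold; default 0.195
        includes citrate sodium, 0.165 is the NaCl-only convention.
    """

    ssc_fold: float = 2.0
    formamide_pct: float = 50.0
    na_per_ssc_fold: float = SSC_NA_PER_FOLD

    def __post_init__(self):
        if self.ssc_fold <= 0:
            raise ValueError("ssc_fold must be > 0 (salt term is log10([Na+]))")
        if not 0 <= self.formamide_pct <= 100:
            raise ValueError("formamide_pct must be within [0, 100]")

    @property
    def na_molarity(self) -> float:
        """Monovalent cation concentration, mol/L."""
        return self.na_per_ssc_fold * self.ssc_fold


@dataclass(frozen=True)
class TmModel:
    """Coefficients of the empirical Tm closed form (°C units throughout)."""

    base_temp: float = 81.5
    salt_coeff: float = 16.6
    gc_coeff: float = 0.41
    length_numerator: float = 675.0
    formamide_coeff: float = 0.65

    def __post_init__(self):
        for name in (
            "base_temp",
            "salt_coeff",
            "gc_coeff",
            "length_numerator",
            "formamide_coeff",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.formamide_coeff < 0:
            raise ValueError("formamide_coeff must be >= 0")


#: Default model: Marmur–Doty GC/length form with McConaughy-style
#: formamide correction, as conventionally applied to FISH oligos.
MARMUR_DOTY_FISH = TmModel()


@dataclass(frozen=True)
class TmRange:
    """Melting-temperature interval of a (possibly degenerate) probe pool."""

    tm_min: float
    tm_max: float

    def __post_init__(self):
        if self.tm_min > self.tm_max + 1e-9:
            raise ValueError("tm_min must be <= tm_max")

    @property
    def width(self) -> float:
        return self.tm_max - self.tm_min

    @property
    def is_point(self) -> bool:
        return self.tm_max - self.tm_min < 1e-9

    @classmethod
    def parse(cls, text: str) -> "TmRange":
        """Parse a printed Tm cell: a single value or a ``lo–hi`` range."""
        t = str(text).strip().replace("–", "-").replace("—", "-")
        if "-" in t[1:]:  # allow (unlikely) leading minus
            lo, hi = t[1:].split("-", 1)
            lo = t[0] + lo
            return cls(float(lo), float(hi))
        v = float(t)
        return cls(v, v)

    def __format__(self, spec: str) -> str:
        spec = spec or ".1f"
        if self.is_point:
            return format(self.tm_min, spec)
        return f"{self.tm_min:{spec}}–{self.tm_max:{spec}}"

    def __str__(self) -> str:
        if self.is_point:
            return f"{self.tm_min:g}"
        return f"{self.tm_min:g}–{self.tm_max:g}"


def _tm_from_gc_count(
    gc_count: int, length: int, cond: HybridizationConditions, model: TmModel
) -> float:
    pct_gc = 100.0 * gc_count / length
    return (
        model.base_temp
        + model.salt_coeff * math.log10(cond.na_molarity)
        + model.gc_coeff * pct_gc
        - model.length_numerator / length
        - model.formamide_coeff * cond.formamide_pct
    )


def tm_fixed(
    seq: DegenerateSeq | str,
    cond: HybridizationConditions = HybridizationConditions(),
    model: TmModel = MARMUR_DOTY_FISH,
) -> float:
    """Tm (°C) of a fixed sequence under the given conditions.

    Raises ``ValueError`` for degenerate sequences (use :func:`tm_range`)
    and for probes shorter than the formula regime (14 nt).
    """
    s = _as_seq(seq)
    if not s.is_fixed:
        raise ValueError("tm_fixed requires a fixed sequence; use tm_range")
    if len(s) < MIN_FORMULA_LENGTH:
        raise ValueError(
            f"length {len(s)} below formula regime (>= {MIN_FORMULA_LENGTH} nt)"
        )
    gc, _ = s.gc_bounds()
    return _tm_from_gc_count(gc, len(s), cond, model)


def tm_range(
    seq: DegenerateSeq | str,
    cond: HybridizationConditions = HybridizationConditions(),
    model: TmModel = MARMUR_DOTY_FISH,
) -> TmRange:
    """Tm interval of a degenerate probe pool.

    The closed form depends on the expanded sequence only through its GC
    count and is monotone in it, so the extremes are attained at the
    minimum- and maximum-GC expansions; no pool enumeration is needed.
    """
    s = _as_seq(seq)
    if len(s) < MIN_FORMULA_LENGTH:
        raise ValueError(
            f"length {len(s)} below formula regime (>= {MIN_FORMULA_LENGTH} nt)"
        )
    lo, hi = s.gc_bounds()
    t_lo = _tm_from_gc_count(lo, len(s), cond, model)
    t_hi = _tm_from_gc_count(hi, len(s), cond, model)
    if model.gc_coeff >= 0:
        return TmRange(t_lo, t_hi)
    return TmRange(t_hi, t_lo)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of fitting Tm coefficients to a printed probe table."""

    model: TmModel
    rmse: float
    residuals: dict[str, float]
    degenerate_fit: bool


def calibrate_model(
    probes: Sequence,
    cond: HybridizationConditions = HybridizationConditions(),
    base_model: TmModel = MARMUR_DOTY_FISH,
    length_numerator_grid: np.ndarray | None = None,
    formamide_coeff_grid: np.ndarray | None = None,
    base_temp_bounds: tuple[float, float] = (75.0, 90.0),
) -> CalibrationResult:
    """Fit Tm coefficients against printed Tm values of fixed-sequence probes.

    Grid search over ``length_numerator`` in [400, 800] and
    ``formamide_coeff`` in [0.5, 0.8]; at each grid point the intercept
    ``base_temp`` is profiled out in closed form (mean residual) and clipped
    to [75, 90].  At a single hybridization condition the intercept and the
    formamide slope are exactly collinear — only their combination is
    identified — so predicted Tm values, not individual coefficients, are
    the meaningful output.  Returns the best model with its RMSE (°C).

    ``probes`` are objects with ``name``, ``sequence`` (:class:`DegenerateSeq`)
    and ``printed_tm`` (:class:`TmRange`) attributes; only degeneracy-1
    probes enter the fit (at least 5 required).  A zero-variance Tm column
    is flagged as a degenerate fit.
    """
    fixed = [p for p in probes if p.sequence.is_fixed]
    if len(fixed) < 5:
        raise ValueError(
            f"calibration needs >= 5 fixed-sequence probes with printed Tm, got {len(fixed)}"
        )
    names = [p.name for p in fixed]
    y = np.array([p.printed_tm.tm_min for p in fixed], dtype=float)
    lengths = np.array([float(len(p.sequence)) for p in fixed])
    pct_gc = np.array(
        [100.0 * p.sequence.gc_bounds()[0] / len(p.sequence) for p in fixed]
    )
    degenerate_fit = bool(np.ptp(y) == 0.0)

    if length_numerator_grid is None:
        length_numerator_grid = np.arange(400.0, 800.0 + 1e-9, 5.0)
    if formamide_coeff_grid is None:
        formamide_coeff_grid = np.arange(0.5, 0.8 + 1e-9, 0.01)

    salt = base_model.salt_coeff * math.log10(cond.na_molarity)
    gc_term = base_model.gc_coeff * pct_gc

    best = None
    for num in length_numerator_grid:
        for fa in formamide_coeff_grid:
            rest = salt + gc_term - num / lengths - fa * cond.formamide_pct
            base = float(np.clip(np.mean(y - rest), *base_temp_bounds))
            resid = y - (base + rest)
            rmse = float(np.sqrt(np.mean(resid**2)))
            if best is None or rmse < best[0] - 1e-12:
                best = (rmse, num, fa, base, resid)

    rmse, num, fa, base, resid = best
    model = replace(
        base_model, base_temp=base, length_numerator=float(num), formamide_coeff=float(fa)
    )
    residuals = dict(zip(names, resid.tolist()))
    return CalibrationResult(
        model=model, rmse=rmse, residuals=residuals, degenerate_fit=degenerate_fit
    )
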