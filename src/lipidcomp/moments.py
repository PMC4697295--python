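"""Cohort data model and summary-moment estimation.

This module holds the two tabular containers used throughout the package —
per-subject fatty-acid concentrations and blood-lipid biomarkers — together
with the elementary statistics the reversal framework is built on: the
leave-one-out "sum of all other fatty acids", Pearson sample correlations,
the Fisher z-transformation test for non-zero correlation, and the
reduction of a cohort to the seven summary moments
(mu1, sigma1, mu2, sigma2, rho12, rho1, rho2, plus sigma_Y) that drive the
delta-method predictions.

Units: the canonical internal concentration unit is mmol/l. Inputs declared
as µmol/l are divided by 1000 at load time. Sample standard deviations use
the unbiased n-1 denominator; Pearson r is denominator-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, UnknownFattyAcidError, ValidationError

__all__ = [
    "ConcentrationMatrix",
    "BiomarkerTable",
    "SummaryMoments",
    "FisherZResult",
    "leave_one_out_sum",
    "pearson",
    "fisher_z_test",
    "cohort_moments",
    "format_p",
    "P_FLOOR",
]

#: p-values below this floor are rendered as "<1e-15" in text reports.
P_FLOOR = 1e-15

_UNIT_FACTORS = {"mmol/l": 1.0, "umol/l": 1e-3, "µmol/l": 1e-3}


def _as_2d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D table, got ndim={arr.ndim}")
    return arr


class ConcentrationMatrix:
    """Per-subject fatty-acid concentrations (mmol/l), the "mass" scale.

    Parameters
    ----------
    values
        ``n_subjects x n_fatty_acids`` table (array or DataFrame). Entries
        must be finite and non-negative; NaN marks a missing measurement
        and is handled by complete-case deletion downstream.
    subject_ids, fatty_acid_names
        Row / column labels. Taken from the DataFrame if one is given.
    unit
        ``"mmol/l"`` (canonical) or ``"umol/l"`` (divided by 1000 on load).
    """

    def __init__(self, values, subject_ids=None, fatty_acid_names=None,
                 unit: str = "mmol/l"):
        if isinstance(values, pd.DataFrame):
            if subject_ids is None:
                subject_ids = list(values.index.astype(str))
            if fatty_acid_names is None:
                fatty_acid_names = list(values.columns.astype(str))
            values = values.to_numpy()
        arr = _as_2d_float(values)
        if unit not in _UNIT_FACTORS:
            raise ValidationError(
                f"unknown concentration unit {unit!r}; expected one of "
                f"{sorted(set(_UNIT_FACTORS))}"
            )
        arr = arr * _UNIT_FACTORS[unit]
        n, k = arr.shape
        if n < 1 or k < 1:
            raise ValidationError("concentration matrix must be non-empty")
        if subject_ids is None:
            subject_ids = [f"S{i + 1}" for i in range(n)]
        if fatty_acid_names is None:
            fatty_acid_names = [f"FA{j + 1}" for j in range(k)]
        subject_ids = [str(s) for s in subject_ids]
        fatty_acid_names = [str(c) for c in fatty_acid_names]
        if len(subject_ids) != n:
            raise ValidationError("subject_ids length does not match values")
        if len(fatty_acid_names) != k:
            raise ValidationError("fatty_acid_names length does not match values")
        if len(set(fatty_acid_names)) != k:
            raise ValidationError("fatty_acid_names must be unique")
        finite_or_nan = np.isnan(arr) | np.isfinite(arr)
        if not finite_or_nan.all():
            raise ValidationError("concentrations must be finite (or NaN for missing)")
        with np.errstate(invalid="ignore"):
            if np.nanmin(arr) < 0:
                raise ValidationError("concentrations must be non-negative")
        self.values = arr
        self.subject_ids = subject_ids
        self.fatty_acid_names = fatty_acid_names

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_csv(cls, path, unit: str = "mmol/l") -> "ConcentrationMatrix":
        """Read a UTF-8 CSV: header row, column 1 = subject ID."""
        df = pd.read_csv(path, index_col=0, comment="#")
        return cls(df, unit=unit)

    # -- views -------------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_fatty_acids(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.fatty_acid_names,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.fatty_acid_names.index(name)
        except ValueError:
            raise UnknownFattyAcidError(name, self.fatty_acid_names) from None
        return self.values[:, j]

    def row_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def scaled(self, factor: float) -> "ConcentrationMatrix":
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return ConcentrationMatrix(
            self.values * factor, self.subject_ids, self.fatty_acid_names
        )

    def __repr__(self) -> str:
        return (f"ConcentrationMatrix(n_subjects={self.n_subjects}, "
                f"n_fatty_acids={self.n_fatty_acids})")


class BiomarkerTable:
    """Per-subject blood-lipid biomarkers (TAG, TC, LDL, HDL, ...).

    The derived TC:HDL ratio column is added by :meth:`with_ratio` when both
    TC and HDL are present; HDL must be strictly positive wherever the ratio
    is computed.
    """

    RATIO_NAME = "TC:HDL"

    def __init__(self, values, subject_ids=None, biomarker_names=None):
        if isinstance(values, pd.DataFrame):
            if subject_ids is None:
                subject_ids = list(values.index.astype(str))
            if biomarker_names is None:
                biomarker_names = list(values.columns.astype(str))
            values = values.to_numpy()
        arr = _as_2d_float(values)
        n, k = arr.shape
        if subject_ids is None:
            subject_ids = [f"S{i + 1}" for i in range(n)]
        subject_ids = [str(s) for s in subject_ids]
        if biomarker_names is None:
            raise ValidationError("biomarker_names are required")
        biomarker_names = [str(c) for c in biomarker_names]
        if len(subject_ids) != n or len(biomarker_names) != k:
            raise ValidationError("label lengths do not match values")
        if len(set(biomarker_names)) != k:
            raise ValidationError("biomarker names must be unique")
        finite_or_nan = np.isnan(arr) | np.isfinite(arr)
        if not finite_or_nan.all():
            raise ValidationError("biomarker values must be finite (or NaN)")
        self.values = arr
        self.subject_ids = subject_ids
        self.biomarker_names = biomarker_names

    @classmethod
    def from_csv(cls, path) -> "BiomarkerTable":
        df = pd.read_csv(path, index_col=0, comment="#")
        return cls(df)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.biomarker_names,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.biomarker_names.index(name)
        except ValueError:
            raise ValidationError(
                f"unknown biomarker {name!r}; valid: {', '.join(self.biomarker_names)}"
            ) from None
        return self.values[:, j]

    def with_ratio(self) -> "BiomarkerTable":
        """Return a copy with the TC:HDL ratio column appended."""
        if self.RATIO_NAME in self.biomarker_names:
            return self
        if not {"TC", "HDL"}.issubset(self.biomarker_names):
            raise ValidationError("TC:HDL requires both TC and HDL columns")
        tc, hdl = self.column("TC"), self.column("HDL")
        observed = ~(np.isnan(tc) | np.isnan(hdl))
        if np.any(hdl[observed] <= 0):
            bad = [self.subject_ids[i]
                   for i in np.nonzero(observed & (hdl <= 0))[0]]
            raise ValidationError(
                f"HDL must be > 0 to form TC:HDL; offending subjects: {bad}"
            )
        ratio = np.full_like(tc, np.nan)
        ratio[observed] = tc[observed] / hdl[observed]
        return BiomarkerTable(
            np.column_stack([self.values, ratio]),
            self.subject_ids,
            self.biomarker_names + [self.RATIO_NAME],
        )

    def aligned_to(self, subject_ids: Sequence[str]) -> "BiomarkerTable":
        """Reorder rows to match ``subject_ids``; error on any mismatch."""
        wanted = [str(s) for s in subject_ids]
        if sorted(wanted) != sorted(self.subject_ids):
            missing = sorted(set(wanted) - set(self.subject_ids))
            extra = sorted(set(self.subject_ids) - set(wanted))
            raise ValidationError(
                f"subject IDs do not match paired concentration matrix "
                f"(missing {missing[:5]}, extra {extra[:5]})"
            )
        order = [self.subject_ids.index(s) for s in wanted]
        return BiomarkerTable(self.values[order], wanted, self.biomarker_names)

    def __repr__(self) -> str:
        return (f"BiomarkerTable(n_subjects={self.n_subjects}, "
                f"biomarkers={self.biomarker_names})")


@dataclass(frozen=True)
class SummaryMoments:
    """The seven-moment reduction feeding every delta-method prediction.

    Attributes
    ----------
    mu1, sigma1 : float
        Mean / sd of the focal fatty-acid concentration (mmol/l).
    mu2, sigma2 : float
        Mean / sd of the per-subject *sum* of all other fatty acids (mmol/l).
    rho12 : float
        Correlation between the focal fatty acid and the sum of others.
    rho1, rho2 : float
        Correlations of focal resp. sum-of-others with the biomarker Y.
    sigmaY : float
        Sample sd of Y (any unit; it cancels in predicted correlations).
    n : int or None
        Effective sample size the moments were estimated from, if known.
    """

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    rho12: float = 0.0
    rho1: float = 0.0
    rho2: float = 0.0
    sigmaY: float = 1.0
    n: int | None = None

    def __post_init__(self):
        for name in ("mu1", "sigma1", "mu2", "sigma2", "sigmaY"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        for name in ("rho12", "rho1", "rho2"):
            v = getattr(self, name)
            if not math.isfinite(v) or abs(v) > 1:
                raise ValidationError(f"{name} must lie in [-1, 1], got {v}")

    @property
    def cv1(self) -> float:
        """Coefficient of variation of the focal fatty acid."""
        if self.mu1 <= 0:
            raise ValidationError("cv1 undefined: mu1 must be > 0")
        return self.sigma1 / self.mu1

    @property
    def cv2(self) -> float:
        """Coefficient of variation of the sum of all other fatty acids."""
        if self.mu2 <= 0:
            raise ValidationError("cv2 undefined: mu2 must be > 0")
        return self.sigma2 / self.mu2

    def scaled(self, factor: float) -> "SummaryMoments":
        """Rescale all concentration moments by a common positive factor."""
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return replace(self, mu1=self.mu1 * factor, sigma1=self.sigma1 * factor,
                       mu2=self.mu2 * factor, sigma2=self.sigma2 * factor)


@dataclass(frozen=True)
class FisherZResult:
    """Outcome of the Fisher z-test for a non-zero Pearson correlation."""

    r: float
    n: int
    z: float          # atanh(r)
    statistic: float  # z * sqrt(n - 3), ~N(0, 1) under the null
    p: float          # two-sided
    underflow: bool   # p at or below the reporting floor (or |r| = 1)


def leave_one_out_sum(conc: ConcentrationMatrix, focal: str) -> np.ndarray:
    """Per-subject sum of all fatty acids except ``focal`` (mmol/l).

    Exactly ``row_totals() - focal column``; an unknown name raises
    :class:`UnknownFattyAcidError` listing the valid names.
    """
    focal_col = conc.column(focal)
    return conc.row_totals() - focal_col


def pearson(x, y) -> float:
    """Pearson sample correlation coefficient of two equal-length vectors.

    Raises :class:`DegenerateInputError` when either vector has zero sample
    variance (the correlation is undefined, never silently 0 or NaN).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValidationError("pearson needs at least 2 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("pearson received NaN; apply complete-case deletion first")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance input: correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(min(1.0, max(-1.0, r)))


def fisher_z_test(r: float, n: int) -> FisherZResult:
    """Two-sided test of rho = 0 via the Fisher z-transformation.

    z = atanh(r) is approximately N(0, 1/(n-3)) under the null, so
    ``z * sqrt(n - 3)`` is referred to the standard normal.
    """
    if not isinstance(n, (int, np.integer)):
        raise ValidationError("n must be an integer sample size")
    if n < 4:
        raise ValidationError(f"Fisher z-test requires n >= 4, got {n}")
    if not math.isfinite(r) or abs(r) > 1:
        raise ValidationError(f"correlation must lie in [-1, 1], got {r}")
    if abs(r) == 1.0:
        # Perfect correlation: atanh diverges; report the floor with a flag.
        return FisherZResult(r=float(r), n=int(n), z=math.copysign(math.inf, r),
                             statistic=math.copysign(math.inf, r),
                             p=P_FLOOR, underflow=True)
    z = math.atanh(r)
    statistic = z * math.sqrt(n - 3)
    p = float(2.0 * stats.norm.sf(abs(statistic)))
    # the two-sided p lives in (0, 1]; keep it strictly positive even when
    # the normal tail underflows, so alpha = 0 can never be "passed"
    p = min(max(p, 1e-300), 1.0)
    return FisherZResult(r=float(r), n=int(n), z=z, statistic=statistic,
                         p=p, underflow=p < P_FLOOR)


def format_p(p: float) -> str:
    """Render a p-value for text reports (floor at 1e-15)."""
    if p < P_FLOOR:
        return "<1e-15"
    return f"{p:.6g}"


def cohort_moments(conc: ConcentrationMatrix, focal: str, y,
                   min_n: int = 4) -> SummaryMoments:
    """Reduce a cohort to the summary moments for one focal fatty acid.

    ``mu1/sigma1`` come from the focal column, ``mu2/sigma2`` from the
    leave-one-out sum, ``rho12/rho1/rho2`` from Pearson correlations and
    ``sigmaY`` is the sample sd of the biomarker ``y``. Subjects with a
    missing focal value, any missing fatty acid (the sum is then undefined)
    or missing ``y`` are dropped (complete-case); the effective n is stored
    on the result.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != conc.n_subjects:
        raise ValidationError(
            f"biomarker vector length {y.shape[0]} != n_subjects {conc.n_subjects}"
        )
    x1 = conc.column(focal)
    x2 = leave_one_out_sum(conc, focal)  # NaN wherever any FA is missing
    mask = ~(np.isnan(x1) | np.isnan(x2) | np.isnan(y))
    n_eff = int(mask.sum())
    if n_eff < min_n:
        raise ValidationError(
            f"only {n_eff} complete cases for focal={focal!r}; need >= {min_n}"
        )
    x1, x2, yy = x1[mask], x2[mask], y[mask]
    return SummaryMoments(
        mu1=float(np.mean(x1)),
        sigma1=float(np.std(x1, ddof=1)),
        mu2=float(np.mean(x2)),
        sigma2=float(np.std(x2, ddof=1)),
        rho12=pearson(x1, x2),
        rho1=pearson(x1, yy),
        rho2=pearson(x2, yy),
        sigmaY=float(np.std(yy, ddof=1)),
        n=n_eff,
    )
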