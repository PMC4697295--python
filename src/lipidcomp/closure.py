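"""Compositional closure: concentrations -> percent-of-total.

Closing a row of fatty-acid concentrations to percentages (the almost
universal reporting convention in fatty-acid lipidomics) is the nonlinear
transformation whose interaction with Pearson correlation this package
studies. The closure is computed over exactly the columns present; callers
providing a partial panel are closing over that panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ValidationError
from .moments import ConcentrationMatrix

__all__ = ["CompositionMatrix", "close_rows", "percent_of_total", "PercentOfTotal"]


class CompositionMatrix:
    """Per-subject fatty-acid profile on the percent-of-total scale.

    Rows sum to ``scale`` (default 100) within 1e-9 relative tolerance and
    all entries lie in [0, scale].
    """

    def __init__(self, values, subject_ids=None, fatty_acid_names=None,
                 scale: float = 100.0):
        if isinstance(values, pd.DataFrame):
            if subject_ids is None:
                subject_ids = list(values.index.astype(str))
            if fatty_acid_names is None:
                fatty_acid_names = list(values.columns.astype(str))
            values = values.to_numpy()
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("composition values must be 2-D")
        if scale <= 0:
            raise ValidationError("percent scale must be positive")
        n, k = arr.shape
        if subject_ids is None:
            subject_ids = [f"S{i + 1}" for i in range(n)]
        if fatty_acid_names is None:
            fatty_acid_names = [f"FA{j + 1}" for j in range(k)]
        subject_ids = [str(s) for s in subject_ids]
        fatty_acid_names = [str(c) for c in fatty_acid_names]
        if len(set(fatty_acid_names)) != k:
            raise ValidationError("fatty_acid_names must be unique")
        row_ok = np.isnan(arr).any(axis=1)  # rows with missing data are not checked
        sums = np.nansum(arr, axis=1)
        complete = ~row_ok
        if complete.any():
            if not np.allclose(sums[complete], scale, rtol=1e-9, atol=0):
                raise ValidationError(f"rows must sum to {scale} (closure violated)")
        with np.errstate(invalid="ignore"):
            if np.nanmin(arr) < 0 or np.nanmax(arr) > scale:
                raise ValidationError(f"entries must lie in [0, {scale}]")
        self.values = arr
        self.subject_ids = subject_ids
        self.fatty_acid_names = fatty_acid_names
        self.scale = float(scale)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.fatty_acid_names,
        )

    def column(self, name: str) -> np.ndarray:
        from .exceptions import UnknownFattyAcidError

        try:
            j = self.fatty_acid_names.index(name)
        except ValueError:
            raise UnknownFattyAcidError(name, self.fatty_acid_names) from None
        return self.values[:, j]

    def to_csv(self, path) -> None:
        """Write CSV with a comment line recording the closure basis."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                f"# closure basis: {len(self.fatty_acid_names)} fatty acids "
                f"({', '.join(self.fatty_acid_names)}); rows sum to {self.scale:g}\n"
            )
            self.to_dataframe().to_csv(fh)

    def __repr__(self) -> str:
        return (f"CompositionMatrix(n_subjects={self.n_subjects}, "
                f"n_fatty_acids={len(self.fatty_acid_names)}, scale={self.scale:g})")


def close_rows(values, scale: float = 100.0, subject_ids=None) -> np.ndarray:
    """Divide each row by its sum and multiply by ``scale``.

    Rows containing NaN propagate NaN. A zero (or negative) row sum is an
    error naming the offending subject, because the composition is undefined.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D table")
    sums = arr.sum(axis=1)  # NaN rows -> NaN sum -> NaN output row
    bad = np.nonzero(~np.isnan(sums) & (sums <= 0))[0]
    if bad.size:
        ids = ([str(subject_ids[i]) for i in bad[:5]] if subject_ids is not None
               else [f"row {i}" for i in bad[:5]])
        raise ValidationError(
            f"cannot close rows with non-positive total: {', '.join(ids)}"
        )
    return scale * arr / sums[:, None]


def percent_of_total(conc: ConcentrationMatrix, scale: float = 100.0) -> CompositionMatrix:
    """Close a concentration matrix to the percent-of-total scale.

    Scale-invariant: ``percent_of_total(c * conc) == percent_of_total(conc)``
    for any c > 0, which is precisely why closed data discard the
    information that absolute concentrations carry.
    """
    closed = close_rows(conc.values, scale=scale, subject_ids=conc.subject_ids)
    return CompositionMatrix(closed, conc.subject_ids, conc.fatty_acid_names,
                             scale=scale)


class PercentOfTotal(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying percent-of-total closure.

    Parameters
    ----------
    scale : float, default 100.0
        Basis of the closure: 100 for percentages, 1 for proportions.

    Examples
    --------
    >>> PercentOfTotal().fit_transform([[3.0, 1.0]])
    array([[75., 25.]])
    """

    def __init__(self, scale: float = 100.0):
        self.scale = scale

    def fit(self, X, y=None):
        if isinstance(X, (ConcentrationMatrix, pd.DataFrame)):
            X_arr = X.to_numpy() if isinstance(X, pd.DataFrame) else X.values
        else:
            X_arr = np.asarray(X, dtype=float)
        if X_arr.ndim != 2:
            raise ValidationError("expected a 2-D table")
        self.n_features_in_ = X_arr.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X):
        if isinstance(X, ConcentrationMatrix):
            return percent_of_total(X, scale=self.scale)
        if isinstance(X, pd.DataFrame):
            closed = close_rows(X.to_numpy(), scale=self.scale,
                                subject_ids=list(X.index))
            return pd.DataFrame(closed, index=X.index, columns=X.columns)
        return close_rows(X, scale=self.scale)

    def get_feature_names_out(self, input_features=None):
        if input_features is not None:
            return np.asarray(input_features, dtype=object)
        if hasattr(self, "feature_names_in_"):
            return self.feature_names_in_
        return np.asarray([f"FA{j + 1}" for j in range(self.n_features_in_)],
                          dtype=object)
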