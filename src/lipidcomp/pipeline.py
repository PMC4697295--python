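"""End-to-end association analysis: the three-way correlation grid.

For every (fatty acid, biomarker) pair the grid holds the observed Pearson
correlation on the concentration ("mass") scale, the observed correlation on
the percent-of-total scale, and the delta-method *predicted* percent-scale
correlation computed purely from concentration-scale moments — together
with Fisher-z p-values, the predicted sign, a reversal flag (the observed
sign changed between scales) and a prediction-agreement flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import closure, taylor
from .exceptions import DegenerateInputError, ValidationError
from .moments import (BiomarkerTable, ConcentrationMatrix, cohort_moments,
                      fisher_z_test, format_p, pearson)

__all__ = [
    "AssociationGrid",
    "AssociationAnalysis",
    "run_association_analysis",
    "classify_reversals",
    "render_report",
    "read_grid",
]

logger = logging.getLogger(__name__)

_R_COLUMNS = ["r_mass_observed", "p_mass", "r_percent_observed", "p_percent",
              "r_percent_predicted"]
_SIGN_CHARS = {"positive": "+", "negative": "-", "zero": "0"}
_CHAR_SIGNS = {v: k for k, v in _SIGN_CHARS.items()}


def _sign(x: float) -> float:
    if np.isnan(x):
        return np.nan
    return float(np.sign(x))


@dataclass
class AssociationGrid:
    """(fatty acid x biomarker) grid of mass/percent/predicted correlations.

    ``data`` is tidy: one row per pair with the raw r/p/predicted values.
    The boolean flags are derived quantities and are recomputed from the r
    columns on every :attr:`frame` access so they can never drift out of
    sync with the values they summarise.
    """

    data: pd.DataFrame

    @property
    def fatty_acids(self) -> list[str]:
        return list(dict.fromkeys(self.data["fatty_acid"]))

    @property
    def biomarkers(self) -> list[str]:
        return list(dict.fromkeys(self.data["biomarker"]))

    @property
    def frame(self) -> pd.DataFrame:
        df = self.data.copy()
        s_mass = df["r_mass_observed"].map(_sign)
        s_pct = df["r_percent_observed"].map(_sign)
        s_pred = df["r_percent_predicted"].map(_sign)
        df["reversal_flag"] = (s_mass * s_pct) < 0
        df["prediction_agreement_flag"] = (s_pred == s_pct) & s_pct.notna()
        return df

    def cell(self, fatty_acid: str, biomarker: str) -> pd.Series:
        df = self.frame
        sel = df[(df["fatty_acid"] == fatty_acid) & (df["biomarker"] == biomarker)]
        if sel.empty:
            raise ValidationError(f"no cell ({fatty_acid!r}, {biomarker!r})")
        return sel.iloc[0]

    def pivot(self, column: str) -> pd.DataFrame:
        """Fig.-4-style wide view of one grid quantity."""
        return self.frame.pivot(index="fatty_acid", columns="biomarker",
                                values=column)


class AssociationAnalysis(BaseEstimator):
    """Estimator computing the association grid for a cohort.

    Parameters
    ----------
    biomarkers : list of str or None
        Biomarker columns to analyse; None means every column in the table
        (plus TC:HDL when ``include_ratio`` and TC, HDL are present).
    include_ratio : bool, default True
        Append the per-subject TC:HDL ratio as an extra biomarker.
    alpha : float, default 0.05
        Significance level used by :meth:`reversals`.
    percent_scale : float, default 100.0
        Closure basis for the percent-of-total scale (correlations are
        invariant to it; it only affects reported compositions).
    min_n : int, default 4
        Minimum complete cases per cell.

    Attributes
    ----------
    grid_ : AssociationGrid
        The fitted grid.
    n_subjects_ : int
        Cohort size after alignment.
    skipped_ : list of (fatty_acid, biomarker, reason)
        Cells left NA because a statistic was undefined.
    """

    def __init__(self, biomarkers=None, include_ratio: bool = True,
                 alpha: float = 0.05, percent_scale: float = 100.0,
                 min_n: int = 4):
        self.biomarkers = biomarkers
        self.include_ratio = include_ratio
        self.alpha = alpha
        self.percent_scale = percent_scale
        self.min_n = min_n

    def fit(self, X: ConcentrationMatrix, y: BiomarkerTable):
        """Compute the grid from aligned concentration and biomarker tables."""
        if not isinstance(X, ConcentrationMatrix):
            X = ConcentrationMatrix(X)
        if not isinstance(y, BiomarkerTable):
            raise ValidationError("y must be a BiomarkerTable")
        lipids = y.aligned_to(X.subject_ids)
        if self.include_ratio and {"TC", "HDL"}.issubset(lipids.biomarker_names):
            lipids = lipids.with_ratio()
        names = (list(self.biomarkers) if self.biomarkers is not None
                 else list(lipids.biomarker_names))
        missing = [b for b in names if b not in lipids.biomarker_names]
        if missing:
            raise ValidationError(f"requested biomarkers not present: {missing}")

        comp = closure.percent_of_total(X, scale=self.percent_scale)
        logger.info("association analysis: n=%d subjects, %d fatty acids, "
                    "%d biomarkers", X.n_subjects, X.n_fatty_acids, len(names))

        rows, skipped = [], []
        for fa in X.fatty_acid_names:
            conc_col = X.column(fa)
            pct_col = comp.column(fa)
            for bm in names:
                y_col = lipids.column(bm)
                mask = ~(np.isnan(conc_col) | np.isnan(pct_col) | np.isnan(y_col))
                n_eff = int(mask.sum())
                rec = {"fatty_acid": fa, "biomarker": bm, "n": n_eff,
                       "r_mass_observed": np.nan, "p_mass": np.nan,
                       "r_percent_observed": np.nan, "p_percent": np.nan,
                       "r_percent_predicted": np.nan, "predicted_sign": "NA"}
                if n_eff < self.min_n:
                    skipped.append((fa, bm, f"only {n_eff} complete cases"))
                    logger.warning("skipping (%s, %s): %d complete cases",
                                   fa, bm, n_eff)
                    rows.append(rec)
                    continue
                try:
                    r_mass = pearson(conc_col[mask], y_col[mask])
                    r_pct = pearson(pct_col[mask], y_col[mask])
                    rec.update(
                        r_mass_observed=r_mass,
                        p_mass=fisher_z_test(r_mass, n_eff).p,
                        r_percent_observed=r_pct,
                        p_percent=fisher_z_test(r_pct, n_eff).p,
                    )
                    m = cohort_moments(X, fa, y_col, min_n=self.min_n)
                    pred = taylor.predicted_corr_biomarker(m)
                    cond = taylor.sign_condition_biomarker(m)
                    rec.update(r_percent_predicted=pred.value,
                               predicted_sign=cond.predicted_sign)
                except (DegenerateInputError, ValidationError) as exc:
                    skipped.append((fa, bm, str(exc)))
                    logger.warning("cell (%s, %s) left NA: %s", fa, bm, exc)
                rows.append(rec)

        self.grid_ = AssociationGrid(pd.DataFrame(rows))
        self.n_subjects_ = X.n_subjects
        self.skipped_ = skipped
        return self

    def reversals(self):
        if not hasattr(self, "grid_"):
            raise ValidationError("call fit() first")
        return classify_reversals(self.grid_, alpha=self.alpha)


def run_association_analysis(conc: ConcentrationMatrix, lipids: BiomarkerTable,
                             config: dict | None = None) -> AssociationGrid:
    """Functional wrapper over :class:`AssociationAnalysis`.

    ``config`` keys (all optional): ``biomarker_columns``, ``percent_scale``,
    ``alpha``, ``min_n``.
    """
    config = config or {}
    est = AssociationAnalysis(
        biomarkers=config.get("biomarker_columns"),
        alpha=config.get("alpha", 0.05),
        percent_scale=config.get("percent_scale", 100.0),
        min_n=config.get("min_n", 4),
    )
    return est.fit(conc, lipids).grid_


def classify_reversals(grid: AssociationGrid, alpha: float = 0.05) -> list[tuple]:
    """Cells whose observed correlation flips sign between scales.

    Returns ``(fatty_acid, biomarker, direction_mass, direction_percent)``
    for every cell with a sign reversal and both Fisher-z p-values <= alpha,
    sorted by |r_mass_observed| descending with a deterministic
    (fatty_acid, biomarker) lexicographic tie-break.
    """
    df = grid.frame
    keep = (df["reversal_flag"]
            & (df["p_mass"] <= alpha) & (df["p_percent"] <= alpha))
    sel = df[keep.fillna(False)].copy()
    sel = sel.sort_values(
        by=["r_mass_observed", "fatty_acid", "biomarker"],
        key=lambda s: -s.abs() if s.name == "r_mass_observed" else s,
    )
    return [
        (row.fatty_acid, row.biomarker,
         "positive" if row.r_mass_observed > 0 else "negative",
         "positive" if row.r_percent_observed > 0 else "negative")
        for row in sel.itertuples()
    ]


def _render_value(v) -> str:
    if isinstance(v, float):
        if np.isnan(v):
            return "NA"
        return f"{v:.6g}"
    return str(v)


def render_report(grid: AssociationGrid, outdir, alpha: float = 0.05) -> dict:
    """Write association_grid.tsv / .json and reversals.tsv into ``outdir``.

    The TSV renders signs as "+"/"-"/"0", p-values below 1e-15 as "<1e-15",
    and floats at 6 significant figures; the JSON keeps full precision.
    Returns the mapping of artefact name -> path.
    """
    from pathlib import Path

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create report directory {outdir}: {exc}")

    df = grid.frame
    paths = {
        "association_grid.tsv": outdir / "association_grid.tsv",
        "association_grid.json": outdir / "association_grid.json",
        "reversals.tsv": outdir / "reversals.tsv",
    }

    cols = ["fatty_acid", "biomarker", "n", *_R_COLUMNS,
            "predicted_sign", "reversal_flag", "prediction_agreement_flag"]
    try:
        with open(paths["association_grid.tsv"], "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in df.itertuples():
                vals = [
                    row.fatty_acid, row.biomarker, str(row.n),
                    _render_value(row.r_mass_observed),
                    "NA" if np.isnan(row.p_mass) else format_p(row.p_mass),
                    _render_value(row.r_percent_observed),
                    "NA" if np.isnan(row.p_percent) else format_p(row.p_percent),
                    _render_value(row.r_percent_predicted),
                    _SIGN_CHARS.get(row.predicted_sign, "NA"),
                    str(bool(row.reversal_flag)),
                    str(bool(row.prediction_agreement_flag)),
                ]
                fh.write("\t".join(vals) + "\n")

        records = json.loads(df.to_json(orient="records"))
        with open(paths["association_grid.json"], "w", encoding="utf-8") as fh:
            json.dump({"n_fatty_acids": len(grid.fatty_acids),
                       "n_biomarkers": len(grid.biomarkers),
                       "cells": records}, fh, indent=1)

        revs = classify_reversals(grid, alpha=alpha)
        with open(paths["reversals.tsv"], "w", encoding="utf-8") as fh:
            fh.write("fatty_acid\tbiomarker\tdirection_mass\tdirection_percent\n")
            for fa, bm, dm, dp in revs:
                fh.write(f"{fa}\t{bm}\t{dm}\t{dp}\n")
    except OSError as exc:
        raise ValidationError(f"report I/O failure at {outdir}: {exc}")
    return {k: str(v) for k, v in paths.items()}


def read_grid(tsv_path) -> AssociationGrid:
    """Reconstruct an :class:`AssociationGrid` from a rendered TSV.

    Values round-trip to the TSV's 6 significant figures; p-values written
    as "<1e-15" are restored as the 1e-15 floor.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    out = pd.DataFrame({"fatty_acid": df["fatty_acid"],
                        "biomarker": df["biomarker"],
                        "n": df["n"].astype(int)})
    for col in _R_COLUMNS:
        raw = df[col].replace({"NA": "nan", "<1e-15": "1e-15"})
        out[col] = raw.astype(float)
    out["predicted_sign"] = df["predicted_sign"].map(
        lambda c: _CHAR_SIGNS.get(c, "NA"))
    return AssociationGrid(out)
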