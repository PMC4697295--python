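"""Moment-matched synthetic cohorts.

The subject-level data behind the motivating cohorts are not distributed,
but the reversal framework only consumes first and second moments, so
cohorts with the printed summary statistics can be simulated exactly. The
default generative law is a joint multivariate normal over fatty-acid
concentrations and biomarkers with user-specified means, sds and
correlations; printed coefficients of variation (<= ~0.35) make the normal's
negative tail negligible and a moment-matched lognormal mode is available
for skewness-robustness checks.

Negative draws (physically impossible concentrations) are handled by a
``negativity_policy``:

* ``"resample_row"`` (default) — redraw any row containing a negative value;
* ``"truncate_at_zero"`` — clip at zero;
* ``"allow"`` — keep raw normal draws (the right choice for Monte-Carlo
  checks of the delta-method formulas, which are statements about the exact
  normal law).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np

from .exceptions import ValidationError
from .moments import BiomarkerTable, ConcentrationMatrix, SummaryMoments

__all__ = [
    "BiomarkerSpec",
    "SyntheticCohortSpec",
    "simulate_cohort",
    "demo_like_spec",
    "filler_panel_spec",
    "max_psd_rho",
    "random_summary_moments",
    "simulate_from_moments",
]

NegativityPolicy = Literal["resample_row", "truncate_at_zero", "allow"]

#: Eigenvalue tolerance when validating positive semidefiniteness.
PSD_TOL = 1e-8


@dataclass(frozen=True)
class BiomarkerSpec:
    """Target moments and fatty-acid coupling for one simulated biomarker."""

    name: str
    mean: float
    sd: float
    fa_correlations: tuple[float, ...]

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError(f"{self.name}: sd must be >= 0")
        if any(abs(r) > 1 for r in self.fa_correlations):
            raise ValidationError(f"{self.name}: correlations must lie in [-1, 1]")


@dataclass
class SyntheticCohortSpec:
    """Full description of a simulated cohort.

    The joint correlation matrix is assembled as::

        [ fa_correlation      B^T ]
        [ B    biomarker_correlation ]

    where row b of B holds biomarker b's correlations with each fatty acid.
    It must be symmetric with unit diagonal and positive semidefinite
    (eigenvalues >= -1e-8).
    """

    fatty_acid_names: list[str]
    mean_vector: Sequence[float]
    sd_vector: Sequence[float]
    fa_correlation: Sequence[Sequence[float]]
    biomarkers: list[BiomarkerSpec]
    n_subjects: int = 93
    seed: int = 0
    negativity_policy: NegativityPolicy = "resample_row"
    lognormal: bool = False
    biomarker_correlation: Sequence[Sequence[float]] | None = None

    # -- assembly ----------------------------------------------------------

    def joint_names(self) -> list[str]:
        return list(self.fatty_acid_names) + [b.name for b in self.biomarkers]

    def joint_mean(self) -> np.ndarray:
        return np.concatenate([
            np.asarray(self.mean_vector, dtype=float),
            np.array([b.mean for b in self.biomarkers], dtype=float),
        ])

    def joint_sd(self) -> np.ndarray:
        return np.concatenate([
            np.asarray(self.sd_vector, dtype=float),
            np.array([b.sd for b in self.biomarkers], dtype=float),
        ])

    def joint_correlation(self) -> np.ndarray:
        k = len(self.fatty_acid_names)
        m = len(self.biomarkers)
        fa_corr = np.asarray(self.fa_correlation, dtype=float)
        if fa_corr.shape != (k, k):
            raise ValidationError(f"fa_correlation must be {k}x{k}")
        if self.biomarker_correlation is None:
            bm_corr = np.eye(m)
        else:
            bm_corr = np.asarray(self.biomarker_correlation, dtype=float)
            if bm_corr.shape != (m, m):
                raise ValidationError(f"biomarker_correlation must be {m}x{m}")
        cross = np.array([b.fa_correlations for b in self.biomarkers],
                         dtype=float).reshape(m, k)
        top = np.hstack([fa_corr, cross.T])
        bottom = np.hstack([cross, bm_corr])
        return np.vstack([top, bottom])

    def validate(self) -> np.ndarray:
        """Check all invariants; return the validated joint correlation."""
        k = len(self.fatty_acid_names)
        if len(set(self.fatty_acid_names)) != k:
            raise ValidationError("fatty_acid_names must be unique")
        means, sds = self.joint_mean(), self.joint_sd()
        if means.shape != sds.shape or means.shape[0] != k + len(self.biomarkers):
            raise ValidationError("mean/sd vectors do not match the name lists")
        if np.any(sds < 0):
            raise ValidationError("sd_vector entries must be >= 0")
        if self.n_subjects < 4:
            raise ValidationError("n_subjects must be >= 4")
        if self.negativity_policy not in ("resample_row", "truncate_at_zero", "allow"):
            raise ValidationError(
                f"unknown negativity_policy {self.negativity_policy!r}"
            )
        corr = self.joint_correlation()
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValidationError("joint correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValidationError("joint correlation matrix must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -PSD_TOL:
            raise ValidationError(
                f"joint correlation matrix is not positive semidefinite: "
                f"smallest eigenvalue {eigmin:.3e}"
            )
        if self.lognormal and np.any(means <= 0):
            raise ValidationError("lognormal mode requires strictly positive means")
        return corr

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_vector"] = list(np.asarray(self.mean_vector, dtype=float))
        d["sd_vector"] = list(np.asarray(self.sd_vector, dtype=float))
        d["fa_correlation"] = np.asarray(self.fa_correlation, dtype=float).tolist()
        if self.biomarker_correlation is not None:
            d["biomarker_correlation"] = np.asarray(
                self.biomarker_correlation, dtype=float).tolist()
        d["biomarkers"] = [
            {"name": b.name, "mean": b.mean, "sd": b.sd,
             "fa_correlations": list(b.fa_correlations)}
            for b in self.biomarkers
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortSpec":
        d = dict(d)
        d["biomarkers"] = [
            BiomarkerSpec(name=b["name"], mean=float(b["mean"]), sd=float(b["sd"]),
                          fa_correlations=tuple(float(r) for r in b["fa_correlations"]))
            for b in d.get("biomarkers", [])
        ]
        return cls(**d)


def _factor(cov: np.ndarray) -> np.ndarray:
    """Symmetric factor F with F F^T = cov, tolerant of PSD round-off."""
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _apply_negativity(draws: np.ndarray, policy: NegativityPolicy,
                      mean: np.ndarray, factor: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    if policy == "allow":
        return draws
    if policy == "truncate_at_zero":
        return np.maximum(draws, 0.0)
    # resample_row: redraw offending rows in vectorised rounds
    k = mean.shape[0]
    for _ in range(1000):
        bad = np.nonzero((draws < 0).any(axis=1))[0]
        if bad.size == 0:
            return draws
        z = rng.standard_normal((bad.size, k))
        draws[bad] = mean + z @ factor.T
    raise ValidationError(
        "resample_row exceeded 1000 rounds: the specified moments imply "
        "non-negligible negative probability mass; use truncate_at_zero "
        "or revise the spec"
    )


def simulate_cohort(spec: SyntheticCohortSpec, seed: int | None = None,
                    n_subjects: int | None = None
                    ) -> tuple[ConcentrationMatrix, BiomarkerTable]:
    """Draw a cohort with the spec's joint moment structure.

    Reproducible: identical spec + seed give bit-identical outputs. Sample
    moments converge to the spec's targets as ``n_subjects`` grows.
    """
    corr = spec.validate()
    seed = spec.seed if seed is None else seed
    n = spec.n_subjects if n_subjects is None else int(n_subjects)
    if n < 4:
        raise ValidationError("n_subjects must be >= 4")
    means, sds = spec.joint_mean(), spec.joint_sd()
    k_fa = len(spec.fatty_acid_names)
    rng = np.random.default_rng(seed)

    if spec.lognormal:
        # Moment-matched lognormal: exp of a joint normal whose parameters
        # reproduce the target means/covariances exactly.
        cov = corr * np.outer(sds, sds)
        ratio = 1.0 + cov / np.outer(means, means)
        if np.any(ratio <= 0):
            raise ValidationError(
                "lognormal moment matching impossible: 1 + cov/(mi*mj) <= 0"
            )
        log_cov = np.log(ratio)
        log_mean = np.log(means) - 0.5 * np.diag(log_cov)
        eigmin = float(np.linalg.eigvalsh(log_cov).min())
        if eigmin < -PSD_TOL:
            raise ValidationError(
                f"log-scale covariance not positive semidefinite "
                f"(smallest eigenvalue {eigmin:.3e})"
            )
        factor = _factor(log_cov)
        z = rng.standard_normal((n, means.shape[0]))
        draws = np.exp(log_mean + z @ factor.T)  # non-negative by construction
    else:
        cov = corr * np.outer(sds, sds)
        factor = _factor(cov)
        z = rng.standard_normal((n, means.shape[0]))
        draws = means + z @ factor.T
        draws = _apply_negativity(draws, spec.negativity_policy, means, factor, rng)

    subject_ids = [f"S{i + 1:05d}" for i in range(n)]
    fa_values = draws[:, :k_fa]
    if spec.negativity_policy == "allow" and np.any(fa_values < 0):
        # "allow" deliberately keeps raw normal draws, so the non-negativity
        # check of ConcentrationMatrix must be bypassed for those rows.
        conc = ConcentrationMatrix.__new__(ConcentrationMatrix)
        conc.values = fa_values
        conc.subject_ids = subject_ids
        conc.fatty_acid_names = list(spec.fatty_acid_names)
    else:
        conc = ConcentrationMatrix(fa_values, subject_ids,
                                   list(spec.fatty_acid_names))
    table = BiomarkerTable(draws[:, k_fa:], subject_ids,
                           [b.name for b in spec.biomarkers])
    return conc, table


def max_psd_rho(rho1: float, rho2: float) -> float:
    """Largest corr(X1, X2) keeping [[1,r,rho1],[r,1,rho2],[rho1,rho2,1]] PSD."""
    disc = (1.0 - rho1 ** 2) * (1.0 - rho2 ** 2)
    return rho1 * rho2 + math.sqrt(max(disc, 0.0))


# Printed cohort moments used by the two worked scenarios (mmol/l):
# focal fatty acid (mean, sd), sum of all other fatty acids (mean, sd) and
# their correlations with TAG.
_SCENARIOS = {
    "LA": {"focal_name": "C18:2n-6", "focal": (3.83, 0.77),
           "others": (8.27, 2.17), "tag_corr": (0.60, 0.87)},
    "OA": {"focal_name": "C18:1n-9", "focal": (2.39, 0.76),
           "others": (9.70, 2.04), "tag_corr": (0.90, 0.82)},
}

#: TAG moments for the simulated cohorts (mmol/l). Not part of the printed
#: summary; every correlation downstream is invariant to this choice. Values
#: are typical of an overweight postmenopausal cohort, with the CV kept at
#: 0.33 so the normal generative law's negative tail stays below the 0.002
#: per-variable mass the resample_row policy is documented to tolerate.
TAG_MEAN = 1.5
TAG_SD = 0.5


def demo_like_spec(scenario: str, rho12: float | None = None,
                   n_subjects: int = 93, seed: int = 0,
                   negativity_policy: NegativityPolicy = "resample_row",
                   lognormal: bool = False) -> SyntheticCohortSpec:
    """Two-column cohort spec matching a printed worked example.

    ``scenario`` is ``"LA"`` (focal linoleic acid; reversal expected) or
    ``"OA"`` (focal oleic acid; concordant positive). The cohort has the
    focal fatty acid, a single aggregate "other fatty acids" column and a
    TAG biomarker with the printed moments.

    The focal <-> others correlation ``rho12`` is NOT a printed quantity;
    by default it is set to the largest value keeping the joint correlation
    matrix positive semidefinite minus a 0.05 margin (serum fatty-acid
    pools co-vary strongly, so a high value is realistic). Pass ``rho12``
    explicitly to study other coupling strengths.
    """
    if scenario not in _SCENARIOS:
        raise ValidationError(
            f"unknown scenario {scenario!r}; expected one of {sorted(_SCENARIOS)}"
        )
    s = _SCENARIOS[scenario]
    rho1, rho2 = s["tag_corr"]
    if rho12 is None:
        lo = rho1 * rho2 - math.sqrt((1 - rho1 ** 2) * (1 - rho2 ** 2))
        hi = max_psd_rho(rho1, rho2)
        rho12 = hi - 0.05 if hi - 0.05 > lo else 0.5 * (lo + hi)
    return SyntheticCohortSpec(
        fatty_acid_names=[s["focal_name"], "other_FA"],
        mean_vector=[s["focal"][0], s["others"][0]],
        sd_vector=[s["focal"][1], s["others"][1]],
        fa_correlation=[[1.0, rho12], [rho12, 1.0]],
        biomarkers=[BiomarkerSpec(name="TAG", mean=TAG_MEAN, sd=TAG_SD,
                                  fa_correlations=(rho1, rho2))],
        n_subjects=n_subjects,
        seed=seed,
        negativity_policy=negativity_policy,
        lognormal=lognormal,
    )


# 19 abundant serum fatty acids with invented but physiologically plausible
# moments (synthetic — NOT the motivating study's Table 1, whose numbers are
# not reproduced here). Means sum to ~12 mmol/l of total fatty acid.
_FILLER_PANEL: list[tuple[str, float, float]] = [
    ("C14:0", 0.12, 0.05), ("C15:0", 0.03, 0.01), ("C16:0", 2.90, 0.65),
    ("C16:1n-7", 0.30, 0.13), ("C17:1", 0.03, 0.01), ("C18:0", 0.85, 0.17),
    ("C18:1n-9", 2.39, 0.76), ("C18:1n-7", 0.18, 0.05), ("C18:2n-6", 3.83, 0.77),
    ("C18:3n-6", 0.05, 0.02), ("C18:3n-3", 0.08, 0.03), ("C20:1n-9", 0.02, 0.01),
    ("C20:2n-6", 0.03, 0.01), ("C20:3n-6", 0.18, 0.06), ("C20:4n-6", 0.90, 0.20),
    ("C20:5n-3", 0.05, 0.03), ("C22:4n-6", 0.03, 0.01), ("C22:5n-3", 0.06, 0.02),
    ("C22:6n-3", 0.15, 0.05),
]

_FILLER_BIOMARKERS: list[tuple[str, float, float]] = [
    # (name, mean, sd) — mmol/l, plausible for an overweight cohort
    ("TAG", 1.5, 0.5), ("TC", 5.5, 0.9), ("LDL", 3.4, 0.8), ("HDL", 1.4, 0.3),
]


def filler_panel_spec(n_subjects: int = 93, seed: int = 0,
                      negativity_policy: NegativityPolicy = "resample_row"
                      ) -> SyntheticCohortSpec:
    """A 19-fatty-acid, 4-biomarker cohort spec for end-to-end runs.

    Synthetic: the moments are invented plausible values, not any study's
    measurements. The joint correlation matrix is built from a seeded
    two-factor loading model (guaranteeing positive semidefiniteness) so
    fatty acids share a common "total lipid pool" factor — which is what
    produces realistic reversal behaviour after closure.
    """
    names = [n for n, _, _ in _FILLER_PANEL]
    means = np.array([m for _, m, _ in _FILLER_PANEL])
    sds = np.array([s for _, _, s in _FILLER_PANEL])
    labels = names + [n for n, _, _ in _FILLER_BIOMARKERS]
    d = len(labels)
    rng = np.random.default_rng(seed + 7919)  # structure seed, not draw seed
    # factor 1: shared pool loading; factor 2: random heterogeneity
    load = np.empty((d, 2))
    load[:, 0] = 0.55 + 0.25 * rng.random(d)
    load[:, 1] = 0.45 * (rng.random(d) - 0.5)
    # HDL typically moves against the TAG-rich pool
    load[labels.index("HDL"), 0] *= -0.4
    uniq = 1.0 - (load ** 2).sum(axis=1)
    cov = load @ load.T + np.diag(uniq)
    dinv = 1.0 / np.sqrt(np.diag(cov))
    corr = cov * np.outer(dinv, dinv)
    k = len(names)
    biomarkers = [
        BiomarkerSpec(name=labels[k + i], mean=_FILLER_BIOMARKERS[i][1],
                      sd=_FILLER_BIOMARKERS[i][2],
                      fa_correlations=tuple(corr[k + i, :k]))
        for i in range(len(_FILLER_BIOMARKERS))
    ]
    return SyntheticCohortSpec(
        fatty_acid_names=names,
        mean_vector=means,
        sd_vector=sds,
        fa_correlation=corr[:k, :k],
        biomarkers=biomarkers,
        biomarker_correlation=corr[k:, k:],
        n_subjects=n_subjects,
        seed=seed,
        negativity_policy=negativity_policy,
    )


def random_summary_moments(rng: np.random.Generator,
                           cv_low: float = 0.05, cv_high: float = 0.4,
                           rho_max: float = 0.9) -> SummaryMoments:
    """Draw a random valid moment set for property sweeps and MC oracles.

    Means are uniform on [1, 10] mmol/l, CVs uniform on [cv_low, cv_high],
    and (rho12, rho1, rho2) are redrawn uniformly on [-rho_max, rho_max]
    until the implied 3x3 correlation matrix is positive definite.
    """
    mu1, mu2 = rng.uniform(1.0, 10.0, size=2)
    cv1, cv2 = rng.uniform(cv_low, cv_high, size=2)
    while True:
        rho12, rho1, rho2 = rng.uniform(-rho_max, rho_max, size=3)
        det = 1 + 2 * rho12 * rho1 * rho2 - rho12 ** 2 - rho1 ** 2 - rho2 ** 2
        if det > 1e-3:
            break
    return SummaryMoments(mu1=mu1, sigma1=cv1 * mu1, mu2=mu2, sigma2=cv2 * mu2,
                          rho12=rho12, rho1=rho1, rho2=rho2,
                          sigmaY=float(rng.uniform(0.3, 3.0)))


def simulate_from_moments(m: SummaryMoments, n: int, seed: int,
                          negativity_policy: NegativityPolicy = "resample_row"
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (X1, X2, Y) directly from a seven-moment summary.

    Returns the three columns. ``Y`` is given mean ``8 * sigmaY`` so that
    negativity handling never touches it in practice. The default
    ``resample_row`` policy matters here: the percent-of-total ratio has no
    finite moments once the total can cross zero, so raw normal draws make
    the empirical Pearson correlation meaningless at large CVs; keeping
    concentrations non-negative keeps the denominator bounded away from
    pathology while perturbing the target moments only in the far tail.
    """
    spec = SyntheticCohortSpec(
        fatty_acid_names=["focal", "others"],
        mean_vector=[m.mu1, m.mu2],
        sd_vector=[m.sigma1, m.sigma2],
        fa_correlation=[[1.0, m.rho12], [m.rho12, 1.0]],
        biomarkers=[BiomarkerSpec(name="Y", mean=8.0 * m.sigmaY, sd=m.sigmaY,
                                  fa_correlations=(m.rho1, m.rho2))],
        n_subjects=n,
        seed=seed,
        negativity_policy=negativity_policy,
    )
    conc, table = simulate_cohort(spec)
    return conc.values[:, 0], conc.values[:, 1], table.values[:, 0]
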