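import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lipidcomp.moments import BiomarkerTable, ConcentrationMatrix, SummaryMoments

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def la_moments() -> SummaryMoments:
    """Printed cohort moments for linoleic acid vs TAG (reversal case)."""
    return SummaryMoments(mu1=3.83, sigma1=0.77, mu2=8.27, sigma2=2.17,
                          rho12=0.85, rho1=0.60, rho2=0.87, sigmaY=0.6)


@pytest.fixture
def oa_moments() -> SummaryMoments:
    """Printed cohort moments for oleic acid vs TAG (concordant case)."""
    return SummaryMoments(mu1=2.39, sigma1=0.76, mu2=9.70, sigma2=2.04,
                          rho12=0.85, rho1=0.90, rho2=0.82, sigmaY=0.6)


@pytest.fixture
def toy_conc() -> ConcentrationMatrix:
    """3 subjects x 4 fatty acids with integer entries (hand-checkable)."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [2.0, 2.0, 2.0, 2.0]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C", "D"],
    )
    return ConcentrationMatrix(df)


@pytest.fixture
def small_cohort():
    """A seeded 200-subject two-FA cohort with a TAG-like biomarker."""
    rng = np.random.default_rng(42)
    n = 200
    z = rng.standard_normal((n, 3))
    x1 = 4.0 + 0.8 * z[:, 0]
    x2 = 8.0 + 2.0 * (0.7 * z[:, 0] + 0.3 * z[:, 1])
    y = 1.5 + 0.5 * (0.6 * z[:, 0] + 0.4 * z[:, 2])
    conc = ConcentrationMatrix(np.column_stack([x1, x2]).clip(min=0.01),
                               fatty_acid_names=["focal", "others"])
    lipids = BiomarkerTable(y[:, None], conc.subject_ids, ["TAG"])
    return conc, lipids
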