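"""Common result containers shared across the estimation modules.

Every estimator in the package — the one-sample 2SLS fit, the
multivariable-adjusted comparator, the summary-statistic sensitivity
suite and the split-sample meta-analysis — reports its answer as an
:class:`MREstimate`: an effect on the additive scale (a mean difference
for continuous outcomes, a risk difference for binary outcomes treated
as linear probability models), a robust standard error, a normal-theory
95% confidence interval and a two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

# normal 97.5% quantile used for all reported confidence intervals;
# analysed n is large throughout so t refinements are not applied
Z_95 = float(stats.norm.ppf(0.975))

#: column layout used when results are written out side by side
RESULT_COLUMNS = [
    "exposure", "outcome", "method", "n",
    "beta", "se", "ci_low", "ci_high", "p", "f_stat", "endogeneity_p",
]


@dataclass
class MREstimate:
    """An effect estimate with its uncertainty and provenance tag.

    ``beta`` is a mean difference (continuous outcome, outcome units) or a
    risk difference (binary outcome, absolute proportion). ``f_stat`` is the
    first-stage partial F and is only populated for instrumental-variable
    fits.
    """

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    method: str
    f_stat: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.se):
            raise ValueError(f"standard error must be positive, got {self.se}")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p}")

    @classmethod
    def from_beta_se(
        cls,
        beta: float,
        se: float,
        n: int,
        method: str,
        f_stat: Optional[float] = None,
        **extra,
    ) -> "MREstimate":
        """Build an estimate with normal CI and two-sided normal p-value."""
        beta = float(beta)
        se = float(se)
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        return cls(
            beta=beta,
            se=se,
            ci_low=beta - Z_95 * se,
            ci_high=beta + Z_95 * se,
            p=float(p),
            n=int(n),
            method=method,
            f_stat=f_stat,
            extra=dict(extra),
        )

    def rescaled(self, factor: float) -> "MREstimate":
        """Express the effect per ``1/factor`` exposure units.

        Used at reporting time for per-5-unit / per-SD display conventions;
        estimation is always done on the raw scale.
        """
        if factor == 0:
            raise ValueError("rescaling factor must be nonzero")
        lo, hi = sorted((self.ci_low * factor, self.ci_high * factor))
        return MREstimate(
            beta=self.beta * factor,
            se=self.se * abs(factor),
            ci_low=lo,
            ci_high=hi,
            p=self.p,
            n=self.n,
            method=self.method,
            f_stat=self.f_stat,
            extra=dict(self.extra),
        )

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("extra")
        return d


@dataclass
class EndogeneityResult:
    """Durbin–Wu–Hausman style comparison of IV and ordinary regression.

    A small p-value is evidence that the instrumented and
    multivariable-adjusted effects differ (confounding or reverse causation
    in the ordinary estimate, or failure of the instrument assumptions).
    """

    statistic: float
    p: float
    df: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p}")


@dataclass
class MetaResult:
    """Fixed-effect (inverse-variance) meta-analytic combination."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    method: str = "fixed-effect meta-analysis"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("meta-analytic SE must be positive")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")


def results_table(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble result rows into the standard side-by-side column layout."""
    df = pd.DataFrame(list(rows))
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[RESULT_COLUMNS]


def write_results_tsv(rows: Iterable[dict], path) -> pd.DataFrame:
    """Write result rows as tab-separated text; returns the frame written."""
    df = results_table(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
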