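"""Paired-difference Student's t analysis of two classifiers' accuracies.

Given accuracy vectors ``a`` and ``b`` over the same experiments, the
analysis forms the absolute paired differences, their mean ``mu`` and
sample standard deviation ``sigma`` (denominator N-1), and the one-sample
statistic

    t = sqrt(N) * mu / sigma,   dof = N - 1,

compared against the two-sided critical interval of the t distribution at
the requested level. ``round_intermediates`` optionally truncates ``mu``
and ``sigma`` toward zero at that many decimals before forming ``t``,
matching printed-table arithmetic where the intermediates appear at three
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class PairedAccuracies:
    """Accuracies (%) of two classifiers across named experiments."""

    labels: list[str]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if len(self.a) != len(self.b) or len(self.a) != len(self.labels):
            raise ValueError("labels, a and b must have equal lengths")
        if len(self.a) < 2:
            raise ValueError("need at least 2 paired experiments")


@dataclass
class TTestResult:
    diffs: np.ndarray
    mean: float
    sd: float
    t: float
    dof: int
    p_level: float
    interval: tuple[float, float]
    inside_interval: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "diffs": self.diffs.tolist(),
            "mean": self.mean,
            "sd": self.sd,
            "t": self.t,
            "dof": self.dof,
            "p_level": self.p_level,
            "interval": list(self.interval),
            "inside_interval": self.inside_interval,
            "degenerate": self.degenerate,
        }

    def summary(self) -> str:
        lo, hi = self.interval
        verdict = "inside" if self.inside_interval else "outside"
        return (
            f"paired |diff|: {np.round(self.diffs, 3).tolist()}\n"
            f"mean = {self.mean:.4f}, sd = {self.sd:.4f} (dof = {self.dof})\n"
            f"t = {self.t:.3f}; critical interval at p={self.p_level}: "
            f"({lo:.3f}, {hi:.3f}) -> t {verdict} the interval"
        )


def paired_ttest(pa: PairedAccuracies, p_level: float = 0.05,
                 round_intermediates: int | None = 3) -> TTestResult:
    """Absolute-paired-difference t-test; see module docstring.

    With all differences zero the statistic is defined as 0 and the result
    flagged degenerate instead of dividing by zero.
    """
    n = len(pa.a)
    diffs = np.abs(pa.a - pa.b)
    mu = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    crit = float(sps.t.ppf(1.0 - p_level / 2.0, df=n - 1))
    interval = (-crit, crit)
    if sd == 0.0:
        return TTestResult(diffs=diffs, mean=mu, sd=sd, t=0.0, dof=n - 1,
                           p_level=p_level, interval=interval,
                           inside_interval=True, degenerate=True)
    if round_intermediates is not None:
        # printed-table arithmetic truncates intermediates toward zero
        # (e.g. sd 0.5315 appears as 0.531, and t is formed from that)
        scale = 10.0 ** round_intermediates
        mu_t = float(np.trunc(mu * scale) / scale)
        sd_t = float(np.trunc(sd * scale) / scale)
    else:
        mu_t, sd_t = mu, sd
    t = float(np.sqrt(n) * mu_t / sd_t)
    return TTestResult(diffs=diffs, mean=mu, sd=sd, t=t, dof=n - 1,
                       p_level=p_level, interval=interval,
                       inside_interval=bool(interval[0] <= t <= interval[1]))
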