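"""Phage titer time courses: fold change and phenotype calls.

A plaque assay measures free-phage concentration (pfu/ml) at a handful of
times post-infection.  Expressed as fold change from the inoculum, the
shape of this series discriminates host mutants whose bacterial growth
curves are indistinguishable: a strain phage cannot adsorb to keeps the
titer flat, one that adsorbs but produces no progeny drains it, and a
productive host amplifies it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: default post-infection sampling schedule (minutes).
DEFAULT_SAMPLE_TIMES_MIN = (90.0, 173.0, 205.0, 236.0, 276.0, 322.0, 364.0, 415.0)


class TiterError(ValueError):
    pass


@dataclass
class PhageTimecourse:
    """Titer series for one strain: minutes post-infection vs pfu/ml.

    When raw plaque counts are given, ``pfu_ml`` must equal
    count * dilution / plated volume (ml).
    """

    strain_id: str
    t_min: np.ndarray
    pfu_ml: np.ndarray
    counts: np.ndarray | None = None
    dilutions: np.ndarray | None = None
    plated_vol_ml: float = 0.1

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.pfu_ml = np.asarray(self.pfu_ml, dtype=float)
        if len(self.t_min) != len(self.pfu_ml):
            raise TiterError("t_min and pfu_ml must have equal length")
        if np.any(np.diff(self.t_min) <= 0):
            raise TiterError("t_min must be strictly increasing")
        if np.any(self.pfu_ml < 0):
            raise TiterError("pfu/ml must be >= 0")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            self.dilutions = np.asarray(self.dilutions, dtype=float)
            implied = self.counts * self.dilutions / self.plated_vol_ml
            if not np.allclose(implied, self.pfu_ml, rtol=1e-6, atol=1e-9):
                raise TiterError("pfu_ml inconsistent with count * dilution / volume")


def fold_change(tc: PhageTimecourse) -> np.ndarray:
    """Titer relative to the first sample: pfu(t) / pfu(t0)."""
    if tc.pfu_ml[0] <= 0:
        raise TiterError(f"zero initial titer for strain {tc.strain_id!r}")
    return tc.pfu_ml / tc.pfu_ml[0]


def titer_phenotype(tc: PhageTimecourse, alpha: float = 0.05) -> str:
    """Call a titer series stable / declining / amplifying.

    Ordinary least squares of log10 titer on time; the call follows the
    (1 - alpha) confidence interval of the slope: containing zero means
    stable, entirely negative declining, entirely positive amplifying.
    Zero-titer points (plates with no plaques) are dropped before the fit.
    """
    if len(tc.t_min) < 4:
        raise TiterError("phenotype call needs at least 4 time points")
    keep = tc.pfu_ml > 0
    t = tc.t_min[keep]
    y = np.log10(tc.pfu_ml[keep])
    if len(t) < 4:
        raise TiterError(
            f"too few nonzero titers for strain {tc.strain_id!r}"
        )
    if np.allclose(y, y[0]):
        return "stable"
    res = stats.linregress(t, y)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, len(t) - 2)
    lo = res.slope - tcrit * res.stderr
    hi = res.slope + tcrit * res.stderr
    if lo > 0:
        return "amplifying"
    if hi < 0:
        return "declining"
    return "stable"
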