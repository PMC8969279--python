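"""Validation arithmetic for RIDD-target follow-up experiments.

Covers the downstream quantitative steps used to confirm discovered targets:

* 2^-dCt relative qPCR expression against an endogenous control (GAPDH-style);
* ER-stress decay calls with IRE1-inhibitor (4u8c) rescue: a target is
  IRE1-dependent when the inducer significantly lowers its mRNA and the
  inhibitor restores it;
* protein half-life from ln-linear fits to densitometry time courses;
* Chou-Talalay median-effect fits and combination indices for drug-pair
  synergy (CI < 1 = synergy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "QpcrSample",
    "DecayCall",
    "MedianEffectFit",
    "relative_expression",
    "decay_call",
    "half_life",
    "fit_median_effect",
    "combination_index",
    "fraction_affected",
]

log = logging.getLogger(__name__)


@dataclass
class QpcrSample:
    """Paired target/reference Ct replicates for one condition."""

    target_ct: np.ndarray
    reference_ct: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.target_ct = np.asarray(self.target_ct, dtype=float)
        self.reference_ct = np.asarray(self.reference_ct, dtype=float)
        if self.target_ct.shape != self.reference_ct.shape:
            raise ValueError("target and reference Ct replicates must be paired")
        if not (np.isfinite(self.target_ct).all() and np.isfinite(self.reference_ct).all()):
            raise ValueError("Ct values must be finite")
        if (self.target_ct <= 0).any() or (self.reference_ct <= 0).any():
            raise ValueError("Ct values must be positive")

    @property
    def delta_ct(self) -> np.ndarray:
        return self.target_ct - self.reference_ct


@dataclass
class DecayCall:
    gene: str
    inducer: str
    expr_control: float
    expr_treated: float
    expr_treated_plus_4u8c: float
    p_decay: float
    p_rescue: float
    ire1_dependent: bool
    testable: bool = True


@dataclass
class MedianEffectFit:
    """Median-effect equation fa/fu = (D/Dm)^m fitted per drug."""

    m: float
    Dm: float
    r2: float

    def dx(self, fa: float) -> float:
        """Dose of this drug alone producing affected fraction *fa*."""
        if not 0 < fa < 1:
            raise ValueError("fa must be strictly inside (0, 1)")
        return self.Dm * (fa / (1 - fa)) ** (1.0 / self.m)


def relative_expression(sample: QpcrSample) -> tuple[float, float]:
    """Mean and SD of per-replicate 2^-dCt relative expression."""
    expr = 2.0 ** (-sample.delta_ct)
    return float(np.mean(expr)), float(np.std(expr, ddof=1)) if len(expr) > 1 else 0.0


def decay_call(
    gene: str,
    inducer: str,
    control: QpcrSample,
    treated: QpcrSample,
    treated_plus_4u8c: QpcrSample,
    alpha: float = 0.05,
    rescue_fraction: float = 0.75,
) -> DecayCall:
    """Call IRE1-dependent decay from control / inducer / inducer+4u8c qPCR.

    Decay: two-sided Welch t-test on replicate dCt, inducer vs control, with
    a lower treated mean expression.  Rescue: the +4u8c condition is either
    not significantly below control (p >= alpha) or recovers at least
    *rescue_fraction* of control expression — partial rescue by the
    inhibitor counts.
    """
    if min(len(control.delta_ct), len(treated.delta_ct), len(treated_plus_4u8c.delta_ct)) < 2:
        return DecayCall(gene, inducer, np.nan, np.nan, np.nan, np.nan, np.nan, False, testable=False)
    e_ctrl, _ = relative_expression(control)
    e_trt, _ = relative_expression(treated)
    e_resc, _ = relative_expression(treated_plus_4u8c)
    p_decay = float(
        stats.ttest_ind(treated.delta_ct, control.delta_ct, equal_var=False).pvalue
    )
    p_rescue = float(
        stats.ttest_ind(treated_plus_4u8c.delta_ct, control.delta_ct, equal_var=False).pvalue
    )
    decayed = p_decay < alpha and e_trt < e_ctrl
    rescued = (p_rescue >= alpha) or (e_resc >= rescue_fraction * e_ctrl)
    # a "rescue" identical to the decayed state is no rescue at all
    if decayed and e_resc <= e_trt and p_rescue < alpha:
        rescued = False
    return DecayCall(gene, inducer, e_ctrl, e_trt, e_resc, p_decay, p_rescue, decayed and rescued)


def half_life(times: np.ndarray, levels: np.ndarray) -> float:
    """Protein half-life (hours) from an ln-linear decay fit.

    Levels are normalised to the t=0 value; the fit is least squares of
    ln(level) on time, t1/2 = ln 2 / k.  A non-decaying series returns inf.
    """
    times = np.asarray(times, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if len(times) < 2 or len(times) != len(levels):
        raise ValueError("need >= 2 paired time points")
    if (levels <= 0).any():
        raise ValueError("densitometry levels must be positive")
    order = np.argsort(times)
    times, levels = times[order], levels[order]
    levels = levels / levels[0]
    slope, _ = np.polyfit(times, np.log(levels), 1)
    k = -slope
    if k <= 0:
        return float("inf")
    return float(np.log(2) / k)


def fraction_affected(viability: np.ndarray, v_control: float) -> np.ndarray:
    """Affected fraction from raw viability readings: fa = 1 - V / V_control."""
    return 1.0 - np.asarray(viability, dtype=float) / v_control


def fit_median_effect(doses: np.ndarray, fa: np.ndarray) -> MedianEffectFit:
    """Fit the median-effect line log(fa/fu) = m log D - m log Dm by OLS.

    Points with fa outside (0, 1) are dropped with a warning (they carry no
    information on the logit scale); at least two usable doses are required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    keep = (fa > 0) & (fa < 1) & (doses > 0)
    if keep.sum() < len(fa):
        log.warning("dropping %d boundary/invalid dose points", int(len(fa) - keep.sum()))
    if keep.sum() < 2:
        raise ValueError("need >= 2 doses with 0 < fa < 1 to fit the median-effect line")
    x = np.log10(doses[keep])
    y = np.log10(fa[keep] / (1 - fa[keep]))
    res = stats.linregress(x, y)
    m = float(res.slope)
    Dm = float(10 ** (-res.intercept / m))
    return MedianEffectFit(m=m, Dm=Dm, r2=float(res.rvalue**2))


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    d1: float,
    d2: float,
    fa_combo: float,
    mutually_exclusive: bool = True,
) -> float:
    """Chou-Talalay combination index at an observed combination effect.

    CI = d1/Dx1 + d2/Dx2 where Dx_i is the single-agent dose of drug i that
    alone yields *fa_combo*; the mutually nonexclusive form adds
    d1*d2/(Dx1*Dx2).  CI < 1 indicates synergy, CI = 1 additivity.
    """
    if not 0 < fa_combo < 1:
        raise ValueError("fa_combo must be strictly inside (0, 1)")
    dx1 = fit1.dx(fa_combo)
    dx2 = fit2.dx(fa_combo)
    ci = d1 / dx1 + d2 / dx2
    if not mutually_exclusive:
        ci += (d1 * d2) / (dx1 * dx2)
    return float(ci)
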