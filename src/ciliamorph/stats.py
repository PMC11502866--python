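"""Expansion-microscopy calibration and group statistics.

U-ExM physically swells a specimen in a hydrogel; image measurements are
made at the expanded scale and converted back through an expansion factor
calibrated against a biological ruler -- the proximal basal-body width,
225 nm across species.  Isotropy of the expansion is validated by comparing
pre-expansion measurements with expansion-factor-corrected post-expansion
measurements (nucleus cross-sectional area, centriole dimensions) using an
unpaired two-tailed t-test.

Group comparisons are computable from raw values or directly from printed
(mean, SD, n) summaries.  The default t-test variant is Student's pooled
test, which reproduces the published islet-cilia length p-values from the
printed summaries; Welch's test is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GroupSummary, TTestResult

#: Proximal basal-body (centriole) width used as the biological ruler, nm.
RULER_REFERENCE_NM = 225.0


@dataclass
class ExpansionCalibration:
    measured_width_nm: float
    reference_nm: float
    factor: float


def expansion_factor(
    measured_width_nm: float, reference_nm: float = RULER_REFERENCE_NM
) -> ExpansionCalibration:
    """Expansion factor from the measured (true-scale) ruler width.

    factor = measured / reference; e.g. a 968 nm measured basal-body width
    against the 225 nm ruler gives a factor of ~4.3.
    """
    if measured_width_nm <= 0 or reference_nm <= 0:
        raise ValueError("widths must be > 0")
    return ExpansionCalibration(
        measured_width_nm=float(measured_width_nm),
        reference_nm=float(reference_nm),
        factor=float(measured_width_nm) / float(reference_nm),
    )


def fwhm(profile: np.ndarray, sample_spacing: float = 1.0) -> float:
    """Full width at half maximum of a 1-D intensity profile.

    Baseline is the global profile minimum; the half level is
    baseline + (max - baseline)/2; the width is the distance between the
    two half-level crossings adjacent to the peak, located by linear
    interpolation.  Raises if either crossing is missing ("peak not
    resolved").
    """
    y = np.asarray(profile, dtype=float)
    if y.size < 3:
        raise ValueError("profile too short")
    baseline = float(y.min())
    peak_val = float(y.max())
    if peak_val == baseline:
        raise ValueError("peak not resolved: flat profile")
    half = baseline + (peak_val - baseline) / 2.0
    ipk = int(np.argmax(y))

    def cross(idx_range, forward: bool) -> float:
        prev = ipk
        for i in idx_range:
            if y[i] <= half:
                # linear interpolation between i and prev
                frac = (half - y[i]) / (y[prev] - y[i])
                return i + frac * (prev - i)
            prev = i
        raise ValueError("peak not resolved: no half-level crossing")

    left = cross(range(ipk - 1, -1, -1), forward=False)
    right = cross(range(ipk + 1, y.size), forward=True)
    return float((right - left) * sample_spacing)


def corrected_ncs(nucleus_area: float | np.ndarray, factor: float) -> float | np.ndarray:
    """Expansion-corrected nucleus cross-sectional size: sqrt(area)/factor.

    Exactly invariant under (area -> f^2 * area, factor -> f * factor).
    """
    if factor <= 0:
        raise ValueError("expansion factor must be > 0")
    area = np.asarray(nucleus_area, dtype=float)
    if np.any(area < 0):
        raise ValueError("area must be >= 0")
    out = np.sqrt(area) / factor
    return float(out) if out.ndim == 0 else out


def t_test_summary(
    g1: GroupSummary, g2: GroupSummary, method: str = "student_pooled"
) -> TTestResult:
    """Unpaired two-tailed t-test from (mean, SD, n) summaries.

    ``student_pooled`` uses the pooled variance with df = n1+n2-2;
    ``welch`` uses Satterthwaite df.  Both SDs zero with equal means is a
    degenerate case reported as t=0, p=1 with a flag.
    """
    if g1.n < 2 or g2.n < 2:
        raise ValueError("t-test needs n >= 2 per group")
    m1, s1, n1 = g1.mean, g1.sd, g1.n
    m2, s2, n2 = g2.mean, g2.sd, g2.n
    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            return TTestResult(t=0.0, df=float(n1 + n2 - 2), p=1.0, method=method, degenerate=True)
        return TTestResult(
            t=float(np.inf) if m1 > m2 else float(-np.inf),
            df=float(n1 + n2 - 2),
            p=0.0,
            method=method,
            degenerate=True,
        )
    if method == "student_pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif method == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p), method=method)


def t_test_raw(
    values1: np.ndarray, values2: np.ndarray, method: str = "student_pooled",
    labels: tuple[str, str] = ("group1", "group2"),
) -> TTestResult:
    """Same test computed from raw samples (summarizes then delegates)."""
    v1 = np.asarray(values1, float)
    v2 = np.asarray(values2, float)
    g1 = GroupSummary(labels[0], float(v1.mean()), float(v1.std(ddof=1)), len(v1))
    g2 = GroupSummary(labels[1], float(v2.mean()), float(v2.std(ddof=1)), len(v2))
    return t_test_summary(g1, g2, method=method)


def ciliation_summary(
    counts: pd.DataFrame, ciliated_col: str = "ciliated", total_col: str = "total"
) -> tuple[float, float, pd.Series]:
    """Percent ciliation per islet, then mean +/- sample SD across islets.

    ``counts`` has one row per islet with ciliated/total cell counts.
    Zero-total islets are excluded with a warning.
    """
    df = counts.copy()
    bad = df[df[total_col] <= 0]
    if len(bad):
        warnings.warn(f"excluding {len(bad)} islet(s) with zero total cells")
        df = df[df[total_col] > 0]
    if df.empty:
        raise ValueError("no islets with positive totals")
    percent = 100.0 * df[ciliated_col] / df[total_col]
    if len(percent) == 1:
        warnings.warn("single islet; SD undefined, reported as 0")
        return float(percent.iloc[0]), 0.0, percent
    return float(percent.mean()), float(percent.std(ddof=1)), percent


def isotropy_report(
    pre: np.ndarray,
    post: np.ndarray,
    factor: float,
    quantity: str = "area",
    alpha: float = 0.05,
    method: str = "student_pooled",
) -> dict:
    """Compare pre-expansion values with corrected post-expansion values.

    ``quantity="area"`` applies the NCS correction sqrt(area)/factor to the
    post values and sqrt() to the pre values (both become linear sizes);
    ``quantity="linear"`` divides post values by the factor.  Returns the
    corrected group summaries, the t-test, and the isotropy decision at
    ``alpha`` (isotropic = fail to reject equality).
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if quantity == "area":
        pre_c = np.sqrt(pre)
        post_c = corrected_ncs(post, factor)
    elif quantity == "linear":
        pre_c = pre
        post_c = post / factor
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    g_pre = GroupSummary("pre", float(pre_c.mean()), float(pre_c.std(ddof=1)), len(pre_c))
    g_post = GroupSummary(
        "post_corrected", float(post_c.mean()), float(post_c.std(ddof=1)), len(post_c)
    )
    res = t_test_summary(g_pre, g_post, method=method)
    return {
        "pre": g_pre,
        "post_corrected": g_post,
        "ttest": res,
        "isotropic": res.p > alpha,
        "alpha": alpha,
    }


def simulate_isotropy_experiment(
    factor: float = 4.2,
    noise: float = 0.03,
    n_pre: int = 25,
    n_post: int = 25,
    anisotropy: float = 0.0,
    true_size: float = 7000.0,
    quantity: str = "area",
    seed: int = 0,
) -> dict:
    """Simulate one pre/post expansion measurement experiment.

    Pre-expansion measurements carry multiplicative Gaussian noise of
    relative scale ``noise`` on the true linear size; post-expansion
    measurements are additionally scaled by ``factor`` (and, for
    ``quantity="linear"``, by ``1 + anisotropy`` to model one axis
    stretching more than the ruler-calibrated factor).  Areas are the
    product of two measured orthogonal extents, one of which carries the
    anisotropic stretch.
    """
    rng = np.random.default_rng(seed)
    pre_lin = true_size * (1.0 + noise * rng.standard_normal(n_pre))
    if quantity == "area":
        pre = pre_lin * true_size * (1.0 + noise * rng.standard_normal(n_pre))
        post_x = true_size * factor * (1.0 + anisotropy) * (
            1.0 + noise * rng.standard_normal(n_post)
        )
        post_y = true_size * factor * (1.0 + noise * rng.standard_normal(n_post))
        post = post_x * post_y
    elif quantity == "linear":
        pre = pre_lin
        post = (
            true_size
            * factor
            * (1.0 + anisotropy)
            * (1.0 + noise * rng.standard_normal(n_post))
        )
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return isotropy_report(pre, post, factor, quantity=quantity)
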