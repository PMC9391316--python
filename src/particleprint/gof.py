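"""Goodness-of-fit testing of embedding populations against a null fingerprint.

To ask "could this particle population have been drawn from that reference
fingerprint?", the 2D embedding points are pushed through the Rosenblatt
transform of the null density: under the null hypothesis the transformed
coordinates are independent uniforms on the unit square, so a one-sample
Kolmogorov-Smirnov test against U(0, 1) applies.

Because a single test on tens of thousands of points over-rejects on
practically irrelevant differences, the test-set points are shuffled
without replacement into disjoint subsets of ``N_test`` (default 100)
points, the KS test is run per subset, and the *fraction of rejected
subsets* is reported.  A fraction near the significance level alpha means
statistical consistency with the null; a fraction near 1 means clear
inconsistency.

The Rosenblatt transform of a Gaussian-mixture null with shared bandwidth
H is closed-form (no numerical integration):

    u1 = F1(x1)        = (1/N) sum_i Phi((x1 - p_i1) / sqrt(H11))
    u2 = F2|1(x2 | x1) = sum_i w_i(x1) Phi((x2 - mu_i(x1)) / sigma_c)

with responsibilities ``w_i(x1) ~ N(x1; p_i1, H11)``, conditional means
``mu_i(x1) = p_i2 + (H21 / H11)(x1 - p_i1)`` and conditional standard
deviation ``sigma_c = sqrt(H22 - H21^2 / H11)``.  The factorization order
(x1 first, then x2 given x1) follows the embedding axis order and is
recorded in the result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .fingerprint import Fingerprint

__all__ = [
    "GofResult",
    "rosenblatt",
    "ks_uniform",
    "subset_rejection_rate",
]


@dataclass
class GofResult:
    """Subset-wise KS outcomes against a null fingerprint."""

    null_label: str
    test_label: str
    n_test: int
    alpha: float
    subset_count: int
    statistics: np.ndarray
    p_values: np.ndarray
    rejection_fraction: float
    seed: int
    variant: str = "pooled"
    coordinate_order: str = "x1_then_x2_given_x1"

    def __post_init__(self) -> None:
        self.statistics = np.asarray(self.statistics, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.statistics) != self.subset_count:
            raise ValueError("one KS statistic per subset required")
        expected = float(np.mean(self.p_values < self.alpha)) if self.subset_count else 0.0
        if abs(expected - self.rejection_fraction) > 1e-12:
            raise ValueError("rejection_fraction inconsistent with p-values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subset_id": np.arange(self.subset_count),
            "D": self.statistics,
            "p": self.p_values,
            "reject": self.p_values < self.alpha,
        })

    def to_json(self, path: Path | str | None = None) -> str:
        obj = {
            "null_label": self.null_label,
            "test_label": self.test_label,
            "n_test": int(self.n_test),
            "alpha": float(self.alpha),
            "subset_count": int(self.subset_count),
            "rejection_fraction": float(self.rejection_fraction),
            "seed": int(self.seed),
            "variant": self.variant,
            "coordinate_order": self.coordinate_order,
            "statistics": self.statistics.tolist(),
            "p_values": self.p_values.tolist(),
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Path | str) -> "GofResult":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        obj = json.loads(text)
        return cls(
            null_label=obj["null_label"], test_label=obj["test_label"],
            n_test=int(obj["n_test"]), alpha=float(obj["alpha"]),
            subset_count=int(obj["subset_count"]),
            statistics=np.array(obj["statistics"], dtype=float),
            p_values=np.array(obj["p_values"], dtype=float),
            rejection_fraction=float(obj["rejection_fraction"]),
            seed=int(obj["seed"]), variant=obj.get("variant", "pooled"),
            coordinate_order=obj.get("coordinate_order", "x1_then_x2_given_x1"),
        )


def rosenblatt(null_fp: Fingerprint, points: np.ndarray) -> np.ndarray:
    """Closed-form Rosenblatt transform under a Gaussian-mixture null.

    Maps (M, 2) points to (M, 2) coordinates in [0, 1]^2 that are i.i.d.
    uniform when the points are drawn from ``null_fp``'s mixture density.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("points must be an (M, 2) array")
    H = null_fp.H
    h11, h12, h22 = H[0, 0], H[0, 1], H[1, 1]
    sig2_c = h22 - h12 * h12 / h11
    if h11 <= 0 or sig2_c <= 0:
        raise ValueError("null fingerprint bandwidth matrix is not positive definite")
    s1 = np.sqrt(h11)
    sc = np.sqrt(sig2_c)
    p1 = null_fp.points[:, 0]
    p2 = null_fp.points[:, 1]

    out = np.empty_like(x)
    chunk = max(1, int(4e6 // max(null_fp.n, 1)))
    for s in range(0, len(x), chunk):
        x1 = x[s:s + chunk, 0][:, None]
        x2 = x[s:s + chunk, 1][:, None]
        z1 = (x1 - p1[None, :]) / s1                      # (m, N)
        out[s:s + chunk, 0] = special.ndtr(z1).mean(axis=1)
        logw = -0.5 * z1 * z1
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        w /= w.sum(axis=1, keepdims=True)
        mu = p2[None, :] + (h12 / h11) * (x1 - p1[None, :])
        out[s:s + chunk, 1] = (w * special.ndtr((x2 - mu) / sc)).sum(axis=1)
    np.clip(out, 0.0, 1.0, out=out)   # guard rounding just past the ends
    return out


def ks_uniform(u: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of ``u`` against U(0, 1).

    D is the exact sup-difference between the empirical CDF and the
    identity (both one-sided gaps evaluated at every jump); the p-value is
    scipy's standard exact/asymptotic evaluation.
    """
    u = np.asarray(u, dtype=float).ravel()
    if u.size == 0:
        raise ValueError("empty sample")
    if np.any((u < 0) | (u > 1)):
        raise ValueError("values must lie in [0, 1]")
    res = stats.kstest(u, stats.uniform.cdf)
    return float(res.statistic), float(res.pvalue)


def subset_rejection_rate(
    null_fp: Fingerprint,
    test_points: np.ndarray,
    n_test: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    variant: str = "pooled",
    null_label: str | None = None,
    test_label: str = "",
) -> GofResult:
    """Fraction of size-``n_test`` subsets rejected by the Rosenblatt/KS test.

    The test points are shuffled without replacement (seeded) and cut into
    ``floor(M / n_test)`` disjoint subsets; any remainder is dropped.  Per
    subset, variant ``"pooled"`` pools the 2 * n_test transformed
    coordinates into one KS test (valid since the two coordinates are
    independent uniforms under the null); variant ``"bonferroni"`` tests
    each coordinate separately and rejects if either p < alpha / 2.
    """
    pts = np.asarray(test_points, dtype=float)
    m = len(pts)
    if m < n_test:
        raise ValueError(f"need at least n_test={n_test} test points, got {m}")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if variant not in ("pooled", "bonferroni"):
        raise ValueError(f"unknown variant {variant!r}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    n_sub = m // n_test
    u = rosenblatt(null_fp, pts[order[: n_sub * n_test]])

    stats_, pvals = np.empty(n_sub), np.empty(n_sub)
    for k in range(n_sub):
        uk = u[k * n_test:(k + 1) * n_test]
        if variant == "pooled":
            d, p = ks_uniform(uk.ravel())
        else:
            d1, p1 = ks_uniform(uk[:, 0])
            d2, p2 = ks_uniform(uk[:, 1])
            # Bonferroni: reject if min p < alpha/2 <=> 2*min p < alpha
            d, p = max(d1, d2), min(1.0, 2.0 * min(p1, p2))
        stats_[k], pvals[k] = d, p

    return GofResult(
        null_label=null_label if null_label is not None else null_fp.label,
        test_label=test_label,
        n_test=int(n_test), alpha=float(alpha), subset_count=int(n_sub),
        statistics=stats_, p_values=pvals,
        rejection_fraction=float(np.mean(pvals < alpha)),
        seed=int(seed), variant=variant,
    )
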