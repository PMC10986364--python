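"""Nonlinear per-channel features: Higuchi fractal dimension and three
template-matching entropies (approximate, sample, fuzzy).

Conventions, pinned so the independent brute-force oracles can mirror them:

* HFD: curve lengths L(k) per Higuchi's normalization; the dimension is the
  least-squares slope of ln L(k) versus ln(1/k) over k = 1..kmax. A straight
  line gives exactly 1, white noise about 2.
* ApEn: Chebyshev distances, matches counted with d <= r *including* the
  self-match; phi(m,r) is the mean log match fraction over the N-m+1
  templates; ApEn = phi(m) - phi(m+1).
* SampEn: strict d < r, self-matches excluded; B^m averages the per-template
  match fraction (count / (N-m)) over the N-m+1 templates of dimension m;
  SampEn = -ln(B^{m+1}/B^m).
* FuzzyEn: templates are mean-removed; similarity exp(-d^n / r); Phi^m is
  the mean pairwise similarity; FuzzyEn = ln Phi^m - ln Phi^{m+1}.

The similarity radius r is ``r_frac`` times the standard deviation of the
series, which makes SampEn/ApEn invariant to affine rescaling and FuzzyEn
additionally exactly invariant to offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("HFD", "ApEn", "SampEn", "FuzzyEn")


@dataclass(frozen=True)
class FeatureParams:
    """Estimator hyperparameters (standard literature defaults)."""

    kmax: int = 10
    m: int = 2
    r_frac: float = 0.2
    fuzzy_n: float = 2.0

    def __post_init__(self):
        if self.kmax < 2:
            raise ValueError("kmax must be >= 2")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("r_frac must be positive")
        if self.fuzzy_n <= 0:
            raise ValueError("fuzzy_n must be positive")


@dataclass
class FeatureBlock:
    """Per-window, per-step, per-channel feature values.

    ``values`` has shape (windows, steps, features, channels).
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    channel_names: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_names = tuple(self.feature_names)
        self.channel_names = tuple(self.channel_names)
        if self.values.ndim != 4:
            raise ValueError("values must be 4-D (windows, steps, features, channels)")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.values.shape[2] != len(self.feature_names):
            raise ValueError("feature axis size mismatch")
        if self.values.shape[3] != len(self.channel_names):
            raise ValueError("channel axis size mismatch")

    def select(self, names: list[str] | tuple[str, ...]) -> "FeatureBlock":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureBlock(self.values[:, :, idx, :], tuple(names), self.channel_names)

    def to_tidy_frame(self) -> pd.DataFrame:
        w, s, f, c = self.values.shape
        wi, si, fi, ci = np.unravel_index(np.arange(w * s * f * c), (w, s, f, c))
        return pd.DataFrame({
            "window_id": wi,
            "step": si,
            "channel": np.asarray(self.channel_names, dtype=object)[ci],
            "feature": np.asarray(self.feature_names, dtype=object)[fi],
            "value": self.values.ravel(),
        })


def higuchi_fd(x, kmax: int = 10) -> float:
    """Higuchi fractal dimension of a 1-D series."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if n <= kmax:
        raise ValueError(f"series length {n} must exceed kmax={kmax}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate series: constant input has no curve length")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lm_sum = 0.0
        for m in range(1, k + 1):
            idx = np.arange(m - 1, n, k)  # 0-based positions of x_m^k
            n_seg = idx.size - 1
            if n_seg < 1:
                raise ValueError(f"series too short for kmax={kmax}")
            seg = np.abs(np.diff(x[idx])).sum()
            lm_sum += seg * (n - 1) / (n_seg * k) / k
        lk[k - 1] = lm_sum / k
    if np.any(lk <= 0):
        raise ValueError("degenerate series: zero curve length")
    k_arr = np.arange(1, kmax + 1, dtype=np.float64)
    slope = np.polyfit(np.log(1.0 / k_arr), np.log(lk), 1)[0]
    return float(slope)


def _prep_series(x, m: int, r_frac: float):
    x = np.asarray(x, dtype=np.float64)
    if x.size < m + 2:
        raise ValueError(f"series length {x.size} too short for m={m}")
    sd = float(x.std())
    return x, sd, r_frac * sd


def approximate_entropy(x, m: int = 2, r_frac: float = 0.2) -> float:
    """ApEn(m, r) with r = r_frac * SD(x); 0 for a constant series."""
    x, sd, r = _prep_series(x, m, r_frac)
    if sd == 0:
        return 0.0
    le_m, le_m1, _, _ = _kernels.cheb_pair_counts(x, m, r)
    phi_m = float(np.mean(np.log((le_m + 1.0) / le_m.size)))  # +1: self-match
    phi_m1 = float(np.mean(np.log((le_m1 + 1.0) / le_m1.size)))
    return phi_m - phi_m1


def sample_entropy(x, m: int = 2, r_frac: float = 0.2) -> float:
    """SampEn(m, r), self-matches excluded; 0 for a constant series."""
    x, sd, r = _prep_series(x, m, r_frac)
    if sd == 0:
        return 0.0
    _, _, lt_m, lt_m1 = _kernels.cheb_pair_counts(x, m, r)
    n = x.size
    b_m = float(np.mean(lt_m / (n - m)))
    b_m1 = float(np.mean(lt_m1 / (n - m - 1)))
    if b_m == 0 or b_m1 == 0:
        raise ValueError("sample entropy undefined (no matches)")
    return float(-np.log(b_m1 / b_m))


def fuzzy_entropy(x, m: int = 2, r_frac: float = 0.2, n: float = 2.0) -> float:
    """FuzzyEn(m, r, n) with Gaussian similarity exp(-d^n / r)."""
    x_arr, sd, r = _prep_series(x, m, r_frac)
    if sd == 0:
        return 0.0
    phi_m = _kernels.fuzzy_phi(x_arr, m, r, n)
    phi_m1 = _kernels.fuzzy_phi(x_arr, m + 1, r, n)
    return float(np.log(phi_m) - np.log(phi_m1))


_DISPATCH = {
    "HFD": lambda x, p: higuchi_fd(x, p.kmax),
    "ApEn": lambda x, p: approximate_entropy(x, p.m, p.r_frac),
    "SampEn": lambda x, p: sample_entropy(x, p.m, p.r_frac),
    "FuzzyEn": lambda x, p: fuzzy_entropy(x, p.m, p.r_frac, p.fuzzy_n),
}


def extract_feature_block(
    steps: np.ndarray,
    params: FeatureParams = FeatureParams(),
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    channel_names: tuple[str, ...] = (),
) -> FeatureBlock:
    """Compute features per channel per step.

    ``steps`` is the (windows, steps, channels, samples) view produced by
    ``preprocess.split_steps``. Individual estimator failures (degenerate
    series) are recorded as 0 with a logged warning rather than aborting.
    """
    if len(feature_names) == 0:
        raise ValueError("at least one feature must be requested")
    unknown = set(feature_names) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    w, s, c, _ = steps.shape
    if not channel_names:
        channel_names = tuple(f"ch{i}" for i in range(c))
    values = np.zeros((w, s, len(feature_names), c))
    n_failures = 0
    for wi in range(w):
        for si in range(s):
            for ci in range(c):
                series = steps[wi, si, ci]
                for fi, name in enumerate(feature_names):
                    try:
                        values[wi, si, fi, ci] = _DISPATCH[name](series, params)
                    except ValueError as exc:
                        n_failures += 1
                        logger.warning(
                            "feature %s failed on window %d step %d channel %s: %s"
                            " (recorded as 0)", name, wi, si, channel_names[ci], exc,
                        )
    if n_failures:
        logger.warning("%d feature evaluations failed and were recorded as 0",
                       n_failures)
    return FeatureBlock(values, tuple(feature_names), tuple(channel_names))
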