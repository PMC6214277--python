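"""Phase Transfer Entropy (PTE) estimation from instantaneous-phase time series.

The pairwise estimator works on phases binned into equal-width histogram bins
over (-pi, pi].  ``pte_pair(x, y, h)`` quantifies the improvement in
predicting x's phase h samples ahead when y's current phase is known in
addition to x's own:

    sum Pr[x_{t+h}, x_t, y_t] * log( Pr[x_{t+h} | x_t, y_t] / Pr[x_{t+h} | x_t] )

with all probabilities taken from joint histograms over one epoch.  The
matrix-level convention is that entry (i, j) measures flow *from* region i
*to* region j, i.e. ``values[i, j] = pte_pair(x=series_j, y=series_i)``, so
that a driver region has the larger entry in its row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .utils import TWO_PI, round_half_away, wrap_phase

__all__ = [
    "PTEMatrix",
    "DelayEstimate",
    "default_n_bins",
    "phase_bins",
    "count_sign_changes",
    "delay_from_counts",
    "estimate_delay",
    "pte_pair",
    "pte_matrix",
    "dpte",
]


@dataclass
class PTEMatrix:
    """N x N nonnegative matrix of pairwise PTE values, zero diagonal.

    Entry (i, j) is the PTE from region i to region j; asymmetry is expected.
    """

    values: np.ndarray
    region_labels: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"PTE matrix must be square, got shape {v.shape}")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("PTE matrix diagonal must be exactly zero")
        if np.any(v < 0.0):
            raise ValueError("PTE values must be nonnegative")
        self.values = v
        if self.region_labels is None:
            self.region_labels = [f"R{i:02d}" for i in range(v.shape[0])]
        else:
            self.region_labels = list(self.region_labels)
            if len(self.region_labels) != v.shape[0]:
                raise ValueError("region_labels length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """All N*(N-1) off-diagonal entries as a flat array."""
        mask = ~np.eye(self.n, dtype=bool)
        return self.values[mask]


@dataclass
class DelayEstimate:
    """Data-driven prediction delay h = round(N_s * N_ROI / N_+-)."""

    h: int
    n_samples: int
    n_regions: int
    n_sign_changes: int
    per_epoch_h: list = field(default_factory=list)

    def __post_init__(self):
        if self.h < 1:
            raise ValueError("delay h must be >= 1")
        if self.n_sign_changes < 1:
            raise ValueError("sign-change count must be >= 1")


def default_n_bins(n_samples: int) -> int:
    """Default histogram bin count, round(exp(0.626 + 0.4*ln(N_s - 1)))."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    return max(2, round_half_away(math.exp(0.626 + 0.4 * math.log(n_samples - 1))))


def phase_bins(x, n_bins: int) -> np.ndarray:
    """Assign phases to equal-width bins over (-pi, pi] (wrapping first)."""
    x = wrap_phase(x)
    idx = np.floor((x + np.pi) * (n_bins / TWO_PI)).astype(np.int64)
    np.clip(idx, 0, n_bins - 1, out=idx)
    return idx


def count_sign_changes(epoch: np.ndarray) -> int:
    """Number of sign changes of consecutive phase values, summed over regions.

    ``epoch`` has shape (regions, samples).
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[1] < 2:
        raise ValueError("epoch must be (regions, samples) with >= 2 samples")
    s = np.sign(epoch)
    return int(np.count_nonzero(s[:, :-1] * s[:, 1:] < 0))


def delay_from_counts(n_samples: int, n_regions: int, n_sign_changes: int) -> int:
    """h = round(N_s * N_ROI / N_+-), half away from zero, clamped to >= 1."""
    if n_sign_changes < 1:
        raise ValueError(
            "degenerate input: no phase sign changes, delay is undefined"
        )
    return max(1, round_half_away(n_samples * n_regions / n_sign_changes))


def estimate_delay(ensemble) -> DelayEstimate:
    """Estimate the prediction delay from a phase ensemble.

    Returns the pooled estimate (sign changes summed over every subject-epoch
    unit) with the per-epoch h values recorded in ``per_epoch_h``; the matrix
    estimator applies the per-epoch values.
    """
    data = np.asarray(ensemble.data, dtype=float)
    if data.ndim != 4:
        raise ValueError("ensemble data must be (subjects, epochs, regions, samples)")
    n_sub, n_ep, n_reg, n_samp = data.shape
    if n_samp < 2:
        raise ValueError("need at least 2 samples per epoch")
    per_epoch = []
    total = 0
    for s in range(n_sub):
        for e in range(n_ep):
            n_pm = count_sign_changes(data[s, e])
            if n_pm == 0:
                raise ValueError(
                    f"degenerate input: subject {s} epoch {e} has constant-sign "
                    "phases (no sign changes)"
                )
            per_epoch.append(delay_from_counts(n_samp, n_reg, n_pm))
            total += n_pm
    h = delay_from_counts(n_sub * n_ep * n_samp, n_reg, total)
    return DelayEstimate(
        h=h,
        n_samples=n_samp,
        n_regions=n_reg,
        n_sign_changes=total,
        per_epoch_h=per_epoch,
    )


def _pte_binned(bx, by, h, n_bins, log_base=None) -> float:
    """PTE from pre-binned sequences; target is x's future."""
    b = int(n_bins)
    xf = bx[h:]
    xp = bx[:-h]
    yp = by[:-h]
    m = xf.size
    codes = (xf * b + xp) * b + yp
    uniq, c3 = np.unique(codes, return_counts=True)
    yp_u = uniq % b
    rest = uniq // b
    xp_u = rest % b
    xf_u = rest // b
    c_x = np.bincount(xp, minlength=b).astype(float)
    c_xy = np.bincount(xp * b + yp, minlength=b * b).astype(float)
    c_fx = np.bincount(xf * b + xp, minlength=b * b).astype(float)
    ratio = (c3 * c_x[xp_u]) / (c_xy[xp_u * b + yp_u] * c_fx[xf_u * b + xp_u])
    val = float(np.sum((c3 / m) * np.log(ratio)))
    if log_base is not None:
        val /= math.log(log_base)
    return max(val, 0.0)


def pte_pair(x, y, h: int, n_bins: int | None = None, log_base: float | None = None) -> float:
    """Phase transfer entropy toward x's future, conditioning on y's present.

    Nonnegative (clamped at 0 against floating error); zero-probability
    histogram cells contribute nothing.  Natural log by default.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("mismatched sequence lengths")
    if int(h) < 1:
        raise ValueError("delay h must be >= 1")
    if x.size <= h:
        raise ValueError("sequences must be longer than h")
    if n_bins is None:
        n_bins = default_n_bins(x.size)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    return _pte_binned(phase_bins(x, n_bins), phase_bins(y, n_bins), int(h), n_bins, log_base)


def pte_matrix(
    ensemble,
    n_bins: int | None = None,
    log_base: float | None = None,
    h: int | None = None,
) -> PTEMatrix:
    """Pairwise PTE averaged over every subject-epoch unit.

    Entry (i, j) is the flow from region i to region j.  The delay h is
    estimated per epoch from the sign-change rule unless overridden.
    """
    data = np.asarray(ensemble.data, dtype=float)
    if data.ndim != 4:
        raise ValueError("ensemble data must be (subjects, epochs, regions, samples)")
    n_sub, n_ep, n_reg, n_samp = data.shape
    if n_sub * n_ep < 1:
        raise ValueError("need at least one epoch")
    bins = n_bins if n_bins is not None else default_n_bins(n_samp)
    if bins < 2:
        raise ValueError("n_bins must be >= 2")
    acc = np.zeros((n_reg, n_reg), dtype=float)
    per_epoch_h = []
    for s in range(n_sub):
        for e in range(n_ep):
            epoch = data[s, e]
            if h is not None:
                h_e = int(h)
            else:
                h_e = delay_from_counts(n_samp, n_reg, count_sign_changes(epoch))
            per_epoch_h.append(h_e)
            binned = phase_bins(epoch, bins)
            for i in range(n_reg):
                for j in range(n_reg):
                    if i == j:
                        continue
                    # flow i -> j: predict j's future conditioning on i
                    acc[i, j] += _pte_binned(binned[j], binned[i], h_e, bins, log_base)
    n_units = n_sub * n_ep
    acc /= n_units
    np.fill_diagonal(acc, 0.0)
    labels = list(getattr(ensemble, "region_labels", None) or [f"R{i:02d}" for i in range(n_reg)])
    meta = {
        "n_bins": bins,
        "n_units": n_units,
        "per_epoch_h": per_epoch_h,
        "log_base": log_base,
    }
    return PTEMatrix(values=acc, region_labels=labels, meta=meta)


def dpte(pte: PTEMatrix) -> np.ndarray:
    """Directed PTE: dPTE_XY = PTE_XY / (PTE_XY + PTE_YX).

    Defined pairs satisfy dPTE_XY + dPTE_YX = 1; pairs with
    PTE_XY + PTE_YX = 0 (and the diagonal) are flagged as NaN.
    """
    v = pte.values
    s = v + v.T
    out = np.full_like(v, np.nan)
    mask = s > 0
    out[mask] = v[mask] / s[mask]
    np.fill_diagonal(out, np.nan)
    return out
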