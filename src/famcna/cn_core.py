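"""Copy-number profiling from SNP-array signal.

Pipeline order: per-marker log2 ratios against a normal reference baseline,
per-sample correction for GC content and fragment length, recursive binary
segmentation of each chromosome, and categorical state calls per segment
(loss / neutral / gain / amplification) from the copy-number estimate
``2 * 2**mean_log2_ratio`` with a normal band of 2 +/- 0.25 copies and
amplification above 6 copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError

STATE_LOSS = "loss"
STATE_NEUTRAL = "neutral"
STATE_GAIN = "gain"
STATE_AMPLIFICATION = "amplification"

NEUTRAL_LOW = 1.75
NEUTRAL_HIGH = 2.25
AMPLIFICATION_MIN = 6.0


@dataclass
class SegmentationParams:
    """Acceptance rule of the recursive binary segmentation.

    A candidate split is accepted iff its two-sided t-test p-value is below
    ``p_threshold``, both resulting segments hold at least ``min_markers``
    markers, and the absolute mean difference divided by the pooled
    within-segment SD is at least ``signal_noise_min``.
    """

    p_threshold: float = 1e-4
    min_markers: int = 20
    signal_noise_min: float = 0.45

    def validate(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if self.min_markers < 2:
            raise ConfigurationError("min_markers must be >= 2")
        if self.signal_noise_min < 0:
            raise ConfigurationError("signal_noise_min must be >= 0")


# ---------------------------------------------------------------------------
# log2 ratio and covariate correction
# ---------------------------------------------------------------------------

def compute_log2_ratio(sample_values: np.ndarray | pd.Series,
                       reference: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Per-marker ``log2(sample / median(reference))``.

    ``reference`` is markers x samples.  Markers whose reference median or
    sample value is non-positive are masked as NaN.
    """
    sample = np.asarray(sample_values, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[1] < 2:
        raise ConfigurationError("reference cohort must hold >= 2 samples")
    if ref.shape[0] != sample.shape[0]:
        raise ConfigurationError("sample and reference marker counts differ")
    baseline = np.median(ref, axis=1)
    out = np.full(sample.shape, np.nan)
    ok = (baseline > 0) & (sample > 0)
    out[ok] = np.log2(sample[ok] / baseline[ok])
    return out


def correct_covariates(log2_ratios: np.ndarray,
                       marker_map: pd.DataFrame) -> np.ndarray:
    """Regress out GC fraction and log fragment length, per sample.

    Fits an ordinary least-squares model of the log2 ratio on GC fraction and
    log(fragment length), subtracts the fitted component and re-adds the
    pre-fit mean, so only covariate-tracking variation is removed.  Constant
    covariates are skipped with a warning.  Accepts a vector (one sample) or a
    markers x samples matrix.
    """
    x = np.asarray(log2_ratios, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[0] != len(marker_map):
        raise ConfigurationError("log2 ratios and marker map length differ")

    cols = []
    for name, values in (
            ("gc_fraction", marker_map["gc_fraction"].to_numpy(dtype=float)),
            ("fragment_length",
             np.log(marker_map["fragment_length"].to_numpy(dtype=float)))):
        if np.ptp(values) == 0.0:
            warnings.warn(f"covariate {name} is constant; skipped",
                          stacklevel=2)
            continue
        cols.append(values)
    out = x.copy()
    if not cols:
        return out[:, 0] if squeeze else out
    design = np.column_stack([np.ones(x.shape[0])] + cols)

    for j in range(x.shape[1]):
        y = x[:, j]
        ok = np.isfinite(y)
        beta, *_ = np.linalg.lstsq(design[ok], y[ok], rcond=None)
        fitted = design[ok] @ beta
        out[ok, j] = y[ok] - fitted + y[ok].mean()
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# recursive binary segmentation
# ---------------------------------------------------------------------------

def _best_split(x: np.ndarray, min_markers: int
                ) -> tuple[int, float, float, float] | None:
    """Best admissible split of ``x``: (index, |t|, p, signal/noise).

    The split before index ``k`` maximises the two-sample pooled-variance t
    statistic between ``x[:k]`` and ``x[k:]``; ties break to the lowest index.
    Returns None when no admissible split exists.
    """
    n = x.size
    if n < 2 * min_markers:
        return None
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    k = np.arange(min_markers, n - min_markers + 1)
    nl = k.astype(float)
    nr = n - nl
    sl = cs[k - 1]
    sr = cs[-1] - sl
    ml = sl / nl
    mr = sr / nr
    ssl = np.maximum(css[k - 1] - nl * ml * ml, 0.0)
    ssr = np.maximum((css[-1] - css[k - 1]) - nr * mr * mr, 0.0)
    pooled_var = (ssl + ssr) / (n - 2)
    diff = ml - mr
    # guard against float rounding on (near-)constant data: differences and
    # variances at relative machine-noise scale are treated as exactly zero
    atol = 1e-10 * max(1.0, float(np.max(np.abs(x))))
    diff[np.abs(diff) < atol] = 0.0
    pooled_var[pooled_var < atol * atol] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled_var * (1.0 / nl + 1.0 / nr))
    degenerate = pooled_var == 0.0
    t[degenerate & (diff != 0.0)] = np.inf * np.sign(diff[degenerate
                                                          & (diff != 0.0)])
    t[degenerate & (diff == 0.0)] = 0.0

    best = int(np.argmax(np.abs(t)))
    if t[best] == 0.0:
        return None
    t_best = t[best]
    split = int(k[best])
    if np.isinf(t_best):
        return split, np.inf, 0.0, np.inf
    p = 2.0 * stats.t.sf(abs(t_best), n - 2)
    pv = pooled_var[best]
    snr = abs(diff[best]) / np.sqrt(pv) if pv > 0 else np.inf
    return split, float(abs(t_best)), float(p), float(snr)


def segment_chromosome(values: np.ndarray,
                       params: SegmentationParams | None = None) -> list[int]:
    """Breakpoints of one chromosome's signal by recursive binary splitting.

    At each step the split maximising the two-sample t statistic between the
    flanks is taken and accepted iff p < ``p_threshold``, both sides hold at
    least ``min_markers`` markers, and |mean difference| / pooled SD is at
    least ``signal_noise_min``; accepted splits recurse on both sides.
    Returned breakpoints are sorted 0-based offsets into ``values`` (a
    breakpoint ``b`` separates ``values[:b]`` from ``values[b:]``).
    """
    params = params or SegmentationParams()
    params.validate()
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return []
    if not np.isfinite(x).all():
        raise ConfigurationError("segmentation input contains non-finite "
                                 "values; mask or impute first")
    breakpoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        found = _best_split(x[lo:hi], params.min_markers)
        if found is None:
            return
        split, _, p, snr = found
        if p < params.p_threshold and snr >= params.signal_noise_min:
            breakpoints.append(lo + split)
            recurse(lo, lo + split)
            recurse(lo + split, hi)

    recurse(0, x.size)
    return sorted(breakpoints)


def call_state(mean_log2_ratio: float) -> tuple[float, str]:
    """Copy-number estimate and categorical state from a segment mean.

    Estimate ``2 * 2**mean_log2_ratio``; loss below 1.75 copies, neutral on
    the inclusive band [1.75, 2.25], amplification strictly above 6 copies,
    gain otherwise.  The estimate is rounded at 1e-9 copies before
    thresholding so boundary values survive the log/exp round trip.
    """
    if not np.isfinite(mean_log2_ratio):
        raise ConfigurationError("mean log2 ratio must be finite")
    estimate = float(2.0 * np.exp2(mean_log2_ratio))
    snapped = round(estimate, 9)
    if snapped < NEUTRAL_LOW:
        state = STATE_LOSS
    elif snapped <= NEUTRAL_HIGH:
        state = STATE_NEUTRAL
    elif snapped > AMPLIFICATION_MIN:
        state = STATE_AMPLIFICATION
    else:
        state = STATE_GAIN
    return estimate, state


def segment_sample(log2_ratios: np.ndarray, marker_map: pd.DataFrame,
                   params: SegmentationParams | None = None,
                   sample_id: str = "sample") -> pd.DataFrame:
    """Genome-wide segmentation with state calls for one sample.

    Returns a segment table (one row per segment, chromosome-local 0-based
    half-open marker indices) that tiles every chromosome.
    """
    params = params or SegmentationParams()
    x = np.asarray(log2_ratios, dtype=float)
    rows = []
    offset = 0
    for chrom, grp in marker_map.groupby("chromosome", sort=False):
        n = len(grp)
        vals = x[offset:offset + n]
        bps = segment_chromosome(vals, params)
        bounds = [0] + bps + [n]
        for lo, hi in zip(bounds, bounds[1:]):
            mean = float(np.mean(vals[lo:hi]))
            estimate, state = call_state(mean)
            rows.append((sample_id, chrom, lo, hi, hi - lo, mean,
                         estimate, state))
        offset += n
    return pd.DataFrame(rows, columns=[
        "sample_id", "chromosome", "start_index", "end_index", "n_markers",
        "mean_log2_ratio", "cn_estimate", "state"])
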