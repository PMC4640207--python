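"""Loss-of-heterozygosity calling from mirrored B-allele frequencies.

BAF is folded to mBAF = max(BAF, 1-BAF); markers above a homozygous cutoff
are dropped as uninformative; the informative-marker mBAF track is segmented
with the copy-number segmentation rule at a 100-marker minimum window; each
segment is called LOH iff its mean mBAF reaches the fixed allelic-imbalance
threshold 0.76 AND a one-sided one-sample t-test against the heterozygous
null mean 0.5 gives p < 0.01.  Detection is unpaired (no germline genotypes)
and therefore finds allelic imbalance, including copy-neutral LOH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cn_core import SegmentationParams, segment_chromosome
from .exceptions import ConfigurationError

#: markers with mBAF above this are treated as germline homozygous and dropped
HOMOZYGOUS_CUTOFF = 0.95

MBAF_THRESHOLD = 0.76
LOH_P_THRESHOLD = 0.01
MIN_INFORMATIVE_MARKERS = 100


@dataclass
class LohParams:
    """Thresholds of the allelic-imbalance LOH caller."""

    mbaf_threshold: float = MBAF_THRESHOLD
    p_threshold: float = LOH_P_THRESHOLD
    min_markers: int = MIN_INFORMATIVE_MARKERS
    homozygous_cutoff: float = HOMOZYGOUS_CUTOFF
    segmentation: SegmentationParams | None = None

    def seg_params(self) -> SegmentationParams:
        if self.segmentation is not None:
            return self.segmentation
        return SegmentationParams(min_markers=self.min_markers)

    def validate(self) -> None:
        if not 0.5 <= self.mbaf_threshold <= 1.0:
            raise ConfigurationError("mbaf_threshold must be in [0.5, 1]")
        if not 0.0 < self.p_threshold < 1.0:
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if self.min_markers < 2:
            raise ConfigurationError("min_markers must be >= 2")
        if not 0.5 < self.homozygous_cutoff <= 1.0:
            raise ConfigurationError("homozygous_cutoff must be in (0.5, 1]")


def mirror_baf(baf: np.ndarray,
               homozygous_cutoff: float = HOMOZYGOUS_CUTOFF,
               informative_mask: np.ndarray | None = None,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Fold BAF to mBAF and drop uninformative (homozygous) markers.

    Without germline genotypes the only handle on informativeness is the
    observed mBAF itself: markers above ``homozygous_cutoff`` are treated as
    germline homozygous and dropped.  When germline heterozygosity IS known
    (``informative_mask``, boolean per marker), it replaces the cutoff filter;
    this keeps fully imbalanced markers (mBAF ~1.0, e.g. copy-neutral LOH in
    a very pure tumour) that the unpaired filter cannot distinguish from
    homozygotes.

    Returns ``(mbaf, index)`` where ``index`` maps each retained value back to
    its position in the input vector.  NaN BAF values are dropped as well.
    """
    b = np.asarray(baf, dtype=float)
    if np.nanmin(b, initial=0.0) < 0.0 or np.nanmax(b, initial=0.0) > 1.0:
        raise ConfigurationError("BAF values must lie in [0, 1]")
    mbaf = np.maximum(b, 1.0 - b)
    if informative_mask is not None:
        keep = np.isfinite(mbaf) & np.asarray(informative_mask, dtype=bool)
    else:
        keep = np.isfinite(mbaf) & (mbaf <= homozygous_cutoff)
    return mbaf[keep], np.flatnonzero(keep)


def segment_mbaf(mbaf: np.ndarray,
                 params: SegmentationParams | None = None) -> list[int]:
    """Segment an informative-marker mBAF track.

    Same contract as :func:`famcna.cn_core.segment_chromosome` with the LOH
    default of a 100-marker minimum window.
    """
    params = params or SegmentationParams(
        min_markers=MIN_INFORMATIVE_MARKERS)
    return segment_chromosome(mbaf, params)


def call_loh(segment_mbaf_values: np.ndarray,
             params: LohParams | None = None) -> dict:
    """LOH verdict for one segmented run of informative-marker mBAF values.

    p-value from a one-sided one-sample t-test of the marker mBAF against the
    heterozygous null mean 0.5; LOH iff mean mBAF >= threshold and
    p < p-threshold.  Segments below the minimum marker count are reported
    but forced non-LOH with a reason code.
    """
    params = params or LohParams()
    params.validate()
    vals = np.asarray(segment_mbaf_values, dtype=float)
    n = vals.size
    mean = float(vals.mean()) if n else float("nan")
    result = {"mean_mbaf": mean, "n_informative_markers": n,
              "p_value": float("nan"), "is_loh": False, "reason": ""}
    if n < params.min_markers:
        result["reason"] = "too_few_informative_markers"
        return result
    sd = float(vals.std(ddof=1))
    if sd < 1e-12:  # constant segment up to float rounding
        p = 0.0 if mean > 0.5 else 1.0
    else:
        p = float(stats.ttest_1samp(vals, 0.5, alternative="greater").pvalue)
    result["p_value"] = p
    result["is_loh"] = bool(mean >= params.mbaf_threshold
                            and p < params.p_threshold)
    if not result["is_loh"]:
        result["reason"] = ("below_mbaf_threshold"
                            if mean < params.mbaf_threshold else
                            "not_significant" if p >= params.p_threshold
                            else "")
    return result


def loh_profile(baf: np.ndarray, marker_map: pd.DataFrame,
                params: LohParams | None = None,
                sample_id: str = "sample") -> pd.DataFrame:
    """Genome-wide LOH segment table for one sample.

    ``start_index``/``end_index`` are chromosome-local genomic marker indices
    (0-based half-open) spanned by the segment's informative markers.
    """
    params = params or LohParams()
    params.validate()
    seg_params = params.seg_params()
    b = np.asarray(baf, dtype=float)
    rows = []
    offset = 0
    for chrom, grp in marker_map.groupby("chromosome", sort=False):
        n = len(grp)
        mbaf, info_idx = mirror_baf(b[offset:offset + n],
                                    params.homozygous_cutoff)
        if mbaf.size:
            bps = segment_mbaf(mbaf, seg_params)
            bounds = [0] + bps + [mbaf.size]
            for lo, hi in zip(bounds, bounds[1:]):
                call = call_loh(mbaf[lo:hi], params)
                rows.append((sample_id, chrom,
                             int(info_idx[lo]), int(info_idx[hi - 1]) + 1,
                             call["n_informative_markers"],
                             call["mean_mbaf"], call["p_value"],
                             call["is_loh"], call["reason"]))
        offset += n
    return pd.DataFrame(rows, columns=[
        "sample_id", "chromosome", "start_index", "end_index",
        "n_informative_markers", "mean_mbaf", "p_value", "is_loh", "reason"])
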