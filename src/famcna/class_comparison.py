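"""Differential copy-number comparison between mutation classes.

Segments from all samples are overlaid into a cohort-wide grid of disjoint
regions; per region the counts of gained / lost / unchanged samples in the
two classes form a 3x2 table tested with Fisher's exact test (exact
conditional enumeration, no multiple-testing correction by default, matching
the reporting convention of uncorrected region p-values); per-class gain and
loss frequency tracks and Ward clustering of marker-level state profiles
complete the comparison.
"""

from __future__ import annotations

from functools import lru_cache
from math import lgamma, exp

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .cn_core import (STATE_AMPLIFICATION, STATE_GAIN, STATE_LOSS,
                      STATE_NEUTRAL)
from .exceptions import ConfigurationError, DegenerateInputError

#: numeric encoding of states for clustering (amplification kept distinct)
STATE_ENCODING = {STATE_AMPLIFICATION: 2.0, STATE_GAIN: 1.0,
                  STATE_NEUTRAL: 0.0, STATE_LOSS: -1.0}


# ---------------------------------------------------------------------------
# region grid
# ---------------------------------------------------------------------------

def build_region_grid(segments: pd.DataFrame) -> tuple[pd.DataFrame,
                                                       pd.DataFrame]:
    """Overlay every sample's segment boundaries into disjoint regions.

    ``segments`` is a concatenated segment table (as from
    :func:`famcna.cn_core.segment_sample`) covering every sample.  Region
    boundaries per chromosome are the sorted union of all samples' segment
    boundaries, so each sample's state is constant within each region.

    Returns ``(regions, states)``: ``regions`` has chromosome and 0-based
    half-open marker indices; ``states`` is regions x samples with the
    categorical state of each sample in each region.
    """
    samples = list(pd.unique(segments["sample_id"]))
    region_rows = []
    state_rows = []
    for chrom, grp in segments.groupby("chromosome", sort=False):
        lo = int(grp["start_index"].min())
        hi = int(grp["end_index"].max())
        for sid, sg in grp.groupby("sample_id"):
            covered = (sg["end_index"] - sg["start_index"]).sum()
            if int(sg["start_index"].min()) != lo or \
                    int(sg["end_index"].max()) != hi or covered != hi - lo:
                raise ConfigurationError(
                    f"sample {sid!r} does not tile chromosome {chrom} "
                    f"([{lo}, {hi}))")
        bounds = np.unique(np.concatenate(
            [grp["start_index"].to_numpy(), grp["end_index"].to_numpy()]))
        # per-sample lookup: state at each region start
        per_sample = {}
        for sid, sg in grp.groupby("sample_id"):
            sg = sg.sort_values("start_index")
            starts = sg["start_index"].to_numpy()
            states = sg["state"].to_numpy()
            idx = np.searchsorted(starts, bounds[:-1], side="right") - 1
            per_sample[sid] = states[idx]
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            region_rows.append((chrom, int(a), int(b)))
            state_rows.append([per_sample[s][i] for s in samples])
    regions = pd.DataFrame(region_rows,
                           columns=["chromosome", "start_index", "end_index"])
    states = pd.DataFrame(state_rows, columns=samples)
    return regions, states


def states_to_marker_matrix(segments: pd.DataFrame,
                            marker_map: pd.DataFrame) -> pd.DataFrame:
    """Expand segment state calls to a markers x samples matrix of states."""
    samples = list(pd.unique(segments["sample_id"]))
    chrom_sizes = marker_map.groupby("chromosome", sort=False).size()
    out = {}
    for sid, sg in segments.groupby("sample_id"):
        parts = []
        for chrom in chrom_sizes.index:
            n = int(chrom_sizes[chrom])
            track = np.empty(n, dtype=object)
            track[:] = STATE_NEUTRAL
            for _, row in sg[sg["chromosome"] == chrom].iterrows():
                track[int(row["start_index"]):int(row["end_index"])] = \
                    row["state"]
            parts.append(track)
        out[sid] = np.concatenate(parts)
    return pd.DataFrame(out, index=marker_map["marker_id"])[samples]


# ---------------------------------------------------------------------------
# 3x2 Fisher exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _lchoose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


@lru_cache(maxsize=100_000)
def _fisher_rx2_cached(rows: tuple[int, ...], col0: tuple[int, ...]) -> float:
    """Exact conditional p for an r x 2 table given by row sums and column-0
    cells, by full enumeration of tables with the same margins."""
    c0 = sum(col0)
    # log-probability of a table = sum_i lchoose(r_i, a_i) - lchoose(N, c0)
    norm = _lchoose(sum(rows), c0)

    def logp(cells: tuple[int, ...]) -> float:
        return sum(_lchoose(r, a) for r, a in zip(rows, cells)) - norm

    obs = logp(col0)
    tol = 1e-9
    total = 0.0

    def enumerate_tables(i: int, remaining: int, cells: list[int]) -> None:
        nonlocal total
        if i == len(rows) - 1:
            if remaining <= rows[i]:
                lp = logp(tuple(cells + [remaining]))
                if lp <= obs + tol:
                    total += exp(lp)
            return
        for a in range(min(rows[i], remaining) + 1):
            enumerate_tables(i + 1, remaining - a, cells + [a])

    enumerate_tables(0, c0, [])
    return min(total, 1.0)


def fisher_3x2(table: np.ndarray | list) -> float:
    """Exact conditional p-value of an r x 2 contingency table.

    Sums the multivariate-hypergeometric probabilities (margins fixed) of all
    tables no more probable than the observed one.  All-zero rows reduce the
    test to the smaller table; both column sums must be positive.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ConfigurationError("expected an r x 2 table")
    if (t < 0).any():
        raise ConfigurationError("table counts must be non-negative")
    cols = t.sum(axis=0)
    if (cols <= 0).any():
        raise ConfigurationError("both column sums must be positive")
    t = t[t.sum(axis=1) > 0]
    if t.shape[0] <= 1:
        return 1.0
    rows = tuple(int(r) for r in t.sum(axis=1))
    col0 = tuple(int(a) for a in t[:, 0])
    return _fisher_rx2_cached(rows, col0)


# ---------------------------------------------------------------------------
# class comparison over the region grid
# ---------------------------------------------------------------------------

def _collapse_state(state: str) -> str:
    """Amplification counts as gained for frequency tables and testing."""
    return STATE_GAIN if state == STATE_AMPLIFICATION else state


def region_tests(regions: pd.DataFrame, states: pd.DataFrame,
                 labels: pd.Series, class_a: str, class_b: str,
                 bh_correct: bool = False) -> pd.DataFrame:
    """Per-region 3x2 Fisher test of state frequencies between two classes.

    Rows of the table are gained (gain or amplification), lost, unchanged;
    columns are the two classes.  p-values are reported uncorrected;
    ``bh_correct=True`` adds a Benjamini-Hochberg step-up column.
    """
    a_samples = labels.index[labels == class_a]
    b_samples = labels.index[labels == class_b]
    if len(a_samples) == 0 or len(b_samples) == 0:
        raise ConfigurationError("both classes need at least one sample")
    rows = []
    for i in range(len(regions)):
        row_states = states.iloc[i]
        counts = []
        for group in (a_samples, b_samples):
            collapsed = [_collapse_state(s) for s in row_states[group]]
            counts.append([
                sum(s == STATE_GAIN for s in collapsed),
                sum(s == STATE_LOSS for s in collapsed),
                sum(s == STATE_NEUTRAL for s in collapsed)])
        table = np.array(counts).T  # rows gained/lost/unchanged
        p = fisher_3x2(table)
        na, nb = len(a_samples), len(b_samples)
        rows.append(list(regions.iloc[i]) + [
            table[0, 0], table[1, 0], table[2, 0],
            table[0, 1], table[1, 1], table[2, 1], p,
            table[0, 0] / na, table[1, 0] / na,
            table[0, 1] / nb, table[1, 1] / nb])
    out = pd.DataFrame(rows, columns=list(regions.columns) + [
        "gained_a", "lost_a", "unchanged_a",
        "gained_b", "lost_b", "unchanged_b", "p_value",
        "gain_freq_a", "loss_freq_a", "gain_freq_b", "loss_freq_b"])
    if bh_correct:
        from .expression import bh_fdr
        out["fdr_p"] = bh_fdr(out["p_value"].to_numpy())
    return out


def frequency_profiles(states: pd.DataFrame,
                       labels: pd.Series) -> pd.DataFrame:
    """Per-region, per-class gain and loss frequencies.

    Gain frequency counts gain-or-amplification states.  Returns one column
    pair ``gain_freq_<class>`` / ``loss_freq_<class>`` per class label.
    """
    out = {}
    for cls in pd.unique(labels):
        members = labels.index[labels == cls]
        if len(members) == 0:
            raise ConfigurationError(f"class {cls!r} is empty")
        sub = states[members]
        gained = sub.isin([STATE_GAIN, STATE_AMPLIFICATION]).sum(axis=1)
        lost = (sub == STATE_LOSS).sum(axis=1)
        out[f"gain_freq_{cls}"] = gained / len(members)
        out[f"loss_freq_{cls}"] = lost / len(members)
    return pd.DataFrame(out)


def cluster_state_profiles(marker_states: pd.DataFrame,
                           n_clusters: int = 2
                           ) -> tuple[np.ndarray, pd.Series]:
    """Ward clustering of samples on numerically encoded state profiles.

    ``marker_states`` is markers x samples with categorical states, encoded
    amplification=2, gain=1, neutral=0, loss=-1; agglomeration is Ward on
    Euclidean distances.  Returns the scipy linkage matrix and flat cluster
    labels (1..n_clusters) per sample.  Deterministic for a fixed sample
    order; among equal merge costs scipy takes the lowest-index pair.
    """
    if marker_states.shape[1] < 2:
        raise DegenerateInputError("clustering needs at least 2 samples")
    raw = marker_states.to_numpy()
    encoded = np.empty(raw.shape, dtype=float)
    for state, value in STATE_ENCODING.items():
        encoded[raw == state] = value
    encoded = encoded.T
    linkage = hierarchy.linkage(encoded, method="ward")
    flat = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return linkage, pd.Series(flat, index=marker_states.columns,
                              name="cluster")
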