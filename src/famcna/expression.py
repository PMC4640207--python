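"""Expression analyses: immune signature, TIL gating, subtypes, DE.

The immune signature is built by median-splitting samples on their TIL
percentage within each intrinsic-subtype stratum, testing every gene with a
one-way ANOVA (two groups), keeping genes passing a Benjamini-Hochberg
step-up FDR below alpha, and intersecting the luminal and basal gene sets.
Samples are then gated into high / low TIL by average-linkage hierarchical
clustering (correlation distance) of the standardized signature submatrix.
Differential expression between mutation classes uses the same one-way ANOVA
with step-up FDR and a signed linear fold-change convention (|FC| >= 1,
positive = higher in the first class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, DegenerateInputError


# ---------------------------------------------------------------------------
# one-way ANOVA (two groups) and BH step-up, vectorised over genes
# ---------------------------------------------------------------------------

def _anova_two_group(x: np.ndarray, in_a: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-row one-way F statistic and p-value for a two-level factor.

    With two groups the one-way ANOVA F equals the square of the
    pooled-variance t statistic; p is from F(1, n-2).  Rows with zero pooled
    within-group variance get p=1 when the group means are equal and p=0
    (flagged infinite F) otherwise.
    """
    a = x[:, in_a]
    b = x[:, ~in_a]
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ConfigurationError("both groups need >= 2 samples")
    ma = a.mean(axis=1)
    mb = b.mean(axis=1)
    ssw = ((a - ma[:, None]) ** 2).sum(axis=1) + \
          ((b - mb[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    pooled = ssw / df
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ma - mb) ** 2 / (pooled * (1.0 / na + 1.0 / nb))
    zero = pooled == 0.0
    f[zero & (ma != mb)] = np.inf
    f[zero & (ma == mb)] = 0.0
    p = stats.f.sf(f, 1, df)
    p[np.isinf(f)] = 0.0
    p[zero & (ma == mb)] = 1.0
    return f, p


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float),
                         method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# immune signature
# ---------------------------------------------------------------------------

@dataclass
class ImmuneSignature:
    """Ordered signature gene ids with per-gene TIL association direction."""

    genes: list[str]
    direction: pd.Series  # +1 higher in high-TIL samples, -1 lower

    def __len__(self) -> int:
        return len(self.genes)


def median_split(values: pd.Series) -> pd.Series:
    """High/low split at the median; ties at the median go to the low group."""
    return values > values.median()


def build_immune_signature(matrix: pd.DataFrame, til_percent: pd.Series,
                           subtypes: pd.Series,
                           alpha: float = 0.05) -> ImmuneSignature:
    """Immune signature = intersection of per-stratum TIL-associated genes.

    Within each subtype stratum separately, samples are median-split on the
    TIL percentage, every gene is tested with a one-way ANOVA between the two
    TIL groups, and genes with BH step-up FDR below ``alpha`` are kept; the
    signature is the intersection of the strata's gene sets.  Directions come
    from the sign of the high-minus-low mean difference (first stratum).
    """
    til_percent = til_percent.loc[matrix.columns]
    subtypes = subtypes.loc[matrix.columns]
    kept: list[set[str]] = []
    direction = pd.Series(0.0, index=matrix.index)
    for stratum in pd.unique(subtypes):
        cols = subtypes.index[subtypes == stratum]
        if len(cols) < 4:
            raise ConfigurationError(
                f"stratum {stratum!r} has {len(cols)} samples; median split "
                "needs at least 4")
        high = median_split(til_percent[cols]).to_numpy()
        if high.sum() < 2 or (~high).sum() < 2:
            raise ConfigurationError(
                f"degenerate median split in stratum {stratum!r}")
        sub = matrix[cols].to_numpy()
        _, p = _anova_two_group(sub, high)
        fdr = bh_fdr(p)
        genes = set(matrix.index[fdr < alpha])
        kept.append(genes)
        if not kept[:-1]:  # first stratum fixes the direction convention
            diff = sub[:, high].mean(axis=1) - sub[:, ~high].mean(axis=1)
            direction[:] = np.sign(diff)
    common = set.intersection(*kept) if kept else set()
    ordered = [g for g in matrix.index if g in common]
    return ImmuneSignature(
        genes=ordered,
        direction=direction.loc[ordered].replace(0.0, 1.0).astype(int))


# ---------------------------------------------------------------------------
# clustering-based gating
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0.0).any():
        raise DegenerateInputError("constant gene row; cannot standardize")
    return (x - mean) / sd


def _correlation_cluster(x: np.ndarray, n_clusters: int = 2) -> np.ndarray:
    """Average-linkage clustering of columns with correlation distance."""
    if x.shape[1] < 2:
        raise DegenerateInputError("clustering needs at least 2 samples")
    d = pdist(x.T, metric="correlation")
    if not np.isfinite(d).all():
        raise DegenerateInputError(
            "correlation distance undefined (constant sample profile)")
    linkage = hierarchy.linkage(d, method="average")
    flat = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    if len(np.unique(flat)) < n_clusters:
        raise DegenerateInputError("samples do not separate into two branches")
    return flat


def signature_score(matrix: pd.DataFrame,
                    signature: ImmuneSignature) -> pd.Series:
    """Per-sample mean of direction-weighted standardized signature genes."""
    if not signature.genes:
        raise ConfigurationError("signature is empty")
    z = _standardize_rows(matrix.loc[signature.genes].to_numpy())
    w = signature.direction.to_numpy(dtype=float)[:, None]
    return pd.Series((z * w).mean(axis=0), index=matrix.columns,
                     name="signature_score")


def gate_til(matrix: pd.DataFrame,
             signature: ImmuneSignature) -> pd.Series:
    """Label each sample high/low TIL by clustering on the signature genes.

    The signature submatrix is gene-wise mean-centered and scaled to unit
    variance, samples are clustered with average linkage on correlation
    distance and cut into two branches; the branch with the higher mean
    signature score is labelled ``True`` (high TIL).
    """
    score = signature_score(matrix, signature)
    z = _standardize_rows(matrix.loc[signature.genes].to_numpy())
    flat = _correlation_cluster(z, 2)
    means = {c: score[flat == c].mean() for c in np.unique(flat)}
    high_branch = max(means, key=means.get)
    return pd.Series(flat == high_branch, index=matrix.columns,
                     name="high_til")


def spearman_til(score: pd.Series, til: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation between signature score and TIL values.

    Returns ``(rho, p)``; constant input is undefined and reported as NaN.
    """
    score, til = score.align(til, join="inner")
    if len(score) < 3:
        raise ConfigurationError("need at least 3 paired values")
    if score.nunique() == 1 or til.nunique() == 1:
        return float("nan"), float("nan")
    res = stats.spearmanr(score, til)
    return float(res.statistic), float(res.pvalue)


def assign_subtype(matrix: pd.DataFrame, intrinsic_genes: list[str],
                   archetypes: pd.DataFrame,
                   top_variance_fraction: float = 0.5) -> pd.Series:
    """Assign luminal/basal labels by clustering on variable intrinsic genes.

    Restricts to the top ``top_variance_fraction`` of intrinsic-list genes by
    variance, clusters samples as in :func:`gate_til`, cuts into two
    branches, and names each branch by the archetype (column of
    ``archetypes``, indexed by gene) whose profile correlates best with the
    branch's mean expression profile.
    """
    genes = [g for g in intrinsic_genes if g in matrix.index]
    if not genes:
        raise ConfigurationError("intrinsic gene list does not overlap matrix")
    sub = matrix.loc[genes]
    variances = sub.var(axis=1, ddof=1)
    n_keep = max(2, int(round(top_variance_fraction * len(genes))))
    top = variances.sort_values(ascending=False, kind="stable")
    top_genes = sorted(top.index[:n_keep], key=list(matrix.index).index)
    z = _standardize_rows(sub.loc[top_genes].to_numpy())
    flat = _correlation_cluster(z, 2)

    arch = archetypes.loc[top_genes]
    labels = {}
    for c in np.unique(flat):
        profile = sub.loc[top_genes].to_numpy()[:, flat == c].mean(axis=1)
        corr = {name: np.corrcoef(profile, arch[name])[0, 1]
                for name in arch.columns}
        labels[c] = max(corr, key=corr.get)
    return pd.Series([labels[c] for c in flat], index=matrix.columns,
                     name="subtype")


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(matrix: pd.DataFrame, labels: pd.Series,
                            class_a: str, class_b: str) -> pd.DataFrame:
    """Per-gene one-way ANOVA between two classes with step-up FDR.

    Fold-change is the signed linear ratio of class means: values are
    log2-scale, so FC = 2**(mean_a - mean_b), reported with magnitude >= 1
    and a negative sign when expression is lower in ``class_a``.
    """
    labels = labels.loc[matrix.columns]
    in_a = (labels == class_a).to_numpy()
    in_b = (labels == class_b).to_numpy()
    if not (in_a | in_b).all():
        matrix = matrix.loc[:, in_a | in_b]
        labels = labels[in_a | in_b]
        in_a = (labels == class_a).to_numpy()
    x = matrix.to_numpy(dtype=float)
    f, p = _anova_two_group(x, in_a)
    fdr = bh_fdr(p)
    delta = x[:, in_a].mean(axis=1) - x[:, ~in_a].mean(axis=1)
    fc = np.where(delta >= 0, np.exp2(delta), -np.exp2(-delta))
    return pd.DataFrame({
        "f_statistic": f,
        "p_value": p,
        "fdr_p": fdr,
        "fold_change": fc,
        "log2_fc": delta,
    }, index=matrix.index)
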