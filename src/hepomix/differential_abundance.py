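"""Per-layer quality filtering, normalization, imputation and testing.

The analysis chain mirrors standard practice for each layer of a two-group
(control vs treatment) design:

* transcripts / miRNAs — drop features with zero counts in every sample,
  normalize between samples by the trimmed mean of M-values (TMM), then test
  each feature with a two-sided equal-variance t-test on counts-per-million;
* proteins — presence filtering (observed in >= ceil(0.6 n) samples of each
  group, or in all samples of exactly one group and none of the other =
  group-exclusive), natural-log transform, group-wise sequential regression
  imputation of the remaining missing cells, then equal-variance t-tests;
* metabolites — optional internal-standard division, median normalization
  and log2 transform, equal-variance t-tests plus a one-component PLS
  variable importance in projection (VIP); a metabolite is differential when
  VIP > 1 and p < alpha.

Significance is an unadjusted p < 0.05 by default; Benjamini-Hochberg
adjustment is available but off by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kb_model import (
    GROUP_CONTROL,
    GROUP_TREATMENT,
    LayerKind,
    OmicsLayer,
    ValidationError,
)

__all__ = [
    "GroupSummary",
    "DifferentialTable",
    "DIRECTION_UP",
    "DIRECTION_DOWN",
    "EXCLUSIVE_TREATMENT",
    "EXCLUSIVE_CONTROL",
    "ttest_from_summary",
    "ttest_equal_var",
    "bh_adjust",
    "filter_transcripts",
    "tmm_normalize",
    "log_transform",
    "filter_proteins_presence",
    "impute_sequential",
    "pls_vip",
    "select_metabolites",
    "normalize_metabolites",
    "sum_duplicate_ids",
    "run_layer",
]

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
EXCLUSIVE_TREATMENT = "exclusive_treatment"
EXCLUSIVE_CONTROL = "exclusive_control"

TABLE_COLUMNS = [
    "id", "layer", "mean_control", "mean_treatment", "ratio", "direction",
    "t", "p", "vip", "passed_quality", "differential",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed group summary statistics (mean, SD, n) for one measure."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"{self.label}: sd must be >= 0")
        if self.n < 2:
            raise ValidationError(f"{self.label}: n must be >= 2")


@dataclass
class DifferentialTable:
    """Per-feature test results for one layer.

    ``table`` has one row per feature with columns
    id, layer, mean_control, mean_treatment, ratio, direction, t, p, vip,
    passed_quality, differential. Group means are on the post-normalization
    scale of the layer's chain. Group-exclusive proteins carry no t statistic
    and a +/-inf ratio sentinel.
    """

    layer_kind: LayerKind
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.layer_kind = LayerKind(self.layer_kind)
        missing = [c for c in TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"differential table lacks columns {missing}")
        bad = self.table["differential"] & ~self.table["passed_quality"]
        if bad.any():
            raise ValidationError("differential features must pass quality filters")
        p = self.table["p"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("p-values must lie in [0, 1]")
        excl = self.table["direction"].isin([EXCLUSIVE_TREATMENT, EXCLUSIVE_CONTROL])
        if self.table.loc[excl, "t"].notna().any():
            raise ValidationError("exclusive features must not carry a t statistic")

    @property
    def universe_ids(self) -> set[str]:
        return set(self.table.loc[self.table["passed_quality"], "id"])

    @property
    def differential_ids(self) -> set[str]:
        return set(self.table.loc[self.table["differential"], "id"])

    def direction_of(self, feature_id: str) -> str:
        row = self.table.loc[self.table["id"] == feature_id]
        if row.empty:
            raise KeyError(feature_id)
        return str(row["direction"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table[TABLE_COLUMNS].to_csv(path, sep="\t", index=False,
                                         lineterminator="\n")

    @classmethod
    def from_tsv(cls, path, layer_kind: LayerKind) -> "DifferentialTable":
        df = pd.read_csv(path, sep="\t")
        return cls(LayerKind(layer_kind), df)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def ttest_from_summary(s1: GroupSummary, s2: GroupSummary) -> tuple[float, float]:
    """Two-sided pooled-variance t-test from group summary statistics.

    Returns (t, p) with df = n1 + n2 - 2; (nan, nan) when the pooled
    variance is zero (the comparison is undefined, not an error).
    """
    n1, n2 = s1.n, s2.n
    pooled = ((n1 - 1) * s1.sd**2 + (n2 - 1) * s2.sd**2) / (n1 + n2 - 2)
    if pooled <= 0:
        if s1.mean == s2.mean:
            return 0.0, 1.0
        return math.nan, math.nan
    se = math.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    t = (s2.mean - s1.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return t, min(p, 1.0)


def ttest_equal_var(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided equal-variance t-test on raw samples (t is y vs x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("both samples need n >= 2")
    sx = GroupSummary("x", float(np.mean(x)), float(np.std(x, ddof=1)), len(x))
    sy = GroupSummary("y", float(np.mean(y)), float(np.std(y, ddof=1)), len(y))
    return ttest_from_summary(sx, sy)


def _ttest_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance t-tests (b vs a); rows with zero pooled
    variance get nan statistics (t=0, p=1 when the means also agree)."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        t = (m2 - m1) / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    degenerate = pooled <= 0
    equal = degenerate & (m1 == m2)
    t[equal], p[equal] = 0.0, 1.0
    t[degenerate & ~equal] = np.nan
    p[degenerate & ~equal] = np.nan
    return t, np.minimum(p, 1.0)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# count layers: zero filter and TMM
# ---------------------------------------------------------------------------

def filter_transcripts(layer: OmicsLayer) -> OmicsLayer:
    """Remove features with zero counts across all samples."""
    if not layer.kind.is_count:
        raise ValidationError("zero-count filtering applies to count layers")
    keep = layer.values.sum(axis=1) > 0
    return OmicsLayer(layer.kind, layer.values.loc[keep], dict(layer.groups))


def tmm_normalize(
    layer: OmicsLayer, trim_m: float = 0.30, trim_a: float = 0.05
) -> tuple[pd.DataFrame, pd.Series]:
    """Trimmed-mean-of-M-values normalization of a count layer.

    The reference sample is the one whose upper-quartile count is closest to
    the mean of upper quartiles. For every other sample, the scaling factor
    is the weighted mean of log2 ratios (M) against the reference over
    features positive in both, after trimming the most extreme ``trim_m`` of
    M values and ``trim_a`` of average log intensities (A) on each side;
    weights are inverse asymptotic variances of M. Factors are centred to a
    geometric mean of 1 and the returned matrix is counts-per-million on the
    effective (factor-adjusted) library sizes.
    """
    counts = layer.values.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = [layer.sample_ids[j] for j in np.flatnonzero(lib == 0)]
        raise ValidationError(f"samples with all-zero counts: {bad}")
    if counts.shape[1] < 2:
        raise ValidationError("TMM needs at least two samples")

    uq = np.quantile(counts, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, ref_idx]
    ref_lib = lib[ref_idx]

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        obs = counts[:, j]
        keep = (obs > 0) & (ref > 0)
        if keep.sum() == 0:
            continue
        x, r = obs[keep], ref[keep]
        m = np.log2((x / lib[j]) / (r / ref_lib))
        a = 0.5 * np.log2((x / lib[j]) * (r / ref_lib))
        w = 1.0 / ((lib[j] - x) / (lib[j] * x) + (ref_lib - r) / (ref_lib * r))
        n = len(m)
        rank_m = stats.rankdata(m, method="ordinal")
        rank_a = stats.rankdata(a, method="ordinal")
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if kept.sum() == 0 or w[kept].sum() == 0:
            continue
        log_factors[j] = float(np.sum(w[kept] * m[kept]) / np.sum(w[kept]))

    log_factors -= log_factors.mean()  # geometric mean of factors = 1
    factors = 2.0 ** log_factors
    eff_lib = lib * factors
    cpm = counts / eff_lib[np.newaxis, :] * 1e6
    cpm_df = pd.DataFrame(cpm, index=layer.values.index, columns=layer.values.columns)
    return cpm_df, pd.Series(factors, index=layer.values.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# proteins: presence filter, log transform, sequential imputation
# ---------------------------------------------------------------------------

def filter_proteins_presence(layer: OmicsLayer) -> tuple[OmicsLayer, pd.Series]:
    """Presence filtering with the group-exclusive branch.

    Retains proteins observed in at least ceil(0.6 n) samples of each group
    (``testable``) and proteins observed in all samples of exactly one group
    and none of the other (``exclusive_treatment`` / ``exclusive_control``).
    Returns (retained layer subset, per-feature labels for retained ids).
    """
    if layer.kind != LayerKind.PROTEIN:
        raise ValidationError("presence filtering applies to protein layers")
    ctrl, trt = layer.control_samples, layer.treatment_samples
    if min(len(ctrl), len(trt)) < 3:
        raise ValidationError("presence filtering needs >= 3 samples per group")
    obs = layer.values.notna()
    n_c, n_t = obs[ctrl].sum(axis=1), obs[trt].sum(axis=1)
    need_c = math.ceil(0.6 * len(ctrl))
    need_t = math.ceil(0.6 * len(trt))

    testable = (n_c >= need_c) & (n_t >= need_t)
    excl_t = (n_t == len(trt)) & (n_c == 0)
    excl_c = (n_c == len(ctrl)) & (n_t == 0)
    keep = testable | excl_t | excl_c

    labels = pd.Series("testable", index=layer.values.index[keep], dtype=object)
    labels[excl_t[keep]] = EXCLUSIVE_TREATMENT
    labels[excl_c[keep]] = EXCLUSIVE_CONTROL
    return OmicsLayer(layer.kind, layer.values.loc[keep], dict(layer.groups)), labels


def log_transform(values) -> pd.DataFrame:
    """Natural log of observed entries; missing entries stay missing."""
    if isinstance(values, OmicsLayer):
        values = values.values
    arr = values.to_numpy(dtype=float)
    observed = ~np.isnan(arr)
    if (arr[observed] <= 0).any():
        raise ValidationError("log transform requires strictly positive observed values")
    out = np.full_like(arr, np.nan)
    out[observed] = np.log(arr[observed])
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _impute_group(
    x: pd.DataFrame, tol: float, max_iter: int
) -> pd.DataFrame:
    """Sequential regression imputation of one group's feature x sample block."""
    arr = x.to_numpy(dtype=float)
    miss = np.isnan(arr)
    if not miss.any():
        return x.copy()
    n_samp = arr.shape[1]
    # initialize missing cells with the feature's group mean
    row_mean = np.nanmean(arr, axis=1)
    filled = np.where(miss, row_mean[:, None], arr)
    incomplete = np.flatnonzero(miss.any(axis=1))
    # order by increasing missingness, ties by index for determinism
    incomplete = incomplete[np.argsort(miss[incomplete].sum(axis=1), kind="stable")]

    # predictor selection from the group-mean-initialized matrix: for each
    # incomplete feature its most correlated other features, at most
    # (observed - 2) of them so the regression keeps a residual df
    # (p >> n makes a full regression underdetermined at small group sizes)
    centred = filled - filled.mean(axis=1, keepdims=True)
    ss = np.sqrt((centred**2).sum(axis=1))
    safe = np.where(ss > 0, ss, 1.0)
    corr = (centred / safe[:, None]) @ (centred / safe[:, None]).T
    corr[ss == 0, :] = 0.0
    corr[:, ss == 0] = 0.0
    np.fill_diagonal(corr, 0.0)
    predictors = {}
    for i in incomplete:
        n_pred = max(0, int((~miss[i]).sum()) - 2)
        predictors[int(i)] = np.argsort(-np.abs(corr[i]), kind="stable")[:n_pred]

    for _ in range(max_iter):
        delta = 0.0
        for i in incomplete:
            obs_rows = ~miss[i]
            design = np.column_stack([np.ones(n_samp), filled[predictors[int(i)]].T])
            beta, *_ = np.linalg.lstsq(design[obs_rows], arr[i, obs_rows], rcond=None)
            pred = design @ beta
            # never extrapolate beyond the feature's observed group range:
            # regression on 3-4 points is otherwise numerically fragile
            lo, hi = arr[i, obs_rows].min(), arr[i, obs_rows].max()
            pred = np.clip(pred, lo, hi)
            for j in np.flatnonzero(miss[i]):
                delta = max(delta, abs(filled[i, j] - pred[j]))
                filled[i, j] = pred[j]
        if delta < tol:
            break
    return pd.DataFrame(filled, index=x.index, columns=x.columns)


def impute_sequential(
    values: pd.DataFrame,
    groups: Mapping[str, str],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Group-wise sequential regression imputation of missing intensities.

    Operates on log-transformed values, separately within each experimental
    group: features are ordered by missingness, missing cells start at the
    feature's group mean, then each incomplete feature is iteratively
    regressed on its most correlated (already complete or imputed) features
    and its missing cells updated, until the largest absolute change is below
    ``tol`` or ``max_iter`` sweeps. Observed entries are never altered.

    Features missing more than n_group - 3 values in a group are rejected
    (group-exclusive proteins must be excluded upstream).
    """
    ctrl = [s for s in values.columns if groups[s] == GROUP_CONTROL]
    trt = [s for s in values.columns if groups[s] == GROUP_TREATMENT]
    out = values.copy()
    for cols in (ctrl, trt):
        block = values[cols]
        n_miss = block.isna().sum(axis=1)
        limit = len(cols) - 3
        bad = n_miss[n_miss > limit]
        if not bad.empty:
            raise ValidationError(
                f"feature '{bad.index[0]}' has {int(bad.iloc[0])} missing values "
                f"in a group of {len(cols)} (limit {limit})"
            )
        out[cols] = _impute_group(block, tol, max_iter)
    return out


# ---------------------------------------------------------------------------
# metabolites: normalization, PLS-VIP, selection
# ---------------------------------------------------------------------------

def normalize_metabolites(
    layer: OmicsLayer, internal_standard: str | None = None
) -> pd.DataFrame:
    """Internal-standard division, median normalization and log2 transform.

    When ``internal_standard`` names a feature, every sample is divided by
    that feature's value first and the standard is dropped from the output;
    then each sample is scaled to a common median and values are log2
    transformed.
    """
    values = layer.values
    if internal_standard is not None:
        if internal_standard not in values.index:
            raise ValidationError(f"internal standard '{internal_standard}' not found")
        values = values.drop(index=internal_standard).div(
            values.loc[internal_standard], axis=1
        )
    med = values.median(axis=0)
    if (med <= 0).any():
        raise ValidationError("non-positive sample median; cannot median-normalize")
    scaled = values.div(med, axis=1) * float(np.exp(np.mean(np.log(med))))
    return pd.DataFrame(
        np.log2(scaled.to_numpy(dtype=float)),
        index=scaled.index, columns=scaled.columns,
    )


def pls_vip(values: pd.DataFrame, groups: Mapping[str, str]) -> pd.Series:
    """One-component PLS variable importance in projection per feature.

    Features are autoscaled and the group indicator centred; with a single
    latent component the VIP reduces to sqrt(P) * |w_j| / ||w|| where w is
    the X-weight vector, so mean(VIP^2) = 1 over scorable features.
    Zero-variance features get VIP 0 with a warning.
    """
    x = values.to_numpy(dtype=float).T  # samples x features
    y = np.array([
        1.0 if groups[s] == GROUP_TREATMENT else 0.0 for s in values.columns
    ])
    if len(set(y)) < 2:
        raise ValidationError("both groups are required for a PLS fit")
    sd = x.std(axis=0, ddof=1)
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} zero-variance feature(s) assigned VIP 0",
            stacklevel=2,
        )
    vip = np.zeros(x.shape[1])
    if ok.any():
        xs = (x[:, ok] - x[:, ok].mean(axis=0)) / sd[ok]
        yc = y - y.mean()
        w = xs.T @ yc
        norm = np.linalg.norm(w)
        if norm > 0:
            vip[ok] = math.sqrt(int(ok.sum())) * np.abs(w) / norm
    return pd.Series(vip, index=values.index, name="vip")


def select_metabolites(
    vip: pd.Series,
    pvalues: pd.Series,
    ratios: pd.Series,
    alpha: float = 0.05,
    vip_threshold: float = 1.0,
) -> DifferentialTable:
    """Differential metabolites: VIP above threshold AND p below alpha."""
    idx = vip.index
    if not (idx.equals(pvalues.index) and idx.equals(ratios.index)):
        raise ValidationError("vip, pvalues and ratios must be aligned")
    differential = (vip > vip_threshold) & (pvalues < alpha)
    df = pd.DataFrame({
        "id": idx,
        "layer": LayerKind.METABOLITE.value,
        "mean_control": np.nan,
        "mean_treatment": np.nan,
        "ratio": ratios.to_numpy(dtype=float),
        "direction": np.where(ratios.to_numpy(dtype=float) >= 1.0,
                              DIRECTION_UP, DIRECTION_DOWN),
        "t": np.nan,
        "p": pvalues.to_numpy(dtype=float),
        "vip": vip.to_numpy(dtype=float),
        "passed_quality": True,
        "differential": differential.to_numpy(),
    })
    return DifferentialTable(LayerKind.METABOLITE, df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# helpers and the layer dispatcher
# ---------------------------------------------------------------------------

def sum_duplicate_ids(values: pd.DataFrame) -> pd.DataFrame:
    """Sum intensity rows sharing a feature id (pre-aggregation helper)."""
    return values.groupby(level=0, sort=False).sum(min_count=1)


def _directions(ratio: np.ndarray) -> np.ndarray:
    return np.where(ratio >= 1.0, DIRECTION_UP, DIRECTION_DOWN)


def _assemble(layer_kind, ids, **cols) -> pd.DataFrame:
    df = pd.DataFrame({"id": list(ids)})
    df["layer"] = LayerKind(layer_kind).value
    for c in TABLE_COLUMNS[2:]:
        df[c] = cols.get(c, np.nan)
    return df


def _run_count_layer(layer: OmicsLayer, alpha: float, normalize: bool) -> DifferentialTable:
    filtered = filter_transcripts(layer)
    if filtered.values.empty:
        return DifferentialTable(layer.kind, _assemble(layer.kind, [],
                                                       passed_quality=[],
                                                       differential=[]))
    if normalize:
        values, _ = tmm_normalize(filtered)
    else:
        values = filtered.values.astype(float)
    ctrl, trt = filtered.control_samples, filtered.treatment_samples
    t, p = _ttest_rows(values[ctrl].to_numpy(), values[trt].to_numpy())
    m_c = values[ctrl].mean(axis=1).to_numpy()
    m_t = values[trt].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m_t / m_c
    kept = _assemble(
        layer.kind, values.index,
        mean_control=m_c, mean_treatment=m_t, ratio=ratio,
        direction=_directions(ratio), t=t, p=p,
        passed_quality=True, differential=(p < alpha) & ~np.isnan(p),
    )
    dropped_ids = [i for i in layer.values.index if i not in set(values.index)]
    dropped = _assemble(layer.kind, dropped_ids,
                        passed_quality=False, differential=False)
    table = pd.concat([kept, dropped], ignore_index=True)
    table["direction"] = table["direction"].where(table["passed_quality"], other=pd.NA)
    return DifferentialTable(layer.kind, table)


def _run_protein_layer(layer: OmicsLayer, alpha: float) -> DifferentialTable:
    retained, labels = filter_proteins_presence(layer)
    testable_ids = labels.index[labels == "testable"]
    logs = log_transform(retained.values.loc[testable_ids])
    imputed = impute_sequential(logs, retained.groups)
    ctrl, trt = retained.control_samples, retained.treatment_samples
    t, p = _ttest_rows(imputed[ctrl].to_numpy(), imputed[trt].to_numpy())
    m_c = imputed[ctrl].mean(axis=1).to_numpy()
    m_t = imputed[trt].mean(axis=1).to_numpy()
    ratio = np.exp(m_t - m_c)
    rows = [_assemble(
        LayerKind.PROTEIN, testable_ids,
        mean_control=m_c, mean_treatment=m_t, ratio=ratio,
        direction=_directions(ratio), t=t, p=p,
        passed_quality=True, differential=(p < alpha) & ~np.isnan(p),
    )]
    for label, sentinel in ((EXCLUSIVE_TREATMENT, np.inf),
                            (EXCLUSIVE_CONTROL, -np.inf)):
        ids = labels.index[labels == label]
        if len(ids) == 0:
            continue
        obs = log_transform(retained.values.loc[ids])
        cols = trt if label == EXCLUSIVE_TREATMENT else ctrl
        means = obs[cols].mean(axis=1).to_numpy()
        rows.append(_assemble(
            LayerKind.PROTEIN, ids,
            mean_control=(np.nan if label == EXCLUSIVE_TREATMENT else means),
            mean_treatment=(means if label == EXCLUSIVE_TREATMENT else np.nan),
            ratio=sentinel, direction=label,
            passed_quality=True, differential=True,
        ))
    dropped_ids = [i for i in layer.values.index if i not in set(labels.index)]
    rows.append(_assemble(LayerKind.PROTEIN, dropped_ids,
                          passed_quality=False, differential=False))
    return DifferentialTable(LayerKind.PROTEIN, pd.concat(rows, ignore_index=True))


def _run_metabolite_layer(
    layer: OmicsLayer, alpha: float, normalize: bool,
    internal_standard: str | None, vip_threshold: float,
) -> DifferentialTable:
    raw = layer.values
    if raw.isna().any().any():
        raise ValidationError("metabolite testing requires a complete matrix")
    if normalize:
        values = normalize_metabolites(layer, internal_standard)
        log_scale = True
    else:
        values = raw.astype(float)
        log_scale = False
    ctrl, trt = layer.control_samples, layer.treatment_samples
    t, p = _ttest_rows(values[ctrl].to_numpy(), values[trt].to_numpy())
    m_c = values[ctrl].mean(axis=1).to_numpy()
    m_t = values[trt].mean(axis=1).to_numpy()
    if log_scale:
        ratio = 2.0 ** (m_t - m_c)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = m_t / m_c
    vip = pls_vip(values, layer.groups)
    differential = (p < alpha) & ~np.isnan(p) & (vip.to_numpy() > vip_threshold)
    df = _assemble(
        LayerKind.METABOLITE, values.index,
        mean_control=m_c, mean_treatment=m_t, ratio=ratio,
        direction=_directions(ratio), t=t, p=p, vip=vip.to_numpy(),
        passed_quality=True, differential=differential,
    )
    return DifferentialTable(LayerKind.METABOLITE, df)


def run_layer(
    layer: OmicsLayer,
    alpha: float = 0.05,
    normalize: bool = True,
    internal_standard: str | None = None,
    vip_threshold: float = 1.0,
) -> DifferentialTable:
    """Dispatch the layer-appropriate filter/normalize/impute/test chain."""
    kind = layer.kind
    if kind.is_count:
        return _run_count_layer(layer, alpha, normalize)
    if kind == LayerKind.PROTEIN:
        return _run_protein_layer(layer, alpha)
    return _run_metabolite_layer(layer, alpha, normalize, internal_standard,
                                 vip_threshold)
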