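"""Differential-abundance chain: t-tests, TMM, presence filter, imputation,
PLS-VIP and the layer dispatcher, each checked against an independent oracle
where one exists."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from hepomix.kb_model import GROUP_CONTROL, GROUP_TREATMENT, LayerKind, OmicsLayer, ValidationError
from hepomix.differential_abundance import (
    EXCLUSIVE_CONTROL,
    EXCLUSIVE_TREATMENT,
    GroupSummary,
    filter_proteins_presence,
    filter_transcripts,
    impute_sequential,
    log_transform,
    normalize_metabolites,
    pls_vip,
    run_layer,
    select_metabolites,
    sum_duplicate_ids,
    tmm_normalize,
    ttest_equal_var,
    ttest_from_summary,
)
from hepomix.synthetic_data import PlantedPathway, SimConfig, make_knowledge_base, planted_effects, simulate_layers

from conftest import make_layer


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def test_ttest_identical_vectors_is_null():
    t, p = ttest_equal_var([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0


def test_ttest_equal_means_zero_t():
    t, p = ttest_from_summary(GroupSummary("a", 5.0, 1.0, 5),
                              GroupSummary("b", 5.0, 2.0, 5))
    assert t == 0.0 and p == 1.0


def test_ttest_zero_pooled_variance_flagged_not_raised():
    t, p = ttest_equal_var([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
    assert math.isnan(t) and math.isnan(p)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    x=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
    y=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
)
def test_ttest_matches_scipy_and_summary_identity(x, y):
    """Raw-sample and summary-statistic routes agree with each other and with
    an independent implementation to 1e-12."""
    t, p = ttest_equal_var(x, y)
    sx = GroupSummary("x", float(np.mean(x)), float(np.std(x, ddof=1)), len(x))
    sy = GroupSummary("y", float(np.mean(y)), float(np.std(y, ddof=1)), len(y))
    ts, ps = ttest_from_summary(sx, sy)
    if math.isnan(t):
        assert math.isnan(ts)
        return
    assert abs(t - ts) < 1e-12 and abs(p - ps) < 1e-12
    if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
        return  # degenerate: scipy yields nan, the contract yields (0, 1)
    ref = stats.ttest_ind(y, x, equal_var=True)
    assert abs(t - ref.statistic) < 1e-9
    assert abs(p - ref.pvalue) < 1e-9


def test_ttest_p_matches_quadrature_oracle():
    """p-value equals direct numerical integration of the t density."""
    x = (1.0, 2.0, 3.0, 4.0, 5.0)
    y = (2.0, 3.0, 4.0, 5.0, 6.0)
    t, p = ttest_equal_var(x, y)
    df = len(x) + len(y) - 2

    def t_pdf(u):
        c = math.exp(special.gammaln((df + 1) / 2) - special.gammaln(df / 2))
        return c / math.sqrt(df * math.pi) * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(t_pdf, abs(t), np.inf)
    assert abs(p - 2 * tail) < 1e-10


# ---------------------------------------------------------------------------
# zero-count filter and TMM
# ---------------------------------------------------------------------------

def test_filter_transcripts_removes_only_all_zero_rows(count_layer_factory):
    values = np.zeros((3, 10))
    values[1, 4] = 1.0  # a single read anywhere retains the feature
    values[2, :] = 7.0
    out = filter_transcripts(count_layer_factory(values))
    assert out.feature_ids == ["F2", "F3"]


def test_filter_transcripts_empty_layer(count_layer_factory):
    layer = count_layer_factory(np.ones((1, 10)))
    empty = OmicsLayer(layer.kind, layer.values.iloc[:0], dict(layer.groups))
    assert filter_transcripts(empty).values.empty


def test_tmm_identical_samples_unit_factors(count_layer_factory):
    rng = np.random.default_rng(0)
    col = rng.integers(1, 500, size=100).astype(float)
    values = np.tile(col[:, None], (1, 10))
    _, factors = tmm_normalize(count_layer_factory(values))
    assert np.allclose(factors, 1.0)


def test_tmm_depth_scaling_equalizes_samples(count_layer_factory):
    rng = np.random.default_rng(1)
    col = rng.integers(1, 500, size=200).astype(float)
    values = np.tile(col[:, None], (1, 10))
    values[:, 5:] *= 2.0  # treatment samples sequenced twice as deep
    cpm, _ = tmm_normalize(count_layer_factory(values))
    assert np.allclose(cpm.iloc[:, 0], cpm.iloc[:, 5], atol=1e-9)


def test_tmm_rejects_all_zero_sample(count_layer_factory):
    values = np.ones((5, 10))
    values[:, 3] = 0.0
    with pytest.raises(ValidationError, match="all-zero"):
        tmm_normalize(count_layer_factory(values))


def _tmm_reference_factors(counts, trim_m=0.30, trim_a=0.05):
    """Independent literal transcription of the TMM factor computation."""
    n_feat, n_samp = counts.shape
    lib = [sum(counts[i][j] for i in range(n_feat)) for j in range(n_samp)]
    uq = [np.percentile(counts[:, j], 75) for j in range(n_samp)]
    mean_uq = sum(uq) / n_samp
    ref = min(range(n_samp), key=lambda j: abs(uq[j] - mean_uq))
    logf = [0.0] * n_samp
    for j in range(n_samp):
        if j == ref:
            continue
        ms, as_, ws = [], [], []
        for i in range(n_feat):
            x, r = counts[i][j], counts[i][ref]
            if x > 0 and r > 0:
                px, pr = x / lib[j], r / lib[ref]
                ms.append(math.log2(px / pr))
                as_.append(0.5 * math.log2(px * pr))
                ws.append(1.0 / ((lib[j] - x) / (lib[j] * x)
                                 + (lib[ref] - r) / (lib[ref] * r)))
        n = len(ms)
        order_m = sorted(range(n), key=lambda i: (ms[i], i))
        order_a = sorted(range(n), key=lambda i: (as_[i], i))
        rank_m = {idx: pos + 1 for pos, idx in enumerate(order_m)}
        rank_a = {idx: pos + 1 for pos, idx in enumerate(order_a)}
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += ws[i] * ms[i]
                den += ws[i]
        logf[j] = num / den if den else 0.0
    centre = sum(logf) / n_samp
    return [2.0 ** (f - centre) for f in logf]


def test_tmm_matches_independent_transcription(count_layer_factory):
    rng = np.random.default_rng(42)
    counts = rng.negative_binomial(5, 0.01, size=(200, 6)).astype(float)
    counts[counts == 0] += rng.integers(0, 2, size=(counts == 0).sum())
    layer = make_layer(
        LayerKind.TRANSCRIPT, counts,
        {f"S{i}": (GROUP_CONTROL if i < 3 else GROUP_TREATMENT) for i in range(6)},
    )
    _, factors = tmm_normalize(layer)
    expected = _tmm_reference_factors(layer.values.to_numpy())
    assert np.allclose(factors.to_numpy(), expected, atol=1e-8)
    assert abs(np.exp(np.mean(np.log(factors))) - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# protein presence filter, log transform, imputation
# ---------------------------------------------------------------------------

def _protein_layer(presence_ctrl, presence_trt, groups):
    """One protein with given per-group observation counts plus a complete
    backbone so that group sizes are valid."""
    rng = np.random.default_rng(5)
    values = rng.lognormal(13, 0.3, size=(6, 10))
    row = values[0].copy()
    row[presence_ctrl:5] = np.nan
    row[5 + presence_trt:] = np.nan
    values[0] = row
    return make_layer(LayerKind.PROTEIN, values, groups, feature_prefix="P")


@pytest.mark.parametrize("obs_c,obs_t,expected", [
    (3, 4, "testable"),
    (5, 0, EXCLUSIVE_CONTROL),
    (0, 5, EXCLUSIVE_TREATMENT),
    (2, 5, None),   # fails both branches: dropped
    (4, 2, None),
])
def test_presence_filter_branches(groups_5v5, obs_c, obs_t, expected):
    layer = _protein_layer(obs_c, obs_t, groups_5v5)
    retained, labels = filter_proteins_presence(layer)
    if expected is None:
        assert "P1" not in labels.index
    else:
        assert labels["P1"] == expected


def test_log_transform_values_and_missing(groups_5v5):
    values = np.full((2, 10), math.e)
    values[0, 0] = 1.0
    values[1, 3] = np.nan
    layer = make_layer(LayerKind.PROTEIN, values, groups_5v5, feature_prefix="P")
    out = log_transform(layer)
    assert out.iloc[0, 0] == 0.0
    assert math.isnan(out.iloc[1, 3])
    assert np.allclose(out.iloc[0, 1:], 1.0)
    layer.values.iloc[0, 1] = 0.0
    with pytest.raises(ValidationError, match="positive"):
        log_transform(layer)


def test_impute_identity_on_complete_data(groups_5v5):
    rng = np.random.default_rng(2)
    values = pd.DataFrame(rng.normal(10, 1, size=(20, 10)),
                          columns=list(groups_5v5))
    out = impute_sequential(values, groups_5v5)
    pd.testing.assert_frame_equal(out, values)


def test_impute_single_cell_constant_neighbours_gives_group_mean(groups_5v5):
    values = pd.DataFrame(np.full((3, 10), 4.0), columns=list(groups_5v5))
    values.iloc[0] = [1.0, 2.0, 3.0, 4.0, np.nan, 7.0, 7.0, 7.0, 7.0, 7.0]
    out = impute_sequential(values, groups_5v5)
    assert out.iloc[0, 4] == pytest.approx(2.5)  # mean of 1,2,3,4


def test_impute_never_alters_observed_cells(groups_5v5):
    rng = np.random.default_rng(3)
    values = pd.DataFrame(rng.normal(10, 1, size=(30, 10)),
                          columns=list(groups_5v5))
    mask = rng.random(values.shape) < 0.08
    mask[mask.sum(axis=1) > 2] = False
    holed = values.mask(pd.DataFrame(mask, columns=values.columns))
    out = impute_sequential(holed, groups_5v5)
    observed = ~holed.isna()
    assert np.array_equal(out[observed].to_numpy(), holed[observed].to_numpy(),
                          equal_nan=True)
    assert not out.isna().any().any()


def test_impute_rejects_excess_missingness(groups_5v5):
    values = pd.DataFrame(np.full((2, 10), 5.0), columns=list(groups_5v5))
    values.iloc[0, 0:3] = np.nan  # 3 missing of 5 in the control group
    with pytest.raises(ValidationError, match="F1"):
        impute_sequential(values.set_axis(["F1", "F2"]), groups_5v5)


def test_impute_beats_group_mean_on_correlated_data(groups_5v5):
    """Sequential regression imputation exploits between-feature correlation
    that group-mean imputation ignores (oracle: the masked ground truth)."""
    errors_reg, errors_mean = [], []
    for seed in range(6):
        rng = np.random.default_rng(100 + seed)
        n_feat = 50
        load = rng.uniform(0.8, 1.2, n_feat) * rng.choice([-1, 1], n_feat)
        truth = np.empty((n_feat, 10))
        for g, cols in ((0, slice(0, 5)), (1, slice(5, 10))):
            f = rng.normal(0, 1, 5)
            truth[:, cols] = 10 + np.outer(load, f) + rng.normal(0, 0.15, (n_feat, 5))
        mask = rng.random((n_feat, 10)) < 0.08
        for cols in (slice(0, 5), slice(5, 10)):
            blk = mask[:, cols]
            blk[blk.sum(axis=1) > 2] = False
        df = pd.DataFrame(np.where(mask, np.nan, truth), columns=list(groups_5v5))
        est = impute_sequential(df, groups_5v5).to_numpy()
        group_means = np.column_stack([
            np.repeat(np.nanmean(df.iloc[:, :5], axis=1)[:, None], 5, axis=1),
            np.repeat(np.nanmean(df.iloc[:, 5:], axis=1)[:, None], 5, axis=1),
        ])
        errors_reg.append(np.abs(est[mask] - truth[mask]).mean())
        errors_mean.append(np.abs(group_means[mask] - truth[mask]).mean())
    assert np.mean(errors_reg) < np.mean(errors_mean)


# ---------------------------------------------------------------------------
# metabolites: PLS-VIP and selection
# ---------------------------------------------------------------------------

def test_vip_single_feature_is_one(groups_5v5):
    rng = np.random.default_rng(4)
    values = pd.DataFrame(rng.normal(0, 1, size=(1, 10)), columns=list(groups_5v5))
    vip = pls_vip(values, groups_5v5)
    assert vip.iloc[0] == pytest.approx(1.0)


def test_vip_mean_square_is_one(groups_5v5):
    rng = np.random.default_rng(5)
    values = pd.DataFrame(rng.normal(0, 1, size=(40, 10)), columns=list(groups_5v5))
    vip = pls_vip(values, groups_5v5)
    assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-9)


def test_vip_signal_above_one_noise_below(groups_5v5):
    """With one pure group separator and one pure noise feature, the
    separator's VIP exceeds 1 and the noise feature's falls below 1
    (brute-force simulation check)."""
    rng = np.random.default_rng(6)
    hits = 0
    for _ in range(20):
        y = np.array([0] * 5 + [1] * 5, dtype=float)
        signal = y * 3 + rng.normal(0, 0.2, 10)
        noise = rng.normal(0, 1, 10)
        values = pd.DataFrame([signal, noise], columns=list(groups_5v5))
        vip = pls_vip(values, groups_5v5)
        hits += vip.iloc[0] > 1 > vip.iloc[1]
    assert hits >= 19


def test_vip_matches_sklearn_pls_weights(groups_5v5):
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    rng = np.random.default_rng(7)
    values = pd.DataFrame(rng.normal(0, 1, size=(15, 10)), columns=list(groups_5v5))
    values.iloc[0] += np.array([0] * 5 + [2] * 5)
    vip = pls_vip(values, groups_5v5)
    pls = sklearn.PLSRegression(n_components=1, scale=True)
    x = values.to_numpy().T
    y = np.array([0.0] * 5 + [1.0] * 5)
    pls.fit(x, y)
    w = pls.x_weights_[:, 0]
    expected = math.sqrt(len(w)) * np.abs(w) / np.linalg.norm(w)
    assert np.allclose(vip.to_numpy(), expected, atol=1e-8)


def test_vip_zero_variance_feature_warns(groups_5v5):
    rng = np.random.default_rng(8)
    values = pd.DataFrame(rng.normal(0, 1, size=(3, 10)), columns=list(groups_5v5))
    values.iloc[1] = 7.0
    with pytest.warns(UserWarning, match="zero-variance"):
        vip = pls_vip(values, groups_5v5)
    assert vip.iloc[1] == 0.0


@pytest.mark.parametrize("vip,p,expected", [
    (1.2, 0.01, True),
    (0.9, 0.001, False),
    (1.2, 0.06, False),
])
def test_select_metabolites_requires_both_criteria(vip, p, expected):
    idx = pd.Index(["M1"])
    table = select_metabolites(pd.Series([vip], index=idx),
                               pd.Series([p], index=idx),
                               pd.Series([2.0], index=idx))
    assert bool(table.table["differential"].iloc[0]) is expected


def test_normalize_metabolites_median_and_internal_standard(groups_5v5):
    rng = np.random.default_rng(9)
    values = rng.lognormal(5, 0.5, size=(20, 10))
    layer = make_layer(LayerKind.METABOLITE, values, groups_5v5, feature_prefix="M")
    out = normalize_metabolites(layer, internal_standard="M1")
    assert "M1" not in out.index
    back = 2.0 ** out
    medians = back.median(axis=0)
    assert np.allclose(medians, medians.iloc[0])


def test_sum_duplicate_ids():
    df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [5.0, np.nan]],
                      index=["A", "A", "B"], columns=["s1", "s2"])
    out = sum_duplicate_ids(df)
    assert out.loc["A"].tolist() == [4.0, 6.0]
    assert out.loc["B", "s1"] == 5.0 and math.isnan(out.loc["B", "s2"])


# ---------------------------------------------------------------------------
# layer dispatcher
# ---------------------------------------------------------------------------

def test_run_layer_marks_exclusive_proteins(groups_5v5):
    layer = _protein_layer(0, 5, groups_5v5)
    table = run_layer(layer).table.set_index("id")
    assert table.loc["P1", "direction"] == EXCLUSIVE_TREATMENT
    assert bool(table.loc["P1", "differential"])
    assert math.isinf(table.loc["P1", "ratio"]) and table.loc["P1", "ratio"] > 0
    assert math.isnan(table.loc["P1", "t"])


def test_run_layer_planted_transcript_power():
    """Strongly planted features (log2 FC 2, all members affected) are
    detected at high rate at n = 5 per group (simulation oracle)."""
    rates = []
    for seed in range(10):
        cfg = SimConfig(
            seed=500 + seed, n_transcripts=300, n_proteins=100,
            n_metabolites=40, n_mirnas=40, n_pathways=4,
            pathway_size_range=(10, 14), n_regulators=1,
            targets_per_regulator=5,
            planted_pathways=[PlantedPathway("PW01", 2.0, 1.0)],
            planted_regulators=[], n_planted_mirnas=0, n_exclusive_proteins=0,
        )
        kb = make_knowledge_base(cfg)
        truth = planted_effects(cfg, kb)
        layer = simulate_layers(cfg, kb)[LayerKind.TRANSCRIPT]
        table = run_layer(layer).table.set_index("id")
        planted = [m for m, v in truth.lfc.items() if m in table.index and v != 0]
        rates.append(table.loc[planted, "differential"].mean())
    assert np.mean(rates) > 0.8


def test_run_layer_dropped_features_not_differential(count_layer_factory):
    values = np.random.default_rng(10).integers(0, 50, size=(30, 10)).astype(float)
    values[0] = 0.0
    table = run_layer(count_layer_factory(values)).table.set_index("id")
    assert not table.loc["F1", "passed_quality"]
    assert not table.loc["F1", "differential"]
    assert len(table) == 30
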