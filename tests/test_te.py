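"""TE computation, consistency filter, category thresholds."""

import pandas as pd
import pytest

from quadte.te import (categorize, compute_te, consistency_filter,
                       stringent_te_down)


def _table(rows):
    cols = ["gene_id"] + [f"{f}_{c}_{r}" for f in ("total", "polysome")
                          for c in ("ctrl", "ko") for r in ("rep1", "rep2")]
    return pd.DataFrame(rows, columns=cols)


def _gene(gene, te_ctrl=1.0, te_ko=1.0, base=10.0, d_mrna=1.0):
    """Noise-free gene, both replicates identical; te_ko is the TE fold change.

    Column order: total ctrl r1/r2, total ko r1/r2, polysome ctrl r1/r2,
    polysome ko r1/r2.
    """
    tot_ctrl, tot_ko = base, base * d_mrna
    poly_ctrl = base * te_ctrl
    poly_ko = base * d_mrna * te_ctrl * te_ko
    return [gene, tot_ctrl, tot_ctrl, tot_ko, tot_ko,
            poly_ctrl, poly_ctrl, poly_ko, poly_ko]


def _full(rows):
    df = compute_te(_table(rows))
    return categorize(consistency_filter(df))


def test_te_ratio_basic():
    # polysome 10 / total 5 -> TE = 2
    df = compute_te(_table([_gene("g1", te_ctrl=2.0, base=5.0)]))
    assert df.loc["g1", "te_ctrl"] == pytest.approx(2.0)
    # TE_ctrl = 2, TE_KO = 1 -> delta 0.5, log2 -1
    df2 = compute_te(_table([_gene("g2", te_ctrl=2.0, te_ko=0.5)]))
    assert df2.loc["g2", "delta_te"] == pytest.approx(0.5)
    assert df2.loc["g2", "log2_delta_te"] == pytest.approx(-1.0)


def test_zero_denominator_flagged():
    row = _gene("g1")
    row[1] = 0.0  # total_ctrl_rep1
    df = compute_te(_table([row]))
    assert not bool(df.loc["g1", "defined"])
    filt = consistency_filter(df)
    assert not bool(filt.loc["g1", "consistent_trend"])


def test_missing_column_schema_error():
    bad = _table([_gene("g1")]).drop(columns=["polysome_ko_rep2"])
    with pytest.raises(KeyError):
        compute_te(bad)


def test_consistency_filter_directions():
    rows = [_gene("both_up", te_ko=1.5), _gene("both_down", te_ko=0.5),
            _gene("flat", te_ko=1.0)]
    df = _full(rows)
    assert bool(df.loc["both_up", "consistent_trend"])
    assert bool(df.loc["both_down", "consistent_trend"])
    # delta TE exactly 1 has sign zero -> not consistent
    assert not bool(df.loc["flat", "consistent_trend"])


def test_consistency_filter_discordant_replicates():
    row = ["g", 10, 10, 10, 10, 10, 10, 15, 5]  # KO TE: rep1 1.5 (up), rep2 0.5 (down)
    df = consistency_filter(compute_te(_table([row])))
    assert not bool(df.loc["g", "consistent_trend"])


def test_single_replicate_bypasses_filter():
    cols = ["gene_id"] + [f"{f}_{c}_r" for f in ("total", "polysome") for c in ("ctrl", "ko")]
    df = pd.DataFrame([["g", 10, 10, 10, 5]], columns=cols)
    out = compute_te(df, replicates=("r",))
    with pytest.warns(UserWarning):
        out = consistency_filter(out, replicates=("r",))
    assert bool(out.loc["g", "consistent_trend"])


@pytest.mark.parametrize("fold,cat", [
    (1.5, "up"),        # inclusive
    (1.51, "up"),
    (1.49, "unchanged"),
    (1.0, "unchanged"),
    (0.67, "unchanged"),
    (0.66, "down"),     # inclusive
    (0.4, "down"),
])
def test_category_thresholds(fold, cat):
    df = _full([_gene("g", te_ko=fold)])
    if cat == "unchanged" and fold == 1.0:
        assert df.loc["g", "te_category"] is pd.NA  # flat genes fail consistency
    else:
        assert df.loc["g", "te_category"] == cat


def test_expressed_filter_boundary():
    low = _gene("low", base=0.5)
    high = _gene("high", base=5.0)
    df = _full([low, high])
    assert not bool(df.loc["low", "expressed"])   # 0.5 FPKM in both conditions
    assert bool(df.loc["high", "expressed"])


@pytest.mark.parametrize("te_ko,d_mrna,included", [
    (0.45, 1.0, True),    # log2(0.45) ~ -1.15 < -1, mRNA constant
    (0.5, 1.0, False),    # log2 = -1 exactly: strict
    (0.25, 1.9, False),   # mRNA not constant (log2(1.9) ~ 0.93)
    (0.45, 1.4, True),    # log2(1.4) ~ 0.49 <= 0.585
])
def test_stringent_te_down(te_ko, d_mrna, included):
    df = _full([_gene("g", te_ko=te_ko, d_mrna=d_mrna)])
    assert (("g" in stringent_te_down(df)) is included)


def test_scale_invariance():
    rows = [_gene("g", te_ko=0.5, base=8.0)]
    df1 = _full(rows)
    scaled = _table(rows)
    for col in scaled.columns:
        if col.endswith(("ko_rep1", "ko_rep2")):
            scaled[col] *= 37.0  # scale the whole KO condition, both fractions
    df2 = categorize(consistency_filter(compute_te(scaled)))
    assert df1.loc["g", "delta_te"] == pytest.approx(df2.loc["g", "delta_te"])


def test_planted_category_recovery_noise_free(small_dataset):
    """In the noise-free limit planted categories are reproduced exactly."""
    from quadte.synth import SyntheticConfig, generate

    cfg = SyntheticConfig(seed=5, n_genes=20, n_utr5_rg4_bound=5,
                          n_cds_bound=1, n_utr3_are_bound=3, sigma_rep=0.0)
    ds = generate(cfg)
    df = categorize(consistency_filter(compute_te(ds.fpkm)))
    for gene, t in ds.ground_truth.items():
        if t["te_category"] == "down":
            assert df.loc[gene, "te_category"] == "down"
            assert gene in stringent_te_down(df)
        if t["mrna_category"] == "down":
            # the mRNA fold change itself is exact; the gene only receives a
            # category if it passed the TE consistency filter (flat TE has
            # sign 0 in the noise-free limit, so it is excluded by design)
            assert df.loc[gene, "delta_mrna"] == pytest.approx(0.4)
            if bool(df.loc[gene, "consistent_trend"]):
                assert df.loc[gene, "mrna_category"] == "down"


def test_planted_recovery_error_decreases_with_noise(rng):
    from quadte.synth import SyntheticConfig, generate

    errs = []
    for sigma in (0.3, 0.05):
        cfg = SyntheticConfig(seed=9, n_genes=40, n_utr5_rg4_bound=10,
                              n_cds_bound=0, n_utr3_are_bound=0, sigma_rep=sigma)
        ds = generate(cfg)
        df = categorize(consistency_filter(compute_te(ds.fpkm)))
        wrong = sum(
            1 for g, t in ds.ground_truth.items()
            if t["te_category"] == "down"
            and not (isinstance(df.loc[g, "te_category"], str)
                     and df.loc[g, "te_category"] == "down")
        )
        errs.append(wrong)
    assert errs[1] <= errs[0]
    assert errs[1] == 0
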