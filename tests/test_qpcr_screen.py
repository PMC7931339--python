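"""Screening layer: Cq IO, detection, MA statistics, normalization, cutoff."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.nonparametric.smoothers_lowess import lowess

from placmir.qpcr_screen import (
    CqMatrix,
    FitError,
    adaptive_cutoff,
    classify_and_summarize,
    compute_MA,
    cyclic_loess_normalize,
    detect_calls,
    quantile_pinball_lp,
    read_cq_table,
    round_half_up,
    venn_from_counts,
    write_cq_table,
    _poly_design,
)
from placmir.synthetic import simulate_cq_array


# ---------------------------------------------------------------------------
# IO


def test_read_cq_table_parses_undetermined(tmp_path, toy_cq_frame):
    p = tmp_path / "cq.tsv"
    p.write_text(
        "assay_id\tplate\tgroup\tcq\n"
        "a1\tA\tCon\t20.0\na1\tA\tN3\t21.5\n"
        "a2\tB\tCon\tUndetermined\na2\tB\tN3\t30.0\n"
    )
    cq = read_cq_table(p)
    assert cq.data["undetermined"].sum() == 1
    assert cq.data.loc[cq.data["undetermined"], "assay_id"].item() == "a2"


def test_read_cq_table_errors(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("assay_id,plate,cq\na1,A,20\n")
    with pytest.raises(ValueError, match="missing required column"):
        read_cq_table(p)
    p2 = tmp_path / "bad2.csv"
    p2.write_text("assay_id,plate,group,cq\na1,A,Con,twenty\n")
    with pytest.raises(ValueError, match="row 2.*twenty"):
        read_cq_table(p2)


def test_duplicate_assay_group_rejected(toy_cq_frame):
    dup = pd.concat([toy_cq_frame, toy_cq_frame.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        CqMatrix(dup)


def test_roundtrip_bit_exact(tmp_path, toy_cq_frame):
    cq = CqMatrix(toy_cq_frame)
    p = tmp_path / "out.tsv"
    write_cq_table(cq, p)
    back = read_cq_table(p)
    pd.testing.assert_frame_equal(
        back.data, cq.data.reset_index(drop=True), check_exact=True
    )


# ---------------------------------------------------------------------------
# detection and MA


def test_detection_rule(toy_cq_frame):
    det = detect_calls(CqMatrix(toy_cq_frame), cq_max=40.0)
    assert det.loc["a1", "detected_con"] and det.loc["a1", "detected_n3"]
    assert not det.loc["a2", "detected_con"]  # undetermined
    # strict inequality at the threshold
    frame = toy_cq_frame.copy()
    frame.loc[0, "cq"] = 40.0
    det2 = detect_calls(CqMatrix(frame), cq_max=40.0)
    assert not det2.loc["a1", "detected_con"]


@pytest.mark.parametrize(
    "con, n3, m_exp, a_exp, fc_exp",
    [
        (20.0, 20.0, 0.0, 20.0, 1.0),
        (18.0, 17.0, 1.0, 17.5, 2.0),
        (17.0, 18.0, -1.0, 17.5, -2.0),
    ],
)
def test_compute_ma_examples(con, n3, m_exp, a_exp, fc_exp):
    m, a, fc = compute_MA(con, n3)
    assert m == pytest.approx(m_exp)
    assert a == pytest.approx(a_exp)
    assert fc == pytest.approx(fc_exp)


def test_signed_fc_down_encoding():
    # M = -3.5176 should print as about -11.45 (down-regulated fold)
    m, _, fc = compute_MA(20.0, 23.5176)
    assert m == pytest.approx(-3.5176)
    assert fc == pytest.approx(-(2.0 ** 3.5176))
    assert round(fc, 2) == -11.45


def test_compute_ma_requires_both_detected():
    with pytest.raises(ValueError):
        compute_MA(20.0, float("nan"))


# ---------------------------------------------------------------------------
# normalization


def test_loess_constant_goes_to_zero():
    rng = np.random.default_rng(0)
    A = rng.uniform(14, 36, 100)
    M = np.full(100, 3.7)
    out = cyclic_loess_normalize(M, A, np.repeat("A", 100))
    assert np.max(np.abs(out)) < 1e-6


def test_loess_removes_planted_quadratic_trend():
    rng = np.random.default_rng(1)
    A = rng.uniform(14, 36, 400)
    f = 0.02 * (A - 25.0) ** 2 - 0.5
    M = f + rng.normal(0, 0.2, 400)
    out = cyclic_loess_normalize(M, A, np.repeat("A", 400))
    # independent smoother oracle: a lowess refit of the residual is flat
    refit = lowess(out, A, frac=0.7, it=0, return_sorted=False)
    assert np.max(np.abs(refit)) < 0.1 * np.max(np.abs(f))


def test_loess_per_plate_centering():
    rng = np.random.default_rng(2)
    A = rng.uniform(14, 36, 200)
    plate = np.where(np.arange(200) % 2 == 0, "A", "B")
    M = np.where(plate == "A", 1.0, -2.0) + rng.normal(0, 0.1, 200)
    out = cyclic_loess_normalize(M, A, plate)
    assert abs(out[plate == "A"].mean()) < 0.05
    assert abs(out[plate == "B"].mean()) < 0.05


def test_loess_idempotent_and_nan_passthrough():
    rng = np.random.default_rng(3)
    A = rng.uniform(14, 36, 300)
    M = 0.1 * (A - 25.0) + rng.normal(0, 0.3, 300)
    M[10] = np.nan
    once = cyclic_loess_normalize(M, A, np.repeat("A", 300))
    twice = cyclic_loess_normalize(once, A, np.repeat("A", 300))
    assert np.isnan(once[10])
    ok = ~np.isnan(once)
    assert np.max(np.abs(twice[ok] - once[ok])) < 1e-6


def test_loess_small_plate_falls_back_to_median():
    A = np.linspace(20, 30, 5)
    M = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    with pytest.warns(UserWarning, match="median-centering"):
        out = cyclic_loess_normalize(M, A, np.repeat("A", 5))
    assert out == pytest.approx(M - 3.0)


# ---------------------------------------------------------------------------
# adaptive cutoff


def test_outlier_flagged_above():
    rng = np.random.default_rng(4)
    A = rng.uniform(14, 36, 200)
    M = rng.normal(0, 0.3, 200)
    M[17] = 10 * 0.3
    _, _, flags = adaptive_cutoff(M, A)
    assert flags[17] == "above"


def test_null_flag_fraction_binomial_bound():
    rng = np.random.default_rng(5)
    n = 500
    A = rng.uniform(14, 36, n)
    M = rng.normal(0, 1.0, n)
    _, _, flags = adaptive_cutoff(M, A)
    frac = np.mean((flags == "above") | (flags == "below"))
    assert abs(frac - 0.10) <= 3 * np.sqrt(0.1 * 0.9 / n)


@pytest.mark.parametrize("tau", [0.05, 0.95])
def test_quantile_fit_matches_lp_oracle_and_coverage(tau):
    """IRLS quantile fit reaches the LP optimum of the pinball loss (n=50)."""
    rng = np.random.default_rng(6)
    n = 50
    A = rng.uniform(14, 36, n)
    M = 0.05 * (A - 25.0) + rng.normal(0, 0.5, n)
    q_low, q_high, _ = adaptive_cutoff(M, A, taus=(0.05, 0.95))
    curve = q_low if tau == 0.05 else q_high

    center, scale = A.mean(), A.std()
    X = _poly_design(A, 2, center, scale)
    beta_lp = quantile_pinball_lp(M, X, tau)
    oracle = X @ beta_lp

    def pinball(resid):
        return np.sum(np.where(resid >= 0, tau * resid, (tau - 1) * resid))

    assert pinball(M - curve) <= pinball(M - oracle) * (1 + 1e-6) + 1e-9
    frac_below = np.mean(M < curve)
    assert abs(frac_below - tau) <= 3.0 / n  # 3 coefficients


def test_adaptive_cutoff_degenerate_inputs():
    with pytest.raises(ValueError, match=">= 10"):
        adaptive_cutoff([0.0] * 5, [20.0] * 5)
    with pytest.raises(FitError, match="collinear"):
        adaptive_cutoff(np.random.default_rng(0).normal(size=20), np.full(20, 25.0))


# ---------------------------------------------------------------------------
# classification and Venn arithmetic


def test_venn_from_counts_inclusion_exclusion():
    v = venn_from_counts(667, 488, 499, 483, n_up=12, n_down=13,
                         n_unique_con_diff=5, n_unique_n3_diff=16)
    assert v.n_union == 504
    assert v.n_diff_common == 25
    assert v.n_diff_total == 46
    assert v.percentages["union"] == 75.6
    assert v.percentages["diff_total"] == 6.9


def test_identical_groups_yield_no_differential():
    rng = np.random.default_rng(7)
    ids = [f"a{i}" for i in range(60)]
    cqs = rng.uniform(15, 35, 60)
    rows = []
    for g in ("Con", "N3"):
        for i, a in enumerate(ids):
            rows.append({"assay_id": a, "plate": "AB"[i % 2], "group": g,
                         "cq": cqs[i], "undetermined": False})
    res, venn = classify_and_summarize(CqMatrix(pd.DataFrame(rows)))
    assert venn.n_unique_con == venn.n_unique_n3 == 0
    assert venn.n_diff_common == 0
    assert all(r.call == "unchanged" for r in res)


def test_summary_matches_set_arithmetic_oracle():
    cq, _ = simulate_cq_array(n_assays=40, noise_sd=0.4,
                              base_cq_range=(25, 41), dropout_midpoint=36,
                              dropout_scale=1.0, seed=11)
    res, venn = classify_and_summarize(cq)
    det = detect_calls(cq)
    con = set(det.index[det["detected_con"]])
    n3 = set(det.index[det["detected_n3"]])
    assert venn.n_det_con == len(con)
    assert venn.n_det_n3 == len(n3)
    assert venn.n_common == len(con & n3)
    assert venn.n_union == len(con | n3)
    assert venn.n_unique_con == len(con - n3)
    assert venn.n_unique_n3 == len(n3 - con)
    by_call = {r.assay_id: r.call for r in res}
    assert {a for a in by_call if by_call[a] == "con_only"} == con - n3
    assert {a for a in by_call if by_call[a] == "n3_only"} == n3 - con


def test_sign_coherence_invariant():
    cq, _ = simulate_cq_array(n_assays=300, seed=13,
                              de_spec={"n": 8, "delta": 2.5, "cq_window": (18, 30)})
    res, _ = classify_and_summarize(cq)
    for r in res:
        if r.call == "up":
            assert r.M_norm > r.q_high and r.signed_fc > 1
        elif r.call == "down":
            assert r.M_norm < r.q_low and r.signed_fc < -1


def test_power_monotonic_in_effect_size():
    rates = []
    for delta in (1.0, 2.0, 3.0):
        hits = tot = 0
        for seed in range(3):
            cq, truth = simulate_cq_array(
                n_assays=300, seed=seed,
                de_spec={"n": 10, "delta": delta, "cq_window": (18, 30)},
            )
            res, _ = classify_and_summarize(cq)
            call = {r.assay_id: r.call for r in res}
            for a in truth.planted_de:
                tot += 1
                hits += call[a] == "up"
        rates.append(hits / tot)
    assert rates[0] <= rates[1] <= rates[2]


def test_round_half_up_matches_printed_style():
    assert round_half_up(75.55, 1) == 75.6
    assert round_half_up(6.85, 1) == 6.9
    assert round_half_up(72.44, 1) == 72.4
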