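"""In silico flow cytometry: thresholds, the 8-gate table, Youden alignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gaussian_kde

from lineagewave.gating import (
    GATE_LABELS,
    GateScheme,
    NoValleyError,
    align_gates_to_pseudotime,
    apply_gate_scheme,
    log_denoised,
    proportion_log_enrichment,
    suggest_threshold_density,
)


# ---------------------------------------------------------------------------
# log transform


def test_log_denoised_basics():
    x = np.array([[0.0, 1.0], [3.0, 7.0]])
    out = log_denoised(x)
    assert out[0, 0] == 0.0
    assert (np.diff(out.ravel()[np.argsort(x.ravel())]) >= 0).all()
    assert np.array_equal(log_denoised(x, already_log=True), x)
    with pytest.raises(ValueError, match="negative"):
        log_denoised(np.array([[-1.0]]))


# ---------------------------------------------------------------------------
# density-valley thresholds


def test_threshold_falls_between_well_separated_modes():
    rng = np.random.default_rng(0)
    values = np.concatenate([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
    thr = suggest_threshold_density(values)
    assert 2 < thr < 8


def test_threshold_matches_brute_force_kde_minimiser():
    rng = np.random.default_rng(1)
    values = np.concatenate([rng.normal(0, 1.2, 400), rng.normal(4, 1.2, 400)])
    bw = 0.25
    thr = suggest_threshold_density(values, bw_method=bw, grid_size=512)
    kde = gaussian_kde(values, bw_method=bw)
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    # brute force: global minimum between the two highest local maxima
    from scipy.signal import argrelextrema
    maxima = argrelextrema(dens, np.greater)[0]
    top2 = np.sort(maxima[np.argsort(dens[maxima])[-2:]])
    brute = grid[top2[0] + np.argmin(dens[top2[0]:top2[1] + 1])]
    assert abs(thr - brute) <= (grid[1] - grid[0]) + 1e-12


def test_constant_and_unimodal_inputs_report_no_valley():
    with pytest.raises(NoValleyError):
        suggest_threshold_density(np.full(200, 3.0))
    rng = np.random.default_rng(2)
    with pytest.raises(NoValleyError) as err:
        suggest_threshold_density(rng.normal(5, 1, 1000), bw_method=0.5)
    assert err.value.mode is not None and 4 < err.value.mode < 6


def test_too_few_values_is_an_error():
    with pytest.raises(ValueError, match="100"):
        suggest_threshold_density(np.arange(50))


# ---------------------------------------------------------------------------
# gate scheme


def _scheme():
    return GateScheme(
        thresholds={"CD4": 1.0, "CD8a": 2.0, "TCRb": 1.0, "CD69": 1.0,
                    "CD127": 1.0},
        cd8_lo_floor=0.5,
    )


def _cells(rows):
    return pd.DataFrame(rows, columns=["CD4", "CD8a", "TCRb", "CD69", "CD127"])


@pytest.mark.parametrize("row, expected", [
    ([2.0, 3.0, 2.0, 2.0, 2.0], "DP3"),       # DP, TCRbhi, CD69+CD127+
    ([2.0, 3.0, 0.0, 0.0, 0.0], "DP1"),       # DP, CD69lo CD127lo
    ([2.0, 3.0, 0.0, 2.0, 0.0], "DP2"),       # DP, CD69+ CD127lo
    ([2.0, 1.2, 2.0, 2.0, 0.0], "CD4+CD8lo"), # CD8 between floor and threshold
    ([2.0, 0.1, 2.0, 2.0, 2.0], "CD4 SM"),
    ([2.0, 0.1, 2.0, 0.0, 2.0], "CD4 Mature"),
    ([0.0, 3.0, 2.0, 2.0, 2.0], "CD8 SM"),
    ([0.0, 3.0, 2.0, 0.0, 2.0], "CD8 Mature"),
    ([0.0, 0.1, 0.0, 0.0, 0.0], "ungated"),
    ([2.0, 3.0, 0.0, 2.0, 2.0], "ungated"),   # DP CD69+CD127+ but TCRb low
])
def test_decision_table_assigns_the_published_populations(row, expected):
    labels = apply_gate_scheme(_cells([row]), _scheme())
    assert labels[0] == expected


def test_value_exactly_at_threshold_counts_positive():
    labels = apply_gate_scheme(_cells([[1.0, 2.0, 1.0, 1.0, 1.0]]), _scheme())
    assert labels[0] == "DP3"


def test_missing_marker_is_named_in_the_error():
    df = _cells([[1, 1, 1, 1, 1]]).drop(columns=["CD69"])
    with pytest.raises(ValueError, match="CD69"):
        apply_gate_scheme(df, _scheme())


def test_scheme_resolves_exactly_eight_populations():
    """All marker sign patterns map to the 8 labels or 'ungated'."""
    rows = []
    for cd4 in (0.0, 2.0):
        for cd8 in (0.1, 1.2, 3.0):   # neg / lo / hi
            for tcrb in (0.0, 2.0):
                for cd69 in (0.0, 2.0):
                    for cd127 in (0.0, 2.0):
                        rows.append([cd4, cd8, tcrb, cd69, cd127])
    labels = apply_gate_scheme(_cells(rows), _scheme())
    assert set(labels) - {"ungated"} == set(GATE_LABELS)
    assert _scheme().n_populations() == 8


def test_gate_labels_recover_true_stages(pipeline_run, truth_arrays):
    _, _, state = pipeline_run
    gates = state["gate_labels"]
    assert (gates == truth_arrays["stage"]).mean() >= 0.85


def test_gate_timeline_follows_the_developmental_ordering(pipeline_run,
                                                          truth_arrays):
    _, _, state = pipeline_run
    traj = state["traj"]
    gates = np.asarray(state["gate_labels"], dtype=object)
    label = np.asarray(state["lineage_label"], dtype=object)
    expectations = {
        "CD4": ["DP1", "DP2", "CD4+CD8lo", "CD4 SM", "CD4 Mature"],
        "CD8": ["DP1", "DP2", "CD4+CD8lo", "DP3", "CD8 SM", "CD8 Mature"],
    }
    for lin, expected in expectations.items():
        m = label == lin
        timeline = align_gates_to_pseudotime(gates[m], traj.pseudotime[m])
        order = [g for g in timeline.order if g in expected]
        assert order == expected
        thr = timeline.boundaries["threshold"].to_numpy()
        assert (np.diff(thr) >= 0).all()


# ---------------------------------------------------------------------------
# Youden alignment


def _naive_youden(earlier, later):
    """Independent exhaustive reference: scan all candidate midpoints."""
    pooled = np.sort(np.unique(np.concatenate([earlier, later])))
    best_c, best_j = None, -np.inf
    for c in 0.5 * (pooled[:-1] + pooled[1:]):
        j = (later >= c).mean() + (earlier < c).mean() - 1.0
        if j > best_j + 1e-15:
            best_j, best_c = j, c
    return best_c, best_j


def test_disjoint_supports_give_perfect_separation():
    t = np.concatenate([np.linspace(0, 1, 30), np.linspace(5, 6, 30)])
    gates = np.array(["early"] * 30 + ["late"] * 30, dtype=object)
    timeline = align_gates_to_pseudotime(gates, t)
    row = timeline.boundaries.iloc[0]
    assert row["youden_j"] == 1.0
    assert 1 < row["threshold"] < 5


def test_identical_distributions_flag_low_confidence():
    rng = np.random.default_rng(3)
    t = rng.uniform(0, 10, 200)
    gates = np.array(["a", "b"] * 100, dtype=object)
    timeline = align_gates_to_pseudotime(gates, t)
    row = timeline.boundaries.iloc[0]
    assert abs(row["youden_j"]) < 0.25
    assert row["low_confidence"]


def test_youden_matches_independent_scan_on_random_instances():
    rng = np.random.default_rng(4)
    for _ in range(100):
        n1, n2 = rng.integers(20, 60, 2)
        earlier = rng.normal(rng.uniform(0, 5), rng.uniform(0.5, 2), n1)
        later = rng.normal(rng.uniform(2, 8), rng.uniform(0.5, 2), n2)
        t = np.concatenate([earlier, later])
        gates = np.array(["e"] * n1 + ["l"] * n2, dtype=object)
        timeline = align_gates_to_pseudotime(gates, t)
        order = timeline.order
        a = t[:n1] if order[0] == "e" else t[n1:]
        b = t[n1:] if order[0] == "e" else t[:n1]
        c_ref, j_ref = _naive_youden(a, b)
        row = timeline.boundaries.iloc[0]
        assert row["threshold"] == pytest.approx(c_ref, abs=0)
        assert row["youden_j"] == pytest.approx(j_ref, abs=0)


def test_small_gates_are_excluded_with_warning(caplog):
    t = np.concatenate([np.linspace(0, 1, 30), np.linspace(2, 3, 30), [5.0] * 5])
    gates = np.array(["a"] * 30 + ["b"] * 30 + ["tiny"] * 5, dtype=object)
    timeline = align_gates_to_pseudotime(gates, t)
    assert "tiny" in timeline.excluded
    assert "tiny" not in timeline.order


# ---------------------------------------------------------------------------
# cluster-proportion enrichment


def test_doubling_a_proportion_gives_log2_of_two():
    labels = np.array(["x"] * 100 + ["y"] * 900 + ["x"] * 50 + ["y"] * 950,
                      dtype=object)
    samples = np.array(["s1"] * 1000 + ["ref"] * 1000, dtype=object)
    out = proportion_log_enrichment(labels, samples,
                                    {"s1": "drug", "ref": "none"}, "none")
    row = out[(out["sample"] == "s1") & (out["cluster"] == "x")]
    assert row["log2_enrichment"].iloc[0] == pytest.approx(1.0, abs=0.02)


def test_proportion_equal_to_reference_gives_zero():
    labels = np.array((["x"] * 100 + ["y"] * 900) * 2, dtype=object)
    samples = np.array(["s1"] * 1000 + ["ref"] * 1000, dtype=object)
    out = proportion_log_enrichment(labels, samples,
                                    {"s1": "drug", "ref": "none"}, "none")
    row = out[(out["sample"] == "s1") & (out["cluster"] == "x")]
    assert row["log2_enrichment"].iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_label_permutation_within_sample_changes_nothing():
    rng = np.random.default_rng(5)
    labels = rng.choice(["x", "y", "z"], 600).astype(object)
    samples = np.repeat(["s1", "ref"], 300).astype(object)
    out1 = proportion_log_enrichment(labels, samples,
                                     {"s1": "d", "ref": "n"}, "n")
    perm = labels.copy()
    perm[:300] = rng.permutation(perm[:300])
    out2 = proportion_log_enrichment(perm, samples, {"s1": "d", "ref": "n"}, "n")
    pd.testing.assert_frame_equal(out1, out2)


def test_cluster_absent_from_reference_is_flagged():
    labels = np.array(["only_s1"] * 10 + ["x"] * 90 + ["x"] * 100, dtype=object)
    samples = np.array(["s1"] * 100 + ["ref"] * 100, dtype=object)
    out = proportion_log_enrichment(labels, samples,
                                    {"s1": "d", "ref": "n"}, "n")
    row = out[(out["sample"] == "s1") & (out["cluster"] == "only_s1")]
    assert row["undefined"].iloc[0]
    assert np.isnan(row["log2_enrichment"].iloc[0])


def test_missing_reference_condition_is_an_error():
    with pytest.raises(ValueError, match="reference"):
        proportion_log_enrichment(np.array(["x"], dtype=object),
                                  np.array(["s1"], dtype=object),
                                  {"s1": "drug"}, "none")
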