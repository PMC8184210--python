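"""Marker testing, logit-method p-value combination, cluster annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vmhatlas import markers
from vmhatlas.containers import NormalizedMatrix
from vmhatlas.normalize import scale_rows


# ----------------------------------------------------------- combine_logitp
def reference_logitp(pvals):
    """Independent evaluation of the logit combination formula."""
    from scipy.special import stdtr
    p = np.clip(np.asarray(pvals, float), 1e-300, 1 - 1e-16)
    k = len(p)
    T = -np.sum(np.log(p) - np.log1p(-p))
    C = np.sqrt(k * np.pi ** 2 * (5 * k + 2) / (3 * (5 * k + 4)))
    return 1.0 - stdtr(5 * k + 4, T / C)


def test_logitp_all_half_is_half():
    for k in (1, 2, 5, 20):
        assert markers.combine_logitp([0.5] * k) == pytest.approx(0.5,
                                                                  abs=1e-12)


def test_logitp_frozen_value():
    assert markers.combine_logitp([0.05, 0.05]) == pytest.approx(
        0.013241832230059, abs=1e-9)


@pytest.mark.parametrize("k", [1, 2, 5, 20])
def test_logitp_matches_reference_formula(k):
    rng = np.random.default_rng(k)
    p = rng.uniform(0.001, 0.999, size=k)
    assert markers.combine_logitp(p) == pytest.approx(reference_logitp(p),
                                                      abs=1e-10)


def test_logitp_monotone_in_each_component():
    base = [0.3, 0.4, 0.5]
    ref = markers.combine_logitp(base)
    assert markers.combine_logitp([0.1, 0.4, 0.5]) < ref
    assert markers.combine_logitp([0.3, 0.4, 0.9]) > ref


def test_logitp_k1_is_monotone_but_not_identity():
    ps = np.linspace(0.05, 0.95, 10)
    out = np.array([markers.combine_logitp([p]) for p in ps])
    assert (np.diff(out) > 0).all()
    assert np.abs(out - ps).max() > 1e-3  # a transform, not the identity


def test_logitp_rejects_empty():
    with pytest.raises(ValueError):
        markers.combine_logitp([])


# ------------------------------------------------------- per_sample_markers
def _norm(values, samples=None):
    values = np.asarray(values, dtype=float)
    G, N = values.shape
    nm = NormalizedMatrix(
        values=values, size_factors=np.ones(N),
        gene_ids=[f"g{i}" for i in range(G)],
        cell_ids=[f"c{i}" for i in range(N)],
        cell_samples=samples)
    return scale_rows(nm)


def test_rank_sum_null_median_p_near_half():
    """Under exchangeability one-sided p-values are uniform, so their
    median over many genes sits near 0.5."""
    rng = np.random.default_rng(0)
    vals = rng.normal(2, 1, size=(200, 400))
    labels = np.array([0] * 200 + [1] * 200)
    out = markers.per_sample_markers(_norm(vals), labels, min_frac=0.0)
    p = out["sample"].xs(0, level="cluster")["p"].to_numpy()
    assert np.isfinite(p).all()
    assert 0.4 <= np.median(p) <= 0.6


def test_rank_sum_extreme_separation_matches_exact_test():
    vals = np.zeros((1, 10))
    vals[0, :4] = [5.0, 6.0, 7.0, 8.0]  # in-cluster strictly above
    vals[0, 4:] = [1.0, 1.1, 1.2, 1.3, 1.4, 1.5]
    labels = np.array([0] * 4 + [1] * 6)
    out = markers.per_sample_markers(_norm(vals), labels, min_frac=0.0)
    got = out["sample"].loc[("g0", 0), "p"]
    exact = stats.mannwhitneyu(vals[0, :4], vals[0, 4:],
                               alternative="greater", method="exact").pvalue
    # asymptotic vs exact agree to within the normal approximation
    assert got == pytest.approx(exact, rel=0.5)
    assert got < 0.05


def test_markers_missing_cluster_is_nan_not_zero():
    vals = np.random.default_rng(0).normal(2, 1, size=(3, 40))
    samples = np.array(["s0"] * 20 + ["s1"] * 20)
    labels = np.array([0] * 10 + [1] * 10 + [0] * 20)  # cluster 1 absent in s1
    out = markers.per_sample_markers(_norm(vals, samples), labels)
    assert out["s1"].xs(1, level="cluster")["p"].isna().all()
    combined = markers.combine_markers(out)
    k = combined.xs(1, level="cluster")["n_samples"]
    assert (k <= 1).all()


def test_combine_markers_sample_order_invariant():
    rng = np.random.default_rng(1)
    vals = rng.normal(2, 1, size=(4, 60))
    vals[0, :15] += 2
    samples = np.array(["a"] * 30 + ["b"] * 30)
    labels = np.tile([0] * 15 + [1] * 15, 2)
    per = markers.per_sample_markers(_norm(vals, samples), labels,
                                     min_frac=0.0)
    c1 = markers.combine_markers(per)
    c2 = markers.combine_markers({"b": per["b"], "a": per["a"]})
    pd.testing.assert_series_equal(c1["combined_p"], c2["combined_p"])


# -------------------------------------------------------- annotate_clusters
def _marker_table(cluster_markers, universe):
    rows = []
    for c, marker_set in cluster_markers.items():
        for g in universe:
            rows.append((g, c, g in marker_set))
    df = pd.DataFrame(rows, columns=["gene", "cluster", "significant"])
    df["fdr_q"] = np.where(df["significant"], 0.001, 0.9)
    df["log2fc"] = 1.0
    return df.set_index(["gene", "cluster"])


def test_annotation_single_set_with_closed_form_p():
    universe = [f"g{i}" for i in range(40)]
    neurons = set(universe[:8])
    tbl = _marker_table({0: neurons, 1: set()}, universe)
    res = markers.annotate_clusters(tbl, {"neuron": neurons,
                                          "glia": set(universe[20:28])})
    assert res.assigned[0] == "neuron"
    assert res.assigned[1] == "junk"
    expected_p = stats.hypergeom.sf(7, 40, 8, 8)
    assert res.enrichment_p.loc[0, "neuron"] == pytest.approx(expected_p)


def test_annotation_two_sets_is_doublets():
    universe = [f"g{i}" for i in range(40)]
    neurons = set(universe[:8])
    glia = set(universe[20:28])
    tbl = _marker_table({0: neurons | glia}, universe)
    res = markers.annotate_clusters(tbl, {"neuron": neurons, "glia": glia})
    assert res.assigned[0] == "doublets"


def test_annotation_rejects_empty_sets():
    tbl = _marker_table({0: set()}, ["g0", "g1"])
    with pytest.raises(ValueError):
        markers.annotate_clusters(tbl, {"neuron": set()})


def test_pipeline_markers_identify_planted_classes(default_data,
                                                   default_chain):
    """Combined marker tables annotate most clusters with the planted class
    whose cells dominate them."""
    from collections import Counter

    cfg, mats, truth = default_data
    norm = default_chain["norm"]
    sol = default_chain["solution"]
    per = markers.per_sample_markers(norm, sol.labels)
    table = markers.combine_markers(per)
    curated = {}
    for g, c in truth.marker_gene_map.items():
        curated.setdefault(f"class{c}", set()).add(g)
    res = markers.annotate_clusters(table, curated)

    cls = truth.cell_class[default_chain["mask"]]
    correct = 0
    for c in np.unique(sol.labels):
        maj = Counter(cls[sol.labels == c]).most_common(1)[0][0]
        if res.assigned[int(c)] == f"class{maj}":
            correct += 1
    assert correct / sol.k >= 0.8
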