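import math

import numpy as np
import pandas as pd
import pytest

from coexage.mutations import (
    centrality,
    centrality_shift,
    cna_module_enrichment,
    driver_fraction,
    focal_gene_calls,
    module_cna_flag,
    recurrent_cna,
    recurrent_point_mutated,
)


def _muts(rows):
    return pd.DataFrame(rows, columns=["gene", "patient", "consequence"])


# ---------------------------------------------------------------------------
# recurrent point mutations


def test_recurrent_point_requires_patients_and_selection_ratio():
    rows = []
    # geneA: 3 patients missense, 4 synonymous -> NS/S = 3/4 < 1 -> recurrent
    rows += [("geneA", f"p{i}", "missense") for i in range(3)]
    rows += [("geneA", f"p{i}", "synonymous") for i in range(3, 7)]
    # geneB: 3 patients missense, 1 synonymous -> NS/S = 3 >= 1 -> fails
    rows += [("geneB", f"p{i}", "missense") for i in range(3)]
    rows += [("geneB", "p9", "synonymous")]
    # geneC: only 2 patients damaged -> fails recurrence
    rows += [("geneC", "p0", "LoF"), ("geneC", "p1", "missense")]
    rows += [("geneC", f"p{i}", "synonymous") for i in range(2, 9)]
    assert recurrent_point_mutated(_muts(rows)) == {"geneA"}


def test_zero_synonymous_means_infinite_ratio_fails():
    rows = [("geneD", f"p{i}", "LoF") for i in range(5)]
    assert recurrent_point_mutated(_muts(rows)) == set()


def test_same_patient_hit_twice_counts_once():
    rows = [("geneE", "p0", "missense")] * 3 + [("geneE", "p1", "missense")]
    rows += [("geneE", f"p{i}", "synonymous") for i in range(2, 12)]
    assert recurrent_point_mutated(_muts(rows)) == set()  # only 2 distinct patients


def test_other_consequence_counts_toward_neither_side():
    rows = [("geneF", f"p{i}", "missense") for i in range(3)]
    rows += [("geneF", f"p{i}", "synonymous") for i in range(3, 7)]
    rows += [("geneF", f"p{i}", "other") for i in range(7, 20)]
    assert recurrent_point_mutated(_muts(rows)) == {"geneF"}


def test_point_table_needs_columns():
    with pytest.raises(ValueError, match="consequence"):
        recurrent_point_mutated(pd.DataFrame({"gene": [], "patient": []}))


# ---------------------------------------------------------------------------
# focality and recurrent CNA


def _coords():
    return pd.DataFrame(
        {
            "gene": ["gA", "gB"],
            "chrom": ["1", "1"],
            "start": [100_000, 700_000],
            "end": [110_000, 710_000],
        }
    )


def test_focal_call_by_midpoint_and_span_threshold():
    # chromosome length 1 Mb (given explicitly); focal cutoff = 250 kb
    segments = pd.DataFrame(
        {
            "patient": ["p1", "p1", "p2"],
            "chrom": ["1", "1", "chr1"],
            "start": [90_000, 600_000, 0],
            "end": [200_000, 1_000_000, 1_000_000],
            "state": ["amp", "del", "amp"],
        }
    )
    calls = focal_gene_calls(segments, _coords(), chrom_sizes={"1": 1_000_000})
    got = set(map(tuple, calls.to_numpy()))
    # p1 seg1 spans 110 kb <= 250 kb: focal amp over gA's midpoint.
    # p1 seg2 spans 400 kb > 250 kb: gB's del is broad, dropped.
    # p2 whole-chromosome amp: broad, dropped for both genes.
    assert got == {("gA", "p1", "amp")}


def test_focal_boundary_span_is_inclusive():
    segments = pd.DataFrame(
        {
            "patient": ["p1"],
            "chrom": ["1"],
            "start": [0],
            "end": [250_000],  # exactly 0.25 * 1 Mb
            "state": ["amp"],
        }
    )
    calls = focal_gene_calls(segments, _coords(), chrom_sizes={"1": 1_000_000})
    assert set(calls["gene"]) == {"gA"}


def test_chrom_sizes_inferred_from_max_end():
    # without explicit sizes the 400 kb segment is judged against max end 1 Mb
    segments = pd.DataFrame(
        {
            "patient": ["p1", "p2"],
            "chrom": ["1", "1"],
            "start": [600_000, 0],
            "end": [1_000_000, 90_000],
            "state": ["del", "amp"],
        }
    )
    calls = focal_gene_calls(segments, _coords())
    assert set(map(tuple, calls.to_numpy())) == set()  # 400kb > 250kb, amp misses midpoints


def test_focal_rejects_bad_coordinates():
    segments = pd.DataFrame(
        {"patient": ["p1"], "chrom": ["1"], "start": [500], "end": [500], "state": ["amp"]}
    )
    with pytest.raises(ValueError):
        focal_gene_calls(segments, _coords())


def test_recurrent_cna_ten_percent_rule():
    calls = pd.DataFrame(
        {
            "gene": ["gA"] * 3 + ["gB"] * 2 + ["gC"] * 3,
            "patient": ["p1", "p2", "p3", "p1", "p2", "p1", "p2", "p3"],
            "state": ["amp"] * 3 + ["amp"] * 2 + ["del"] * 3,
        }
    )
    amp, dele = recurrent_cna(calls, n_patients=30)  # floor = 3 patients
    assert amp == {"gA"} and dele == {"gC"}
    with pytest.raises(ValueError):
        recurrent_cna(calls, n_patients=0)


def test_module_cna_flag_threshold_inclusive():
    module = [f"g{i}" for i in range(10)]
    assert module_cna_flag(module, ["g0"]) == (True, 0.1)
    assert module_cna_flag(module, []) == (False, 0.0)
    with pytest.raises(ValueError):
        module_cna_flag([], ["g0"])


def test_cna_module_enrichment_direction():
    # 0/8 normal modules flagged vs 6/10 tumor modules flagged
    res, table = cna_module_enrichment([False] * 8, [True] * 6 + [False] * 4)
    assert table.tolist() == [[0, 8], [6, 4]]
    assert res.p_value < 0.05
    assert res.odds_ratio < 1  # normal flagged less often


def test_cna_module_enrichment_null_is_insignificant():
    res, _ = cna_module_enrichment([True, False] * 5, [True, False] * 5)
    assert res.p_value > 0.5


# ---------------------------------------------------------------------------
# drivers


def test_driver_fraction_and_exclusion():
    drivers = pd.DataFrame(
        {"gene": ["TP53", "KRAS", "VHL"], "tumor_type": ["lung", "lung", "kidney"]}
    )
    pct, excluded = driver_fraction(["TP53", "KRAS", "other1", "other2"], drivers, "lung")
    assert pct == pytest.approx(50.0) and not excluded
    pct, excluded = driver_fraction(["other1"], drivers, "lung")
    assert pct == 0.0 and excluded
    with pytest.raises(ValueError, match="kidney"):
        driver_fraction(["TP53"], drivers, "brain")


# ---------------------------------------------------------------------------
# centrality


def _net(w, genes):
    return pd.DataFrame(w, index=genes, columns=genes)


def test_star_graph_hub_has_centrality_zero():
    # hub connected to 4 spokes with weight 1; spokes unconnected
    n = 5
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    np.fill_diagonal(w, 1.0)
    tab = centrality(_net(w, [f"g{i}" for i in range(n)]))
    assert tab.loc["g0", "centrality"] == pytest.approx(0.0)
    assert tab.loc["g0", "degree"] == pytest.approx(4.0)
    # spokes tie at average rank (1+2+3+4)/4 = 2.5 -> 2.5/5 - 1 = -0.5
    for g in ["g1", "g2", "g3", "g4"]:
        assert tab.loc[g, "centrality"] == pytest.approx(-0.5)
    assert tab.loc["g0", "norm_degree"] == pytest.approx(4.0)  # median degree 1


def test_complete_graph_all_tied():
    w = np.ones((4, 4))
    tab = centrality(_net(w, list("abcd")))
    assert np.allclose(tab["centrality"], (1 + 2 + 3 + 4) / 4 / 4 - 1)
    assert np.allclose(tab["norm_degree"], 1.0)


def test_centrality_hand_oracle():
    genes = ["a", "b", "c"]
    w = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
    tab = centrality(_net(w, genes))
    # degrees: a=1.0, b=1.1, c=0.3 -> ranks 2,3,1 -> rel 2/3,1,1/3
    assert tab.loc["a", "centrality"] == pytest.approx(2 / 3 - 1)
    assert tab.loc["b", "centrality"] == pytest.approx(0.0)
    assert tab.loc["c", "centrality"] == pytest.approx(1 / 3 - 1)
    with pytest.raises(ValueError):
        centrality(_net(np.ones((1, 1)), ["a"]))


def test_centrality_shift_tumor_minus_normal():
    t1 = pd.DataFrame({"centrality": [0.0, -0.5]}, index=["hub", "x"])
    n1 = pd.DataFrame({"centrality": [-0.8, 0.0]}, index=["hub", "y"])
    n2 = pd.DataFrame({"centrality": [-0.2]}, index=["z"])
    assert centrality_shift("hub", [t1], [n1, n2]) == pytest.approx(0.8)
    with pytest.raises(ValueError, match="0 modules"):
        centrality_shift("absent", [t1], [n1])
    with pytest.raises(ValueError, match="2 modules"):
        centrality_shift("hub", [t1, t1], [n1])
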