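"""Cell QC, normalisation, cell typing, LCS erosion and transcriptomic age."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from musicpipe.cellstate import (
    LCS_ERODED_THRESHOLD,
    assign_cell_types,
    filter_cells,
    lcs_erosion,
    lcs_gene_assoc,
    lognormalize,
    transcriptomic_age,
)
from musicpipe.contacts import logbin_profile
from musicpipe.synthdata import (
    simulate_ageing_expression,
    simulate_distance_populations,
)


def test_filter_cells_boundaries():
    df = pd.DataFrame(
        {"n_rna": [100, 99, 1_000_000, 100], "n_dna": [5_000, 1_000_000, 4_999, 50_000]},
        index=["keep_edge", "low_rna", "low_dna", "keep"],
    )
    kept, report = filter_cells(df)
    assert set(kept) == {"keep_edge", "keep"}
    assert report["kept"] == 2 and report["input"] == 4


def test_filter_cells_matches_brute_force():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {"n_rna": rng.integers(0, 300, 200), "n_dna": rng.integers(0, 10_000, 200)}
    )
    kept, _ = filter_cells(df)
    brute = [i for i in df.index if df.loc[i, "n_rna"] >= 100 and df.loc[i, "n_dna"] >= 5_000]
    assert list(kept) == brute


def test_lognormalize_spot_values():
    counts = pd.DataFrame([[0, 10], [5, 5]], columns=["g1", "g2"], dtype=float)
    out = lognormalize(counts, scale=1e4)
    assert out.iloc[0, 0] == 0.0
    assert out.iloc[0, 1] == pytest.approx(np.log1p(1e4 * 10 / 10))
    assert out.iloc[1, 0] == pytest.approx(np.log1p(1e4 * 5 / 10))
    # monotone in raw count for equal library sizes
    assert out.iloc[0, 1] > out.iloc[1, 1]


def test_assign_cell_types_planted_recovery():
    rng = np.random.default_rng(1)
    markers = {"typeA": ["a1", "a2"], "typeB": ["b1", "b2"], "typeC": ["c1", "c2"]}
    genes = [g for gs in markers.values() for g in gs] + ["h1", "h2"]
    cells, labels, truth = [], [], {}
    rows = []
    for clust, t in enumerate(["typeA", "typeB", "typeC"]):
        truth[clust] = t
        for i in range(40):
            row = pd.Series(rng.poisson(3.0, len(genes)).astype(float), index=genes)
            row[markers[t]] = rng.poisson(12.0, 2)  # 4-fold own-marker mean
            rows.append(row)
            cells.append(f"c{clust}_{i}")
            labels.append(clust)
    counts = pd.DataFrame(rows, index=cells)
    expr = lognormalize(counts)
    assignment, ties = assign_cell_types(pd.Series(labels, index=cells), markers, expr)
    assert assignment == truth and not ties


def test_assign_cell_types_tie_and_missing_markers():
    expr = pd.DataFrame({"g": [1.0, 1.0]}, index=["c1", "c2"])
    labels = pd.Series([0, 0], index=["c1", "c2"])
    assignment, ties = assign_cell_types(labels, {"A": ["g"], "B": ["g"]}, expr)
    assert assignment[0] == "A" and len(ties) == 1
    # a type with no marker present is ineligible
    assignment, _ = assign_cell_types(labels, {"A": ["g"], "B": ["absent"]}, expr)
    assert assignment[0] == "A"
    with pytest.raises(ValueError):
        assign_cell_types(labels, {"A": ["absent"]}, expr)


def test_lcs_trivial_extremes():
    short = lcs_erosion(logbin_profile(np.full(100, 5.0e4)))
    assert short.score < 1e5 and not short.eroded
    long = lcs_erosion(logbin_profile(np.full(100, 2.0e7)))
    assert long.score > 1e7 and long.eroded
    assert short.low_confidence and long.low_confidence  # single-bin profiles


def test_lcs_low_confidence_flag_and_empty():
    rng = np.random.default_rng(2)
    full = lcs_erosion(logbin_profile(10 ** rng.uniform(4, 8, size=500)))
    assert not full.low_confidence
    with pytest.raises(ValueError):
        lcs_erosion(logbin_profile(np.array([])))


def test_lcs_two_population_recovery():
    dists, eroded = simulate_distance_populations(400, 0.4, seed=4)
    pred = np.array([lcs_erosion(logbin_profile(d)).eroded for d in dists])
    assert (pred == eroded).mean() >= 0.95


def test_lcs_eroded_fraction_monotone_in_mixture_weight():
    fractions = []
    for frac in (0.1, 0.5, 0.9):
        dists, _ = simulate_distance_populations(200, frac, seed=5)
        pred = [lcs_erosion(logbin_profile(d)).eroded for d in dists]
        fractions.append(np.mean(pred))
    assert fractions[0] < fractions[1] < fractions[2]


def _age_inputs(n_cells=40, seed=0):
    sim = simulate_ageing_expression(n_cells=n_cells, n_genes=10, n_samples=4, seed=seed)
    return sim


def test_transcriptomic_age_zero_z_scores():
    counts = pd.DataFrame(np.full((10, 3), 5), columns=["a", "b", "c"])
    counts.index = [f"c{i}" for i in range(10)]
    sample_ids = pd.Series(["s0"] * 5 + ["s1"] * 5, index=counts.index)
    age, info = transcriptomic_age(counts, ["a", "b", "c"], sample_ids, {"s0": 60, "s1": 80})
    assert np.allclose(age, 0.0)  # constant genes -> all skipped
    assert info["n_genes_used"] == 0


def test_transcriptomic_age_monotone_single_gene():
    # a stable reference gene keeps library sizes comparable so the
    # ageing gene's signal survives normalisation
    counts = pd.DataFrame(
        {"g": [1, 5, 9, 2, 6, 10], "ref": [50] * 6}, index=[f"c{i}" for i in range(6)]
    )
    sample_ids = pd.Series(["s0", "s0", "s0", "s1", "s1", "s1"], index=counts.index)
    age, _ = transcriptomic_age(counts, ["g"], sample_ids, {"s0": 60, "s1": 80})
    # positively signed gene: higher expression -> higher age
    assert age["c0"] < age["c2"]


def test_transcriptomic_age_recovery():
    sim = simulate_ageing_expression(n_cells=500, n_genes=50, seed=5)
    age, info = transcriptomic_age(
        sim["counts"], list(sim["counts"].columns), sim["sample_ids"], sim["sample_ages"]
    )
    assert info["n_genes_used"] == 50
    rho = stats.spearmanr(sim["true_factor"], age).statistic
    assert rho >= 0.8


@given(st.floats(min_value=0.2, max_value=5.0), st.floats(min_value=-3.0, max_value=3.0))
def test_transcriptomic_age_affine_invariance(scale, shift):
    """Z-scoring makes the age invariant to per-gene affine rescaling of
    the expression values (weights held fixed via identical counts)."""
    sim = _age_inputs(seed=1)
    counts = sim["counts"]
    expr = lognormalize(counts)
    age1, _ = transcriptomic_age(
        counts, list(counts.columns), sim["sample_ids"], sim["sample_ages"], expr=expr
    )
    age2, _ = transcriptomic_age(
        counts, list(counts.columns), sim["sample_ids"], sim["sample_ages"],
        expr=expr * scale + shift,
    )
    assert np.allclose(age1, age2, atol=1e-8)


def test_lcs_gene_assoc_deterministic_and_null():
    rng = np.random.default_rng(6)
    n = 1_000
    scores = pd.Series(rng.uniform(1e4, 1e7, n), index=[f"c{i}" for i in range(n)])
    expr = pd.DataFrame(
        {
            "linear": 2.0 * scores.to_numpy() + 1.0,
            "constant": np.ones(n),
            **{f"noise{j}": rng.normal(size=n) for j in range(50)},
        },
        index=scores.index,
    )
    out = lcs_gene_assoc(expr, scores)
    assert bool(out.loc["linear", "pass"]) and out.loc["linear", "P"] < 1e-10
    assert not bool(out.loc["constant", "pass"]) and np.isnan(out.loc["constant", "F"])
    noise = out.loc[[f"noise{j}" for j in range(50)]]
    # joint threshold (P<0.01 & F>1 & |rho|>0.1) keeps false positives < 1%
    assert noise["pass"].mean() < 0.01 + 1e-9
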