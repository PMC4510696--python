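"""Count building, TMM/RPM normalization, NB dispersion/testing, enrichment
calls, seven-way partitions, and sample-relationship summaries."""
import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exomir import (
    build_counts,
    call_enriched,
    estimate_dispersion,
    nb_test,
    parse_category_table,
    partition_sets,
    pca,
    rpm_normalize,
    spearman_matrix,
    tmm_factors,
)
from exomir.fixtures import fixture_text
from exomir.mapanno import AnnotatedRead


# --- counts and normalization ---------------------------------------------


def test_build_counts_sums_weights_per_mature():
    ann = {
        "s1": [AnnotatedRead(f"r{i}", "miRNA", "mirA", 1.0) for i in range(10)]
        + [AnnotatedRead("rx", "miRNA", "mirA", 0.5), AnnotatedRead("rx", "miRNA", "mirB", 0.5)]
        + [AnnotatedRead("rt", "tRNA", None, 1.0)],
    }
    counts = build_counts(ann)
    assert counts.loc["mirA", "s1"] == pytest.approx(10.5)
    assert counts.loc["mirB", "s1"] == pytest.approx(0.5)
    assert counts["s1"].sum() == pytest.approx(11.0)  # tRNA read not counted


def test_rpm_scales_columns_to_one_million():
    counts = pd.DataFrame({"a": [5.0, 5.0], "b": [1.0, 3.0]}, index=["x", "y"])
    rpm = rpm_normalize(counts)
    assert rpm["a"].tolist() == [5e5, 5e5]
    assert rpm.sum(axis=0).tolist() == pytest.approx([1e6, 1e6])
    assert (rpm["b"] / rpm["b"].sum() == counts["b"] / counts["b"].sum()).all()
    with pytest.raises(ValueError):
        rpm_normalize(pd.DataFrame({"a": [0.0, 0.0]}))


def test_tmm_identical_columns_give_unit_factors():
    rng = np.random.default_rng(0)
    col = rng.poisson(50, size=100).astype(float) + 1
    counts = pd.DataFrame({"a": col, "b": col})
    assert tmm_factors(counts).tolist() == pytest.approx([1.0, 1.0])


def test_tmm_pure_depth_difference_gives_unit_factors():
    rng = np.random.default_rng(1)
    col = rng.poisson(100, size=200).astype(float) + 1
    counts = pd.DataFrame({"a": col, "b": 2 * col})
    # doubling every gene is pure depth; all M vs reference are 0
    assert tmm_factors(counts).tolist() == pytest.approx([1.0, 1.0])


def test_tmm_trims_away_five_percent_outlier_genes():
    # 5% wildly deviating genes inflate the library size; double trimming
    # must leave the *effective* library size (lib x factor) of the spiked
    # sample at its clean value within 1%
    rng = np.random.default_rng(2)
    base = rng.poisson(80, size=400).astype(float) + 1
    clean = pd.DataFrame({"a": base, "b": base * rng.uniform(0.95, 1.05, 400)})
    spiked = clean.copy()
    spiked.iloc[:20, 0] *= 50
    eff_clean = clean.sum(axis=0) * tmm_factors(clean)
    eff_spiked = spiked.sum(axis=0) * tmm_factors(spiked)
    ratio_clean = eff_clean["a"] / eff_clean["b"]
    ratio_spiked = eff_spiked["a"] / eff_spiked["b"]
    assert ratio_spiked == pytest.approx(ratio_clean, rel=0.01)


def test_tmm_invariant_to_global_depth_rescaling():
    # rescaling one sample's depth leaves M, A and the reference choice
    # untouched; only the inverse-variance weights shift slightly
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.poisson(60, size=(300, 3)).astype(float) + 1,
                          columns=list("abc"))
    f1 = tmm_factors(counts)
    scaled = counts.copy()
    scaled["b"] *= 7.0
    f2 = tmm_factors(scaled)
    assert np.allclose(f1, f2, rtol=5e-3)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_tmm_matches_edger_reference_implementation(tmp_path):
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.01, size=(150, 4)).astype(float),
        index=[f"m{i}" for i in range(150)], columns=list("ABCD"),
    )
    counts.iloc[:8, 0] *= 6
    path = tmp_path / "counts.tsv"
    counts.to_csv(path, sep="\t")
    script = (
        'suppressMessages(library(edgeR));'
        f'x <- as.matrix(read.delim("{path}", row.names=1));'
        'cat(calcNormFactors(x, method="TMM"), sep="\\n")'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
    r_factors = [float(v) for v in out.stdout.split()]
    py_factors = tmm_factors(counts).tolist()
    assert py_factors == pytest.approx(r_factors, abs=1e-6)


# --- dispersion ------------------------------------------------------------


def _nb_counts(rng, mu, alpha, size):
    if alpha <= 0:
        return rng.poisson(mu, size=size).astype(float)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size).astype(float)


def test_dispersion_near_zero_for_poisson_data():
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(_nb_counts(rng, 100, 0.0, (500, 10)),
                          columns=[f"s{i}" for i in range(10)])
    groups = {f"s{i}": "A" for i in range(10)}
    disp = estimate_dispersion(counts, groups, method="pooled", trend=False)
    assert disp.median() < 0.01


def test_dispersion_recovers_true_alpha():
    rng = np.random.default_rng(13)
    counts = pd.DataFrame(_nb_counts(rng, 100, 0.2, (800, 10)),
                          columns=[f"s{i}" for i in range(10)])
    groups = {f"s{i}": "A" for i in range(10)}
    disp = estimate_dispersion(counts, groups, method="pooled", trend=False)
    assert 0.1 <= disp.median() <= 0.3


def test_constant_counts_give_zero_genewise_dispersion():
    counts = pd.DataFrame({"s1": [50.0, 10.0], "s2": [50.0, 10.0], "s3": [50.0, 10.0]},
                          index=["x", "y"])
    disp = estimate_dispersion(counts, {"s1": "A", "s2": "A", "s3": "A"}, trend=False)
    assert disp.tolist() == [0.0, 0.0]


def test_per_condition_method_and_unreplicated_error():
    rng = np.random.default_rng(17)
    counts = pd.DataFrame(_nb_counts(rng, 80, 0.1, (300, 6)),
                          columns=[f"s{i}" for i in range(6)])
    groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
    disp = estimate_dispersion(counts, groups, method="per-condition", trend=False)
    assert (disp >= 0).all()
    with pytest.raises(ValueError):
        estimate_dispersion(counts.iloc[:, :2], {"s0": "A", "s1": "B"})


# --- NB test ---------------------------------------------------------------


def test_null_symmetry_small_counts():
    counts = pd.DataFrame({"s1": [20.0], "s2": [20.0], "s3": [20.0], "s4": [20.0]},
                          index=["m"])
    groups = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    res = nb_test(counts, groups, 0.0, normalize=None)
    assert res.p_value.iloc[0] == pytest.approx(1.0, abs=1e-6)
    assert res.log2_fold_change.iloc[0] == pytest.approx(0.0)


def test_type_one_error_calibrated_on_null_simulation():
    rng = np.random.default_rng(19)
    n_genes, n = 3000, 3
    counts = pd.DataFrame(_nb_counts(rng, 100, 0.1, (n_genes, 2 * n)),
                          columns=[f"s{i}" for i in range(2 * n)])
    groups = {f"s{i}": ("A" if i < n else "B") for i in range(2 * n)}
    res = nb_test(counts, groups, 0.1, normalize=None)
    frac = (res.p_value < 0.05).mean()
    se = math.sqrt(0.05 * 0.95 / n_genes)
    assert abs(frac - 0.05) <= 3 * se


def test_power_at_fourfold_change():
    rng = np.random.default_rng(23)
    n_genes, n = 500, 3
    a = _nb_counts(rng, 400, 0.1, (n_genes, n))
    b = _nb_counts(rng, 100, 0.1, (n_genes, n))
    counts = pd.DataFrame(np.hstack([a, b]), columns=[f"s{i}" for i in range(2 * n)])
    groups = {f"s{i}": ("A" if i < n else "B") for i in range(2 * n)}
    res = nb_test(counts, groups, 0.1, normalize=None)
    assert (res.fdr <= 0.05).mean() > 0.8


def test_all_zero_mirna_reported_untested():
    counts = pd.DataFrame({"s1": [0.0, 10.0], "s2": [0.0, 12.0],
                           "s3": [0.0, 11.0], "s4": [0.0, 9.0]}, index=["z", "m"])
    groups = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    res = nb_test(counts, groups, 0.0, normalize=None)
    assert np.isnan(res.loc["z", "p_value"]) and np.isnan(res.loc["z", "fdr"])
    assert np.isfinite(res.loc["m", "p_value"])


def test_wald_branch_used_for_large_totals():
    counts = pd.DataFrame({"s1": [4000.0], "s2": [4100.0], "s3": [1000.0], "s4": [950.0]},
                          index=["m"])
    groups = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    res = nb_test(counts, groups, 0.01, normalize=None)
    assert res.p_value.iloc[0] < 0.01
    assert res.log2_fold_change.iloc[0] == pytest.approx(2.0, abs=0.1)


# --- enrichment calls ------------------------------------------------------


def test_enrichment_thresholds_boundary_inclusive():
    res = pd.DataFrame(
        {"log2_fold_change": [1.0, 0.99, -1.5], "fdr": [0.001, 1e-9, 1e-4]},
        index=["at_boundary", "small_lfc", "cellward"],
    )
    calls = call_enriched(res)
    assert calls["at_boundary"] == "exosome-enriched"
    assert calls["small_lfc"] == "not-called"
    assert calls["cellward"] == "cell-enriched"


# --- partitions ------------------------------------------------------------


def test_partition_example_and_identical_and_disjoint_sets():
    part = partition_sets({"L1": {"a", "b"}, "L2": {"b", "c"}, "L3": {"b"}})
    assert part.count("L1", "L2", "L3") == 1
    assert part.count("L1") == 1 and part.count("L2") == 1 and part.count("L3") == 0
    assert part.count("L1", "L2") == 0

    same = partition_sets({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
    assert same.count("A", "B", "C") == 2 and same.all_members() == {1, 2}

    disj = partition_sets({"A": {1}, "B": {2}, "C": {3}})
    assert disj.count("A") == disj.count("B") == disj.count("C") == 1
    assert disj.count("A", "B", "C") == 0


def test_partition_matches_bruteforce_membership_lattice():
    # all 2^6 configurations of two elements over three sets
    for bits in itertools.product([0, 1], repeat=6):
        sets = {"A": set(), "B": set(), "C": set()}
        for e, offset in (("x", 0), ("y", 3)):
            for k, name in enumerate("ABC"):
                if bits[offset + k]:
                    sets[name].add(e)
        part = partition_sets({k: set(v) for k, v in sets.items()})
        regions = list(part.regions.values())
        for r1, r2 in itertools.combinations(regions, 2):
            assert not (r1 & r2)
        assert part.all_members() == sets["A"] | sets["B"] | sets["C"]
        for e in ("x", "y"):
            membership = frozenset(n for n in "ABC" if e in sets[n])
            if membership:
                assert e in part.regions[membership]


def test_fixture_tables_reproduce_footnote_counts():
    cells = parse_category_table(fixture_text("table1_cells_enriched.tsv"))
    assert cells.count("DKO-1", "DKs-8", "DLD-1") == 25
    assert cells.count("DKO-1") == 39
    assert cells.count("DKs-8") == 13
    exo = parse_category_table(fixture_text("table2_exosome_enriched.tsv"))
    assert exo.count("DKO-1", "DKs-8", "DLD-1") == 29
    assert exo.count("DKO-1") == 94
    assert exo.count("DKs-8") == 10
    assert exo.count("DLD-1") == 6


def test_category_parser_rejects_malformed_input():
    with pytest.raises(ValueError, match="line 1"):
        parse_category_table("not a header\nDKO-1\thsa-miR-1")
    with pytest.raises(ValueError, match="line 3"):
        parse_category_table("category\tmirna\nDKO-1\thsa-miR-1\nBadBlock\thsa-miR-2")
    with pytest.raises(ValueError, match="duplicate"):
        parse_category_table("category\tmirna\nDKO-1\thsa-miR-1\nDKO-1\thsa-miR-1")
    empty = parse_category_table("category\tmirna\n")
    assert empty.count("DKO-1") == 0


# --- correlation / PCA -----------------------------------------------------


def test_spearman_self_reverse_and_oracle():
    rng = np.random.default_rng(29)
    x = rng.random(20)
    expr = pd.DataFrame({"a": x, "b": x, "c": x.max() - x})
    mat = spearman_matrix(expr)
    assert mat.loc["a", "b"] == pytest.approx(1.0)
    assert mat.loc["a", "c"] == pytest.approx(-1.0)
    y = rng.random(20)
    expr2 = pd.DataFrame({"a": x, "b": y})
    got = spearman_matrix(pd.concat([expr2, expr2.a.rename("pad")], axis=1)).loc["a", "b"]
    rx, ry = stats.rankdata(x), stats.rankdata(y)  # rank-formula oracle
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert got == pytest.approx(oracle, abs=1e-12)


def test_spearman_flags_constant_vector():
    expr = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    mat = spearman_matrix(expr)
    assert np.isnan(mat.loc["a", "b"])


def test_pca_separates_two_sample_clusters():
    rng = np.random.default_rng(31)
    base1, base2 = rng.random(50) * 100, rng.random(50) * 100
    cols = {}
    for i in range(3):
        cols[f"g1_{i}"] = base1 + rng.normal(0, 0.5, 50)
        cols[f"g2_{i}"] = base2 + rng.normal(0, 0.5, 50)
    expr = pd.DataFrame(cols)
    scores, explained, _ = pca(expr, log_transform=False)
    assert explained[0] > 0.9
    pc1 = scores["PC1"]
    g1 = pc1[[c for c in expr if c.startswith("g1")]]
    g2 = pc1[[c for c in expr if c.startswith("g2")]]
    assert g1.max() < g2.min() or g2.max() < g1.min()


def test_pca_reconstruction_and_variance_ordering():
    rng = np.random.default_rng(37)
    expr = pd.DataFrame(rng.random((30, 5)) * 50, columns=list("abcde"))
    scores, explained, loadings = pca(expr, log_transform=False)
    x = expr.to_numpy() - expr.to_numpy().mean(axis=1, keepdims=True)
    recon = loadings.to_numpy() @ scores.to_numpy().T
    assert np.allclose(recon, x, atol=1e-9)
    assert all(explained[i] >= explained[i + 1] for i in range(len(explained) - 1))
    assert explained.sum() <= 1.0 + 1e-12
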