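"""Population-genetic statistics against oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import (
    amova_naive,
    kosman_naive,
    mantel_exact_p,
    nei_naive,
    wc_theta_naive,
)
from conftest import random_panel
from dunefly.popgen import (
    GenotypePanel,
    amova,
    filter_loci,
    genotype_pca,
    geographic_distances,
    haversine_km,
    heterozygosities,
    kosman_distance,
    mantel,
    mantel_ibd,
    nei_distance,
    pairwise_fst,
    population_specific_fst,
    private_alleles,
    read_dosage_csv,
    read_vcf,
    wc_fst,
)


def _panel_from_blocks(blocks, coords=None):
    """GenotypePanel from {pop: (n_ind, L) dosage array} dict."""
    frames, pops = [], {}
    for pop, g in blocks.items():
        idx = [f"{pop}{i}" for i in range(g.shape[0])]
        frames.append(pd.DataFrame(
            np.asarray(g, float), index=idx,
            columns=[f"L{j}" for j in range(g.shape[1])],
        ))
        pops.update({i: pop for i in idx})
    return GenotypePanel(pd.concat(frames), pd.Series(pops), coords)


# ---------------------------------------------------------------- filtering


def test_filter_loci_threshold_semantics():
    """Reproducibility (0.99, 0.97, 0.98, 0.95, 1.0) at 0.98 keeps loci 1,3,5."""
    g = pd.DataFrame(
        np.tile([0.0, 1.0, 2.0, 1.0], (5, 1)).T,
        index=list("abcd"), columns=[f"L{i}" for i in range(5)],
    )
    meta = pd.DataFrame(
        {"reproducibility": [0.99, 0.97, 0.98, 0.95, 1.0],
         "call_rate": [1.0] * 5},
        index=g.columns,
    )
    panel = GenotypePanel(g, pd.Series({"a": "P", "b": "P", "c": "Q", "d": "Q"}),
                          metadata=meta)
    out, report = filter_loci(panel, repro_min=0.98, callrate_min=0.0, maf_min=0.0)
    assert out.loci == ["L0", "L2", "L4"]
    assert report["steps"][0]["removed"] == 2
    assert "frequency" in report["maf_threshold_note"]


def test_filter_loci_matches_three_pass_oracle():
    rng = np.random.default_rng(7)
    g = rng.integers(0, 3, size=(20, 60)).astype(float)
    g[rng.random(g.shape) < 0.08] = np.nan
    geno = pd.DataFrame(g, index=[f"i{k}" for k in range(20)],
                        columns=[f"L{j}" for j in range(60)])
    meta = pd.DataFrame(
        {"reproducibility": rng.uniform(0.9, 1.0, 60),
         "call_rate": 1 - np.isnan(g).mean(axis=0)},
        index=geno.columns,
    )
    pops = pd.Series(["A"] * 10 + ["B"] * 10, index=geno.index)
    panel = GenotypePanel(geno, pops, metadata=meta)
    out, _ = filter_loci(panel, 0.95, 0.9, 0.05)

    surviving = []
    for j, locus in enumerate(geno.columns):
        if meta.loc[locus, "reproducibility"] < 0.95:
            continue
        col = g[:, j]
        if np.mean(~np.isnan(col)) < 0.9:
            continue
        p = np.nanmean(col) / 2
        if min(p, 1 - p) < 0.05:
            continue
        surviving.append(locus)
    assert out.loci == surviving


def test_filter_loci_all_removed_reports_attrition():
    g = pd.DataFrame([[0.0, 0.0], [0.0, 0.0]], index=["a", "b"], columns=["L0", "L1"])
    panel = GenotypePanel(g, pd.Series({"a": "P", "b": "Q"}))
    with pytest.raises(ValueError, match="attrition"):
        filter_loci(panel, 0.0, 0.0, 0.1)  # monomorphic -> MAF filter kills all


# ----------------------------------------------------------- heterozygosity


def test_heterozygosity_definitional():
    panel = _panel_from_blocks({"P": np.array([[0], [1], [1], [2]]),
                                "Q": np.array([[0], [0], [0], [0]])})
    with pytest.warns(UserWarning, match="monomorphic"):
        het = heterozygosities(panel)
    assert het.loc["P", "Ho"] == pytest.approx(0.5)
    # Hs = n/(n-1) (1 - p^2 - q^2 - Ho/(2n)), n=4, p=0.5
    assert het.loc["P", "He"] == pytest.approx((4 / 3) * (1 - 0.5 - 0.5 / 8))
    assert het.loc["Q", "Ho"] == 0.0 and het.loc["Q", "He"] == 0.0
    assert np.isnan(het.loc["Q", "Fis"])


def test_fis_identity():
    rng = np.random.default_rng(1)
    panel = random_panel(rng, n_pops=3, n_ind=8, n_loci=40, missing=0.05)
    het = heterozygosities(panel)
    for pop in het.index:
        if het.loc[pop, "He"] > 0:
            assert het.loc[pop, "Fis"] == pytest.approx(
                1 - het.loc[pop, "Ho"] / het.loc[pop, "He"], abs=1e-12
            )


def test_all_homozygous_zero_ho():
    panel = _panel_from_blocks({"P": np.array([[0, 2], [2, 0]]),
                                "Q": np.array([[0, 0], [2, 2]])})
    het = heterozygosities(panel)
    assert (het["Ho"] == 0).all()


# ------------------------------------------------------------------- F_ST


def test_fst_identical_frequencies_near_zero():
    rng = np.random.default_rng(2)
    base = rng.integers(0, 3, size=(40, 100))
    order = rng.permutation(40)
    blocks = {"P": base[order[:20]], "Q": base[order[20:]]}
    fst, _ = pairwise_fst(_panel_from_blocks(blocks), n_boot=0)
    assert abs(fst.loc["P", "Q"]) < 0.02


def test_fst_fixed_opposite_alleles_is_one():
    blocks = {"P": np.zeros((6, 30)), "Q": np.full((6, 30), 2.0)}
    fst, _ = pairwise_fst(_panel_from_blocks(blocks), n_boot=0)
    assert fst.loc["P", "Q"] == pytest.approx(1.0)


def test_fst_matches_scalar_oracle():
    rng = np.random.default_rng(3)
    blocks = {p: rng.integers(0, 3, size=(8, 25)) for p in ("P", "Q", "R")}
    panel = _panel_from_blocks({p: b.astype(float) for p, b in blocks.items()})
    fst, _ = pairwise_fst(panel, n_boot=0)
    for a, b in (("P", "Q"), ("P", "R"), ("Q", "R")):
        expected = wc_theta_naive([blocks[a], blocks[b]])
        assert fst.loc[a, b] == pytest.approx(expected, rel=1e-10)
    assert wc_fst(panel) == pytest.approx(wc_theta_naive(list(blocks.values())), rel=1e-10)


def test_fst_bootstrap_p_significant_for_structured_pair():
    rng = np.random.default_rng(4)
    blocks = {
        "P": rng.binomial(2, 0.15, size=(12, 300)),
        "Q": rng.binomial(2, 0.75, size=(12, 300)),
    }
    fst, p = pairwise_fst(_panel_from_blocks(blocks), n_boot=199, seed=0)
    assert p.loc["P", "Q"] == pytest.approx(1 / 200)
    assert fst.loc["P", "Q"] > 0.3


def test_fst_excludes_singleton_population():
    blocks = {"P": np.array([[0, 1, 2]] * 4), "Q": np.array([[2, 1, 0]] * 4),
              "S": np.array([[1, 1, 1]])}
    with pytest.warns(UserWarning, match="single-individual"):
        fst, _ = pairwise_fst(_panel_from_blocks(blocks), n_boot=0)
    assert list(fst.index) == ["P", "Q"]


def test_population_specific_fst_island_model():
    """All demes drifted with the same F recover beta ~= F each."""
    rng = np.random.default_rng(5)
    F, L = 0.2, 5000
    p_anc = rng.uniform(0.1, 0.9, L)
    blocks = {}
    for k in range(5):
        pf = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F)
        blocks[f"D{k}"] = rng.binomial(2, pf, size=(15, L))
    betas = population_specific_fst(_panel_from_blocks(blocks))
    assert np.all(np.abs(betas.to_numpy() - F) < 0.03)


def test_population_specific_fst_undrifted_deme_is_minimal():
    rng = np.random.default_rng(6)
    F, L = 0.25, 4000
    p_anc = rng.uniform(0.2, 0.8, L)
    blocks = {"anc": rng.binomial(2, p_anc, size=(15, L))}
    for k in range(3):
        pf = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F)
        blocks[f"D{k}"] = rng.binomial(2, pf, size=(15, L))
    betas = population_specific_fst(_panel_from_blocks(blocks))
    assert betas.idxmin() == "anc"
    assert betas["anc"] < 0.1


def test_population_specific_fst_requires_two_pops():
    panel = _panel_from_blocks({"P": np.array([[0, 1], [1, 2]])})
    with pytest.raises(ValueError):
        population_specific_fst(panel)


# ------------------------------------------------------------------ AMOVA


def test_amova_matches_copy_expansion_oracle():
    """Toy instance: components equal the brute-force decomposition."""
    rng = np.random.default_rng(8)
    g = rng.integers(0, 3, size=(6, 2))
    groups = ["A", "A", "A", "B", "B", "B"]
    panel = _panel_from_blocks({"A": g[:3], "B": g[3:]})
    res = amova(panel, n_perm=0)
    oracle = amova_naive(g, groups)
    for k in ("among_pops", "among_ind_within", "within_ind"):
        assert res["ss"][k] == pytest.approx(oracle["ss"][k], abs=1e-10)
        assert res["sigma"][k] == pytest.approx(oracle["sigma"][k], abs=1e-10)


def test_amova_percentages_sum_and_p_range():
    rng = np.random.default_rng(9)
    panel = random_panel(rng, n_pops=3, n_ind=6, n_loci=30)
    res = amova(panel, n_perm=99, seed=0)
    assert sum(res["percent"].values()) == pytest.approx(100.0, abs=1e-9)
    assert 1 / 100 <= res["p_value"] <= 1.0


def test_amova_structured_panel_significant():
    rng = np.random.default_rng(10)
    blocks = {
        "P": rng.binomial(2, 0.1, size=(10, 200)),
        "Q": rng.binomial(2, 0.9, size=(10, 200)),
    }
    res = amova(_panel_from_blocks(blocks), n_perm=199, seed=1)
    assert res["percent"]["among_pops"] > 50
    assert res["p_value"] == pytest.approx(1 / 200)


def test_amova_input_validation():
    panel = _panel_from_blocks({"P": np.array([[0, 1], [1, 2]])})
    with pytest.raises(ValueError, match="two populations"):
        amova(panel, n_perm=0)
    two = _panel_from_blocks({"P": np.array([[0, 1]] * 3), "Q": np.array([[1, 2]] * 3)})
    with pytest.raises(ValueError, match="99"):
        amova(two, n_perm=10)


# -------------------------------------------------------------- distances


def test_nei_distance_closed_forms():
    same = np.array([[0, 1, 2, 1]] * 6)
    panel = _panel_from_blocks({"P": same, "Q": same})
    assert nei_distance(panel).loc["P", "Q"] == pytest.approx(0.0, abs=1e-12)
    opp = _panel_from_blocks({"P": np.zeros((4, 5)), "Q": np.full((4, 5), 2.0)})
    assert np.isinf(nei_distance(opp).loc["P", "Q"])


def test_nei_distance_matches_oracle():
    rng = np.random.default_rng(11)
    blocks = {"P": rng.integers(0, 3, (10, 15)), "Q": rng.integers(0, 3, (8, 15))}
    panel = _panel_from_blocks(blocks)
    p1 = blocks["P"].mean(axis=0) / 2
    p2 = blocks["Q"].mean(axis=0) / 2
    assert nei_distance(panel).loc["P", "Q"] == pytest.approx(
        nei_naive(p1, p2), rel=1e-10
    )


def test_kosman_definitional_values():
    panel = _panel_from_blocks({
        "P": np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 2.0]]),
        "Q": np.array([[0.0, 0.0]]),
    })
    D, _ = kosman_distance(panel)
    assert D.loc["P0", "Q0"] == 0.0  # identical
    assert D.loc["P2", "Q0"] == 1.0  # opposite homozygotes everywhere
    assert D.loc["P1", "P0"] == pytest.approx(0.25)  # one 0-vs-1 locus of two


def test_kosman_matches_naive_with_missing():
    rng = np.random.default_rng(12)
    panel = random_panel(rng, n_pops=2, n_ind=5, n_loci=20, missing=0.2)
    D, _ = kosman_distance(panel)
    g = panel.genotypes.to_numpy()
    for i, a in enumerate(panel.individuals):
        for j, b in enumerate(panel.individuals):
            expected = 0.0 if i == j else kosman_naive(g[i], g[j])
            if np.isnan(expected):
                assert np.isnan(D.loc[a, b])
            else:
                assert D.loc[a, b] == pytest.approx(expected, rel=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.data())
def test_kosman_is_a_metric_on_complete_data(data):
    n_loci = data.draw(st.integers(1, 6))
    g = np.array([
        data.draw(st.lists(st.integers(0, 2), min_size=n_loci, max_size=n_loci))
        for _ in range(3)
    ], dtype=float)
    geno = pd.DataFrame(g, index=["x", "y", "z"], columns=[f"L{j}" for j in range(n_loci)])
    panel = GenotypePanel(geno, pd.Series({"x": "P", "y": "P", "z": "Q"}))
    D, _ = kosman_distance(panel)
    M = D.to_numpy()
    assert np.allclose(M, M.T)
    assert np.all(np.diag(M) == 0)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                assert M[i, j] <= M[i, k] + M[k, j] + 1e-12


def test_private_alleles_engineered_counts():
    # L0: alt allele only in P; L1: ref only in Q; L2: alt everywhere;
    # L3: alt only in R; L4: monomorphic ref (no private allele anywhere)
    blocks = {
        "P": np.array([[1, 2, 1, 0, 0], [2, 2, 1, 0, 0]]),
        "Q": np.array([[0, 1, 2, 0, 0], [0, 1, 1, 0, 0]]),
        "R": np.array([[0, 2, 1, 1, 0], [0, 2, 0, 2, 0]]),
    }
    priv = private_alleles(_panel_from_blocks(blocks))
    assert priv.to_dict() == {"P": 1, "Q": 1, "R": 1}


def test_private_alleles_shared_allele_counts_zero():
    blocks = {"P": np.array([[1]] * 3), "Q": np.array([[1]] * 3)}
    priv = private_alleles(_panel_from_blocks(blocks))
    assert priv.to_dict() == {"P": 0, "Q": 0}


# ----------------------------------------------------------------- Mantel


def test_mantel_affine_relation_gives_r_one():
    rng = np.random.default_rng(13)
    n = 5
    X = np.abs(rng.standard_normal((n, n)))
    X = (X + X.T) / 2
    np.fill_diagonal(X, 0)
    Y = 2.5 * X + 1.0
    np.fill_diagonal(Y, 0)
    r, p = mantel(X, Y, n_perm=499, seed=0)
    assert r == pytest.approx(1.0)
    assert p <= 0.05


def test_mantel_p_matches_full_enumeration_four_pops():
    rng = np.random.default_rng(14)
    A = np.abs(rng.standard_normal((4, 4)))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0)
    B = A + 0.3 * np.abs(rng.standard_normal((4, 4)))
    B = (B + B.T) / 2
    np.fill_diagonal(B, 0)
    r_exact, p_exact = mantel_exact_p(A, B)
    r, p = mantel(A, B, n_perm=4999, seed=1)
    assert r == pytest.approx(r_exact)
    # MC estimate of the enumerated p (24 relabelings)
    assert p == pytest.approx(p_exact, abs=0.02)


def test_mantel_agrees_with_skbio():
    pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

    rng = np.random.default_rng(15)
    n = 8
    A = np.abs(rng.standard_normal((n, n)))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0)
    B = A + np.abs(rng.standard_normal((n, n))) * 0.5
    B = (B + B.T) / 2
    np.fill_diagonal(B, 0)
    r, p = mantel(A, B, n_perm=999, seed=2)
    r_sk, p_sk, _ = sk_mantel(
        DistanceMatrix(A), DistanceMatrix(B), method="pearson",
        permutations=999, alternative="greater",
    )
    assert r == pytest.approx(float(r_sk), rel=1e-10)
    assert p == pytest.approx(float(p_sk), abs=0.03)


def test_mantel_ibd_serial_structure(small_config):
    from dunefly.simulate import PopulationSpec, simulate_snps

    cfg = small_config
    cfg.populations = [
        PopulationSpec(f"P{i}", 2, 10, -35.0 - 0.5 * i, 150.0) for i in range(5)
    ]
    cfg.genetics.n_loci = 1500
    cfg.genetics.fst = 0.04
    cfg.genetics.spatial = "serial"
    panel = simulate_snps(cfg)
    res = mantel_ibd(panel, n_perm=499, seed=3)
    assert res["r"] > 0.5
    assert res["p_value"] < 0.05


def test_mantel_requires_enough_populations():
    rng = np.random.default_rng(16)
    panel = random_panel(rng, n_pops=2, n_ind=4, n_loci=10, coords=True)
    with pytest.raises(ValueError):
        mantel_ibd(panel)


def test_haversine_known_distance():
    # one degree of latitude is ~111.2 km
    assert haversine_km(-35.0, 150.0, -36.0, 150.0) == pytest.approx(111.2, rel=0.01)
    coords = pd.DataFrame({"lat": [-35.0, -36.0], "lon": [150.0, 150.0]},
                          index=["a", "b"])
    geo = geographic_distances(coords)
    assert geo.loc["a", "b"] == pytest.approx(111.2, rel=0.01)
    planar = geographic_distances(coords, method="euclidean")
    assert planar.loc["a", "b"] == pytest.approx(1.0)


# -------------------------------------------------------------------- PCA


def test_pca_two_clusters_rank_one():
    g = np.vstack([np.tile([0.0, 0.0, 2.0, 2.0], (5, 1)),
                   np.tile([2.0, 2.0, 0.0, 0.0], (5, 1))])
    geno = pd.DataFrame(g, index=[f"i{k}" for k in range(10)],
                        columns=[f"L{j}" for j in range(4)])
    panel = GenotypePanel(geno, pd.Series(["P"] * 5 + ["Q"] * 5, index=geno.index))
    res = genotype_pca(panel)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)
    scores = np.sign(res.scores["PC1"].to_numpy())
    assert len(set(scores[:5])) == 1
    assert (scores[:5] != scores[5:]).all()


def test_pca_matches_sklearn():
    sklearn = pytest.importorskip("sklearn.decomposition")
    rng = np.random.default_rng(17)
    panel = random_panel(rng, n_pops=2, n_ind=10, n_loci=30)
    res = genotype_pca(panel, n_components=5)
    skp = sklearn.PCA(n_components=5).fit(panel.genotypes.to_numpy())
    assert np.allclose(res.explained_variance_ratio, skp.explained_variance_ratio_,
                       atol=1e-10)


def test_pca_mean_imputes_missing():
    rng = np.random.default_rng(18)
    panel = random_panel(rng, n_pops=2, n_ind=6, n_loci=15, missing=0.1)
    res = genotype_pca(panel)
    assert np.isfinite(res.scores.to_numpy()).all()


# --------------------------------------------------------------------- IO


def test_dosage_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(19)
    panel = random_panel(rng, n_pops=2, n_ind=4, n_loci=8, missing=0.1, coords=True)
    from dunefly.simulate import write_panel_csv

    paths = [tmp_path / n for n in ("g.csv", "pm.csv", "md.csv")]
    write_panel_csv(panel, *paths)
    back = read_dosage_csv(paths[0], paths[1])
    pd.testing.assert_frame_equal(back.genotypes, panel.genotypes,
                                  check_names=False)
    assert back.populations.to_dict() == panel.populations.to_dict()
    pd.testing.assert_frame_equal(back.coords, panel.coords, check_names=False)


def test_read_vcf_biallelic_dosages(tmp_path):
    vcf = tmp_path / "tiny.vcf"
    vcf.write_text("""##fileformat=VCFv4.2
##contig=<ID=1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t10\tv1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t20\tv2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1
1\t30\tv3\tG\tA,C\t.\tPASS\t.\tGT\t0/0\t0/1\t0/2
""")
    popmap = tmp_path / "pm.csv"
    popmap.write_text("individual_id,population\ns1,P\ns2,P\ns3,Q\n")
    panel = read_vcf(vcf, popmap)
    assert panel.loci == ["v1", "v2"]  # multiallelic v3 dropped
    assert panel.genotypes.loc["s1", "v1"] == 0.0
    assert panel.genotypes.loc["s2", "v1"] == 1.0
    assert panel.genotypes.loc["s3", "v1"] == 2.0
    assert np.isnan(panel.genotypes.loc["s1", "v2"])


def test_panel_rejects_bad_entries():
    g = pd.DataFrame([[0.0, 3.0]], index=["a"], columns=["L0", "L1"])
    with pytest.raises(ValueError, match="0, 1, 2 or missing"):
        GenotypePanel(g, pd.Series({"a": "P"}))
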