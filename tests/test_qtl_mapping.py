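"""Scan numerics: LOD identities, pseudomarker consistency, thresholds, cofactors."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from qtlconverge.genome_model import QtlInterval
from qtlconverge.qtl_mapping import (
    QTLScan,
    composite_scan,
    interval_scan,
    permutation_threshold,
    single_marker_scan,
)
from qtlconverge.synthetic_data import (
    MappingPopulationConfig,
    PlantedQtl,
    SimulationConfig,
    simulate_mapping_population,
)


def _toy_population(rng, n=60, n_markers=8, spacing_cm=10.0, beta=0.0, qtl_idx=3):
    markers = [f"m{j}" for j in range(n_markers)]
    X = 2.0 * (rng.random((n, n_markers)) < 0.5)
    y = 100.0 + beta * X[:, qtl_idx] + rng.normal(0, 1, n)
    geno = pd.DataFrame(X, columns=markers)
    mm = pd.DataFrame(
        {
            "marker_id": markers,
            "chromosome": "chr1",
            "position_bp": (np.arange(n_markers) * spacing_cm * 250_000).astype(int),
            "position_cM": np.arange(n_markers) * spacing_cm,
        }
    )
    return geno, pd.Series(y), mm


def test_constant_phenotype_all_lod_zero(rng):
    geno, y, mm = _toy_population(rng)
    res = single_marker_scan(geno, np.full(len(y), 7.0), mm)
    assert np.allclose(res.profile["LOD"], 0.0)


def test_lod_f_equivalence(rng):
    """LOD = (n/2) log10(1 + F/(n-2)) for the single-marker regression."""
    geno, y, mm = _toy_population(rng, beta=0.7)
    res = single_marker_scan(geno, y, mm)
    n = len(y)
    r2 = res.profile["r_squared"].to_numpy()
    F = r2 / (1 - r2) * (n - 2)
    lod_from_f = (n / 2) * np.log10(1 + F / (n - 2))
    assert np.allclose(res.profile["LOD"], lod_from_f, atol=1e-8)


def test_r_squared_invariant_under_affine_phenotype(rng):
    geno, y, mm = _toy_population(rng, beta=0.5)
    r2_a = single_marker_scan(geno, y, mm).profile["r_squared"]
    r2_b = single_marker_scan(geno, 3.0 * y - 250.0, mm).profile["r_squared"]
    assert np.allclose(r2_a, r2_b, atol=1e-12)


def test_perfect_separation_lod_capped(rng):
    geno, y, mm = _toy_population(rng)
    y = pd.Series(np.where(geno["m3"] == 2.0, 10.0, 0.0))  # two point masses
    res = single_marker_scan(geno, y, mm)
    row = res.profile.set_index("marker_id").loc["m3"]
    assert row["r_squared"] >= 1 - 1e-9
    assert np.isfinite(row["LOD"])
    # capped at the RSS floor: LOD <= (n/2) * 12 (up to float rounding of the floor)
    assert row["LOD"] <= len(y) / 2 * 12.001


def test_monomorphic_marker_lod_zero_with_warning(rng):
    geno, y, mm = _toy_population(rng, beta=0.4)
    geno["m0"] = 0.0
    with pytest.warns(UserWarning, match="monomorphic"):
        res = single_marker_scan(geno, y, mm)
    assert res.profile.set_index("marker_id").loc["m0", "LOD"] == 0.0


def test_additive_effect_is_half_homozygote_difference(rng):
    geno, y, mm = _toy_population(rng, beta=1.0)
    res = single_marker_scan(geno, y, mm)
    y_arr = np.asarray(y)
    for j, m in enumerate(mm["marker_id"]):
        x = geno[m].to_numpy()
        expected = (y_arr[x == 2.0].mean() - y_arr[x == 0.0].mean()) / 2
        assert res.profile.set_index("marker_id").loc[m, "additive_effect"] == (
            pytest.approx(expected, abs=1e-10)
        )


def test_interval_scan_matches_single_marker_at_markers(rng):
    geno, y, mm = _toy_population(rng, beta=0.8)
    sm = single_marker_scan(geno, y, mm).profile.set_index("marker_id")
    iv = interval_scan(geno, y, mm).profile
    at_markers = iv[iv["position_cM"].isin(mm["position_cM"])].set_index("marker_id")
    for m in mm["marker_id"]:
        assert at_markers.loc[m, "LOD"] == pytest.approx(sm.loc[m, "LOD"], abs=1e-10)


def test_interval_peak_recovers_midpoint_qtl():
    """QTL midway between 10 cM markers: peak within 5 cM in >= 90% of seeds."""
    iv_q = QtlInterval("q", "chr1", 4_750_000, 5_250_000)  # midpoint 5.0 Mb = 20 cM
    ok = 0
    n_seeds = 40
    for seed in range(n_seeds):
        cfg = SimulationConfig(
            seed=1000 + seed, n_chromosomes=2, chromosome_length_bp=10_000_000,
            n_genes=100, hotspots=(), polymorphic_blocks=(),
            mapping_pop=MappingPopulationConfig(
                n_individuals=300, marker_spacing_bp=2_500_000,  # 10 cM spacing
                planted_qtl=(PlantedQtl(iv_q, 0.15),),
            ),
        )
        pop = simulate_mapping_population(cfg)
        res = interval_scan(pop.genotypes, pop.phenotype, pop.marker_map)
        prof = res.profile
        peak = prof.loc[prof["LOD"].idxmax()]
        if peak["chromosome"] == "chr1" and abs(peak["position_cM"] - 20.0) <= 5.0:
            ok += 1
    assert ok >= 0.9 * n_seeds


def test_threshold_deterministic_and_alpha_edges(rng):
    geno, y, mm = _toy_population(rng)
    t1 = permutation_threshold(geno, y, mm, n_perm=100, alpha=0.05, seed=12)
    t2 = permutation_threshold(geno, y, mm, n_perm=100, alpha=0.05, seed=12)
    assert t1 == t2
    tmin = permutation_threshold(geno, y, mm, n_perm=100, alpha=1.0, seed=12)
    # alpha = 1 -> the minimum permuted max-LOD
    assert tmin <= t1


def test_threshold_monotone_in_alpha(rng):
    geno, y, mm = _toy_population(rng)
    thresholds = [
        permutation_threshold(geno, y, mm, n_perm=200, alpha=a, seed=5)
        for a in (0.01, 0.05, 0.2, 0.5)
    ]
    assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))


def test_composite_zero_cofactors_equals_interval(rng):
    geno, y, mm = _toy_population(rng, beta=0.6)
    a = interval_scan(geno, y, mm).profile
    b = composite_scan(geno, y, mm, n_cofactors=0).profile
    pd.testing.assert_frame_equal(a, b)


def test_composite_separates_linked_qtl():
    """Two QTL 60 cM apart on one chromosome: cofactors resolve both peaks."""
    rng = np.random.default_rng(8)
    n, n_markers = 400, 21
    markers = [f"m{j}" for j in range(n_markers)]
    cm = np.arange(n_markers) * 5.0  # 0..100 cM
    # simulate linked genotypes along the chromosome
    from qtlconverge.synthetic_data import _simulate_chain

    states = _simulate_chain(rng, n, cm, 0.5)
    X = 2.0 * states
    q1, q2 = 4, 16  # 20 cM and 80 cM
    y = X[:, q1] * 2.0 + X[:, q2] * 2.0 + rng.normal(0, 2.0, n)
    geno = pd.DataFrame(X, columns=markers)
    mm = pd.DataFrame(
        {"marker_id": markers, "chromosome": "chr1",
         "position_bp": (cm * 250_000).astype(int), "position_cM": cm}
    )
    res = composite_scan(geno, pd.Series(y), mm, n_cofactors=4)
    prof = res.profile.sort_values("position_cM")
    lod = prof["LOD"].to_numpy()
    pos = prof["position_cM"].to_numpy()
    # local maxima above half the global max
    peaks = [
        pos[i]
        for i in range(1, len(lod) - 1)
        if lod[i] >= lod[i - 1] and lod[i] >= lod[i + 1] and lod[i] > lod.max() / 2
    ]
    assert any(abs(p - 20.0) <= 10 for p in peaks)
    assert any(abs(p - 80.0) <= 10 for p in peaks)


def test_missing_genotypes_handled_close_to_complete(rng):
    geno, y, mm = _toy_population(rng, n=200, beta=0.8)
    full = single_marker_scan(geno, y, mm).profile["LOD"].to_numpy()
    holey = geno.mask(rng.random(geno.shape) < 0.05)
    miss = single_marker_scan(holey, y, mm).profile["LOD"].to_numpy()
    assert np.all(np.isfinite(miss))
    assert np.corrcoef(full, miss)[0, 1] > 0.95
    # interval mode imputes from flanking markers
    res = interval_scan(holey, y, mm)
    assert np.all(np.isfinite(res.profile["LOD"]))


def test_small_population_rejected(rng):
    geno, y, mm = _toy_population(rng, n=20)
    with pytest.raises(ValueError, match="n >= 30"):
        single_marker_scan(geno, y, mm)


def test_summary_and_peak_schema(rng):
    """Peak table mirrors the standard scan-report columns."""
    geno, y, mm = _toy_population(rng, beta=0.9)
    model = QTLScan(geno, y, mm)
    res = model.fit(method="interval", n_perm=50, alpha=0.05, perm_seed=1)
    peaks = res.peaks()
    assert list(peaks.columns) == [
        "chromosome", "marker_interval", "peak_marker", "position_cM",
        "position_bp", "LOD", "r_squared", "additive_effect",
    ]
    text = res.summary()
    assert "permutation threshold" in text and "LOD" in text
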