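"""Multiphase equilibrium partitioning: tissue log K, ratios, phase loads."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfer2p import (
    TissueComposition,
    builtin_tissue_compositions,
    distribution_ratio,
    load_tissue_compositions,
    milk_k,
    phase_loads,
    phase_logk_from_2p,
    tissue_k,
)

MIXED = TissueComposition("demo", f_water=0.7, f_storage_lipid=0.2,
                          f_structural_protein=0.1)
MIXED_K = {"storage_lipid": 3.0, "structural_protein": 2.0}

fractions = st.lists(
    st.floats(min_value=0.0, max_value=1.0), min_size=4, max_size=4)
logks = st.lists(
    st.floats(min_value=-2.0, max_value=6.0), min_size=4, max_size=4)


def composition_from(fs):
    total = sum(fs) + 1.0  # ensure water dominates denominator sanity
    return TissueComposition(
        "rand", f_water=1.0 / total,
        f_storage_lipid=fs[0] / total, f_phospholipid=fs[1] / total,
        f_structural_protein=fs[2] / total, f_albumin=fs[3] / total,
    )


def test_pure_water_is_identity():
    assert tissue_k(TissueComposition("water", f_water=1.0), {}) == 0.0


def test_single_phase_identity():
    comp = TissueComposition("protein", f_water=0.0, f_structural_protein=1.0)
    assert tissue_k(comp, {"structural_protein": 2.0}) == pytest.approx(2.0)


def test_mixed_tissue_hand_arithmetic():
    # 0.7 + 0.2*10^3 + 0.1*10^2 = 210.7
    assert tissue_k(MIXED, MIXED_K) == pytest.approx(math.log10(210.7), abs=1e-9)
    assert tissue_k(MIXED, MIXED_K) == pytest.approx(2.3236, abs=1e-4)


def test_missing_phase_logk_is_named():
    with pytest.raises(ValueError, match="structural_protein"):
        tissue_k(MIXED, {"storage_lipid": 3.0})


def test_distribution_ratio_identity_and_vs_water():
    assert distribution_ratio(MIXED, MIXED, MIXED_K) == 0.0
    water = TissueComposition("water", f_water=1.0)
    assert distribution_ratio(MIXED, water, MIXED_K) == pytest.approx(
        2.3236, abs=1e-4)


@given(fs=fractions, ks=logks)
@settings(max_examples=50, derandomize=True)
def test_distribution_ratio_antisymmetric(fs, ks):
    a = composition_from(fs)
    b = composition_from(fs[::-1])
    phase_logK = dict(zip(
        ("storage_lipid", "phospholipid", "structural_protein", "albumin"), ks))
    assert distribution_ratio(a, b, phase_logK) == pytest.approx(
        -distribution_ratio(b, a, phase_logK), abs=1e-12)


def test_phase_loads_two_term_closure():
    comp = TissueComposition("x", f_water=0.9, f_storage_lipid=0.1)
    loads = phase_loads(comp, {"storage_lipid": 2.0})
    expected = 0.1 * 100 / (0.9 + 0.1 * 100)
    assert loads["storage_lipid"] == pytest.approx(expected, abs=1e-12)


def test_phase_loads_hand_arithmetic():
    loads = phase_loads(MIXED, MIXED_K)
    assert loads["storage_lipid"] == pytest.approx(200 / 210.7, abs=1e-9)
    assert loads["storage_lipid"] == pytest.approx(0.9492, abs=1e-4)


@given(fs=fractions, ks=logks)
@settings(max_examples=50, derandomize=True)
def test_phase_loads_sum_to_one(fs, ks):
    comp = composition_from(fs)
    phase_logK = dict(zip(
        ("storage_lipid", "phospholipid", "structural_protein", "albumin"), ks))
    loads = phase_loads(comp, phase_logK)
    assert sum(loads.fractions.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(v >= 0 for v in loads.fractions.values())


def test_tissue_k_monotone_in_phase_logk_and_fraction():
    base = tissue_k(MIXED, MIXED_K)
    higher_k = tissue_k(MIXED, {**MIXED_K, "structural_protein": 3.0})
    assert higher_k > base
    fatter = TissueComposition("f", f_water=0.6, f_storage_lipid=0.3,
                               f_structural_protein=0.1)
    assert tissue_k(fatter, MIXED_K) > base


def test_tissue_k_convexity_bounds():
    rng = np.random.default_rng(17)
    for _ in range(25):
        fs = rng.dirichlet(np.ones(5))
        comp = TissueComposition("r", f_water=fs[0], f_storage_lipid=fs[1],
                                 f_phospholipid=fs[2],
                                 f_structural_protein=fs[3], f_albumin=fs[4])
        ks = dict(zip(("storage_lipid", "phospholipid",
                       "structural_protein", "albumin"),
                      rng.uniform(-2, 6, size=4)))
        logk = tissue_k(comp, ks)
        assert logk >= min(0.0, *ks.values()) - 1e-9
        upper = max(k + math.log10(f) for k, f in [
            (0.0, comp.f_water), (ks["storage_lipid"], comp.f_storage_lipid),
            (ks["phospholipid"], comp.f_phospholipid),
            (ks["structural_protein"], comp.f_structural_protein),
            (ks["albumin"], comp.f_albumin)] if f > 0)
        assert logk <= upper + math.log10(5) + 1e-9


def test_milk_with_zero_solids_and_fat_asymptote():
    assert milk_k(TissueComposition("skim", f_water=1.0), {}) == 0.0
    fatty = TissueComposition("cream", f_water=0.5, f_storage_lipid=0.5)
    for klw in (6.0, 8.0, 10.0):
        got = milk_k(fatty, {"storage_lipid": klw})
        assert got == pytest.approx(klw + math.log10(0.5), abs=1e-3)


def test_composition_validation_and_renormalization():
    with pytest.raises(ValueError, match="outside"):
        TissueComposition("bad", f_water=0.5)
    with pytest.raises(ValueError):
        TissueComposition("neg", f_water=1.2, f_albumin=-0.2)
    with pytest.warns(UserWarning, match="renormalizing"):
        comp = TissueComposition("round", f_water=0.99, f_albumin=0.02)
    assert sum(comp.as_dict().values()) == pytest.approx(1.0, abs=1e-12)


def test_builtin_compositions_load_and_work():
    tissues = builtin_tissue_compositions()
    assert {"plasma", "muscle", "liver", "milk"} <= set(tissues)
    phase_logK = phase_logk_from_2p(4.0, -4.24)
    for comp in tissues.values():
        logk = tissue_k(comp, phase_logK)
        assert math.isfinite(logk)
        assert sum(phase_loads(comp, phase_logK).fractions.values()) == \
            pytest.approx(1.0, abs=1e-9)


def test_protein_rich_tissue_binds_more_than_plasma():
    # a hydrophobic, low-volatility chemical partitions more into muscle than plasma
    tissues = builtin_tissue_compositions()
    phase_logK = phase_logk_from_2p(5.0, -5.0)
    assert distribution_ratio(tissues["muscle"], tissues["plasma"],
                              phase_logK) > 0


def test_load_compositions_from_file(tmp_path):
    path = tmp_path / "comps.json"
    path.write_text('{"tissues": {"demo": {"f_water": 0.8, '
                    '"f_storage_lipid": 0.2}}}')
    comps = load_tissue_compositions(path)
    assert comps["demo"].f_storage_lipid == 0.2


def test_phase_logk_from_2p_consistency():
    phase_logK = phase_logk_from_2p(6.13, -4.73)
    assert phase_logK["structural_protein"] == pytest.approx(4.572, abs=1e-3)
    assert set(phase_logK) == {"storage_lipid", "phospholipid",
                               "structural_protein", "albumin"}
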