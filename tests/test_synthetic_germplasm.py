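"""Generator: determinism, genetic-model identities, structural fixtures."""

import numpy as np
import pytest

from pedbreed.pedfile_io import (
    PedimapParseError,
    PedimapValidationError,
    parse_pedimap,
    validate_dataset,
    write_pedimap,
)
from pedbreed.pedigree_graph import build_graph
from pedbreed.synthetic_germplasm import (
    GenerationPlan,
    QuantTraitSpec,
    SimConfig,
    default_config,
    fixture_suite,
    simulate,
    study_scale_config,
    tbv_to_tsv,
)


def test_same_seed_reproduces_byte_identical_files():
    a, tbv_a = simulate(default_config(7))
    b, tbv_b = simulate(default_config(7))
    assert write_pedimap(a) == write_pedimap(b)
    assert tbv_to_tsv(tbv_a) == tbv_to_tsv(tbv_b)
    c, _ = simulate(default_config(8))
    assert write_pedimap(c) != write_pedimap(a)


def test_output_validates_and_roundtrips():
    ds, _ = simulate(default_config(3))
    assert [i for i in validate_dataset(ds) if i.severity == "error"] == []
    assert parse_pedimap(write_pedimap(ds)).equals(ds)


def test_noise_free_limit_perfect_accuracy():
    cfg = SimConfig(
        n_founders=40,
        plan=[GenerationPlan(n_crosses=20)],
        traits=[QuantTraitSpec("yield", 5.0, var_a=0.5, var_e=0.0)],
        missing_rate=0.0,
        lg_map=None,
        seed=5,
    )
    ds, tbv = simulate(cfg)
    p = np.array([r.phenotypes["yield"] for r in ds.records])
    assert np.corrcoef(p, tbv["yield"].to_numpy())[0, 1] == pytest.approx(1.0)


def test_founder_cohort_tbv_variance():
    cfg = SimConfig(
        n_founders=4000, plan=[], traits=[QuantTraitSpec("t", 0.0, var_a=2.0, var_e=1.0)],
        missing_rate=0.0, lg_map=None, seed=11,
    )
    _, tbv = simulate(cfg)
    assert tbv["t"].var() == pytest.approx(2.0, rel=0.1)


def test_realized_heritability_near_configured():
    cfg = SimConfig(
        n_founders=2000, plan=[], traits=[QuantTraitSpec("yield", 5.5, var_a=0.4, var_e=0.4)],
        missing_rate=0.0, lg_map=None, seed=2,
    )
    ds, tbv = simulate(cfg)
    p = np.array([r.phenotypes["yield"] for r in ds.records])
    realized = tbv["yield"].to_numpy().var() / p.var()
    assert realized == pytest.approx(0.5, abs=0.05)


def test_midparent_offspring_regression_slope_is_h2():
    """Classic identity: slope of offspring phenotype on midparent phenotype = H^2."""
    cfg = SimConfig(
        n_founders=1000,
        plan=[GenerationPlan(n_crosses=2000)],
        traits=[QuantTraitSpec("yield", 5.5, var_a=0.4, var_e=0.4)],
        missing_rate=0.0,
        lg_map=None,
        seed=6,
    )
    ds, _ = simulate(cfg)
    pheno = {r.name: r.phenotypes["yield"] for r in ds.records}
    mid, off = [], []
    for r in ds.records:
        if r.mother is not None and r.mother != r.father:
            mid.append(0.5 * (pheno[r.mother] + pheno[r.father]))
            off.append(pheno[r.name])
    slope = np.polyfit(mid, off, 1)[0]
    assert slope == pytest.approx(0.5, abs=0.05)


def test_categorical_traits_are_heritable_and_penetrant():
    cfg = SimConfig(
        n_founders=6,
        plan=[GenerationPlan(n_crosses=10)],
        categorical_traits=default_config().categorical_traits[:1],  # pericarp
        missing_rate=0.0,
        lg_map=None,
        seed=9,
    )
    ds, _ = simulate(cfg)
    levels = {r.phenotypes["pericarp_color"] for r in ds.records}
    assert levels <= {"white", "red"}
    # recessive level breeds true: red x red -> red (white is dominant)
    red = {r.name for r in ds.records if r.phenotypes["pericarp_color"] == "red"}
    for r in ds.records:
        if r.mother in red and r.father in red:
            assert r.phenotypes["pericarp_color"] == "red"


def test_study_scale_counts():
    """224 records: 36 unreported intermediates, 188 named with trait records."""
    ds, _ = simulate(study_scale_config(0))
    assert len(ds.records) == 224
    intermediates = [r for r in ds.records if r.name.startswith("X")]
    assert len(intermediates) == 36
    assert all(all(v is None for v in r.phenotypes.values()) for r in intermediates)
    named = [r for r in ds.records if not r.name.startswith("X")]
    assert len(named) == 188
    assert [i for i in validate_dataset(ds) if i.severity == "error"] == []


def test_markers_follow_map_and_pedigree():
    ds, _ = simulate(default_config(1))
    assert ds.maps and ds.genotypes
    loci = {l for m in ds.maps for l in m.locus_names}
    assert {g.locus for g in ds.genotypes} == loci
    # founder marker alleles are the founder's own two labels, children inherit
    g = build_graph(ds.records)
    by = {(x.individual, x.locus): x.alleles for x in ds.genotypes}
    for rec in ds.records:
        m, p = g.parents(rec.name)
        if m is None or m in g.phantoms or p in g.phantoms:
            continue
        for locus in loci:
            a = set(by[(rec.name, locus)])
            assert a <= set(by[(m, locus)]) | set(by[(p, locus)])


def test_backcross_fixture_topology(backcross):
    """Phase-1 cross, selfing chain, phase-2 backcross to a donor parent."""
    g = build_graph(backcross.records)
    assert g.is_selfing("F2") and g.is_selfing("RIL")
    m, p = g.parents("BC1")
    assert {m, p} == {"RIL", "DONOR"}
    assert g.parents("F1") == ("P1", "P2")


def test_malformed_fixtures_each_fail(fixtures):
    for name, text in fixtures["malformed"].items():
        with pytest.raises((PedimapParseError, PedimapValidationError)):
            parse_pedimap(text)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(n_founders=0)
    with pytest.raises(ValueError):
        SimConfig(missing_rate=1.0)
    with pytest.raises(ValueError):
        QuantTraitSpec("x", 0.0, var_a=-1.0, var_e=0.0)
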