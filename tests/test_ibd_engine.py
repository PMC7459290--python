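"""Founder-allele IBD: exact recursion, gene dropping, conservation, kinship consistency."""

import numpy as np
import pytest

from pedbreed.ibd_engine import (
    attach_ibd,
    founder_allele_index,
    gene_drop,
    haldane,
    ibd_exact,
    ibd_to_tsv,
    kinship_gene_drop,
)
from pedbreed.pedfile_io import LinkageGroupMap, PedigreeRecord, parse_pedimap, validate_dataset, write_pedimap
from pedbreed.pedigree_graph import build_graph, kinship


def _bc1_graph():
    recs = [
        PedigreeRecord("A", None, None),
        PedigreeRecord("B", None, None),
        PedigreeRecord("F1", "A", "B"),
        PedigreeRecord("BC1", "F1", "A"),
    ]
    return build_graph(recs)


def test_exact_founder_base_case(trio):
    g = build_graph(trio.records)
    v = ibd_exact(g)
    idx = founder_allele_index(g)
    assert idx.entries == [("A", 1), ("A", 2), ("B", 1), ("B", 2)]
    assert list(v["A"]) == [1.0, 1.0, 0.0, 0.0]
    assert list(v["F1"]) == [0.5, 0.5, 0.5, 0.5]


def test_exact_backcross_enumeration_oracle():
    """BC1 = (AxB) x A: enumerate the 2-generation gamete transmissions.

    The F1 gamete carries A's slot1/slot2/B's slot1/slot2 with probability
    1/4 each; the recurrent A gamete carries A's slots with 1/2 each. Summing
    gives 0.75 per A slot and 0.25 per B slot (1.5 vs 0.5 total mass).
    """
    v = ibd_exact(_bc1_graph())["BC1"]
    assert np.allclose(v, [0.75, 0.75, 0.25, 0.25])
    assert v[:2].sum() == pytest.approx(1.5)
    assert v[2:].sum() == pytest.approx(0.5)


def test_exact_selfing_invariance():
    recs = [
        PedigreeRecord("A", None, None),
        PedigreeRecord("B", None, None),
        PedigreeRecord("F1", "A", "B"),
        PedigreeRecord("F2", "F1", "F1"),
    ]
    v = ibd_exact(build_graph(recs))
    assert np.allclose(v["F2"], v["F1"])


def test_exact_conservation(germplasm50):
    g = build_graph(germplasm50.records)
    for vec in ibd_exact(g).values():
        assert vec.sum() == pytest.approx(2.0, abs=1e-9)
        assert np.all(vec >= 0) and np.all(vec <= 1 + 1e-12)


def test_gene_drop_f1_binomial(trio):
    g = build_graph(trio.records)
    m = LinkageGroupMap("LG1", [("M1", 0.0)])
    res = gene_drop(g, m, n_reps=8000, seed=11)
    v, se = res.freq["F1"][0], res.se["F1"][0]
    assert np.all(np.abs(v - 0.5) <= 3 * se)
    assert v.sum() == pytest.approx(2.0, abs=1e-9)


def test_gene_drop_zero_distance_identical_inheritance():
    g = _bc1_graph()
    m = LinkageGroupMap("LG1", [("M1", 10.0), ("M2", 10.0)])
    res = gene_drop(g, m, n_reps=500, seed=5)
    for ind in ("F1", "BC1"):
        assert np.array_equal(res.freq[ind][0], res.freq[ind][1])


def test_gene_drop_distant_positions_uncorrelated():
    """At r -> 1/2 the inheritance indicators at two positions decouple."""
    from pedbreed.ibd_engine import _drop_alleles

    g = _bc1_graph()
    idx = founder_allele_index(g)
    rng = np.random.default_rng(7)
    pos = np.array([0.0, 10000.0])  # r ~ 0.5
    a = _drop_alleles(g, pos, n_reps=20000, rng=rng, index=idx)
    # indicator: BC1's F1-derived copy carries a B allele (slot >= 2)
    ind = (a["BC1"][:, :, 0] >= 2).astype(float)
    corr = np.corrcoef(ind[:, 0], ind[:, 1])[0, 1]
    assert abs(corr) < 3.0 / np.sqrt(len(ind))


def test_gene_drop_determinism(germplasm50):
    g = build_graph(germplasm50.records)
    m = germplasm50.maps[0]
    r1 = gene_drop(g, m, n_reps=200, seed=42)
    r2 = gene_drop(g, m, n_reps=200, seed=42)
    for ind in r1.freq:
        assert np.array_equal(r1.freq[ind], r2.freq[ind])


def test_gene_drop_rejects_bad_args(trio):
    g = build_graph(trio.records)
    m = LinkageGroupMap("LG1", [("M1", 0.0)])
    with pytest.raises(ValueError):
        gene_drop(g, m, n_reps=0, seed=1)
    with pytest.raises(ValueError):
        gene_drop(g, m, n_reps=10, seed=1, positions_cm=[99.0])


def test_haldane_limits():
    assert haldane(0.0) == 0.0
    assert haldane(1e9) == pytest.approx(0.5)
    assert 0 < haldane(10.0) < haldane(50.0) < 0.5


def test_exact_vs_gene_drop_agreement(germplasm50):
    """Monte-Carlo frequencies agree with the recursion on every entry.

    The 3-sigma confidence level is applied family-wise (Bonferroni over the
    stochastic entries), since per-entry 3 SE across thousands of comparisons
    would flag chance excursions by construction.
    """
    from scipy.stats import norm

    g = build_graph(germplasm50.records)
    m = germplasm50.maps[0]
    res = gene_drop(g, m, n_reps=4000, seed=99)
    exact = ibd_exact(g)
    n_stochastic = sum(int(np.count_nonzero(res.se[ind])) for ind in exact)
    z = norm.isf(norm.sf(3.0) / max(n_stochastic, 1))
    for ind, v in exact.items():
        for pi in range(len(res.positions)):
            diff = np.abs(res.freq[ind][pi] - v)
            se = res.se[ind][pi]
            assert np.all(diff[se == 0] == 0), ind  # deterministic entries exact
            assert np.all(diff <= z * np.maximum(se, 1e-12) + 1e-12), ind


def test_gene_drop_kinship_consistency(backcross):
    """Single-replicate gamete IBD frequencies converge to pedigree kinship."""
    g = build_graph(backcross.records)
    names, est, sem = kinship_gene_drop(g, n_reps=20000, seed=13)
    k = kinship(g)
    for i, x in enumerate(names):
        for j, y in enumerate(names):
            expected = k.get(x, y)
            assert abs(est[i, j] - expected) <= 3 * max(sem[i, j], 1e-4)


def test_attach_ibd_exact_trio(trio):
    ds = parse_pedimap(write_pedimap(trio))  # work on a copy
    attach_ibd(ds, method="exact")
    assert ds.header.n_founder_alleles == 4
    assert len(ds.ibd) == 1  # map-less: one pseudo-position
    for row in ds.ibd[0].rows.values():
        assert sum(row) == pytest.approx(2.0)
    assert validate_dataset(ds) == []
    assert parse_pedimap(write_pedimap(ds)).equals(ds)


def test_attach_ibd_founders_only_identity():
    text = (
        "POPULATION\tF\nPLOIDY\t2\nUNKNOWN\t-\nPOSSIBLENULL\t?\nCONFIRMEDNULL\t!\n"
        "PEDIGREE\nName\tMother\tFather\nA\t-\t-\nB\t-\t-\n"
    )
    ds = parse_pedimap(text)
    attach_ibd(ds, method="exact")
    assert ds.ibd[0].rows["A"] == [1.0, 1.0, 0.0, 0.0]
    assert ds.ibd[0].rows["B"] == [0.0, 0.0, 1.0, 1.0]


def test_attach_ibd_nalleles_conflict(trio):
    ds = parse_pedimap(write_pedimap(trio))
    ds.header.n_founder_alleles = 99
    with pytest.raises(ValueError):
        attach_ibd(ds, method="exact")


def test_attach_gene_drop_requires_map(trio):
    ds = parse_pedimap(write_pedimap(trio))
    with pytest.raises(ValueError):
        attach_ibd(ds, method="gene_drop")


def test_ibd_tsv_export(trio):
    ds = parse_pedimap(write_pedimap(trio))
    attach_ibd(ds, method="exact")
    tsv = ibd_to_tsv(ds)
    lines = tsv.strip().splitlines()
    assert lines[0].split("\t") == ["individual", "group", "position_cm", "founder", "allele_slot", "probability"]
    assert len(lines) == 1 + 3 * 4  # 3 individuals x 4 founder alleles
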