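"""TMT filters, reporter matching, rollup, and normalizations."""

import numpy as np
import pandas as pd
import pytest

from ubquant import tmt
from ubquant.simulate import EffectModel, eleven_plex_parkin, gen_tmt_experiment, ten_plex_usp30


def make_psm(spec=1.0, sn=1000.0, ms3=True, protein="P1", site=10,
             mod="diGLY", ascore=100.0, channels=("126", "127N"), values=(5.0, 7.0)):
    row = {"peptide": "PEPK", "protein": protein, "mod_type": mod, "site": site,
           "ascore": ascore, "isolation_specificity": spec, "summed_sn": sn,
           "has_ms3": ms3}
    for ch, v in zip(channels, values):
        row[f"sn_{ch}"] = v
    return row


@pytest.mark.parametrize(
    "spec,sn,ms3,kept",
    [
        (0.69, 1000.0, True, False),   # specificity below 0.7 -> excluded
        (0.70, 1000.0, True, True),    # boundary retained
        (1.00, 150.0, True, True),     # summed S/N boundary retained
        (1.00, 149.9, True, False),    # below 150 -> excluded
        (1.00, 1000.0, False, False),  # no MS3 -> excluded
    ],
)
def test_filter_psms_thresholds(spec, sn, ms3, kept):
    df = pd.DataFrame([make_psm(spec=spec, sn=sn, ms3=ms3)])
    retained, audit = tmt.filter_psms(df)
    assert (len(retained) == 1) is kept
    assert audit["retained"] + audit["excluded_total"] == 1


def test_filter_idempotent_and_audit_matches_generator():
    psms, truth = gen_tmt_experiment(
        eleven_plex_parkin(), EffectModel(), 300, seed=21
    )
    once, audit = tmt.filter_psms(psms)
    twice, audit2 = tmt.filter_psms(once)
    pd.testing.assert_frame_equal(once, twice)
    assert audit2["excluded_total"] == 0
    v = truth.attrs["filter_violations"]
    assert audit["low_specificity"] == v["low_specificity"]
    assert audit["low_sn"] == v["low_sn"]
    assert audit["no_ms3"] == v["no_ms3"]


def test_match_reporter_centroids():
    refs = tmt.load_reporter_masses(11)
    assert len(refs) == 11
    ref = refs["128C"]
    # exact centroid
    out = tmt.match_reporter_centroids([(ref, 42.0)], refs)
    assert out["128C"] == 42.0
    # nearer of two candidates wins
    out = tmt.match_reporter_centroids([(ref + 0.002, 1.0), (ref - 0.0025, 2.0)], refs)
    assert out["128C"] == 1.0
    # nearest beyond the 0.003 Da tolerance reads zero
    out = tmt.match_reporter_centroids([(ref + 0.004, 9.0)], refs)
    assert out["128C"] == 0.0


def test_rollup_sums_psms_and_is_linear():
    rows = [
        make_psm(values=(1.0, 2.0)),
        make_psm(values=(3.0, 4.0)),
        make_psm(protein="P2", site=5, values=(10.0, 20.0)),
    ]
    df = pd.DataFrame(rows)
    mat = tmt.rollup(df, level="site")
    assert mat.loc[("P1", 10, "diGLY")].tolist() == [4.0, 6.0]
    assert mat.loc[("P2", 5, "diGLY")].tolist() == [10.0, 20.0]
    # linearity: rollup(concat) == rollup(a) + rollup(b)
    a, b = df.iloc[:1], df.iloc[1:]
    summed = tmt.rollup(a, "site").add(tmt.rollup(b, "site"), fill_value=0.0)
    pd.testing.assert_frame_equal(mat.sort_index(), summed.sort_index())


def test_rollup_site_requires_localization():
    df = pd.DataFrame([make_psm(ascore=12.9), make_psm(ascore=13.0)])
    mat = tmt.rollup(df, level="site")
    assert mat.loc[("P1", 10, "diGLY")].tolist() == [5.0, 7.0]  # only AScore>=13


def test_shared_peptides_resolved_by_parsimony():
    rows = [
        make_psm(protein="B", mod="none", site=0),
        make_psm(protein="B", mod="none", site=0),
        make_psm(protein="A;B", mod="none", site=0),
    ]
    mat = tmt.rollup(pd.DataFrame(rows), level="protein")
    assert list(mat.index) == ["B"]


def test_equal_loading_normalization():
    mat = pd.DataFrame({"sn_126": [1.0, 3.0], "sn_127N": [2.0, 6.0]})
    out = tmt.normalize_equal_loading(mat)
    sums = out.sum()
    assert np.allclose(sums, sums.iloc[0], rtol=1e-12)
    # already equal columns unchanged
    eq = pd.DataFrame({"sn_126": [1.0, 2.0], "sn_127N": [2.0, 1.0]})
    pd.testing.assert_frame_equal(tmt.normalize_equal_loading(eq), eq)
    # doubled column scaled back by 0.5
    doubled = pd.DataFrame({"sn_126": [1.0, 1.0], "sn_127N": [2.0, 2.0]})
    out = tmt.normalize_equal_loading(doubled)
    assert np.allclose(out["sn_127N"], [1.5, 1.5])


def test_equal_loading_random_matrix_property(rng):
    mat = pd.DataFrame(rng.uniform(1, 100, size=(40, 11)))
    mat.columns = [f"sn_{i}" for i in range(11)]
    out = tmt.normalize_equal_loading(mat)
    sums = out.sum()
    assert (abs(sums - sums.mean()) / sums.mean() < 1e-6).all()
    # per-feature cross-channel pattern preserved up to per-channel scalars
    scale = out.iloc[0] / mat.iloc[0]
    for i in range(1, 5):
        assert np.allclose(out.iloc[i], mat.iloc[i] * scale)


def test_site_to_protein_normalization_algebra():
    cols = ["sn_126", "sn_127N", "sn_128N"]
    site = pd.DataFrame(
        [[10.0, 10.0, 10.0]], columns=cols,
        index=pd.MultiIndex.from_tuples([("P1", 5, "diGLY")]),
    )
    # flat protein leaves the site unchanged
    prot = pd.DataFrame([[4.0, 4.0, 4.0]], columns=cols, index=["P1"])
    out, flags = tmt.normalize_site_to_protein(site, prot)
    assert np.allclose(out.values, site.values)
    assert flags.iloc[0] == "normalized"
    # protein halves in the last channel -> constant site doubles there
    prot = pd.DataFrame([[4.0, 4.0, 2.0]], columns=cols, index=["P1"])
    out, _ = tmt.normalize_site_to_protein(site, prot)
    rel = out.values[0] / out.values[0][0]
    assert rel[2] == pytest.approx(2.0 * rel[0] / rel[0] * (10/10), rel=1e-9)
    # absent protein passes through flagged
    orphan = site.rename(index={"P1": "PX"}, level=0)
    out, flags = tmt.normalize_site_to_protein(orphan, prot)
    assert flags.iloc[0] == "unnormalized"
    assert np.allclose(out.values, site.values)
    # zero protein channel -> missing site value
    prot = pd.DataFrame([[4.0, 0.0, 4.0]], columns=cols, index=["P1"])
    out, _ = tmt.normalize_site_to_protein(site, prot)
    assert np.isnan(out.values[0][1])


def test_site_to_protein_inverts_planted_drift():
    """A planted protein-abundance drift is inverted exactly noise-free."""
    cols = ["sn_126", "sn_127N", "sn_128N"]
    drift = np.array([1.0, 0.5, 2.0])
    site = pd.DataFrame(
        [100.0 * drift], columns=cols,
        index=pd.MultiIndex.from_tuples([("P1", 5, "diGLY")]),
    )
    prot = pd.DataFrame([50.0 * drift], columns=cols, index=["P1"])
    out, _ = tmt.normalize_site_to_protein(site, prot)
    vals = out.values[0]
    assert np.allclose(vals, vals[0])


def test_relative_to_untreated():
    design = ten_plex_usp30()
    cols = [f"sn_{ch}" for ch in design.channel_names]
    mat = pd.DataFrame([np.arange(1.0, 11.0)], columns=cols, index=["K6"])
    out = tmt.relative_to_untreated(mat, design)
    # untreated channels read exactly 1
    for geno in ("WT", "USP30KO"):
        ut = design.group(genotype=geno, treatment="UT")[0]
        assert out.loc["K6", f"sn_{ut}"] == pytest.approx(1.0)
    # each genotype normalized by its own untreated channel
    wt_ut = mat.loc["K6", f"sn_{design.group('WT', 'UT')[0]}"]
    four_h = design.group("WT", "AO", 4.0)[0]
    assert out.loc["K6", f"sn_{four_h}"] == pytest.approx(
        mat.loc["K6", f"sn_{four_h}"] / wt_ut
    )


def test_relative_to_untreated_requires_untreated_channels():
    design = eleven_plex_parkin()  # S65A has no untreated channel
    cols = [f"sn_{ch}" for ch in design.channel_names]
    mat = pd.DataFrame([np.ones(11)], columns=cols, index=["K6"])
    with pytest.raises(ValueError, match="untreated"):
        tmt.relative_to_untreated(mat, design)
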