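"""Deconvolution: peak picking, deisotoping, XIC integration, proteoform
quantification, and the mixture round-trip invariants."""

import math

import numpy as np
import pytest

from ubquant import intact
from ubquant.chem import UbProteoform, mz_for_charge, ub_dgg_candidates
from ubquant.intact import (
    Centroid,
    DeconvParams,
    DeconvolvedSpecies,
    ProfileSpectrum,
    UB_MASS_RANGE,
    deconvolve_run,
    deisotope,
    integrate_xic,
    pick_peaks,
    quantify_proteoforms,
)
from ubquant.simulate import (
    ProteoformMixture,
    SpectrumSimParams,
    gen_intact_spectra,
)


def gaussian_spectrum(mu, area, sigma=0.01):
    mz = np.arange(699.0, 703.0, 0.002)
    inten = area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
        -0.5 * ((mz - mu) / sigma) ** 2
    )
    return ProfileSpectrum(mz=mz, intensity=inten)


def test_flat_spectrum_yields_no_centroids():
    spec = ProfileSpectrum(mz=np.linspace(625, 925, 1000), intensity=np.zeros(1000))
    assert pick_peaks(spec) == []


def test_single_gaussian_centroid_at_apex():
    spec = gaussian_spectrum(700.5, area=1000.0)
    cents = pick_peaks(spec, sn_threshold=3.0)
    assert len(cents) == 1
    assert cents[0].mz == pytest.approx(700.5, abs=0.001)  # < half a bin


def test_two_resolved_isotopologues_spacing():
    z = 12
    mz = np.arange(699.0, 703.0, 0.002)
    inten = np.zeros_like(mz)
    for k in range(2):
        mu = 700.0 + k * 1.0033548 / z
        inten += 500.0 * np.exp(-0.5 * ((mz - mu) / 0.008) ** 2)
    cents = pick_peaks(ProfileSpectrum(mz=mz, intensity=inten))
    assert len(cents) == 2
    assert cents[1].mz - cents[0].mz == pytest.approx(1.0033548 / z, abs=0.002)


def test_deisotope_empty_centroids():
    species, unassigned = deisotope([], DeconvParams())
    assert species == [] and unassigned == 0.0


def test_deisotope_single_species_mass_accuracy(noise_free_sim, deconv_params):
    """Noise-free single proteoform deconvolves to one species within
    0.01 Da of the theoretical monoisotopic mass."""
    target = UbProteoform(1, True)
    mix = ProteoformMixture({target: 1.0})
    spectra, _ = gen_intact_spectra(mix, noise_free_sim)
    spec = spectra[len(spectra) // 2]
    species, _ = deisotope(pick_peaks(spec), deconv_params, spectrum=spec)
    assert len(species) == 1
    assert species[0].monoisotopic_mass == pytest.approx(
        target.monoisotopic_mass, abs=0.01
    )
    assert set(species[0].charges) <= set(range(1, 18))


def test_phospho_pair_equal_areas(noise_free_sim, deconv_params):
    """Species differing by the phospho delta at 50/50 deconvolve with an
    area ratio of 1 within 1%."""
    pair = ProteoformMixture(
        {UbProteoform(0, False): 0.5, UbProteoform(0, True): 0.5}
    )
    spectra, _ = gen_intact_spectra(pair, noise_free_sim)
    merged, _ = deconvolve_run(spectra, deconv_params)
    assert len(merged) == 2
    areas = sorted(sp.summed_area for sp in merged)
    assert areas[1] / areas[0] == pytest.approx(1.0, abs=0.01)


def test_integrate_xic_single_scan_identity(deconv_params):
    sp = DeconvolvedSpecies(monoisotopic_mass=8445.57, charges=(12,),
                            scan_areas={0: 123.0})
    merged = integrate_xic([[sp]], deconv_params)
    assert len(merged) == 1 and merged[0].summed_area == 123.0


def test_integrate_xic_gaussian_elution_total(deconv_params):
    """Areas over a 5-scan Gaussian elution sum to the generated total."""
    params = SpectrumSimParams(noise_level=0.0, n_scans=5, seed=2)
    mix = ProteoformMixture({UbProteoform(0, False): 1.0})
    spectra, truth = gen_intact_spectra(mix, params)
    merged, _ = deconvolve_run(spectra, deconv_params)
    assert len(merged) == 1
    expected = truth["species"][0]["total_area"]
    assert merged[0].summed_area == pytest.approx(expected, rel=1e-3)


def test_integrate_xic_merges_species_absent_mid_run(deconv_params):
    scans = [
        [DeconvolvedSpecies(8445.57, (12,), {0: 10.0})],
        [],
        [DeconvolvedSpecies(8445.60, (11,), {2: 5.0})],
    ]
    merged = integrate_xic(scans, deconv_params)
    assert len(merged) == 1
    assert merged[0].summed_area == pytest.approx(15.0)
    assert set(merged[0].charges) == {11, 12}


def test_quantify_all_area_on_one_candidate(candidates):
    sp = DeconvolvedSpecies(candidates[0].monoisotopic_mass, (12,), {0: 50.0})
    result = quantify_proteoforms([sp], candidates)
    assert result.fractions[candidates[0]] == pytest.approx(1.0)
    assert result.unassigned_fraction == 0.0


def test_quantify_rejects_overlapping_candidates(candidates):
    with pytest.raises(ValueError):
        quantify_proteoforms([], candidates, tolerance=60.0)


def test_quantify_routes_unmatched_mass_to_unassigned(candidates):
    stray = DeconvolvedSpecies(8445.57 + 40.0, (12,), {0: 10.0})
    hit = DeconvolvedSpecies(candidates[0].monoisotopic_mass, (12,), {0: 30.0})
    result = quantify_proteoforms([hit, stray], candidates)
    assert result.unassigned_fraction == pytest.approx(0.25)
    total = sum(result.fractions.values()) + result.unassigned_fraction
    assert total == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("n_branches,phospho", [(n, p) for n in range(4) for p in (False, True)])
def test_single_species_roundtrip_all_candidates(n_branches, phospho, deconv_params):
    """Each of the 8 Ub^dGG candidates survives a noise-free round trip with
    mass error below 0.01 Da and full fractional assignment."""
    target = UbProteoform(n_branches, phospho)
    params = SpectrumSimParams(noise_level=0.0, n_scans=3, seed=1)
    spectra, _ = gen_intact_spectra(ProteoformMixture({target: 1.0}), params)
    merged, result = deconvolve_run(spectra, deconv_params, ub_dgg_candidates())
    assert len(merged) == 1
    assert merged[0].monoisotopic_mass == pytest.approx(
        target.monoisotopic_mass, abs=0.01
    )
    assert result.relative_abundance[target] == pytest.approx(1.0, abs=1e-9)


def test_mixture_roundtrip_recovery(deconv_params):
    """Fractions >= 0.001 with well-separated masses recover within 0.005
    absolute on noise-free spectra."""
    mix = ProteoformMixture({
        UbProteoform(0, False): 0.60,
        UbProteoform(1, False): 0.25,
        UbProteoform(0, True): 0.12,
        UbProteoform(2, True): 0.03,
    })
    params = SpectrumSimParams(noise_level=0.0, n_scans=3, seed=5)
    spectra, _ = gen_intact_spectra(mix, params)
    _, result = deconvolve_run(spectra, deconv_params, ub_dgg_candidates())
    for proteoform, truth in mix.items():
        assert result.relative_abundance[proteoform] == pytest.approx(
            truth, abs=0.005
        )


def test_recovery_monotone_in_true_fraction(deconv_params):
    """Raising one species' true fraction (others renormalized) never
    lowers its recovered fraction on noise-free input."""
    recovered = []
    for f in (0.05, 0.20, 0.50):
        rest = 1.0 - f
        mix = ProteoformMixture({
            UbProteoform(0, True): f,
            UbProteoform(0, False): rest * 0.7,
            UbProteoform(1, False): rest * 0.3,
        })
        params = SpectrumSimParams(noise_level=0.0, n_scans=2, seed=3)
        spectra, _ = gen_intact_spectra(mix, params)
        _, result = deconvolve_run(spectra, deconv_params, ub_dgg_candidates())
        recovered.append(result.relative_abundance[UbProteoform(0, True)])
    assert recovered == sorted(recovered)


def test_mass_accuracy_with_default_noise(deconv_params):
    """At a realistic noise level the recovered mass stays within 0.1 Da."""
    target = UbProteoform(0, False)
    params = SpectrumSimParams(noise_level=0.01, n_scans=3, seed=8)
    spectra, _ = gen_intact_spectra(ProteoformMixture({target: 1.0}), params)
    merged, _ = deconvolve_run(spectra, deconv_params)
    best = max(merged, key=lambda s: s.summed_area)
    assert best.monoisotopic_mass == pytest.approx(target.monoisotopic_mass, abs=0.1)
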