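import math

import pytest
from hypothesis import HealthCheck, settings

from fpf.model import ChannelDesign, Psm, SpectrumKey
from fpf.synth import SynthConfig, generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_psm(
    scan,
    intensities,
    peptide="PEPTIDEK",
    protein="PROT1",
    proteins=None,
    charge=2,
    run="run",
    observed=None,
    theoretical=1500.2,
    f_value=1.0,
    spectrast=None,
    is_shared=False,
    modifications=(),
):
    observed = theoretical if observed is None else observed
    return Psm(
        key=SpectrumKey(run, scan, charge),
        peptide=peptide,
        protein_accessions=tuple(proteins) if proteins else (protein,),
        reporter_intensities=tuple(intensities),
        modifications=tuple(modifications),
        is_shared=is_shared,
        precursor_neutral_mass_da=observed,
        theoretical_peptide_mass_da=theoretical,
        mass_diff_da=observed - theoretical,
        f_value=f_value,
        spectrast_scores=spectrast,
    )


def assert_psms_close(a, b, rel=1e-9):
    """Field-level equality of two Psm lists, floats within `rel` relative."""
    assert len(a) == len(b)
    for x, y in zip(sorted(a, key=lambda p: p.key), sorted(b, key=lambda p: p.key)):
        assert x.key == y.key
        assert x.peptide == y.peptide
        assert x.protein_accessions == y.protein_accessions
        assert x.is_shared == y.is_shared
        assert x.provenance == y.provenance
        assert x.precursor_neutral_mass_da == pytest.approx(y.precursor_neutral_mass_da, rel=rel)
        assert x.theoretical_peptide_mass_da == pytest.approx(y.theoretical_peptide_mass_da, rel=rel)
        assert x.mass_diff_da == pytest.approx(y.mass_diff_da, rel=rel, abs=1e-9)
        assert x.iprophet_probability == pytest.approx(y.iprophet_probability, rel=rel)
        if x.f_value is None:
            assert y.f_value is None
        else:
            assert x.f_value == pytest.approx(y.f_value, rel=rel)
        assert len(x.modifications) == len(y.modifications)
        for mx, my in zip(
            sorted(x.modifications, key=lambda m: m.position),
            sorted(y.modifications, key=lambda m: m.position),
        ):
            assert mx.position == my.position
            assert mx.is_label == my.is_label
            assert mx.mass_delta == pytest.approx(my.mass_delta, rel=rel, abs=1e-9)
        assert len(x.reporter_intensities) == len(y.reporter_intensities)
        for vx, vy in zip(x.reporter_intensities, y.reporter_intensities):
            if vx is None:
                assert vy is None
            else:
                assert vx == pytest.approx(vy, rel=rel)
        if x.spectrast_scores is None:
            assert y.spectrast_scores is None
        else:
            sx, sy = x.spectrast_scores, y.spectrast_scores
            assert sx.n_hits == sy.n_hits
            for field in ("precursor_mz_diff_abs", "dot_product", "delta_score", "hit_mean", "hit_std"):
                assert getattr(sx, field) == pytest.approx(getattr(sy, field), rel=rel, abs=1e-12)


@pytest.fixture
def design2():
    """Two channels, one ratio (theoretical 1)."""
    return ChannelDesign(("ch01", "ch02"), 0, (1.0,))


@pytest.fixture
def design3():
    """Three channels, denominator first, theoretical ratios all 1."""
    return ChannelDesign(("ch01", "ch02", "ch03"), 0, (1.0, 1.0))


@pytest.fixture(scope="session")
def small_dataset():
    """Small mixed synthetic dataset (shared peptides, SL scores, missing)."""
    cfg = SynthConfig(
        seed=3, n_proteins=10, n_psms=60, frac_missing_reporter=0.1, frac_shared_peptides=0.2
    )
    psms, truth = generate(cfg)
    return cfg, psms, truth


@pytest.fixture(scope="session")
def efficacy_run():
    """Feature-coupled synthetic study at N = 4000 with a quarter bad PSMs."""
    import fpf

    cfg = SynthConfig(seed=11, n_proteins=500, n_psms=4000, frac_bad=0.25)
    psms, truth = generate(cfg)
    norm = fpf.normalize_reporters(psms, cfg.design)
    feats = fpf.featurize(norm, cfg.design)
    decisions = fpf.apply_filter(feats)
    ares = fpf.psm_ares(norm, cfg.design)
    return {
        "config": cfg,
        "psms": norm,
        "truth": truth,
        "features": feats,
        "decisions": decisions,
        "ares": ares,
        "removed": {d.key for d in decisions if d.removed},
    }
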