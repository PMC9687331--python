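import pytest

from csfscreen import (
    OCBStatus,
    SampleRecord,
    build_profile,
    discovery_spec,
    generate,
    run_cohort,
    validation_spec,
)


def make_sample(**overrides) -> SampleRecord:
    """A fully-measured, unremarkable sample (no synthesis, OCB negative)."""
    defaults = dict(
        sample_id="fixture",
        albumin_csf=250.0,
        albumin_serum=42000.0,
        igg_csf=25.0,
        igg_serum=10500.0,
        iga_csf=3.0,
        iga_serum=2250.0,
        igm_csf=1.0,
        igm_serum=1100.0,
        flck_csf=0.15,
        flck_serum=13.1,
        erythrocytes_csf=2,
        leukocytes_csf=1.0,
        ocb_status=OCBStatus.NEGATIVE,
    )
    defaults.update(overrides)
    return SampleRecord(**defaults)


@pytest.fixture
def plain_sample() -> SampleRecord:
    return make_sample()


@pytest.fixture(scope="session")
def discovery_cohort():
    """One seeded synthetic discovery-style cohort plus its labels."""
    return generate(discovery_spec(), seed=1234)


@pytest.fixture(scope="session")
def discovery_run(discovery_cohort):
    samples, _ = discovery_cohort
    return run_cohort(samples)


@pytest.fixture(scope="session")
def validation_cohort():
    return generate(validation_spec(), seed=5678)


@pytest.fixture(scope="session")
def validation_run(validation_cohort):
    samples, _ = validation_cohort
    return run_cohort(samples)


from csfscreen import Analyte, q_lim  # noqa: E402

_SERUM = {
    Analyte.IGG: 10500.0,
    Analyte.IGA: 2250.0,
    Analyte.IGM: 1100.0,
    Analyte.FLCK: 13.1,
}
_STEMS = {
    Analyte.IGG: "igg",
    Analyte.IGA: "iga",
    Analyte.IGM: "igm",
    Analyte.FLCK: "flck",
}


def sample_with_ifs(ifs, q_alb=6.4e-3, **overrides):
    """Construct a sample whose intrathecal fractions equal the given
    targets exactly, by inverting Q = Qlim / (1 - IF/100).

    ``ifs`` maps analyte -> IF percent (< 100; negative allowed); analytes
    not in the map are left unmeasured.  FLCkappa defaults to IF = -50.
    """
    kwargs = dict(
        sample_id="constructed",
        albumin_csf=q_alb * 42000.0,
        albumin_serum=42000.0,
        erythrocytes_csf=0,
        ocb_status=OCBStatus.NEGATIVE,
    )
    ifs = dict(ifs)
    ifs.setdefault(Analyte.FLCK, -50.0)
    for analyte, target in ifs.items():
        if target is None:
            continue
        serum = overrides.get(f"{_STEMS[analyte]}_serum", _SERUM[analyte])
        quotient = q_lim(analyte, q_alb) / (1.0 - target / 100.0)
        kwargs[f"{_STEMS[analyte]}_csf"] = quotient * serum
        kwargs[f"{_STEMS[analyte]}_serum"] = serum
    kwargs.update(overrides)
    return SampleRecord(**kwargs)
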