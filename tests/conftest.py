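"""Shared fixtures: small synthetic cohorts and a hand-built censored panel."""

import numpy as np
import pytest

from ascites_pfi import (
    AssayPanel,
    GeneratorConfig,
    build_cohort_table,
    filter_low_detection,
    generate_cohort,
)

#: A small, fast cohort shape used by most model-level tests.
SMALL = GeneratorConfig(n_patients=30, n_analytes=12, n_informative=3, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """(panel, truth) for a 30-patient, 12-analyte cohort with 3 signals."""
    return generate_cohort(SMALL)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    panel, _ = small_cohort
    return build_cohort_table(filter_low_detection(panel))


def make_hand_panel():
    """4 patients x 3 analytes with hand-placed censoring.

    analyte Alow: 3 of 4 below-limit  -> removed by the 75% rule (detected 25%)
    analyte B:    1 below, 1 above    -> retained (detected 75%; above counts)
    analyte C:    all detected        -> retained
    """
    conc = np.array(
        [
            [np.nan, 50.0, 123.4],
            [np.nan, np.nan, 200.0],
            [np.nan, np.nan, 10.0],
            [8.0, 80.0, 40.0],
        ]
    )
    flags = np.array(
        [
            ["below", "none", "none"],
            ["below", "below", "none"],
            ["below", "above", "none"],
            ["none", "none", "none"],
        ],
        dtype=object,
    )
    return AssayPanel(
        patient_ids=["p1", "p2", "p3", "p4"],
        cohort_labels=["NACT"] * 4,
        pfi_days=np.array([100.0, 200.0, 300.0, 400.0]),
        analyte_names=["Alow", "B", "C"],
        concentrations=conc,
        censor_flags=flags,
        lower_limit=np.array([2.0, 4.0, 1.0]),
        upper_limit=np.array([500.0, 1000.0, 800.0]),
        dilution_factor=np.array([1.0, 2.0, 2.0]),
    )


@pytest.fixture
def hand_panel():
    return make_hand_panel()
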