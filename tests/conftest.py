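import numpy as np
import pandas as pd
import pytest

from pgxcca import default_parameters, with_default_distributions


@pytest.fixture(scope="session")
def params():
    """Calibrated default decision-model inputs."""
    return default_parameters()


@pytest.fixture(scope="session")
def params_with_dists(params):
    """Defaults with the standard PSA distributions attached."""
    return with_default_distributions(params)


def make_toy_records(rows):
    """Build a patient-record table from compact row dicts.

    Unspecified columns default to the 'no care, no costs' patient so
    hand-computable desk checks stay short.
    """
    defaults = {
        "patient_id": 0,
        "provider_id": 1,
        "arm": "PGx-",
        "genotype": "TT",
        "high_risk": True,
        "offered_statin": False,
        "prescribed_statin": False,
        "statin_type": "",
        "sams": False,
        "discontinued": False,
        "inpatient_stays": 0,
        "outpatient_encounters": 0,
        "primary_care_visits": 0,
        "cardiology_visits": 0,
        "cost_pgx_test": 0.0,
        "cost_statin": 0.0,
        "cost_other_lipid": 0.0,
        "cost_sams_care": 0.0,
        "cost_primary_care": 0.0,
        "cost_cardiology": 0.0,
        "cost_imaging": 0.0,
        "cost_laboratory": 0.0,
        "cost_other_outpatient": 0.0,
        "cost_inpatient": 0.0,
    }
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r["patient_id"] = i + 1
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full)
    df["cost_lipid_rx"] = df["cost_statin"] + df["cost_other_lipid"]
    df["cost_total"] = df[
        ["cost_pgx_test", "cost_lipid_rx", "cost_sams_care", "cost_primary_care",
         "cost_cardiology", "cost_imaging", "cost_laboratory",
         "cost_other_outpatient", "cost_inpatient"]
    ].sum(axis=1)
    return df
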