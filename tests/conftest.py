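import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import thermoprofile as tp

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(matrix, labels=None, columns=None, ids=None) -> tp.FeatureTable:
    """Ad-hoc FeatureTable over arbitrary column names for algorithm tests."""
    matrix = np.asarray(matrix, dtype=float)
    if columns is None:
        aas = "ACDEFGHIKLMNPQRSTVWY"
        if matrix.shape[1] <= len(aas):
            columns = [f"count_{a}" for a in aas[: matrix.shape[1]]]
        else:
            columns = [f"attr_{i:03d}" for i in range(matrix.shape[1])]
    ids = ids or [f"r{i}" for i in range(len(matrix))]
    values = pd.DataFrame(matrix, index=pd.Index(ids, name="id"), columns=columns)
    label_series = None
    if labels is not None:
        label_series = pd.Series(
            ["F" if l in (1, "F") else "T" for l in labels], index=values.index
        )
    schema = tp.FeatureSchema(
        tuple(tp.schema.SchemaEntry(c, "aa_count", "numeric") for c in columns)
    )
    return tp.FeatureTable(values, label_series, None, schema)


@pytest.fixture(scope="session")
def default_records():
    return tp.generate_dataset(tp.default_thermo_config())


@pytest.fixture(scope="session")
def default_pipeline(default_records):
    """Featurize + clean + normalize + weighting suite on the shipped
    default synthetic dataset (shared across tests: the expensive part)."""
    table = tp.featurize(default_records)
    cleaned, report = tp.clean(table)
    normalized, params = tp.normalize(cleaned)
    vectors, selections, failures = tp.weighting_suite(normalized)
    return {
        "table": table,
        "cleaned": cleaned,
        "normalized": normalized,
        "cleaning_report": report,
        "minmax": params,
        "vectors": vectors,
        "selections": selections,
        "failures": failures,
    }
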