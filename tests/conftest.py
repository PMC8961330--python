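import numpy as np
import pandas as pd
import pytest

from famloading import CohortConfig, FLSParameters, OutcomeSpec, generate_cohort


@pytest.fixture(scope="session")
def default_params() -> FLSParameters:
    return FLSParameters()


def make_relatives_frame(rows):
    """rows: iterable of (proband_id, relation, age, sym, trt)."""
    return pd.DataFrame(
        rows,
        columns=[
            "proband_id",
            "relation",
            "age_years",
            "endorsement_symptoms",
            "endorsement_treatment",
        ],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_participants=600, seed=42))


@pytest.fixture(scope="session")
def single_outcome_config():
    def factory(seed: int, effect: float = 0.13, n: int = 1425, **kw) -> CohortConfig:
        return CohortConfig(
            seed=seed,
            n_participants=n,
            outcome_specs=(OutcomeSpec("childhood_trauma", effect),),
            **kw,
        )

    return factory


def random_families(rng: np.random.Generator, n_families: int, max_size: int = 10):
    """Random relative-level frame for oracle comparisons."""
    rows = []
    for i in range(n_families):
        for j in range(rng.integers(0, max_size + 1)):
            affected = rng.random() < 0.3
            rows.append(
                (
                    f"F{i:04d}",
                    rng.choice(["parent", "sibling"]),
                    float(rng.uniform(0, 100)),
                    int(affected or rng.random() < 0.2),
                    int(affected),
                )
            )
    df = make_relatives_frame(rows)
    df["endorsement_symptoms"] = np.maximum(df.endorsement_symptoms, df.endorsement_treatment)
    return df
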