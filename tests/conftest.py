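import numpy as np
import pandas as pd
import pytest

from radgex.cohort import CohortConfig, Coupling, generate_cohort


def unbalanced_design(n_patients: int = 28, n_net: int = 15, n_ed: int = 7) -> pd.DataFrame:
    """Patient x subcompartment skeleton mirroring the unbalanced cohort."""
    rows = []
    for i in range(n_patients):
        p = f"P{i:03d}"
        rows.append((p, "ET"))
        if i < n_net:
            rows.append((p, "NET"))
        if i < n_ed:
            rows.append((p, "ED"))
    return pd.DataFrame(rows, columns=["patient_id", "subcompartment"])


def null_lmm_frame(rng: np.random.Generator, k: int = 5, icc_sd: float = 0.7,
                   resid_sd: float = 0.7) -> pd.DataFrame:
    """Null cohort-scale analysis table: features independent of the response."""
    df = unbalanced_design()
    n = len(df)
    for j in range(k):
        df[f"z_rad_{j}"] = rng.normal(size=n)
    intercepts = {p: rng.normal(0, icc_sd) for p in df["patient_id"].unique()}
    df["z_pathway"] = df["patient_id"].map(intercepts) + rng.normal(0, resid_sd, n)
    return df


def null_patient_table(rng: np.random.Generator, n: int = 8, m: int = 6) -> pd.DataFrame:
    tab = pd.DataFrame(rng.normal(size=(n, m)), columns=[f"rad_{j:03d}" for j in range(m)])
    tab.insert(0, "patient_id", [f"P{i:03d}" for i in range(n)])
    tab["pathway"] = rng.normal(size=n)
    return tab


SMALL_COHORT_CONFIG = dict(
    n_features=80, n_nzv_features=4, n_corr_blocks=2, block_size=4,
    n_genes=600, n_gene_sets=4, genes_per_set=25,
)


@pytest.fixture(scope="session")
def planted_cohort():
    """28-patient cohort with one strong coupling on features 10-14."""
    beta = Coupling.beta_for_signal_fraction(0.8)
    cfg = CohortConfig(planted_couplings=(Coupling("HALLMARK_SET_01",
                                                   (10, 11, 12, 13, 14), beta),),
                       seed=3, **SMALL_COHORT_CONFIG)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    cfg = CohortConfig(seed=5, **SMALL_COHORT_CONFIG)
    return generate_cohort(cfg)
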