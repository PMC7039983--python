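import numpy as np
import pytest

from famgxe.exposures import ExposureProfile
from famgxe.prs import SnpWeight, SnpWeightPanel
from famgxe.simulate import SimConfig, simulate_families


@pytest.fixture(scope="session")
def tiny_panel():
    return SnpWeightPanel((
        SnpWeight("rs1", "A", 1.1),
        SnpWeight("rs2", "C", 1.2),
        SnpWeight("rs3", "G", 0.9),
    ))


@pytest.fixture(scope="session")
def sim_dataset():
    """A moderate synthetic study shared by read-only tests."""
    return simulate_families(SimConfig(n_families=600, seed=42))


def random_design(rng, n_sets=30, n_cols=3, sizes=(2, 4)):
    """Random matched-set design arrays (case row first per set)."""
    X_rows, starts = [], [0]
    for _ in range(n_sets):
        k = int(rng.choice(sizes))
        X_rows.append(rng.normal(size=(k, n_cols)))
        starts.append(starts[-1] + k)
    return np.vstack(X_rows), np.asarray(starts), [f"x{j}" for j in range(n_cols)]


def make_profile(subject_id="s1", index_age=45.0, **kw):
    """An eligible-for-everything exposure profile with overridable fields."""
    defaults = dict(
        height=65.0, bmi_at_30=23.0, smoking="never", alcohol="never",
        premenopausal=True, age_menarche=12.5, ever_hbc=True, years_hbc=5.0,
        hbc_within_5y=False, parity=2, age_first_birth=26.0,
        last_birth_within_5y=False, breastfeeding=True, birth_order_rank=1,
    )
    defaults.update(kw)
    return ExposureProfile(subject_id=subject_id, index_age=index_age, **defaults)
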