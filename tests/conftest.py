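import numpy as np
import pytest

from adalert.alerts import builtin_alerts
from adalert.screening import ADLabel, DrugRecord
from adalert.synthetic import SyntheticConfig, generate_drug_set


@pytest.fixture(scope="session")
def builtin():
    return builtin_alerts()


@pytest.fixture(scope="session")
def small_synthetic():
    """A small synthetic drug set with a strongly planted aromatic-amine alert."""
    config = SyntheticConfig(
        n_pos=40,
        n_neg=160,
        alert_prevalence={
            "aryl_amine_primary": (0.45, 0.12),
            "alkene": (0.2, 0.2),
            "phenol": (0.15, 0.15),
        },
        seed=7,
    )
    drugs, truth = generate_drug_set(config)
    return config, drugs, truth


def make_drug(drug_id, smiles, dose, positive):
    return DrugRecord(
        drug_id=drug_id,
        name=drug_id,
        smiles=smiles,
        daily_dose_mg=dose,
        label=ADLabel.AD_POSITIVE if positive else ADLabel.AD_NEGATIVE,
    )


@pytest.fixture()
def toy_panel():
    """Aniline, toluene, benzene — the reference molecules for alert behavior."""
    return [
        make_drug("aniline", "Nc1ccccc1", 150.0, True),
        make_drug("toluene", "Cc1ccccc1", 50.0, False),
        make_drug("benzene", "c1ccccc1", 200.0, False),
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
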