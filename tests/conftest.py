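import pandas as pd
import pytest

from fuzzpk import build_reference_fis

#: The six printed candidate-model criteria rows with their published FSE
#: scores, in table order.
PRINTED_MODELS = pd.DataFrame([
    {"model_id": 2, "n_params": 6, "covariates": "(WT,AGE/V)",
     "aic": 679.9, "cs": 695.0, "mse": 0.093, "fse_printed": 88.4},
    {"model_id": 4, "n_params": 6, "covariates": "(SEX,AGE/V)",
     "aic": 673.1, "cs": 689.2, "mse": 0.09336, "fse_printed": 31.6},
    {"model_id": 5, "n_params": 9, "covariates": "(SEX,AGE/V)/(SEX,AGE,WT/Cl)",
     "aic": 670.4, "cs": 693.0, "mse": 0.0936, "fse_printed": 55.6},
    {"model_id": 6, "n_params": 7, "covariates": "(SEX,AGE/V)(SEX/Cl)",
     "aic": 672.7, "cs": 691.0, "mse": 0.093, "fse_printed": 34.4},
    {"model_id": 7, "n_params": 7, "covariates": "(WT,AGE,SEX/Cl)",
     "aic": 675.3, "cs": 691.3, "mse": 0.139, "fse_printed": 88.9},
    {"model_id": 8, "n_params": 10, "covariates": "(WT,HT/V)/(WT,AGE,HT,BMI/Cl)",
     "aic": 682.7, "cs": 707.5, "mse": 0.0928, "fse_printed": 88.7},
])


@pytest.fixture(scope="session")
def reference_fis():
    """Default published system: corrected rulebase, centroid, saturation."""
    return build_reference_fis()


@pytest.fixture
def criteria_csv(tmp_path):
    path = tmp_path / "criteria.csv"
    PRINTED_MODELS.drop(columns="fse_printed").to_csv(path, index=False)
    return path
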