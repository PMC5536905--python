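import numpy as np
import pandas as pd
import pytest

from atroprot import quant
from atroprot.synthetic import (GeneratorConfig, generate_expression_study,
                                generate_pulse_study, generate_site_study)
from atroprot.tables import SampleDesign


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    return GeneratorConfig(n_proteins=200, n_atrogene_up=8, n_atrogene_down=6,
                           seed=42)


@pytest.fixture(scope="session")
def noise_free_cfg() -> GeneratorConfig:
    return GeneratorConfig(n_proteins=200, n_atrogene_up=8, n_atrogene_down=6,
                           noise_sd_log2=0.0, frac_missing=0.0, seed=42)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    table, design, truth = generate_expression_study(small_cfg)
    return table, design, truth


@pytest.fixture(scope="session")
def noise_free_study(noise_free_cfg):
    table, design, truth = generate_expression_study(noise_free_cfg)
    return table, design, truth


@pytest.fixture(scope="session")
def small_profiles(small_study):
    table, design, truth = small_study
    norm = quant.normalize_sample_ratios(table)
    return quant.build_time_profiles(quant.fold_change_table(norm))


@pytest.fixture()
def tiny_design() -> SampleDesign:
    rows = []
    for cond in ("control", "denervated"):
        for r in (1, 2, 3):
            rows.append((f"{cond[:3]}_d7_r{r}", cond, 7.0, r, "expression"))
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "condition", "time_day", "replicate", "assay"]))
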