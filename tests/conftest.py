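import numpy as np
import pandas as pd
import pytest

from dyeswapde import (
    ExperimentDesign,
    NormalizedSlide,
    SimulationConfig,
    SlideTable,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_experiment():
    """A modest seeded synthetic experiment shared across read-only tests."""
    config = SimulationConfig(n_genes=300, seed=7)
    slides, design, truth = simulate_experiment(config)
    return config, slides, design, truth


@pytest.fixture(scope="session")
def clean_experiment():
    """Noise-free, artifact-free experiment: planted signal only."""
    config = SimulationConfig(
        n_genes=120, de_fraction=0.1, de_log2fc=1.0, noise_sd=0.0,
        dye_bias_coeffs=(0.0,), low_intensity_fraction=0.0,
        discordant_fraction=0.0, seed=11,
    )
    slides, design, truth = simulate_experiment(config)
    return config, slides, design, truth


def make_slide(slide_id="s1", **columns) -> SlideTable:
    """Build a SlideTable from channel arrays with zero background."""
    n = len(columns["ch1_fg"])
    data = {
        "spot_id": columns.get("spot_id", [f"spot{i}" for i in range(n)]),
        "gene_id": columns.get("gene_id", [f"g{i}" for i in range(n)]),
        "ch1_fg": columns["ch1_fg"],
        "ch1_bg": columns.get("ch1_bg", np.zeros(n)),
        "ch2_fg": columns["ch2_fg"],
        "ch2_bg": columns.get("ch2_bg", np.zeros(n)),
    }
    return SlideTable(slide_id=slide_id, data=pd.DataFrame(data))


def make_normalized(slide_id, gene_ids, m_norm, low=None, outlier=None,
                    A=None) -> NormalizedSlide:
    n = len(gene_ids)
    m = np.asarray(m_norm, dtype=float)
    data = pd.DataFrame({
        "spot_id": [f"{slide_id}_spot{i}" for i in range(n)],
        "gene_id": gene_ids,
        "A": np.full(n, 10.0) if A is None else np.asarray(A, float),
        "M_raw": m,
        "M_norm": m,
        "low_intensity": np.zeros(n, bool) if low is None else np.asarray(low),
        "lowess_outlier": (np.zeros(n, bool) if outlier is None
                           else np.asarray(outlier)),
    })
    data.loc[data["low_intensity"] | data["lowess_outlier"], "M_norm"] = np.nan
    return NormalizedSlide(slide_id=slide_id, data=data)


def make_design(n_patients=1) -> ExperimentDesign:
    rows = []
    for p in range(n_patients):
        rows.append({"slide_id": f"slide{2*p+1}", "patient_id": f"PT{p+1}",
                     "pair_id": f"pair{p+1}", "orientation": "patient_in_ch1"})
        rows.append({"slide_id": f"slide{2*p+2}", "patient_id": f"PT{p+1}",
                     "pair_id": f"pair{p+1}", "orientation": "patient_in_ch2"})
    return ExperimentDesign(data=pd.DataFrame(rows))
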