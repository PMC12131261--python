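import numpy as np
import pandas as pd
import pytest

from facebias import (SimulationConfig, compute_bias, generate_dataset)
from facebias.coding import apply_inclusion_filters


@pytest.fixture(scope="session")
def small_config():
    """A quick 25-subject study configuration."""
    return SimulationConfig(seed=42, n_subjects=25, n_groups=5)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def study_dataset():
    """A full study-sized dataset at the default configuration."""
    return generate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def study_bias_tables(study_dataset):
    """Included-trial bias tables for the paired experiments."""
    inc1, _ = apply_inclusion_filters(study_dataset.trials_exp1, "exp1")
    inc2, _ = apply_inclusion_filters(study_dataset.trials_exp2, "exp2")
    return compute_bias(inc1), compute_bias(inc2)


def make_event_rows(trial_id, specs, coder="C1"):
    """Helper: specs are (target, start, stop) tuples."""
    return pd.DataFrame(
        [{"trial_id": trial_id, "coder_id": coder, "target": t,
          "start_s": a, "stop_s": b} for t, a, b in specs]
    )


def paired_manifest_row(trial_id, subject_id="S1", experiment="exp1",
                        expression="threat", intensity="", expr_side="left",
                        group_id="G1"):
    return {
        "trial_id": trial_id, "subject_id": subject_id, "group_id": group_id,
        "experiment": experiment, "expression": expression,
        "intensity": intensity, "sequence_expression": "",
        "violating_expression": "", "win1_start": 0.0, "win1_dur": 5.0,
        "win2_start": 5.5, "win2_dur": 5.0, "expr_side_win1": expr_side,
        "image_onsets": "", "image_dur": "",
    }


def exp3_manifest_row(trial_id, subject_id="S1", group_id="G1"):
    return {
        "trial_id": trial_id, "subject_id": subject_id, "group_id": group_id,
        "experiment": "exp3", "expression": "", "intensity": "",
        "sequence_expression": "threat", "violating_expression": "scream",
        "win1_start": "", "win1_dur": "", "win2_start": "", "win2_dur": "",
        "expr_side_win1": "",
        "image_onsets": "0;3.5;7;10.5;14;17.5", "image_dur": 3.0,
    }
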