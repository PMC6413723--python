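import numpy as np
import pandas as pd
import pytest

from receptseq.io_formats import PWM, ExpressionMatrix


@pytest.fixture
def simple_pwm() -> PWM:
    """Informative 6-mer with consensus ACGTAC (dominant count 10 vs 1)."""
    consensus = "ACGTAC"
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.ones((4, len(consensus)))
    for i, base in enumerate(consensus):
        mat[idx[base], i] = 10.0
    return PWM(tf_name="TF_TEST", matrix=mat)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x (3+3) samples; g1 strongly up, g2 strongly down in day4."""
    rng = np.random.default_rng(7)
    base = np.array([[100.0], [80.0], [50.0], [9.0]])
    vals = base * np.exp2(rng.normal(0, 0.05, size=(4, 6)))
    vals[0, 3:] *= 8.0
    vals[1, 3:] /= 8.0
    samples = [f"day3_r{i}" for i in range(1, 4)] + [f"day4_r{i}" for i in range(1, 4)]
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=["g1", "g2", "g3", "g4"], columns=samples),
        condition_of_sample=pd.Series(["day3"] * 3 + ["day4"] * 3, index=samples),
    )
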