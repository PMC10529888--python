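import numpy as np
import pytest

from remliver import GeneratorParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A default-parameter synthetic cohort of study size."""
    return generate_cohort(GeneratorParams(n=71, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """A large cohort for moment / calibration checks."""
    return generate_cohort(GeneratorParams(n=5000, seed=42))


def brute_force_auc(scores, reference):
    """Pairwise concordance probability: P(score_pos > score_neg) + 0.5 ties.

    Independent oracle for the ROC area; O(n_pos * n_neg) enumeration.
    """
    scores = np.asarray(scores, dtype=float)
    reference = np.asarray(reference, dtype=bool)
    pos = scores[reference]
    neg = scores[~reference]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (pos.size * neg.size)
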