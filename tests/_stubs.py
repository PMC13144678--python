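"""Test doubles shared across test modules."""

import numpy as np

from promplace.determiner import DeterminerEnsemble, DeterminerOutput


class RiggedEnsemble(DeterminerEnsemble):
    """Ensemble stub returning fixed head outputs with a chosen match tally."""

    def __init__(self, msrl_pred: int, region_pred: int, n_match: int, n_members: int = 10):
        super().__init__(models=[])
        self._fixed = (msrl_pred, region_pred, n_match, n_members)

    def __len__(self):
        return self._fixed[3]

    def predict_all(self, stack, peak_threshold=0.5):
        msrl_pred, region_pred, n_match, n_members = self._fixed
        msrl_probs = np.array([0.9, 0.1]) if msrl_pred == 5 else np.array([0.1, 0.9])
        region_probs = np.full(10, 0.04)
        region_probs[region_pred - 1] = 1.0 - 0.04 * 9
        return [
            DeterminerOutput(msrl_probs=msrl_probs, region_probs=region_probs,
                             msrl_pred=msrl_pred, region_pred=region_pred, match=i < n_match)
            for i in range(n_members)
        ]
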