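"""Shared helpers for hyperparameter tuning on an 80-20 reference split."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError

log = logging.getLogger(__name__)


@dataclass
class TuneResult:
    """Winning configuration, the refit model, and the full grid trace."""

    config: object
    fit: object
    grid: pd.DataFrame


def reference_split(n: int, test_fraction: float, seed: int, y=None, max_retries: int = 10):
    """Seeded train/test index split of a reference set.

    If ``y`` is provided and the drawn test block is constant, the split is
    redrawn with the next seed (logged), so MSE-based selection stays
    meaningful.
    """
    if n < 10:
        raise ParameterError(f"reference set of size {n} too small to split")
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        perm = rng.permutation(n)
        n_test = max(1, int(round(test_fraction * n)))
        test, train = perm[:n_test], perm[n_test:]
        if y is None or np.asarray(y)[test].std() > 0:
            if attempt:
                log.warning("degenerate split; resampled with seed %d", seed + attempt)
            return train, test
    raise ParameterError("could not draw a non-degenerate train/test split")
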