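"""Cross-validation fold construction shared by the PLS and metrics layers."""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError


def make_folds(y: np.ndarray, scheme="loo", seed: int | None = None) -> list[np.ndarray]:
    """Return a list of held-out index arrays.

    ``scheme`` is ``"loo"`` or ``("kfold", k)``.  K-fold assignment is
    seeded and stratified by response quantile: samples are sorted by y and
    dealt round-robin into folds after a seeded shuffle within blocks, so
    every fold spans the concentration range.
    """
    n = y.size
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if isinstance(scheme, (tuple, list)) and scheme[0] == "kfold":
        k = int(scheme[1])
        if not 2 <= k <= n:
            raise ValidationError(f"k-fold needs 2 <= k <= n, got k={k}, n={n}")
        rng = np.random.default_rng(seed)
        order = np.argsort(y, kind="stable")
        folds: list[list[int]] = [[] for _ in range(k)]
        # deal consecutive response-sorted blocks across folds, shuffling
        # within each block so fold membership is not deterministic in rank
        for start in range(0, n, k):
            block = order[start : start + k].copy()
            rng.shuffle(block)
            for j, idx in enumerate(block):
                folds[j].append(int(idx))
        return [np.sort(np.array(f)) for f in folds if f]
    raise ValidationError(f"unknown CV scheme: {scheme!r}")
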