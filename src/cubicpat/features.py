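"""CubicPat: ordinal channel-triplet histogram features.

At every time sample the n channel values are sorted in descending order;
the resulting rank permutation ``id`` (1-based channel indices, ties broken
by ascending channel index) is scanned with a sliding window of three and
each window is encoded as a base-n integer

    map_j = (id_j - 1) * n**2 + (id_{j+1} - 1) * n + (id_{j+2} - 1),

so each time sample contributes n - 2 codes in [0, n**3 - 1].  The per-epoch
feature vector is the dense histogram of these codes, of length n**3
(32,768 for 32 channels, 2,744 for 14).  Counts therefore always sum to
ln * (n - 2), and the features depend only on the per-sample channel
ordering: any strictly increasing elementwise transform of the epoch, or a
permutation of its time samples, leaves them unchanged.
"""

from __future__ import annotations

import numpy as np

from .io import EpochMatrix

__all__ = [
    "rank_channels",
    "cubic_code",
    "encode_triplet",
    "extract_features",
    "extract_features_batch",
]


def _as_matrix(epoch: EpochMatrix | np.ndarray) -> np.ndarray:
    data = epoch.data if isinstance(epoch, EpochMatrix) else np.asarray(epoch, dtype=float)
    if data.ndim != 2:
        raise ValueError("epoch data must be 2-D (time x channels)")
    if data.shape[1] < 3:
        raise ValueError(f"cubic coding requires >= 3 channels, got {data.shape[1]}")
    bad = ~np.isfinite(data)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise ValueError(f"non-finite value in epoch at sample {row}")
    return data


def rank_channels(sample: np.ndarray) -> np.ndarray:
    """Descending rank permutation of one time sample (1-based channel ids).

    ``ids[0]`` is the channel holding the largest value; tied values keep
    ascending channel order (stable sort).
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size < 3:
        raise ValueError(f"cubic coding requires >= 3 channels, got {sample.size}")
    return np.argsort(-sample, kind="stable") + 1


def encode_triplet(ids3, n: int) -> int:
    """Base-n code of one channel triplet (1-based channel indices)."""
    a, b, c = (int(v) for v in ids3)
    for v in (a, b, c):
        if not 1 <= v <= n:
            raise ValueError(f"channel index {v} out of range 1..{n}")
    return (a - 1) * n * n + (b - 1) * n + (c - 1)


def cubic_code(perm: np.ndarray) -> np.ndarray:
    """All n - 2 sliding-triplet codes of a rank permutation (1-based ids)."""
    ids = np.asarray(perm, dtype=np.int64).ravel()
    n = ids.size
    if n < 3:
        raise ValueError("rank permutation must have length >= 3")
    if sorted(ids.tolist()) != list(range(1, n + 1)):
        raise ValueError("ids must be a permutation of 1..n")
    z = ids - 1
    return z[:-2] * n * n + z[1:-1] * n + z[2:]


def extract_features(epoch: EpochMatrix | np.ndarray) -> np.ndarray:
    """Length-n**3 histogram of cubic codes accumulated over all time samples."""
    data = _as_matrix(epoch)
    ln, n = data.shape
    # stable descending argsort; ties keep ascending channel index
    ids = np.argsort(-data, axis=1, kind="stable")  # 0-based ranks, (ln, n)
    codes = ids[:, :-2] * (n * n) + ids[:, 1:-1] * n + ids[:, 2:]
    return np.bincount(codes.ravel(), minlength=n**3).astype(np.int64)


def extract_features_batch(
    epochs: list[EpochMatrix],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-epoch feature vectors; returns (X, labels, subject_ids).

    Rows follow the input order.  All epochs must share the channel count.
    """
    if not epochs:
        return np.empty((0, 0), dtype=np.int64), np.empty(0, object), np.empty(0, object)
    n = epochs[0].n_channels
    for ep in epochs:
        if ep.n_channels != n:
            raise ValueError(
                f"mixed channel counts in batch: epoch {ep.epoch_id!r} has "
                f"{ep.n_channels}, expected {n}"
            )
    X = np.vstack([extract_features(ep) for ep in epochs])
    y = np.asarray([ep.label for ep in epochs])
    subjects = np.asarray([ep.subject_id for ep in epochs], dtype=object)
    return X, y, subjects
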