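"""Subject-structured synthetic multichannel signals for pipeline testing.

The real use case — 14- or 32-channel EEG, 15 s epochs at 128/256 Hz,
binary labels, several epochs per subject — is private, so this module
generates surrogates whose class signal lives where the ordinal
channel-triplet statistic can see it: in the *amplitude ordering* of the
channels.  Each epoch is

    x[t, c] = (m[t] + eps[t, c]) * g_class[c] * exp(subject_sd * z[s, c])

where ``m`` is a shared oscillatory mixture (alpha/theta/beta sinusoids
with random phases per epoch), ``eps`` is white Gaussian noise, ``g_class``
boosts a designated channel subset by ``1 + effect_size`` for one class,
and the per-subject log-normal channel gain gives leave-one-subject-out CV
a genuine generalization gap relative to 10-fold CV.  A spectral-only class
contrast would be invisible to a pure rank statistic, hence the gain-order
construction.  With ``effect_size = 0`` and ``subject_sd = 0`` the labels
are independent of the data by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DatasetManifest, EpochMatrix, save_dataset

__all__ = ["SimConfig", "generate_dataset", "write_dataset", "make_worked_epoch"]

# oscillatory base mixture: (frequency Hz, amplitude) for alpha/theta/beta
_OSCILLATIONS = ((10.0, 1.0), (6.0, 0.7), (22.0, 0.5))


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the 14-channel study shape at desk scale."""

    n_channels: int = 14
    fs: float = 128.0
    epoch_seconds: float = 15.0
    n_subjects_per_class: int = 10
    epochs_per_subject: int = 10
    effect_size: float = 1.0     # class gain contrast: affected channels x (1 + effect_size)
    subject_sd: float = 0.2      # sd of the per-subject log-gain
    noise_sd: float = 1.0        # white-noise sd, same units as the oscillatory mixture
    seed: int = 0
    affected_channels: tuple[int, ...] | None = None  # 0-based; default: 4 spread evenly
    class_labels: tuple = (0, 1)

    def validate(self) -> None:
        problems = []
        if self.n_channels < 3:
            problems.append(f"n_channels={self.n_channels} (need >= 3)")
        if self.fs <= 0:
            problems.append(f"fs={self.fs} (need > 0)")
        if int(self.fs * self.epoch_seconds) < 3:
            problems.append(f"epoch_seconds={self.epoch_seconds} (epoch too short)")
        if self.n_subjects_per_class < 1:
            problems.append(f"n_subjects_per_class={self.n_subjects_per_class}")
        if self.epochs_per_subject < 1:
            problems.append(f"epochs_per_subject={self.epochs_per_subject}")
        if self.effect_size < 0:
            problems.append(f"effect_size={self.effect_size} (need >= 0)")
        if self.subject_sd < 0:
            problems.append(f"subject_sd={self.subject_sd} (need >= 0)")
        if self.noise_sd <= 0:
            problems.append(f"noise_sd={self.noise_sd} (need > 0)")
        if len(self.class_labels) != 2:
            problems.append(f"class_labels={self.class_labels} (need exactly 2)")
        if self.affected_channels is not None and any(
            not 0 <= c < self.n_channels for c in self.affected_channels
        ):
            problems.append(f"affected_channels={self.affected_channels} out of range")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    @property
    def ln(self) -> int:
        return int(self.fs * self.epoch_seconds)

    def resolved_affected_channels(self) -> tuple[int, ...]:
        if self.affected_channels is not None:
            return tuple(self.affected_channels)
        # four channels spread across the montage
        return tuple(int(c) for c in np.linspace(0, self.n_channels - 1, 6)[1:5].round())


def generate_dataset(cfg: SimConfig) -> tuple[list[EpochMatrix], DatasetManifest]:
    """Generate labeled, subject-structured epochs; reproducible from cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ln, n = cfg.ln, cfg.n_channels
    t = np.arange(ln) / cfg.fs
    affected = cfg.resolved_affected_channels()

    epochs: list[EpochMatrix] = []
    rows = []
    sub_counter = 0
    for ci, label in enumerate(cfg.class_labels):
        gain_class = np.ones(n)
        if ci == 1:
            gain_class[list(affected)] *= 1.0 + cfg.effect_size
        for _ in range(cfg.n_subjects_per_class):
            subject_id = f"sub{sub_counter:03d}"
            sub_counter += 1
            gain_subject = np.exp(cfg.subject_sd * rng.standard_normal(n))
            gains = gain_class * gain_subject
            for e in range(cfg.epochs_per_subject):
                phases = rng.uniform(0.0, 2.0 * np.pi, size=len(_OSCILLATIONS))
                m = np.zeros(ln)
                for (freq, amp), ph in zip(_OSCILLATIONS, phases):
                    m += amp * np.sin(2.0 * np.pi * freq * t + ph)
                eps = rng.normal(0.0, cfg.noise_sd, size=(ln, n))
                data = (m[:, None] + eps) * gains[None, :]
                epoch_id = f"{subject_id}_e{e:03d}"
                epochs.append(
                    EpochMatrix(data=data, label=label, subject_id=subject_id,
                                epoch_id=epoch_id)
                )
                rows.append(
                    {"epoch_id": epoch_id, "subject_id": subject_id,
                     "label": label, "path": ""}
                )
    table = pd.DataFrame(rows, columns=["epoch_id", "subject_id", "label", "path"])
    return epochs, DatasetManifest(table=table, n_channels=n, fs=cfg.fs)


def write_dataset(cfg: SimConfig, out_dir: str | Path) -> Path:
    """Generate a dataset and write epoch CSVs plus a manifest; return manifest path."""
    epochs, _ = generate_dataset(cfg)
    return save_dataset(epochs, out_dir, fs=cfg.fs)


def make_worked_epoch(kind: str) -> EpochMatrix:
    """Tiny fixed epochs used in the hand-worked coding examples."""
    if kind == "tiny3":
        return EpochMatrix(data=np.array([[3.0, 2.0, 1.0]]), label=0,
                           subject_id="worked", epoch_id="tiny3")
    if kind == "tiny4":
        return EpochMatrix(data=np.array([[10.0, 40.0, 20.0, 30.0]]), label=0,
                           subject_id="worked", epoch_id="tiny4")
    raise ValueError(f"unknown worked epoch kind {kind!r}; use 'tiny3' or 'tiny4'")
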