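"""Reading, writing and segmenting multichannel EEG epochs.

The in-memory convention throughout the package is rows = time samples,
columns = channels.  Channel indices exposed to users are 1-based (the
convention of the coding formulas); everything internal is 0-based.

Epoch payloads are headerless numeric CSV (one row per time sample) or
``.npy`` arrays.  Datasets are described by a manifest CSV with columns
``epoch_id,subject_id,label,path``; paths are resolved relative to the
manifest file.  Continuous EDF recordings can be read through :func:`read_edf`
(requires the optional ``mne`` dependency) and cut into fixed-length epochs
with :func:`segment_recording`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EpochMatrix",
    "DatasetManifest",
    "read_edf",
    "segment_recording",
    "load_epoch_file",
    "load_dataset",
    "save_dataset",
]

MANIFEST_COLUMNS = ("epoch_id", "subject_id", "label", "path")


@dataclass
class Recording:
    """A continuous multichannel recording (samples x channels)."""

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be a 2-D samples x channels array")
        if self.data.shape[0] < 1 or self.data.shape[1] < 3:
            raise ValueError(
                "Recording needs >= 1 sample and >= 3 channels, got shape "
                f"{self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be > 0, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} data columns"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


@dataclass
class EpochMatrix:
    """One fixed-length EEG segment with its label and subject identity.

    ``data`` is an (ln, n) array: ln time samples of n channels.  Ordinal
    channel coding needs at least three channels; missing values are
    rejected rather than imputed.
    """

    data: np.ndarray
    label: object = None
    subject_id: str = ""
    epoch_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EpochMatrix.data must be 2-D (time x channels)")
        ln, n = self.data.shape
        if n < 3:
            raise ValueError(f"cubic coding requires >= 3 channels, got {n}")
        if ln < 1:
            raise ValueError("epoch must contain at least one time sample")
        bad = ~np.isfinite(self.data)
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise ValueError(f"epoch contains a missing/non-finite value at sample {row}")

    @property
    def ln(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class DatasetManifest:
    """Tabular index of a dataset: one row per epoch."""

    table: pd.DataFrame
    n_channels: int | None = None
    fs: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest is missing columns {missing}")
        ids = self.table["epoch_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate epoch_id in manifest: {dup!r}")

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].astype(str).to_numpy()

    def require_classification(self) -> None:
        if self.table["label"].nunique() < 2:
            raise ValueError("classification needs >= 2 distinct labels in the manifest")


def read_edf(path: str | Path) -> Recording:
    """Read a continuous EDF recording into a :class:`Recording`.

    Convenience wrapper around ``mne.io.read_raw_edf`` (optional dependency).
    The EDF channel-major layout is transposed to samples x channels.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data().T, fs=float(raw.info["sfreq"]), channel_names=list(raw.ch_names)
    )


def segment_recording(
    rec: Recording,
    epoch_seconds: float,
    *,
    label: object = None,
    subject_id: str = "",
    id_prefix: str = "e",
) -> list[EpochMatrix]:
    """Cut a recording into consecutive non-overlapping fixed-length epochs.

    Epoch length is ``floor(epoch_seconds * fs)`` samples; the trailing
    remainder is dropped.  A recording shorter than one epoch yields an
    empty list with a warning.
    """
    epoch_len = int(np.floor(epoch_seconds * rec.fs))
    if epoch_len < 3:
        raise ValueError(
            f"epoch length {epoch_len} samples (= {epoch_seconds} s x {rec.fs} Hz) is too short"
        )
    count = rec.n_samples // epoch_len
    if count == 0:
        warnings.warn(
            f"recording of {rec.n_samples} samples is shorter than one epoch "
            f"({epoch_len} samples); returning no epochs",
            stacklevel=2,
        )
        return []
    return [
        EpochMatrix(
            data=rec.data[k * epoch_len : (k + 1) * epoch_len],
            label=label,
            subject_id=subject_id,
            epoch_id=f"{id_prefix}{k:04d}",
        )
        for k in range(count)
    ]


def _read_numeric_csv(path: Path) -> np.ndarray:
    raw = pd.read_csv(path, header=None)
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at row {int(r)}, column {int(c)}: "
            f"{raw.iat[int(r), int(c)]!r}"
        )
    return coerced.to_numpy(dtype=float)


def load_epoch_file(path: str | Path) -> np.ndarray:
    """Load one epoch payload (headerless CSV or ``.npy``) as a float matrix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"epoch file does not exist: {path}")
    if path.suffix == ".npy":
        arr = np.asarray(np.load(path), dtype=float)
    else:
        arr = _read_numeric_csv(path)
    if arr.ndim != 2:
        raise ValueError(f"epoch file {path} is not a 2-D matrix")
    return arr


def load_dataset(manifest_path: str | Path) -> tuple[list[EpochMatrix], DatasetManifest]:
    """Load all epochs listed in a manifest CSV, in manifest order.

    Every referenced file must parse as a numeric matrix and all epochs must
    share the same channel count.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest does not exist: {manifest_path}")
    table = pd.read_csv(manifest_path)
    manifest = DatasetManifest(table=table)
    root = manifest_path.parent

    epochs: list[EpochMatrix] = []
    n_channels: int | None = None
    for row in table.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        data = load_epoch_file(p)
        if n_channels is None:
            n_channels = data.shape[1]
        elif data.shape[1] != n_channels:
            raise ValueError(
                f"inconsistent channel count: epoch {row.epoch_id!r} has "
                f"{data.shape[1]} channels, expected {n_channels}"
            )
        epochs.append(
            EpochMatrix(
                data=data,
                label=row.label,
                subject_id=str(row.subject_id),
                epoch_id=str(row.epoch_id),
            )
        )
    manifest.n_channels = n_channels
    return epochs, manifest


def save_dataset(
    epochs: list[EpochMatrix],
    out_dir: str | Path,
    *,
    fs: float | None = None,
    fmt: str = "%.12g",
) -> Path:
    """Write epochs as headerless CSVs plus a manifest CSV; return manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ep in epochs:
        fname = f"{ep.epoch_id}.csv"
        np.savetxt(out_dir / fname, ep.data, delimiter=",", fmt=fmt)
        rows.append(
            {
                "epoch_id": ep.epoch_id,
                "subject_id": ep.subject_id,
                "label": ep.label,
                "path": fname,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest_path, index=False)
    return manifest_path
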