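"""Data containers and file I/O for the EEG connectivity pipeline.

This module holds the pipeline's domain types (:class:`EpochSet`,
:class:`CovariateTable`, :class:`PipelineConfig`, :class:`BandSpec`), the
readers/writers for the formats the pipeline consumes and produces (EDF,
delimited epoch matrices, covariate tables, result tables), and the error
hierarchy shared by the other modules.

Conventions
-----------
* Signals are stored in microvolts.  EDF physical dimensions are honoured on
  read and converted.
* Channel order is canonicalised to the configured montage list regardless of
  the order channels appear in a file, so that adjacency matrices are
  comparable across subjects.
* Continuous recordings are segmented into non-overlapping consecutive
  fixed-length epochs; trailing samples that do not fill an epoch are dropped
  (and logged).
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("eegraph")
if not logger.handlers:  # stderr by default; CLI installs its own handler
    logger.addHandler(logging.NullHandler())


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class EEGraphError(Exception):
    """Base class for all pipeline errors."""


class MissingChannelError(EEGraphError):
    """A required channel label is absent from the input."""


class SamplingRateMismatchError(EEGraphError):
    """Channels in one recording disagree on sampling rate."""


class NonFiniteDataError(EEGraphError):
    """Input signal contains NaN or infinite values."""


class FileFormatError(EEGraphError):
    """Input file is malformed (ragged rows, missing header, bad cells)."""


class DegenerateEstimatorError(EEGraphError):
    """Spectral estimate requested from too few epochs."""


class DegeneratePowerError(EEGraphError):
    """A channel has zero power where coherence is required."""


class EmptyBandError(EEGraphError):
    """No FFT bin falls inside a requested frequency band."""


class ZeroWeightGraphError(EEGraphError):
    """Graph has no positive edge weight."""


class UndefinedCorrelationError(EEGraphError):
    """Correlation requested against a constant vector."""


# ---------------------------------------------------------------------------
# Montage / band constants
# ---------------------------------------------------------------------------

#: The classic 19-electrode 10-20 montage, in the canonical (anterior to
#: posterior) order used for every adjacency matrix produced by this package.
STANDARD_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)


@dataclass(frozen=True)
class BandSpec:
    """A frequency band: half-open interval [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_low < f_high, "
                f"got [{self.f_low}, {self.f_high})"
            )


#: The five clinical EEG bands used throughout: delta, theta, alpha, beta,
#: gamma.  The delta lower edge of 0.1 Hz effectively starts at the first
#: nonzero FFT bin; the DC bin is always excluded from band averages.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.1, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 50.0),
)

#: The twelve global weighted-graph measures, in reporting order.
MEASURE_NAMES: tuple[str, ...] = (
    "degree", "strength", "radius", "diameter",
    "characteristic_path_length", "global_efficiency", "local_efficiency",
    "clustering_coefficient", "transitivity", "modularity",
    "assortativity", "small_worldness",
)


# ---------------------------------------------------------------------------
# EpochSet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochSet:
    """One subject's epoched multichannel EEG.

    Parameters
    ----------
    subject_id : str
    channel_labels : tuple of str
        Unique montage labels, one per channel, in storage order.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Signal in microvolts; must be finite everywhere.
    """

    subject_id: str
    channel_labels: tuple[str, ...]
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError(f"data must be 3-d (epochs, channels, samples); got {data.shape}")
        if data.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"{data.shape[1]} channels in data but {len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(data)):
            raise NonFiniteDataError(
                f"subject {self.subject_id!r}: data contains non-finite values"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_seconds(self) -> float:
        return self.n_samples / self.fs

    def reorder(self, labels: Sequence[str]) -> "EpochSet":
        """Return a copy with channels in the given canonical order."""
        missing = [c for c in labels if c not in self.channel_labels]
        if missing:
            raise MissingChannelError(
                f"subject {self.subject_id!r}: missing channel(s) {missing}"
            )
        idx = [self.channel_labels.index(c) for c in labels]
        return replace(self, channel_labels=tuple(labels), data=self.data[:, idx, :])


def segment_epochs(continuous: np.ndarray, fs: float, epoch_seconds: float) -> np.ndarray:
    """Cut a continuous (n_channels, n_total) array into non-overlapping epochs.

    Only whole epochs are emitted; trailing samples are dropped and logged.
    """
    continuous = np.asarray(continuous, dtype=float)
    spe = int(round(epoch_seconds * fs))
    n_epochs = continuous.shape[1] // spe
    dropped = continuous.shape[1] - n_epochs * spe
    if dropped:
        logger.info("segment_epochs: dropping %d trailing samples (< one epoch)", dropped)
    return (
        continuous[:, : n_epochs * spe]
        .reshape(continuous.shape[0], n_epochs, spe)
        .transpose(1, 0, 2)
    )


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

BASE_COVARIATE_COLUMNS = ("subject_id", "group", "sex", "mmse")


@dataclass
class CovariateTable:
    """Per-subject covariates: group label, sex, MMSE and cognitive z-scores.

    ``frame`` has one row per subject with at least the columns
    ``subject_id, group, sex, mmse``; every further numeric column is treated
    as a cognitive test score (typically a demographically-normed z-score).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = pd.DataFrame(self.frame).reset_index(drop=True)
        for col in BASE_COVARIATE_COLUMNS:
            if col not in frame.columns:
                raise ValueError(f"covariate table missing column {col!r}")
        if frame["subject_id"].duplicated().any():
            raise ValueError("covariate table has duplicate subject_id rows")
        self.frame = frame

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame["subject_id"])

    @property
    def score_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c not in BASE_COVARIATE_COLUMNS)

    def group_levels(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.frame["group"]))

    def require_two_groups(self) -> tuple[str, str]:
        levels = self.group_levels()
        if len(levels) != 2:
            raise ValueError(f"expected exactly two group levels, got {levels}")
        return levels  # type: ignore[return-value]


def read_covariates(path: str | Path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path))


def write_covariates(table: CovariateTable, path: str | Path) -> Path:
    path = Path(path)
    table.frame.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All pipeline constants in one place.

    Defaults follow the study design this pipeline implements: a 19-channel
    10-20 montage sampled at 200 Hz, ten 2-s epochs per subject, the five
    clinical bands, 5000-permutation group tests at FDR 0.05, and stratified
    70/30 classifier validation repeated 10 times.
    """

    channels: tuple[str, ...] = STANDARD_1020
    fs: float = 200.0
    epoch_seconds: float = 2.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    # group statistics
    n_permutations: int = 5000
    fdr_level: float = 0.05
    # graph measures
    edge_threshold: float = 0.0          # 0 keeps the dense weighted graph
    louvain_gamma: float = 1.0
    louvain_restarts: int = 10
    sw_nulls: int = 20
    sw_rewires_per_edge: int = 10
    # classification
    train_fraction: float = 0.7
    n_repeats: int = 10
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.bands = tuple(
            b if isinstance(b, BandSpec) else BandSpec(**b) for b in self.bands
        )
        if not self.bands:
            raise ValueError("at least one band must be configured")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if not (0 < self.fdr_level < 1):
            raise ValueError("fdr_level must lie in (0, 1)")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_seconds * self.fs))

    def band(self, name: str) -> BandSpec:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"no band named {name!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from TOML (.toml) or YAML (.yml/.yaml).

        Keys mirror the dataclass fields; ``bands`` is a list of
        ``{name, f_low, f_high}`` mappings.  Missing keys keep their defaults.
        """
        path = Path(path)
        if path.suffix == ".toml":
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        elif path.suffix in (".yml", ".yaml"):
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        else:
            raise FileFormatError(f"unsupported config extension: {path.suffix!r}")
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(raw))


# ---------------------------------------------------------------------------
# EDF read / write
# ---------------------------------------------------------------------------

def read_edf(
    path: str | Path,
    channels: Sequence[str] | None = None,
    epoch_seconds: float = 2.0,
    subject_id: str | None = None,
) -> EpochSet:
    """Read an EDF recording and segment it into fixed-length epochs.

    The continuous record is cut into non-overlapping consecutive epochs of
    ``epoch_seconds``; trailing samples are dropped.  Channels are reordered
    to ``channels`` (default: the 19-label 10-20 montage); a missing label
    raises :class:`MissingChannelError`.  Amplitudes are returned in µV
    (EDF physical dimensions are converted by the reader).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if channels is None:
        channels = STANDARD_1020
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:  # pragma: no cover - mne resamples internally
        raise SamplingRateMismatchError(f"multiple sampling rates in {path}: {sfreqs}")
    fs = float(raw.info["sfreq"])
    missing = [c for c in channels if c not in raw.ch_names]
    if missing:
        raise MissingChannelError(f"{path.name}: missing channel(s) {missing}")
    data_uv = raw.get_data(picks=list(channels)) * 1e6  # volts -> µV
    if not np.all(np.isfinite(data_uv)):
        raise NonFiniteDataError(f"{path.name}: non-finite samples")
    rms = float(np.sqrt(np.mean(data_uv**2)))
    if rms > 1e4 or (rms > 0 and rms < 1e-3):
        logger.warning("read_edf %s: unusual amplitude RMS %.3g µV", path.name, rms)
    data = segment_epochs(data_uv, fs, epoch_seconds)
    return EpochSet(
        subject_id=subject_id or path.stem,
        channel_labels=tuple(channels),
        fs=fs,
        data=data,
    )


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(epochs: EpochSet, path: str | Path) -> Path:
    """Write an :class:`EpochSet` as a 16-bit EDF file.

    One EDF data record per epoch (record duration = epoch length); physical
    dimension µV.  Values are quantised to the int16 grid spanning each
    channel's range, so a round trip reproduces the signal to within one
    quantisation step.
    """
    path = Path(path)
    data = epochs.data  # (E, C, S)
    n_ch, spe, n_rec = epochs.n_channels, epochs.n_samples, epochs.n_epochs
    flat = data.transpose(1, 0, 2).reshape(n_ch, -1)
    pmin = flat.min(axis=1)
    pmax = flat.max(axis=1)
    pmax = np.where(pmax - pmin <= 0, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)

    def fields(values: Iterable, width: int) -> bytes:
        return b"".join(_edf_field(v, width) for v in values)

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field(f"Startdate X {epochs.subject_id}", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field("%g" % epochs.epoch_seconds, 8),
        _edf_field(n_ch, 4),
        fields(epochs.channel_labels, 16),
        fields([""] * n_ch, 80),              # transducer
        fields(["uV"] * n_ch, 8),             # physical dimension
        fields(["%g" % v for v in pmin], 8),
        fields(["%g" % v for v in pmax], 8),
        fields([dmin] * n_ch, 8),
        fields([dmax] * n_ch, 8),
        fields([""] * n_ch, 80),              # prefiltering
        fields([spe] * n_ch, 8),
        fields([""] * n_ch, 32),
    ])
    assert len(header) == 256 * (1 + n_ch)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(n_ch):
                dig = np.round((data[r, c] - pmin[c]) / scale[c] + dmin)
                fh.write(dig.astype("<i2").tobytes())
    return path


# ---------------------------------------------------------------------------
# Delimited epoch matrices
# ---------------------------------------------------------------------------

_MATRIX_MAGIC = "# eegraph-epochs"


def write_epoch_matrix(epochs: EpochSet, path: str | Path) -> Path:
    """Write an :class:`EpochSet` as a delimited text file.

    Layout: a metadata comment line declaring subject and sampling rate,
    then a CSV with ``epoch``/``sample`` index columns and one column per
    channel.  Lossless for float64 values (shortest round-trip repr).
    """
    path = Path(path)
    e, c, s = epochs.data.shape
    idx = pd.MultiIndex.from_product([range(e), range(s)], names=["epoch", "sample"])
    frame = pd.DataFrame(
        epochs.data.transpose(0, 2, 1).reshape(e * s, c),
        index=idx,
        columns=list(epochs.channel_labels),
    )
    with open(path, "w") as fh:
        fh.write(f"{_MATRIX_MAGIC} subject={epochs.subject_id} fs={epochs.fs!r}\n")
        frame.to_csv(fh, float_format="%.17g")  # exact float64 round trip
    return path


def read_epoch_matrix(path: str | Path) -> EpochSet:
    """Read an epoch matrix written by :func:`write_epoch_matrix`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith(_MATRIX_MAGIC):
            raise FileFormatError(
                f"{path.name}: missing '{_MATRIX_MAGIC}' header declaring fs"
            )
        meta = dict(tok.split("=", 1) for tok in first[len(_MATRIX_MAGIC):].split())
        if "fs" not in meta:
            raise FileFormatError(f"{path.name}: header does not declare fs")
        try:
            frame = pd.read_csv(
                fh, index_col=["epoch", "sample"], float_precision="round_trip"
            )
        except (pd.errors.ParserError, ValueError) as exc:
            raise FileFormatError(f"{path.name}: {exc}") from exc
    if frame.empty:
        raise FileFormatError(f"{path.name}: no data rows")
    bad = frame.columns[[not pd.api.types.is_numeric_dtype(t) for t in frame.dtypes]]
    if len(bad):
        raise FileFormatError(f"{path.name}: non-numeric cells in column(s) {list(bad)}")
    epochs_idx = frame.index.get_level_values("epoch")
    n_epochs = int(epochs_idx.max()) + 1
    counts = frame.groupby(level="epoch").size()
    if counts.nunique() != 1:
        raise FileFormatError(f"{path.name}: ragged epochs (unequal sample counts)")
    n_samples = int(counts.iloc[0])
    data = frame.to_numpy(float).reshape(n_epochs, n_samples, len(frame.columns))
    return EpochSet(
        subject_id=str(meta.get("subject", path.stem)),
        channel_labels=tuple(frame.columns),
        fs=float(meta["fs"]),
        data=data.transpose(0, 2, 1),
    )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def metrics_to_frame(records: Sequence) -> pd.DataFrame:
    """Long-format (subject, band, measure, value) table from GraphMetricsRecords."""
    rows = []
    for rec in records:
        for measure in MEASURE_NAMES:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "band": rec.band,
                    "measure": measure,
                    "value": getattr(rec, measure),
                }
            )
    return pd.DataFrame(rows)


def write_results(
    comparisons: pd.DataFrame,
    metrics: Sequence | pd.DataFrame,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the group-comparison table and the per-subject metric table.

    Produces ``group_stats.csv`` (one row per measure × band, with group
    means, permutation and FDR-adjusted p-values) and ``metrics.csv``
    (long-format per-subject values).  Both reread losslessly and rewriting
    the reread tables reproduces the same bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comparisons = pd.DataFrame(comparisons)
    if comparisons.empty:
        raise ValueError("empty comparison table: refusing to write")
    if not isinstance(metrics, pd.DataFrame):
        metrics = metrics_to_frame(metrics)
    if metrics.empty:
        raise ValueError("empty metric table: refusing to write")
    stats_path = out_dir / "group_stats.csv"
    metrics_path = out_dir / "metrics.csv"
    comparisons.to_csv(stats_path, index=False)
    metrics.to_csv(metrics_path, index=False)
    return stats_path, metrics_path


def write_adjacency(W: np.ndarray, labels: Sequence[str], path: str | Path) -> Path:
    """Square-matrix CSV for one adjacency matrix."""
    path = Path(path)
    pd.DataFrame(np.asarray(W, float), index=list(labels), columns=list(labels)).to_csv(path)
    return path


def read_adjacency(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    frame = pd.read_csv(path, index_col=0)
    return frame.to_numpy(float), tuple(frame.columns)


def graphs_to_frame(subject_id: str, graphs: Sequence) -> pd.DataFrame:
    """Long-format (subject, band, channel_i, channel_j, coherence) edge list."""
    rows = []
    for g in graphs:
        labels = g.channel_labels
        n = len(labels)
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            rows.append(
                {
                    "subject_id": subject_id,
                    "band": g.band.name,
                    "channel_i": labels[i],
                    "channel_j": labels[j],
                    "coherence": g.W[i, j],
                }
            )
    return pd.DataFrame(rows)
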