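"""Synthetic EEG cohorts with known band-specific network structure.

The generator emulates the shape of a clinical resting-state recording set
— 19 channels of the 10-20 montage, 200 Hz, ten 2-s epochs per subject —
while giving every downstream stage a controllable ground truth:

* channels are partitioned into scalp-region modules (frontal /
  central-temporal / posterior, a labelling convenience only: no volume
  conduction or leadfield mixing is modelled);
* for each frequency band b, each channel mixes a module-shared and a
  global band-limited latent oscillator,

      x_c = sum_b [ alpha_b * s_module(c),b + beta_b * s_global,b ] + eps,

  where the latents are unit-variance white noise band-filtered to b
  (pure sinusoids would make coherence estimation degenerate), alpha is the
  intra-module coupling, beta the inter-module coupling, and eps white
  sensor noise;
* group "B" receives an additive per-band shift of its intra-module
  coupling (``group_effect``), so a planted effect raises within-module
  coherence — and hence modularity — in that band;
* each subject gets an independent per-band coupling jitter, and cognitive
  scores are linear in the subject's true coupling deviation, so Pearson
  correlation recovery is testable.

Every subject draws from an rng stream derived from the master seed and the
subject's index, making cohorts reproducible independently of generation
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import band_bins
from .io import (
    BandSpec,
    CovariateTable,
    DEFAULT_BANDS,
    EpochSet,
    STANDARD_1020,
)

__all__ = [
    "SyntheticCohortConfig",
    "DEFAULT_MODULES",
    "REFERENCE_GROUP_EFFECT",
    "generate_subject",
    "generate_cohort",
]

#: Default partition of the 19-channel montage into three scalp regions.
DEFAULT_MODULES: tuple[tuple[str, ...], ...] = (
    ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),          # frontal
    ("T3", "C3", "Cz", "C4", "T4"),                         # central-temporal
    ("T5", "P3", "Pz", "P4", "T6", "O1", "O2"),             # posterior
)

#: Reference planted effect: the additive beta-band intra-coupling shift
#: used by the package's power experiments (raises group-B within-module
#: beta coherence from 0.6 to 0.75 of the latent amplitude).
REFERENCE_GROUP_EFFECT: float = 0.15


def _per_band(value, bands: Sequence[BandSpec]) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {b.name: 0.0 for b in bands}
        unknown = set(value) - set(out)
        if unknown:
            raise ValueError(f"unknown band name(s) in coupling map: {sorted(unknown)}")
        out.update({k: float(v) for k, v in value.items()})
        return out
    return {b.name: float(value) for b in bands}


@dataclass
class SyntheticCohortConfig:
    """Ground-truth parameters of a two-group synthetic cohort.

    Couplings are per-band amplitudes in [0, 1) on unit-variance latents;
    scalars broadcast to all bands, mappings may name a subset of bands.
    ``group_effect`` is added to the intra-module coupling of group B.
    Covariates: per-group female probability and MMSE mean/SD; each entry
    of ``score_loadings`` maps a score name to ``(band, loading)`` and the
    score is ``loading * (subject's intra-coupling deviation in that band,
    in jitter-SD units) + N(0, score_noise_sd)``.
    """

    n_per_group: int = 30
    group_labels: tuple[str, str] = ("A", "B")
    channels: tuple[str, ...] = STANDARD_1020
    module_assignment: tuple[tuple[str, ...], ...] = DEFAULT_MODULES
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    fs: float = 200.0
    epoch_seconds: float = 2.0
    n_epochs: int = 10
    intra_coupling: Mapping[str, float] | float = 0.6
    inter_coupling: Mapping[str, float] | float = 0.3
    group_effect: Mapping[str, float] | float = 0.0
    coupling_jitter_sd: float = 0.05
    noise_sd: float = 1.0
    sex_female_p: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.71, "B": 0.47}
    )
    mmse_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (26.0, 3.0), "B": (24.0, 3.8)}
    )
    score_loadings: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {
            "rcft_delayed_recall": ("gamma", 0.5),
            "cowat_phonemic": ("gamma", 0.5),
            "cowat_semantic": ("beta", -0.5),
        }
    )
    score_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.bands = tuple(
            b if isinstance(b, BandSpec) else BandSpec(**b) for b in self.bands
        )
        self.module_assignment = tuple(tuple(m) for m in self.module_assignment)
        flat = [c for mod in self.module_assignment for c in mod]
        if sorted(flat) != sorted(self.channels):
            raise ValueError("module_assignment must cover every channel exactly once")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        self.intra_coupling = _per_band(self.intra_coupling, self.bands)
        self.inter_coupling = _per_band(self.inter_coupling, self.bands)
        self.group_effect = _per_band(self.group_effect, self.bands)
        for name, coupling in (("intra", self.intra_coupling), ("inter", self.inter_coupling)):
            for band, v in coupling.items():
                if not (0 <= v < 1):
                    raise ValueError(
                        f"{name}_coupling[{band!r}] = {v} outside [0, 1)"
                    )

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_seconds * self.fs))

    @property
    def module_index(self) -> np.ndarray:
        idx = np.empty(len(self.channels), dtype=int)
        for m, members in enumerate(self.module_assignment):
            for c in members:
                idx[self.channels.index(c)] = m
        return idx

    def subject_rng(self, counter: int) -> np.random.Generator:
        """Independent stream for subject ``counter``, derived from the
        master seed by counter (generation-order independent)."""
        return np.random.default_rng([int(self.seed) % (2**31), int(counter)])


def _band_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n: int, fs: float, band: BandSpec
) -> np.ndarray:
    """Unit-variance white noise band-limited to ``band`` (FFT masking).

    Returns shape ``(*shape, n)``; each trace is independently standardised.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = band_bins(freqs, band)
    white = rng.standard_normal((*shape, n))
    spec = np.fft.rfft(white, axis=-1)
    spec[..., ~mask] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _subject_couplings(
    config: SyntheticCohortConfig, group: str, rng: np.random.Generator
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """(alpha per band, beta per band, intra-coupling deviation per band).

    The deviation is the subject's intra coupling minus the cohort-level
    default — it includes both the group effect and the subject jitter, and
    is what cognitive scores load on.
    """
    affected = group == config.group_labels[1]
    alpha, beta, deviation = {}, {}, {}
    for b in config.bands:
        jitter = rng.normal(0.0, config.coupling_jitter_sd)
        a = config.intra_coupling[b.name] + (config.group_effect[b.name] if affected else 0.0) + jitter
        alpha[b.name] = float(np.clip(a, 0.0, 0.99))
        beta[b.name] = config.inter_coupling[b.name]
        deviation[b.name] = alpha[b.name] - config.intra_coupling[b.name]
    return alpha, beta, deviation


def _generate_signals(
    config: SyntheticCohortConfig,
    alpha: Mapping[str, float],
    beta: Mapping[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    n, n_epochs = config.n_samples, config.n_epochs
    n_ch = len(config.channels)
    n_mod = len(config.module_assignment)
    mod_idx = config.module_index
    data = np.zeros((n_epochs, n_ch, n))
    for b in config.bands:
        latents = _band_noise(rng, (n_epochs, n_mod + 1), n, config.fs, b)
        s_mod = latents[:, :n_mod, :]          # (E, M, n)
        s_glob = latents[:, n_mod, :]          # (E, n)
        data += alpha[b.name] * s_mod[:, mod_idx, :]
        data += beta[b.name] * s_glob[:, None, :]
    data += rng.normal(0.0, config.noise_sd, size=data.shape)
    return data


def generate_subject(
    config: SyntheticCohortConfig,
    group: str,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "synthetic",
) -> EpochSet:
    """Generate one subject's :class:`EpochSet` for the given group label.

    Deterministic for a fixed ``rng`` seed and config.
    """
    if group not in config.group_labels:
        raise ValueError(f"unknown group {group!r}; expected one of {config.group_labels}")
    rng = np.random.default_rng(rng)
    alpha, beta, _ = _subject_couplings(config, group, rng)
    data = _generate_signals(config, alpha, beta, rng)
    return EpochSet(
        subject_id=subject_id,
        channel_labels=config.channels,
        fs=config.fs,
        data=data,
    )


def generate_cohort(
    config: SyntheticCohortConfig,
    return_truth: bool = False,
):
    """Generate the full two-group cohort.

    Returns ``(epoch_sets, covariates)`` — or, with ``return_truth=True``,
    ``(epoch_sets, covariates, truth)`` where ``truth`` is a DataFrame of
    each subject's realised per-band intra/inter couplings.
    """
    subjects: list[EpochSet] = []
    cov_rows = []
    truth_rows = []
    counter = 0
    for group in config.group_labels:
        for _ in range(config.n_per_group):
            rng = config.subject_rng(counter)
            subject_id = f"{group}{counter:03d}"
            alpha, beta, deviation = _subject_couplings(config, group, rng)
            data = _generate_signals(config, alpha, beta, rng)
            subjects.append(
                EpochSet(
                    subject_id=subject_id,
                    channel_labels=config.channels,
                    fs=config.fs,
                    data=data,
                )
            )
            sex = int(rng.random() < config.sex_female_p[group])
            mu, sd = config.mmse_mean_sd[group]
            mmse = float(np.clip(np.round(rng.normal(mu, sd)), 0, 30))
            row = {"subject_id": subject_id, "group": group, "sex": sex, "mmse": mmse}
            for score, (band, loading) in config.score_loadings.items():
                z = deviation[band] / config.coupling_jitter_sd
                row[score] = float(loading * z + rng.normal(0.0, config.score_noise_sd))
            cov_rows.append(row)
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    **{f"alpha_{b}": v for b, v in alpha.items()},
                    **{f"beta_{b}": v for b, v in beta.items()},
                }
            )
            counter += 1
    covariates = CovariateTable(pd.DataFrame(cov_rows))
    if return_truth:
        return subjects, covariates, pd.DataFrame(truth_rows)
    return subjects, covariates
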