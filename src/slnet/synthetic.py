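"""Synthetic multichannel cohorts with planted coupling and topology.

Sources are band-limited filtered Gaussian noise (the simplest model with the
band-power structure the pipeline assumes); observed channels are linear
mixtures of their own source, the sources of coupled channels, and
independent sensor noise. Linear mixing gives a controllable ground truth
that synchronization likelihood responds to monotonically. Cohorts attach
twin-family structure: family members share a random family-level offset on
coupling strength (intraclass correlation ~0.5), so resampling families is
genuinely different from resampling subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import PROTOTYPE_KINDS, gen_prototype, random_gnm_adjacency
from .preprocess import BandDefinition, fir_bandpass
from .recording import CohortDataset, ConfigurationError, Recording

TOPOLOGIES = PROTOTYPE_KINDS + ("random", "uniform")

#: Scale of the shared family-level and subject-level offsets on coupling
#: strength; equal scales give an intraclass correlation of 0.5.
FAMILY_SD = 0.05
SUBJECT_SD = 0.05


@dataclass(frozen=True)
class CouplingSpec:
    """Signal-level description of one synthetic recording condition."""

    n_channels: int = 14
    topology: str = "clustered_sw"
    coupling_strength: float = 0.5
    band: tuple[float, float] = (6.0, 13.0)
    fs: float = 250.0
    duration: float = 12.0
    noise_level: float = 0.1

    def __post_init__(self) -> None:
        if self.n_channels < 3:
            raise ConfigurationError("need at least 3 channels")
        if self.topology not in TOPOLOGIES:
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        if not 0 <= self.coupling_strength <= 1:
            raise ConfigurationError("coupling_strength must lie in [0, 1]")
        low, high = self.band
        if not 0 < low < high < self.fs / 2:
            raise ConfigurationError(f"band {self.band} outside (0, fs/2)")
        if self.noise_level < 0:
            raise ConfigurationError("noise_level must be >= 0")
        if self.duration <= 0 or self.n_samples < 1:
            raise ConfigurationError("duration must yield >= 1 sample")

    @property
    def n_samples(self) -> int:
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"duration {self.duration} s x fs {self.fs} Hz is not an "
                "integer sample count"
            )
        return int(round(n))


@dataclass(frozen=True)
class CohortDesign:
    """Group / family / wave layout of a synthetic cohort.

    ``groups`` lists (label, n_families); every family has
    ``members_per_family`` subjects (a twin pair plus optional siblings) and
    every subject is measured at each of ``waves`` repeated measures.
    ``coupling_by_group`` maps each group label to its mean coupling
    strength.
    """

    groups: tuple[tuple[str, int], ...]
    coupling_by_group: dict[str, float]
    members_per_family: int = 2
    waves: int = 1
    seed: int = 0
    with_volumes: bool = False

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("need at least one group")
        for label, n_fam in self.groups:
            if n_fam < 1:
                raise ConfigurationError(f"group {label}: need >= 1 family")
            if label not in self.coupling_by_group:
                raise ConfigurationError(f"group {label}: no coupling strength given")
        if self.members_per_family < 1 or self.waves < 1:
            raise ConfigurationError("members_per_family and waves must be >= 1")


def gen_sources(n_sources: int, band: tuple[float, float], fs: float,
                duration: float, seed: int) -> Recording:
    """Independent band-limited Gaussian sources, unit variance per channel."""
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ConfigurationError(f"band {band} outside (0, fs/2)")
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    n_samples = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    # generate with padding so filter edge effects do not reach the output
    bdef = BandDefinition("source", low, high)
    pad = 4 * int(np.ceil(3.3 * fs / max(0.5, min(2.0, 0.25 * low))))
    white = rng.standard_normal((n_sources, n_samples + 2 * pad))
    rec = Recording(data=white, fs=fs, labels=[f"S{i + 1}" for i in range(n_sources)])
    filtered = fir_bandpass(rec, bdef).data[:, pad:pad + n_samples]
    sd = filtered.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return Recording(
        data=filtered / sd, fs=fs,
        labels=[f"S{i + 1}" for i in range(n_sources)],
        meta={"band": band, "seed": seed, "kind": "filtered-noise source"},
    )


def mix_coupled(sources: Recording, coupling: np.ndarray, noise_level: float,
                seed: int) -> Recording:
    """Observed channels as linear mixtures of coupled sources plus noise.

    Channel i is s_i + sum_j coupling[i, j] * s_j + noise_level * n_i with
    n_i independent white noise. ``coupling`` must be symmetric with zero
    diagonal and entries in [0, 1]; coupling[i, j] = 1 with zero noise makes
    channels i and j identical up to scale (for an isolated coupled pair).
    """
    c = np.asarray(coupling, dtype=float)
    n = sources.n_channels
    if c.shape != (n, n):
        raise ConfigurationError(f"coupling shape {c.shape} != ({n}, {n})")
    if not np.allclose(c, c.T):
        raise ConfigurationError("coupling matrix must be symmetric")
    if np.diag(c).any():
        raise ConfigurationError("coupling diagonal must be zero")
    if c.min() < 0 or c.max() > 1:
        raise ConfigurationError("coupling entries must lie in [0, 1]")
    if noise_level < 0:
        raise ConfigurationError("noise_level must be >= 0")
    rng = np.random.default_rng(seed)
    mixed = sources.data + c @ sources.data
    mixed = mixed + noise_level * rng.standard_normal(mixed.shape)
    meta = dict(sources.meta)
    meta["coupling_mean"] = float(c[np.triu_indices(n, 1)].mean())
    return sources.copy_with(data=mixed, meta=meta)


def coupling_matrix(spec: CouplingSpec, seed: int) -> np.ndarray:
    """Planted coupling matrix for a spec: the adjacency of the requested
    topology scaled by the coupling strength (``uniform`` couples every pair,
    ``random`` uses a G(N, M) adjacency at average degree 4)."""
    n = spec.n_channels
    if spec.topology == "uniform":
        adj = ~np.eye(n, dtype=bool)
    elif spec.topology == "random":
        rng = np.random.default_rng(seed)
        adj = random_gnm_adjacency(n, int(n * 4 // 2), 1, rng)[0]
    else:
        adj = gen_prototype(spec.topology, n, K=4.0, n_rewire=3, seed=seed).adjacency
    return adj * spec.coupling_strength


def gen_recording(spec: CouplingSpec, seed: int,
                  coupling: np.ndarray | None = None) -> Recording:
    """One recording drawn from a coupling spec (sources, mixing, labels)."""
    if coupling is None:
        coupling = coupling_matrix(spec, seed)
    src = gen_sources(spec.n_channels, spec.band, spec.fs, spec.duration, seed)
    rec = mix_coupled(src, coupling, spec.noise_level, seed + 1)
    labels = _eeg_labels(spec.n_channels)
    return rec.copy_with(labels=labels)


_LABELS_16 = ["Fp1", "Fp2", "F7", "F3", "F4", "F8", "C3", "C4",
              "T5", "P3", "P4", "T6", "O1", "O2", "EOGh", "EOGv"]


def _eeg_labels(n: int) -> list[str]:
    if n <= len(_LABELS_16):
        return _LABELS_16[:n]
    return _LABELS_16 + [f"X{i}" for i in range(n - len(_LABELS_16))]


def gen_cohort(design: CohortDesign, spec: CouplingSpec) -> CohortDataset:
    """Synthetic cohort: one recording per subject per wave.

    Coupling strength for subject s in family f of group g is
    clip(mean_g + u_f + e_s, 0, 1) with u_f ~ N(0, FAMILY_SD) shared within
    the family and e_s ~ N(0, SUBJECT_SD). The planted topology adjacency is
    common to the whole cohort. With ``with_volumes`` the table carries gray/
    white-matter volumes linearly related to the subject's coupling strength
    plus a sex effect, for exercising the partial-correlation path.
    """
    rng = np.random.default_rng(design.seed)
    base_adj = (coupling_matrix(spec, design.seed) > 0)
    rows = []
    recordings: dict[tuple[str, int], Recording] = {}
    fam_counter = 0
    for label, n_fam in design.groups:
        mean_c = design.coupling_by_group[label]
        for _ in range(n_fam):
            fam_counter += 1
            fam_id = f"fam{fam_counter:03d}"
            u_f = rng.normal(0.0, FAMILY_SD)
            for mem in range(design.members_per_family):
                subj = f"{fam_id}s{mem + 1}"
                c_subj = float(np.clip(mean_c + u_f + rng.normal(0.0, SUBJECT_SD), 0, 1))
                sex = "M" if rng.random() < 0.5 else "F"
                row = {"subject_id": subj, "family_id": fam_id, "group": label,
                       "sex": sex, "coupling": c_subj}
                if design.with_volumes:
                    sex_eff = 60_000 if sex == "M" else 0
                    row["gmv"] = 650_000 + sex_eff + 80_000 * c_subj \
                        + rng.normal(0, 25_000)
                    row["wmv"] = 450_000 + sex_eff + 90_000 * c_subj \
                        + rng.normal(0, 25_000)
                for wave in range(1, design.waves + 1):
                    rec_seed = int(rng.integers(2**31))
                    rec = gen_recording(spec, rec_seed, coupling=base_adj * c_subj)
                    rec.meta.update(subject_id=subj, wave=wave, id=f"{subj}w{wave}")
                    recordings[(subj, wave)] = rec
                    rows.append({**row, "wave": wave})
    return CohortDataset(table=pd.DataFrame(rows), recordings=recordings)


def gen_metric_cohort(design: CohortDesign, effect_by_group: dict[str, float],
                      sd: float = 1.0, family_icc: float = 0.5,
                      metric: str = "value") -> CohortDataset:
    """Cohort with metric values drawn directly (no signal stage).

    Observation for a member of family f in group g is
    effect_g + u_f + e, with var(u_f) = family_icc * sd^2 and
    var(e) = (1 - family_icc) * sd^2. Used for statistical power and
    type-I-error studies where the signal pipeline would only add noise of
    its own.
    """
    rng = np.random.default_rng(design.seed)
    sd_f = sd * np.sqrt(family_icc)
    sd_e = sd * np.sqrt(1 - family_icc)
    rows = []
    fam_counter = 0
    for label, n_fam in design.groups:
        eff = effect_by_group[label]
        for _ in range(n_fam):
            fam_counter += 1
            fam_id = f"fam{fam_counter:03d}"
            u_f = rng.normal(0.0, sd_f)
            for mem in range(design.members_per_family):
                subj = f"{fam_id}s{mem + 1}"
                sex = "M" if rng.random() < 0.5 else "F"
                for wave in range(1, design.waves + 1):
                    rows.append({
                        "subject_id": subj, "family_id": fam_id, "group": label,
                        "wave": wave, "sex": sex,
                        metric: eff + u_f + rng.normal(0.0, sd_e),
                    })
    return CohortDataset(table=pd.DataFrame(rows))
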