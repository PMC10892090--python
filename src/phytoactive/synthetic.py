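"""Synthetic fractionation datasets with known ground truth.

Emulates the data a bioactivity-guided fractionation screen produces:
~21 chemically distinct fractions of a botanical extract, each profiled
by flow-injection HRMS (>1500 molecular features) and assayed for % cell
viability (clipped to the observed 5-117% span).  A small set of spiked
features drives viability linearly on the log-intensity scale; adduct and
isotopologue satellite features at fixed mass offsets exercise the
deconvolution step; MS/MS spectra come in families sharing fragments so
the molecular network has known components; and the compound library
contains caffeoylquinic-acid anchors plus out-of-window decoys.

Every generator is a pure function of its :class:`SyntheticConfig`
(including the seed): identical config => bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import PROTON_MASS, CompoundLibrary, LibraryEntry, neutral_mass
from .network import MsmsSpectrum
from .preprocess import BioactivityVector, FeatureMatrix, feature_id

__all__ = [
    "SyntheticConfig",
    "SpikeRecord",
    "SyntheticDataset",
    "generate_fraction_profiles",
    "generate_spectra",
    "generate_library",
    "generate_dataset",
    "ANCHOR_FEATURES",
]

#: Table-style NEG-mode anchor features planted in every NEG matrix large
#: enough to hold them: mono-CQA [M-H]-, di-CQA [M-H]-, and an unannotated ion.
ANCHOR_FEATURES: tuple[str, ...] = ("1.41_353.0874", "1.79_515.1191", "1.62_257.0554")

# satellite mass offsets, cycled: Na-H exchange, 13C isotopologues
_SATELLITE_OFFSETS = (21.9819, 1.0034, 2.0068, 43.9639)


@dataclass(frozen=True)
class SyntheticConfig:
    """The stated world of the generator.

    Defaults mirror the screening campaign being emulated: 21 fractions,
    1500 features, 3 bioactive spikes, viability clipped to [5, 117]%.
    Effect sizes are % viability per unit log-intensity; viability noise is
    Gaussian with sd 3% (the error of a replicate-averaged assay mean).
    """

    n_fractions: int = 21
    n_features: int = 1500
    n_bioactive: int = 3
    effect_sizes: tuple[float, ...] = (16.0, 11.0, 8.0)
    co_eluting_spikes: bool = True
    baseline_viability: float = 55.0
    noise_sd: float = 3.0
    viability_range: tuple[float, float] | None = (5.0, 117.0)
    n_satellite_parents: int = 30
    adduct_satellites_per_feature: int = 2
    n_spectrum_families: int = 6
    family_size_range: tuple[int, int] = (3, 6)
    n_singleton_spectra: int = 5
    fragments_per_spectrum: int = 10
    intensity_floor: float = 50.0
    ion_mode: str = "NEG"
    n_replicates: int = 12
    include_anchor_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bioactive >= self.n_features:
            raise ValueError("n_bioactive must be smaller than n_features")
        if self.viability_range is not None and not (
            self.viability_range[0] < self.viability_range[1]
        ):
            raise ValueError("viability_range low must be below high")
        for name in (
            "n_fractions", "n_features", "n_spectrum_families",
            "fragments_per_spectrum", "n_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_sat = self.n_satellite_parents * self.adduct_satellites_per_feature
        if self.n_features - n_sat <= self.n_bioactive:
            raise ValueError("too many satellite features for n_features")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("effect_sizes", "viability_range", "family_size_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class SpikeRecord:
    """Ground truth for one spiked bioactive feature."""

    feature_id: str
    true_coefficient: float  # % viability per unit log-intensity
    family_id: int           # spectrum family carrying this compound


@dataclass
class SyntheticDataset:
    matrix: FeatureMatrix
    viability: BioactivityVector
    spikes: list[SpikeRecord]
    spectra: list[MsmsSpectrum]
    library: CompoundLibrary


def _unique_fid(rt: float, mz: float, taken: set[str]) -> str:
    fid = feature_id(rt, mz)
    while fid in taken:
        mz += 0.0007
        fid = feature_id(rt, mz)
    taken.add(fid)
    return fid


def generate_fraction_profiles(
    config: SyntheticConfig,
) -> tuple[FeatureMatrix, BioactivityVector, list[SpikeRecord]]:
    """Fraction x feature intensities, viability response, and spike truth.

    Each feature gets a smooth, elution-like abundance profile over the
    fraction index (Gaussian bump with random centre/width, log-normal
    amplitude, multiplicative noise, floored at the limit of detection).
    Spiked features ride on a positive baseline so their log-intensity is
    defined in every fraction, and viability is their linear combination
    on the log scale plus Gaussian noise, clipped to the configured range.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_fractions, config.n_features
    n_sat = config.n_satellite_parents * config.adduct_satellites_per_feature
    n_parents = p - n_sat

    idx = np.arange(n, dtype=float)
    taken: set[str] = set()
    fids: list[str] = []
    cols: list[np.ndarray] = []
    parent_amp = np.zeros(n_parents)
    parent_rt = np.zeros(n_parents)
    parent_mz = np.zeros(n_parents)

    spike_idx = rng.choice(n_parents, size=config.n_bioactive, replace=False)
    spike_set = set(int(i) for i in spike_idx)
    # bioactives emulate a family of structurally related isomers/homologues
    # (the usual situation for plant phenolics) that co-fractionate: one
    # shared elution profile, amplitude-scaled per member with small
    # proportional jitter
    spike_centre = float(rng.uniform(0.25 * (n - 1), 0.75 * (n - 1)))
    spike_width = float(rng.uniform(3.0, 4.0))

    for j in range(n_parents):
        rt = float(rng.uniform(0.3, 2.2))
        mz = float(rng.uniform(150.0, 800.0))
        centre = float(rng.uniform(0, n - 1))
        if j in spike_set:
            amp = float(rng.lognormal(11.0, 0.3))
            if config.co_eluting_spikes:
                centre, width = spike_centre, spike_width
                jitter_sd = 0.1
            else:
                width = float(rng.uniform(3.0, 4.0))
                jitter_sd = 0.25
            bump = np.exp(-((idx - centre) ** 2) / (2 * width**2))
            profile = amp * (0.15 + bump) * np.exp(rng.normal(0.0, jitter_sd, size=n))
        else:
            amp = float(rng.lognormal(10.0, 1.2))
            width = float(rng.uniform(1.2, 3.0))
            profile = (
                amp
                * np.exp(-((idx - centre) ** 2) / (2 * width**2))
                * np.exp(rng.normal(0.0, 0.25, size=n))
            )
        parent_amp[j], parent_rt[j], parent_mz[j] = amp, rt, mz
        fids.append(_unique_fid(rt, mz, taken))
        cols.append(profile)

    # replace the first non-spike parents with fixed anchor ids (NEG mode)
    if config.include_anchor_features and config.ion_mode == "NEG" and n_parents > 10:
        replaceable = [j for j in range(n_parents) if j not in spike_set]
        for fid, j in zip(ANCHOR_FEATURES, replaceable):
            taken.discard(fids[j])
            taken.add(fid)
            fids[j] = fid
            parent_rt[j], parent_mz[j] = (
                float(fid.split("_")[0]),
                float(fid.split("_")[1]),
            )

    # adduct/isotopologue satellites: proportional copies at fixed mass offsets
    eligible = np.array(
        [j for j in range(n_parents)
         if j not in spike_set and parent_amp[j] >= np.median(parent_amp)]
    )
    sat_parents = rng.choice(
        eligible, size=min(config.n_satellite_parents, eligible.size), replace=False
    )
    for j in sat_parents:
        for k in range(config.adduct_satellites_per_feature):
            offset = _SATELLITE_OFFSETS[k % len(_SATELLITE_OFFSETS)]
            ratio = float(rng.uniform(0.1, 0.5))
            rt = parent_rt[j] + float(rng.uniform(-0.03, 0.03))
            mz = parent_mz[j] + offset + float(rng.uniform(-0.002, 0.002))
            fids.append(_unique_fid(rt, mz, taken))
            cols.append(ratio * cols[j])

    X = np.column_stack(cols)
    X[X < config.intensity_floor] = 0.0

    # viability: linear in spike log-intensities, baseline-anchored
    z = np.column_stack([np.log(np.maximum(X[:, j], 1e-12)) for j in spike_idx])
    effects = np.array(
        [config.effect_sizes[s % len(config.effect_sizes)]
         for s in range(config.n_bioactive)]
    )
    b0 = config.baseline_viability - float(z.mean(axis=0) @ effects)
    v = b0 + z @ effects + rng.normal(0.0, config.noise_sd, size=n)
    if config.viability_range is not None:
        v = np.clip(v, *config.viability_range)

    fraction_ids = [f"A{i + 1}" for i in range(n)]
    matrix = FeatureMatrix(
        pd.DataFrame(X, index=fraction_ids, columns=fids), ion_mode=config.ion_mode
    )
    viability = BioactivityVector(
        fraction_ids=fraction_ids,
        viability_pct=v,
        se_pct=np.full(n, config.noise_sd / np.sqrt(config.n_replicates)),
        n_replicates=config.n_replicates,
    )
    spikes = [
        SpikeRecord(
            feature_id=fids[int(j)],
            true_coefficient=float(effects[s]),
            family_id=s % config.n_spectrum_families,
        )
        for s, j in enumerate(spike_idx)
    ]
    return matrix, viability, spikes


def _fragment_positions(rng: np.random.Generator, n_sets: int, per_set: int) -> np.ndarray:
    """Disjoint, well-separated fragment m/z sets (spacing >> fragment_tol)."""
    total = n_sets * per_set
    slots = rng.permutation(total * 2)[:total]
    mz = 50.0 + 0.7 * slots + rng.uniform(-0.05, 0.05, size=total)
    return mz.reshape(n_sets, per_set)


def _pick_feature(rng: np.random.Generator, n: int, used: set[int]) -> int:
    if len(used) >= n:  # tiny matrices: allow reuse rather than loop forever
        return int(rng.integers(0, n))
    j = int(rng.integers(0, n))
    while j in used:
        j = int(rng.integers(0, n))
    return j


def generate_spectra(
    config: SyntheticConfig,
    matrix: FeatureMatrix,
    spikes: Sequence[SpikeRecord] = (),
) -> list[MsmsSpectrum]:
    """MS/MS spectra in families sharing fragments, plus singletons.

    Members of one family share all but two fragment peaks (the two
    member-specific peaks are low-intensity), so pairwise cosine within a
    family clears 0.70 with >= 6 matched peaks; families draw from
    mutually disjoint fragment-position sets so no inter-family edge can
    reach 6 matched peaks.  Spiked features are the first member of their
    assigned family.
    """
    f = config.fragments_per_spectrum
    if f < 6:
        raise ValueError("fragments_per_spectrum must be at least 6")
    rng = np.random.default_rng((config.seed, 1))
    n_unique = 2 if f >= 8 else f - 6
    n_shared = f - n_unique

    fids = matrix.feature_ids
    rts = matrix.retention_min
    mzs = matrix.mz
    spike_ids = {s.family_id: s.feature_id for s in spikes}

    n_sets = config.n_spectrum_families + config.n_singleton_spectra
    shared_pool = _fragment_positions(rng, n_sets, f)

    spectra: list[MsmsSpectrum] = []
    used_features: set[int] = set()
    for fam in range(config.n_spectrum_families):
        size = int(rng.integers(config.family_size_range[0],
                                config.family_size_range[1] + 1))
        base_mz = shared_pool[fam, :n_shared]
        unique_mz = shared_pool[fam, n_shared:]
        base_int = rng.uniform(0.3, 1.0, size=n_shared)
        for m in range(size):
            if m == 0 and fam in spike_ids:
                j = fids.index(spike_ids[fam])
            else:
                j = _pick_feature(rng, len(fids), used_features)
            used_features.add(j)
            inten = base_int * np.exp(rng.normal(0.0, 0.1, size=n_shared))
            frags = [(float(mzf), float(ii)) for mzf, ii in zip(base_mz, inten)]
            if n_unique:
                umz = unique_mz + m * 0.31  # keep member-specific peaks apart
                frags += [(float(u), float(rng.uniform(0.03, 0.08))) for u in umz[:n_unique]]
            spectra.append(
                MsmsSpectrum(
                    spectrum_id=f"fam{fam}_m{m}_{fids[j]}",
                    precursor_mz=float(mzs[j]),
                    ion_mode=matrix.ion_mode,
                    retention_min=float(rts[j]),
                    fragments=frags,
                )
            )
    for s in range(config.n_singleton_spectra):
        j = _pick_feature(rng, len(fids), used_features)
        used_features.add(j)
        pos = shared_pool[config.n_spectrum_families + s]
        inten = rng.uniform(0.2, 1.0, size=f)
        spectra.append(
            MsmsSpectrum(
                spectrum_id=f"single{s}_{fids[j]}",
                precursor_mz=float(mzs[j]),
                ion_mode=matrix.ion_mode,
                retention_min=float(rts[j]),
                fragments=[(float(mzf), float(ii)) for mzf, ii in zip(pos, inten)],
            )
        )
    return spectra


# reference fragments of the caffeoylquinic-acid anchors ([M-H]- series)
_CQA_FRAGMENTS = {
    "mono-CQA": (191.0561, 179.0350, 135.0441),
    "di-CQA": (353.0873, 191.0561, 179.0350, 173.0455),
}


def generate_library(
    config: SyntheticConfig,
    matrix: FeatureMatrix | None = None,
    spectra: Sequence[MsmsSpectrum] | None = None,
    spikes: Sequence[SpikeRecord] = (),
) -> CompoundLibrary:
    """Compound library with CQA anchors, spike entries, and +50 ppm decoys.

    Anchor neutral masses are the [M-H]- ions 353.0874 / 515.1191 plus a
    proton; decoys sit 50 ppm above real features, guaranteed outside any
    10 ppm annotation window.
    """
    rng = np.random.default_rng((config.seed, 2))
    entries = [
        LibraryEntry("mono-CQA", 353.0874 + PROTON_MASS, _CQA_FRAGMENTS["mono-CQA"]),
        LibraryEntry("di-CQA", 515.1191 + PROTON_MASS, _CQA_FRAGMENTS["di-CQA"]),
        LibraryEntry("quercetin", 303.0502 - PROTON_MASS),  # [M+H]+ anchor
    ]
    feature_neutrals = np.array([])
    if matrix is not None:
        feature_neutrals = np.array(
            [neutral_mass(m, matrix.ion_mode) for m in matrix.mz]
        )
        frag_by_feature = {}
        for sp in spectra or ():
            frag_by_feature[sp.precursor_mz] = tuple(m for m, _ in sp.fragments[:4])
        for i, s in enumerate(spikes):
            smz = float(s.feature_id.split("_")[1])
            entries.append(
                LibraryEntry(
                    f"bioactive_{i + 1}",
                    neutral_mass(smz, matrix.ion_mode),
                    frag_by_feature.get(smz, ()),
                )
            )
    # decoys: 50 ppm above a real mass, rejected if within 10 ppm of any feature
    decoy_sources = (
        feature_neutrals[: min(10, feature_neutrals.size)]
        if feature_neutrals.size
        else np.array([e.neutral_mass for e in entries])
    )
    k = 0
    for base in decoy_sources:
        mass = base * (1 + 50e-6)
        if feature_neutrals.size and np.any(
            np.abs(1e6 * (feature_neutrals - mass) / mass) <= 10.0
        ):
            continue
        k += 1
        entries.append(LibraryEntry(f"decoy_{k}", float(mass)))
    # a few random fillers far from everything
    for i in range(5):
        mass = float(rng.uniform(900.0, 1200.0))
        entries.append(LibraryEntry(f"filler_{i + 1}", mass))
    return CompoundLibrary(entries)


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """One call for the full stated world: matrix, viability, truth, spectra, library."""
    matrix, viability, spikes = generate_fraction_profiles(config)
    spectra = generate_spectra(config, matrix, spikes)
    library = generate_library(config, matrix, spectra, spikes)
    return SyntheticDataset(matrix, viability, spikes, spectra, library)
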