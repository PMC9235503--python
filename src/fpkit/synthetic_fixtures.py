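"""Desk-scale synthetic benchmarks with the statistical shape of real data.

Each binary label is linked to a small set of characteristic fragment
masses; a structure's spectra contain the characteristic peaks of its
positive labels plus background peaks, replicated with variable counts and
perturbed by the noise simulator. The linkage is a generative stand-in for
substructure-driven fragmentation chemistry, not a physical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fpkit.dbsearch import CandidateSet
from fpkit.spectra_data.model import CompoundRecord, FingerprintMatrix, Spectrum
from fpkit.spectra_data.noise import NoiseParams, simulate_noise
from fpkit.spectra_data.preprocess import compute_sample_weights, merge_spectra


@dataclass
class FixtureConfig:
    """Knobs of the synthetic benchmark generator; ``seed`` is mandatory."""

    seed: int
    n_structures: int = 300
    n_labels: int = 40
    fragments_per_label: int = 3
    peak_mass_range: tuple[float, float] = (50.0, 500.0)
    label_prevalence: tuple[float, float] = (0.2, 0.6)
    replicate_mean: float = 5.0
    replicate_max: int = 100
    n_background_peaks: int = 5
    noise: NoiseParams = field(
        default_factory=lambda: NoiseParams(
            drop_fraction=0.1, intensity_jitter_sd=0.2, n_noise_peaks=3
        )
    )
    eval_fraction: float = 0.2
    n_decoys: int = 9
    decoy_hamming: int = 5

    def __post_init__(self) -> None:
        if self.n_structures < 2 or self.n_labels < 1:
            raise ValueError("need at least 2 structures and 1 label")
        lo, hi = self.label_prevalence
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("label_prevalence must be an ordered range in [0, 1]")
        if self.peak_mass_range[0] <= 0 or (
            self.peak_mass_range[1] <= self.peak_mass_range[0]
        ):
            raise ValueError("peak_mass_range must be an increasing positive range")
        if self.replicate_mean < 1:
            raise ValueError("replicate_mean must be >= 1")


@dataclass
class Benchmark:
    """Structure-disjoint train/eval bundle produced by the generator."""

    train_records: list[CompoundRecord]
    additional_records: list[CompoundRecord]
    eval_records: list[CompoundRecord]
    fingerprints: FingerprintMatrix
    candidate_sets: list[CandidateSet]
    label_fragments: np.ndarray
    eval_single_records: list[CompoundRecord] = field(default_factory=list)

    @property
    def train_single_records(self) -> list[CompoundRecord]:
        """One clean (replicate-0) spectrum per training structure, weight 1."""
        return [
            CompoundRecord(
                spectrum=r.spectrum,
                structure_key=r.structure_key,
                dataset_tag="main",
            )
            for r in self.additional_records
            if r.spectrum.compound_id.endswith("_r0")
        ]

    @property
    def train_structures(self) -> list[str]:
        return [r.structure_key for r in self.train_records]

    @property
    def eval_structures(self) -> list[str]:
        return [r.structure_key for r in self.eval_records]


def _structure_keys(n: int) -> list[str]:
    return [f"STRUCT{i:05d}" for i in range(n)]


def calibrated_fixture_config(seed: int = 7) -> FixtureConfig:
    """The benchmark configuration the end-to-end thresholds are calibrated on.

    300 structures, 40 labels with prevalences down to 5%, two characteristic
    fragments per label, ten background peaks and moderate replicate noise —
    hard enough that the heads separate, easy enough to run in minutes.
    """
    return FixtureConfig(
        seed=seed,
        n_structures=300,
        n_labels=40,
        fragments_per_label=2,
        label_prevalence=(0.05, 0.5),
        n_background_peaks=10,
        noise=NoiseParams(
            drop_fraction=0.3, intensity_jitter_sd=0.5, n_noise_peaks=8
        ),
    )


def generate_fingerprints(cfg: FixtureConfig) -> FingerprintMatrix:
    """Random binary matrix with per-label prevalence from the configured range."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.label_prevalence
    prevalence = rng.uniform(lo, hi, size=cfg.n_labels)
    values = (rng.random((cfg.n_structures, cfg.n_labels)) < prevalence).astype(
        np.uint8
    )
    return FingerprintMatrix(
        _structure_keys(cfg.n_structures),
        [f"L{j:04d}" for j in range(cfg.n_labels)],
        values,
    )


def label_fragment_masses(cfg: FixtureConfig) -> np.ndarray:
    """Characteristic fragment masses, drawn once per fixture
    (``n_labels x fragments_per_label``)."""
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.peak_mass_range
    return rng.uniform(lo, hi, size=(cfg.n_labels, cfg.fragments_per_label))


def generate_spectra(
    fp: FingerprintMatrix, cfg: FixtureConfig
) -> list[Spectrum]:
    """Replicated noisy spectra for every structure in the fingerprint matrix.

    Replicate 0 of each structure is the clean base spectrum; further
    replicates are noise-perturbed copies. Replicate counts follow a
    geometric distribution with the configured mean, truncated at
    ``replicate_max``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    fragments = label_fragment_masses(cfg)
    lo, hi = cfg.peak_mass_range
    # Noise masses are drawn from peaks of other (synthetic) spectra.
    pool = fragments.ravel().tolist()

    spectra: list[Spectrum] = []
    for i, skey in enumerate(fp.structures):
        positive = np.flatnonzero(fp.values[i])
        peaks: list[tuple[float, float]] = []
        for j in positive:
            for m in fragments[j]:
                peaks.append((float(m), float(rng.uniform(0.4, 1.0))))
        n_bg = cfg.n_background_peaks
        for _ in range(n_bg):
            peaks.append(
                (float(rng.uniform(lo, hi)), float(rng.uniform(0.05, 0.3)))
            )
        if not peaks:  # structure with no positive label at all
            peaks.append((float(rng.uniform(lo, hi)), 1.0))
        precursor = hi + float(rng.uniform(10.0, 50.0))
        formula = (
            f"C{int(rng.integers(5, 40))}H{int(rng.integers(6, 60))}"
            f"N{int(rng.integers(0, 6))}O{int(rng.integers(0, 12))}"
        )
        base = Spectrum(
            peaks=tuple(peaks),
            precursor_mz=precursor,
            collision_energy="10",
            instrument="synth-qtof",
            structure_key=skey,
            compound_id=f"{skey}_r0",
            formula=formula,
        )
        spectra.append(base)
        n_rep = int(min(rng.geometric(1.0 / cfg.replicate_mean), cfg.replicate_max))
        for r in range(1, n_rep):
            noisy = simulate_noise(
                base,
                peak_pool=pool,
                params=cfg.noise,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            spectra.append(
                Spectrum(
                    peaks=noisy.peaks,
                    precursor_mz=base.precursor_mz,
                    collision_energy=str(10 * (r + 1)),
                    instrument="synth-qtof",
                    structure_key=skey,
                    compound_id=f"{skey}_r{r}",
                    formula=formula,
                )
            )
    return spectra


def make_decoys(
    truth: np.ndarray, n_decoys: int, hamming: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Decoy fingerprints at exact Hamming distance ``hamming`` from truth."""
    n_labels = len(truth)
    if hamming > n_labels:
        raise ValueError("Hamming distance exceeds label count")
    decoys = []
    for _ in range(n_decoys):
        flip = rng.choice(n_labels, size=hamming, replace=False)
        d = truth.copy()
        d[flip] = 1 - d[flip]
        decoys.append(d)
    return decoys


def generate_benchmark(cfg: FixtureConfig) -> Benchmark:
    """Structure-disjoint train/eval split with candidate sets per query.

    * ``train_records``: one merged clean compound per training structure
      (the landmark / 'main' set).
    * ``additional_records``: all unmerged replicate spectra of the training
      structures, weighted by the reciprocal square root of their counts.
    * ``eval_records``: one merged compound per held-out structure.
    * ``candidate_sets``: the true fingerprint plus ``n_decoys`` bit-flip
      decoys per evaluation structure.
    """
    fp = generate_fingerprints(cfg)
    spectra = generate_spectra(fp, cfg)
    rng = np.random.default_rng(cfg.seed + 3)
    structures = list(fp.structures)
    order = rng.permutation(len(structures))
    n_eval = max(1, int(round(cfg.eval_fraction * len(structures))))
    eval_keys = {structures[i] for i in order[:n_eval]}

    train_spectra = [s for s in spectra if s.structure_key not in eval_keys]
    eval_spectra = [s for s in spectra if s.structure_key in eval_keys]

    train_records = merge_spectra(train_spectra, dataset_tag="main")
    eval_records = merge_spectra(eval_spectra, dataset_tag="eval")

    counts: dict[str, int] = {}
    for s in train_spectra:
        counts[s.structure_key] = counts.get(s.structure_key, 0) + 1
    weights = compute_sample_weights(counts)
    additional_records = [
        CompoundRecord(
            spectrum=s,
            structure_key=s.structure_key,
            dataset_tag="additional",
            sample_weight=weights[s.structure_key],
        )
        for s in train_spectra
    ]

    candidate_sets = []
    for rec in eval_records:
        skey = rec.structure_key
        truth = fp.row(skey).astype(np.uint8)
        candidates = [(skey, truth)]
        for d, decoy in enumerate(
            make_decoys(truth, cfg.n_decoys, cfg.decoy_hamming, rng)
        ):
            candidates.append((f"{skey}_decoy{d}", decoy))
        candidate_sets.append(
            CandidateSet(
                query_id=rec.compound_id,
                molecular_formula=rec.spectrum.formula or "",
                candidates=candidates,
                correct_key=skey,
            )
        )
    eval_single_records = [
        CompoundRecord(spectrum=s, structure_key=s.structure_key, dataset_tag="eval")
        for s in eval_spectra
        if s.compound_id.endswith("_r0")
    ]
    return Benchmark(
        train_records=train_records,
        additional_records=additional_records,
        eval_records=eval_records,
        fingerprints=fp,
        candidate_sets=candidate_sets,
        label_fragments=label_fragment_masses(cfg),
        eval_single_records=eval_single_records,
    )
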