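"""Core data model: peaks, spectra, compound records and fingerprint matrices."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np

#: Slack allowed between the largest fragment m/z and the precursor m/z (Da).
PRECURSOR_TOLERANCE_DA = 0.5


class Peak(NamedTuple):
    """A single fragment peak: m/z in Da and relative abundance."""

    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """One MS/MS record (single energy, ramp, or a merge of several spectra).

    Peaks are kept sorted by ascending m/z; construction normalizes order and
    validates basic physical constraints (positive masses, non-negative
    intensities, fragments not exceeding the precursor mass beyond a small
    tolerance).

    Parameters
    ----------
    peaks:
        Fragment peaks. Any iterable of ``(mz, intensity)`` pairs.
    precursor_mz:
        Precursor ion m/z in Da, or ``None`` if unknown.
    adduct:
        Positive-mode adduct string, e.g. ``"[M+H]+"``.
    collision_energy:
        Single value, comma-separated list, or ``"ramp"``.
    instrument:
        Free-text instrument descriptor.
    structure_key:
        2D structure identifier (first block of a hashed structure key);
        stereoisomers share this key.
    compound_id:
        Unique record identifier.
    formula:
        Optional molecular formula string, e.g. ``"C6H12O6"``.
    """

    peaks: tuple[Peak, ...]
    precursor_mz: float | None = None
    adduct: str = "[M+H]+"
    collision_energy: str = ""
    instrument: str = ""
    structure_key: str = ""
    compound_id: str = ""
    formula: str | None = None

    def __post_init__(self) -> None:
        peaks = tuple(Peak(float(m), float(i)) for m, i in self.peaks)
        if any(p.mz <= 0 for p in peaks):
            raise ValueError("all peak m/z values must be positive")
        if any(p.intensity < 0 for p in peaks):
            raise ValueError("peak intensities must be non-negative")
        peaks = tuple(sorted(peaks, key=lambda p: p.mz))
        if self.precursor_mz is not None and peaks:
            limit = float(self.precursor_mz) + PRECURSOR_TOLERANCE_DA
            if peaks[-1].mz > limit:
                raise ValueError(
                    f"peak at m/z {peaks[-1].mz:.4f} exceeds precursor "
                    f"{self.precursor_mz:.4f} + {PRECURSOR_TOLERANCE_DA} Da"
                )
        object.__setattr__(self, "peaks", peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        """Peak m/z values as a float array (ascending)."""
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        """Peak intensities as a float array, aligned with :attr:`mz`."""
        return np.array([p.intensity for p in self.peaks], dtype=float)

    @property
    def base_peak_index(self) -> int:
        """Index of the most intense peak."""
        if not self.peaks:
            raise ValueError("empty spectrum has no base peak")
        return int(np.argmax(self.intensities))

    def with_peaks(self, peaks: Sequence[tuple[float, float]]) -> "Spectrum":
        """Copy of this spectrum with a replaced peak list."""
        return replace(self, peaks=tuple(Peak(m, i) for m, i in peaks))

    def normalized(self, mode: str = "sum") -> "Spectrum":
        """Copy with intensities scaled to sum 1 (``"sum"``) or max 1 (``"max"``)."""
        if not self.peaks:
            return self
        inten = self.intensities
        denom = inten.sum() if mode == "sum" else inten.max()
        if denom <= 0:
            raise ValueError("cannot normalize a spectrum with zero total intensity")
        return self.with_peaks(list(zip(self.mz, inten / denom)))


@dataclass
class CompoundRecord:
    """A machine-learning input unit: one (possibly merged) spectrum per compound."""

    spectrum: Spectrum
    molecular_formula: Mapping[str, int] = field(default_factory=dict)
    structure_key: str = ""
    dataset_tag: str = "main"
    sample_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sample_weight <= 0:
            raise ValueError("sample_weight must be positive")
        if any(
            (int(v) != v or v < 0) for v in self.molecular_formula.values()
        ):
            raise ValueError("molecular formula counts must be non-negative integers")
        if not self.structure_key:
            self.structure_key = self.spectrum.structure_key
        if self.dataset_tag not in ("main", "additional", "eval"):
            raise ValueError(f"unknown dataset_tag {self.dataset_tag!r}")

    @property
    def compound_id(self) -> str:
        return self.spectrum.compound_id


class FingerprintMatrix:
    """Binary label matrix over structures with per-label bookkeeping.

    Rows are structures (unique ``structure_key``), columns are binary
    substructure labels. ``positive_counts`` gives, per label, the number of
    structures with value 1.
    """

    def __init__(
        self,
        structures: Sequence[str],
        labels: Sequence[str],
        values: np.ndarray,
        label_sources: Mapping[str, str] | None = None,
    ) -> None:
        structures = list(structures)
        labels = list(labels)
        values = np.asarray(values)
        if values.shape != (len(structures), len(labels)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(structures)}, {len(labels)})"
            )
        if not np.isin(values, (0, 1)).all():
            raise ValueError("fingerprint values must be 0 or 1")
        if len(set(structures)) != len(structures):
            raise ValueError("duplicate structure_keys in fingerprint matrix")
        self.structures = structures
        self.labels = labels
        self.values = values.astype(np.uint8)
        self.label_sources = dict(label_sources or {})
        self._row_index = {s: i for i, s in enumerate(structures)}

    @property
    def positive_counts(self) -> np.ndarray:
        """Number of positive structures per label."""
        return self.values.sum(axis=0).astype(int)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, structure_key: str) -> np.ndarray:
        """Fingerprint vector of one structure."""
        try:
            return self.values[self._row_index[structure_key]]
        except KeyError:
            raise KeyError(f"structure {structure_key!r} not in fingerprint matrix")

    def rows(self, structure_keys: Sequence[str]) -> np.ndarray:
        """Stacked fingerprint vectors for an ordered list of structures."""
        return np.stack([self.row(k) for k in structure_keys])

    def subset_structures(self, structure_keys: Sequence[str]) -> "FingerprintMatrix":
        """Restrict to the given structures, preserving the given order."""
        idx = [self._row_index[k] for k in structure_keys]
        return FingerprintMatrix(
            [self.structures[i] for i in idx],
            self.labels,
            self.values[idx],
            self.label_sources,
        )

    def subset_labels(self, label_ids: Sequence[str]) -> "FingerprintMatrix":
        """Restrict to the given labels, preserving the given order."""
        col_index = {l: j for j, l in enumerate(self.labels)}
        idx = [col_index[l] for l in label_ids]
        return FingerprintMatrix(
            self.structures,
            [self.labels[j] for j in idx],
            self.values[:, idx],
            {l: s for l, s in self.label_sources.items() if l in set(label_ids)},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FingerprintMatrix):
            return NotImplemented
        return (
            self.structures == other.structures
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"FingerprintMatrix({len(self.structures)} structures x "
            f"{len(self.labels)} labels)"
        )


def structure_key_from_inchikey(inchikey: str) -> str:
    """First (2D-skeleton) block of a hashed structure key.

    Stereoisomers differ only in later blocks, so truncating to the first
    block makes them share an identity.
    """
    return inchikey.strip().split("-")[0]
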