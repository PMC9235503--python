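"""Spectrum merging, replicate weighting, noise removal and label selection."""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from fpkit.spectra_data.model import CompoundRecord, FingerprintMatrix, Spectrum

logger = logging.getLogger(__name__)

#: Mass tolerance for merging peaks across replicate spectra.
DEFAULT_MERGE_PPM = 10.0
#: Tolerance for precursor m/z agreement within a merge group (Da).
PRECURSOR_AGREEMENT_DA = 0.1

_GROUP_FIELDS = ("structure", "instrument", "adduct")


def merge_peaks(
    peaks: Sequence[tuple[float, float]], ppm: float = DEFAULT_MERGE_PPM
) -> list[tuple[float, float]]:
    """Agglomerate peaks within ``ppm`` mass tolerance.

    Peaks are scanned in ascending m/z; a peak joins the current cluster when
    it lies within ``ppm`` of the cluster's intensity-weighted mean m/z.
    The merged peak has the intensity-weighted mean m/z and the maximum
    intensity of its members.
    """
    if not peaks:
        return []
    ordered = sorted((float(m), float(i)) for m, i in peaks)
    merged: list[tuple[float, float]] = []
    cluster_mz = [ordered[0][0]]
    cluster_int = [ordered[0][1]]

    def flush() -> None:
        weights = np.asarray(cluster_int)
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
        mean_mz = float(np.average(cluster_mz, weights=weights))
        merged.append((mean_mz, float(max(cluster_int))))

    for mz, inten in ordered[1:]:
        weights = np.asarray(cluster_int)
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
        mean_mz = float(np.average(cluster_mz, weights=weights))
        # 1e-9 Da slack so boundary cases are not split by float representation
        if abs(mz - mean_mz) <= mean_mz * ppm * 1e-6 + 1e-9:
            cluster_mz.append(mz)
            cluster_int.append(inten)
        else:
            flush()
            cluster_mz, cluster_int = [mz], [inten]
    flush()
    return merged


def merge_spectra(
    spectra: Iterable[Spectrum],
    group_by: Sequence[str] = _GROUP_FIELDS,
    ppm: float = DEFAULT_MERGE_PPM,
    dataset_tag: str = "main",
) -> list[CompoundRecord]:
    """Merge spectra of the same structure measured under the same conditions.

    One :class:`CompoundRecord` is produced per distinct combination of the
    ``group_by`` fields (default: structure, instrument and adduct). Peaks of
    all group members are pooled and agglomerated within ``ppm``.

    Raises
    ------
    ValueError
        If a group's precursor masses disagree beyond tolerance, or a
        spectrum is missing a grouping field.
    """
    for f in group_by:
        if f not in _GROUP_FIELDS:
            raise ValueError(f"unknown group_by field {f!r}")
    groups: dict[tuple, list[Spectrum]] = defaultdict(list)
    for s in spectra:
        if not s.structure_key:
            raise ValueError(f"spectrum {s.compound_id!r} has no structure_key")
        key = tuple(
            {
                "structure": s.structure_key,
                "instrument": s.instrument,
                "adduct": s.adduct,
            }[f]
            for f in group_by
        )
        groups[key].append(s)

    records: list[CompoundRecord] = []
    for key, members in groups.items():
        precursors = [s.precursor_mz for s in members if s.precursor_mz is not None]
        if precursors and max(precursors) - min(precursors) > PRECURSOR_AGREEMENT_DA:
            raise ValueError(
                f"conflicting precursor masses in group {key}: "
                f"{min(precursors):.4f} .. {max(precursors):.4f}"
            )
        first = members[0]
        if len(members) == 1:
            merged_spectrum = first
        else:
            pooled = [(p.mz, p.intensity) for s in members for p in s.peaks]
            energies = sorted(
                {s.collision_energy for s in members if s.collision_energy}
            )
            merged_spectrum = Spectrum(
                peaks=tuple(merge_peaks(pooled, ppm=ppm)),
                precursor_mz=max(precursors) if precursors else None,
                adduct=first.adduct,
                collision_energy=",".join(energies),
                instrument=first.instrument,
                structure_key=first.structure_key,
                compound_id=first.compound_id + "|merged",
                formula=first.formula,
            )
        records.append(
            CompoundRecord(
                spectrum=merged_spectrum,
                structure_key=first.structure_key,
                dataset_tag=dataset_tag,
            )
        )
    return records


def compute_sample_weights(
    replicate_counts: Mapping[str, int]
) -> dict[str, float]:
    """Per-structure training weight: reciprocal square root of the replicate count.

    Downweights structures with many recorded spectra while still letting
    repeated measurements contribute.
    """
    weights: dict[str, float] = {}
    for key, count in replicate_counts.items():
        if count < 1:
            raise ValueError(f"replicate count for {key!r} must be >= 1, got {count}")
        weights[key] = 1.0 / float(np.sqrt(count))
    return weights


def select_labels(
    fp: FingerprintMatrix, min_structures: int = 20
) -> FingerprintMatrix:
    """Keep labels positive in at least ``min_structures`` training structures.

    Counts must be computed on training structures only; pass a training
    subset of the matrix if needed. Label order is preserved.
    """
    if min_structures < 1:
        raise ValueError("min_structures must be >= 1")
    counts = fp.positive_counts
    retained = [l for l, c in zip(fp.labels, counts) if c >= min_structures]
    if not retained:
        raise ValueError(
            f"no label has >= {min_structures} positive structures"
        )
    return fp.subset_labels(retained)


def remove_noise_peaks(
    s: Spectrum,
    min_relative_intensity: float = 1e-3,
    max_peaks: int = 500,
) -> Spectrum:
    """Drop peaks below a relative-intensity floor and cap the peak count.

    Intensities are judged relative to the base peak; at most ``max_peaks``
    most-intense peaks are kept.
    """
    if not s.peaks:
        return s
    inten = s.intensities
    rel = inten / inten.max()
    keep = np.flatnonzero(rel >= min_relative_intensity)
    if len(keep) > max_peaks:
        order = np.argsort(inten[keep])[::-1][:max_peaks]
        keep = keep[np.sort(order)]
    mz = s.mz
    return s.with_peaks([(mz[i], inten[i]) for i in keep])
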