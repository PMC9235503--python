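"""Readers and writers for MGF / MSP spectrum files and fingerprint TSVs."""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

from fpkit.spectra_data.model import (
    FingerprintMatrix,
    Spectrum,
    structure_key_from_inchikey,
)

logger = logging.getLogger(__name__)


class SpectrumParseError(ValueError):
    """Raised for malformed records; carries the offending line number."""

    def __init__(self, message: str, line_number: int) -> None:
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_spectra(path: str | Path, format: str | None = None) -> list[Spectrum]:
    """Read spectra from an MGF or MSP file.

    Parameters
    ----------
    path:
        Input file. ``.gz`` suffixes are handled transparently.
    format:
        ``"mgf"`` or ``"msp"``; inferred from the filename when omitted.

    Returns
    -------
    One :class:`Spectrum` per record, peaks sorted by ascending m/z.
    Records without a precursor m/z are skipped with a logged warning.

    Raises
    ------
    SpectrumParseError
        On malformed records, naming the line number.
    """
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        format = Path(stem).suffix.lstrip(".").lower()
    if format == "mgf":
        return list(_read_mgf(path))
    if format == "msp":
        return list(_read_msp(path))
    raise ValueError(f"unsupported spectrum format {format!r}")


# MGF metadata keys we map onto Spectrum fields (upper-cased for lookup).
_MGF_FIELDS = {
    "TITLE": "compound_id",
    "ADDUCT": "adduct",
    "ION": "adduct",
    "COLLISIONENERGY": "collision_energy",
    "COLLISION_ENERGY": "collision_energy",
    "INSTRUMENT": "instrument",
    "SOURCE_INSTRUMENT": "instrument",
    "STRUCTUREKEY": "structure_key",
    "INCHIKEY": "inchikey",
    "FORMULA": "formula",
}


def _read_mgf(path: Path) -> Iterator[Spectrum]:
    with _open_text(path) as fh:
        in_block = False
        meta: dict[str, str] = {}
        peaks: list[tuple[float, float]] = []
        block_start = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise SpectrumParseError("nested BEGIN IONS", lineno)
                in_block, meta, peaks, block_start = True, {}, [], lineno
                continue
            if line == "END IONS":
                if not in_block:
                    raise SpectrumParseError("END IONS without BEGIN IONS", lineno)
                spectrum = _build_spectrum(meta, peaks, block_start)
                if spectrum is not None:
                    yield spectrum
                in_block = False
                continue
            if not in_block:
                raise SpectrumParseError(f"unexpected content {line!r}", lineno)
            if "=" in line:
                key, _, value = line.partition("=")
                meta[key.strip().upper()] = value.strip()
            else:
                peaks.append(_parse_peak_line(line, lineno))
        if in_block:
            raise SpectrumParseError("unterminated BEGIN IONS block", block_start)


def _read_msp(path: Path) -> Iterator[Spectrum]:
    """NIST-style MSP: `Key: value` headers, `Num Peaks:`, then peak lines."""
    with _open_text(path) as fh:
        meta: dict[str, str] = {}
        peaks: list[tuple[float, float]] = []
        n_expected: int | None = None
        block_start = 0

        def flush() -> Spectrum | None:
            if not meta and not peaks:
                return None
            if n_expected is not None and len(peaks) != n_expected:
                raise SpectrumParseError(
                    f"expected {n_expected} peaks, found {len(peaks)}", block_start
                )
            mgf_meta = {
                "TITLE": meta.get("NAME", ""),
                "PEPMASS": meta.get("PRECURSORMZ", meta.get("PRECURSOR_MZ", "")),
                "ADDUCT": meta.get("PRECURSOR_TYPE", meta.get("PRECURSORTYPE", "")),
                "COLLISIONENERGY": meta.get("COLLISION_ENERGY", ""),
                "INSTRUMENT": meta.get("INSTRUMENT", meta.get("INSTRUMENT_TYPE", "")),
                "INCHIKEY": meta.get("INCHIKEY", ""),
                "STRUCTUREKEY": meta.get("STRUCTUREKEY", ""),
                "FORMULA": meta.get("FORMULA", ""),
            }
            return _build_spectrum(mgf_meta, peaks, block_start)

        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                spectrum = flush()
                if spectrum is not None:
                    yield spectrum
                meta, peaks, n_expected = {}, [], None
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key = key.strip().upper().replace(" ", "_")
                value = value.strip()
                if not meta and not peaks:
                    block_start = lineno
                if key == "NUM_PEAKS":
                    try:
                        n_expected = int(value)
                    except ValueError:
                        raise SpectrumParseError(
                            f"bad Num Peaks value {value!r}", lineno
                        ) from None
                else:
                    meta[key] = value
            else:
                peaks.append(_parse_peak_line(line, lineno))
        spectrum = flush()
        if spectrum is not None:
            yield spectrum


def _parse_peak_line(line: str, lineno: int) -> tuple[float, float]:
    parts = line.replace(";", " ").split()
    if len(parts) < 2:
        raise SpectrumParseError(f"malformed peak line {line!r}", lineno)
    try:
        return float(parts[0]), float(parts[1])
    except ValueError:
        raise SpectrumParseError(f"malformed peak line {line!r}", lineno) from None


def _build_spectrum(
    meta: dict[str, str], peaks: list[tuple[float, float]], lineno: int
) -> Spectrum | None:
    pepmass = meta.get("PEPMASS", "")
    if not pepmass:
        logger.warning(
            "record near line %d has no precursor m/z; skipped", lineno
        )
        return None
    try:
        precursor_mz = float(pepmass.split()[0])
    except ValueError:
        raise SpectrumParseError(f"bad precursor m/z {pepmass!r}", lineno) from None
    fields: dict[str, str] = {}
    for key, attr in _MGF_FIELDS.items():
        if meta.get(key):
            fields.setdefault(attr, meta[key])
    inchikey = fields.pop("inchikey", "")
    structure_key = fields.get("structure_key") or (
        structure_key_from_inchikey(inchikey) if inchikey else ""
    )
    fields["structure_key"] = structure_key
    fields.setdefault("adduct", "[M+H]+")
    return Spectrum(
        peaks=tuple(peaks),
        precursor_mz=precursor_mz,
        **{k: v for k, v in fields.items() if v},
    )


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as an MGF file (one BEGIN/END IONS block per spectrum)."""
    with _open_text(path, "wt") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            if s.compound_id:
                fh.write(f"TITLE={s.compound_id}\n")
            if s.precursor_mz is not None:
                fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write("CHARGE=1+\n")
            if s.adduct:
                fh.write(f"ADDUCT={s.adduct}\n")
            if s.collision_energy:
                fh.write(f"COLLISIONENERGY={s.collision_energy}\n")
            if s.instrument:
                fh.write(f"INSTRUMENT={s.instrument}\n")
            if s.structure_key:
                fh.write(f"STRUCTUREKEY={s.structure_key}\n")
            if s.formula:
                fh.write(f"FORMULA={s.formula}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.6g}\n")
            fh.write("END IONS\n\n")


def write_fingerprints(fp: FingerprintMatrix, path: str | Path) -> None:
    """Write a fingerprint matrix as (optionally gzipped) TSV.

    Layout: header row ``structure_key<TAB>label...``, one 0/1 row per
    structure.
    """
    with _open_text(path, "wt") as fh:
        fh.write("structure_key\t" + "\t".join(fp.labels) + "\n")
        for key, row in zip(fp.structures, fp.values):
            fh.write(key + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_fingerprints(path: str | Path) -> FingerprintMatrix:
    """Read a fingerprint matrix written by :func:`write_fingerprints`."""
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "structure_key":
            raise ValueError("fingerprint TSV must start with a structure_key column")
        labels = header[1:]
        structures: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(labels) + 1:
                raise ValueError(
                    f"row for {parts[0]!r} has {len(parts) - 1} cells, "
                    f"expected {len(labels)}"
                )
            structures.append(parts[0])
            rows.append([int(v) for v in parts[1:]])
    values = np.array(rows, dtype=np.uint8) if rows else np.zeros((0, len(labels)))
    return FingerprintMatrix(structures, labels, values)


def write_candidates(
    path: str | Path,
    candidates: Sequence[tuple[str, np.ndarray]],
    formula: str = "",
) -> None:
    """Write a candidate list as TSV: structure_key, formula, bitstring."""
    with _open_text(path, "wt") as fh:
        fh.write("structure_key\tformula\tfingerprint\n")
        for key, bits in candidates:
            bitstring = "".join(str(int(b)) for b in np.asarray(bits).ravel())
            fh.write(f"{key}\t{formula}\t{bitstring}\n")


def read_candidates(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read a candidate TSV written by :func:`write_candidates`."""
    out: list[tuple[str, np.ndarray]] = []
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.startswith("structure_key"):
            raise ValueError("candidate TSV must have a structure_key header")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, _formula, bitstring = line.split("\t")
            out.append((key, np.array([int(c) for c in bitstring], dtype=np.uint8)))
    return out
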