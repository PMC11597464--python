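"""Minimal Mascot Generic Format (MGF) reader/writer and a plain
two-column peak-list reader.

Only the keys the pipeline uses are handled: TITLE, PEPMASS, RTINSECONDS.
Retention times are minutes in memory and seconds on disk, following the
MGF convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .fingerprint import MsmsSpectrum

__all__ = ["read_mgf", "write_mgf", "read_peaklist"]


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Read all spectra from an MGF file."""
    with open(path, encoding="utf-8") as handle:
        return list(_parse_mgf(handle, str(path)))


def _parse_mgf(handle: TextIO, source: str) -> Iterator[MsmsSpectrum]:
    in_block = False
    title = ""
    precursor = None
    rt_minutes = 0.0
    peaks: list[tuple[float, float]] = []
    for lineno, raw in enumerate(handle, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            in_block, title, precursor, rt_minutes, peaks = True, "", None, 0.0, []
        elif line == "END IONS":
            if not in_block:
                raise ValueError(f"{source}:{lineno}: END IONS outside a block")
            if precursor is None:
                raise ValueError(f"{source}:{lineno}: spectrum without PEPMASS")
            yield MsmsSpectrum(
                precursor_mz=precursor, rt=rt_minutes, peaks=tuple(peaks), title=title
            )
            in_block = False
        elif not in_block:
            continue
        elif "=" in line:
            key, _, value = line.partition("=")
            key = key.upper()
            if key == "TITLE":
                title = value.strip()
            elif key == "PEPMASS":
                precursor = float(value.split()[0])
            elif key == "RTINSECONDS":
                rt_minutes = float(value) / 60.0
        else:
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{source}:{lineno}: malformed peak line {line!r}")
            peaks.append((float(fields[0]), float(fields[1])))
    if in_block:
        raise ValueError(f"{source}: truncated file, missing END IONS")


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    """Write spectra as MGF; deterministic output for identical input."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for spectrum in spectra:
            handle.write("BEGIN IONS\n")
            if spectrum.title:
                handle.write(f"TITLE={spectrum.title}\n")
            handle.write(f"PEPMASS={spectrum.precursor_mz:.4f}\n")
            handle.write(f"RTINSECONDS={spectrum.rt * 60.0:.3f}\n")
            for mz, intensity in spectrum.peaks:
                handle.write(f"{mz:.4f} {intensity:.1f}\n")
            handle.write("END IONS\n")


def read_peaklist(path: str | Path) -> MsmsSpectrum:
    """Read a single spectrum from a delimited peak list.

    The first non-comment line carries the precursor m/z and retention time
    (minutes); subsequent lines are ``m/z intensity`` pairs.  Whitespace or
    tab delimited.
    """
    header = None
    peaks: list[tuple[float, float]] = []
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace("\t", " ").split()
            if header is None:
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}: header must be '<precursor_mz> <rt_min>', got {line!r}"
                    )
                header = (float(fields[0]), float(fields[1]))
            else:
                peaks.append((float(fields[0]), float(fields[1])))
    if header is None:
        raise ValueError(f"{path}: empty peak list")
    return MsmsSpectrum(
        precursor_mz=header[0], rt=header[1], peaks=tuple(peaks), title=str(path)
    )
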