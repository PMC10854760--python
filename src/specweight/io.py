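"""Reading and writing MGF and NIST-style MSP spectral libraries.

These parsers are deliberately strict: a malformed record raises a
:class:`RecordError` carrying the line number where the record starts,
and in lenient mode bad records are skipped and reported instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .spectra import Spectrum, SpectrumLibrary

__all__ = ["read_mgf", "read_msp", "write_mgf", "write_msp", "RecordError"]


class RecordError(ValueError):
    """A malformed library record, annotated with its starting line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class _Skipped:
    line: int
    reason: str


def _finish(precursor, mzs, intens, identifier, inchikey, metadata):
    return Spectrum(
        precursor_mz=precursor,
        mz=mzs,
        intensities=intens,
        identifier=identifier,
        inchikey=inchikey,
        metadata=metadata,
    )


def read_mgf(path, lenient: bool = False) -> SpectrumLibrary:
    """Parse a Mascot Generic Format file into a :class:`SpectrumLibrary`.

    Records are delimited by ``BEGIN IONS``/``END IONS``; ``PEPMASS`` is
    required (first token taken as the precursor m/z).  ``TITLE`` (or a
    generated ordinal) becomes the identifier; ``INCHIKEY``/``INCHIAUX``
    are captured when present.  With ``lenient=True`` malformed records
    are skipped and listed in ``library.skipped``.
    """
    spectra, skipped = [], []
    in_record = False
    start_line = 0
    ordinal = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper() == "BEGIN IONS":
                if in_record:
                    raise RecordError("nested BEGIN IONS", lineno)
                in_record = True
                start_line = lineno
                precursor, title, inchikey = None, None, None
                mzs, intens, meta = [], [], {}
                continue
            if line.upper() == "END IONS":
                if not in_record:
                    raise RecordError("END IONS without BEGIN IONS", lineno)
                in_record = False
                ordinal += 1
                err = None
                if precursor is None:
                    err = "record missing PEPMASS"
                try:
                    if err is None:
                        spectra.append(_finish(
                            precursor, mzs, intens,
                            title if title is not None else f"spectrum_{ordinal}",
                            inchikey, meta))
                except ValueError as exc:
                    err = str(exc)
                if err is not None:
                    if lenient:
                        skipped.append(_Skipped(start_line, err))
                    else:
                        raise RecordError(err, start_line)
                continue
            if not in_record:
                continue
            if "=" in line:
                key, _, value = line.partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "PEPMASS":
                    try:
                        precursor = float(value.split()[0])
                    except (ValueError, IndexError):
                        raise RecordError(f"unparseable PEPMASS {value!r}", lineno)
                elif key == "TITLE":
                    title = value
                elif key in ("INCHIKEY", "INCHIAUX"):
                    inchikey = value
                    meta[key.lower()] = value
                else:
                    meta[key.lower()] = value
                continue
            parts = line.split()
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                raise RecordError(f"unparseable peak line {line!r}", lineno)
            mzs.append(mz)
            intens.append(inten)
    if in_record:
        raise RecordError("unterminated record (missing END IONS)", start_line)
    library = SpectrumLibrary(spectra, source=str(path))
    library.skipped = skipped
    return library


def read_msp(path, lenient: bool = False) -> SpectrumLibrary:
    """Parse a NIST-style MSP text library.

    Each record opens with ``Name:`` and carries ``PrecursorMZ:`` and
    ``Num Peaks:`` headers; the declared peak count must match the
    number of peak lines that follow (``mz<TAB>intensity`` or
    whitespace-separated).
    """
    spectra, skipped = [], []
    record = None   # (start_line, headers dict, peaks list, declared count)
    ordinal = 0

    def close(record):
        nonlocal ordinal
        start, headers, mzs, intens, declared = record
        ordinal += 1
        if "precursormz" not in headers:
            raise RecordError("record missing PrecursorMZ", start)
        if declared is None:
            raise RecordError("record missing Num Peaks", start)
        if declared != len(mzs):
            raise RecordError(
                f"Num Peaks: {declared} but {len(mzs)} peak lines parsed", start)
        try:
            precursor = float(headers["precursormz"])
        except ValueError:
            raise RecordError(
                f"unparseable PrecursorMZ {headers['precursormz']!r}", start)
        return _finish(
            precursor, mzs, intens,
            headers.get("name", f"spectrum_{ordinal}"),
            headers.get("inchikey"),
            dict(headers),
        )

    def close_or_skip(record):
        try:
            spectra.append(close(record))
        except RecordError as exc:
            if lenient:
                skipped.append(_Skipped(exc.line, str(exc)))
            else:
                raise

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                if record is not None:
                    close_or_skip(record)
                    record = None
                continue
            if line.lower().startswith("name:"):
                if record is not None:
                    close_or_skip(record)
                record = (lineno, {"name": line[5:].strip()}, [], [], None)
                continue
            if record is None:
                raise RecordError("content before first Name: header", lineno)
            start, headers, mzs, intens, declared = record
            if line.lower().startswith("num peaks:"):
                try:
                    declared = int(line.split(":", 1)[1])
                except ValueError:
                    raise RecordError(f"unparseable Num Peaks {line!r}", lineno)
                record = (start, headers, mzs, intens, declared)
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                headers[key.strip().lower()] = value.strip()
                continue
            tokens = line.replace(";", " ").replace("\t", " ").split()
            if len(tokens) % 2 != 0:
                raise RecordError(f"unparseable peak line {line!r}", lineno)
            try:
                for t_mz, t_int in zip(tokens[::2], tokens[1::2]):
                    mzs.append(float(t_mz))
                    intens.append(float(t_int))
            except ValueError:
                raise RecordError(f"unparseable peak line {line!r}", lineno)
    if record is not None:
        close_or_skip(record)
    library = SpectrumLibrary(spectra, source=str(path))
    library.skipped = skipped
    return library


def write_mgf(library: SpectrumLibrary, path) -> None:
    """Write a library as MGF; precursor and peaks at 6 decimal places."""
    if len(library) == 0:
        raise ValueError("refusing to write an empty library")
    with open(path, "w") as fh:
        for s in library:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.identifier}\n")
            if s.precursor_mz is not None:
                fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.inchikey:
                fh.write(f"INCHIKEY={s.inchikey}\n")
            for mz, inten in zip(s.mz, s.intensities):
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n")


def write_msp(library: SpectrumLibrary, path) -> None:
    """Write a library as NIST-style MSP text."""
    if len(library) == 0:
        raise ValueError("refusing to write an empty library")
    with open(path, "w") as fh:
        for s in library:
            fh.write(f"Name: {s.identifier}\n")
            if s.precursor_mz is not None:
                fh.write(f"PrecursorMZ: {s.precursor_mz:.6f}\n")
            if s.inchikey:
                fh.write(f"InChIKey: {s.inchikey}\n")
            fh.write(f"Num Peaks: {len(s)}\n")
            for mz, inten in zip(s.mz, s.intensities):
                fh.write(f"{mz:.6f}\t{inten:.6f}\n")
            fh.write("\n")
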