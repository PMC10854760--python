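"""m/z occurrence frequency tables over a reference library.

The table records, per 0.1-Da m/z bin (configurable), the fraction of
spectra in a reference library that contain at least one peak in that
bin.  These relative frequencies are the f(m/z) factor of the
frequency-aware weighting scheme: peaks at commonly observed m/z values
are weighted up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectrumLibrary

__all__ = ["FrequencyTable", "build_frequency_table", "save_table", "load_table"]


def _bin_index(mz: float, resolution: float) -> int:
    # half-up rounding on an integer grid; immune to binary-decimal drift
    # of naive round(mz, 1)-style keys
    return int(np.floor(mz / resolution + 0.5))


@dataclass
class FrequencyTable:
    """Per-spectrum presence counts of binned m/z values.

    ``counts`` maps integer bin index (``round(mz / resolution)``) to the
    number of spectra containing at least one peak in that bin; a
    spectrum contributes at most 1 to any bin.
    """

    resolution: float
    counts: dict[int, int]
    n_spectra: int
    unseen_policy: str = "floor"   # floor | zero | one

    def __post_init__(self):
        if self.unseen_policy not in ("floor", "zero", "one"):
            raise ValueError(f"unknown unseen_policy {self.unseen_policy!r}")

    @property
    def floor(self) -> float:
        """Smallest nonzero relative frequency in the table."""
        return min(self.counts.values()) / self.n_spectra

    def bin_of(self, mz: float) -> float:
        return _bin_index(mz, self.resolution) * self.resolution

    def lookup(self, mz: float) -> float:
        """Relative frequency of the bin containing ``mz``.

        Bins never seen in the reference library return the table's
        minimum nonzero frequency under the default ``floor`` policy, so
        an unseen query peak is down-weighted rather than annihilated;
        ``zero`` and ``one`` policies are available for sensitivity
        analysis.
        """
        if mz <= 0:
            raise ValueError("m/z must be positive")
        idx = _bin_index(mz, self.resolution)
        if idx in self.counts:
            return self.counts[idx] / self.n_spectra
        if self.unseen_policy == "floor":
            return self.floor
        return 0.0 if self.unseen_policy == "zero" else 1.0

    def __eq__(self, other):
        return (
            isinstance(other, FrequencyTable)
            and np.isclose(self.resolution, other.resolution)
            and self.counts == other.counts
            and self.n_spectra == other.n_spectra
        )


def build_frequency_table(
    library: SpectrumLibrary,
    resolution: float = 0.1,
    unseen_policy: str = "floor",
) -> FrequencyTable:
    """Count, per m/z bin, the spectra containing at least one peak there."""
    if len(library) == 0:
        raise ValueError("cannot build a frequency table from an empty library")
    counts: dict[int, int] = {}
    for spectrum in library:
        bins = {_bin_index(mz, resolution) for mz in spectrum.mz}
        for b in bins:
            counts[b] = counts.get(b, 0) + 1
    return FrequencyTable(resolution, counts, len(library), unseen_policy)


def save_table(table: FrequencyTable, path) -> None:
    """Write the table as TSV with an ``# n_spectra=… resolution=…`` header."""
    with open(path, "w") as fh:
        fh.write(f"# n_spectra={table.n_spectra} resolution={table.resolution}\n")
        fh.write("mz_bin\tcount\trelative_frequency\n")
        for idx in sorted(table.counts):
            count = table.counts[idx]
            fh.write(f"{idx * table.resolution:.6g}\t{count}"
                     f"\t{count / table.n_spectra:.10g}\n")


def load_table(path, unseen_policy: str = "floor") -> FrequencyTable:
    """Load a table written by :func:`save_table` (its inverse)."""
    n_spectra = resolution = None
    counts: dict[int, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    key, _, value = token.partition("=")
                    if key == "n_spectra":
                        n_spectra = int(value)
                    elif key == "resolution":
                        resolution = float(value)
                continue
            if line.startswith("mz_bin"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected tab-separated columns")
            if resolution is None:
                raise ValueError(f"line {lineno}: data before the metadata line")
            try:
                mz_bin = float(parts[0])
                count = int(parts[1])
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric field in {line!r}")
            counts[_bin_index(mz_bin, resolution)] = count
    if n_spectra is None or resolution is None:
        raise ValueError("missing '# n_spectra=… resolution=…' metadata line")
    return FrequencyTable(resolution, counts, n_spectra, unseen_policy)
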