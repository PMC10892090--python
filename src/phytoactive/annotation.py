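"""Exact-mass compound annotation with MS/MS fragment validation.

A ranked molecular feature is annotated by converting its measured m/z to
a neutral monoisotopic mass ([M-H]- or [M+H]+ arithmetic) and querying a
compound library within a relative mass window (default 10 ppm, closed
interval).  Candidate annotations carrying reference fragments can be
validated against the feature's MS/MS spectrum at a wider fragment
tolerance (default 50 ppm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MsmsSpectrum
from .preprocess import parse_feature_id

__all__ = [
    "PROTON_MASS",
    "LibraryEntry",
    "CompoundLibrary",
    "AnnotationRecord",
    "neutral_mass",
    "ion_mz",
    "annotate",
    "validate_msms",
    "read_library",
    "write_library",
]

PROTON_MASS = 1.007276  # Da, [M+-H] adduct arithmetic


@dataclass(frozen=True)
class LibraryEntry:
    name: str
    neutral_mass: float  # monoisotopic, Da
    reference_fragments: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be positive")


@dataclass
class CompoundLibrary:
    entries: list[LibraryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("library entry names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> LibraryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass
class AnnotationRecord:
    feature_id: str
    compound_name: str
    ppm_error: float            # signed, observed vs library
    msms_validated: bool | None = None   # None = no reference fragments
    n_fragments_matched: int = 0


def neutral_mass(mz: float, ion_mode: str) -> float:
    """Neutral monoisotopic mass from a singly charged [M+-H] ion m/z."""
    if ion_mode == "NEG":
        return mz + PROTON_MASS
    if ion_mode == "POS":
        if mz <= PROTON_MASS:
            raise ValueError("m/z must exceed the proton mass in POS mode")
        return mz - PROTON_MASS
    raise ValueError(f"unsupported ion mode {ion_mode!r}")


def ion_mz(neutral: float, ion_mode: str) -> float:
    """Inverse of :func:`neutral_mass`."""
    if ion_mode == "NEG":
        return neutral - PROTON_MASS
    if ion_mode == "POS":
        return neutral + PROTON_MASS
    raise ValueError(f"unsupported ion mode {ion_mode!r}")


def annotate(
    fid: str, ion_mode: str, library: CompoundLibrary, ppm: float = 10.0
) -> list[AnnotationRecord]:
    """All library entries within ``ppm`` (closed window) of the feature's
    neutral mass, sorted by |ppm error| then name; empty list means "N/A"."""
    _, mz = parse_feature_id(fid)
    observed = neutral_mass(mz, ion_mode)
    records = []
    for e in library.entries:
        err = 1e6 * (observed - e.neutral_mass) / e.neutral_mass
        if abs(err) <= ppm:
            records.append(AnnotationRecord(fid, e.name, float(err)))
    records.sort(key=lambda r: (abs(r.ppm_error), r.compound_name))
    return records


def validate_msms(
    spectrum: MsmsSpectrum,
    entry: LibraryEntry,
    ppm: float = 50.0,
    min_fragments: int = 3,
) -> tuple[bool | None, int]:
    """Count reference fragments matched by any observed fragment within
    ``ppm`` (relative); validated iff >= ``min_fragments`` match.  Entries
    without reference fragments return (None, 0): indeterminate."""
    if not entry.reference_fragments:
        return None, 0
    observed = spectrum.mz_array
    n = 0
    for ref in entry.reference_fragments:
        tol = ref * ppm * 1e-6
        if np.any(np.abs(observed - ref) <= tol):
            n += 1
    return n >= min_fragments, n


def read_library(path) -> CompoundLibrary:
    """CSV columns: name, neutral_mass, fragments ("mz;mz;..." or empty)."""
    df = pd.read_csv(path)
    entries = []
    for _, row in df.iterrows():
        frags: tuple[float, ...] = ()
        if "fragments" in df.columns and isinstance(row["fragments"], str) and row["fragments"]:
            frags = tuple(float(x) for x in row["fragments"].split(";"))
        entries.append(LibraryEntry(str(row["name"]), float(row["neutral_mass"]), frags))
    return CompoundLibrary(entries)


def write_library(library: CompoundLibrary, path) -> None:
    pd.DataFrame(
        {
            "name": [e.name for e in library.entries],
            "neutral_mass": [f"{e.neutral_mass:.6f}" for e in library.entries],
            "fragments": [
                ";".join(f"{m:.4f}" for m in e.reference_fragments)
                for e in library.entries
            ],
        }
    ).to_csv(path, index=False)
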