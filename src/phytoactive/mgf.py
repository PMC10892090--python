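"""Minimal Mascot Generic Format (MGF) reader/writer for MS/MS spectra.

Handles the BEGIN IONS/END IONS blocks with TITLE, PEPMASS, CHARGE,
RTINSECONDS and IONMODE headers — everything the networking and annotation
stages need.  Fragment lines are ``mz intensity`` pairs.
"""

from __future__ import annotations

from .network import MsmsSpectrum

__all__ = ["read_mgf", "write_mgf"]


def read_mgf(path) -> list[MsmsSpectrum]:
    spectra: list[MsmsSpectrum] = []
    in_block = False
    meta: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block, meta, peaks = True, {}, []
            elif line == "END IONS":
                if "PEPMASS" not in meta:
                    raise ValueError(f"spectrum block without PEPMASS in {path}")
                charge = meta.get("CHARGE", "")
                ion_mode = meta.get("IONMODE")
                if ion_mode is None:
                    ion_mode = "NEG" if charge.endswith("-") else "POS"
                rt = float(meta["RTINSECONDS"]) / 60.0 if "RTINSECONDS" in meta else None
                spectra.append(
                    MsmsSpectrum(
                        spectrum_id=meta.get("TITLE", f"scan_{len(spectra) + 1}"),
                        precursor_mz=float(meta["PEPMASS"].split()[0]),
                        ion_mode=ion_mode,
                        retention_min=rt,
                        fragments=peaks,
                    )
                )
                in_block = False
            elif in_block:
                if "=" in line:
                    key, _, val = line.partition("=")
                    meta[key.upper()] = val
                else:
                    parts = line.split()
                    peaks.append((float(parts[0]), float(parts[1])))
    return spectra


def write_mgf(spectra: list[MsmsSpectrum], path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.4f}\n")
            fh.write(f"CHARGE=1{'-' if s.ion_mode == 'NEG' else '+'}\n")
            fh.write(f"IONMODE={s.ion_mode}\n")
            if s.retention_min is not None:
                fh.write(f"RTINSECONDS={s.retention_min * 60.0:.2f}\n")
            for mz, inten in s.fragments:
                fh.write(f"{mz:.4f} {inten:.4f}\n")
            fh.write("END IONS\n")
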