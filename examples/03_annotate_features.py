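"""Annotate ranked features against a compound library by exact mass.

A feature's m/z (from its "RT_mz" id) is converted to a neutral
monoisotopic mass via [M-H]-/[M+H]+ arithmetic and matched against
library entries within 10 ppm; candidate hits with reference fragments
are validated against an MS/MS spectrum at 50 ppm.
"""

from phytoactive import (
    SyntheticConfig,
    annotate,
    generate_library,
    validate_msms,
)
from phytoactive.network import MsmsSpectrum

library = generate_library(SyntheticConfig(seed=0))

for fid in ("1.41_353.0874", "1.79_515.1191", "1.62_257.0554"):
    records = annotate(fid, "NEG", library, ppm=10.0)
    if records:
        r = records[0]
        print(f"{fid}: {r.compound_name} ({r.ppm_error:+.2f} ppm)")
    else:
        print(f"{fid}: N/A (no library mass within 10 ppm)")

# fragment-level validation of the di-CQA assignment
entry = library.get("di-CQA")
spectrum = MsmsSpectrum(
    "dicqa_msms",
    precursor_mz=515.1191,
    ion_mode="NEG",
    fragments=[(353.0871, 0.8), (191.0563, 1.0), (179.0351, 0.6), (135.0441, 0.2)],
)
flag, n = validate_msms(spectrum, entry, ppm=50.0, min_fragments=3)
print(f"\ndi-CQA MS/MS validation: matched {n} reference fragments -> {flag}")
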