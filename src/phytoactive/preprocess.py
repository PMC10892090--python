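"""Feature-table I/O, adduct/isotopologue collapsing and variable transforms.

The central objects are :class:`FeatureMatrix` (fractions x molecular
features, one per ionization mode) and :class:`BioactivityVector`
(% cell viability per fraction).  Molecular features are named by their
``"RT_mz"`` string — retention time in minutes to two decimals, m/z to
four decimals — which doubles as the carrier of the feature's mass.

Because flow-injection profiling records every adduct and isotopologue of
a compound as a separate feature, :func:`deconvolute` collapses satellite
features (fixed mass offset, co-eluting, near-perfectly correlated across
fractions) back onto their parent before any modelling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureMatrix",
    "BioactivityVector",
    "AdductRule",
    "DEFAULT_ADDUCT_RULES",
    "feature_id",
    "parse_feature_id",
    "read_feature_table",
    "write_feature_table",
    "read_viability_table",
    "write_viability_table",
    "deconvolute",
    "log_transform",
    "log_transform_response",
    "pearson_feature_viability",
    "total_intensity_normalize",
]

_FEATURE_ID_RE = re.compile(r"^\d+(\.\d+)?_\d+(\.\d+)?$")


def feature_id(rt: float, mz: float) -> str:
    """Format an ``"RT_mz"`` feature identifier (RT 2 dp, m/z 4 dp)."""
    return f"{rt:.2f}_{mz:.4f}"


def parse_feature_id(fid: str) -> tuple[float, float]:
    """Return ``(retention_min, mz)`` parsed from an ``"RT_mz"`` string."""
    if not _FEATURE_ID_RE.match(fid):
        raise ValueError(f"feature id {fid!r} does not match the 'RT_mz' pattern")
    rt_s, mz_s = fid.split("_")
    return float(rt_s), float(mz_s)


@dataclass
class FeatureMatrix:
    """Fractions x molecular-features intensity table for one ion mode.

    Parameters
    ----------
    intensities
        DataFrame with fraction labels as the index and ``"RT_mz"`` feature
        ids as columns.  Raw intensities must be non-negative; a matrix
        carrying log-transformed values sets ``transformed=True`` which
        lifts that check.
    ion_mode
        ``"POS"`` or ``"NEG"``.  Kept separate end to end; models are never
        fitted on a mixed-mode matrix.
    """

    intensities: pd.DataFrame
    ion_mode: str = "NEG"
    transformed: bool = False

    def __post_init__(self) -> None:
        if self.ion_mode not in ("POS", "NEG"):
            raise ValueError(f"ion_mode must be 'POS' or 'NEG', got {self.ion_mode!r}")
        cols = list(self.intensities.columns)
        seen: set[str] = set()
        for c in cols:
            if c in seen:
                raise ValueError(f"duplicate feature id {c!r}")
            seen.add(c)
            parse_feature_id(str(c))
        if not self.transformed:
            vals = self.intensities.to_numpy(dtype=float)
            if vals.size and np.any(vals < 0):
                i, j = np.argwhere(vals < 0)[0]
                raise ValueError(
                    "negative intensity at fraction "
                    f"{self.intensities.index[i]!r}, feature {cols[j]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return [str(c) for c in self.intensities.columns]

    @property
    def fraction_ids(self) -> list[str]:
        return [str(i) for i in self.intensities.index]

    @property
    def n_fractions(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def retention_min(self) -> np.ndarray:
        return np.array([parse_feature_id(f)[0] for f in self.feature_ids])

    @property
    def mz(self) -> np.ndarray:
        return np.array([parse_feature_id(f)[1] for f in self.feature_ids])

    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)


@dataclass
class BioactivityVector:
    """Per-fraction % viability with replicate standard error."""

    fraction_ids: list[str]
    viability_pct: np.ndarray
    se_pct: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.viability_pct = np.asarray(self.viability_pct, dtype=float)
        if np.any(self.viability_pct < 0):
            raise ValueError("viability_pct must be non-negative")
        if len(self.fraction_ids) != self.viability_pct.shape[0]:
            raise ValueError("fraction_ids and viability_pct length mismatch")
        if self.se_pct is None:
            self.se_pct = np.zeros_like(self.viability_pct)
        else:
            self.se_pct = np.asarray(self.se_pct, dtype=float)

    def aligned_to(self, matrix: FeatureMatrix) -> "BioactivityVector":
        """Return a copy ordered like ``matrix.fraction_ids`` (must match as sets)."""
        if set(self.fraction_ids) != set(matrix.fraction_ids):
            raise ValueError("fraction_ids do not match the feature matrix")
        order = [self.fraction_ids.index(f) for f in matrix.fraction_ids]
        return BioactivityVector(
            fraction_ids=list(matrix.fraction_ids),
            viability_pct=self.viability_pct[order],
            se_pct=self.se_pct[order],
            n_replicates=self.n_replicates,
        )


@dataclass(frozen=True)
class AdductRule:
    """One satellite relationship: parent m/z + ``mass_offset`` = satellite m/z."""

    name: str
    mass_offset: float
    max_rt_diff: float = 0.2
    min_profile_correlation: float = 0.9

    def __post_init__(self) -> None:
        if self.mass_offset == 0:
            raise ValueError("mass_offset must be nonzero")
        if not -1.0 <= self.min_profile_correlation <= 1.0:
            raise ValueError("min_profile_correlation must lie in [-1, 1]")


#: [M+Na-H] sodium exchange and the M+1 carbon isotopologue — the two
#: satellite types the flow-injection profiles carry most prominently.
DEFAULT_ADDUCT_RULES: tuple[AdductRule, ...] = (
    AdductRule("Na-H", 21.9819),
    AdductRule("13C isotope", 1.0034),
)


# ---------------------------------------------------------------------------
# I/O: comma-separated tables, features as rows labelled "RT_mz"
# ---------------------------------------------------------------------------

def read_feature_table(path, ion_mode: str = "NEG") -> FeatureMatrix:
    """Read a features-as-rows CSV (header = fraction labels) into a matrix."""
    df = pd.read_csv(path, index_col=0)
    ids = [str(i) for i in df.index]
    seen: set[str] = set()
    for fid in ids:
        if fid in seen:
            raise ValueError(f"duplicate feature id {fid!r} in {path}")
        seen.add(fid)
        parse_feature_id(fid)
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0):
        i, j = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative intensity in {path} at feature {ids[i]!r}, "
            f"fraction {df.columns[j]!r}"
        )
    wide = df.T
    wide.columns = ids
    wide.index = [str(c) for c in df.columns]
    return FeatureMatrix(intensities=wide.astype(float), ion_mode=ion_mode)


def write_feature_table(matrix: FeatureMatrix, path) -> None:
    """Write the matrix as a features-as-rows CSV (round-trips with the reader)."""
    out = matrix.intensities.T
    out.index.name = "feature_id"
    out.to_csv(path)


def read_viability_table(path) -> BioactivityVector:
    df = pd.read_csv(path)
    return BioactivityVector(
        fraction_ids=[str(f) for f in df["fraction"]],
        viability_pct=df["viability_pct"].to_numpy(dtype=float),
        se_pct=df["se_pct"].to_numpy(dtype=float) if "se_pct" in df else None,
        n_replicates=int(df["n"].iloc[0]) if "n" in df else 1,
    )


def write_viability_table(viability: BioactivityVector, path) -> None:
    pd.DataFrame(
        {
            "fraction": viability.fraction_ids,
            "viability_pct": viability.viability_pct,
            "se_pct": viability.se_pct,
            "n": viability.n_replicates,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Adduct/isotopologue deconvolution
# ---------------------------------------------------------------------------

def deconvolute(
    matrix: FeatureMatrix,
    rules: tuple[AdductRule, ...] = DEFAULT_ADDUCT_RULES,
    mz_tol: float = 0.01,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Collapse satellite features onto their parents.

    Two features are grouped when some rule's mass offset relates their m/z
    within ``mz_tol``, their retention times agree within the rule's window,
    and their cross-fraction intensity profiles correlate at or above the
    rule's Pearson threshold.  Groups are closed transitively (a parent, its
    sodium adduct and its isotopologue all merge).  The merged feature keeps
    the id of the lowest-m/z member — the un-offset parent — and its
    intensity is the sum over the group, so total matrix intensity is
    conserved exactly.

    Returns the reduced matrix and a report with one row per merge group.
    """
    X = matrix.values()
    mz = matrix.mz
    rt = matrix.retention_min
    n = matrix.n_features
    order = np.argsort(mz, kind="stable")

    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # profile correlation on mean-centred columns
    Xc = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Xc, axis=0)

    pair_rules: dict[tuple[int, int], str] = {}
    mz_sorted = mz[order]
    for rule in rules:
        for a_pos, i in enumerate(order):
            target = mz[i] + rule.mass_offset
            lo = np.searchsorted(mz_sorted, target - mz_tol)
            hi = np.searchsorted(mz_sorted, target + mz_tol)
            for b_pos in range(lo, hi):
                j = order[b_pos]
                if j == i or abs(rt[i] - rt[j]) > rule.max_rt_diff:
                    continue
                if norms[i] == 0 or norms[j] == 0:
                    continue
                r = float(Xc[:, i] @ Xc[:, j] / (norms[i] * norms[j]))
                if r >= rule.min_profile_correlation:
                    union(i, j)
                    pair_rules[(min(i, j), max(i, j))] = rule.name

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    keep_ids: list[str] = []
    cols: list[np.ndarray] = []
    report_rows = []
    fids = matrix.feature_ids
    for root in sorted(groups, key=lambda r: fids.index(fids[r])):
        members = groups[root]
        rep = members[int(np.argmin(mz[members]))]
        keep_ids.append(fids[rep])
        cols.append(X[:, members].sum(axis=1))
        if len(members) > 1:
            rule_names = sorted(
                {v for k, v in pair_rules.items() if k[0] in members or k[1] in members}
            )
            report_rows.append(
                {
                    "representative": fids[rep],
                    "members": ";".join(fids[m] for m in sorted(members)),
                    "n_members": len(members),
                    "rules": ";".join(rule_names),
                }
            )

    merged = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((matrix.n_fractions, 0)),
        index=matrix.intensities.index,
        columns=keep_ids,
    )
    report = pd.DataFrame(
        report_rows, columns=["representative", "members", "n_members", "rules"]
    )
    return FeatureMatrix(merged, ion_mode=matrix.ion_mode), report


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log_transform(
    matrix: FeatureMatrix, pseudocount: float | str = "half-min"
) -> FeatureMatrix:
    """Natural-log transform ``x -> ln(x + delta)``.

    ``delta`` defaults to half the smallest nonzero intensity of the matrix
    ("half-min" policy), which keeps zeros finite on a scale adapted to the
    data; pass a number for a fixed pseudo-count instead.
    """
    X = matrix.values()
    if pseudocount == "half-min":
        nonzero = X[X > 0]
        if nonzero.size == 0:
            raise ValueError("cannot log-transform an all-zero matrix")
        delta = float(nonzero.min()) / 2.0
    else:
        delta = float(pseudocount)
        if np.any(X + delta <= 0):
            raise ValueError("pseudocount too small: ln of non-positive value")
    out = pd.DataFrame(
        np.log(X + delta), index=matrix.intensities.index, columns=matrix.feature_ids
    )
    return FeatureMatrix(out, ion_mode=matrix.ion_mode, transformed=True)


def log_transform_response(
    viability: BioactivityVector, floor_pct: float = 1.0
) -> np.ndarray:
    """ln of % viability, floored at ``floor_pct`` so dead-cell wells stay finite."""
    v = np.maximum(viability.viability_pct, floor_pct)
    return np.log(v)


def pearson_feature_viability(
    matrix: FeatureMatrix, viability: BioactivityVector, fid: str
) -> float:
    """Pearson r between one feature's intensity and % viability across fractions."""
    if fid not in matrix.feature_ids:
        raise KeyError(f"feature {fid!r} not in matrix")
    if matrix.n_fractions < 3:
        raise ValueError("need at least 3 fractions for a correlation")
    v = viability.aligned_to(matrix)
    x = matrix.intensities[fid].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError(f"feature {fid!r} has zero variance; correlation undefined")
    if np.std(v.viability_pct) == 0:
        raise ValueError("viability has zero variance; correlation undefined")
    r, _ = stats.pearsonr(x, v.viability_pct)
    return float(r)


def total_intensity_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Scale each fraction to the mean total ion intensity (optional, off by default
    in the pipeline: fractions genuinely differ in load)."""
    X = matrix.values()
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("cannot normalize: a fraction has zero total intensity")
    scaled = X * (totals.mean() / totals)[:, None]
    out = pd.DataFrame(
        scaled, index=matrix.intensities.index, columns=matrix.feature_ids
    )
    return FeatureMatrix(out, ion_mode=matrix.ion_mode)
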