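"""Molecular networking of MS/MS spectra.

Spectra become nodes; an edge joins two spectra when their (modified)
cosine similarity reaches the cutoff (default 0.70) with at least the
minimum number of matched fragment peaks (default 6).  Connected
components of the resulting graph approximate families of structurally
related compounds; components with >= 3 nodes are reported as clusters.
Per-node bioactivity mapping attaches, for every fraction that contains
the node's molecular feature, a pie-slice weight proportional to the
feature's intensity there together with the fraction's viability bin.

The modified cosine (default) additionally pairs fragment peaks offset by
the two precursors' mass difference, so that spectra of analogues sharing
a neutral-loss series still score highly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .preprocess import BioactivityVector, FeatureMatrix

__all__ = [
    "MsmsSpectrum",
    "NetworkParams",
    "SpectralNetwork",
    "cosine_score",
    "merge_identical",
    "build_network",
    "map_bioactivity",
    "export_graphml",
    "read_graphml",
]


@dataclass
class MsmsSpectrum:
    """One MS/MS spectrum: precursor plus a fragment peak list sorted by m/z."""

    spectrum_id: str
    precursor_mz: float
    ion_mode: str = "NEG"
    retention_min: float | None = None
    fragments: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if not self.fragments:
            raise ValueError("fragment list must be non-empty")
        if any(i < 0 for _, i in self.fragments):
            raise ValueError("fragment intensities must be non-negative")
        self.fragments = sorted((float(m), float(i)) for m, i in self.fragments)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.fragments])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.fragments])


@dataclass(frozen=True)
class NetworkParams:
    precursor_tol: float = 0.01     # Da
    fragment_tol: float = 0.05      # Da
    cosine_cutoff: float = 0.70
    min_matched_peaks: int = 6
    min_cluster_size: int = 3
    use_modified_cosine: bool = True
    exact_matching: bool = False    # optimal assignment instead of greedy

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 <= self.cosine_cutoff <= 1:
            raise ValueError("cosine_cutoff must lie in [0, 1]")


def _candidate_pairs(
    a: MsmsSpectrum, b: MsmsSpectrum, params: NetworkParams
) -> list[tuple[int, int]]:
    mza, mzb = a.mz_array, b.mz_array
    shifts = [0.0]
    if params.use_modified_cosine:
        shifts.append(a.precursor_mz - b.precursor_mz)
    pairs: set[tuple[int, int]] = set()
    for shift in shifts:
        # peak i of a matches peak j of b when mza_i ~ mzb_j + shift
        target = mzb + shift
        order = np.argsort(target)
        ts = target[order]
        for i, m in enumerate(mza):
            lo = np.searchsorted(ts, m - params.fragment_tol)
            hi = np.searchsorted(ts, m + params.fragment_tol)
            for k in range(lo, hi):
                pairs.add((i, int(order[k])))
    return sorted(pairs)


def cosine_score(
    a: MsmsSpectrum, b: MsmsSpectrum, params: NetworkParams = NetworkParams()
) -> tuple[float, int]:
    """(Modified) cosine similarity between two spectra.

    Intensities are L2-normalized per spectrum; candidate peak pairs (within
    the fragment tolerance, directly or precursor-shifted) are matched
    greedily by descending intensity product with each peak used at most
    once, or by optimal assignment when ``params.exact_matching``.  Returns
    the score in [0, 1] and the number of matched peak pairs.  Symmetric in
    its arguments; identical spectra score exactly 1, spectra with no
    pairable peaks exactly 0.
    """
    pairs = _candidate_pairs(a, b, params)
    if not pairs:
        return 0.0, 0
    ia = a.intensity_array
    ib = b.intensity_array
    # norms via exactly rounded sums so that identical spectra score 1.0
    # bit-exactly: the matched-product list then equals the norm-square list
    na2 = math.fsum(float(x) * float(x) for x in ia)
    nb2 = math.fsum(float(x) * float(x) for x in ib)
    if na2 == 0 or nb2 == 0:
        return 0.0, 0
    denom = math.sqrt(na2 * nb2)

    if params.exact_matching:
        profit = np.zeros((len(a.fragments), len(b.fragments)))
        for i, j in pairs:
            profit[i, j] = ia[i] * ib[j]
        ri, cj = linear_sum_assignment(-profit)
        chosen = [(i, j) for i, j in zip(ri, cj) if profit[i, j] > 0]
    else:
        ranked = sorted(pairs, key=lambda ij: (-ia[ij[0]] * ib[ij[1]], ij))
        used_a: set[int] = set()
        used_b: set[int] = set()
        chosen = []
        for i, j in ranked:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            chosen.append((i, j))
    dot = math.fsum(float(ia[i]) * float(ib[j]) for i, j in chosen)
    return float(min(dot / denom, 1.0)), len(chosen)


def merge_identical(
    spectra: list[MsmsSpectrum],
    merge_cosine: float = 0.95,
    params: NetworkParams = NetworkParams(),
) -> list[MsmsSpectrum]:
    """Greedy single-pass merge of (near-)identical spectra into consensus nodes.

    A spectrum joins an existing consensus when their precursors agree
    within the precursor tolerance and their cosine reaches
    ``merge_cosine``; merged fragments within the fragment tolerance are
    combined into intensity-weighted mean m/z with summed intensity.
    Stand-in for full MS/MS clustering: adequate for collapsing repeat
    acquisitions of the same compound, not for deep consensus building.
    """
    consensus: list[MsmsSpectrum] = []
    counts: list[int] = []
    for s in spectra:
        merged = False
        for k, c in enumerate(consensus):
            if abs(s.precursor_mz - c.precursor_mz) > params.precursor_tol:
                continue
            score, _ = cosine_score(s, c, params)
            if score >= merge_cosine:
                consensus[k] = _combine(c, s, params.fragment_tol, counts[k])
                counts[k] += 1
                merged = True
                break
        if not merged:
            consensus.append(s)
            counts.append(1)
    return consensus


def _combine(
    c: MsmsSpectrum, s: MsmsSpectrum, fragment_tol: float, c_weight: int
) -> MsmsSpectrum:
    frags = sorted(list(c.fragments) + list(s.fragments))
    out: list[tuple[float, float]] = []
    cur_mz: list[float] = []
    cur_int: list[float] = []
    for m, i in frags:
        if cur_mz and m - cur_mz[-1] > fragment_tol:
            w = np.array(cur_int)
            out.append((float(np.average(cur_mz, weights=np.maximum(w, 1e-12))), float(w.sum())))
            cur_mz, cur_int = [], []
        cur_mz.append(m)
        cur_int.append(i)
    if cur_mz:
        w = np.array(cur_int)
        out.append((float(np.average(cur_mz, weights=np.maximum(w, 1e-12))), float(w.sum())))
    prec = (c.precursor_mz * c_weight + s.precursor_mz) / (c_weight + 1)
    return MsmsSpectrum(
        spectrum_id=c.spectrum_id,
        precursor_mz=prec,
        ion_mode=c.ion_mode,
        retention_min=c.retention_min,
        fragments=out,
    )


@dataclass
class SpectralNetwork:
    """Graph over consensus spectra with cosine-scored edges."""

    graph: nx.Graph
    params: NetworkParams = field(default_factory=NetworkParams)

    @property
    def components(self) -> list[list[str]]:
        comps = [sorted(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), c))

    @property
    def clusters(self) -> list[list[str]]:
        """Components with at least ``min_cluster_size`` nodes."""
        return [c for c in self.components if len(c) >= self.params.min_cluster_size]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    spectra: list[MsmsSpectrum], params: NetworkParams = NetworkParams()
) -> SpectralNetwork:
    """All-pairs cosine scoring; edges kept iff score >= cutoff and enough
    matched peaks.  Deterministic for a given spectrum list."""
    g = nx.Graph()
    for s in spectra:
        g.add_node(
            s.spectrum_id,
            precursor_mz=float(s.precursor_mz),
            ion_mode=s.ion_mode,
            retention_min=float(s.retention_min) if s.retention_min is not None else -1.0,
        )
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            score, n_matched = cosine_score(spectra[i], spectra[j], params)
            if score >= params.cosine_cutoff and n_matched >= params.min_matched_peaks:
                g.add_edge(
                    spectra[i].spectrum_id,
                    spectra[j].spectrum_id,
                    cosine=float(score),
                    n_matched=int(n_matched),
                )
    return SpectralNetwork(graph=g, params=params)


DEFAULT_VIABILITY_BINS: tuple[tuple[float, str], ...] = (
    (100.0, "full"),     # >= 100%: complete protection
    (50.0, "partial"),   # 50-100%: partial protection
    (0.0, "low"),        # < 50%
)


def viability_bin(
    pct: float, bins: tuple[tuple[float, str], ...] = DEFAULT_VIABILITY_BINS
) -> str:
    for threshold, label in bins:
        if pct >= threshold:
            return label
    return bins[-1][1]


def map_bioactivity(
    network: SpectralNetwork,
    matrix: FeatureMatrix,
    viability: BioactivityVector,
    bins: tuple[tuple[float, str], ...] = DEFAULT_VIABILITY_BINS,
    rt_tol: float = 0.2,
) -> SpectralNetwork:
    """Attach per-fraction abundance pie slices and viability bins to nodes.

    A node is mapped to the feature whose m/z lies within the precursor
    tolerance (closest wins; retention time must also agree within
    ``rt_tol`` when both sides carry one).  Slice weights over the
    fractions containing the feature sum to 1.  Unmatched nodes are tagged
    ``unmapped`` rather than rejected.
    """
    v = viability.aligned_to(matrix)
    mz = matrix.mz
    rts = matrix.retention_min
    fids = matrix.feature_ids
    for node, attrs in network.graph.nodes(data=True):
        pmz = attrs["precursor_mz"]
        nrt = attrs.get("retention_min", -1.0)
        dm = np.abs(mz - pmz)
        cand = np.where(dm <= network.params.precursor_tol)[0]
        if nrt is not None and nrt >= 0:
            cand = cand[np.abs(rts[cand] - nrt) <= rt_tol]
        if cand.size == 0:
            attrs["unmapped"] = True
            continue
        j = cand[np.argmin(dm[cand])]
        attrs["unmapped"] = False
        attrs["feature_id"] = fids[j]
        x = matrix.intensities[fids[j]].to_numpy(dtype=float)
        present = x > 0
        total = x[present].sum()
        slices = {}
        bin_weights: dict[str, float] = {}
        for i in np.where(present)[0]:
            frac = matrix.fraction_ids[i]
            w = float(x[i] / total)
            vb = viability_bin(float(v.viability_pct[i]), bins)
            slices[frac] = {"weight": w, "viability_pct": float(v.viability_pct[i]), "bin": vb}
            bin_weights[vb] = bin_weights.get(vb, 0.0) + w
        attrs["slices"] = json.dumps(slices, sort_keys=True)
        attrs["bin_weights"] = json.dumps(bin_weights, sort_keys=True)
    return network


def export_graphml(network: SpectralNetwork, path) -> None:
    """Write GraphML (Cytoscape-importable); dict attributes are JSON strings."""
    g = network.graph.copy()
    for _, attrs in g.nodes(data=True):
        for k, val in list(attrs.items()):
            if val is None:
                attrs[k] = ""
    nx.write_graphml(g, path)


def read_graphml(path, params: NetworkParams = NetworkParams()) -> SpectralNetwork:
    g = nx.read_graphml(path)
    return SpectralNetwork(graph=nx.Graph(g), params=params)
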